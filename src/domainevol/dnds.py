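"""Nei-Gojobori synonymous/non-synonymous substitution analysis.

The counting estimator of dN/dS: each codon contributes fractional
potentially-synonymous sites ``s`` (the fraction of its nine
single-nucleotide neighbours that preserve the amino acid) with
``s + n = 3``; observed differences between two codons are averaged over
the minimal mutational pathways connecting them, pathways through stop
codons excluded.  Proportions ``pS = Sd/S`` and ``pN = Nd/N`` are
converted to distances with the Jukes-Cantor multiple-hit correction
``d = -(3/4) ln(1 - (4/3) p)``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple, Optional, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .conservation import DomainPartition
from .seqio import Alignment

logger = logging.getLogger(__name__)

BASES = "TCAG"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
#: the 61 sense codons of the standard genetic code, lexicographic in TCAG
SENSE_CODONS = tuple(
    sorted(standard_dna_table.forward_table, key=lambda c: [BASES.index(b) for b in c])
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACID = dict(standard_dna_table.forward_table)


class DnDsError(ValueError):
    pass


class SaturationError(DnDsError):
    """Observed proportion of differences at or beyond the JC domain."""

    def __init__(self, p: float):
        self.p = p
        super().__init__(f"proportion {p} >= 3/4: Jukes-Cantor correction undefined")


class CodonSiteCounts(NamedTuple):
    s: float  # potentially synonymous sites
    n: float  # potentially nonsynonymous sites (s + n = 3)


def _check_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise DnDsError(f"not an unambiguous codon: {codon!r}")
    if codon in STOP_CODONS:
        raise DnDsError(f"stop codon {codon!r} not allowed")
    return codon


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> CodonSiteCounts:
    """Fractional synonymous/nonsynonymous site counts of a sense codon.

    Per position, the fraction of the three single-nucleotide changes
    that preserve the amino acid; changes producing stop codons count as
    nonsynonymous.
    """
    codon = _check_codon(codon)
    aa = AMINO_ACID[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant not in STOP_CODONS and AMINO_ACID[mutant] == aa:
                syn += 1
        s += syn / 3.0
    return CodonSiteCounts(s, 3.0 - s)


class PathwayDiffs(NamedTuple):
    sd: float
    nd: float


def _path_steps(a: str, b: str, order: Sequence[int]) -> Optional[tuple[float, float]]:
    """(syn, nonsyn) steps along one mutational pathway, or None if it
    passes through a stop codon."""
    sd = nd = 0.0
    current = a
    for pos in order:
        nxt = current[:pos] + b[pos] + current[pos + 1 :]
        if nxt in STOP_CODONS and nxt != b:
            return None
        if nxt in STOP_CODONS or current in STOP_CODONS:
            nd += 1  # only reachable in the logged fallback
        elif AMINO_ACID[current] == AMINO_ACID[nxt]:
            sd += 1
        else:
            nd += 1
        current = nxt
    return sd, nd


def _path_steps_with_stops(a: str, b: str, order: Sequence[int]) -> tuple[float, float]:
    sd = nd = 0.0
    current = a
    for pos in order:
        nxt = current[:pos] + b[pos] + current[pos + 1 :]
        if current in STOP_CODONS or nxt in STOP_CODONS:
            nd += 1
        elif AMINO_ACID[current] == AMINO_ACID[nxt]:
            sd += 1
        else:
            nd += 1
        current = nxt
    return sd, nd


@lru_cache(maxsize=None)
def pairwise_codon_diffs(a: str, b: str) -> PathwayDiffs:
    """Pathway-averaged synonymous/nonsynonymous differences of two codons.

    All orderings of the differing positions are enumerated; pathways
    passing through a stop codon are excluded and the remaining pathways
    averaged with equal weight.  If every pathway hits a stop, all
    pathways are used with stop-involving steps counted nonsynonymous
    (logged).
    """
    a, b = _check_codon(a), _check_codon(b)
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return PathwayDiffs(0.0, 0.0)
    valid = []
    for order in itertools.permutations(diff):
        steps = _path_steps(a, b, order)
        if steps is not None:
            valid.append(steps)
    if not valid:
        logger.info(
            "all pathways %s->%s pass through stops; counting stop steps "
            "as nonsynonymous",
            a,
            b,
        )
        valid = [
            _path_steps_with_stops(a, b, order)
            for order in itertools.permutations(diff)
        ]
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return PathwayDiffs(sd, nd)


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction ``d = -(3/4) ln(1 - (4/3) p)``."""
    if p < 0:
        raise DnDsError(f"negative proportion {p}")
    if p >= 0.75:
        raise SaturationError(p)
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


@dataclass
class DnDsResult:
    """Counts, proportions and corrected distances for one comparison.

    ``dS``/``dN`` are NaN with the corresponding ``*_saturated`` flag when
    the proportion reaches the Jukes-Cantor domain boundary.  Ratios are
    ``None`` (``*_defined = False``) when their denominator is zero.
    """

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    dS_saturated: bool = False
    dN_saturated: bool = False
    n_codons: int = 0

    @property
    def ratio_dN_dS(self) -> Optional[float]:
        if not self.dS or math.isnan(self.dS) or math.isnan(self.dN):
            return None
        return self.dN / self.dS

    @property
    def ratio_dS_dN(self) -> Optional[float]:
        if not self.dN or math.isnan(self.dN) or math.isnan(self.dS):
            return None
        return self.dS / self.dN

    def as_dict(self) -> dict:
        return {
            "S": self.S, "N": self.N, "Sd": self.Sd, "Nd": self.Nd,
            "pS": self.pS, "pN": self.pN, "dS": self.dS, "dN": self.dN,
            "dN_dS": self.ratio_dN_dS, "dS_dN": self.ratio_dS_dN,
            "dS_saturated": self.dS_saturated,
            "dN_saturated": self.dN_saturated,
            "n_codons": self.n_codons,
        }


def _result_from_counts(
    S: float, N: float, Sd: float, Nd: float, n_codons: int
) -> DnDsResult:
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = dN = float("nan")
    sat_s = sat_n = False
    try:
        dS = jukes_cantor(pS)
    except SaturationError:
        sat_s = True
    try:
        dN = jukes_cantor(pN)
    except SaturationError:
        sat_n = True
    return DnDsResult(S, N, Sd, Nd, pS, pN, dS, dN, sat_s, sat_n, n_codons)


def _split_codons(cds: str, label: str = "") -> list[str]:
    if len(cds) % 3:
        raise DnDsError(f"CDS length {len(cds)} not divisible by 3 {label}")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def _pair_codon_columns(cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    """Codon-wise complete deletion: a codon column is dropped when either
    sequence has a gap or ambiguous base anywhere in it."""
    ca, cb = _split_codons(cds_a, "(A)"), _split_codons(cds_b, "(B)")
    if len(ca) != len(cb):
        raise DnDsError("sequences differ in codon count")
    keep = []
    for x, y in zip(ca, cb):
        if any(ch not in BASES for ch in x + y):
            continue
        if x in STOP_CODONS or y in STOP_CODONS:
            raise DnDsError(f"internal stop codon in pair ({x}, {y})")
        keep.append((x, y))
    return keep


def pair_counts(cds_a: str, cds_b: str) -> tuple[float, float, float, float, int]:
    """(S, N, Sd, Nd, codons used) for one sequence pair."""
    pairs = _pair_codon_columns(cds_a, cds_b)
    if not pairs:
        raise DnDsError("no complete codon columns shared by the pair")
    sa = sum(codon_sites(x).s for x, _ in pairs)
    sb = sum(codon_sites(y).s for _, y in pairs)
    S = (sa + sb) / 2.0
    N = 3.0 * len(pairs) - S
    Sd = Nd = 0.0
    for x, y in pairs:
        d = pairwise_codon_diffs(x, y)
        Sd += d.sd
        Nd += d.nd
    return S, N, Sd, Nd, len(pairs)


def nei_gojobori_pair(cds_a: str, cds_b: str) -> DnDsResult:
    """Nei-Gojobori estimate for a pair of in-frame coding sequences."""
    S, N, Sd, Nd, n_codons = pair_counts(cds_a, cds_b)
    return _result_from_counts(S, N, Sd, Nd, n_codons)


def group_domain_dnds(
    codon_aln: Alignment,
    partition: DomainPartition,
    group_ids: Sequence[str],
    estimator: str = "pooled",
) -> dict[str, DnDsResult]:
    """Per-domain dN/dS over all unordered within-group pairs.

    ``codon_aln`` is an aligned nucleotide alignment whose codon columns
    correspond to the protein columns the partition's reference
    coordinates refer to.  With the default ``pooled`` estimator the raw
    counts (S, N, Sd, Nd) are summed over pairs before normalisation and
    correction; ``estimator="mean"`` instead averages the per-pair
    corrected distances (less stable at small S).
    """
    if len(group_ids) < 2:
        raise DnDsError("need at least two group members")
    if estimator not in ("pooled", "mean"):
        raise DnDsError(f"unknown estimator {estimator!r}")
    # project protein-coordinate domains onto codon columns
    prot_aln = _codon_to_protein_columns(codon_aln)
    results: dict[str, DnDsResult] = {}
    for name in partition.intervals:
        cols = partition.columns_for(name, prot_aln)
        if not cols:
            raise DnDsError(f"domain {name!r} has no codon columns")
        slices = {}
        for gid in group_ids:
            nt = codon_aln.get(gid).residues
            slices[gid] = "".join(nt[3 * c : 3 * c + 3] for c in cols)
        if estimator == "pooled":
            tot = np.zeros(4)
            n_codons = 0
            for a, b in itertools.combinations(group_ids, 2):
                S, N, Sd, Nd, nc = pair_counts(slices[a], slices[b])
                tot += (S, N, Sd, Nd)
                n_codons = max(n_codons, nc)
            results[name] = _result_from_counts(*tot, n_codons)
        else:
            per_pair = [
                nei_gojobori_pair(slices[a], slices[b])
                for a, b in itertools.combinations(group_ids, 2)
            ]
            results[name] = DnDsResult(
                S=float(np.mean([r.S for r in per_pair])),
                N=float(np.mean([r.N for r in per_pair])),
                Sd=float(np.mean([r.Sd for r in per_pair])),
                Nd=float(np.mean([r.Nd for r in per_pair])),
                pS=float(np.mean([r.pS for r in per_pair])),
                pN=float(np.mean([r.pN for r in per_pair])),
                dS=float(np.mean([r.dS for r in per_pair])),
                dN=float(np.mean([r.dN for r in per_pair])),
                dS_saturated=any(r.dS_saturated for r in per_pair),
                dN_saturated=any(r.dN_saturated for r in per_pair),
                n_codons=max(r.n_codons for r in per_pair),
            )
    return results


def _codon_to_protein_columns(codon_aln: Alignment) -> Alignment:
    """Translate an aligned CDS alignment column-wise ('---' -> '-').

    Codon columns with partial gaps or ambiguity translate to 'X' so the
    partition projection still has a residue to count."""
    from Bio.Seq import Seq

    from .seqio import SequenceRecord

    records = []
    for r in codon_aln.records:
        if len(r.residues) % 3:
            raise DnDsError(f"aligned CDS {r.id!r} length not divisible by 3")
        chars = []
        for i in range(0, len(r.residues), 3):
            codon = r.residues[i : i + 3]
            if codon == "---":
                chars.append("-")
            elif any(ch not in BASES for ch in codon):
                chars.append("X")
            else:
                chars.append(str(Seq(codon).translate()))
        records.append(SequenceRecord(r.id, "".join(chars)))
    return Alignment(records)
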