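"""Classical nuclear-localisation-signal detection and scoring.

Monopartite cNLS candidates are 4-mers matching ``K-(K/R)-X-(K/R)``;
bipartite candidates are two basic clusters (at least two K/R within a
three-residue window) separated by a 10-12 residue linker.  Candidates
are scored on a 0-10 scale with a transparent surrogate scheme: one
point per basic core residue, a two-point penalty per tryptophan in the
core (tryptophan in place of a core arginine is the decisive
loss-of-function substitution), and a one-point bonus for an extra
basic residue flanking the core within two positions.  Scores below 2
are classified non-functional.

This scheme is deliberately simple; it reproduces the decisive contrast
(``KKRR`` functional, ``KKWR`` non-functional) rather than the exact
numerics of position-specific activity matrices trained on importin-α
binding data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
BASIC = {"K", "R"}

#: scores below this are non-functional
FUNCTIONAL_THRESHOLD = 2.0


class NlsError(ValueError):
    pass


@dataclass
class NlsCandidate:
    """One candidate signal with its flanking context.

    ``span`` is 1-based inclusive on the ungapped sequence; ``core`` is
    the candidate residues themselves (both clusters joined for
    bipartite candidates); the flanks hold up to two residues either
    side of the span, used by the flank-bonus rule.
    """

    kind: str  # "monopartite" | "bipartite"
    span: tuple[int, int]
    core: str
    flank_up: str = ""
    flank_down: str = ""
    score: float = field(default=0.0)

    @property
    def functional(self) -> bool:
        return self.score >= FUNCTIONAL_THRESHOLD


def score_candidate(candidate: NlsCandidate) -> float:
    """0-10 surrogate cNLS score (see module docstring for the rules)."""
    basics = sum(1 for ch in candidate.core if ch in BASIC)
    tryptophans = candidate.core.count("W")
    score = basics - 2 * tryptophans
    if any(ch in BASIC for ch in candidate.flank_up + candidate.flank_down):
        score += 1
    return float(min(10.0, max(0.0, score)))


def _check_sequence(residues: str) -> str:
    residues = residues.upper()
    bad = set(residues) - AMINO_ACIDS
    if bad:
        raise NlsError(f"non-amino-acid symbols in sequence: {sorted(bad)}")
    return residues


def _cluster_starts(residues: str) -> list[int]:
    """0-based starts of 3-residue windows holding >= 2 basic residues."""
    out = []
    for i in range(len(residues) - 2):
        if sum(1 for ch in residues[i : i + 3] if ch in BASIC) >= 2:
            out.append(i)
    return out


def scan_nls(
    residues: str, region: Optional[tuple[int, int]] = None
) -> list[NlsCandidate]:
    """All monopartite and bipartite candidates in an ungapped sequence.

    ``region`` (1-based inclusive) restricts the scan to candidates
    entirely within that window.  Overlapping candidates are all
    reported, sorted by score descending then position.
    """
    residues = _check_sequence(residues)
    if len(residues) < 4:
        raise NlsError("sequence shorter than 4 residues")
    lo, hi = (1, len(residues)) if region is None else region
    lo0, hi0 = lo - 1, hi - 1  # 0-based inclusive
    candidates: list[NlsCandidate] = []

    # monopartite: K-(K/R)-X-(K/R)
    for i in range(lo0, min(hi0 - 2, len(residues) - 4) + 1):
        core = residues[i : i + 4]
        if core[0] == "K" and core[1] in BASIC and core[3] in BASIC:
            cand = NlsCandidate(
                kind="monopartite",
                span=(i + 1, i + 4),
                core=core,
                flank_up=residues[max(0, i - 2) : i],
                flank_down=residues[i + 4 : i + 6],
            )
            cand.score = score_candidate(cand)
            candidates.append(cand)

    # bipartite: two basic clusters separated by a 10-12 residue linker
    starts = [s for s in _cluster_starts(residues) if lo0 <= s]
    for p in starts:
        for q in starts:
            linker = q - (p + 3)
            if not 10 <= linker <= 12:
                continue
            if q + 2 > hi0:
                continue
            cand = NlsCandidate(
                kind="bipartite",
                span=(p + 1, q + 3),
                core=residues[p : p + 3] + residues[q : q + 3],
                flank_up=residues[max(0, p - 2) : p],
                flank_down=residues[q + 3 : q + 5],
            )
            cand.score = score_candidate(cand)
            candidates.append(cand)

    candidates.sort(key=lambda c: (-c.score, c.span))
    return candidates


def classify_alignment(aln, partition) -> dict[str, tuple[bool, float]]:
    """Functional/non-functional call per sequence over the NLS window.

    The window is the partition's ``NLS`` interval projected onto
    alignment columns through the reference's gap pattern, so per-taxon
    gaps elsewhere cannot shift the scanned region.  Gap characters
    inside the window are dropped before scanning.
    """
    cols = partition.columns_for("NLS", aln)
    out = {}
    for rec in aln.records:
        window = "".join(rec.residues[c] for c in cols).replace("-", "")
        if len(window) < 4:
            out[rec.id] = (False, 0.0)
            continue
        functional, best, _ = classify_sequence(window)
        out[rec.id] = (functional, best)
    return out


def classify_sequence(
    residues: str, region: Optional[tuple[int, int]] = None
) -> tuple[bool, float, list[NlsCandidate]]:
    """Functional/non-functional call for a sequence (or a window of it).

    Returns ``(functional, best_score, candidates)``; a sequence with no
    candidates is non-functional with score 0.
    """
    candidates = scan_nls(residues, region=region)
    best = candidates[0].score if candidates else 0.0
    return best >= FUNCTIONAL_THRESHOLD, best, candidates
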