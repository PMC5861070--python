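"""Codon-alignment simulator with domain-specific selection pressure.

Generates the kind of data the analysis pipeline assumes: a paralogue
family evolved along a clade tree under a Goldman-Yang-style 61-state
codon model with uniform sense-codon equilibrium, transition/
transversion ratio 1 and a per-domain nonsynonymous rate multiplier
(omega), so the configured omega *is* the dN/dS truth.  A basic-residue
NLS motif (core ``KKRR``) is written into the pro-domain after
simulation, with a designated monophyletic subclade carrying the
loss-of-function ``KKWR`` core (R -> W); whole gap columns are injected
at a configurable rate.

Defaults model the study conditions: 16 mammalian taxa, pro and mature
domains of 200 codons each under strong (omega 0.1) and relaxed (omega
0.6) purifying selection, tree depth 0.3 substitutions/site, and a
four-taxon loss clade mirroring the toothed-whale scenario.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
from Bio.Seq import Seq
from dendropy.simulate import treesim

from .conservation import DomainPartition
from .dnds import BASES, CODON_INDEX, SENSE_CODONS
from .seqio import (
    Alignment,
    Metadata,
    MetaEntry,
    SequenceRecord,
    tree_to_newick,
    write_fasta,
    write_metadata,
)

N_CODONS = 61

#: codons used when writing the NLS window: Ser-Ser-Lys-Lys-Arg-Arg-Ser-Ser
MOTIF_FLANK_CODON = "TCT"  # Ser; guarantees no basic flank bonus
MOTIF_CORE_CODONS = ("AAA", "AAA", "CGG", "AGA")  # K K R R
MOTIF_LOSS_CODONS = ("AAA", "AAA", "TGG", "AGA")  # K K W R (single C->T)
MOTIF_FLANK = 2  # codons of Ser padding either side of the core


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic family."""

    n_taxa: int = 16
    tree: Optional[str] = None  # Newick; None -> random Yule shape
    depth: float = 0.3  # mean root-to-tip length, substitutions/site
    pro_codons: int = 200
    mature_codons: int = 200
    omega_pro: float = 0.1
    omega_mature: float = 0.6
    nls_core: str = "KKRR"
    nls_insert_codon: int = 70  # 1-based codon position within pro
    loss_clade: Optional[list[str]] = None  # None -> auto-pick ~4 taxa
    loss_clade_size: int = 4
    gap_rate: float = 0.02  # per protein column
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega_pro <= 0 or self.omega_mature <= 0:
            raise SimulationError("omega must be positive")
        if self.pro_codons < 1 or self.mature_codons < 1:
            raise SimulationError("domain lengths must be >= 1 codon")
        window = self.nls_insert_codon + len(self.nls_core) + 2 * MOTIF_FLANK - 1
        if not 1 <= self.nls_insert_codon or window > self.pro_codons:
            raise SimulationError("NLS window does not fit inside the pro domain")


@dataclass
class SimulationTruth:
    """Everything needed to regenerate and verify one simulated family."""

    newick: str
    omega: dict[str, float]
    loss_clade: list[str]
    motif_status: dict[str, str]  # taxon -> "intact" | "lost"
    seed: int
    config: dict
    manifest: dict[str, str] = field(default_factory=dict)  # file -> sha256

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class SimulationResult:
    codon_alignment: Alignment
    protein_alignment: Alignment
    metadata: Metadata
    partition: DomainPartition
    truth: SimulationTruth
    tree: dendropy.Tree

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "codon_fasta": outdir / "family_codon.fasta",
            "protein_fasta": outdir / "family_protein.fasta",
            "metadata": outdir / "metadata.tsv",
            "partition": outdir / "partition.json",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.codon_alignment, paths["codon_fasta"])
        write_fasta(self.protein_alignment, paths["protein_fasta"])
        write_metadata(self.metadata, paths["metadata"])
        self.partition.to_json(paths["partition"])
        for key in ("codon_fasta", "protein_fasta", "metadata", "partition"):
            digest = hashlib.sha256(paths[key].read_bytes()).hexdigest()
            self.truth.manifest[paths[key].name] = digest
        self.truth.to_json(paths["truth"])
        return paths


# -- codon model -------------------------------------------------------------


def _codon_arrays() -> tuple[np.ndarray, np.ndarray]:
    """(61x61 single-change mask, 61x61 nonsynonymous mask)."""
    codons = SENSE_CODONS
    aa = [str(Seq(c).translate()) for c in codons]
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    nonsyn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if i == j:
                continue
            diffs = sum(a != b for a, b in zip(ci, cj))
            if diffs == 1:
                single[i, j] = True
                nonsyn[i, j] = aa[i] != aa[j]
    return single, nonsyn


@lru_cache(maxsize=8)
def codon_rate_spectrum(omega: float) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the scaled codon rate matrix for one omega.

    Uniform codon frequencies and symmetric exchangeabilities make Q
    symmetric, so ``eigh`` applies directly.  Scaled to one expected
    substitution per codon site per unit time.
    """
    single, nonsyn = _codon_arrays()
    q = np.zeros((N_CODONS, N_CODONS))
    q[single & ~nonsyn] = 1.0
    q[single & nonsyn] = omega
    q /= N_CODONS  # uniform target frequency 1/61
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.mean(np.diag(q))  # pi_i = 1/61
    q /= scale
    eigval, eigvec = np.linalg.eigh(q)
    return eigval, eigvec


def codon_transition_matrix(omega: float, t: float) -> np.ndarray:
    eigval, eigvec = codon_rate_spectrum(omega)
    p = (eigvec * np.exp(eigval * t)) @ eigvec.T
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _evolve(parent: np.ndarray, p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample child codon states given parent states and P(t)."""
    cdf = np.cumsum(p, axis=1)
    u = rng.random(parent.size)
    return (u[:, None] < cdf[parent]).argmax(axis=1)


# -- tree --------------------------------------------------------------------


def _yule_tree(n_taxa: int, depth: float, seed: int) -> dendropy.Tree:
    """Pure-birth tree with mean root-to-tip path scaled to ``depth``."""
    labels = [f"t{i:02d}" for i in range(1, n_taxa + 1)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        taxon_namespace=taxa,
        rng=random.Random(seed),
    )
    root_dists = tree.calc_node_root_distances(return_leaf_distances_only=True)
    mean_depth = float(np.mean(root_dists))
    factor = depth / mean_depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree


def _pick_loss_clade(tree: dendropy.Tree, target_size: int) -> list[str]:
    """Deterministically pick a monophyletic clade closest to the target
    size (preferring the earliest in postorder on ties)."""
    n = len(tree.taxon_namespace)
    best: tuple[int, int, list[str]] | None = None
    for rank, node in enumerate(tree.postorder_internal_node_iter()):
        leaves = [l.taxon.label for l in node.leaf_iter()]
        if len(leaves) >= n:  # whole tree
            continue
        key = (abs(len(leaves) - target_size), rank)
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], leaves)
    if best is None:
        raise SimulationError("tree has no internal clade to assign the loss to")
    return sorted(best[2])


def _check_monophyletic(tree: dendropy.Tree, taxa: Sequence[str]) -> None:
    target = set(taxa)
    for node in tree.postorder_internal_node_iter():
        if {l.taxon.label for l in node.leaf_iter()} == target:
            return
    raise SimulationError(
        "loss_clade is not monophyletic in the tree (the scenario is a "
        "single ancestral loss-of-function event)"
    )


# -- main entry --------------------------------------------------------------


def simulate_family(config: SimulationConfig) -> SimulationResult:
    """Simulate one paralogue family; see the module docstring.

    Deterministic: the same config (including seed) yields byte-identical
    outputs.
    """
    rng = np.random.default_rng(config.seed)
    if config.tree is not None:
        tree = dendropy.Tree.get(
            data=config.tree, schema="newick", preserve_underscores=True
        )
    else:
        tree = _yule_tree(config.n_taxa, config.depth, seed=config.seed % (2**31 - 1))
    taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())

    if config.loss_clade is not None:
        loss = sorted(config.loss_clade)
        unknown = set(loss) - set(taxa)
        if unknown:
            raise SimulationError(f"loss_clade taxa not in tree: {sorted(unknown)}")
        _check_monophyletic(tree, loss)
    else:
        loss = _pick_loss_clade(tree, config.loss_clade_size)

    n_pro, n_mat = config.pro_codons, config.mature_codons
    length = n_pro + n_mat
    omegas = np.where(np.arange(length) < n_pro, config.omega_pro, config.omega_mature)

    root_state = rng.integers(0, N_CODONS, size=length)
    states: dict[int, np.ndarray] = {id(tree.seed_node): root_state}
    leaf_states: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        child = parent.copy()
        for omega in (config.omega_pro, config.omega_mature):
            mask = omegas == omega
            if not mask.any():
                continue
            p = codon_transition_matrix(omega, t)
            child[mask] = _evolve(parent[mask], p, rng)
        states[id(node)] = child
        if node.is_leaf():
            leaf_states[node.taxon.label] = child

    # post-hoc motif overwrite: Ser flanks + KKRR core (KKWR in loss clade)
    w0 = config.nls_insert_codon - 1  # 0-based start of the padded window
    core_idx = [CODON_INDEX[c] for c in MOTIF_CORE_CODONS]
    loss_idx = [CODON_INDEX[c] for c in MOTIF_LOSS_CODONS]
    flank_idx = CODON_INDEX[MOTIF_FLANK_CODON]
    window = list(range(w0, w0 + 2 * MOTIF_FLANK + len(MOTIF_CORE_CODONS)))
    motif_status = {}
    for taxon in taxa:
        st = leaf_states[taxon]
        st[w0 : w0 + MOTIF_FLANK] = flank_idx
        st[w0 + MOTIF_FLANK + 4 : w0 + 2 * MOTIF_FLANK + 4] = flank_idx
        idx = loss_idx if taxon in loss else core_idx
        st[w0 + MOTIF_FLANK : w0 + MOTIF_FLANK + 4] = idx
        motif_status[taxon] = "lost" if taxon in loss else "intact"

    # whole-column gap injection (never inside the motif window); each
    # selected column is gapped in a strict majority of taxa
    n_taxa = len(taxa)
    gap_cols = [
        c
        for c in range(length)
        if c not in window and rng.random() < config.gap_rate
    ]
    gapped: dict[str, set[int]] = {t: set() for t in taxa}
    max_keep = (n_taxa - 1) // 2
    for c in gap_cols:
        keep = int(min(max_keep, rng.binomial(n_taxa, 0.25)))
        kept = set(rng.choice(n_taxa, size=keep, replace=False)) if keep else set()
        for i, taxon in enumerate(taxa):
            if i not in kept:
                gapped[taxon].add(c)

    codon_records, protein_records = [], []
    for taxon in taxa:
        st = leaf_states[taxon]
        codons, prots = [], []
        for c in range(length):
            if c in gapped[taxon]:
                codons.append("---")
                prots.append("-")
            else:
                codon = SENSE_CODONS[st[c]]
                codons.append(codon)
                prots.append(str(Seq(codon).translate()))
        codon_records.append(SequenceRecord(taxon, "".join(codons)))
        protein_records.append(SequenceRecord(taxon, "".join(prots)))
    codon_aln = Alignment(codon_records)
    protein_aln = Alignment(protein_records)

    meta = Metadata(
        {
            t: MetaEntry(
                species=t,
                clade="mammal",
                group="toothed_whale" if t in loss else "land_mammal",
            )
            for t in taxa
        }
    )

    # partition on the reference's ungapped coordinates
    reference = next(t for t in taxa if t not in loss)
    ref_gaps = gapped[reference]
    def ungapped(col: int) -> int:  # 1-based ungapped coordinate of a column
        return sum(1 for c in range(col + 1) if c not in ref_gaps)

    pro_end = ungapped(n_pro - 1)
    intervals = {
        "pro": (1, pro_end),
        "mature": (pro_end + 1, ungapped(length - 1)),
        "NLS": (ungapped(window[0]), ungapped(window[-1])),
    }
    if pro_end >= 40:
        intervals["HCPR"] = (1, 40)
    partition = DomainPartition(reference, intervals)

    truth = SimulationTruth(
        newick=tree_to_newick(tree),
        omega={"pro": config.omega_pro, "mature": config.omega_mature},
        loss_clade=loss,
        motif_status=motif_status,
        seed=config.seed,
        config=asdict(config),
    )
    return SimulationResult(codon_aln, protein_aln, meta, partition, truth, tree)
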