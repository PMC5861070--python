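"""JTT distances, neighbor-joining, bootstrap supports and tree likelihood.

The tree-building recipe is NJ on maximum-likelihood pairwise distances
under the JTT empirical amino-acid model, with column-bootstrap supports
and collapse of weakly supported (<50%) branches.  A fixed-topology
log-likelihood (Felsenstein pruning) is provided to compare candidate
topologies under the same model; heuristic topology search is out of
scope.

All distances and branch lengths are in expected substitutions
(amino-acid replacements) per site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from . import _jtt_data
from .seqio import Alignment

logger = logging.getLogger(__name__)

#: search bounds for the pairwise ML distance optimiser
DISTANCE_BOUNDS = (1e-6, 10.0)
DISTANCE_TOL = 1e-6


class PhyloError(ValueError):
    pass


@dataclass
class SubstitutionModel:
    """A general time-reversible amino-acid substitution model.

    Built from a symmetric exchangeability matrix ``s`` and equilibrium
    frequencies ``pi``: ``Q[i, j] = s[i, j] * pi[j]`` off-diagonal, rows
    summing to zero, scaled so the expected rate ``-sum_i pi_i Q_ii`` is
    one substitution per site per unit time.  Transition matrices
    ``P(t) = expm(Q t)`` are computed through the spectral decomposition
    of the symmetrised rate matrix, which reversibility guarantees.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alphabet: str = _jtt_data.AA_ORDER

    def __post_init__(self) -> None:
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        k = len(self.alphabet)
        if s.shape != (k, k) or not np.allclose(s, s.T):
            raise PhyloError("exchangeability matrix must be symmetric k x k")
        if pi.shape != (k,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise PhyloError("frequencies must be positive and sum to 1")
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(pi * np.diag(q)).sum()
        q /= scale
        self.rate_matrix = q
        self.frequencies = pi
        self._index = {a: i for i, a in enumerate(self.alphabet)}
        # symmetrise: B = D^{1/2} Q D^{-1/2} with D = diag(pi)
        sqrt_pi = np.sqrt(pi)
        b = sqrt_pi[:, None] * q / sqrt_pi[None, :]
        eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
        self._eigval = eigval
        self._left = eigvec / sqrt_pi[:, None]       # D^{-1/2} U
        self._right = (eigvec * sqrt_pi[:, None]).T  # U^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        """``P(t) = expm(Q t)``; rows sum to 1 for all t >= 0."""
        if t < 0:
            raise PhyloError(f"negative branch length {t}")
        p = (self._left * np.exp(self._eigval * t)) @ self._right
        np.clip(p, 0.0, None, out=p)
        return p

    def encode(self, residues: str) -> np.ndarray:
        try:
            return np.array([self._index[a] for a in residues], dtype=np.intp)
        except KeyError as exc:
            raise PhyloError(
                f"residue {exc.args[0]!r} outside the model alphabet "
                f"{self.alphabet!r} (was the alignment gap-filtered?)"
            ) from None


def jtt_model() -> SubstitutionModel:
    """The Jones-Taylor-Thornton (1992) empirical model."""
    return SubstitutionModel(
        _jtt_data.exchangeability_matrix(), _jtt_data.frequencies()
    )


class DistanceEstimate(NamedTuple):
    distance: float
    saturated: bool


def jtt_distance(a: str, b: str, model: SubstitutionModel) -> DistanceEstimate:
    """Pairwise ML distance: argmax_t sum_sites log(pi_a P_ab(t)).

    Bounded scalar maximisation on ``DISTANCE_BOUNDS`` to absolute
    tolerance 1e-6.  Identical sequences return the lower bound; an
    optimum at the upper bound sets the ``saturated`` flag instead of
    failing.
    """
    if len(a) != len(b):
        raise PhyloError("sequences must have equal length")
    ia, ib = model.encode(a), model.encode(b)
    counts = np.zeros((20, 20))
    np.add.at(counts, (ia, ib), 1.0)
    if np.array_equal(ia, ib):
        return DistanceEstimate(DISTANCE_BOUNDS[0], False)
    log_pi = np.log(model.frequencies)

    def neg_loglik(t: float) -> float:
        p = model.transition_matrix(t)
        with np.errstate(divide="ignore"):
            ll = counts * (log_pi[:, None] + np.log(p))
        return -np.sum(ll[counts > 0])

    res = minimize_scalar(
        neg_loglik,
        bounds=DISTANCE_BOUNDS,
        method="bounded",
        options={"xatol": DISTANCE_TOL},
    )
    t_hat = float(res.x)
    saturated = t_hat > DISTANCE_BOUNDS[1] - 1e-3
    return DistanceEstimate(t_hat, saturated)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair saturation flags."""

    ids: list[str]
    matrix: np.ndarray
    saturated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise PhyloError("distance matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T):
            raise PhyloError("distance matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise PhyloError("distance matrix diagonal must be zero")
        if np.any(self.matrix < 0):
            raise PhyloError("distances must be non-negative")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.ids)]
        for i, name in enumerate(self.ids):
            row = "\t".join(format(v, ".6f") for v in self.matrix[i])
            lines.append(f"{name}\t{row}")
        return "\n".join(lines) + "\n"


def distance_matrix(aln: Alignment, model: SubstitutionModel) -> DistanceMatrix:
    """All pairwise JTT ML distances of a gap-free alignment."""
    n = len(aln)
    d = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    seqs = [r.residues for r in aln.records]
    for i in range(n):
        for j in range(i + 1, n):
            est = jtt_distance(seqs[i], seqs[j], model)
            d[i, j] = d[j, i] = est.distance
            sat[i, j] = sat[j, i] = est.saturated
    return DistanceMatrix(aln.ids, d, sat)


# -- neighbor joining --------------------------------------------------------


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree.

    Negative intermediate branch lengths are clamped to zero and the
    deficit logged.
    """
    n = len(dist.ids)
    if n < 3:
        raise PhyloError(f"neighbor joining needs >= 3 taxa, got {n}")
    taxa = dendropy.TaxonNamespace(dist.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in dist.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    d = dist.matrix.astype(float).copy()
    active = list(range(n))

    def clamp(value: float, context: str) -> float:
        if value < 0:
            logger.info("clamping negative NJ branch length %g (%s)", value, context)
            return 0.0
        return value

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), m)
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = clamp(li, f"join {i},{j}")
        parent.add_child(nodes[j])
        nodes[j].edge.length = clamp(lj, f"join {i},{j}")
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d[i, :] = new_row
        d[:, i] = new_row
        nodes[i] = parent
        active.remove(j)

    a, b, c = active
    la = clamp(0.5 * (d[a, b] + d[a, c] - d[b, c]), "terminal star")
    lb = clamp(0.5 * (d[a, b] + d[b, c] - d[a, c]), "terminal star")
    lc = clamp(0.5 * (d[a, c] + d[b, c] - d[a, b]), "terminal star")
    root = tree.seed_node
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        root.add_child(node)
        node.edge.length = length
    tree.is_rooted = False
    return tree


# -- bootstrap ---------------------------------------------------------------


def _bipartitions(tree: dendropy.Tree, ref: str) -> dict[frozenset, dendropy.Node]:
    """Non-trivial bipartitions keyed by the leaf side not containing ``ref``.

    Canonicalising on a fixed reference taxon makes the keys independent
    of rooting.
    """
    out: dict[frozenset, dendropy.Node] = {}
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    n = len(all_leaves)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) < 2 or n - len(side) < 2:
            continue  # trivial split
        if ref in side:
            side = all_leaves - side
        out[side] = node
    return out


def bootstrap_supports(
    aln: Alignment,
    n_reps: int,
    seed: int,
    model: SubstitutionModel,
    collapse_below: int = 50,
) -> dendropy.Tree:
    """NJ tree with column-bootstrap supports; weak branches collapsed.

    Columns are resampled with replacement ``n_reps`` times; the support
    of a bipartition is the percentage of replicate NJ trees containing
    it.  Bipartitions with support below ``collapse_below`` are collapsed
    to polytomies.  Replicate ``r`` draws from a generator seeded with
    ``seed + r`` so results are independent of execution order.
    """
    if len(aln) < 3:
        raise PhyloError("bootstrap needs >= 3 taxa")
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    from .seqio import SequenceRecord

    # resampling may duplicate columns; work on residues only
    aln = Alignment([SequenceRecord(r.id, r.residues) for r in aln.records])
    main_tree = nj_tree(distance_matrix(aln, model))
    ref = aln.ids[0]
    counts: dict[frozenset, int] = {}
    n_cols = aln.length
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_aln = aln.take_columns(cols)
        rep_tree = nj_tree(distance_matrix(rep_aln, model))
        for bip in _bipartitions(rep_tree, ref):
            counts[bip] = counts.get(bip, 0) + 1

    to_collapse = []
    for bip, node in _bipartitions(main_tree, ref).items():
        support = int(round(100.0 * counts.get(bip, 0) / n_reps))
        node.label = str(support)
        if support < collapse_below:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()  # merge into parent -> polytomy
    return main_tree


# -- fixed-topology likelihood ----------------------------------------------


def tree_loglik(
    tree: dendropy.Tree, aln: Alignment, model: SubstitutionModel
) -> float:
    """Log-likelihood of a gap-free alignment on a fixed tree.

    Felsenstein pruning with transition matrices from the model's
    spectral decomposition; per-site log values are summed, with
    per-node rescaling for numerical safety.  Reversibility makes the
    result invariant to root placement.
    """
    leaf_labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    if leaf_labels != sorted(aln.ids):
        raise PhyloError("tree leaf labels do not match alignment ids")
    n_sites = aln.length
    k = len(model.alphabet)
    encoded = {r.id: model.encode(r.residues) for r in aln.records}

    log_scale = np.zeros(n_sites)
    partials: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            part = np.zeros((n_sites, k))
            part[np.arange(n_sites), encoded[node.taxon.label]] = 1.0
        else:
            part = np.ones((n_sites, k))
            for child in node.child_nodes():
                t = child.edge.length or 0.0
                p = model.transition_matrix(t)
                part *= partials.pop(id(child)) @ p.T
            peak = part.max(axis=1)
            peak[peak == 0] = 1.0
            part /= peak[:, None]
            log_scale += np.log(peak)
        partials[id(node)] = part
    root_part = partials[id(tree.seed_node)]
    site_lik = root_part @ model.frequencies
    if np.any(site_lik <= 0):
        raise PhyloError("zero site likelihood (inconsistent data/tree)")
    return float(np.sum(np.log(site_lik) + log_scale))
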