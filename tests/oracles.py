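"""Independent brute-force oracles used by the tests.

These deliberately re-derive quantities from first principles (plain
enumeration, grid search, normal equations) without touching the
package's implementation paths.
"""

from __future__ import annotations

import itertools

import numpy as np

_BASES = "TCAG"
# standard genetic code built from the canonical TCAG-ordered table string
_CODE_STRING = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
GENETIC_CODE = {
    a + b + c: _CODE_STRING[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
SENSE = sorted(
    (c for c, aa in GENETIC_CODE.items() if aa != "*"),
    key=lambda c: [_BASES.index(b) for b in c],
)


def brute_codon_sites(codon: str) -> tuple[float, float]:
    """Fraction of single-base neighbours preserving the amino acid."""
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if GENETIC_CODE[mut] == aa:  # '*' never equals a residue
                s += 1.0 / 3.0
    return s, 3.0 - s


def brute_pairwise_diffs(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) differences by full enumeration."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur, steps, blocked = a, [], False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*" and nxt != b:
                blocked = True
                break
            steps.append((cur, nxt))
            cur = nxt
        if not blocked:
            paths.append(steps)
    if not paths:  # fall back: count stop steps as nonsynonymous
        paths = []
        for order in itertools.permutations(diff):
            cur, steps = a, []
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                steps.append((cur, nxt))
                cur = nxt
            paths.append(steps)
    sd = nd = 0.0
    for steps in paths:
        for x, y in steps:
            if GENETIC_CODE[x] == "*" or GENETIC_CODE[y] == "*":
                nd += 1
            elif GENETIC_CODE[x] == GENETIC_CODE[y]:
                sd += 1
            else:
                nd += 1
    return sd / len(paths), nd / len(paths)


def grid_search_distance(counts: np.ndarray, model, step: float = 1e-4,
                         lo: float = 1e-6, hi: float = 10.0) -> float:
    """Maximise the pairwise JTT likelihood on a fixed grid."""
    log_pi = np.log(model.frequencies)
    best_t, best_ll = lo, -np.inf
    grid = np.arange(lo, hi, step)
    for start in range(0, grid.size, 20000):
        for t in grid[start : start + 20000]:
            p = model.transition_matrix(t)
            with np.errstate(divide="ignore"):
                ll = np.sum((counts * (log_pi[:, None] + np.log(p)))[counts > 0])
            if ll > best_ll:
                best_ll, best_t = ll, t
    return best_t


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Solve (X'X) beta = X'y directly."""
    return np.linalg.solve(x.T @ x, x.T @ y)
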