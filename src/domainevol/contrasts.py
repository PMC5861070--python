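"""Factorial protein x domain comparison with Holm-Sidak post-hocs.

Per-species conservation (or dN/dS) values enter a fixed-effects model
``value ~ species + protein * domain``: the species indicators are a
fixed-effect surrogate for by-subject random intercepts, which gives
identical point estimates for the within-subject contrasts in balanced
designs without mixed-model machinery.  Least-square-means pairwise
contrasts (within protein and within domain) are corrected with the
Holm-Sidak step-down procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats as sps


class ContrastError(ValueError):
    pass


def holm_sidak(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, input order preserved.

    Sort ascending; ``adj_(i) = 1 - (1 - p_(i))^(m - i + 1)`` (1-based
    rank ``i``); enforce a running maximum; restore the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ContrastError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ContrastError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


@dataclass
class FactorialFit:
    """OLS fit of ``value ~ C(species) + C(protein) * C(domain)``."""

    result: "sm.regression.linear_model.RegressionResultsWrapper"
    data: pd.DataFrame
    term_tests: pd.DataFrame  # omnibus F test per term

    @property
    def note(self) -> str:
        return (
            "FE approximation: species fixed effects stand in for "
            "by-subject random intercepts; random slopes not modelled"
        )


def fit_factorial(data: pd.DataFrame) -> FactorialFit:
    """Fit the species-adjusted protein x domain factorial model.

    ``data`` is long format with columns ``species``, ``protein``,
    ``domain`` and ``value``.  Term significance comes from partial
    (type II) F tests.
    """
    required = {"species", "protein", "domain", "value"}
    missing = required - set(data.columns)
    if missing:
        raise ContrastError(f"missing columns: {sorted(missing)}")
    for factor in ("species", "protein", "domain"):
        if data[factor].nunique() < 2:
            raise ContrastError(f"factor {factor!r} has fewer than 2 levels")
    result = smf.ols(
        "value ~ C(species) + C(protein) * C(domain)", data=data
    ).fit()
    if result.ssr < 1e-12:  # perfect fit: F tests are 0/0, define p = 1
        terms = ["C(species)", "C(protein)", "C(domain)", "C(protein):C(domain)"]
        term_tests = pd.DataFrame(
            {"F": [0.0] * len(terms), "PR(>F)": [1.0] * len(terms)}, index=terms
        )
    else:
        term_tests = sm.stats.anova_lm(result, typ=2)
    return FactorialFit(result, data.copy(), term_tests)


def _lsmean_row(fit: FactorialFit, protein: str, domain: str) -> np.ndarray:
    """Design row of the least-square mean of one (protein, domain) cell:
    the prediction averaged over all observed species."""
    design_info = fit.result.model.data.design_info
    species = sorted(fit.data["species"].unique())
    frame = pd.DataFrame(
        {"species": species, "protein": protein, "domain": domain}
    )
    (mat,) = build_design_matrices([design_info], frame)
    return np.asarray(mat).mean(axis=0)


def lsmeans_contrasts(fit: FactorialFit, family: str) -> pd.DataFrame:
    """Holm-Sidak-corrected pairwise least-square-means contrasts.

    ``family="within-protein"`` compares domains inside each protein;
    ``family="within-domain"`` compares proteins inside each domain.
    Each family is corrected separately.
    """
    proteins = sorted(fit.data["protein"].unique())
    domains = sorted(fit.data["domain"].unique())
    rows = []
    if family == "within-protein":
        pairs = [
            (f"{p}: {d1} - {d2}", (p, d1), (p, d2))
            for p in proteins
            for i, d1 in enumerate(domains)
            for d2 in domains[i + 1 :]
        ]
    elif family == "within-domain":
        pairs = [
            (f"{d}: {p1} - {p2}", (p1, d), (p2, d))
            for d in domains
            for i, p1 in enumerate(proteins)
            for p2 in proteins[i + 1 :]
        ]
    else:
        raise ContrastError(f"unknown contrast family {family!r}")
    for label, cell_a, cell_b in pairs:
        vec = _lsmean_row(fit, *cell_a) - _lsmean_row(fit, *cell_b)
        test = fit.result.t_test(vec)
        est = float(np.squeeze(test.effect))
        se = float(np.squeeze(test.sd))
        tval = float(np.squeeze(test.tvalue))
        p_raw = float(np.squeeze(test.pvalue))
        if not np.isfinite(p_raw):  # zero-residual fit: se == 0
            p_raw = 1.0 if abs(est) < 1e-10 else 0.0
            tval = 0.0 if abs(est) < 1e-10 else float("inf")
        rows.append(
            {"contrast": label, "estimate": est, "se": se, "t": tval,
             "p_raw": p_raw}
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = holm_sidak(table["p_raw"].to_numpy())
    return table


def fwer_under_null(
    m: int = 4,
    n_reps: int = 1000,
    n_per_group: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo family-wise error of Holm-Sidak under the global null.

    Each replicate draws ``m`` independent two-sample comparisons of
    standard-normal groups, computes Welch t-test p-values, adjusts the
    family and records whether anything was rejected at ``alpha``.
    Returns ``(fwer_estimate, monte_carlo_se)``.
    """
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_reps, m, n_per_group))
    b = rng.standard_normal((n_reps, m, n_per_group))
    p = sps.ttest_ind(a, b, axis=2).pvalue  # (n_reps, m)
    # vectorised Holm-Sidak across replicates
    order = np.argsort(p, axis=1)
    p_sorted = np.take_along_axis(p, order, axis=1)
    exponents = m - np.arange(m)
    adj = 1.0 - (1.0 - p_sorted) ** exponents
    adj = np.maximum.accumulate(adj, axis=1)
    any_reject = (adj < alpha).any(axis=1)
    fwer = float(any_reject.mean())
    mcse = float(np.sqrt(fwer * (1.0 - fwer) / n_reps)) if 0 < fwer < 1 else float(
        np.sqrt(alpha * (1 - alpha) / n_reps)
    )
    return fwer, mcse
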