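"""Significance testing for heritability estimates.

The null hypothesis h2 = 0 lies on the boundary of the parameter space, so
the Wald statistic W = (h2/se)^2 follows a half-half mixture of a point
mass at zero (chi2 with 0 df) and a chi2 with 1 df. A nonparametric
alternative jointly permutes the rows and columns of the genetic
similarity matrix and recomputes the estimate; the add-one permutation p
value never returns zero. Benjamini-Hochberg controls the FDR across
structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimator import ProjectedData, fit_moment_matching

__all__ = ["TestResult", "wald_test", "permutation_test", "fdr_adjust"]


@dataclass
class TestResult:
    statistic: float
    p_wald: float | None = None
    p_perm: float | None = None
    n_perm: int = 0


def wald_test(h2: float, se: float) -> TestResult:
    """Boundary-null Wald test: W = (h2/se)^2, p = 0.5 * P(chi2_1 >= W).

    A nonpositive point estimate sits at the boundary and gets p = 0.5
    (the chi2_0 half of the mixture plus the full chi2_1 tail at zero).
    """
    if se <= 0:
        raise ValueError(f"standard error must be positive, got {se}")
    if h2 <= 0:
        return TestResult(statistic=0.0, p_wald=0.5)
    W = (h2 / se) ** 2
    return TestResult(statistic=float(W), p_wald=float(0.5 * stats.chi2.sf(W, df=1)))


def _h2_for_permutation(Y: np.ndarray, K: np.ndarray) -> float:
    """Unclamped trace-ratio h2; traces only, no full Sigma matrices."""
    n = K.shape[0]
    tr_K = float(np.trace(K))
    tr_K2 = float(np.sum(K * K))
    k_bar = tr_K / n
    v_K = tr_K2 - tr_K**2 / n
    tr_YKY = float(np.sum((K @ Y) * Y))
    tr_YY = float(np.sum(Y * Y))
    t_A = (tr_YKY - k_bar * tr_YY) / v_K
    t_E = (tr_K2 / n * tr_YY - k_bar * tr_YKY) / v_K
    return t_A / (t_A + t_E)


def permutation_test(
    P: ProjectedData, n_perm: int = 10_000, seed: int = 0
) -> TestResult:
    """Permutation p for h2 by shuffling rows/columns of the similarity matrix.

    For each of ``n_perm`` draws the (projected) similarity matrix is
    symmetrically permuted, the trait matrix left fixed, and the unclamped
    trace-ratio estimate recomputed; p = (1 + #{h2_perm >= h2_obs}) /
    (n_perm + 1). Deterministic for a given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    Y, K = P.Y, P.K
    h2_obs = _h2_for_permutation(Y, K)

    # tr[Y' PKP' Y] = <PKP', YY'>; permuting K and contracting against the
    # fixed cross-product matrix C avoids recomputing K @ Y each draw.
    C = Y @ Y.T
    n = K.shape[0]
    tr_K = float(np.trace(K))
    tr_K2 = float(np.sum(K * K))
    k_bar = tr_K / n
    kappa = tr_K2 / n
    v_K = tr_K2 - tr_K**2 / n
    tr_YY = float(np.trace(C))

    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        tr_YKY = float(np.sum(K[np.ix_(perm, perm)] * C))
        t_A = (tr_YKY - k_bar * tr_YY) / v_K
        t_E = (kappa * tr_YY - k_bar * tr_YKY) / v_K
        if t_A / (t_A + t_E) >= h2_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return TestResult(statistic=float(h2_obs), p_perm=float(p), n_perm=n_perm)


def fdr_adjust(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up: (significant flags, adjusted p values)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
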