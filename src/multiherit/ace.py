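"""ACE variance-component models for twin/family designs.

For familial samples the genetic similarity matrix is twice the kinship
matrix (entries 1 between MZ twins, 0.5 between DZ twins and full
siblings) and a household matrix Lambda (1 within a family) captures the
shared-environment component:

    cov[y] = sigma2_A * K_ped + sigma2_C * Lambda + sigma2_E * I.

Each component of a multidimensional trait is fitted separately by REML
(fixed effects profiled out), the per-component heritabilities are
combined by a variance-weighted average, and uncertainty comes from a
family-block bootstrap: families are resampled with replacement, the whole
fit repeated, and the standard deviation over replicates reported.

Because relatives never span families, all likelihood evaluations factor
into small per-family blocks, which keeps hundreds of REML fits (as the
bootstrap requires) cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .estimator import CovariateMatrix, TraitMatrix
from .grm import GeneticSimilarity

__all__ = [
    "PedigreeStructure",
    "ACEComponentFit",
    "ACEHeritability",
    "fit_ace_component",
    "combine_components",
    "block_bootstrap_se",
]

ZYGOSITY_CODES = ("MZ", "DZ", "SIB", "SINGLETON")


@dataclass
class PedigreeStructure:
    """Kinship-derived similarity (2*Phi) and household-sharing matrices.

    Built from a member table with one row per sample: family ID plus a
    zygosity/relationship code (MZ, DZ, SIB, SINGLETON). Within a family,
    the MZ-coded pair has similarity 1; every other within-family pair has
    0.5 (DZ twins and full siblings); across families 0. Lambda is 1
    within a family (twins and their non-twin siblings share a household)
    and 0 elsewhere.
    """

    sample_ids: list[str]
    family_ids: list[str]
    zygosity: list[str]
    K_ped: np.ndarray = field(init=False)
    Lambda: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if not len(self.family_ids) == len(self.zygosity) == n:
            raise ValueError("sample, family and zygosity lists differ in length")
        bad = set(self.zygosity) - set(ZYGOSITY_CODES)
        if bad:
            raise ValueError(f"unknown zygosity codes {bad}; expected {ZYGOSITY_CODES}")
        fam = np.asarray(self.family_ids)
        zyg = np.asarray(self.zygosity)
        K = np.zeros((n, n))
        L = np.zeros((n, n))
        for f in np.unique(fam):
            idx = np.flatnonzero(fam == f)
            K[np.ix_(idx, idx)] = 0.5
            L[np.ix_(idx, idx)] = 1.0
            mz = idx[zyg[idx] == "MZ"]
            if len(mz) not in (0, 2):
                raise ValueError(f"family {f!r}: MZ code must mark exactly one pair")
            if len(mz) == 2:
                K[np.ix_(mz, mz)] = 1.0
        np.fill_diagonal(K, 1.0)
        self.K_ped = K
        self.Lambda = L

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "PedigreeStructure":
        """Columns: sample (or first column), family, zygosity."""
        cols = {c.lower(): c for c in table.columns}
        sample = cols.get("sample", table.columns[0])
        return cls(
            sample_ids=[str(s) for s in table[sample]],
            family_ids=[str(f) for f in table[cols.get("family", table.columns[1])]],
            zygosity=[str(z).upper() for z in table[cols.get("zygosity", table.columns[2])]],
        )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def families(self) -> dict[str, np.ndarray]:
        fam = np.asarray(self.family_ids)
        return {f: np.flatnonzero(fam == f) for f in pd.unique(fam)}

    def similarity(self) -> GeneticSimilarity:
        return GeneticSimilarity(K=self.K_ped, sample_ids=list(self.sample_ids),
                                 source="pedigree")


@dataclass
class ACEComponentFit:
    sigma2_a: float
    sigma2_c: float
    sigma2_e: float
    loglik: float
    converged: bool
    message: str = ""

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_a + self.sigma2_c + self.sigma2_e

    @property
    def h2(self) -> float:
        return self.sigma2_a / self.sigma2_p


# ---------------------------------------------------------------------------
# blockwise REML


def _family_blocks(y, K, Lam, X, families):
    """Group per-family blocks by family size into batched 3D arrays."""
    by_size: dict[int, list] = {}
    for idx in families.values():
        by_size.setdefault(len(idx), []).append(idx)
    groups = []
    for size, idx_list in by_size.items():
        Ks = np.stack([K[np.ix_(i, i)] for i in idx_list])
        Ls = np.stack([Lam[np.ix_(i, i)] for i in idx_list])
        rhs = np.stack([np.column_stack([y[i], X[i]]) for i in idx_list])
        groups.append((Ks, Ls, rhs, np.eye(size)))
    return groups


def _reml_neg2ll(theta: np.ndarray, groups, q: int) -> float:
    """-2 * restricted log-likelihood, accumulated over family blocks.

    -2 l_R = log|V| + log|X'V^-1 X| + y'Py  (+ const), where
    P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1. V is block diagonal by family,
    so every term is a sum over small blocks, evaluated batched per family
    size for speed (the bootstrap re-fits the model thousands of times).
    """
    sa, sc, se = theta
    logdet = 0.0
    xtvix = np.zeros((q, q))
    xtviy = np.zeros(q)
    ytviy = 0.0
    for Ks, Ls, rhs, eye in groups:
        V = sa * Ks + sc * Ls + se * eye
        try:
            c = np.linalg.cholesky(V)  # batched; raises if any block fails
        except np.linalg.LinAlgError:
            return 1e12  # infeasible; finite so finite-difference gradients stay clean
        logdet += 2.0 * np.log(np.diagonal(c, axis1=1, axis2=2)).sum()
        sol = np.linalg.solve(c, rhs)  # (B, s, 1 + q)
        ytviy += float(np.einsum("bs,bs->", sol[:, :, 0], sol[:, :, 0]))
        xtviy += np.einsum("bsq,bs->q", sol[:, :, 1:], sol[:, :, 0])
        xtvix += np.einsum("bsp,bsq->pq", sol[:, :, 1:], sol[:, :, 1:])
    sign, ld2 = np.linalg.slogdet(xtvix)
    if sign <= 0:
        return 1e12
    beta_term = xtviy @ np.linalg.solve(xtvix, xtviy)
    return logdet + ld2 + (ytviy - beta_term)


def fit_ace_component(
    y: np.ndarray,
    pedigree: PedigreeStructure,
    X: CovariateMatrix | np.ndarray | None = None,
) -> ACEComponentFit:
    """REML fit of (sigma2_A, sigma2_C, sigma2_E) for one trait component.

    Variances are bound-constrained to be nonnegative; a fit is flagged
    non-converged when the optimizer fails or when the pedigree carries no
    relatedness contrast (K_ped = I, Lambda = 0) that would identify the
    genetic component.
    """
    y = np.asarray(y, float).ravel()
    n = pedigree.n_samples
    if y.size != n:
        raise ValueError("trait length does not match pedigree")
    if X is None:
        Xv = np.ones((n, 1))
    else:
        Xv = X.X if isinstance(X, CovariateMatrix) else np.atleast_2d(np.asarray(X, float))
        if Xv.shape[0] != n:
            Xv = Xv.T
    K, Lam = pedigree.K_ped, pedigree.Lambda
    offdiag = K - np.diag(np.diag(K))
    identifiable = np.abs(offdiag).max() > 1e-12
    for M, name in ((K, "K_ped"), (Lam, "Lambda")):
        w = np.linalg.eigvalsh(M)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError(f"{name} is not positive semidefinite")

    vy = y.var()
    if vy <= 0:
        raise ValueError("constant trait; ACE model undefined")
    blocks = _family_blocks(y / np.sqrt(vy), K, Lam, Xv, pedigree.families)
    q = Xv.shape[1]

    # log-variance scale: the zero boundary maps to -inf, so degenerate
    # components drift to the lower bound instead of stalling the line search
    lo, hi = np.log(1e-8), np.log(10.0)

    def objective(u):
        return _reml_neg2ll(np.exp(u), blocks, q)

    best = None
    for x0 in ([0.3, 0.3, 0.4], [0.05, 0.05, 0.9], [0.8, 0.05, 0.15]):
        res = optimize.minimize(
            objective, x0=np.log(x0), args=(), method="L-BFGS-B",
            bounds=[(lo, hi)] * 3,
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = np.exp(best.x)
    theta[theta < 2e-8] = 0.0  # snap lower-bound components to the boundary
    sa, sc, se = theta * vy
    converged = bool(best.success) and best.fun < 1e11 and identifiable
    msg = "" if converged else ("no relatedness contrast; sigma2_A unidentifiable"
                                if not identifiable else str(best.message))
    return ACEComponentFit(
        sigma2_a=float(sa), sigma2_c=float(sc), sigma2_e=float(se),
        loglik=float(-0.5 * best.fun), converged=converged, message=msg,
    )


def combine_components(
    fits: list[ACEComponentFit],
    sigma_p_diag: np.ndarray | None = None,
) -> float:
    """Variance-weighted average of per-component heritabilities.

    Weights gamma_m are the per-component phenotypic variances divided by
    their total (pass ``sigma_p_diag`` to override the fitted variances),
    so the combined value is the trace-ratio heritability of the
    multidimensional trait. Non-converged fits are excluded.
    """
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError("no converged component fits to combine")
    if sigma_p_diag is None:
        var = np.array([f.sigma2_p for f in ok])
    else:
        sigma_p_diag = np.asarray(sigma_p_diag, float)
        if sigma_p_diag.size != len(fits):
            raise ValueError("sigma_p_diag length does not match number of fits")
        var = sigma_p_diag[[i for i, f in enumerate(fits) if f.converged]]
    gamma = var / var.sum()
    return float(np.sum(gamma * np.array([f.h2 for f in ok])))


def block_bootstrap_se(
    Y: TraitMatrix | np.ndarray,
    pedigree: PedigreeStructure,
    X: CovariateMatrix | np.ndarray | None = None,
    n_boots: int = 1000,
    seed: int = 0,
) -> tuple[float, int]:
    """Family-block bootstrap s.e. of the combined ACE heritability.

    Families are resampled with replacement to the original family count
    (members move together, preserving within-family correlation); the full
    per-component REML + combination is re-run on each replicate and the
    sd over replicates returned, together with the number of replicates
    dropped for non-convergence.
    """
    if n_boots < 2:
        raise ValueError("n_boots must be >= 2")
    Yv = Y.Y if isinstance(Y, TraitMatrix) else np.atleast_2d(np.asarray(Y, float))
    if Yv.shape[0] != pedigree.n_samples:
        Yv = Yv.T
    fam_groups = list(pedigree.families.values())
    if len(fam_groups) < 2:
        raise ValueError("block bootstrap needs at least 2 families")
    Xv = None if X is None else (X.X if isinstance(X, CovariateMatrix) else np.asarray(X, float))
    rng = np.random.default_rng(seed)
    estimates = []
    dropped = 0
    for _ in range(n_boots):
        pick = rng.integers(0, len(fam_groups), size=len(fam_groups))
        idx = np.concatenate([fam_groups[j] for j in pick])
        fam_ids = np.concatenate(
            [np.full(len(fam_groups[j]), f"b{i}") for i, j in enumerate(pick)]
        )
        ped_b = PedigreeStructure(
            sample_ids=[f"s{i}" for i in range(len(idx))],
            family_ids=list(fam_ids),
            zygosity=[pedigree.zygosity[k] for k in idx],
        )
        Xb = None if Xv is None else Xv[idx]
        try:
            fits = [fit_ace_component(Yv[idx, m], ped_b, Xb) for m in range(Yv.shape[1])]
            estimates.append(combine_components(fits))
        except ValueError:
            dropped += 1
    if len(estimates) < 2:
        raise ValueError("too few converged bootstrap replicates")
    return float(np.std(estimates, ddof=1)), dropped


class ACEHeritability(BaseEstimator):
    """Combined ACE heritability of a multidimensional trait in a family design.

    Fits a univariate ACE model per trait component by blockwise REML,
    combines with variance weights, and (optionally) attaches a
    family-block bootstrap standard error.

    Attributes (after ``fit``): ``component_fits_``, ``h2_``,
    ``bootstrap_se_`` (if ``n_boots > 0``), ``n_dropped_boots_``.
    """

    def __init__(self, n_boots: int = 0, random_state: int | None = None):
        self.n_boots = n_boots
        self.random_state = random_state

    def fit(
        self,
        Y: TraitMatrix | np.ndarray,
        pedigree: PedigreeStructure,
        covariates: CovariateMatrix | np.ndarray | None = None,
    ) -> "ACEHeritability":
        Yv = Y.Y if isinstance(Y, TraitMatrix) else np.atleast_2d(np.asarray(Y, float))
        if Yv.shape[0] != pedigree.n_samples:
            Yv = Yv.T
        self.component_fits_ = [
            fit_ace_component(Yv[:, m], pedigree, covariates)
            for m in range(Yv.shape[1])
        ]
        self.h2_ = combine_components(self.component_fits_)
        if self.n_boots:
            self.bootstrap_se_, self.n_dropped_boots_ = block_bootstrap_se(
                Yv, pedigree, covariates,
                n_boots=self.n_boots, seed=self.random_state or 0,
            )
        return self
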