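"""Moment-matching heritability estimation for multidimensional traits.

Model
-----
An N x M trait matrix Y observed on nominally unrelated samples is modelled
as Y = G + E with

    vec(G) ~ N(0, Sigma_A  (x)  K),     vec(E) ~ N(0, Sigma_E  (x)  I),

where K is the empirical genetic similarity matrix, Sigma_A the M x M
genetic covariance across trait components, and Sigma_E the unique
environmental covariance. Heritability of the multidimensional trait is
defined as the trace ratio

    h2 = tr[Sigma_A] / tr[Sigma_A + Sigma_E],

which is invariant to orthogonal rotations of the trait components and
equals the variance-weighted average of the per-component heritabilities.

Estimation
----------
Regressing the empirical cross-product y_r y_s' elementwise on (K, I) and
solving the normal equations in closed form gives unbiased moment
estimators (a multivariate generalization of Haseman-Elston regression):

    Sigma_A = Y'(K - kbar I)Y / v_K,   Sigma_E = Y'(kappa I - kbar K)Y / v_K,

with kbar = tr[K]/N, kappa = tr[K^2]/N and v_K = tr[K^2] - tr^2[K]/N.
Covariates are removed beforehand by projecting data and K onto the
(N - q)-dimensional null space of the covariate matrix.

The delta-method sampling variance (assuming small off-diagonal relatedness
and a well-estimated phenotypic covariance) is

    var(h2) ~= (2 / v_K) * tr[Sigma_P^2] / tr^2[Sigma_P],

which depends only on the sample size (through v_K) and the phenotypic
correlation structure; for a scalar trait it reduces to 2 / v_K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space
from sklearn.base import BaseEstimator

from .grm import GeneticSimilarity

__all__ = [
    "TraitMatrix",
    "CovariateMatrix",
    "ProjectedData",
    "CovarianceDecomposition",
    "HeritabilityHE",
    "project_out_covariates",
    "fit_moment_matching",
    "sampling_variance",
    "trait_reliability",
]

# relative tolerance below which the relatedness contrast v_K is treated as zero
V_K_RTOL = 1e-8


@dataclass
class TraitMatrix:
    """N x M phenotype matrix with sample IDs and trait names."""

    Y: np.ndarray
    sample_ids: list[str]
    trait_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.Y.shape[0] == 1 and len(self.sample_ids) > 1:
            self.Y = self.Y.T
        if self.Y.shape[0] != len(self.sample_ids):
            raise ValueError("trait rows do not match sample IDs")
        if not np.isfinite(self.Y).all():
            raise ValueError("trait matrix contains non-finite values")
        if self.trait_names is None:
            self.trait_names = [f"t{m + 1}" for m in range(self.Y.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.Y.shape[0]

    @property
    def n_traits(self) -> int:
        return self.Y.shape[1]


@dataclass
class CovariateMatrix:
    """N x q full-column-rank covariate matrix (include an intercept column)."""

    X: np.ndarray
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] == 1:
            self.X = self.X.T
        if self.names is None:
            self.names = [f"x{j + 1}" for j in range(self.X.shape[1])]
        r = np.linalg.matrix_rank(self.X)
        if r < self.X.shape[1]:
            # pivoted QR identifies a maximal independent set; rest are collinear
            from scipy.linalg import qr

            _, _, piv = qr(self.X, pivoting=True)
            bad = [self.names[j] for j in piv[r:]]
            raise ValueError(f"covariate matrix is rank deficient; collinear columns: {bad}")

    @property
    def q(self) -> int:
        return self.X.shape[1]


@dataclass
class ProjectedData:
    """Trait and similarity matrices after covariate projection."""

    Y: np.ndarray  # (N - q) x M
    K: np.ndarray  # (N - q) x (N - q)
    dof: int  # N - q

    @property
    def n_traits(self) -> int:
        return self.Y.shape[1]


@dataclass
class CovarianceDecomposition:
    """Estimated genetic/environmental covariances and the trace-ratio h2."""

    Sigma_A: np.ndarray
    Sigma_E: np.ndarray
    t_A: float
    t_E: float
    t_P: float
    h2: float  # clamped to [0, 1]
    h2_raw: float  # unclamped moment estimate, used for inference
    k_bar: float
    kappa: float
    v_K: float
    se: float | None = None


# ---------------------------------------------------------------------------


def _null_space_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal N x (N - q) basis U with U'X = 0 and U U' = I - X(X'X)^-1 X'."""
    U = null_space(X.T)
    if U.shape[1] != X.shape[0] - X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    return U


def project_out_covariates(
    Y: TraitMatrix | np.ndarray,
    K: GeneticSimilarity | np.ndarray,
    X: CovariateMatrix | np.ndarray | None = None,
) -> ProjectedData:
    """Remove fixed-effect covariates by projection onto their null space.

    Returns Y~ = U'Y and K~ = U'KU for an orthonormal basis U of the null
    space of X'. Downstream heritability estimates are invariant to the
    basis choice. With ``X=None`` the data pass through unchanged.
    """
    Yv = Y.Y if isinstance(Y, TraitMatrix) else np.atleast_2d(np.asarray(Y, float))
    if Yv.ndim == 2 and Yv.shape[0] == 1:
        Yv = Yv.T
    Kv = K.K if isinstance(K, GeneticSimilarity) else np.asarray(K, float)
    if Yv.shape[0] != Kv.shape[0]:
        raise ValueError("trait matrix and K have different sample counts")
    if X is None:
        return ProjectedData(Y=Yv, K=Kv, dof=Yv.shape[0])
    Xv = X.X if isinstance(X, CovariateMatrix) else np.asarray(X, float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    if Xv.shape[1] == 0:
        return ProjectedData(Y=Yv, K=Kv, dof=Yv.shape[0])
    if not isinstance(X, CovariateMatrix):
        X = CovariateMatrix(Xv)  # validates rank, names collinear columns
    U = _null_space_basis(X.X)
    return ProjectedData(Y=U.T @ Yv, K=U.T @ Kv @ U, dof=U.shape[1])


def fit_moment_matching(P: ProjectedData) -> CovarianceDecomposition:
    """Closed-form moment (Haseman-Elston) fit of Sigma_A, Sigma_E and h2.

    Raises ``ValueError`` when the similarity matrix carries no relatedness
    contrast (v_K ~ 0, e.g. K proportional to I), in which case the
    regression of cross-products on (K, I) is singular.
    """
    Yv, Kv, n = P.Y, P.K, P.dof
    tr_K = float(np.trace(Kv))
    tr_K2 = float(np.sum(Kv * Kv))  # tr[K^2] for symmetric K
    k_bar = tr_K / n
    kappa = tr_K2 / n
    v_K = tr_K2 - tr_K**2 / n
    if v_K <= V_K_RTOL * n * kappa:
        raise ValueError(
            "estimator undefined: v_K = tr[K^2] - tr^2[K]/N is (numerically) zero; "
            "the similarity matrix has no relatedness contrast"
        )
    KY = Kv @ Yv
    YtKY = Yv.T @ KY
    YtY = Yv.T @ Yv
    Sigma_A = (YtKY - k_bar * YtY) / v_K
    Sigma_E = (kappa * YtY - k_bar * YtKY) / v_K
    Sigma_A = (Sigma_A + Sigma_A.T) / 2
    Sigma_E = (Sigma_E + Sigma_E.T) / 2
    t_A = float(np.trace(Sigma_A))
    t_E = float(np.trace(Sigma_E))
    t_P = t_A + t_E
    if t_P <= 0:
        raise ValueError("total phenotypic variance estimate is nonpositive")
    h2_raw = t_A / t_P
    return CovarianceDecomposition(
        Sigma_A=Sigma_A,
        Sigma_E=Sigma_E,
        t_A=t_A,
        t_E=t_E,
        t_P=t_P,
        h2=float(np.clip(h2_raw, 0.0, 1.0)),
        h2_raw=h2_raw,
        k_bar=k_bar,
        kappa=kappa,
        v_K=v_K,
    )


def sampling_variance(P: ProjectedData, D: CovarianceDecomposition) -> float:
    """Delta-method standard error of the trace-ratio heritability.

    var(h2) ~= (2 / v_K) * tr[Sigma_P^2] / tr^2[Sigma_P], with Sigma_P
    replaced by its moment estimate Sigma_A + Sigma_E. Given K, this
    depends only on the sample size and the phenotypic correlation
    structure, not on the heritability point estimate. With eigenvalues
    lambda_m of Sigma_P, tr[Sigma_P^2]/tr^2[Sigma_P] = sum lambda^2 /
    (sum lambda)^2 <= 1, with equality iff the M components are perfectly
    correlated — combining components can only reduce the variance.
    """
    if D.t_P <= 0:
        raise ValueError("degenerate phenotypic variance")
    Sigma_P = D.Sigma_A + D.Sigma_E
    ratio = float(np.sum(Sigma_P * Sigma_P)) / D.t_P**2
    return float(np.sqrt(2.0 * ratio / D.v_K))


def trait_reliability(y_test: np.ndarray, y_retest: np.ndarray) -> float:
    """Lin's concordance correlation coefficient between paired measurements.

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2), using
    1/n moment estimates. For multidimensional descriptors, apply per
    component and average.
    """
    x = np.asarray(y_test, float).ravel()
    y = np.asarray(y_retest, float).ravel()
    if x.shape != y.shape or x.size < 3:
        raise ValueError("paired vectors of equal length >= 3 required")
    vx, vy = x.var(), y.var()
    denom = vx + vy + (x.mean() - y.mean()) ** 2
    if denom <= 0:
        raise ValueError("zero total variance; concordance undefined")
    cxy = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * cxy / denom)


# ---------------------------------------------------------------------------


class HeritabilityHE(BaseEstimator):
    """Moment-matching SNP heritability estimator for multidimensional traits.

    Fits the multivariate variance-component model Y = G + E on unrelated
    samples by Haseman-Elston-type regression of trait cross-products on
    the genetic similarity matrix, after projecting out covariates.

    Parameters
    ----------
    n_permutations : int
        Number of permutations for the nonparametric p value; 0 disables
        permutation inference (the Wald p is always computed).
    random_state : int or None
        Seed for the permutation RNG.

    Attributes
    ----------
    sigma_a_ : (M, M) ndarray — genetic covariance estimate.
    sigma_e_ : (M, M) ndarray — environmental covariance estimate.
    h2_ : float — trace-ratio heritability, clamped to [0, 1].
    h2_raw_ : float — unclamped moment estimate (used by the tests).
    se_ : float — delta-method standard error.
    p_wald_ : float — boundary-null (half-half chi-square mixture) p value.
    p_perm_ : float — permutation p value (if n_permutations > 0).
    decomposition_ : CovarianceDecomposition with traces and K summaries.
    """

    def __init__(self, n_permutations: int = 0, random_state: int | None = None):
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(
        self,
        Y: TraitMatrix | np.ndarray,
        K: GeneticSimilarity | np.ndarray,
        covariates: CovariateMatrix | np.ndarray | None = None,
    ) -> "HeritabilityHE":
        from . import inference

        P = project_out_covariates(Y, K, covariates)
        D = fit_moment_matching(P)
        D.se = sampling_variance(P, D)
        self.projected_ = P
        self.decomposition_ = D
        self.sigma_a_ = D.Sigma_A
        self.sigma_e_ = D.Sigma_E
        self.h2_ = D.h2
        self.h2_raw_ = D.h2_raw
        self.se_ = D.se
        self.p_wald_ = inference.wald_test(D.h2_raw, D.se).p_wald
        if self.n_permutations:
            res = inference.permutation_test(
                P, n_perm=self.n_permutations, seed=self.random_state or 0
            )
            self.p_perm_ = res.p_perm
        return self

    def score(self, *args, **kwargs) -> float:  # pragma: no cover - sklearn API shim
        return self.h2_
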