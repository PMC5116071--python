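"""Principal modes of shape variation and their heritability.

Because the trace-ratio heritability of a multidimensional trait is
invariant to rotations and equals a variance-weighted average of
per-component heritabilities, PCA — a pure rotation of the
(covariate-residualized) descriptors — gives an equivalent decomposition:
the variance-weighted average of per-PC heritabilities reproduces the
multivariate estimate exactly, and the first PC carries the greatest
shape variation and hence the largest weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .estimator import (
    CovariateMatrix,
    ProjectedData,
    TraitMatrix,
    fit_moment_matching,
    project_out_covariates,
    sampling_variance,
)
from .grm import GeneticSimilarity

__all__ = ["PCDecomposition", "ShapePCHeritability", "decompose", "pc_heritability"]


@dataclass
class PCDecomposition:
    """Rotation of the residualized descriptors into principal components."""

    loadings: np.ndarray  # M x M orthonormal columns
    scores: np.ndarray  # (N - q) x M, in the projected sample space
    variance_explained: np.ndarray  # descending, sums to 1
    rank_deficient: bool = False
    per_pc_h2: np.ndarray | None = None
    per_pc_se: np.ndarray | None = None
    combined_h2: float | None = None


def decompose(
    Y: TraitMatrix | np.ndarray,
    K: GeneticSimilarity | np.ndarray | None = None,
    covariates: CovariateMatrix | np.ndarray | None = None,
) -> PCDecomposition:
    """PCA of covariate-residualized descriptors.

    With no covariates given, an intercept (mean-centering) is used. The
    decomposition is computed from the cross-product of the projected data
    so that it is a pure rotation of the matrix entering heritability
    estimation; ``K`` is only used for sample alignment and may be omitted.
    """
    Yv = Y.Y if isinstance(Y, TraitMatrix) else np.atleast_2d(np.asarray(Y, float))
    n = Yv.shape[0]
    if covariates is None:
        covariates = np.ones((n, 1))
    Kv = np.eye(n) if K is None else (K.K if isinstance(K, GeneticSimilarity) else K)
    P = project_out_covariates(Yv, Kv, covariates)
    if P.dof <= P.n_traits:
        raise ValueError("need more samples than trait dimensions after residualization")
    C = (P.Y.T @ P.Y) / P.dof
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    rank_deficient = bool((vals <= 1e-12 * max(vals[0], 1e-300)).any())
    ve = np.clip(vals, 0.0, None)
    return PCDecomposition(
        loadings=vecs,
        scores=P.Y @ vecs,
        variance_explained=ve / ve.sum(),
        rank_deficient=rank_deficient,
    )


def pc_heritability(
    Y: TraitMatrix | np.ndarray,
    K: GeneticSimilarity | np.ndarray,
    covariates: CovariateMatrix | np.ndarray | None = None,
) -> PCDecomposition:
    """Per-PC heritability plus the variance-weighted combination.

    The weighted average over all PCs equals the multivariate trace-ratio
    estimate of the original descriptor (rotation invariance), an identity
    that holds to numerical precision on any input.
    """
    Yv = Y.Y if isinstance(Y, TraitMatrix) else np.atleast_2d(np.asarray(Y, float))
    Kv = K.K if isinstance(K, GeneticSimilarity) else np.asarray(K, float)
    if covariates is None:
        covariates = np.ones((Yv.shape[0], 1))
    P = project_out_covariates(Yv, Kv, covariates)
    dec = decompose(Yv, Kv, covariates)
    scores = dec.scores
    h2 = np.empty(scores.shape[1])
    se = np.empty(scores.shape[1])
    weights = np.empty(scores.shape[1])
    for m in range(scores.shape[1]):
        Pm = ProjectedData(Y=scores[:, m:m + 1], K=P.K, dof=P.dof)
        Dm = fit_moment_matching(Pm)
        h2[m] = Dm.h2_raw
        se[m] = sampling_variance(Pm, Dm)
        weights[m] = Dm.t_P
    dec.per_pc_h2 = h2
    dec.per_pc_se = se
    dec.combined_h2 = float(np.sum(weights / weights.sum() * h2))
    return dec


class ShapePCHeritability(BaseEstimator):
    """Principal-component heritability decomposition of a shape descriptor.

    Attributes (after ``fit``): ``loadings_``, ``scores_``,
    ``variance_explained_``, ``per_pc_h2_``, ``per_pc_se_``,
    ``combined_h2_`` (equals the multivariate estimate).
    """

    def fit(
        self,
        Y: TraitMatrix | np.ndarray,
        K: GeneticSimilarity | np.ndarray,
        covariates: CovariateMatrix | np.ndarray | None = None,
    ) -> "ShapePCHeritability":
        dec = pc_heritability(Y, K, covariates)
        self.decomposition_ = dec
        self.loadings_ = dec.loadings
        self.scores_ = dec.scores
        self.variance_explained_ = dec.variance_explained
        self.per_pc_h2_ = dec.per_pc_h2
        self.per_pc_se_ = dec.per_pc_se
        self.combined_h2_ = dec.combined_h2
        return self

    def transform(self, Y: np.ndarray) -> np.ndarray:
        return np.asarray(Y, float) @ self.loadings_
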