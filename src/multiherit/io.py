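"""Delimited-table I/O for phenotypes, covariates and pedigrees.

All tables are whitespace/comma-delimited text with a header row and the
sample ID in the first column. Lines starting with '#' are provenance
headers and are skipped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ace import PedigreeStructure
from .estimator import CovariateMatrix, TraitMatrix
from .grm import GeneticSimilarity

__all__ = [
    "read_trait_table",
    "read_covariate_table",
    "read_pedigree_table",
    "align_samples",
]


def _read(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return df


def read_trait_table(path: str) -> TraitMatrix:
    df = _read(path)
    return TraitMatrix(
        Y=df.to_numpy(float), sample_ids=list(df.index), trait_names=list(df.columns)
    )


def read_covariate_table(path: str, add_intercept: bool = True) -> tuple[list[str], CovariateMatrix]:
    df = _read(path)
    X = df.to_numpy(float)
    names = list(df.columns)
    if add_intercept:
        X = np.column_stack([np.ones(len(df)), X])
        names = ["intercept"] + names
    return list(df.index), CovariateMatrix(X=X, names=names)


def read_pedigree_table(path: str) -> PedigreeStructure:
    return PedigreeStructure.from_table(_read(path).reset_index())


def align_samples(
    K: GeneticSimilarity,
    Y: TraitMatrix,
    covar_ids: list[str] | None = None,
    X: CovariateMatrix | None = None,
):
    """Intersect samples by ID and return (K, Y, X) in a common order.

    Phenotype rows with missing values are dropped listwise beforehand by
    the table readers' validation (TraitMatrix admits no NaNs).
    """
    common = [s for s in K.sample_ids if s in set(Y.sample_ids)]
    if X is not None and covar_ids is not None:
        cset = set(covar_ids)
        common = [s for s in common if s in cset]
    if len(common) < 3:
        raise ValueError("fewer than 3 samples shared between inputs")
    kpos = {s: i for i, s in enumerate(K.sample_ids)}
    ypos = {s: i for i, s in enumerate(Y.sample_ids)}
    ki = [kpos[s] for s in common]
    yi = [ypos[s] for s in common]
    K2 = GeneticSimilarity(
        K=K.K[np.ix_(ki, ki)], sample_ids=common, source=K.source,
        n_variants=K.n_variants,
    )
    Y2 = TraitMatrix(Y=Y.Y[yi], sample_ids=common, trait_names=Y.trait_names)
    X2 = None
    if X is not None and covar_ids is not None:
        xpos = {s: i for i, s in enumerate(covar_ids)}
        X2 = CovariateMatrix(X=X.X[[xpos[s] for s in common]], names=X.names)
    return K2, Y2, X2
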