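"""Synthetic data with known ground truth for every analysis mode.

Generators for SNP genotype panels (independent sites, binomial dosages),
multivariate traits drawn from the variance-component model
vec(Y) ~ N(0, Sigma_A (x) K + Sigma_C (x) Lambda + Sigma_E (x) I),
twin/sibling pedigree designs, and analytic test meshes (icosphere,
ellipsoid, box) with known volume and — for the sphere — known spectrum.
Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .ace import PedigreeStructure
from .estimator import TraitMatrix
from .grm import GenotypeMatrix, GeneticSimilarity, Variant

__all__ = [
    "SimulationSpec",
    "simulate_genotypes",
    "simulate_traits",
    "simulate_pedigree",
    "make_test_mesh",
]


@dataclass
class SimulationSpec:
    """Study-design parameters for the generators.

    ``Sigma_A/Sigma_C/Sigma_E`` are M x M (scalars accepted for M = 1); the
    implied true heritability is tr[Sigma_A] / tr[Sigma_A+Sigma_C+Sigma_E].
    ``pedigree_design`` counts families by type: (n_mz_pairs, n_dz_pairs,
    n_sib_pairs, n_singletons).
    """

    n_samples: int = 500
    n_snps: int = 5000
    n_traits: int = 1
    Sigma_A: np.ndarray | float = 0.5
    Sigma_C: np.ndarray | float = 0.0
    Sigma_E: np.ndarray | float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    pedigree_design: tuple[int, int, int, int] = (100, 100, 0, 0)
    seed: int = 0

    def _mat(self, S) -> np.ndarray:
        S = np.atleast_2d(np.asarray(S, float))
        if S.shape == (1, 1) and self.n_traits > 1:
            S = S[0, 0] * np.eye(self.n_traits)
        if S.shape != (self.n_traits, self.n_traits):
            raise ValueError(f"covariance shape {S.shape} != M={self.n_traits}")
        if not np.allclose(S, S.T):
            raise ValueError("covariance not symmetric")
        if np.linalg.eigvalsh(S).min() < -1e-10:
            raise ValueError("covariance not positive semidefinite")
        return S

    @property
    def true_h2(self) -> float:
        tA = np.trace(self._mat(self.Sigma_A))
        tot = tA + np.trace(self._mat(self.Sigma_C)) + np.trace(self._mat(self.Sigma_E))
        return float(tA / tot)


def simulate_genotypes(spec: SimulationSpec, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Independent biallelic sites: dosage ~ Binomial(2, p_s), p_s ~ U(maf_range)."""
    lo, hi = spec.maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    p = rng.uniform(lo, hi, size=spec.n_snps)
    dosages = rng.binomial(2, p, size=(spec.n_samples, spec.n_snps)).astype(np.int8)
    variants = [
        Variant(id=f"snp{j + 1}", chromosome="1", position=1000 * (j + 1))
        for j in range(spec.n_snps)
    ]
    samples = [f"s{i + 1}" for i in range(spec.n_samples)]
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def _sqrt_psd(S: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root, clipping tiny negative eigenvalues."""
    w, v = np.linalg.eigh(S)
    if w.min() < -1e-8 * max(abs(w.max()), 1.0):
        raise ValueError("matrix is not positive semidefinite")
    return v * np.sqrt(np.clip(w, 0.0, None)) @ v.T


def simulate_traits(
    K: GeneticSimilarity | np.ndarray,
    spec: SimulationSpec,
    Lambda: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> TraitMatrix:
    """Draw Y with vec(Y) ~ N(0, Sigma_A(x)K + Sigma_C(x)Lambda + Sigma_E(x)I).

    Sampled matrix-normal term by term as L_K Z L_Sigma' (Kronecker
    factorization), never assembling the NM x NM covariance.
    """
    Kv = K.K if isinstance(K, GeneticSimilarity) else np.asarray(K, float)
    ids = K.sample_ids if isinstance(K, GeneticSimilarity) else [
        f"s{i + 1}" for i in range(Kv.shape[0])
    ]
    n, m = Kv.shape[0], spec.n_traits
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    SA = spec._mat(spec.Sigma_A)
    SC = spec._mat(spec.Sigma_C)
    SE = spec._mat(spec.Sigma_E)

    LK = _sqrt_psd(Kv)
    Y = (LK @ rng.standard_normal((n, m))) @ _sqrt_psd(SA).T
    if np.trace(SC) > 0:
        if Lambda is None:
            raise ValueError("Sigma_C > 0 requires a household matrix Lambda")
        Y += (_sqrt_psd(np.asarray(Lambda, float)) @ rng.standard_normal((n, m))) @ _sqrt_psd(SC).T
    Y += rng.standard_normal((n, m)) @ _sqrt_psd(SE).T
    return TraitMatrix(Y=Y, sample_ids=list(ids))


def simulate_pedigree(spec: SimulationSpec) -> PedigreeStructure:
    """Twin/sibling family structure from ``spec.pedigree_design`` counts."""
    n_mz, n_dz, n_sib, n_single = spec.pedigree_design
    samples, families, zyg = [], [], []
    fam = 0
    for _ in range(n_mz):
        fam += 1
        for _ in range(2):
            samples.append(f"s{len(samples) + 1}")
            families.append(f"f{fam}")
            zyg.append("MZ")
    for _ in range(n_dz):
        fam += 1
        for _ in range(2):
            samples.append(f"s{len(samples) + 1}")
            families.append(f"f{fam}")
            zyg.append("DZ")
    for _ in range(n_sib):
        fam += 1
        for _ in range(2):
            samples.append(f"s{len(samples) + 1}")
            families.append(f"f{fam}")
            zyg.append("SIB")
    for _ in range(n_single):
        fam += 1
        samples.append(f"s{len(samples) + 1}")
        families.append(f"f{fam}")
        zyg.append("SINGLETON")
    if not samples:
        raise ValueError("empty pedigree design")
    return PedigreeStructure(sample_ids=samples, family_ids=families, zygosity=zyg)


def make_test_mesh(
    shape: str = "sphere",
    scale: float | tuple[float, float, float] = 1.0,
    refinement: int = 3,
) -> trimesh.Trimesh:
    """Watertight analytic meshes with known volume.

    'sphere': icosphere of given radius (10*4^r + 2 vertices at refinement
    r); 'ellipsoid': icosphere stretched by per-axis scales; 'cube':
    axis-aligned box with edge length ``scale``.
    """
    if refinement < 0:
        raise ValueError("refinement must be >= 0")
    if shape == "sphere":
        return trimesh.creation.icosphere(subdivisions=refinement, radius=float(scale))
    if shape == "ellipsoid":
        axes = (scale,) * 3 if np.isscalar(scale) else tuple(scale)
        m = trimesh.creation.icosphere(subdivisions=refinement, radius=1.0)
        m.vertices *= np.asarray(axes)
        return m
    if shape == "cube":
        edge = float(scale)
        m = trimesh.creation.box(extents=(edge, edge, edge))
        for _ in range(refinement):
            m = m.subdivide()
        return m
    raise ValueError(f"unknown shape {shape!r}; expected sphere/ellipsoid/cube")
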