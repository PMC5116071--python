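"""Genetic relationship (similarity) matrices from SNP genotypes.

Builds the allele-frequency standardized GRM used by SNP heritability
analyses of unrelated samples, with the usual per-variant quality-control
filters (call rate, minor allele frequency, Hardy-Weinberg equilibrium)
applied beforehand, plus readers/writers for the GCTA binary GRM dialect
and plain-text square matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "GeneticSimilarity",
    "Variant",
    "hwe_exact_test",
    "qc_filter",
    "compute_grm",
    "grm_principal_components",
    "read_grm",
    "write_grm",
]

MISSING = -9  # missing dosage marker


@dataclass(frozen=True)
class Variant:
    id: str
    chromosome: str = "1"
    position: int = 0
    allele1: str = "A"  # counted allele
    allele2: str = "B"


@dataclass
class GenotypeMatrix:
    """N x S matrix of counted-allele dosages in {0, 1, 2}, missing = -9.

    Rows are samples, columns variants.
    """

    samples: list[str]
    variants: list[Variant]
    dosages: np.ndarray  # int8/int16, N x S

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        n, s = self.dosages.shape
        if n != len(self.samples):
            raise ValueError(
                f"dosage rows ({n}) != number of samples ({len(self.samples)})"
            )
        if s != len(self.variants):
            raise ValueError(
                f"dosage columns ({s}) != number of variants ({len(self.variants)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample IDs are not unique")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"invalid dosage values {bad}; expected 0/1/2/{MISSING}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class GeneticSimilarity:
    """Symmetric N x N genetic similarity matrix with sample IDs.

    ``source`` is 'empirical' for SNP-based GRMs and 'pedigree' for
    kinship-derived (2*Phi) matrices.
    """

    K: np.ndarray
    sample_ids: list[str]
    source: str = "empirical"
    n_variants: int | None = None

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 2 or self.K.shape[0] != self.K.shape[1]:
            raise ValueError("K must be square")
        if self.K.shape[0] != len(self.sample_ids):
            raise ValueError("K dimension does not match number of sample IDs")
        if not np.allclose(self.K, self.K.T, atol=1e-8):
            raise ValueError("K is not symmetric")
        if np.trace(self.K) <= 0:
            raise ValueError("tr[K] must be positive")

    @property
    def n_samples(self) -> int:
        return self.K.shape[0]


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int, midp: bool = True) -> float:
    """Exact Hardy-Weinberg equilibrium test on genotype counts.

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts (Levene-Haldane) and returns the two-sided exact p
    (probability of configurations no more likely than the observed one).
    ``midp`` applies the mid-p correction (half the observed configuration's
    probability), which is better calibrated at low counts.
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0

    # log-probabilities of all heterozygote counts with the observed parity
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    from scipy.special import gammaln

    n_common = 2 * n - n_rare
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln((n_rare - hets) // 2 + 1)
        - gammaln((n_common - hets) // 2 + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(n_common + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = np.searchsorted(hets, n_het)
    p_obs = p[obs]
    tail = p[p <= p_obs * (1 + 1e-12)].sum()
    if midp:
        tail -= 0.5 * p_obs
    return float(min(tail, 1.0))


# ---------------------------------------------------------------------------
# QC and GRM construction


def qc_filter(
    g: GenotypeMatrix,
    call_rate_min: float = 0.97,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
) -> GenotypeMatrix:
    """Drop variants failing call-rate, MAF or HWE thresholds.

    The sample set is unchanged. Raises ``ValueError`` if every variant is
    removed, or if any threshold is outside [0, 1].
    """
    for name, t in (
        ("call_rate_min", call_rate_min),
        ("maf_min", maf_min),
        ("hwe_p_min", hwe_p_min),
    ):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")

    d = g.dosages
    observed = d != MISSING
    n_obs = observed.sum(axis=0)
    call_rate = n_obs / d.shape[0]

    with np.errstate(invalid="ignore"):
        freq = np.where(n_obs > 0, np.where(observed, d, 0).sum(axis=0) / (2 * n_obs), 0.0)
    maf = np.minimum(freq, 1.0 - freq)

    keep = (call_rate >= call_rate_min) & (maf >= maf_min)
    # HWE only needs testing on variants still in play
    for j in np.flatnonzero(keep):
        col = d[observed[:, j], j]
        n_het = int((col == 1).sum())
        n_hom1 = int((col == 2).sum())
        n_hom2 = int((col == 0).sum())
        if hwe_exact_test(n_het, n_hom1, n_hom2) < hwe_p_min:
            keep[j] = False

    if not keep.any():
        raise ValueError("QC removed all variants")
    idx = np.flatnonzero(keep)
    return GenotypeMatrix(
        samples=list(g.samples),
        variants=[g.variants[j] for j in idx],
        dosages=d[:, idx].copy(),
    )


def compute_grm(g: GenotypeMatrix) -> GeneticSimilarity:
    """Allele-frequency standardized GRM.

    K_ij = (1/S) * sum_s (x_is - 2 p_s)(x_js - 2 p_s) / (2 p_s (1 - p_s))
    with p_s the in-sample allele frequency of the counted allele. Missing
    genotypes are mean-imputed per variant before standardization, so they
    contribute zero to the cross-products.
    """
    if g.n_samples < 2:
        raise ValueError("GRM needs at least 2 samples")
    d = g.dosages.astype(float)
    observed = d != MISSING
    n_obs = observed.sum(axis=0)
    if (n_obs == 0).any():
        raise ValueError("variant with no observed genotypes")
    freq = np.where(observed, d, 0.0).sum(axis=0) / (2 * n_obs)
    mono = (freq <= 0) | (freq >= 1)
    if mono.any():
        ids = [g.variants[j].id for j in np.flatnonzero(mono)[:5]]
        raise ValueError(f"monomorphic variants (zero variance), e.g. {ids}")

    z = np.where(observed, d, 2 * freq)  # mean imputation
    z = (z - 2 * freq) / np.sqrt(2 * freq * (1 - freq))
    K = (z @ z.T) / g.n_variants
    K = (K + K.T) / 2.0
    return GeneticSimilarity(K=K, sample_ids=list(g.samples), source="empirical",
                             n_variants=g.n_variants)


def grm_principal_components(K: GeneticSimilarity, n_pc: int) -> np.ndarray:
    """Top eigenvectors of K (unit norm, descending eigenvalue order).

    Used as ancestry/stratification covariates.
    """
    n = K.n_samples
    if not 0 < n_pc < n:
        raise ValueError(f"n_pc must be in [1, {n - 1}], got {n_pc}")
    vals, vecs = np.linalg.eigh(K.K)
    order = np.argsort(vals)[::-1][:n_pc]
    return vecs[:, order]


# ---------------------------------------------------------------------------
# GCTA binary GRM and plain-text I/O


def write_grm(K: GeneticSimilarity, prefix: str) -> None:
    """Write GCTA binary GRM: ``prefix.grm.bin`` (lower triangle incl.
    diagonal, row-major, float32), ``prefix.grm.id`` (FID IID per line) and
    ``prefix.grm.N.bin`` (per-pair variant count, float32)."""
    n = K.n_samples
    tril = np.tril_indices(n)
    vals = K.K[tril].astype("<f4")
    vals.tofile(f"{prefix}.grm.bin")
    nv = float(K.n_variants if K.n_variants is not None else 0)
    np.full(vals.shape, nv, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for sid in K.sample_ids:
            fh.write(f"{sid}\t{sid}\n")


def read_grm(prefix: str) -> GeneticSimilarity:
    """Read a GCTA binary GRM written by :func:`write_grm` or GCTA itself."""
    with open(f"{prefix}.grm.id") as fh:
        ids = [line.split()[1] for line in fh if line.strip()]
    n = len(ids)
    vals = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    expected = n * (n + 1) // 2
    if vals.size != expected:
        raise ValueError(
            f"{prefix}.grm.bin has {vals.size} elements; "
            f"{expected} expected for {n} samples in {prefix}.grm.id"
        )
    K = np.zeros((n, n))
    K[np.tril_indices(n)] = vals
    K = K + np.tril(K, -1).T
    n_variants: int | None = None
    try:
        nv = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
        if nv.size == expected and nv[0] > 0:
            n_variants = int(nv[0])
    except FileNotFoundError:
        pass
    return GeneticSimilarity(K=K, sample_ids=ids, source="empirical",
                             n_variants=n_variants)


def write_grm_text(K: GeneticSimilarity, path: str, sep: str = "\t") -> None:
    """Plain-text square matrix with an ID header column."""
    with open(path, "w") as fh:
        fh.write("id" + sep + sep.join(K.sample_ids) + "\n")
        for sid, row in zip(K.sample_ids, K.K):
            fh.write(sid + sep + sep.join(f"{v:.10g}" for v in row) + "\n")


def read_grm_text(path: str, source: str = "empirical") -> GeneticSimilarity:
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return GeneticSimilarity(
        K=df.to_numpy(dtype=float), sample_ids=[str(s) for s in df.index],
        source=source,
    )
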