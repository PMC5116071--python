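"""Minimal PLINK 1 binary (bed/bim/fam) reader and writer.

Handles SNP-major .bed files (magic ``6c 1b 01``): each variant is stored
as ceil(N/4) bytes of 2-bit genotype codes, samples packed low bits first.
Codes: 00 = homozygous A1 (dosage 2 of the counted allele), 10 = het,
11 = homozygous A2 (dosage 0), 01 = missing.
"""

from __future__ import annotations

import numpy as np

from .grm import MISSING, GenotypeMatrix, Variant

__all__ = ["read_plink", "write_plink"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit code -> dosage of A1
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read ``prefix.bed/.bim/.fam`` into a :class:`GenotypeMatrix`."""
    with open(f"{prefix}.fam") as fh:
        samples = [line.split()[1] for line in fh if line.strip()]
    variants = []
    with open(f"{prefix}.bim") as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            variants.append(
                Variant(id=f[1], chromosome=f[0], position=int(f[3]),
                        allele1=f[4], allele2=f[5])
            )
    n, s = len(samples), len(variants)
    raw = np.fromfile(f"{prefix}.bed", dtype=np.uint8)
    if raw[:3].tobytes() != _MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic; not a SNP-major PLINK1 bed file")
    bytes_per_variant = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_variant * s:
        raise ValueError(
            f"{prefix}.bed has {body.size} data bytes; expected "
            f"{bytes_per_variant * s} for {n} samples x {s} variants"
        )
    body = body.reshape(s, bytes_per_variant)
    # expand each byte into four 2-bit codes, low bits = first sample
    codes = np.empty((s, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # N x S
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def write_plink(g: GenotypeMatrix, prefix: str) -> None:
    """Write a :class:`GenotypeMatrix` as ``prefix.bed/.bim/.fam``."""
    n, s = g.n_samples, g.n_variants
    with open(f"{prefix}.fam", "w") as fh:
        for sid in g.samples:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(f"{prefix}.bim", "w") as fh:
        for v in g.variants:
            fh.write(f"{v.chromosome} {v.id} 0 {v.position} {v.allele1} {v.allele2}\n")
    code = np.empty((s, n), dtype=np.uint8)
    for dosage, c in _DOSAGE_TO_CODE.items():
        code[g.dosages.T == dosage] = c
    bytes_per_variant = (n + 3) // 4
    padded = np.zeros((s, bytes_per_variant * 4), dtype=np.uint8)
    padded[:, :n] = code
    out = np.zeros((s, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        out |= padded[:, k::4] << (2 * k)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_MAGIC)
        out.tofile(fh)
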