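"""Minimal PLINK bed/bim/fam reader and writer (SNP-major .bed).

The .bed payload is the 3-byte magic 0x6c 0x1b 0x01 followed by
ceil(n/4) bytes per SNP, two bits per sample:

    00 hom A1/A1    01 missing    10 het    11 hom A2/A2

The bim A1 allele is treated as the counted allele on read, then the
orientation is fixed to the minor allele from the sample frequencies
(flips are logged), so the returned matrix is always a minor-allele
dosage. SNPs are returned sorted by (chromosome, position); an unsorted
.bim is reordered with a warning.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["read_plink", "write_plink"]

logger = logging.getLogger(__name__)

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> (dosage of A1, missing?)
_CODE_DOSAGE = np.array([2, 0, 1, 0], dtype=np.int8)  # 00, 01, 10, 11
_CODE_MISSING = np.array([False, True, False, False])


def read_plink(prefix) -> GenotypeMatrix:
    """Read a bed/bim/fam triplet into a minor-allele dosage matrix."""
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
    )
    n, p = len(fam), len(bim)
    if n == 0:
        raise ValueError(f"{prefix}.fam lists no samples")
    if p == 0:
        raise ValueError(f"{prefix}.bim lists no SNPs")
    raw = bed_path.read_bytes()
    if raw[:3] != _MAGIC:
        raise ValueError(f"{bed_path} has an invalid magic / not SNP-major")
    bps = (n + 3) // 4  # bytes per SNP
    if len(raw) != 3 + bps * p:
        raise ValueError(
            f"{bed_path} payload size {len(raw) - 3} does not match "
            f"{n} samples x {p} SNPs ({bps * p} bytes expected)"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(p, bps)
    # unpack 2-bit codes, sample-fastest within each byte
    codes = np.empty((p, bps * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (data >> (2 * shift)) & 0b11
    codes = codes[:, :n]
    values = _CODE_DOSAGE[codes].T.copy()  # (n, p), dosage of A1
    missing = _CODE_MISSING[codes].T.copy()

    # orient to minor allele from sample frequencies
    with np.errstate(invalid="ignore"):
        obs = (~missing).sum(axis=0)
        freq = np.where(obs > 0, (values * ~missing).sum(axis=0) / (2 * np.maximum(obs, 1)), 0.0)
    flip = freq > 0.5
    if flip.any():
        logger.info("re-oriented %d SNP(s) so the counted allele is minor", int(flip.sum()))
        values[:, flip] = 2 - values[:, flip]
        values[missing] = 0

    chrom = bim["chrom"].to_numpy().astype(str)
    pos = bim["pos"].to_numpy()
    order = np.lexsort((pos, chrom))
    if not (order == np.arange(p)).all():
        warnings.warn("bim not sorted by (chrom, pos); reordering SNPs")
    return GenotypeMatrix(
        values=values[:, order],
        missing_mask=missing[:, order],
        snp_ids=bim["id"].to_numpy()[order],
        chrom=chrom[order],
        pos=pos[order],
        sample_ids=fam["iid"].astype(str).to_numpy(),
    )


def write_plink(X: GenotypeMatrix, prefix) -> None:
    """Write the matrix as bed/bim/fam, with A1 = the counted (minor) allele."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, p = X.n, X.p
    # dosage -> 2-bit code: 2 -> 00, 1 -> 10, 0 -> 11, missing -> 01
    code_of = np.array([0b11, 0b10, 0b00], dtype=np.uint8)
    codes = code_of[X.values]
    codes[X.missing_mask] = 0b01
    bps = (n + 3) // 4
    padded = np.zeros((p, bps * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    out = np.zeros((p, bps), dtype=np.uint8)
    for shift in range(4):
        out |= padded[:, shift::4] << (2 * shift)
    prefix.with_suffix(".bed").write_bytes(_MAGIC + out.tobytes())
    bim = pd.DataFrame(
        {
            "chrom": X.chrom, "id": X.snp_ids, "cm": 0, "pos": X.pos,
            "a1": "A", "a2": "B",
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": X.sample_ids, "iid": X.sample_ids, "father": 0,
            "mother": 0, "sex": 0, "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
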