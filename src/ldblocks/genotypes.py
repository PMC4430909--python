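"""Genotype matrix container and basic manipulations.

Genotypes are ordinal minor-allele counts in {0, 1, 2}, one row per sample
and one column per SNP. Column order is genomic order and defines the
adjacency used by the constrained clustering: SNPs are sorted by
(chromosome, position), with 1-based base-pair positions as in .bim files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "impute_modal", "read_genotype_tsv", "write_genotype_tsv"]


@dataclass
class GenotypeMatrix:
    """n x p ordinal genotypes with a missingness mask and genomic metadata.

    Parameters
    ----------
    values : ndarray of shape (n, p)
        Minor-allele dosages; entries under ``missing_mask`` are ignored
        (conventionally stored as 0 but never read).
    missing_mask : ndarray of bool, shape (n, p)
        True where the genotype is missing.
    snp_ids, chrom, pos : per-SNP identifiers, chromosome labels and
        1-based base-pair coordinates (ascending within chromosome).
    sample_ids : per-sample identifiers.
    """

    values: np.ndarray
    missing_mask: np.ndarray = None
    snp_ids: np.ndarray = None
    chrom: np.ndarray = None
    pos: np.ndarray = None
    sample_ids: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D array (samples x SNPs)")
        n, p = self.values.shape
        if self.missing_mask is None:
            self.missing_mask = np.zeros((n, p), dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (n, p):
            raise ValueError("missing_mask shape does not match values")
        if self.snp_ids is None:
            self.snp_ids = np.array([f"snp{j + 1}" for j in range(p)])
        else:
            self.snp_ids = np.asarray(self.snp_ids)
        if self.chrom is None:
            self.chrom = np.array(["1"] * p)
        else:
            self.chrom = np.asarray(self.chrom).astype(str)
        if self.pos is None:
            self.pos = np.arange(1, p + 1, dtype=np.int64)
        else:
            self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.sample_ids is None:
            self.sample_ids = np.array([f"sample{i + 1}" for i in range(n)])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
        for name, arr, length in (
            ("snp_ids", self.snp_ids, p),
            ("chrom", self.chrom, p),
            ("pos", self.pos, p),
            ("sample_ids", self.sample_ids, n),
        ):
            if len(arr) != length:
                raise ValueError(f"{name} has length {len(arr)}, expected {length}")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.isin(observed, [0, 1, 2]).all():
            raise ValueError("non-missing genotypes must be in {0, 1, 2}")
        # within each chromosome, positions must be strictly increasing
        for c in pd.unique(self.chrom):
            pc = self.pos[self.chrom == c]
            if len(pc) > 1 and not (np.diff(pc) > 0).all():
                raise ValueError(
                    f"positions on chromosome {c} are not strictly increasing"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def dosages(self) -> np.ndarray:
        """Float copy of the genotypes with missing entries as NaN."""
        d = self.values.astype(float)
        d[self.missing_mask] = np.nan
        return d

    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.chrom))

    def take_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            values=self.values[:, idx],
            missing_mask=self.missing_mask[:, idx],
            snp_ids=self.snp_ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            sample_ids=self.sample_ids,
        )

    def subset_chromosome(self, chrom: str) -> "GenotypeMatrix":
        return self.take_snps(np.where(self.chrom == str(chrom))[0])


def impute_modal(X: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing genotypes by the per-SNP modal genotype.

    Ties between equally frequent genotypes break toward the smaller code.
    Raises if a SNP has no observed genotype at all.
    """
    values = X.values.copy()
    for j in range(X.p):
        miss = X.missing_mask[:, j]
        if not miss.any():
            continue
        obs = values[~miss, j]
        if obs.size == 0:
            raise ValueError(f"SNP {X.snp_ids[j]} is fully missing; cannot impute")
        counts = np.bincount(obs.astype(int), minlength=3)
        values[miss, j] = int(np.argmax(counts))  # argmax takes the smallest code on ties
    return GenotypeMatrix(
        values=values,
        missing_mask=np.zeros_like(X.missing_mask),
        snp_ids=X.snp_ids,
        chrom=X.chrom,
        pos=X.pos,
        sample_ids=X.sample_ids,
    )


def write_genotype_tsv(X: GenotypeMatrix, path) -> None:
    """Write a headered samples-x-SNPs TSV with NA for missing genotypes."""
    df = pd.DataFrame(X.dosages(), index=X.sample_ids, columns=X.snp_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def read_genotype_tsv(path, chrom=None, pos=None) -> GenotypeMatrix:
    """Read the headered samples-x-SNPs TSV dialect (NA for missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=float)
    mask = np.isnan(vals)
    vals = np.where(mask, 0, vals).astype(np.int8)
    return GenotypeMatrix(
        values=vals,
        missing_mask=mask,
        snp_ids=df.columns.to_numpy(),
        chrom=chrom,
        pos=pos,
        sample_ids=df.index.to_numpy(),
    )
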