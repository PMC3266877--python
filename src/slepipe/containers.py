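"""Core in-memory containers shared by every pipeline stage.

Genotypes live in a dense ``int8`` matrix (samples x SNPs) counting copies of
allele 1, with ``MISSING`` (-1) for no-calls.  Marker and sample metadata ride
along as pandas DataFrames, mirroring how PLINK-style tooling pairs a .bed
matrix with .bim/.fam sheets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.
MISSING: int = -1

#: Sample sheet status codes (PLINK convention).
CONTROL, CASE = 1, 2

SNP_COLUMNS = ["snp_id", "chrom", "pos", "allele1", "allele2"]
SAMPLE_COLUMNS = ["sample_id", "status", "stage"]


class SlepipeError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(SlepipeError):
    """A configuration field failed validation."""


@dataclass
class GenotypeCounts:
    """Genotype distribution of one SNP in one sample group.

    Counts of allele-1 homozygotes is ``n_hom_alt`` when allele 1 is the
    alternate allele; naming follows the 0/1/2 dosage coding.
    """

    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hom_ref", "n_het", "n_hom_alt", "n_missing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_called(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def allele1_count(self) -> int:
        """Copies of the dosage-counted allele among called genotypes."""
        return 2 * self.n_hom_alt + self.n_het

    @property
    def allele1_freq(self) -> float:
        n = self.n_called
        if n == 0:
            raise ValueError("no called genotypes")
        return self.allele1_count / (2 * n)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with marker map and sample sheet.

    Parameters
    ----------
    genotypes
        ``int8`` array of shape ``(n_samples, n_snps)`` holding counts of
        ``allele1`` (0, 1, 2) or ``MISSING``.
    snps
        DataFrame with columns ``snp_id, chrom, pos, allele1, allele2``;
        positions are 1-based as in VCF.
    samples
        DataFrame with columns ``sample_id, status, stage``; status is
        1 = control, 2 = case.
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x SNPs)")
        if len(self.snps) != self.genotypes.shape[1]:
            raise ValueError("snps table does not match genotype columns")
        if len(self.samples) != self.genotypes.shape[0]:
            raise ValueError("samples table does not match genotype rows")
        for col in SNP_COLUMNS:
            if col not in self.snps.columns:
                raise ValueError(f"snps table missing column {col!r}")
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"samples table missing column {col!r}")
        valid = (self.genotypes >= 0) & (self.genotypes <= 2)
        if not np.all(valid | (self.genotypes == MISSING)):
            raise ValueError("genotypes must be in {0,1,2} or MISSING")
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        return self.samples["status"].to_numpy() == CASE

    @property
    def control_mask(self) -> np.ndarray:
        return self.samples["status"].to_numpy() == CONTROL

    def snp_index(self, snp_id: str) -> int:
        idx = self.snps.index[self.snps["snp_id"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"unknown SNP {snp_id!r}")
        return int(idx[0])

    # -- summaries ------------------------------------------------------

    def sample_call_rate(self) -> np.ndarray:
        """Per-sample fraction of non-missing genotypes."""
        return (self.genotypes != MISSING).mean(axis=1)

    def snp_call_rate(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        g = self.genotypes if sample_mask is None else self.genotypes[sample_mask]
        if g.shape[0] == 0:
            raise ValueError("empty sample selection")
        return (g != MISSING).mean(axis=0)

    def allele1_freq(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        """Per-SNP frequency of allele 1 among called genotypes (NaN if none)."""
        g = self.genotypes if sample_mask is None else self.genotypes[sample_mask]
        called = g != MISSING
        dose = np.where(called, g, 0).sum(axis=0, dtype=np.int64)
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, dose / (2.0 * n), np.nan)

    def genotype_counts(
        self, snp: int | str, sample_mask: np.ndarray | None = None
    ) -> GenotypeCounts:
        j = self.snp_index(snp) if isinstance(snp, str) else int(snp)
        g = self.genotypes[:, j] if sample_mask is None else self.genotypes[sample_mask, j]
        return GenotypeCounts(
            n_hom_ref=int(np.sum(g == 0)),
            n_het=int(np.sum(g == 1)),
            n_hom_alt=int(np.sum(g == 2)),
            n_missing=int(np.sum(g == MISSING)),
        )

    def stacked_genotype_counts(
        self, sample_mask: np.ndarray | None = None
    ) -> pd.DataFrame:
        """Vectorized genotype counts for every SNP (columns n0,n1,n2,nmiss)."""
        g = self.genotypes if sample_mask is None else self.genotypes[sample_mask]
        out = pd.DataFrame(
            {
                "n0": (g == 0).sum(axis=0),
                "n1": (g == 1).sum(axis=0),
                "n2": (g == 2).sum(axis=0),
                "nmiss": (g == MISSING).sum(axis=0),
            },
            index=self.snps["snp_id"],
        )
        return out

    # -- subsetting -----------------------------------------------------

    def subset(
        self,
        sample_mask: np.ndarray | Sequence[int] | None = None,
        snp_mask: np.ndarray | Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        g = self.genotypes
        samples = self.samples
        snps = self.snps
        if sample_mask is not None:
            sample_mask = np.asarray(sample_mask)
            g = g[sample_mask]
            samples = samples.iloc[np.arange(len(samples))[sample_mask]] \
                if sample_mask.dtype == bool else samples.iloc[sample_mask]
        if snp_mask is not None:
            snp_mask = np.asarray(snp_mask)
            g = g[:, snp_mask]
            snps = snps.iloc[np.arange(len(snps))[snp_mask]] \
                if snp_mask.dtype == bool else snps.iloc[snp_mask]
        return GenotypeMatrix(g.copy(), snps.reset_index(drop=True),
                              samples.reset_index(drop=True))


@dataclass
class ExpressionMatrix:
    """Probe x sample expression values with aligned sample ids."""

    values: pd.DataFrame  # index: probe_id, columns: sample_id

    def __post_init__(self) -> None:
        if self.values.index.name is None:
            self.values.index.name = "probe_id"

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class ProbeAnnotation:
    """Probe genomic intervals, BED-style 0-based half-open."""

    table: pd.DataFrame  # probe_id, chrom, start, end, gene_label

    def __post_init__(self) -> None:
        required = ["probe_id", "chrom", "start", "end", "gene_label"]
        for col in required:
            if col not in self.table.columns:
                raise ValueError(f"probe annotation missing column {col!r}")
        if not (self.table["start"] < self.table["end"]).all():
            raise ValueError("probe intervals must satisfy start < end")
        self.table = self.table.reset_index(drop=True)
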