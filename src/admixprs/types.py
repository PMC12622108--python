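"""Core in-memory data model shared by every pipeline stage.

Conventions: variant positions are 1-based (VCF style); local-ancestry
segments use 0-based half-open intervals (BED style). The conversion between
the two happens exactly once, at segment-window lookup
(:func:`admixprs.ancestry.ancestry_at`).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "SummaryStatRecord",
    "AncestrySegment",
    "HaplotypeCohort",
]


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One biallelic variant on the target side.

    ``effect_allele`` is the counted allele of the dosage encoding; ``id``
    defaults to the ``chrom:pos:other:effect`` convention when not supplied.
    """

    chrom: str
    pos: int  # 1-based physical position (bp)
    effect_allele: str
    other_allele: str
    id: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"effect and other allele identical ({self.effect_allele}) at "
                f"{self.chrom}:{self.pos}"
            )
        if not self.id:
            object.__setattr__(
                self,
                "id",
                f"{self.chrom}:{self.pos}:{self.other_allele}:{self.effect_allele}",
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True, slots=True)
class SummaryStatRecord:
    """One base-GWAS association: effect size (log-odds) and p-value."""

    variant: VariantRecord
    beta: float
    p_value: float

    def __post_init__(self):
        if not np.isfinite(self.beta):
            raise ValueError(f"non-finite beta for {self.variant.id}")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(
                f"p-value must be in (0,1], got {self.p_value} for {self.variant.id}"
            )


@dataclass(frozen=True, slots=True)
class AncestrySegment:
    """One local-ancestry tract on one haplotype (0-based half-open)."""

    sample: str
    haplotype: int  # 0 or 1
    chrom: str
    start: int
    end: int
    ancestry: str

    def __post_init__(self):
        if self.haplotype not in (0, 1):
            raise ValueError(f"haplotype must be 0 or 1, got {self.haplotype}")
        if not self.start < self.end:
            raise ValueError(
                f"segment start must precede end: {self.sample} hap {self.haplotype} "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HaplotypeCohort:
    """Phased cohort: allele matrix, covariates, phenotype, ancestry tracts.

    ``alleles`` is an (n_samples, 2, n_variants) binary array of
    effect-allele indicators; diploid dosages are the haplotype sums.
    ``phenotype`` is None until :func:`admixprs.simulate.simulate_phenotype`
    fills it.
    """

    samples: list[str]
    variants: list[VariantRecord]
    alleles: np.ndarray  # (n, 2, m) int8
    age: np.ndarray  # years
    sex: np.ndarray  # 0/1
    segments: list[AncestrySegment]
    ancestry_labels: tuple[str, ...]
    chrom_lengths: dict[str, int]  # bp, for segment tiling / spans
    phenotype: np.ndarray | None = None
    missing_mask: np.ndarray | None = None  # (n, m) bool, True = masked
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n, two, m = self.alleles.shape
        if two != 2 or n != len(self.samples) or m != len(self.variants):
            raise ValueError("alleles must have shape (n_samples, 2, n_variants)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def dosages(self) -> np.ndarray:
        """(n, m) float dosages; masked entries are NaN."""
        d = self.alleles.sum(axis=1).astype(float)
        if self.missing_mask is not None:
            d = d.copy()
            d[self.missing_mask] = np.nan
        return d

    def covariate_frame(self) -> pd.DataFrame:
        """AGE/SEX columns indexed by sample; ancestry columns are appended
        by :func:`admixprs.ancestry.global_proportions`."""
        return pd.DataFrame(
            {"AGE": self.age, "SEX": self.sex}, index=pd.Index(self.samples, name="ID")
        )

    def subset(self, sample_ids: list[str]) -> "HaplotypeCohort":
        """Row-subset the cohort to the given samples (order preserved)."""
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample IDs: {missing[:5]}")
        idx = np.array([pos[s] for s in sample_ids])
        keep = set(sample_ids)
        return HaplotypeCohort(
            samples=list(sample_ids),
            variants=self.variants,
            alleles=self.alleles[idx],
            age=self.age[idx],
            sex=self.sex[idx],
            segments=[s for s in self.segments if s.sample in keep],
            ancestry_labels=self.ancestry_labels,
            chrom_lengths=dict(self.chrom_lengths),
            phenotype=None if self.phenotype is None else self.phenotype[idx],
            missing_mask=None if self.missing_mask is None else self.missing_mask[idx],
            meta=dict(self.meta),
        )
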