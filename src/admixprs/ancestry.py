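"""Global ancestry proportions and carrier-haplotype local-ancestry lookups.

Global proportions are the covariate-file quantity: per sample, the total
genomic span (bp) of each ancestry over both haplotypes, normalised by the
total diploid span. Carrier profiles cross-reference a variant's
effect-allele-carrying haplotypes with the local-ancestry tract covering the
variant position; the carrier unit is the haplotype (a dosage-2 individual
contributes two carrier haplotypes), because local ancestry is
haplotype-resolved.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import AncestrySegment, HaplotypeCohort, VariantRecord

__all__ = [
    "AncestryIndex",
    "CarrierAncestryProfile",
    "global_proportions",
    "covariates_from_proportions",
    "ancestry_at",
    "carrier_ancestry",
]


def global_proportions(
    segments: list[AncestrySegment], labels: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Per-sample ancestry fractions of the total diploid genomic span.

    Rows sum to 1 exactly (same arithmetic as the generator's realized tract
    fractions). Column order follows ``labels`` when given, else sorted.
    """
    spans: dict[str, dict[str, int]] = {}
    for s in segments:
        spans.setdefault(s.sample, {}).setdefault(s.ancestry, 0)
        spans[s.sample][s.ancestry] += s.length
    if labels is None:
        labels = tuple(sorted({s.ancestry for s in segments}))
    df = pd.DataFrame(
        [[spans[smp].get(lab, 0) for lab in labels] for smp in spans],
        index=pd.Index(list(spans), name="ID"),
        columns=list(labels),
        dtype=float,
    )
    return df.div(df.sum(axis=1), axis=0)


def covariates_from_proportions(
    proportions: pd.DataFrame, drop_label: str = "MAL"
) -> pd.DataFrame:
    """Ancestry covariate columns with one label dropped against perfect
    multicollinearity (default MAL, the smallest contribution in the
    reference design)."""
    if drop_label not in proportions.columns:
        raise ValueError(f"drop_label {drop_label!r} not among ancestry columns")
    kept = [c for c in proportions.columns if c != drop_label]
    if not kept:
        raise ValueError("dropping the label would leave zero covariate columns")
    out = proportions[kept].copy()
    out.attrs["dropped_ancestry"] = drop_label
    return out


class AncestryIndex:
    """Sorted-interval index over segments for O(log k) position lookups."""

    def __init__(self, segments: list[AncestrySegment]):
        self._idx: dict[tuple[str, int, str], tuple[np.ndarray, np.ndarray, list[str]]] = {}
        groups: dict[tuple[str, int, str], list[AncestrySegment]] = {}
        for s in segments:
            groups.setdefault((s.sample, s.haplotype, s.chrom), []).append(s)
        for key, segs in groups.items():
            segs = sorted(segs, key=lambda s: s.start)
            self._idx[key] = (
                np.array([s.start for s in segs]),
                np.array([s.end for s in segs]),
                [s.ancestry for s in segs],
            )

    def lookup(self, sample: str, haplotype: int, chrom: str, pos: int) -> str:
        """Ancestry at a 1-based variant position (converted to the 0-based
        half-open segment convention: the segment containing pos - 1)."""
        key = (sample, haplotype, chrom)
        if key not in self._idx:
            raise KeyError(f"no segments for sample {sample} hap {haplotype} {chrom}")
        starts, ends, labels = self._idx[key]
        p0 = pos - 1
        i = int(np.searchsorted(starts, p0, side="right")) - 1
        if i < 0 or p0 >= ends[i]:
            raise ValueError(
                f"position {chrom}:{pos} not covered for sample {sample} hap {haplotype}"
            )
        return labels[i]


def ancestry_at(
    segments: list[AncestrySegment] | AncestryIndex,
    sample: str,
    haplotype: int,
    chrom: str,
    pos: int,
) -> str:
    """Label of the unique tract covering a 1-based position."""
    idx = segments if isinstance(segments, AncestryIndex) else AncestryIndex(segments)
    return idx.lookup(sample, haplotype, chrom, pos)


@dataclass
class CarrierAncestryProfile:
    """Per-ancestry percentages of effect-allele-carrying haplotypes at one
    variant. Percentages sum to 100 (undefined and flagged when there are no
    carriers)."""

    variant: VariantRecord
    percentages: dict[str, float]
    n_carrier_haplotypes: int

    @property
    def defined(self) -> bool:
        return self.n_carrier_haplotypes > 0


def carrier_ancestry(
    variant: VariantRecord,
    cohort: HaplotypeCohort,
    index: AncestryIndex | None = None,
) -> CarrierAncestryProfile:
    """Tabulate local ancestry over all haplotypes carrying the effect
    allele at the variant position."""
    vids = [v.id for v in cohort.variants]
    try:
        j = vids.index(variant.id)
    except ValueError as e:
        raise KeyError(f"variant {variant.id} not in cohort") from e
    if index is None:
        index = AncestryIndex(cohort.segments)
    counts = {lab: 0 for lab in cohort.ancestry_labels}
    n_carriers = 0
    for i, smp in enumerate(cohort.samples):
        for hap in (0, 1):
            if cohort.alleles[i, hap, j] == 1:
                lab = index.lookup(smp, hap, variant.chrom, variant.pos)
                counts[lab] += 1
                n_carriers += 1
    if n_carriers == 0:
        return CarrierAncestryProfile(variant, {lab: float("nan") for lab in counts}, 0)
    pct = {lab: 100.0 * c / n_carriers for lab, c in counts.items()}
    return CarrierAncestryProfile(variant, pct, n_carriers)
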