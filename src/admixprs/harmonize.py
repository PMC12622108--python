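"""Base/target allele harmonization and greedy LD clumping.

Harmonization matches base summary statistics to target variants by
chromosome and position, flips the effect sign when the allele pair is
swapped, and excludes strand-ambiguous (A/T, C/G) and mismatched pairs.

Clumping is the classic greedy index-variant selection: repeatedly take the
unabsorbed variant with the smallest p-value as an index and absorb every
unabsorbed variant on the same chromosome within the physical window whose
dosage r-squared with the index exceeds the cut-off. LD is computed on the
target cohort's own dosages (training data), the usual C+T tool default
when no external reference panel is supplied.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .types import SummaryStatRecord, VariantRecord

logger = logging.getLogger(__name__)

__all__ = ["HarmonizedVariant", "ClumpResult", "harmonize", "ld_r2", "clump",
           "mean_impute"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return len(a1) == 1 and len(a2) == 1 and _COMPLEMENT.get(a1) == a2


@dataclass(frozen=True)
class HarmonizedVariant:
    """One base variant aligned to the target's counted allele.

    ``exclusion_reason`` is None for usable variants; excluded variants carry
    no aligned effect. ``target_index`` is the column of the variant in the
    target dosage matrix (None when absent from the target).
    """

    variant: VariantRecord
    p_value: float
    beta_aligned: float | None
    flip_applied: bool
    exclusion_reason: str | None  # None | "mismatch" | "palindromic" | "absent"
    target_index: int | None


def harmonize(
    sumstats: list[SummaryStatRecord],
    target_variants: list[VariantRecord],
    exclude_palindromic: bool = True,
) -> list[HarmonizedVariant]:
    """Align base effects to the target's counted alleles.

    Matching is by (chrom, pos). A swapped allele pair negates the effect and
    marks ``flip_applied``; anything else is excluded with a reason.
    Duplicate positions on either side are an error.
    """
    base_keys = [s.variant.key for s in sumstats]
    if len(set(base_keys)) != len(base_keys):
        raise ValueError("duplicate chrom+pos in base summary statistics")
    tkeys = [v.key for v in target_variants]
    if len(set(tkeys)) != len(tkeys):
        raise ValueError("duplicate chrom+pos in target variants")
    tmap = {v.key: (j, v) for j, v in enumerate(target_variants)}

    out: list[HarmonizedVariant] = []
    for s in sumstats:
        hit = tmap.get(s.variant.key)
        if hit is None:
            out.append(
                HarmonizedVariant(s.variant, s.p_value, None, False, "absent", None)
            )
            continue
        j, tv = hit
        b_eff, b_oth = s.variant.effect_allele, s.variant.other_allele
        if exclude_palindromic and _is_palindromic(b_eff, b_oth):
            out.append(
                HarmonizedVariant(tv, s.p_value, None, False, "palindromic", j)
            )
            continue
        if (b_eff, b_oth) == (tv.effect_allele, tv.other_allele):
            out.append(HarmonizedVariant(tv, s.p_value, s.beta, False, None, j))
        elif (b_oth, b_eff) == (tv.effect_allele, tv.other_allele):
            out.append(HarmonizedVariant(tv, s.p_value, -s.beta, True, None, j))
        else:
            out.append(HarmonizedVariant(tv, s.p_value, None, False, "mismatch", j))
    return out


def ld_r2(dosage_x: np.ndarray, dosage_y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors on complete pairs.

    Returns 0.0 (with a monomorphic warning) when either vector is constant.
    """
    x = np.asarray(dosage_x, dtype=float)
    y = np.asarray(dosage_y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        raise ValueError("ld_r2 needs at least 2 complete pairs")
    x, y = x[ok], y[ok]
    vx = x - x.mean()
    vy = y - y.mean()
    sx = vx @ vx
    sy = vy @ vy
    if sx == 0.0 or sy == 0.0:
        warnings.warn("monomorphic dosage vector in ld_r2; returning 0.0")
        return 0.0
    r = (vx @ vy) / np.sqrt(sx * sy)
    return float(min(r * r, 1.0))


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-variant mean (columns all-missing
    become 0)."""
    d = np.asarray(dosages, dtype=float)
    if not np.isnan(d).any():
        return d
    d = d.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(d, axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    idx = np.where(np.isnan(d))
    d[idx] = col_mean[idx[1]]
    return d


@dataclass
class ClumpResult:
    """Greedy clumping outcome: retained index variants (in selection order),
    a map from each absorbed variant ID to the index that absorbed it, and
    the parameters used."""

    index_variants: list[VariantRecord]
    index_positions: list[int]  # target dosage columns of the retained set
    removed: dict[str, str]
    window_kb: float
    r2_max: float


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def clump(
    harmonized: list[HarmonizedVariant],
    dosages: np.ndarray,
    window_kb: float,
    r2_max: float,
) -> ClumpResult:
    """Greedy p-value-ordered clumping on target-cohort LD.

    Ties on p break by chromosome label (numeric first), then position, then
    variant ID, so the result is invariant to input row order. Missing
    dosages are mean-imputed before LD.
    """
    if window_kb <= 0:
        raise ValueError("window_kb must be > 0")
    if not (0.0 <= r2_max <= 1.0):
        raise ValueError("r2_max must lie in [0, 1]")
    usable = [h for h in harmonized if h.exclusion_reason is None]
    order = sorted(
        range(len(usable)),
        key=lambda i: (
            usable[i].p_value,
            _chrom_sort_key(usable[i].variant.chrom),
            usable[i].variant.pos,
            usable[i].variant.id,
        ),
    )
    d = mean_impute(dosages)
    window_bp = window_kb * 1000.0

    absorbed: dict[str, str] = {}
    taken = np.zeros(len(usable), dtype=bool)
    index_variants: list[VariantRecord] = []
    index_positions: list[int] = []
    by_chrom: dict[str, list[int]] = {}
    for i, h in enumerate(usable):
        by_chrom.setdefault(h.variant.chrom, []).append(i)

    for i in order:
        if taken[i]:
            continue
        hi = usable[i]
        taken[i] = True
        index_variants.append(hi.variant)
        index_positions.append(hi.target_index)
        xi = d[:, hi.target_index]
        for j in by_chrom[hi.variant.chrom]:
            if taken[j]:
                continue
            hj = usable[j]
            if abs(hj.variant.pos - hi.variant.pos) > window_bp:
                continue
            if ld_r2(xi, d[:, hj.target_index]) > r2_max:
                taken[j] = True
                absorbed[hj.variant.id] = hi.variant.id
    return ClumpResult(index_variants, index_positions, absorbed, window_kb, r2_max)
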