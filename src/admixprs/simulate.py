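"""Synthetic admixed case-control cohorts.

Emulates the data a five-way admixed Parkinson's disease cohort analysis
consumes: phased genotypes with local-ancestry tracts, age/sex covariates, a
logistic case-control phenotype, and noisy base-GWAS summary statistics.

The admixture model is the standard Poisson-switch one: each individual draws
ancestry proportions from a Dirichlet; each haplotype is tiled by tracts whose
switch points follow a Poisson process with rate g (generations since
admixture) per Morgan, each tract's ancestry drawn independently from the
individual's proportions. Population allele frequencies follow
Balding-Nichols: for ancestral frequency p and divergence F, the
population-specific frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), i.e. mean p
and variance F.p(1-p).

The phenotype is logistic on the log-odds scale,
``logit P(case) = c + sum_j beta_j (G_ij - mean G_j) + covariate terms``,
with the intercept c solved numerically so the expected case fraction matches
a target (default 661/1398, the cohort shape this generator mirrors).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .types import AncestrySegment, HaplotypeCohort, SummaryStatRecord, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AncestryModel",
    "PhenotypeModel",
    "VariantMap",
    "default_variant_map",
    "generate_cohort",
    "simulate_phenotype",
    "emulate_gwas",
    "default_phenotype_model",
    "default_cohort",
]

#: default cohort size mirrors the 661 cases + 737 controls design
DEFAULT_N_SAMPLES = 1398
DEFAULT_CASE_FRACTION = 661 / 1398

# cM per Mb when no genetic map is supplied
_CM_PER_MB = 1.0


@dataclass(frozen=True)
class AncestryModel:
    """Five-way admixture model (AFR, EUR, MAL, NAMA, SAS by default).

    ``dirichlet_alpha`` sets both the mean ancestry proportions and their
    between-individual spread; ``fst`` is the per-population Balding-Nichols
    divergence from the shared ancestral frequency; ``generations`` is the
    admixture age g driving tract lengths (mean tract 1/g Morgans).
    """

    labels: tuple[str, ...] = ("AFR", "EUR", "MAL", "NAMA", "SAS")
    dirichlet_alpha: tuple[float, ...] = (3.0, 2.5, 1.0, 2.5, 1.0)
    fst: tuple[float, ...] = (0.15, 0.10, 0.12, 0.20, 0.11)
    generations: float = 15.0

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("ancestry labels must be unique")
        if len(self.dirichlet_alpha) != len(self.labels) or len(self.fst) != len(
            self.labels
        ):
            raise ValueError("dirichlet_alpha and fst must match labels in length")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha entries must be > 0")
        if any(not (0.0 <= f < 1.0) for f in self.fst):
            raise ValueError("fst entries must lie in [0, 1)")
        if self.generations <= 0:
            raise ValueError("generations must be > 0")


@dataclass(frozen=True)
class PhenotypeModel:
    """Log-odds liability model for binary case-control status.

    Effects are per-unit on the log-odds scale: ``age_effect`` per year,
    ``sex_effect`` for sex=1, ``ancestry_effects`` per unit global proportion.
    ``true_betas`` are the per-variant causal effects (aligned to the cohort's
    variant order).
    """

    true_betas: np.ndarray
    age_effect: float = 0.04
    sex_effect: float = 0.4
    ancestry_effects: dict[str, float] = field(default_factory=dict)
    target_case_fraction: float = DEFAULT_CASE_FRACTION

    def __post_init__(self):
        if not (0.0 < self.target_case_fraction < 1.0):
            raise ValueError("target_case_fraction must lie strictly in (0, 1)")


@dataclass(frozen=True)
class VariantMap:
    """Physical variant positions plus chromosome lengths.

    Genetic positions come from a uniform 1 cM/Mb map unless ``genetic_pos``
    (Morgans) is supplied.
    """

    chroms: tuple[str, ...]  # per-variant chromosome
    pos: np.ndarray  # per-variant 1-based bp
    chrom_lengths: dict[str, int]  # bp
    genetic_pos: np.ndarray | None = None  # Morgans

    def __post_init__(self):
        if len(self.chroms) != len(self.pos):
            raise ValueError("chroms and pos must align")
        for c in dict.fromkeys(self.chroms):
            p = self.pos[np.array([x == c for x in self.chroms])]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions must be strictly increasing on {c}")
            if p[-1] > self.chrom_lengths[c]:
                raise ValueError(f"position beyond chromosome length on {c}")

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def morgans(self) -> np.ndarray:
        if self.genetic_pos is not None:
            return self.genetic_pos
        return self.pos * (_CM_PER_MB / 100.0) * 1e-6

    def chrom_morgans(self, chrom: str) -> float:
        return self.chrom_lengths[chrom] * (_CM_PER_MB / 100.0) * 1e-6


def default_variant_map(
    n_variants: int = 1200,
    n_chroms: int = 4,
    chrom_length: int = 50_000_000,
) -> VariantMap:
    """Evenly spaced variants on ``n_chroms`` equal-length chromosomes."""
    per = n_variants // n_chroms
    counts = [per + (1 if i < n_variants % n_chroms else 0) for i in range(n_chroms)]
    chroms: list[str] = []
    pos: list[int] = []
    for i, cnt in enumerate(counts):
        name = str(i + 1)
        step = chrom_length // (cnt + 1)
        chroms.extend([name] * cnt)
        pos.extend(step * (j + 1) for j in range(cnt))
    lengths = {str(i + 1): chrom_length for i in range(n_chroms)}
    return VariantMap(tuple(chroms), np.asarray(pos, dtype=np.int64), lengths)


def _balding_nichols_freqs(
    model: AncestryModel, ancestral: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(k, m) population frequencies around ancestral frequencies."""
    k, m = len(model.labels), len(ancestral)
    out = np.empty((k, m))
    for i, f in enumerate(model.fst):
        if f == 0.0:
            out[i] = ancestral
        else:
            c = (1.0 - f) / f
            out[i] = rng.beta(ancestral * c, (1.0 - ancestral) * c)
    return np.clip(out, 1e-4, 1.0 - 1e-4)


def generate_cohort(
    ancestry_model: AncestryModel,
    n_samples: int,
    variant_map: VariantMap,
    seed: int,
) -> HaplotypeCohort:
    """Simulate phased genotypes and local-ancestry tracts (no phenotype).

    Deterministic given ``seed``. Age is drawn N(60, 12) truncated to
    [20, 90] years (a Parkinson's-like recruitment age profile) and sex is
    Bernoulli(1/2); both are later tied to case status only through the
    phenotype model's covariate effects.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    k = len(ancestry_model.labels)
    m = variant_map.n_variants
    g = ancestry_model.generations

    ancestral = rng.uniform(0.05, 0.95, size=m)
    pop_freqs = _balding_nichols_freqs(ancestry_model, ancestral, rng)

    # normalized Dirichlet draws; degenerate alphas handled by normalization
    props = rng.dirichlet(ancestry_model.dirichlet_alpha, size=n_samples)

    variants = [
        VariantRecord(chrom=c, pos=int(p), effect_allele="A", other_allele="G")
        for c, p in zip(variant_map.chroms, variant_map.pos)
    ]
    chrom_names = list(dict.fromkeys(variant_map.chroms))
    chrom_idx = {
        c: np.flatnonzero(np.array([x == c for x in variant_map.chroms]))
        for c in chrom_names
    }
    gmorgans = variant_map.morgans()

    samples = [f"S{i:05d}" for i in range(n_samples)]
    alleles = np.zeros((n_samples, 2, m), dtype=np.int8)
    segments: list[AncestrySegment] = []

    for i in range(n_samples):
        pvec = props[i]
        for hap in (0, 1):
            for c in chrom_names:
                L = variant_map.chrom_morgans(c)
                bp_len = variant_map.chrom_lengths[c]
                n_switch = rng.poisson(g * L)
                cuts = np.sort(rng.uniform(0.0, L, size=n_switch))
                # tract ancestries: independent categorical draws per tract
                anc = rng.choice(k, size=n_switch + 1, p=pvec)
                # tile the chromosome in bp, merging zero-length tracts
                # (bp rounding) and same-ancestry neighbours
                bounds_bp = np.concatenate(
                    ([0], np.round(cuts / L * bp_len).astype(np.int64), [bp_len])
                )
                runs: list[tuple[int, int, int]] = []  # start, end, ancestry idx
                for t in range(n_switch + 1):
                    s, e = int(bounds_bp[t]), int(bounds_bp[t + 1])
                    if e <= s:
                        continue
                    if runs and runs[-1][2] == anc[t]:
                        runs[-1] = (runs[-1][0], e, anc[t])
                    else:
                        runs.append((s, e, int(anc[t])))
                for s, e, a in runs:
                    segments.append(
                        AncestrySegment(
                            samples[i], hap, c, s, e, ancestry_model.labels[a]
                        )
                    )
                # alleles on this chromosome: local ancestry at each variant
                vidx = chrom_idx[c]
                if len(vidx):
                    local_m = gmorgans[vidx]
                    tract = np.searchsorted(cuts, local_m, side="right")
                    anc_at = anc[tract]
                    p_site = pop_freqs[anc_at, vidx]
                    alleles[i, hap, vidx] = rng.random(len(vidx)) < p_site

    age = np.clip(rng.normal(60.0, 12.0, size=n_samples), 20.0, 90.0)
    sex = rng.integers(0, 2, size=n_samples).astype(np.int8)

    cohort = HaplotypeCohort(
        samples=samples,
        variants=variants,
        alleles=alleles,
        age=age,
        sex=sex,
        segments=segments,
        ancestry_labels=ancestry_model.labels,
        chrom_lengths=dict(variant_map.chrom_lengths),
        meta={
            "seed": seed,
            "generations": g,
            "dirichlet_alpha": list(ancestry_model.dirichlet_alpha),
            "ancestral_freqs": ancestral,
            "pop_freqs": pop_freqs,
            "dirichlet_props": props,
        },
    )
    return cohort


def _pooled_freqs(cohort: HaplotypeCohort) -> np.ndarray:
    return cohort.alleles.mean(axis=(0, 1))


def simulate_phenotype(
    cohort: HaplotypeCohort, model: PhenotypeModel, seed: int
) -> HaplotypeCohort:
    """Fill the cohort's binary phenotype from the logistic liability model.

    The intercept is solved with Brent's method so the expected case fraction
    equals ``model.target_case_fraction``; a liability so degenerate that no
    intercept in [-30, 30] achieves the target raises ValueError.
    """
    betas = np.asarray(model.true_betas, dtype=float)
    if len(betas) != cohort.n_variants:
        raise ValueError(
            f"true_betas has length {len(betas)}, cohort has "
            f"{cohort.n_variants} variants"
        )
    rng = np.random.default_rng(seed)
    G = cohort.alleles.sum(axis=1).astype(float)
    eta = (G - G.mean(axis=0)) @ betas
    eta = eta + model.age_effect * (cohort.age - cohort.age.mean())
    eta = eta + model.sex_effect * (cohort.sex - cohort.sex.mean())
    if model.ancestry_effects:
        from .ancestry import global_proportions

        props = global_proportions(cohort.segments, cohort.ancestry_labels)
        props = props.loc[cohort.samples]
        for lab, eff in model.ancestry_effects.items():
            col = props[lab].to_numpy()
            eta = eta + eff * (col - col.mean())

    target = model.target_case_fraction

    def gap(c: float) -> float:
        return float(expit(c + eta).mean()) - target

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("degenerate liability: intercept unsolvable in [-30, 30]")
    intercept = brentq(gap, lo, hi, xtol=1e-10)
    prob = expit(intercept + eta)
    phenotype = (rng.random(cohort.n_samples) < prob).astype(np.int8)

    out = HaplotypeCohort(
        samples=cohort.samples,
        variants=cohort.variants,
        alleles=cohort.alleles,
        age=cohort.age,
        sex=cohort.sex,
        segments=cohort.segments,
        ancestry_labels=cohort.ancestry_labels,
        chrom_lengths=dict(cohort.chrom_lengths),
        phenotype=phenotype,
        missing_mask=cohort.missing_mask,
        meta={**cohort.meta, "intercept": intercept},
    )
    return out


def emulate_gwas(
    true_betas: np.ndarray,
    freqs: np.ndarray,
    variants: list[VariantRecord],
    base_n: int,
    seed: int,
) -> list[SummaryStatRecord]:
    """Noisy base-GWAS effect estimates with Wald p-values.

    The standard error of a log-odds effect at allele frequency f in a study
    of ``base_n`` individuals is approximated as 1/sqrt(2.N.f(1-f)); the
    estimate is the true effect plus Gaussian noise of that scale, the
    p-value the two-sided Wald test of the estimate.
    """
    betas = np.asarray(true_betas, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0.0) | (freqs >= 1.0)):
        raise ValueError("frequencies must lie strictly in (0, 1)")
    if base_n <= 1:
        raise ValueError("base_n must be > 1")
    rng = np.random.default_rng(seed)
    se = 1.0 / np.sqrt(2.0 * base_n * freqs * (1.0 - freqs))
    est = betas + rng.normal(0.0, se)
    z = est / se
    p = np.clip(2.0 * norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return [
        SummaryStatRecord(variant=v, beta=float(b), p_value=float(pv))
        for v, b, pv in zip(variants, est, p)
    ]


def default_phenotype_model(
    n_variants: int,
    n_causal: int = 50,
    effect_scale: float = 0.12,
    seed: int = 0,
    target_case_fraction: float = DEFAULT_CASE_FRACTION,
) -> PhenotypeModel:
    """Sparse causal architecture: ``n_causal`` variants with +-effect_scale
    log-odds effects at random positions, plus modest age/sex/ancestry
    covariate effects."""
    rng = np.random.default_rng(seed)
    betas = np.zeros(n_variants)
    idx = rng.choice(n_variants, size=min(n_causal, n_variants), replace=False)
    betas[idx] = rng.choice([-effect_scale, effect_scale], size=len(idx))
    return PhenotypeModel(
        true_betas=betas,
        ancestry_effects={"AFR": 0.3, "EUR": -0.2},
        target_case_fraction=target_case_fraction,
    )


def default_cohort(
    seed: int,
    n_samples: int = DEFAULT_N_SAMPLES,
    n_variants: int = 1200,
    base_n: int = 40_000,
    phenotype_model: PhenotypeModel | None = None,
) -> tuple[HaplotypeCohort, list[SummaryStatRecord]]:
    """The package's reference study conditions: a five-way admixed cohort of
    1,398 individuals (case fraction 661/1398) with emulated base-GWAS
    summary statistics from a 40,000-individual discovery study."""
    vmap = default_variant_map(n_variants)
    cohort = generate_cohort(AncestryModel(), n_samples, vmap, seed)
    if phenotype_model is None:
        phenotype_model = default_phenotype_model(n_variants, seed=seed + 1)
    cohort = simulate_phenotype(cohort, phenotype_model, seed + 2)
    sumstats = emulate_gwas(
        phenotype_model.true_betas,
        np.clip(_pooled_freqs(cohort), 1e-3, 1 - 1e-3),
        cohort.variants,
        base_n=base_n,
        seed=seed + 3,
    )
    return cohort, sumstats
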