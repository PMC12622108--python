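"""Readers and writers for every file dialect the pipeline touches.

All tabular formats are UTF-8, tab-delimited, with a mandatory header row.
Variant positions are 1-based; ancestry segments are BED-style 0-based
half-open. Genotypes travel either as plain VCF with phased GT fields
(read back through cyvcf2) or as a TSV dosage matrix (samples x variants).
"""
from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import AncestrySegment, SummaryStatRecord, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_sumstats",
    "write_sumstats",
    "read_genotypes",
    "write_vcf",
    "write_dosage_tsv",
    "read_segments",
    "write_segments",
    "read_covariates",
    "write_covariates",
    "read_phenotype",
    "write_phenotype",
    "align_samples",
    "GenotypeData",
]

_SUMSTAT_DEFAULTS = {
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "beta": "BETA",
    "p": "P",
}


def read_sumstats(path: str, column_map: dict | None = None) -> list[SummaryStatRecord]:
    """Read base-GWAS summary statistics.

    ``column_map`` overrides the default column names (CHR, BP, A1, A2,
    BETA, P). An odds-ratio column is accepted only explicitly, by mapping
    ``"or"`` instead of ``"beta"``; its values are log-transformed. Rows with
    missing or unparseable required fields are dropped and counted in the
    run log.
    """
    cmap = dict(_SUMSTAT_DEFAULTS)
    use_or = False
    if column_map:
        if "or" in column_map:
            use_or = True
            cmap.pop("beta", None)
            cmap["or"] = column_map["or"]
        for k, v in column_map.items():
            if k != "or":
                cmap[k] = v
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"empty summary-statistics file: {path}")
    effect_col = cmap["or"] if use_or else cmap["beta"]
    missing_cols = [
        c
        for c in (cmap["chrom"], cmap["pos"], cmap["effect_allele"],
                  cmap["other_allele"], effect_col, cmap["p"])
        if c not in df.columns
    ]
    if missing_cols:
        raise ValueError(f"unresolvable columns in {path}: {missing_cols}")

    records: list[SummaryStatRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        try:
            eff = float(d[effect_col])
            beta = math.log(eff) if use_or else eff
            rec = SummaryStatRecord(
                variant=VariantRecord(
                    chrom=str(d[cmap["chrom"]]),
                    pos=int(d[cmap["pos"]]),
                    effect_allele=str(d[cmap["effect_allele"]]),
                    other_allele=str(d[cmap["other_allele"]]),
                ),
                beta=beta,
                p_value=float(d[cmap["p"]]),
            )
        except (TypeError, ValueError):
            dropped += 1
            continue
        records.append(rec)
    if dropped:
        logger.warning("read_sumstats(%s): dropped %d malformed rows", path, dropped)
    if not records:
        raise ValueError(f"no parseable rows in {path}")
    return records


def write_sumstats(records: list[SummaryStatRecord], path: str) -> None:
    df = pd.DataFrame(
        {
            "CHR": [r.variant.chrom for r in records],
            "BP": [r.variant.pos for r in records],
            "A1": [r.variant.effect_allele for r in records],
            "A2": [r.variant.other_allele for r in records],
            "BETA": [repr(r.beta) for r in records],
            "P": [repr(r.p_value) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass
class GenotypeData:
    """Dosage view of a genotype file; haplotypes present only when the
    source dialect was phased."""

    samples: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray  # (n, m) float, NaN = missing
    haplotypes: np.ndarray | None = None  # (n, 2, m) int8


def write_vcf(
    samples: list[str],
    variants: list[VariantRecord],
    alleles: np.ndarray,
    path: str,
    missing_mask: np.ndarray | None = None,
) -> None:
    """Write phased genotypes as plain VCF (GT field, '|' separator).

    REF is the variant's other allele, ALT the effect allele, so an ALT count
    equals the effect-allele dosage.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j, v in enumerate(variants):
            gts = []
            for i in range(len(samples)):
                if missing_mask is not None and missing_mask[i, j]:
                    gts.append(".|.")
                else:
                    gts.append(f"{alleles[i, 0, j]}|{alleles[i, 1, j]}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.other_allele}\t{v.effect_allele}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_dosage_tsv(
    samples: list[str], variants: list[VariantRecord], dosages: np.ndarray, path: str
) -> None:
    df = pd.DataFrame(dosages, index=pd.Index(samples, name="ID"),
                      columns=[v.id for v in variants])
    df.to_csv(path, sep="\t")


def _read_vcf(path: str) -> GenotypeData:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    dosage_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    phased_everywhere = True
    for rec in vcf:
        v = VariantRecord(
            chrom=str(rec.CHROM),
            pos=int(rec.POS),
            effect_allele=rec.ALT[0],
            other_allele=rec.REF,
            id=rec.ID if rec.ID and rec.ID != "." else "",
        )
        variants.append(v)
        gts = np.asarray(rec.genotypes)  # (n, 3): allele0, allele1, phased flag
        a = gts[:, :2].astype(float)
        miss = a < 0
        a[miss] = np.nan
        dosage_rows.append(a[:, 0] + a[:, 1])  # NaN propagates for missing
        if not np.all(gts[:, 2][~miss.any(axis=1)]):
            phased_everywhere = False
        hap_rows.append(np.nan_to_num(a, nan=0).astype(np.int8))
    if not variants:
        raise ValueError(f"no variant records in {path}")
    ids = [v.id for v in variants]
    dup = sorted({i for i in ids if ids.count(i) > 1})
    if dup:
        raise ValueError(f"duplicated variant IDs in {path}: {dup}")
    dosages = np.stack(dosage_rows, axis=1)
    if np.nanmin(dosages) < 0 or np.nanmax(dosages) > 2:
        raise ValueError(f"dosage outside [0, 2] in {path}")
    haplotypes = None
    if phased_everywhere:
        haplotypes = np.stack(hap_rows, axis=2)  # (n, 2, m)
    return GenotypeData(samples, variants, dosages, haplotypes)


def _read_dosage_tsv(path: str) -> GenotypeData:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    ids = header[1:]  # pandas would mangle duplicate column names
    df = pd.read_csv(path, sep="\t", index_col=0)
    dup = sorted({i for i in ids if ids.count(i) > 1})
    if dup:
        raise ValueError(f"duplicated variant IDs in {path}: {dup}")
    variants = []
    for vid in ids:
        chrom, pos, other, effect = vid.split(":")
        variants.append(
            VariantRecord(chrom=chrom, pos=int(pos), effect_allele=effect,
                          other_allele=other, id=vid)
        )
    dosages = df.to_numpy(dtype=float)
    if np.nanmin(dosages) < 0 or np.nanmax(dosages) > 2:
        raise ValueError(f"dosage outside [0, 2] in {path}")
    return GenotypeData([str(s) for s in df.index], variants, dosages, None)


def read_genotypes(path: str) -> GenotypeData:
    """Read a VCF (``.vcf``/``.vcf.gz``) or a TSV dosage matrix.

    Sample and variant order are preserved exactly as on disk.
    """
    if path.endswith((".vcf", ".vcf.gz")):
        return _read_vcf(path)
    return _read_dosage_tsv(path)


def write_segments(segments: list[AncestrySegment], path: str) -> None:
    df = pd.DataFrame(
        {
            "sample": [s.sample for s in segments],
            "haplotype": [s.haplotype for s in segments],
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "ancestry": [s.ancestry for s in segments],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_segments(path: str) -> list[AncestrySegment]:
    """Read local-ancestry tracts and validate that each haplotype's segments
    tile its chromosome without gaps or overlaps."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    segs = [
        AncestrySegment(
            sample=r.sample,
            haplotype=int(r.haplotype),
            chrom=r.chrom,
            start=int(r.start),
            end=int(r.end),
            ancestry=str(r.ancestry),
        )
        for r in df.itertuples(index=False)
    ]
    validate_tiling(segs)
    # stable per-haplotype ordering by start
    segs.sort(key=lambda s: (s.sample, s.haplotype, s.chrom, s.start))
    return segs


def validate_tiling(segments: list[AncestrySegment]) -> None:
    """Raise if any haplotype's segments overlap or leave internal gaps."""
    groups: dict[tuple, list[AncestrySegment]] = {}
    for s in segments:
        groups.setdefault((s.sample, s.haplotype, s.chrom), []).append(s)
    for (sample, hap, chrom), segs in groups.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"segment overlap: sample {sample} hap {hap} {chrom}:"
                    f"{a.start}-{a.end} overlaps {b.start}-{b.end}"
                )
            if b.start > a.end:
                raise ValueError(
                    f"segment gap: sample {sample} hap {hap} {chrom}:"
                    f"{a.end}-{b.start} uncovered"
                )


def write_covariates(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="ID")


def read_covariates(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="ID")
    df.index = df.index.astype(str)
    return df


def write_phenotype(samples: list[str], status: np.ndarray, path: str) -> None:
    pd.DataFrame({"ID": samples, "STATUS": np.asarray(status, dtype=int)}).to_csv(
        path, sep="\t", index=False
    )


def read_phenotype(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"ID": str})
    status = df["STATUS"].astype(int)
    if not status.isin([0, 1]).all():
        raise ValueError(f"STATUS must be 0/1 in {path}")
    return pd.Series(status.to_numpy(), index=pd.Index(df["ID"], name="ID"))


def align_samples(reference_ids: list[str], *frames: pd.DataFrame | pd.Series):
    """Reindex covariate/phenotype tables to the genotype sample order.

    Hard error when any table's ID set differs from the reference — readers
    never silently reorder or subset samples.
    """
    ref = list(reference_ids)
    out = []
    for f in frames:
        if set(f.index) != set(ref):
            missing = sorted(set(ref) - set(f.index))[:5]
            extra = sorted(set(f.index) - set(ref))[:5]
            raise ValueError(
                f"sample ID mismatch (missing={missing}, unexpected={extra})"
            )
        out.append(f.loc[ref])
    return out[0] if len(out) == 1 else tuple(out)
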