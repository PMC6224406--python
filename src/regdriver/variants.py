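"""Somatic SNV table I/O, record-level QC filters, and WGS sensitivity.

The variant tables are MAF-like TSVs with 1-based inclusive positions and
per-record QC metrics (strand-split alternative read counts, mean base
quality, mean mapping quality, alignability).  Filters retain records with
at least one alternative read on each strand, mean Phred base quality > 26,
mean mapping quality >= 50, and alignability exactly 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

QC_COLUMNS = ["alt_fwd", "alt_rev", "mean_bq", "mean_mq", "alignability"]
MAF_COLUMNS = ["tumor_id", "chrom", "pos", "ref", "alt", *QC_COLUMNS]

#: QC rules in fixed attribution order: (name, predicate on a record row).
FILTER_RULES = [
    ("strand", lambda r: r.alt_fwd >= 1 and r.alt_rev >= 1),
    ("bq", lambda r: r.mean_bq > 26),
    ("mq", lambda r: r.mean_mq >= 50),
    ("alignability", lambda r: r.alignability == 1.0),
]


@dataclass(frozen=True)
class SNVRecord:
    """One somatic single-nucleotide substitution in one tumor."""

    tumor_id: str
    chrom: str
    pos: int                      # 1-based
    ref: str
    alt: str
    alt_fwd: int = 1
    alt_rev: int = 1
    mean_bq: float = 30.0
    mean_mq: float = 60.0
    alignability: float = 1.0

    def __post_init__(self):
        if self.ref == self.alt or len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"not a substitution: {self.ref}>{self.alt}")
        if self.alt_fwd < 0 or self.alt_rev < 0:
            raise ValueError("negative strand read counts")
        if not 0.0 <= self.alignability <= 1.0:
            raise ValueError("alignability outside [0, 1]")


@dataclass
class VariantCallSet:
    """Called variants of one sample with per-variant alternate allele ratios."""

    sample_id: str
    variants: set[tuple[str, int, str, str]]
    allele_ratios: dict[tuple[str, int, str, str], float] | None = None

    def __post_init__(self):
        if self.allele_ratios:
            bad = [v for v, r in self.allele_ratios.items() if not 0 <= r <= 1]
            if bad:
                raise ValueError(f"allele ratios outside [0, 1] for {bad[:3]}")


def filter_variants(
    records: list[SNVRecord],
) -> tuple[list[SNVRecord], dict[str, int]]:
    """Apply the record-level QC filters.

    Returns the passing records and a per-rule rejection count where each
    rejected record is attributed to the first rule it fails, in the fixed
    order strand, bq, mq, alignability.
    """
    passing: list[SNVRecord] = []
    rejections = {name: 0 for name, _ in FILTER_RULES}
    for rec in records:
        for name, ok in FILTER_RULES:
            if not ok(rec):
                rejections[name] += 1
                break
        else:
            passing.append(rec)
    return passing, rejections


def filter_variant_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Vectorized :func:`filter_variants` over a MAF-like DataFrame."""
    missing = [c for c in QC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records missing QC fields: {missing}")
    ok_strand = (df["alt_fwd"] >= 1) & (df["alt_rev"] >= 1)
    ok_bq = df["mean_bq"] > 26
    ok_mq = df["mean_mq"] >= 50
    ok_align = df["alignability"] == 1.0
    first_fail = pd.Series("pass", index=df.index)
    for name, ok in [("alignability", ok_align), ("mq", ok_mq),
                     ("bq", ok_bq), ("strand", ok_strand)]:
        first_fail[~ok] = name
    counts = first_fail.value_counts().to_dict()
    rejections = {name: int(counts.get(name, 0))
                  for name in ("strand", "bq", "mq", "alignability")}
    return df.loc[first_fail == "pass"].reset_index(drop=True), rejections


def estimate_sensitivity(
    wgs: VariantCallSet,
    wes: VariantCallSet,
    aar_min: float = 0.2,
) -> float | None:
    """WGS sensitivity against clonal WES variants.

    Clonal WES variants are those with alternate allele ratio > ``aar_min``.
    Returns the fraction of those recovered in the WGS call set (matching on
    full chrom/pos/ref/alt), or None when the WES clonal set is empty.
    """
    if wgs.sample_id != wes.sample_id:
        raise ValueError(
            f"sample mismatch: {wgs.sample_id} vs {wes.sample_id}"
        )
    if not 0 <= aar_min < 1:
        raise ValueError("aar_min must be in [0, 1)")
    ratios = wes.allele_ratios or {}
    clonal = {v for v in wes.variants if ratios.get(v, 1.0) > aar_min}
    if not clonal:
        return None
    return len(wgs.variants & clonal) / len(clonal)


def cohort_sensitivity(pairs: list[tuple[VariantCallSet, VariantCallSet]],
                       aar_min: float = 0.2) -> float | None:
    """Unweighted mean of per-sample sensitivities; None if none defined."""
    vals = [s for wgs, wes in pairs
            if (s := estimate_sensitivity(wgs, wes, aar_min)) is not None]
    return sum(vals) / len(vals) if vals else None


def read_maf(path: str | Path) -> pd.DataFrame:
    """Read a MAF-like TSV (1-based inclusive positions)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF-like table missing columns: {missing}")
    return df


def write_maf(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def records_from_frame(df: pd.DataFrame) -> list[SNVRecord]:
    return [
        SNVRecord(
            tumor_id=r.tumor_id, chrom=r.chrom, pos=int(r.pos),
            ref=r.ref, alt=r.alt, alt_fwd=int(r.alt_fwd),
            alt_rev=int(r.alt_rev), mean_bq=float(r.mean_bq),
            mean_mq=float(r.mean_mq), alignability=float(r.alignability),
        )
        for r in df.itertuples(index=False)
    ]
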