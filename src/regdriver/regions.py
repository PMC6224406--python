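"""Definition and filtering of regulatory regions.

Promoter windows are built around annotated transcription start sites
(400 bp upstream to 250 bp downstream, strand-aware, 651 bp total including
the TSS base); cis-regulatory element (CRE) fragments come from promoter
capture Hi-C interactions filtered on interaction score and linear distance.
Fragments are additionally screened for mappability and coding/UTR bases are
masked out of the testable region.

Internal coordinates are 0-based half-open throughout; 1-based inclusive
conventions (TSS tables, MAF-like variant tables) are converted at the I/O
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 400
PROMOTER_DOWNSTREAM = 250
CHICAGO_MIN_SCORE = 5.0
MAX_INTERACTION_DISTANCE = 1_000_000
MIN_MAPPABLE_FRACTION = 0.95
ORF_SPLICE_PAD = 5


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class PromoterRegion:
    """Promoter window with the set of bases that may host testable mutations."""

    gene_id: str
    tss: int                      # 0-based position of (one of) the TSS
    strand: str
    interval: GenomicInterval
    testable_mask: np.ndarray = field(default=None)  # bool over interval

    def __post_init__(self):
        if self.testable_mask is None:
            self.testable_mask = np.ones(len(self.interval), dtype=bool)

    @property
    def region_id(self) -> str:
        return f"promoter:{self.gene_id}:{self.interval.chrom}:{self.interval.start}"

    @property
    def n_testable(self) -> int:
        return int(self.testable_mask.sum())

    def testable_positions(self) -> np.ndarray:
        return self.interval.start + np.flatnonzero(self.testable_mask)


@dataclass
class CREFragment:
    """CRE fragment with interaction-backed target genes and testable mask."""

    fragment_id: str
    interval: GenomicInterval
    target_genes: list[str] = field(default_factory=list)
    scores: dict[str, float] = field(default_factory=dict)
    testable_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.testable_mask is None:
            self.testable_mask = np.ones(len(self.interval), dtype=bool)

    @property
    def region_id(self) -> str:
        return f"cre:{self.fragment_id}"

    @property
    def n_testable(self) -> int:
        return int(self.testable_mask.sum())

    def testable_positions(self) -> np.ndarray:
        return self.interval.start + np.flatnonzero(self.testable_mask)


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals (sorted, merged)."""
    out: list[list[int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(v) for v in out]


def define_promoters(
    tss_table: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
) -> list[PromoterRegion]:
    """Build strand-aware promoter windows from a TSS table.

    ``tss_table`` columns: gene, chrom, tss (1-based), strand.  The window
    spans ``PROMOTER_UPSTREAM`` bases upstream and ``PROMOTER_DOWNSTREAM``
    downstream of the TSS in gene orientation (651 bp including the TSS
    base).  Overlapping windows of the same gene are merged; windows are
    clipped at chromosome ends when lengths are supplied.
    """
    required = {"gene", "chrom", "tss", "strand"}
    missing = required - set(tss_table.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    bad = set(tss_table["strand"]) - {"+", "-"}
    if bad:
        raise ValueError(f"unknown strand symbols: {sorted(bad)}")

    promoters: list[PromoterRegion] = []
    for (gene, chrom, strand), grp in tss_table.groupby(
        ["gene", "chrom", "strand"], sort=True
    ):
        windows = []
        for tss_1b in grp["tss"]:
            tss0 = int(tss_1b) - 1
            if strand == "+":
                s, e = tss0 - PROMOTER_UPSTREAM, tss0 + PROMOTER_DOWNSTREAM + 1
            else:
                s, e = tss0 - PROMOTER_DOWNSTREAM, tss0 + PROMOTER_UPSTREAM + 1
            s = max(s, 0)
            if chrom_lengths is not None and chrom in chrom_lengths:
                e = min(e, chrom_lengths[chrom])
            if s < e:
                windows.append((s, e, tss0))
        merged = _merge_intervals([(s, e) for s, e, _ in windows])
        for s, e in merged:
            tss0 = next(t for ws, we, t in windows if ws >= s and we <= e)
            promoters.append(
                PromoterRegion(
                    gene_id=gene,
                    tss=tss0,
                    strand=strand,
                    interval=GenomicInterval(chrom, s, e),
                )
            )
    return promoters


def filter_interactions(interactions: pd.DataFrame) -> pd.DataFrame:
    """Retain promoter-CRE interactions with score >= 5 and distance <= 1 Mb.

    ``interactions`` columns: chrom, start, end (fragment, 0-based half-open),
    gene, score, distance.  Both thresholds are inclusive.
    """
    if (interactions["distance"] < 0).any():
        raise ValueError("negative promoter-fragment distance")
    keep = (interactions["score"] >= CHICAGO_MIN_SCORE) & (
        interactions["distance"] <= MAX_INTERACTION_DISTANCE
    )
    return interactions.loc[keep].reset_index(drop=True)


def _covered_bases(interval: GenomicInterval, track: pd.DataFrame) -> int:
    """Bases of ``interval`` covered by the union of track intervals."""
    sel = track.loc[track["chrom"] == interval.chrom, ["start", "end"]]
    clipped = [
        (max(s, interval.start), min(e, interval.end))
        for s, e in sel.itertuples(index=False)
        if max(s, interval.start) < min(e, interval.end)
    ]
    return sum(e - s for s, e in _merge_intervals(clipped))


def mappability_filter(
    fragments: list[CREFragment],
    well_mapped_track: pd.DataFrame,
    min_fraction: float = MIN_MAPPABLE_FRACTION,
) -> list[CREFragment]:
    """Keep fragments whose well-mapped base fraction is >= ``min_fraction``.

    ``well_mapped_track`` is a BED-like frame (chrom, start, end) of
    well-mapped intervals.  A fragment with no track coverage counts as 0%
    well mapped and is dropped (logged).
    """
    kept = []
    for frag in fragments:
        covered = _covered_bases(frag.interval, well_mapped_track)
        frac = covered / len(frag.interval)
        if covered == 0:
            logger.info("fragment %s has no mappability coverage; dropped", frag.fragment_id)
        if frac >= min_fraction:
            kept.append(frag)
    return kept


def mask_coding(
    region: PromoterRegion | CREFragment,
    annotation: pd.DataFrame,
    kind: str,
) -> np.ndarray:
    """Mask coding/UTR bases out of a region's testable set.

    ``annotation`` is BED-like (chrom, start, end, class) with class in
    {ORF, UTR5, UTR3}.  For CREs, ORFs are padded by 5 bp on each side to
    cover splice sites and UTR bases are removed from the mask.  Promoter
    windows keep their full mask; ORF-overlapping promoter mutations are
    instead excluded at test time (see :func:`orf_positions`).
    """
    if kind not in ("promoter", "CRE"):
        raise ValueError(f"unknown region kind {kind!r}")
    mask = np.ones(len(region.interval), dtype=bool)
    if kind == "promoter":
        region.testable_mask = mask
        return mask
    iv = region.interval
    sel = annotation.loc[annotation["chrom"] == iv.chrom]
    for s, e, cls in sel[["start", "end", "class"]].itertuples(index=False):
        if cls == "ORF":
            s, e = s - ORF_SPLICE_PAD, e + ORF_SPLICE_PAD
        elif cls not in ("UTR5", "UTR3"):
            continue
        lo, hi = max(s, iv.start), min(e, iv.end)
        if lo < hi:
            mask[lo - iv.start : hi - iv.start] = False
    region.testable_mask = mask
    return mask


def orf_positions(annotation: pd.DataFrame, chrom: str) -> list[tuple[int, int]]:
    """Merged ORF intervals on one chromosome (for promoter mutation exclusion)."""
    sel = annotation.loc[
        (annotation["chrom"] == chrom) & (annotation["class"] == "ORF"),
        ["start", "end"],
    ]
    return _merge_intervals([tuple(r) for r in sel.itertuples(index=False)])
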