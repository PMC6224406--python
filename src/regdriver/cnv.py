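"""Copy-number events, karyotype assignment, and CNV-at-CRE expression tests.

Events are called from pre-segmented copy-number data (|log2 ratio| >=
0.1613); focal events are additionally shorter than 3 Mb.  A chromosome
counts as amplified when at least 90% of its length is covered by
amplification events, and hyperdiploidy (HD) requires at least two amplified
autosomes.  CNV groups at a CRE are compared to copy-neutral samples with
the exact-style NB expression test, skipping groups of fewer than 7 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _fisher_exact

from .expression import ExpressionMatrix, estimate_dispersion, nb_two_group_test
from .recurrence import bh_fdr
from .regions import GenomicInterval, _merge_intervals

CNV_LOG2_MIN = 0.1613
FOCAL_MAX_SIZE = 3_000_000
CHROM_AMP_FRACTION = 0.90
MIN_CNV_GROUP = 7
AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


@dataclass(frozen=True)
class CNVSegment:
    sample_id: str
    interval: GenomicInterval
    log2_ratio: float


@dataclass
class KaryotypeCall:
    sample_id: str
    hd: bool
    amplified_chromosomes: set = field(default_factory=set)
    translocations: set = field(default_factory=set)


def call_events(segments: pd.DataFrame, focal_only: bool = False) -> pd.DataFrame:
    """Copy-number events with |log2 ratio| >= 0.1613.

    ``segments``: sample_id, chrom, start, end, log2_ratio.  Adds a
    ``direction`` column (amplification/deletion); with ``focal_only`` the
    event must additionally span < 3 Mb.
    """
    ev = segments.loc[segments["log2_ratio"].abs() >= CNV_LOG2_MIN].copy()
    if focal_only:
        ev = ev.loc[(ev["end"] - ev["start"]) < FOCAL_MAX_SIZE]
    ev["direction"] = np.where(ev["log2_ratio"] > 0, "amplification", "deletion")
    return ev.reset_index(drop=True)


def chromosome_amplified(
    segments: pd.DataFrame,
    chrom_lengths: dict[str, int],
) -> dict[str, bool]:
    """Per-chromosome flag: >= 90% of length covered by amplification events."""
    amps = call_events(segments)
    amps = amps.loc[amps["direction"] == "amplification"]
    out: dict[str, bool] = {}
    for chrom, grp in amps.groupby("chrom"):
        if chrom not in chrom_lengths:
            raise ValueError(f"no length for chromosome {chrom}")
        L = chrom_lengths[chrom]
        ivals = [(max(0, s), min(e, L)) for s, e in
                 grp[["start", "end"]].itertuples(index=False) if s < e]
        covered = sum(e - s for s, e in _merge_intervals(ivals))
        out[chrom] = covered / L >= CHROM_AMP_FRACTION
    for chrom in chrom_lengths:
        out.setdefault(chrom, False)
    return out


def assign_karyotype(
    sample_id: str,
    segments: pd.DataFrame,
    chrom_lengths: dict[str, int],
    translocations: set | None = None,
) -> KaryotypeCall:
    """HD call (>= 2 amplified autosomes) plus pass-through translocations."""
    amp = chromosome_amplified(segments, chrom_lengths)
    amplified = {c for c, flag in amp.items() if flag}
    n_auto = sum(1 for c in amplified if c in AUTOSOMES)
    return KaryotypeCall(
        sample_id=sample_id,
        hd=n_auto >= 2,
        amplified_chromosomes=amplified,
        translocations=set(translocations or ()),
    )


def karyotype_table(
    segments: pd.DataFrame,
    chrom_lengths: dict[str, int],
    metadata: pd.DataFrame,
) -> list[KaryotypeCall]:
    """Karyotype calls for every sample in ``metadata`` (sample_id, translocations)."""
    calls = []
    seg_by_sample = {s: g for s, g in segments.groupby("sample_id")}
    empty = segments.iloc[0:0]
    for row in metadata.itertuples(index=False):
        labels = set()
        if getattr(row, "translocations", ""):
            val = getattr(row, "translocations")
            if isinstance(val, str) and val:
                labels = set(val.split(";"))
        calls.append(assign_karyotype(
            row.sample_id, seg_by_sample.get(row.sample_id, empty),
            chrom_lengths, labels))
    return calls


def cre_cnv_expression(
    cre_iv: GenomicInterval,
    gene_id: str,
    gene_iv: GenomicInterval,
    segments: pd.DataFrame,
    expr: ExpressionMatrix,
    min_group: int = MIN_CNV_GROUP,
    dispersion: float | None = None,
) -> list[dict]:
    """NB expression test of CNV-at-CRE groups against copy-neutral samples.

    Samples are grouped by focal amplification / focal deletion overlapping
    the CRE; samples whose target gene itself carries an event (including a
    single CNV spanning both CRE and gene) are excluded.  Groups smaller
    than ``min_group`` are skipped.  Returns one dict per tested direction
    with fold change and p-value.
    """
    events = call_events(segments)
    focal = call_events(segments, focal_only=True)

    def overlapping(ev: pd.DataFrame, iv: GenomicInterval) -> pd.DataFrame:
        return ev.loc[(ev["chrom"] == iv.chrom)
                      & (ev["start"] < iv.end) & (ev["end"] > iv.start)]

    gene_hit = set(overlapping(events, gene_iv)["sample_id"])
    cre_hits = overlapping(focal, cre_iv)
    amp = set(cre_hits.loc[cre_hits["direction"] == "amplification", "sample_id"])
    dele = set(cre_hits.loc[cre_hits["direction"] == "deletion", "sample_id"])
    profiled = set(expr.samples)
    amp = (amp - gene_hit) & profiled
    dele = (dele - gene_hit) & profiled
    neutral = (profiled - set(overlapping(events, cre_iv)["sample_id"])
               - gene_hit)
    results = []
    for direction, group in (("amplification", amp), ("deletion", dele)):
        if len(group) < min_group or len(neutral) < 2:
            continue
        g_l, n_l = sorted(group), sorted(neutral)
        y1 = expr.adjusted(gene_id, g_l)
        y2 = expr.adjusted(gene_id, n_l)
        if dispersion is None:
            labels = np.array([0] * len(g_l) + [1] * len(n_l))
            phi = estimate_dispersion(np.concatenate([y1, y2]), labels)
        else:
            phi = dispersion
        fc, p = nb_two_group_test(y1, y2, phi)
        results.append({
            "gene_id": gene_id, "direction": direction,
            "n_group": len(group), "n_neutral": len(neutral),
            "fold_change": fc, "p": p,
        })
    return results


def cnv_de_table(rows: list[dict]) -> pd.DataFrame:
    """Collect cre_cnv_expression outputs and BH-adjust within the batch."""
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_fdr(np.clip(df["p"].to_numpy(), 1e-300, 1.0))
    return df


def cnv_translocation_enrichment(
    cnv_group: set,
    translocated: set,
    cohort: set,
) -> tuple[np.ndarray, float, float]:
    """One-sided (greater) Fisher test of translocation enrichment in a CNV group."""
    if not cohort:
        raise ValueError("empty cohort")
    if not (cnv_group <= cohort and translocated <= cohort):
        raise ValueError("groups must be subsets of the cohort")
    a = len(cnv_group & translocated)
    b = len(cnv_group - translocated)
    c = len(translocated - cnv_group)
    d = len(cohort) - a - b - c
    table = np.array([[a, b], [c, d]])
    odds, p = _fisher_exact(table, alternative="greater")
    return table, float(odds), float(p)


def genes_near_breakpoints(
    breakpoints: list[tuple[str, int]],
    gene_table: pd.DataFrame,
    window: int = 1_000_000,
) -> list[str]:
    """Genes whose interval lies within ``window`` bp of any breakpoint.

    ``gene_table``: gene, chrom, start, end (0-based half-open).  Distance 0
    for overlapping genes; boundary inclusive.  Deduplicated, sorted.
    """
    hits = set()
    for chrom, pos in breakpoints:
        sel = gene_table.loc[gene_table["chrom"] == chrom]
        for g, s, e in sel[["gene", "start", "end"]].itertuples(index=False):
            dist = max(s - pos, pos - (e - 1), 0)
            if dist <= window:
                hits.add(g)
    return sorted(hits)
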