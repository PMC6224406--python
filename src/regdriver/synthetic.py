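"""Synthetic tumor-cohort generator with known ground truth.

Emits every input the analysis consumes — TSS table, promoter-CRE
interaction table, covariate tracks, mappability BED, MAF-like SNV table,
SEG copy-number file, gene x sample count matrix, sample metadata, and a
signature catalog — from one integer seed, together with a truth object
recording the spiked driver regions, background coefficients, expression
effects, karyotypes, and signature exposures.

Background mutations follow the same logistic model the analysis fits:
logit(p) = b0 + b_ref*refclass + b_rt*reptime + b_cov*coverage + offset_t,
with covariates piecewise constant over 1-kb windows.  Driver regions get a
rate multiplier and, optionally, a hotspot: a fixed fraction of the
region's mutations are moved onto one shared position.  The default
per-base rate is far above a patient genome's: the cohort (50 tumors) and
genome (a few Mb) are desk-scale, and the rate is set so per-region counts
give the discrete recurrence statistics the same resolution they have at
population scale (see docs/methods.md).

All randomness derives from the single seed through named substreams, so
identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import regions as reg
from .signatures import (
    CHANNELS,
    SignatureCatalog,
    make_synthetic_catalog,
    revcomp,
)

WINDOW = 1000  # bp; covariates are piecewise constant over these windows
_COMP = str.maketrans("ACGT", "TGCA")

# named substreams off the global seed
_STAGES = {
    "covariates": 1, "tss": 2, "interactions": 3, "mappability": 4,
    "snv": 5, "hotspot": 6, "alleles": 7, "expression": 8, "cnv": 9,
    "metadata": 10, "qc": 11,
}

TRANSLOCATION_PROBS = {
    "t(4;14)": 0.12, "t(11;14)": 0.19, "t(14;16)": 0.04,
    "t(14;20)": 0.015, "MYC": 0.24,
}


@dataclass
class BackgroundCoefs:
    intercept: float = -7.0
    beta_refclass: float = 0.25
    beta_reptime: float = 0.5
    beta_coverage: float = 0.3
    tumor_offset_sd: float = 0.5


@dataclass
class DriverSpec:
    """A spiked driver: ``region`` is 'promoter:<gene>' or 'cre:<fragment>'."""

    region: str
    multiplier: float = 10.0
    concentration: float = 0.5
    expression_fold_change: float = 1.0

    def __post_init__(self):
        if self.multiplier < 1:
            raise ValueError("rate multiplier must be >= 1")
        if not 0 <= self.concentration <= 1:
            raise ValueError("hotspot concentration must be in [0, 1]")

    @property
    def is_true_driver(self) -> bool:
        return (self.multiplier > 1 or self.concentration > 0
                or self.expression_fold_change != 1.0)


@dataclass
class CNVSpec:
    """Focal sizes default to desk-genome scale (tens of kb), so CNV
    exclusions thin, rather than erase, the expression comparison groups."""

    focal_rate: float = 3.0          # mean focal events per sample
    focal_size_mean: float = 50_000   # bp, exponential
    hd_fraction: float = 0.3
    translocation_fraction: float = 1.0  # scales the per-label probabilities


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_tumors: int = 50
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 750_000 for i in range(1, 5)})
    n_genes: int = 100
    fragment_size: int = 2000
    interaction_score_dist: tuple[float, float] = (6.0, 2.0)
    background_coefs: BackgroundCoefs = field(default_factory=BackgroundCoefs)
    driver_spec: list[DriverSpec] = field(default_factory=list)
    expression_spec: dict[str, tuple[float, float, float]] | None = None
    cnv_spec: CNVSpec = field(default_factory=CNVSpec)
    signature_mix: dict[str, float] = field(
        default_factory=lambda: {"S1": 0.5, "S2": 0.3, "S3": 0.2})
    expression_baseline_mean: float = 200.0
    expression_dispersion: float = 0.2
    qc_fail_fraction: float = 0.02

    def validate(self) -> None:
        if self.n_tumors <= 0 or self.n_genes <= 0:
            raise ValueError("degenerate config: need > 0 tumors and genes")
        if any(v <= 0 for v in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.fragment_size >= min(self.chrom_lengths.values()):
            raise ValueError("fragment_size must be smaller than chromosomes")
        if abs(sum(self.signature_mix.values()) - 1.0) > 1e-9:
            raise ValueError("signature mix weights must sum to 1")


@dataclass
class SyntheticTruth:
    driver_regions: dict[str, dict]
    true_background_coefs: dict[str, float]
    true_expression_effects: dict[str, float]
    sample_karyotypes: dict[str, dict]
    true_exposures: dict[str, dict[str, float]]
    region_ids: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rng(config: GeneratorConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STAGES[stage],)))


def spike_hotspot(
    positions: np.ndarray,
    region_positions: np.ndarray,
    concentration: float,
    rng_seed: int | np.random.Generator,
) -> np.ndarray:
    """Move a ``concentration`` fraction of mutations onto one shared base.

    ``region_positions`` are the candidate (testable) bases of the region.
    Exactly round(concentration * m) mutations are relocated to a single
    randomly chosen hotspot position; the rest keep their uniform placement.
    """
    if not 0 <= concentration <= 1:
        raise ValueError("concentration must be in [0, 1]")
    region_positions = np.asarray(region_positions)
    if region_positions.size == 0:
        raise ValueError("empty region")
    positions = np.asarray(positions).copy()
    m = len(positions)
    k = int(round(concentration * m))
    if k == 0 or m == 0:
        return positions
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    hotspot = int(rng.choice(region_positions))
    moved = rng.permutation(m)[:k]
    positions[moved] = hotspot
    return positions


# ---------------------------------------------------------------------------
# stage generators

def _smooth_field(rng: np.random.Generator, n: int,
                  rho: float = 0.99) -> np.ndarray:
    """Stationary AR(1) field with N(0,1) marginals.

    Replication timing and coverage vary smoothly along the genome
    (correlation length ~100 windows here), unlike base composition.
    """
    z = np.empty(n)
    z[0] = rng.normal()
    eps = rng.normal(0, np.sqrt(1 - rho**2), n - 1) if n > 1 else []
    for i in range(1, n):
        z[i] = rho * z[i - 1] + eps[i - 1]
    return z


def _make_windows(config: GeneratorConfig) -> pd.DataFrame:
    rng = _rng(config, "covariates")
    rows = []
    for chrom in sorted(config.chrom_lengths):
        L = config.chrom_lengths[chrom]
        starts = np.arange(0, L, WINDOW)
        ends = np.minimum(starts + WINDOW, L)
        n = len(starts)
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "ref_class": rng.integers(0, 2, n),   # 1 = A/T, 0 = G/C
            "reptime": np.round(_smooth_field(rng, n), 6),
            "coverage": np.round(_smooth_field(rng, n), 6),
        }))
    return pd.concat(rows, ignore_index=True)


def _make_tss(config: GeneratorConfig) -> pd.DataFrame:
    rng = _rng(config, "tss")
    chroms = sorted(config.chrom_lengths)
    weights = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    per_chrom = rng.multinomial(config.n_genes, weights)
    rows = []
    g = 0
    pad = reg.PROMOTER_UPSTREAM + reg.PROMOTER_DOWNSTREAM + 10
    for chrom, n in zip(chroms, per_chrom):
        L = config.chrom_lengths[chrom]
        # evenly spaced with jitter keeps promoters mostly non-overlapping
        slots = np.linspace(pad, L - pad, max(n, 1), dtype=int)
        jitter = rng.integers(-200, 201, len(slots))
        for s, j in zip(slots[:n], jitter[:n]):
            rows.append((f"G{g:05d}", chrom, int(np.clip(s + j, pad, L - pad)) + 1,
                         "+" if rng.random() < 0.5 else "-"))
            g += 1
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])


def _make_interactions(config: GeneratorConfig, tss: pd.DataFrame) -> pd.DataFrame:
    """Fragment tiling plus promoter-CRE links with scores straddling 5."""
    rng = _rng(config, "interactions")
    mean, sd = config.interaction_score_dist
    rows = []
    fid = 0
    tss_by_chrom = {c: g for c, g in tss.groupby("chrom")}
    for chrom in sorted(config.chrom_lengths):
        L = config.chrom_lengths[chrom]
        genes = tss_by_chrom.get(chrom)
        if genes is None:
            continue
        n_frags = L // config.fragment_size
        # link roughly 3 fragments per gene
        n_links = min(3 * len(genes), int(n_frags))
        frag_idx = rng.choice(int(n_frags), size=n_links, replace=False)
        for i in sorted(frag_idx):
            start = int(i) * config.fragment_size
            end = min(start + config.fragment_size, L)
            gene_row = genes.iloc[int(rng.integers(0, len(genes)))]
            tss0 = int(gene_row["tss"]) - 1
            dist = max(0, max(start - tss0, tss0 - (end - 1)))
            score = float(np.round(rng.normal(mean, sd), 3))
            rows.append((f"F{fid:05d}", chrom, start, end,
                         gene_row["gene"], max(score, 0.0), dist))
            fid += 1
    return pd.DataFrame(rows, columns=[
        "fragment_id", "chrom", "start", "end", "gene", "score", "distance"])


def _make_mappability(config: GeneratorConfig,
                      interactions: pd.DataFrame) -> pd.DataFrame:
    """Well-mapped BED: whole genome minus holes in ~8% of fragments."""
    rng = _rng(config, "mappability")
    holes: list[tuple[str, int, int]] = []
    for row in interactions.itertuples(index=False):
        if rng.random() < 0.08:
            span = row.end - row.start
            hole = int(span * 0.10)  # 10% hole -> below the 95% rule
            s = row.start + int(rng.integers(0, max(span - hole, 1)))
            holes.append((row.chrom, s, s + hole))
    rows = []
    for chrom in sorted(config.chrom_lengths):
        L = config.chrom_lengths[chrom]
        cuts = sorted([h for h in holes if h[0] == chrom],
                      key=lambda h: h[1])
        pos = 0
        for _, hs, he in cuts:
            hs, he = max(hs, 0), min(he, L)
            if hs > pos:
                rows.append((chrom, pos, hs))
            pos = max(pos, he)
        if pos < L:
            rows.append((chrom, pos, L))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _resolve_driver_interval(spec: DriverSpec, promoters, fragments):
    if spec.region.startswith("promoter:"):
        gene = spec.region.split(":", 1)[1]
        for p in promoters:
            if p.gene_id == gene:
                return p.region_id, p.interval
        raise ValueError(f"driver references unknown gene {gene}")
    if spec.region.startswith("cre:"):
        frag = spec.region.split(":", 1)[1]
        for f in fragments:
            if f.fragment_id == frag:
                return f.region_id, f.interval
        raise ValueError(f"driver references unknown fragment {frag}")
    raise ValueError(f"unparseable driver region {spec.region!r}")


def _sample_snv_positions(config: GeneratorConfig, windows: pd.DataFrame,
                          driver_ivals: dict[str, tuple],
                          ) -> tuple[pd.DataFrame, np.ndarray]:
    """Place background + driver-excess mutations; returns (snv frame, offsets)."""
    from scipy.special import expit

    rng = _rng(config, "snv")
    bc = config.background_coefs
    offsets = np.round(rng.normal(0, bc.tumor_offset_sd, config.n_tumors), 6)
    eta_w = (bc.intercept + bc.beta_refclass * windows["ref_class"].to_numpy()
             + bc.beta_reptime * windows["reptime"].to_numpy()
             + bc.beta_coverage * windows["coverage"].to_numpy())
    w_chrom = windows["chrom"].to_numpy()
    w_start = windows["start"].to_numpy()
    w_len = (windows["end"] - windows["start"]).to_numpy()
    tumors = [f"T{t:04d}" for t in range(config.n_tumors)]

    chroms_out, pos_out, tum_out = [], [], []
    for t, tid in enumerate(tumors):
        p_w = expit(eta_w + offsets[t])
        counts = rng.binomial(w_len, p_w)
        nz = np.flatnonzero(counts)
        for wi in nz:
            offs = rng.integers(0, w_len[wi], counts[wi])
            pos_out.append(w_start[wi] + offs)
            chroms_out.extend([w_chrom[wi]] * counts[wi])
            tum_out.extend([tid] * counts[wi])
    snv = pd.DataFrame({
        "tumor_id": tum_out,
        "chrom": chroms_out,
        "pos0": (np.concatenate(pos_out) if pos_out
                 else np.array([], dtype=int)),
    })

    # driver excess: extra mutations at rate (multiplier - 1) * p over the region
    extra_rows = []
    widx_by_chrom = {
        c: (np.flatnonzero(w_chrom == c), w_start[w_chrom == c])
        for c in sorted(config.chrom_lengths)
    }
    for rid, (spec, ival) in driver_ivals.items():
        if spec.multiplier <= 1:
            continue
        idx, starts = widx_by_chrom[ival.chrom]
        pos_all = np.arange(ival.start, ival.end)
        wi = idx[np.searchsorted(starts, pos_all, side="right") - 1]
        base_eta = eta_w[wi]
        for t, tid in enumerate(tumors):
            p_extra = np.clip(expit(base_eta + offsets[t])
                              * (spec.multiplier - 1), 0, 0.9)
            hits = rng.random(len(pos_all)) < p_extra
            for p in pos_all[hits]:
                extra_rows.append((tid, ival.chrom, int(p)))
    if extra_rows:
        snv = pd.concat([snv, pd.DataFrame(
            extra_rows, columns=["tumor_id", "chrom", "pos0"])],
            ignore_index=True)
    return snv, offsets


def _apply_hotspots(config: GeneratorConfig, snv: pd.DataFrame,
                    driver_ivals: dict[str, tuple]) -> pd.DataFrame:
    rng = _rng(config, "hotspot")
    for rid, (spec, ival) in sorted(driver_ivals.items()):
        if spec.concentration <= 0:
            continue
        sel = ((snv["chrom"] == ival.chrom) & (snv["pos0"] >= ival.start)
               & (snv["pos0"] < ival.end))
        if sel.sum() == 0:
            continue
        moved = spike_hotspot(snv.loc[sel, "pos0"].to_numpy(),
                              np.arange(ival.start, ival.end),
                              spec.concentration, rng)
        snv.loc[sel, "pos0"] = moved
    return snv


def _assign_alleles(config: GeneratorConfig, snv: pd.DataFrame,
                    windows: pd.DataFrame,
                    catalog: SignatureCatalog) -> pd.DataFrame:
    """Draw ref/alt/context from the signature mixture, honoring window class."""
    rng = _rng(config, "alleles")
    mix = pd.Series(config.signature_mix)
    probs = catalog.matrix[mix.index].to_numpy() @ mix.to_numpy()
    ch_ref = np.array([c[2] for c in CHANNELS])       # C or T
    ch_alt = np.array([c[4] for c in CHANNELS])
    ch_five = np.array([c[0] for c in CHANNELS])
    ch_three = np.array([c[6] for c in CHANNELS])
    is_c = ch_ref == "C"
    p_gc = np.where(is_c, probs, 0); p_gc /= p_gc.sum()
    p_at = np.where(~is_c, probs, 0); p_at /= p_at.sum()

    w_sorted = windows.sort_values(["chrom", "start"])
    starts_by_chrom = {c: (g["start"].to_numpy(), g["ref_class"].to_numpy())
                       for c, g in w_sorted.groupby("chrom")}
    n = len(snv)
    refs = np.empty(n, dtype=object)
    alts = np.empty(n, dtype=object)
    ctxs = np.empty(n, dtype=object)
    chroms = snv["chrom"].to_numpy()
    pos0 = snv["pos0"].to_numpy()
    for chrom, (starts, refclass) in starts_by_chrom.items():
        m = chroms == chrom
        if not m.any():
            continue
        wi = np.searchsorted(starts, pos0[m], side="right") - 1
        at_class = refclass[wi] == 1
        idx = np.flatnonzero(m)
        for at, p_ch in ((True, p_at), (False, p_gc)):
            sub = idx[at_class == at]
            if sub.size == 0:
                continue
            ch = rng.choice(96, size=sub.size, p=p_ch)
            flip = rng.random(sub.size) < 0.5
            outer = rng.integers(0, 4, size=(sub.size, 2))
            bases = np.array(list("ACGT"))
            for j, (i_snv, c_i, fl, (o1, o2)) in enumerate(
                    zip(sub, ch, flip, outer)):
                tri = ch_five[c_i] + ch_ref[c_i] + ch_three[c_i]
                ctx5 = bases[o1] + tri + bases[o2]
                r, a = ch_ref[c_i], ch_alt[c_i]
                if fl:
                    ctx5 = revcomp(ctx5)
                    r, a = r.translate(_COMP), a.translate(_COMP)
                refs[i_snv], alts[i_snv], ctxs[i_snv] = r, a, ctx5
    out = snv.copy()
    out["ref"], out["alt"], out["context"] = refs, alts, ctxs
    return out


def _attach_qc(config: GeneratorConfig, snv: pd.DataFrame) -> pd.DataFrame:
    rng = _rng(config, "qc")
    n = len(snv)
    out = snv.copy()
    out["alt_fwd"] = rng.integers(1, 6, n)
    out["alt_rev"] = rng.integers(1, 6, n)
    out["mean_bq"] = np.round(rng.uniform(27.0, 38.0, n), 2)
    out["mean_mq"] = np.round(rng.uniform(50.0, 60.0, n), 2)
    out["alignability"] = 1.0
    fail = rng.random(n) < config.qc_fail_fraction
    mode = rng.integers(0, 4, n)
    out.loc[fail & (mode == 0), "alt_rev"] = 0
    out.loc[fail & (mode == 1), "mean_bq"] = 24.0
    out.loc[fail & (mode == 2), "mean_mq"] = 42.0
    out.loc[fail & (mode == 3), "alignability"] = 0.9
    return out


def _make_cnv(config: GeneratorConfig, tumors: list[str]
              ) -> tuple[pd.DataFrame, dict[str, dict]]:
    rng = _rng(config, "cnv")
    cs = config.cnv_spec
    rows = []
    karyo: dict[str, dict] = {}
    chroms = sorted(config.chrom_lengths)
    for tid in tumors:
        events: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chroms}
        hd = bool(rng.random() < cs.hd_fraction)
        amp_chroms: list[str] = []
        if hd:
            n_amp = min(2 + int(rng.integers(0, 2)), len(chroms))
            amp_chroms = list(rng.choice(chroms, size=n_amp, replace=False))
            for c in amp_chroms:
                L = config.chrom_lengths[c]
                events[c].append((0, int(L * 0.97), 0.32))
        n_focal = rng.poisson(cs.focal_rate)
        for _ in range(n_focal):
            c = chroms[int(rng.integers(0, len(chroms)))]
            if c in amp_chroms:
                continue
            L = config.chrom_lengths[c]
            size = int(min(max(rng.exponential(cs.focal_size_mean), 5_000),
                           2_900_000))
            s = int(rng.integers(0, max(L - size, 1)))
            lr = float(np.round(rng.uniform(0.2, 0.8)
                                * (1 if rng.random() < 0.5 else -1), 4))
            # keep segments non-overlapping: drop if clashing
            if any(s < e2 and s + size > s2 for s2, e2, _ in events[c]):
                continue
            events[c].append((s, s + size, lr))
        for c in chroms:
            L = config.chrom_lengths[c]
            evs = sorted(events[c])
            pos = 0
            for s, e, lr in evs:
                if s > pos:
                    rows.append((tid, c, pos, s, 0.0))
                rows.append((tid, c, s, e, lr))
                pos = e
            if pos < L:
                rows.append((tid, c, pos, L, 0.0))
        karyo[tid] = {"hd": hd, "amplified": sorted(amp_chroms)}
    seg = pd.DataFrame(rows, columns=[
        "sample_id", "chrom", "start", "end", "log2_ratio"])
    return seg, karyo


def _make_metadata(config: GeneratorConfig, tumors: list[str],
                   karyo: dict[str, dict]) -> pd.DataFrame:
    rng = _rng(config, "metadata")
    rows = []
    scale = config.cnv_spec.translocation_fraction
    for tid in tumors:
        labels = [lab for lab, pr in TRANSLOCATION_PROBS.items()
                  if rng.random() < pr * scale]
        rows.append((tid, ";".join(labels), int(karyo[tid]["hd"])))
        karyo[tid]["translocations"] = labels
    return pd.DataFrame(rows, columns=["sample_id", "translocations", "hd"])


def _make_expression(config: GeneratorConfig, tumors: list[str],
                     tss: pd.DataFrame,
                     mutated_by_gene: dict[str, set],
                     expr_spec: dict[str, tuple[float, float, float]] | None = None,
                     ) -> tuple[pd.DataFrame, dict[str, float]]:
    rng = _rng(config, "expression")
    genes = list(tss["gene"])
    spec = expr_spec if expr_spec is not None else (config.expression_spec or {})
    lib = np.exp(rng.normal(0, 0.05, len(tumors)))
    counts = np.zeros((len(genes), len(tumors)), dtype=int)
    effects: dict[str, float] = {}
    for gi, g in enumerate(genes):
        base, phi, fc = spec.get(
            g, (float(np.round(rng.lognormal(np.log(config.expression_baseline_mean),
                                             0.5), 2)),
                config.expression_dispersion, 1.0))
        effects[g] = fc
        mutated = mutated_by_gene.get(g, set())
        mu = np.array([base * fc if t in mutated else base for t in tumors]) * lib
        if phi > 0:
            r = 1.0 / phi
            counts[gi] = rng.negative_binomial(r, r / (r + mu))
        else:
            counts[gi] = rng.poisson(mu)
    df = pd.DataFrame(counts, index=genes, columns=tumors)
    df.index.name = "gene"
    return df, effects


# ---------------------------------------------------------------------------
# top level

def generate_cohort(config: GeneratorConfig, outdir: str | Path
                    ) -> tuple[dict[str, Path], SyntheticTruth]:
    """Generate a full synthetic cohort under ``outdir``.

    Returns ({file key: path}, truth).  Reproducible byte-for-byte from
    ``config.seed``.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    windows = _make_windows(config)
    tss = _make_tss(config)
    interactions = _make_interactions(config, tss)
    mappability = _make_mappability(config, interactions)
    catalog = make_synthetic_catalog(
        n_signatures=max(3, len(config.signature_mix)), seed=config.seed)

    promoters = reg.define_promoters(tss, config.chrom_lengths)
    fragments = [
        reg.CREFragment(fragment_id=r.fragment_id,
                        interval=reg.GenomicInterval(r.chrom, r.start, r.end),
                        target_genes=[r.gene], scores={r.gene: r.score})
        for r in interactions.itertuples(index=False)
    ]
    driver_ivals: dict[str, tuple[DriverSpec, reg.GenomicInterval]] = {}
    for spec in config.driver_spec:
        rid, ival = _resolve_driver_interval(spec, promoters, fragments)
        driver_ivals[rid] = (spec, ival)

    snv, offsets = _sample_snv_positions(config, windows, driver_ivals)
    snv = _apply_hotspots(config, snv, driver_ivals)
    snv = snv.sort_values(["chrom", "pos0", "tumor_id"]).reset_index(drop=True)
    snv = _assign_alleles(config, snv, windows, catalog)
    snv = _attach_qc(config, snv)
    snv["pos"] = snv["pos0"] + 1  # MAF convention: 1-based inclusive

    tumors = [f"T{t:04d}" for t in range(config.n_tumors)]
    seg, karyo = _make_cnv(config, tumors)
    metadata = _make_metadata(config, tumors, karyo)

    # expression effects tied to mutation of driver regions
    mutated_by_gene: dict[str, set] = {}
    gene_of_driver: dict[str, list[str]] = {}
    for rid, (spec, ival) in driver_ivals.items():
        if spec.region.startswith("promoter:"):
            genes = [spec.region.split(":", 1)[1]]
        else:
            frag = spec.region.split(":", 1)[1]
            genes = next(f.target_genes for f in fragments
                         if f.fragment_id == frag)
        gene_of_driver[rid] = genes
        sel = ((snv["chrom"] == ival.chrom) & (snv["pos0"] >= ival.start)
               & (snv["pos0"] < ival.end))
        mut = set(snv.loc[sel, "tumor_id"])
        if spec.expression_fold_change != 1.0:
            for g in genes:
                mutated_by_gene.setdefault(g, set()).update(mut)
    expr_spec = dict(config.expression_spec or {})
    for rid, (spec, _) in driver_ivals.items():
        if spec.expression_fold_change != 1.0:
            for g in gene_of_driver[rid]:
                base, phi, _ = expr_spec.get(
                    g, (config.expression_baseline_mean,
                        config.expression_dispersion, 1.0))
                expr_spec[g] = (base, phi, spec.expression_fold_change)
    counts, effects = _make_expression(config, tumors, tss, mutated_by_gene,
                                       expr_spec)

    paths = {
        "tss": outdir / "tss.tsv",
        "interactions": outdir / "interactions.tsv",
        "reptime": outdir / "reptime.track.tsv",
        "coverage": outdir / "coverage.track.tsv",
        "refclass": outdir / "refclass.track.tsv",
        "mappability": outdir / "mappability.bed",
        "snvs": outdir / "snvs.maf.tsv",
        "cnv": outdir / "cnv.seg",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "catalog": outdir / "signatures.catalog.tsv",
        "truth": outdir / "truth.json",
    }
    tss.to_csv(paths["tss"], sep="\t", index=False)
    interactions.to_csv(paths["interactions"], sep="\t", index=False,
                        float_format="%.6g")
    for key, col in (("reptime", "reptime"), ("coverage", "coverage"),
                     ("refclass", "ref_class")):
        windows[["chrom", "start", "end", col]].rename(
            columns={col: "value"}).to_csv(
            paths[key], sep="\t", index=False, float_format="%.6g")
    mappability.to_csv(paths["mappability"], sep="\t", index=False,
                       header=False)
    maf = snv[["tumor_id", "chrom", "pos", "ref", "alt", "alt_fwd", "alt_rev",
               "mean_bq", "mean_mq", "alignability", "context"]]
    maf.to_csv(paths["snvs"], sep="\t", index=False, float_format="%.6g")
    seg.to_csv(paths["cnv"], sep="\t", index=False, float_format="%.6g")
    counts.to_csv(paths["counts"], sep="\t")
    metadata.to_csv(paths["samples"], sep="\t", index=False)
    catalog.write(paths["catalog"])

    bc = config.background_coefs
    mix = config.signature_mix
    truth = SyntheticTruth(
        driver_regions={
            rid: {"multiplier": spec.multiplier,
                  "concentration": spec.concentration,
                  "expression_fold_change": spec.expression_fold_change,
                  "genes": gene_of_driver[rid]}
            for rid, (spec, _) in driver_ivals.items() if spec.is_true_driver
        },
        true_background_coefs={
            "intercept": bc.intercept, "ref_class": bc.beta_refclass,
            "reptime": bc.beta_reptime, "coverage": bc.beta_coverage,
            "tumor_offset_sd": bc.tumor_offset_sd,
        },
        true_expression_effects={g: fc for g, fc in effects.items()
                                 if fc != 1.0},
        sample_karyotypes=karyo,
        true_exposures={t: dict(sorted(mix.items())) for t in tumors},
        region_ids=[p.region_id for p in promoters]
        + [f.region_id for f in fragments],
    )
    truth.to_json(paths["truth"])
    return paths, truth
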