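"""Recurrence testing of regulatory-region mutations.

The background model is a logistic regression of the per-base, per-tumor
mutation indicator on tumor identity, reference base class (A/T vs G/C),
replication timing, and sequencing coverage, fitted separately for promoters
and CREs.  For a region of s testable bases the per-tumor probability of
carrying at least one mutation is q_t = 1 - prod_k (1 - p_k); the number of
mutated tumors is then Poisson-binomial distributed over tumors, giving a
background P-value P(X >= x_obs).  Positional clustering is scored by
S = m - (distinct mutated positions) against a uniform permutation null
(10,000 draws), and the two P-values are combined by Fisher's method
(chi-square, 4 df) with Benjamini-Hochberg adjustment across regions.

Tumor identity enters as a fixed per-tumor rate offset estimated from
marginal mutation loads (a two-pass scheme); because every tumor sees the
same covariate tracks, the marginal load is independent of the covariate
effects and the shared coefficients are estimated without bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import chi2, norm
from statsmodels.stats.multitest import multipletests

from .regions import CREFragment, PromoterRegion

EXACT_DP_MAX_T = 5000
MIN_CLUSTER_MUTATIONS = 3
DEFAULT_N_PERM = 10_000


# ---------------------------------------------------------------------------
# covariate tracks

class CovariateTracks:
    """Piecewise-constant per-base covariates (windowed interval tracks).

    All tracks must share identical window boundaries.  ``ref_class`` is the
    binary A/T (1) vs G/C (0) class of the window's reference bases;
    ``reptime`` the averaged replication-timing value; ``coverage`` the mean
    sequencing depth.
    """

    def __init__(self, windows: pd.DataFrame):
        required = {"chrom", "start", "end", "ref_class", "reptime", "coverage"}
        missing = required - set(windows.columns)
        if missing:
            raise ValueError(f"covariate windows missing columns: {sorted(missing)}")
        self.windows = windows.sort_values(["chrom", "start"]).reset_index(drop=True)
        self._starts: dict[str, np.ndarray] = {}
        self._offsets: dict[str, int] = {}
        for chrom, grp in self.windows.groupby("chrom", sort=False):
            self._starts[chrom] = grp["start"].to_numpy()
            self._offsets[chrom] = grp.index[0]

    @classmethod
    def from_tracks(cls, reptime: pd.DataFrame, coverage: pd.DataFrame,
                    ref_class: pd.DataFrame) -> "CovariateTracks":
        key = ["chrom", "start", "end"]
        a = reptime.rename(columns={"value": "reptime"})
        b = coverage.rename(columns={"value": "coverage"})
        c = ref_class.rename(columns={"value": "ref_class"})
        merged = a.merge(b, on=key, validate="one_to_one").merge(
            c, on=key, validate="one_to_one")
        if len(merged) != len(reptime):
            raise ValueError("covariate tracks have mismatched windows")
        return cls(merged)

    def window_index(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Global window index for 0-based positions on one chromosome."""
        starts = self._starts[chrom]
        idx = np.searchsorted(starts, pos, side="right") - 1
        if (idx < 0).any():
            raise ValueError(f"positions before first window on {chrom}")
        return idx + self._offsets[chrom]

    def design(self, window_idx: np.ndarray) -> np.ndarray:
        """Design rows [1, ref_class, reptime, coverage] for window indices."""
        w = self.windows
        return np.column_stack([
            np.ones(len(window_idx)),
            w["ref_class"].to_numpy()[window_idx],
            w["reptime"].to_numpy()[window_idx],
            w["coverage"].to_numpy()[window_idx],
        ])


def read_track(path) -> pd.DataFrame:
    """Read an interval track TSV (chrom, start, end, value; 0-based half-open)."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


# ---------------------------------------------------------------------------
# background model

@dataclass
class BackgroundModel:
    """Fitted per-base logistic background mutation model."""

    intercept: float
    beta_ref_class: float
    beta_reptime: float
    beta_coverage: float
    tumor_effects: dict[str, float]
    sampling_offset: float = 0.0
    fitted_on: str = "promoter"
    conf_int: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.intercept, self.beta_ref_class,
                         self.beta_reptime, self.beta_coverage])

    def rates(self, design: np.ndarray, tumor_id: str) -> np.ndarray:
        """Per-base mutation probabilities p_k for one tumor, strictly in (0,1)."""
        eta = design @ self.coef + self.tumor_effects[tumor_id] + self.sampling_offset
        p = expit(eta)
        return np.clip(p, 1e-300, 1 - 1e-12)


def _region_testable_windows(regions, tracks: CovariateTracks):
    """Per-region window indices and testable-base counts per window."""
    out = []
    for reg in regions:
        pos = reg.testable_positions()
        widx = tracks.window_index(reg.interval.chrom, pos)
        uw, counts = np.unique(widx, return_counts=True)
        out.append((uw, counts))
    return out


def fit_background(
    snvs: pd.DataFrame,
    tracks: CovariateTracks,
    regions: list[PromoterRegion | CREFragment],
    kind: str = "promoter",
    negative_sampling_fraction: float = 1.0,
    tumor_ids: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> BackgroundModel:
    """Fit the logistic background model on testable bases of ``regions``.

    ``snvs`` is a MAF-like frame restricted to testable bases (1-based
    ``pos``).  Observations are aggregated into binomial counts per
    (tumor, covariate window), which is exact because covariates are
    piecewise constant within windows.  When ``negative_sampling_fraction``
    < 1 the unmutated observations are binomially thinned and the intercept
    corrected by ln(fraction).
    """
    if not 0 < negative_sampling_fraction <= 1:
        raise ValueError("negative_sampling_fraction must be in (0, 1]")
    tumors = sorted(tumor_ids if tumor_ids is not None
                    else snvs["tumor_id"].unique())
    if not tumors:
        raise ValueError("no tumors to fit on")
    n_t = len(tumors)
    t_index = {t: i for i, t in enumerate(tumors)}

    # unique testable bases per chromosome; trials per window count each
    # base once even when regions overlap, and successes are restricted to
    # exactly these bases
    testable: dict[str, np.ndarray] = {}
    for reg_ in regions:
        c = reg_.interval.chrom
        testable.setdefault(c, [])
        testable[c].append(reg_.testable_positions())
    testable = {c: np.unique(np.concatenate(v)) for c, v in testable.items()}

    n_windows = len(tracks.windows)
    trials_all = np.zeros(n_windows)
    for c, tpos in testable.items():
        widx = tracks.window_index(c, tpos)
        np.add.at(trials_all, widx, 1)
    used = np.flatnonzero(trials_all > 0)
    trials_w = trials_all[used]
    pos_in_used = {w: i for i, w in enumerate(used)}

    # successes per (tumor, window)
    succ = np.zeros((n_t, len(used)))
    by_chrom = {c: g for c, g in snvs.groupby("chrom")}
    for chrom, grp in by_chrom.items():
        if chrom not in tracks._starts or chrom not in testable:
            continue
        pos0 = grp["pos"].to_numpy() - 1
        tpos = testable[chrom]
        hit = tpos[np.clip(np.searchsorted(tpos, pos0), 0, len(tpos) - 1)] == pos0
        grp = grp.loc[hit]
        widx = tracks.window_index(chrom, grp["pos"].to_numpy() - 1)
        for t, w in zip(grp["tumor_id"], widx):
            if w in pos_in_used and t in t_index:
                succ[t_index[t], pos_in_used[w]] += 1

    trials = np.tile(trials_w, (n_t, 1))
    fails = np.maximum(trials - succ, 0)
    if negative_sampling_fraction < 1:
        rng = rng if rng is not None else np.random.default_rng(0)
        fails = rng.binomial(fails.astype(int), negative_sampling_fraction)

    # two-pass tumor effects: offsets from marginal per-tumor loads
    tot_succ = succ.sum(axis=1)
    tot_trials = succ.sum(axis=1) + fails.sum(axis=1)
    rate_t = (tot_succ + 0.5) / (tot_trials + 1.0)
    overall = (tot_succ.sum() + 0.5) / (tot_trials.sum() + 1.0)
    offsets_t = logit(rate_t) - logit(overall)

    X = tracks.design(np.repeat(used, n_t).reshape(len(used), n_t).T.ravel())
    # rows ordered tumor-major: tumor 0 windows..., tumor 1 windows...
    endog = np.column_stack([succ.ravel(), fails.ravel()])
    offset = np.repeat(offsets_t, len(used))
    keep = endog.sum(axis=1) > 0
    try:
        res = sm.GLM(endog[keep], X[keep], family=sm.families.Binomial(),
                     offset=offset[keep]).fit(maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels wraps several
        raise RuntimeError(f"background model failed to converge: {exc}") from exc
    if not res.converged:
        raise RuntimeError(
            "background model failed to converge; check covariates "
            "[ref_class, reptime, coverage] for separation")
    params = res.params
    ci = res.conf_int()
    names = ["intercept", "ref_class", "reptime", "coverage"]
    conf = {n: (float(ci[i, 0]), float(ci[i, 1])) for i, n in enumerate(names)}
    correction = float(np.log(negative_sampling_fraction))
    return BackgroundModel(
        intercept=float(params[0]) + correction,
        beta_ref_class=float(params[1]),
        beta_reptime=float(params[2]),
        beta_coverage=float(params[3]),
        tumor_effects={t: float(offsets_t[i]) for t, i in t_index.items()},
        sampling_offset=0.0,
        fitted_on=kind,
        conf_int=conf,
    )


# ---------------------------------------------------------------------------
# per-region probabilities and tail

def region_tumor_probability(p_k: np.ndarray) -> float:
    """Probability a tumor carries >=1 mutation: q = 1 - prod_k (1 - p_k)."""
    p_k = np.asarray(p_k, dtype=float)
    if (p_k < 0).any() or (p_k >= 1).any():
        raise ValueError("per-base probabilities must lie in [0, 1)")
    return float(-np.expm1(np.log1p(-p_k).sum()))


def poisson_binomial_pmf(q: np.ndarray) -> np.ndarray:
    """Exact Poisson-binomial pmf by dynamic-programming convolution."""
    pmf = np.array([1.0])
    for qi in np.asarray(q, dtype=float):
        pmf = np.convolve(pmf, [1.0 - qi, qi])
    return pmf


def poisson_binomial_tail(q: np.ndarray, x_obs: int) -> float:
    """P(X >= x_obs) for X = sum of independent Bernoulli(q_t).

    Exact dynamic programming for up to 5,000 tumors; a refined normal
    (skewness-corrected) approximation beyond that.
    """
    q = np.asarray(q, dtype=float)
    if (q < 0).any() or (q > 1).any():
        raise ValueError("success probabilities must lie in [0, 1]")
    T = len(q)
    if not 0 <= x_obs <= T:
        raise ValueError(f"x_obs={x_obs} outside [0, {T}]")
    if x_obs == 0:
        return 1.0
    if T <= EXACT_DP_MAX_T:
        pmf = poisson_binomial_pmf(q)
        # sum smallest-first for accuracy in the far tail; clamp the
        # rounding error that can push a near-total sum past 1
        return float(min(np.sum(pmf[x_obs:][::-1]), 1.0))
    mu = q.sum()
    var = (q * (1 - q)).sum()
    sigma = np.sqrt(var)
    gamma = ((q * (1 - q) * (1 - 2 * q)).sum()) / sigma**3
    z = (x_obs - 0.5 - mu) / sigma
    cdf = norm.cdf(z) + gamma * (1 - z**2) * norm.pdf(z) / 6
    return float(min(max(1 - cdf, 0.0), 1.0))


# ---------------------------------------------------------------------------
# clustering permutation test

def clustering_statistic(positions: np.ndarray) -> int:
    """S = m - number of distinct positions (excess recurrence)."""
    positions = np.asarray(positions)
    return int(len(positions) - len(np.unique(positions)))


def _perm_null_statistics(m: int, s: int, n_perm: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Null draws of S for m uniform positions over s testable bases."""
    stats = np.empty(n_perm, dtype=np.int64)
    chunk = max(1, int(2e6) // max(m, 1))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        draws = rng.integers(0, s, size=(k, m))
        draws.sort(axis=1)
        distinct = 1 + (np.diff(draws, axis=1) > 0).sum(axis=1)
        stats[done:done + k] = m - distinct
        done += k
    return stats


def clustering_pvalue(
    mutation_positions: np.ndarray,
    region_length: int,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
) -> float | None:
    """Permutation P-value for positional clustering of region mutations.

    Requires at least three mutations (returns None otherwise).  The null
    permutes m positions uniformly (with replacement) over the region's
    ``region_length`` testable bases; the P-value uses add-one smoothing
    (r + 1) / (n_perm + 1).
    """
    if region_length < 1:
        raise ValueError("region length must be >= 1")
    positions = np.asarray(mutation_positions)
    m = len(positions)
    if m < MIN_CLUSTER_MUTATIONS:
        return None
    s_obs = clustering_statistic(positions)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    null = _perm_null_statistics(m, region_length, n_perm, rng)
    return float((1 + (null >= s_obs).sum()) / (n_perm + 1))


class ClusteringNullCache:
    """Permutation-null tail tables cached per (m, s).

    The null distribution of S depends only on the mutation count m and the
    testable length s, so cohort-level runs reuse one permutation table per
    (m, s) pair.  Each table gets its own deterministic substream derived
    from the base seed and (m, s).
    """

    def __init__(self, seed: int, n_perm: int = DEFAULT_N_PERM):
        self.seed = int(seed)
        self.n_perm = n_perm
        self._tables: dict[tuple[int, int], np.ndarray] = {}

    def pvalue(self, positions: np.ndarray, region_length: int) -> float | None:
        m = len(positions)
        if m < MIN_CLUSTER_MUTATIONS:
            return None
        key = (m, region_length)
        if key not in self._tables:
            ss = np.random.SeedSequence(self.seed, spawn_key=key)
            rng = np.random.default_rng(ss)
            null = _perm_null_statistics(m, region_length, self.n_perm, rng)
            # tail counts: tail[s] = #{null >= s}
            self._tables[key] = np.bincount(null, minlength=m + 1)[::-1].cumsum()[::-1]
        s_obs = clustering_statistic(positions)
        tail = self._tables[key]
        r = int(tail[s_obs]) if s_obs < len(tail) else 0
        return float((1 + r) / (self.n_perm + 1))


# ---------------------------------------------------------------------------
# combination and FDR

def combine_fisher(p_background: float, p_cluster: float | None) -> float:
    """Fisher combination (chi-square, 4 df); pass-through when clustering absent."""
    if p_background <= 0 or p_background > 1:
        raise ValueError("p_background outside (0, 1]")
    if p_cluster is None:
        return float(p_background)
    if p_cluster <= 0 or p_cluster > 1:
        raise ValueError("p_cluster outside (0, 1]")
    stat = -2.0 * (np.log(p_background) + np.log(p_cluster))
    return float(chi2.sf(stat, df=4))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values outside (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# cohort-level driver

@dataclass
class RecurrenceResult:
    """Per-region recurrence test summary."""

    region_id: str
    n_mutations: int          # m
    n_mutated_tumors: int     # x
    n_distinct_positions: int # u
    p_background: float
    p_cluster: float | None
    p_combined: float
    q: float = np.nan


def assign_mutations(
    regions,
    snvs: pd.DataFrame,
    orf_intervals: dict[str, list[tuple[int, int]]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Map SNVs onto testable bases of each region.

    Returns region_id -> frame (tumor_id, pos0).  For promoter regions,
    mutations falling in ``orf_intervals`` (merged per chromosome) are
    excluded at this stage; CRE masks already exclude coding bases.
    Duplicate (tumor, position) pairs are collapsed.
    """
    out: dict[str, pd.DataFrame] = {}
    by_chrom = {c: g for c, g in snvs.groupby("chrom")}
    for reg in regions:
        chrom = reg.interval.chrom
        grp = by_chrom.get(chrom)
        if grp is None:
            out[reg.region_id] = pd.DataFrame(columns=["tumor_id", "pos0"])
            continue
        pos0 = grp["pos"].to_numpy() - 1
        inside = (pos0 >= reg.interval.start) & (pos0 < reg.interval.end)
        sel = grp.loc[inside].copy()
        sel["pos0"] = pos0[inside]
        if len(sel):
            offs = sel["pos0"].to_numpy() - reg.interval.start
            sel = sel.loc[reg.testable_mask[offs]]
        if (orf_intervals is not None and isinstance(reg, PromoterRegion)
                and len(sel)):
            merged = orf_intervals.get(chrom, [])
            if merged:
                starts = np.array([s for s, _ in merged])
                ends = np.array([e for _, e in merged])
                p = sel["pos0"].to_numpy()
                idx = np.searchsorted(starts, p, side="right") - 1
                in_orf = (idx >= 0) & (p < ends[np.clip(idx, 0, None)])
                sel = sel.loc[~in_orf]
        out[reg.region_id] = (
            sel[["tumor_id", "pos0"]].drop_duplicates().reset_index(drop=True)
        )
    return out


def run_recurrence(
    regions,
    snvs: pd.DataFrame,
    model: BackgroundModel,
    tracks: CovariateTracks,
    tumor_ids: list[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    orf_intervals: dict[str, list[tuple[int, int]]] | None = None,
) -> pd.DataFrame:
    """Full recurrence scan over one batch of regions (one BH batch)."""
    muts = assign_mutations(regions, snvs, orf_intervals)
    cache = ClusteringNullCache(seed, n_perm)
    rows = []
    per_region = _region_testable_windows(regions, tracks)
    for reg, (uw, counts) in zip(regions, per_region):
        design = tracks.design(uw)
        mdf = muts[reg.region_id]
        m = len(mdf)
        x = mdf["tumor_id"].nunique()
        u = mdf["pos0"].nunique()
        q_t = np.empty(len(tumor_ids))
        for i, t in enumerate(tumor_ids):
            p_w = model.rates(design, t)
            q_t[i] = -np.expm1((counts * np.log1p(-p_w)).sum())
        p_bg = poisson_binomial_tail(q_t, x)
        p_cl = cache.pvalue(mdf["pos0"].to_numpy(), reg.n_testable)
        p_comb = combine_fisher(max(p_bg, 1e-300), p_cl)
        rows.append((reg.region_id, m, x, u, p_bg, p_cl, p_comb))
    df = pd.DataFrame(rows, columns=[
        "region_id", "m", "x", "u", "p_background", "p_cluster", "p_combined"])
    df["q"] = bh_fdr(np.clip(df["p_combined"].to_numpy(), 1e-300, 1.0))
    return df
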