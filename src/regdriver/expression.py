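"""Expression effects of regulatory-region mutation.

Target-gene expression is compared between mutated and non-mutated tumors
with a two-group exact-style negative-binomial (NB) test: counts are scaled
to a common effective library size (trimmed-mean-of-M-values factors), a
common NB dispersion is estimated by conditional maximum likelihood, and the
test conditions on the pooled count total — the conditional distribution of
the group-1 sum given the total is the NB analogue of the hypergeometric.
In the Poisson limit (dispersion 0) the conditional distribution is exactly
binomial.

Samples carrying copy-number events over either the tested region or the
target gene are excluded before grouping; a region is not testable when
fewer than three mutated samples remain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

from .recurrence import bh_fdr
from .regions import GenomicInterval

logger = logging.getLogger(__name__)

FC_UP = 1.2
FC_DOWN = 0.8
Q_DE = 0.1
MIN_MUTATED = 3
PRIOR_COUNT = 0.5
CNV_LOG2_MIN = 0.1613


@dataclass
class DEResult:
    """One (region, gene) differential-expression comparison."""

    region_id: str
    gene_id: str
    n_mutated: int
    n_unmutated: int
    fold_change: float
    p: float
    q: float = np.nan

    @property
    def candidate(self) -> bool:
        return (self.fold_change >= FC_UP or self.fold_change <= FC_DOWN) \
            and self.q < Q_DE


# ---------------------------------------------------------------------------
# library normalization (trimmed mean of M-values)

def tmm_factors(counts: np.ndarray, m_trim: float = 0.30,
                a_trim: float = 0.05) -> np.ndarray:
    """TMM scaling factors (genes x samples), normalized to geometric mean 1."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    uq = np.array([np.quantile(counts[:, j][counts[:, j] > 0], 0.75)
                   / lib[j] if (counts[:, j] > 0).any() else 0
                   for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    f = np.ones(counts.shape[1])
    yr, Nr = counts[:, ref], lib[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        y, N = counts[:, j], lib[j]
        ok = (y > 0) & (yr > 0)
        if ok.sum() < 10:
            continue
        M = np.log2((y[ok] / N) / (yr[ok] / Nr))
        A = 0.5 * np.log2((y[ok] / N) * (yr[ok] / Nr))
        w = (N - y[ok]) / (N * y[ok]) + (Nr - yr[ok]) / (Nr * yr[ok])
        mlo, mhi = np.quantile(M, [m_trim, 1 - m_trim])
        alo, ahi = np.quantile(A, [a_trim, 1 - a_trim])
        keep = (M >= mlo) & (M <= mhi) & (A >= alo) & (A <= ahi)
        if keep.any():
            f[j] = 2 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    return f / np.exp(np.mean(np.log(f)))


@dataclass
class ExpressionMatrix:
    """Raw count matrix with per-sample effective library factors."""

    counts: pd.DataFrame              # genes x samples, raw integers
    library_factors: pd.Series | None = None

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.library_factors is None:
            f = tmm_factors(self.counts.to_numpy())
            self.library_factors = pd.Series(f, index=self.counts.columns)
        if (self.library_factors <= 0).any():
            raise ValueError("library factors must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def effective_lib(self) -> pd.Series:
        return self.counts.sum(axis=0) * self.library_factors

    def adjusted(self, gene: str, samples: list[str]) -> np.ndarray:
        """Counts scaled to the geometric-mean effective library size."""
        eff = self.effective_lib()
        common = np.exp(np.mean(np.log(eff)))
        y = self.counts.loc[gene, samples].to_numpy(dtype=float)
        return y * (common / eff[samples].to_numpy())


# ---------------------------------------------------------------------------
# dispersion

def _cml_loglik(r: float, groups: list[np.ndarray]) -> float:
    """Conditional NB log-likelihood at size r = 1/dispersion."""
    ll = 0.0
    for y in groups:
        n, z = len(y), y.sum()
        ll += (gammaln(y + r).sum() - n * gammaln(r)
               + gammaln(n * r) - gammaln(z + n * r))
    return ll


def estimate_dispersion(counts: np.ndarray, groups: np.ndarray) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    ``counts``: genes x samples array of library-adjusted (rounded) counts;
    ``groups``: per-sample labels.  Counts within each group are assumed on
    a common library scale.  Returns dispersion >= 0 (0 = Poisson limit).
    """
    counts = np.round(np.asarray(counts, dtype=float))
    if counts.ndim == 1:
        counts = counts[None, :]
    labels = np.unique(groups)
    gene_groups: list[np.ndarray] = []
    for row in counts:
        if row.sum() == 0:
            logger.info("skipping all-zero gene row in dispersion estimation")
            continue
        for g in labels:
            y = row[groups == g]
            if len(y) >= 2:
                gene_groups.append(y)
    if not gene_groups:
        raise ValueError("no usable gene rows (need >=2 samples per group)")

    def neg(log_phi):
        return -_cml_loglik(1.0 / np.exp(log_phi), gene_groups)

    res = minimize_scalar(neg, bounds=(np.log(1e-6), np.log(10.0)),
                          method="bounded")
    phi = float(np.exp(res.x))
    # Poisson limit: accept phi=0 if it fits at least as well
    if _cml_loglik(1e12, gene_groups) >= -res.fun - 1e-9 or phi <= 2e-6:
        return 0.0
    return phi


# ---------------------------------------------------------------------------
# exact-style two-group NB test

def _conditional_logpmf(z: int, a1: float, a2: float) -> np.ndarray:
    """log P(S1 = s | S1+S2 = z) for S_i ~ NB(size a_i) with shared mean."""
    s = np.arange(z + 1)
    lp = (gammaln(s + a1) - gammaln(s + 1)
          + gammaln(z - s + a2) - gammaln(z - s + 1))
    return lp - logsumexp(lp)


def nb_two_group_test(
    y1: np.ndarray,
    y2: np.ndarray,
    dispersion: float,
    prior_count: float = PRIOR_COUNT,
) -> tuple[float, float]:
    """Two-sided exact-style NB test of group means on adjusted counts.

    ``y1``/``y2`` are counts already scaled to a common library size
    (rounded to integers internally for the conditional test).  Returns
    (fold_change, p) with fold change = (mean1 + c) / (mean2 + c) computed
    on the unrounded values; p doubles the smaller conditional tail.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    n1, n2 = len(y1), len(y2)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty group")
    fc = (y1.mean() + prior_count) / (y2.mean() + prior_count)
    s1 = int(round(y1.sum()))
    z = s1 + int(round(y2.sum()))
    if z == 0:
        return fc, 1.0
    if dispersion <= 0:
        pi = n1 / (n1 + n2)
        lo = binom.cdf(s1, z, pi)
        hi = binom.sf(s1 - 1, z, pi)
    else:
        r = 1.0 / dispersion
        lp = _conditional_logpmf(z, n1 * r, n2 * r)
        cum = np.exp(logsumexp(lp[: s1 + 1]))
        tail = np.exp(logsumexp(lp[s1:]))
        lo, hi = cum, tail
    return fc, float(min(1.0, 2.0 * min(lo, hi)))


# ---------------------------------------------------------------------------
# sample selection

def _samples_with_cnv_overlap(cnv: pd.DataFrame, iv: GenomicInterval) -> set:
    """Samples with a copy-number event (|log2| >= threshold) over ``iv``."""
    if cnv is None or len(cnv) == 0:
        return set()
    sel = cnv[(cnv["chrom"] == iv.chrom)
              & (cnv["start"] < iv.end) & (cnv["end"] > iv.start)
              & (cnv["log2_ratio"].abs() >= CNV_LOG2_MIN)]
    return set(sel["sample_id"])


def select_testable(
    region_iv: GenomicInterval,
    gene_iv: GenomicInterval,
    mutated_samples: set,
    sibling_mutated: dict[str, set] | None,
    cnv: pd.DataFrame,
    expression_samples: list[str],
    min_mutated: int = MIN_MUTATED,
) -> tuple[set, set] | None:
    """Build the mutated / comparison sample groups for one region-gene pair.

    Excludes samples with a CNV overlapping either the region or the target
    gene.  ``sibling_mutated`` maps the other recurrently mutated CREs of
    the same promoter to their mutated sample sets: samples mutated in more
    than one such fragment are excluded, and the comparison group contains
    only samples unmutated in every one of them.  Returns None when fewer
    than ``min_mutated`` mutated samples remain.
    """
    profiled = set(expression_samples)
    if not profiled:
        return None
    excluded = (_samples_with_cnv_overlap(cnv, region_iv)
                | _samples_with_cnv_overlap(cnv, gene_iv))
    sibling_mutated = sibling_mutated or {}
    any_sibling = set().union(*sibling_mutated.values()) if sibling_mutated else set()
    multi = {
        s for s in mutated_samples
        if 1 + sum(s in v for v in sibling_mutated.values()) > 1
    }
    mut = (mutated_samples - excluded - multi) & profiled
    comp = (profiled - mutated_samples - any_sibling - excluded)
    if len(mut) < min_mutated:
        return None
    return mut, comp


def de_pipeline(
    region_gene_pairs: list[tuple[str, GenomicInterval, str, GenomicInterval]],
    mutated_by_region: dict[str, set],
    siblings_by_region: dict[str, dict[str, set]],
    cnv: pd.DataFrame,
    expr: ExpressionMatrix,
    dispersion: float | None = None,
) -> list[DEResult]:
    """Run the per-(region, gene) NB tests with BH adjustment over the batch.

    ``region_gene_pairs``: (region_id, region interval, gene_id, gene
    interval), one row per tested pair (regions interacting with several
    genes appear once per gene).
    """
    results: list[DEResult] = []
    tested: list[tuple[DEResult, float]] = []
    for region_id, region_iv, gene_id, gene_iv in region_gene_pairs:
        if gene_id not in expr.counts.index:
            continue
        sel = select_testable(
            region_iv, gene_iv, mutated_by_region.get(region_id, set()),
            siblings_by_region.get(region_id), cnv, expr.samples)
        if sel is None:
            continue
        mut, comp = sel
        if len(comp) < 2:
            continue
        mut_l, comp_l = sorted(mut), sorted(comp)
        y1 = expr.adjusted(gene_id, mut_l)
        y2 = expr.adjusted(gene_id, comp_l)
        if dispersion is None:
            groups = np.array([0] * len(mut_l) + [1] * len(comp_l))
            phi = estimate_dispersion(np.concatenate([y1, y2]), groups)
        else:
            phi = dispersion
        fc, p = nb_two_group_test(y1, y2, phi)
        res = DEResult(region_id=region_id, gene_id=gene_id,
                       n_mutated=len(mut), n_unmutated=len(comp),
                       fold_change=fc, p=p)
        results.append(res)
    if results:
        qs = bh_fdr([max(r.p, 1e-300) for r in results])
        for r, q in zip(results, qs):
            r.q = float(q)
    return results
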