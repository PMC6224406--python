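"""Cohort-level statistics: Fisher tests, burden comparisons, enrichment scans.

Thin, explicit wrappers used across the pipeline: 2x2 Fisher's exact tests
for subgroup enrichment/paucity, Wilcoxon rank-sum comparison of mutation
burden by karyotype, and interaction-level hypergeometric term enrichment
(the universe is the set of promoter/CRE-promoter interactions, not genes,
so genes contacted by many fragments do not dominate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .recurrence import bh_fdr

logger = logging.getLogger(__name__)

SUBGROUPS = ("HD", "t(4;14)", "t(11;14)", "t(14;16)", "MYC")


def default_go_terms() -> list[str]:
    """Shipped default term list for enrichment scans (configuration, not
    code: replace the packaged text file for project-specific terms)."""
    from pathlib import Path

    path = Path(__file__).parent / "data" / "default_go_terms.txt"
    return [line.strip() for line in path.read_text().splitlines()
            if line.strip() and not line.startswith("#")]


@dataclass(frozen=True)
class Contingency2x2:
    """Counts with rows = condition, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative counts")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact(table, sided: str = "two") -> tuple[float, float]:
    """Exact hypergeometric test on a 2x2 table.

    Returns (odds ratio ad/bc, p).  ``sided`` in {greater, less, two}.
    Degenerate margins give p = 1; a zero denominator gives odds inf (or
    nan when the numerator is zero too).
    """
    t = table.as_array() if isinstance(table, Contingency2x2) else np.asarray(table)
    if (t < 0).any():
        raise ValueError("negative counts")
    alt = {"greater": "greater", "less": "less", "two": "two-sided"}[sided]
    _, p = sps.fisher_exact(t, alternative=alt)
    a, b, c, d = t.ravel()
    if b * c > 0:
        odds = (a * d) / (b * c)
    else:
        odds = np.nan if a * d == 0 else np.inf
    return float(odds), float(p)


def wilcoxon_burden(
    burden: pd.Series,
    subgroup_members: dict[str, set],
) -> pd.DataFrame:
    """Two-sided rank-sum test of mutation burden per karyotype subgroup.

    Each subgroup is compared against all other samples.  Exact null
    distribution when the smaller side has <= 25 samples and there are no
    ties; normal approximation with tie correction otherwise.  Constant
    data yields p = 1.
    """
    rows = []
    samples = set(burden.index)
    for label, members in subgroup_members.items():
        inside = sorted(members & samples)
        outside = sorted(samples - members)
        if len(inside) < 2 or len(outside) < 2:
            logger.info("subgroup %s too small for burden test; skipped", label)
            continue
        x = burden[inside].to_numpy(dtype=float)
        y = burden[outside].to_numpy(dtype=float)
        if np.ptp(np.concatenate([x, y])) == 0:
            rows.append((label, len(inside), 1.0))
            continue
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = ("exact" if min(len(x), len(y)) <= 25 and not has_ties
                  else "asymptotic")
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append((label, len(inside), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["subgroup", "n", "p"])


def interaction_go_enrichment(
    significant: set,
    background: set,
    annotations: dict[str, set],
    terms: list[str] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per term over interactions.

    N = |background|, K = |background interactions annotated with the
    term|, n = |significant|, k = |significant annotated|;
    p = P(X >= k).  Terms with K = 0 are skipped (logged).  Raw and
    BH-adjusted p-values are reported.
    """
    if not significant <= background:
        raise ValueError("significant set must be within the background")
    N, n = len(background), len(significant)
    rows = []
    for term in (terms if terms is not None else sorted(annotations)):
        ann = annotations.get(term, set()) & background
        K = len(ann)
        if K == 0:
            logger.info("term %s annotates nothing in background; skipped", term)
            continue
        k = len(ann & significant)
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((term, k, K, n, N, p))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(df):
        df["q"] = bh_fdr(np.clip(df["p"].to_numpy(), 1e-300, 1.0))
    return df


def subgroup_scan(
    feature_samples: set,
    subgroup_members: dict[str, set],
    cohort: set,
    direction: str = "greater",
) -> pd.DataFrame:
    """Per-subgroup Fisher scan of a binary sample feature.

    ``direction`` 'greater' tests enrichment, 'less' paucity (e.g. a
    depleted mutation target in one translocation group).  Subgroups may
    overlap (a sample can be HD and translocated); empty subgroups are
    skipped.
    """
    rows = []
    feature_samples = feature_samples & cohort
    for label, members in subgroup_members.items():
        members = members & cohort
        if not members:
            continue
        a = len(members & feature_samples)
        b = len(members - feature_samples)
        c = len(feature_samples - members)
        d = len(cohort) - a - b - c
        odds, p = fisher_exact(Contingency2x2(a, b, c, d), sided=direction)
        rows.append((label, a, b, c, d, odds, p))
    return pd.DataFrame(
        rows, columns=["subgroup", "a", "b", "c", "d", "odds_ratio", "p"])
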