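"""Trinucleotide mutation spectra, signature refitting, and AID motifs.

Spectra use the community-standard 96 pyrimidine-centered channels
(substitution C>A/C>G/C>T/T>A/T>C/T>G by 5' and 3' flanking base);
purine-reference mutations are reverse-complemented before counting.
Signature exposures are refit against a provided 96 x K catalog by
non-negative least squares, iteratively zeroing weights below an exposure
floor (default 0.06) and refitting, mirroring the behavior of standard
refitting tools.

AID (activation-induced cytidine deaminase) target motifs: canonical
C>T/G at the C of a WRCY match (W = A/T, R = purine, Y = pyrimidine),
non-canonical A>C/G in WA context, both matched strand-symmetrically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import fisher_exact as _fisher_exact

logger = logging.getLogger(__name__)

EXPOSURE_FLOOR = 0.06
SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
BASES = "ACGT"
#: canonical channel order: substitution-major, then 5' and 3' flank
CHANNELS = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
]
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SignatureCatalog:
    """96 x K matrix of channel probabilities, one column per signature."""

    matrix: pd.DataFrame  # index = CHANNELS, columns = signature ids

    def __post_init__(self):
        if list(self.matrix.index) != CHANNELS:
            self.matrix = self.matrix.reindex(CHANNELS)
            if self.matrix.isna().any().any():
                raise ValueError("catalog does not cover the 96 channels")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("catalog columns must sum to 1")

    @classmethod
    def read(cls, path) -> "SignatureCatalog":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write(self, path) -> None:
        self.matrix.to_csv(path, sep="\t", float_format="%.8g")

    @property
    def signature_ids(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class ExposureProfile:
    sample_id: str
    weights: pd.Series
    residual: float


def channel_of(ref: str, alt: str, context: str) -> str | None:
    """96-channel label for one substitution with trinucleotide ``context``.

    ``context`` is the reference trinucleotide centered on the mutated base;
    purine-reference mutations are collapsed onto the reverse-complement
    strand.  Returns None when the context is unusable.
    """
    if len(context) != 3 or any(b not in BASES for b in context) \
            or context[1] != ref or alt not in BASES or ref == alt:
        return None
    if ref in "AG":
        context = revcomp(context)
        ref, alt = ref.translate(_COMP), alt.translate(_COMP)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def trinucleotide_spectrum(snvs: pd.DataFrame, reference=None) -> np.ndarray:
    """96-channel spectrum of a MAF-like frame.

    Context comes from a ``context`` column (trinucleotide or any odd-length
    window centered on the mutated base) or, failing that, from
    ``reference`` — a mapping chrom -> sequence string (or pyfaidx-like
    object).  SNVs lacking usable context are skipped with a log entry.
    """
    counts = np.zeros(96, dtype=int)
    skipped = 0
    for row in snvs.itertuples(index=False):
        ctx = None
        if hasattr(row, "context") and isinstance(row.context, str):
            c = row.context
            mid = len(c) // 2
            if len(c) % 2 == 1 and len(c) >= 3:
                ctx = c[mid - 1 : mid + 2]
        elif reference is not None:
            seq = reference[row.chrom]
            pos0 = int(row.pos) - 1
            if 1 <= pos0 <= len(seq) - 2:
                ctx = str(seq[pos0 - 1 : pos0 + 2]).upper()
        ch = channel_of(row.ref, row.alt, ctx) if ctx else None
        if ch is None:
            skipped += 1
            continue
        counts[_CHANNEL_INDEX[ch]] += 1
    if skipped:
        logger.info("spectrum: skipped %d SNVs lacking usable context", skipped)
    return counts


def refit_exposures(
    spectrum: np.ndarray,
    catalog: SignatureCatalog,
    exposure_floor: float = EXPOSURE_FLOOR,
    sample_id: str = "sample",
) -> ExposureProfile:
    """Non-negative least-squares refit of a spectrum against a catalog.

    The normalized spectrum is regressed on the catalog columns; weights
    below ``exposure_floor`` are iteratively zeroed and the remainder
    refit.  Residual is the Euclidean norm of the final fit.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    total = spectrum.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum")
    target = spectrum / total
    A = catalog.matrix.to_numpy()
    active = np.arange(A.shape[1])
    while True:
        w_active, resid = nnls(A[:, active], target)
        low = (w_active < exposure_floor) & (w_active > 0)
        if not low.any() or (w_active >= exposure_floor).sum() == 0:
            w_active[w_active < exposure_floor] = 0.0
            break
        active = active[w_active >= exposure_floor]
    weights = np.zeros(A.shape[1])
    weights[active] = w_active
    if weights.sum() > 1:
        weights = weights / weights.sum()
    return ExposureProfile(
        sample_id=sample_id,
        weights=pd.Series(weights, index=catalog.signature_ids),
        residual=float(resid),
    )


# ---------------------------------------------------------------------------
# AID motif classification

W, R, Y = set("AT"), set("AG"), set("CT")


def _aid_label(ref: str, alt: str, ctx5: str) -> str:
    """Label from a 5-base context centered on the mutated base."""
    if len(ctx5) != 5 or any(b not in BASES for b in ctx5) or ctx5[2] != ref:
        return "other"
    # strand-collapse: view the pyrimidine (C) / adenine strand
    if ref in "GT":
        ctx5 = revcomp(ctx5)
        ref, alt = ref.translate(_COMP), alt.translate(_COMP)
    # canonical: WRCY with the mutated C third, alt T or G
    if ref == "C" and alt in "TG" and ctx5[0] in W and ctx5[1] in R \
            and ctx5[3] in Y:
        return "canonical_AID"
    # non-canonical: WA with the mutated A second, alt C or G
    if ref == "A" and alt in "CG" and ctx5[1] in W:
        return "noncanonical_AID"
    return "other"


def classify_aid(snvs: pd.DataFrame, reference=None) -> pd.Series:
    """Per-mutation AID labels {canonical_AID, noncanonical_AID, other}.

    Context handling as in :func:`trinucleotide_spectrum` but requires two
    flanking bases on each side; missing context yields "other".
    """
    labels = []
    for row in snvs.itertuples(index=False):
        ctx = None
        if hasattr(row, "context") and isinstance(row.context, str):
            c = row.context
            mid = len(c) // 2
            if len(c) % 2 == 1 and len(c) >= 5:
                ctx = c[mid - 2 : mid + 3]
        elif reference is not None:
            seq = reference[row.chrom]
            pos0 = int(row.pos) - 1
            if 2 <= pos0 <= len(seq) - 3:
                ctx = str(seq[pos0 - 2 : pos0 + 3]).upper()
        labels.append(_aid_label(row.ref, row.alt, ctx) if ctx else "other")
    return pd.Series(labels, index=snvs.index if hasattr(snvs, "index") else None)


def signature_subgroup_association(
    positive_samples: set,
    subgroups: dict[str, set],
    cohort: set,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of signature presence per subgroup."""
    rows = []
    for label, members in subgroups.items():
        members = members & cohort
        if not members:
            logger.info("subgroup %s absent from cohort; skipped", label)
            continue
        a = len(members & positive_samples)
        b = len(members - positive_samples)
        c = len(positive_samples - members)
        d = len(cohort) - a - b - c
        odds, p = _fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((label, a, b, c, d, odds, p))
    return pd.DataFrame(
        rows, columns=["subgroup", "a", "b", "c", "d", "odds_ratio", "p"])


def make_synthetic_catalog(n_signatures: int = 5, seed: int = 0,
                           concentration: float = 0.08) -> SignatureCatalog:
    """Synthetic signature catalog: sparse Dirichlet channel profiles.

    A stand-in for a reference signature catalog, for simulation and tests;
    each column concentrates mass on a few channels, like real mutational
    signatures.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for i in range(n_signatures):
        w = rng.dirichlet(np.full(96, concentration))
        cols[f"S{i + 1}"] = w
    return SignatureCatalog(pd.DataFrame(cols, index=CHANNELS))
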