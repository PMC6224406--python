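"""Calibration and recovery studies run on synthetic cohorts.

These are the package's standing validation experiments: null-cohort
type-I calibration of the recurrence test, spiked-driver recovery,
background-coefficient recovery, NB expression-test calibration and effect
recovery, signature-refit accuracy, and agreement of the AID classifier
with a brute-force oracle.  Each experiment regenerates its inputs from a
seed and measures the result by running the package itself; the problem
sizes are desk-scale (tens of tumors, megabase genomes) with the
background mutation rate set so the discrete test statistics have the
resolution they would have at population scale (see docs/methods.md).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import recurrence as rec
from .expression import bh_fdr, estimate_dispersion, nb_two_group_test
from .regions import CREFragment, GenomicInterval, define_promoters
from .signatures import _aid_label, make_synthetic_catalog, refit_exposures
from .stats import fisher_exact
from .synthetic import BackgroundCoefs, DriverSpec, GeneratorConfig, generate_cohort
from .variants import filter_variant_frame


def _load_cohort_for_recurrence(paths):
    maf, _ = filter_variant_frame(pd.read_csv(paths["snvs"], sep="\t"))
    tracks = rec.CovariateTracks.from_tracks(
        rec.read_track(paths["reptime"]),
        rec.read_track(paths["coverage"]),
        rec.read_track(paths["refclass"]))
    tss = pd.read_csv(paths["tss"], sep="\t", dtype={"chrom": str})
    samples = pd.read_csv(paths["samples"], sep="\t", keep_default_na=False)
    return maf, tracks, tss, sorted(samples["sample_id"])


def _promoter_recurrence(paths, seed, n_perm=10_000):
    maf, tracks, tss, tumors = _load_cohort_for_recurrence(paths)
    promoters = define_promoters(tss)
    model = rec.fit_background(maf, tracks, promoters, kind="promoter",
                               tumor_ids=tumors)
    return rec.run_recurrence(promoters, maf, model, tracks, tumors,
                              n_perm=n_perm, seed=seed)


def null_type1(seed: int, workdir, n_regions: int = 2000,
               n_tumors: int = 50) -> dict:
    """Fraction of null promoter regions with combined p < 0.05.

    One cohort of ``n_regions`` promoters with no spiked drivers; the
    baseline rate gives each promoter tens of mutations so both component
    statistics are informative.
    """
    cfg = GeneratorConfig(
        seed=seed, n_tumors=n_tumors, n_genes=n_regions,
        chrom_lengths={f"chr{i}": 1_000_000 for i in range(1, 5)})
    paths, _ = generate_cohort(cfg, workdir)
    res = _promoter_recurrence(paths, seed)
    return {
        "fraction_p05": float((res["p_combined"] < 0.05).mean()),
        "n_q05": int((res["q"] < 0.05).sum()),
        "n_regions": len(res),
    }


def null_fdr_calls(seed: int, workdir, n_seeds: int = 20) -> dict:
    """False recurrence calls at Q < 0.05 over repeated null cohorts."""
    calls = []
    for i in range(n_seeds):
        cfg = GeneratorConfig(
            seed=seed + 1000 + i, n_tumors=30, n_genes=300,
            chrom_lengths={"chr1": 800_000})
        paths, _ = generate_cohort(cfg, f"{workdir}/fdr{i}")
        res = _promoter_recurrence(paths, seed + 1000 + i, n_perm=4000)
        calls.append(int((res["q"] < 0.05).sum()))
    return {"calls_per_cohort": calls,
            "mean_calls": float(np.mean(calls)),
            "n_regions_each": 300, "n_seeds": n_seeds}


def driver_recovery(seed: int, workdir) -> dict:
    """Recovery of spiked promoter drivers (>=10x rate, >=0.5 hotspot)."""
    drivers = [
        DriverSpec(region=f"promoter:G{g:05d}", multiplier=mult,
                   concentration=conc)
        for g, (mult, conc) in enumerate(
            itertools.product([10.0, 15.0, 20.0, 25.0], [0.5, 0.8, 1.0]))
    ]
    cfg = GeneratorConfig(
        seed=seed + 17, n_tumors=50, n_genes=300,
        chrom_lengths={"chr1": 1_000_000, "chr2": 1_000_000},
        driver_spec=drivers)
    paths, truth = generate_cohort(cfg, workdir)
    res = _promoter_recurrence(paths, seed + 17)
    hit = res.loc[res["region_id"].isin(truth.driver_regions)]
    null_res = res.loc[~res["region_id"].isin(truth.driver_regions)]
    return {
        "recovery_rate": float((hit["q"] < 0.05).mean()),
        "null_call_rate": float((null_res["q"] < 0.05).mean()),
        "n_drivers": len(hit),
        "n_null_regions": len(null_res),
    }


def background_recovery(seed: int, workdir, n_seeds: int = 20) -> dict:
    """95% CI coverage of the replication-timing coefficient (truth 0.5)."""
    covered, estimates = 0, []
    for i in range(n_seeds):
        cfg = GeneratorConfig(
            seed=seed + 500 + i, n_tumors=50, n_genes=400,
            chrom_lengths={"chr1": 5_000_000, "chr2": 5_000_000})
        paths, truth = generate_cohort(cfg, f"{workdir}/bg{i}")
        maf, tracks, tss, tumors = _load_cohort_for_recurrence(paths)
        inter = pd.read_csv(paths["interactions"], sep="\t",
                            dtype={"chrom": str})
        frags = [CREFragment(r.fragment_id,
                             GenomicInterval(r.chrom, r.start, r.end))
                 for r in inter.drop_duplicates("fragment_id")
                 .itertuples(index=False)]
        model = rec.fit_background(maf, tracks, frags, kind="cre",
                                   tumor_ids=tumors)
        lo, hi = model.conf_int["reptime"]
        truth_beta = truth.true_background_coefs["reptime"]
        covered += int(lo <= truth_beta <= hi)
        estimates.append(model.beta_reptime)
    return {"coverage": covered / n_seeds, "n_seeds": n_seeds,
            "mean_estimate": float(np.mean(estimates))}


def nb_calibration(seed: int, n_genes: int = 2000,
                   n1: int = 13, n2: int = 187) -> dict:
    """Type-I error of the NB test on null genes (common dispersion)."""
    rng = np.random.default_rng(seed + 3)
    phi, mu = 0.2, 200.0
    r = 1 / phi
    counts = rng.negative_binomial(r, r / (r + mu), size=(200, n1 + n2))
    groups = np.array([0] * n1 + [1] * n2)
    phi_hat = estimate_dispersion(counts, groups)
    ps = []
    for _ in range(n_genes):
        y1 = rng.negative_binomial(r, r / (r + mu), n1)
        y2 = rng.negative_binomial(r, r / (r + mu), n2)
        ps.append(nb_two_group_test(y1, y2, phi_hat)[1])
    return {"type1_fraction": float(np.mean(np.array(ps) < 0.05)),
            "dispersion_estimate": float(phi_hat), "n_genes": n_genes}


def nb_effect_recovery(seed: int, n1: int = 13, n2: int = 187) -> dict:
    """Spiked 4.6-fold-down and 2.3-fold-up genes flagged among nulls.

    100 genes: 98 null, one down-regulated 4.6-fold in the mutated group,
    one up-regulated 2.3-fold; candidates require fold change >= 1.2 or
    <= 0.8 and BH Q < 0.1, as in the SNV expression screen.
    """
    rng = np.random.default_rng(seed + 11)
    phi, mu, r = 0.2, 200.0, 5.0
    rows = []
    for g in range(98):
        rows.append((f"null{g}",
                     rng.negative_binomial(r, r / (r + mu), n1),
                     rng.negative_binomial(r, r / (r + mu), n2)))
    rows.append(("down", rng.negative_binomial(r, r / (r + mu / 4.6), n1),
                 rng.negative_binomial(r, r / (r + mu), n2)))
    rows.append(("up", rng.negative_binomial(r, r / (r + mu * 2.3), n1),
                 rng.negative_binomial(r, r / (r + mu), n2)))
    res = {}
    ps = []
    for name, y1, y2 in rows:
        fc, p = nb_two_group_test(y1, y2, phi)
        res[name] = fc
        ps.append(p)
    qs = bh_fdr(np.clip(ps, 1e-300, 1))
    flagged = {name: (fc >= 1.2 or fc <= 0.8) and q < 0.1
               for (name, _, _), fc, q in zip(rows, res.values(), qs)}
    return {
        "down_fold_change": float(res["down"]),
        "up_fold_change": float(res["up"]),
        "down_flagged": bool(flagged["down"]),
        "up_flagged": bool(flagged["up"]),
        "n_false_flags": int(sum(v for k, v in flagged.items()
                                 if k.startswith("null"))),
        "n_samples": n1 + n2,
    }


def nb_poisson_limit_error(seed: int, n_cases: int = 50) -> float:
    """Max |p - exact conditional binomial| at dispersion 0."""
    rng = np.random.default_rng(seed + 13)
    worst = 0.0
    for _ in range(n_cases):
        n1, n2 = (int(x) for x in rng.integers(3, 20, 2))
        y1 = rng.poisson(80, n1)
        y2 = rng.poisson(80, n2)
        _, p = nb_two_group_test(y1, y2, 0.0)
        s1, z = y1.sum(), y1.sum() + y2.sum()
        pi = n1 / (n1 + n2)
        oracle = min(1, 2 * min(binom.cdf(s1, z, pi), binom.sf(s1 - 1, z, pi)))
        worst = max(worst, abs(p - oracle))
    return worst


def pb_enumeration_error(seed: int, n_cases: int = 1000,
                         max_t: int = 12) -> float:
    """Max |DP tail - exhaustive 2^T enumeration| over random cases."""
    rng = np.random.default_rng(seed + 7)
    worst = 0.0
    for _ in range(n_cases):
        T = int(rng.integers(1, max_t + 1))
        q = rng.random(T)
        x = int(rng.integers(0, T + 1))
        outcomes = np.array(list(itertools.product([0, 1], repeat=T)))
        probs = np.prod(np.where(outcomes == 1, q, 1 - q), axis=1)
        brute = probs[outcomes.sum(axis=1) >= x].sum()
        worst = max(worst, abs(rec.poisson_binomial_tail(q, x) - brute))
    return worst


def pb_binomial_error(seed: int, n_cases: int = 200) -> float:
    """Max |DP tail - binomial survival| when all probabilities equal."""
    rng = np.random.default_rng(seed + 9)
    worst = 0.0
    for _ in range(n_cases):
        T = int(rng.integers(1, 200))
        p = float(rng.uniform(0.01, 0.99))
        x = int(rng.integers(0, T + 1))
        worst = max(worst, abs(rec.poisson_binomial_tail(np.full(T, p), x)
                               - float(binom.sf(x - 1, T, p))))
    return worst


def clustering_examples(seed: int) -> dict:
    """Clustering p at its two analytic anchors (hotspot and no-repeat)."""
    p_hot = rec.clustering_pvalue([500, 500, 500], 1000, seed=seed)
    p_flat = rec.clustering_pvalue([10, 400, 900], 1000, seed=seed)
    return {"hotspot_p": float(p_hot), "distinct_p": float(p_flat)}


def printed_fisher_tables() -> dict:
    """One-sided Fisher p-values for the published contingency tables.

    Inputs are the published cohort counts: 51 tumors with amplified MYC
    CREs of which 34 translocated (209/765 overall); APOBEC-signature
    positivity 230/765 against the t(14;16) (30/31), t(14;20) (7/9) and
    t(4;14) (46/93) translocation groups.
    """
    tables = {
        "myc_cre_translocation": (34, 17, 175, 539),
        "apobec_t14_16": (30, 1, 200, 534),
        "apobec_t14_20": (7, 2, 223, 533),
        "apobec_t4_14": (46, 47, 184, 488),
    }
    return {name: fisher_exact([[a, b], [c, d]], "greater")[1]
            for name, (a, b, c, d) in tables.items()}


def signature_refit_errors(seed: int) -> dict:
    """Exact single-signature recovery and 0.6/0.4 mixture error."""
    catalog = make_synthetic_catalog(n_signatures=5, seed=3)
    single = refit_exposures(1000 * catalog.matrix["S2"].to_numpy(), catalog)
    rng = np.random.default_rng(seed + 21)
    probs = (0.6 * catalog.matrix["S1"] + 0.4 * catalog.matrix["S4"]).to_numpy()
    spectrum = rng.multinomial(10_000, probs)
    mix = refit_exposures(spectrum, catalog)
    mix_err = max(abs(mix.weights["S1"] - 0.6), abs(mix.weights["S4"] - 0.4))
    return {
        "single_weight": float(single.weights["S2"]),
        "single_residual": float(single.residual),
        "mixture_max_abs_error": float(mix_err),
    }


def aid_oracle_agreement() -> dict:
    """Agreement of the AID classifier with a regex oracle on all 4-mer
    contexts x substitutions (via the full 5-mer enumeration)."""
    import re

    from .signatures import revcomp

    def oracle(ref, alt, ctx5):
        comp = str.maketrans("ACGT", "TGCA")
        rc = revcomp(ctx5)
        if alt in "TG" and re.match(r"[AT][AG]C[CT]", ctx5[:4]):
            return "canonical_AID"
        if alt.translate(comp) in "TG" and re.match(r"[AT][AG]C[CT]", rc[:4]):
            return "canonical_AID"
        if alt in "CG" and re.match(r"[AT]A", ctx5[1:3]):
            return "noncanonical_AID"
        if alt.translate(comp) in "CG" and re.match(r"[AT]A", rc[1:3]):
            return "noncanonical_AID"
        return "other"

    n, agree = 0, 0
    for ctx in map("".join, itertools.product("ACGT", repeat=5)):
        ref = ctx[2]
        for alt in "ACGT":
            if alt == ref:
                continue
            n += 1
            agree += _aid_label(ref, alt, ctx) == oracle(ref, alt, ctx)
    return {"agreement": agree / n, "n_cases": n}
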