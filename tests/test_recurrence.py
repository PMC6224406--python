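"""Background model, Poisson-binomial tail, clustering test, combination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h
from scipy.stats import binom, chi2

import regdriver.recurrence as rec
from regdriver.regions import CREFragment, GenomicInterval
from regdriver.variants import filter_variant_frame


def enumerate_tail(q, x_obs):
    """Brute-force P(X >= x_obs) over all 2^T outcomes."""
    q = np.asarray(q)
    T = len(q)
    total = 0.0
    for mask in range(2 ** T):
        bits = np.array([(mask >> i) & 1 for i in range(T)], dtype=bool)
        if bits.sum() >= x_obs:
            total += np.prod(np.where(bits, q, 1 - q))
    return total


class TestRegionTumorProbability:
    def test_zero_rates_give_zero(self):
        assert rec.region_tumor_probability(np.zeros(10)) == 0.0

    def test_single_base_identity(self):
        assert rec.region_tumor_probability([0.37]) == pytest.approx(0.37)

    def test_closed_form_product(self):
        q = rec.region_tumor_probability(np.full(100, 0.001))
        assert q == pytest.approx(1 - 0.999 ** 100, rel=1e-12)
        assert q == pytest.approx(0.09521, abs=5e-6)

    def test_rate_of_one_rejected(self):
        with pytest.raises(ValueError):
            rec.region_tumor_probability([0.5, 1.0])


class TestPoissonBinomialTail:
    def test_symmetric_binomial(self):
        assert rec.poisson_binomial_tail([0.5, 0.5, 0.5], 2) == pytest.approx(0.5)

    def test_zero_threshold_is_certain(self):
        assert rec.poisson_binomial_tail(np.random.default_rng(0).random(20), 0) == 1.0

    def test_hand_enumerated_example(self):
        p = rec.poisson_binomial_tail([0.1, 0.2, 0.3], 1)
        assert p == pytest.approx(1 - 0.9 * 0.8 * 0.7, rel=1e-12)

    def test_threshold_above_count_rejected(self):
        with pytest.raises(ValueError):
            rec.poisson_binomial_tail([0.5], 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(2, 13))
        q = rng.random(T)
        x = int(rng.integers(0, T + 1))
        assert rec.poisson_binomial_tail(q, x) == pytest.approx(
            enumerate_tail(q, x), abs=1e-12)

    @given(p=st_h.floats(0.01, 0.99), T=st_h.integers(1, 60),
           frac=st_h.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_equal_probabilities_reduce_to_binomial(self, p, T, frac):
        x = int(round(frac * T))
        ours = rec.poisson_binomial_tail(np.full(T, p), x)
        assert ours == pytest.approx(float(binom.sf(x - 1, T, p)), abs=1e-10)

    def test_large_cohort_approximation_close_to_dp(self):
        rng = np.random.default_rng(3)
        q = rng.uniform(0, 0.4, 6000)
        x = int(q.sum() + 2 * np.sqrt((q * (1 - q)).sum()))
        approx = rec.poisson_binomial_tail(q, x)
        exact = rec.poisson_binomial_pmf(q)[x:].sum()
        assert approx == pytest.approx(float(exact), rel=0.05)


class TestClusteringPvalue:
    def test_all_distinct_gives_one(self):
        assert rec.clustering_pvalue([1, 5, 9], 1000, seed=0) == 1.0

    def test_triple_coincidence_is_extreme(self):
        # analytic P(all 3 coincide or 2+ collide beyond S>=2) = 1e-6 at s=1000
        p = rec.clustering_pvalue([7, 7, 7], 1000, seed=0)
        assert p <= 2 / 10_001

    def test_fewer_than_three_mutations_not_tested(self):
        assert rec.clustering_pvalue([4, 4], 1000, seed=0) is None

    def test_zero_length_region_rejected(self):
        with pytest.raises(ValueError):
            rec.clustering_pvalue([1, 2, 3], 0, seed=0)

    def test_seeded_reproducibility(self):
        a = rec.clustering_pvalue([3, 3, 9, 20], 500, seed=42)
        b = rec.clustering_pvalue([3, 3, 9, 20], 500, seed=42)
        assert a == b

    def test_across_seed_variability_is_binomial(self):
        """Permutation noise matches the binomial error of 10,000 draws."""
        # m=6, s=200: analytic P(S>=1) = 1 - prod(1 - i/200)
        p_true = 1 - np.prod([1 - i / 200 for i in range(6)])
        ps = [rec.clustering_pvalue([1, 2, 3, 4, 5, 5], 200, seed=s)
              for s in range(20)]
        se = np.sqrt(p_true * (1 - p_true) / 10_000)
        assert abs(np.mean(ps) - p_true) < 4 * se

    def test_cache_agrees_with_direct_call_semantics(self):
        cache = rec.ClusteringNullCache(seed=1, n_perm=10_000)
        positions = np.array([10, 10, 30, 50])
        p_cached = cache.pvalue(positions, 651)
        p_direct = rec.clustering_pvalue(positions, 651, seed=1)
        # same statistic, same null family; values agree to Monte Carlo error
        assert p_cached == pytest.approx(p_direct, abs=0.02)
        assert cache.pvalue(np.array([1, 2]), 651) is None


class TestCombineFisher:
    def test_both_uninformative(self):
        assert rec.combine_fisher(1.0, 1.0) == 1.0

    def test_closed_form_chi2_four_df(self):
        x = -4 * np.log(0.05)
        expected = np.exp(-x / 2) * (1 + x / 2)
        got = rec.combine_fisher(0.05, 0.05)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.0175, abs=5e-4)

    def test_absent_clustering_passes_through(self):
        assert rec.combine_fisher(0.03, None) == 0.03

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            rec.combine_fisher(0.0, 0.5)
        with pytest.raises(ValueError):
            rec.combine_fisher(0.5, -0.1)

    @given(p1=st_h.floats(1e-10, 1.0), p2=st_h.floats(1e-10, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_scipy_chi2(self, p1, p2):
        got = rec.combine_fisher(p1, p2)
        assert got == pytest.approx(
            float(chi2.sf(-2 * (np.log(p1) + np.log(p2)), 4)), rel=1e-9)


class TestBHFdr:
    def test_textbook_step_up(self):
        np.testing.assert_allclose(
            rec.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert rec.bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        np.testing.assert_allclose(rec.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_empty_input(self):
        assert rec.bh_fdr([]).size == 0

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        q = rec.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def _toy_tracks(n_windows=600, seed=0):
    rng = np.random.default_rng(seed)
    w = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n_windows) * 1000,
        "end": (np.arange(n_windows) + 1) * 1000,
        "ref_class": rng.integers(0, 2, n_windows),
        "reptime": rng.normal(0, 1, n_windows),
        "coverage": rng.normal(0, 1, n_windows),
    })
    return rec.CovariateTracks(w)


def _simulate_fit_data(tracks, betas, n_tumors=30, seed=0):
    """Simulate per-base mutations from the logistic model over fragments."""
    from scipy.special import expit
    rng = np.random.default_rng(seed)
    w = tracks.windows
    frags = [CREFragment(f"f{i}", GenomicInterval("chr1", int(s), int(e)))
             for i, (s, e) in enumerate(zip(w["start"], w["end"]))]
    eta = (betas[0] + betas[1] * w["ref_class"].to_numpy()
           + betas[2] * w["reptime"].to_numpy()
           + betas[3] * w["coverage"].to_numpy())
    rows = []
    for t in range(n_tumors):
        counts = rng.binomial(1000, expit(eta))
        for wi in np.flatnonzero(counts):
            for pos in rng.integers(w["start"][wi], w["end"][wi], counts[wi]):
                rows.append((f"T{t:03d}", "chr1", pos + 1))
    snvs = pd.DataFrame(rows, columns=["tumor_id", "chrom", "pos"])
    return snvs, frags, [f"T{t:03d}" for t in range(n_tumors)]


class TestFitBackground:
    def test_null_model_recovers_flat_rate(self):
        """With all covariate effects zero, fitted rates match the true rate."""
        tracks = _toy_tracks()
        snvs, frags, tumors = _simulate_fit_data(
            tracks, betas=(-6.0, 0, 0, 0), seed=1)
        model = rec.fit_background(snvs, tracks, frags, tumor_ids=tumors)
        lo, hi = model.conf_int["intercept"]
        assert lo <= -6.0 <= hi
        for name in ("ref_class", "reptime", "coverage"):
            lo, hi = model.conf_int[name]
            assert lo <= 0.0 <= hi

    def test_covariate_effect_recovered(self):
        tracks = _toy_tracks()
        snvs, frags, tumors = _simulate_fit_data(
            tracks, betas=(-6.0, 0.25, 0.5, 0.3), seed=2)
        model = rec.fit_background(snvs, tracks, frags, tumor_ids=tumors)
        lo, hi = model.conf_int["reptime"]
        assert lo <= 0.5 <= hi

    def test_negative_sampling_offset_correction(self):
        """Thinned-control fit agrees with the full-data fit."""
        tracks = _toy_tracks()
        snvs, frags, tumors = _simulate_fit_data(
            tracks, betas=(-6.0, 0.25, 0.5, 0.3), seed=3)
        full = rec.fit_background(snvs, tracks, frags, tumor_ids=tumors)
        thin = rec.fit_background(snvs, tracks, frags, tumor_ids=tumors,
                                  negative_sampling_fraction=0.1,
                                  rng=np.random.default_rng(0))
        design = tracks.design(np.arange(50))
        p_full = full.rates(design, tumors[0])
        p_thin = thin.rates(design, tumors[0])
        assert np.abs(p_thin / p_full - 1).max() < 0.05

    def test_rates_strictly_inside_unit_interval(self):
        tracks = _toy_tracks()
        snvs, frags, tumors = _simulate_fit_data(tracks, (-6, 0, 0, 0), seed=4)
        model = rec.fit_background(snvs, tracks, frags, tumor_ids=tumors)
        p = model.rates(tracks.design(np.arange(len(tracks.windows))), tumors[0])
        assert (p > 0).all() and (p < 1).all()


class TestRunRecurrence:
    def test_spiked_driver_detected_on_cohort(self, spiked_cohort):
        cfg, paths, truth = spiked_cohort
        maf, _ = filter_variant_frame(pd.read_csv(paths["snvs"], sep="\t"))
        tracks = rec.CovariateTracks.from_tracks(
            rec.read_track(paths["reptime"]), rec.read_track(paths["coverage"]),
            rec.read_track(paths["refclass"]))
        inter = pd.read_csv(paths["interactions"], sep="\t")
        frags = {}
        for r in inter.itertuples(index=False):
            frags.setdefault(r.fragment_id, CREFragment(
                r.fragment_id, GenomicInterval(r.chrom, r.start, r.end)))
        frags = list(frags.values())
        tumors = sorted(maf["tumor_id"].unique())
        model = rec.fit_background(maf, tracks, frags, kind="cre",
                                   tumor_ids=tumors)
        res = rec.run_recurrence(frags, maf, model, tracks, tumors,
                                 n_perm=2000, seed=0)
        driver_ids = [r for r in truth.driver_regions if r.startswith("cre:")]
        hit = res.loc[res["region_id"].isin(driver_ids)]
        assert (hit["q"] < 0.05).all()
        # u <= m and x <= n_tumors everywhere
        assert (res["u"] <= res["m"]).all()
        assert (res["x"] <= len(tumors)).all()
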