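"""Synthetic cohort generator: determinism, truth, marginal statistics."""

import filecmp

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from regdriver import DriverSpec, GeneratorConfig, generate_cohort, spike_hotspot
from regdriver.synthetic import _make_windows, _rng


class TestSpikeHotspot:
    region = np.arange(1000, 2000)

    def test_zero_concentration_identity(self):
        pos = np.array([1005, 1100, 1500, 1999])
        out = spike_hotspot(pos, self.region, 0.0, 0)
        np.testing.assert_array_equal(out, pos)

    def test_full_concentration_collapses_all(self):
        pos = np.array([1005, 1100, 1500, 1999, 1001])
        out = spike_hotspot(pos, self.region, 1.0, 0)
        assert len(np.unique(out)) == 1
        # clustering statistic S = m - distinct = 4
        assert len(out) - len(np.unique(out)) == 4

    def test_partial_concentration_exact_count(self):
        rng = np.random.default_rng(3)
        pos = rng.choice(np.arange(10_000, 20_000), 10, replace=False)
        out = spike_hotspot(pos, np.arange(10_000, 20_000), 0.6, 7)
        top = np.bincount(out - 10_000).max()
        assert top == 6

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            spike_hotspot(np.array([1, 2, 3]), np.array([]), 0.5, 0)

    def test_invalid_concentration_rejected(self):
        with pytest.raises(ValueError):
            spike_hotspot(np.array([1]), self.region, 1.5, 0)


class TestGeneratorValidation:
    def test_zero_tumors_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            GeneratorConfig(n_tumors=0).validate()

    def test_signature_mix_must_sum_to_one(self):
        cfg = GeneratorConfig(signature_mix={"S1": 0.5, "S2": 0.2})
        with pytest.raises(ValueError, match="sum"):
            cfg.validate()

    def test_fragment_larger_than_chromosome_rejected(self):
        cfg = GeneratorConfig(chrom_lengths={"chr1": 1000}, fragment_size=2000)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_driver_multiplier_below_one_rejected(self):
        with pytest.raises(ValueError):
            DriverSpec(region="promoter:G00001", multiplier=0.5)


class TestGeneratedCohort:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(seed=5, n_tumors=10, n_genes=15,
                              chrom_lengths={"chr1": 300_000})
        paths_a, _ = generate_cohort(cfg, tmp_path / "a")
        paths_b, _ = generate_cohort(cfg, tmp_path / "b")
        for key in paths_a:
            assert filecmp.cmp(paths_a[key], paths_b[key], shallow=False), key

    def test_null_cohort_has_no_true_drivers(self, null_cohort):
        _, _, truth = null_cohort
        assert truth.driver_regions == {}

    def test_neutral_driver_spec_not_a_truth_driver(self, tmp_path):
        cfg = GeneratorConfig(
            seed=6, n_tumors=10, n_genes=15,
            chrom_lengths={"chr1": 300_000},
            driver_spec=[DriverSpec(region="promoter:G00002", multiplier=1.0,
                                    concentration=0.0,
                                    expression_fold_change=1.0)])
        _, truth = generate_cohort(cfg, tmp_path / "n")
        assert truth.driver_regions == {}

    def test_driver_ids_exist_in_region_set(self, spiked_cohort):
        _, _, truth = spiked_cohort
        assert set(truth.driver_regions) <= set(truth.region_ids)

    def test_exposures_sum_to_one(self, null_cohort):
        _, _, truth = null_cohort
        for t, w in truth.true_exposures.items():
            assert sum(w.values()) == pytest.approx(1.0)

    def test_interaction_table_exercises_filters(self, null_cohort):
        """Scores straddle the 5.0 cutoff; the emitted tables include rows
        on both sides of every filter used downstream."""
        _, paths, _ = null_cohort
        inter = pd.read_csv(paths["interactions"], sep="\t")
        assert (inter["score"] >= 5).any() and (inter["score"] < 5).any()

    def test_distances_straddle_one_megabase(self, tmp_path):
        cfg = GeneratorConfig(seed=9, n_tumors=5, n_genes=30,
                              chrom_lengths={"chr1": 3_000_000})
        paths, _ = generate_cohort(cfg, tmp_path / "d")
        inter = pd.read_csv(paths["interactions"], sep="\t")
        assert (inter["distance"] <= 1e6).any() and (inter["distance"] > 1e6).any()

    def test_mappability_track_has_holes(self, null_cohort):
        _, paths, _ = null_cohort
        bed = pd.read_csv(paths["mappability"], sep="\t", header=None,
                          names=["chrom", "start", "end"])
        total = bed.groupby("chrom").apply(
            lambda g: (g["end"] - g["start"]).sum(), include_groups=False)
        assert (total < pd.Series({"chr1": 600_000, "chr2": 600_000})).any()

    def test_maf_uses_one_based_positions_with_context(self, null_cohort):
        _, paths, _ = null_cohort
        maf = pd.read_csv(paths["snvs"], sep="\t")
        assert (maf["pos"] >= 1).all()
        ok = maf["context"].str[2] == maf["ref"]
        assert ok.all()

    def test_mutation_load_within_sampling_bound(self, null_cohort):
        """Cohort-wide SNV count is within 4 SD of the rate-model expectation."""
        cfg, paths, _ = null_cohort
        maf = pd.read_csv(paths["snvs"], sep="\t")
        windows = _make_windows(cfg)
        bc = cfg.background_coefs
        eta = (bc.intercept + bc.beta_refclass * windows["ref_class"]
               + bc.beta_reptime * windows["reptime"]
               + bc.beta_coverage * windows["coverage"]).to_numpy()
        w_len = (windows["end"] - windows["start"]).to_numpy()
        # offsets drawn first in the snv substream, as in generation
        offsets = _rng(cfg, "snv").normal(0, bc.tumor_offset_sd, cfg.n_tumors)
        expected = sum((w_len * expit(eta + o)).sum() for o in offsets)
        var = sum((w_len * expit(eta + o) * (1 - expit(eta + o))).sum()
                  for o in offsets)
        assert abs(len(maf) - expected) < 4 * np.sqrt(var)

    def test_cnv_segments_non_overlapping_per_sample(self, null_cohort):
        _, paths, _ = null_cohort
        seg = pd.read_csv(paths["cnv"], sep="\t")
        for (s, c), grp in seg.groupby(["sample_id", "chrom"]):
            g = grp.sort_values("start")
            assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()

    def test_null_gene_expression_balanced_between_groups(self, tmp_path):
        """For fold-change-1 genes, mutated vs unmutated means agree."""
        zs = []
        for seed in range(6):
            cfg = GeneratorConfig(seed=100 + seed, n_tumors=30, n_genes=10,
                                  chrom_lengths={"chr1": 300_000})
            paths, _ = generate_cohort(cfg, tmp_path / f"e{seed}")
            counts = pd.read_csv(paths["counts"], sep="\t", index_col=0)
            maf = pd.read_csv(paths["snvs"], sep="\t")
            tss = pd.read_csv(paths["tss"], sep="\t")
            for _, g in tss.iloc[:3].iterrows():
                near = maf[(maf["pos"] - 1 - g["tss"]).abs() < 400]
                mut = set(near["tumor_id"])
                y = counts.loc[g["gene"]]
                a = y[[c for c in y.index if c in mut]]
                b = y[[c for c in y.index if c not in mut]]
                if len(a) >= 3 and len(b) >= 3:
                    se = np.sqrt(a.var() / len(a) + b.var() / len(b))
                    zs.append((a.mean() - b.mean()) / se)
        assert np.abs(np.mean(zs)) < 3 / np.sqrt(len(zs)) * 3


class TestRefitFromEmittedData:
    def test_signature_mixture_visible_in_spectrum(self, null_cohort):
        """The pooled spectrum is closer to the configured mixture than to
        a uniform spectrum."""
        from regdriver.signatures import SignatureCatalog, trinucleotide_spectrum
        cfg, paths, truth = null_cohort
        maf = pd.read_csv(paths["snvs"], sep="\t")
        catalog = SignatureCatalog.read(paths["catalog"])
        mix = pd.Series(cfg.signature_mix)
        target = catalog.matrix[mix.index].to_numpy() @ mix.to_numpy()
        spec = trinucleotide_spectrum(maf.sample(3000, random_state=0))
        spec = spec / spec.sum()
        # channel sampling is class-conditioned, so allow loose agreement
        d_mix = np.abs(spec - target).sum()
        d_flat = np.abs(spec - 1 / 96).sum()
        assert d_mix < d_flat
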