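"""Recurrence scan: background model + Poisson-binomial + clustering test.

Fits the per-base logistic background mutation model on a spiked cohort's
promoters, computes each region's mutated-tumor count against its
Poisson-binomial expectation, the positional clustering permutation test,
and the Fisher-combined, BH-adjusted significance.  The spiked driver
promoter should surface at Q < 0.05.
"""

import tempfile

import pandas as pd

import regdriver.recurrence as rec
from regdriver import BackgroundCoefs, DriverSpec, GeneratorConfig, generate_cohort
from regdriver.regions import define_promoters
from regdriver.variants import filter_variant_frame

cfg = GeneratorConfig(
    seed=23, n_tumors=60, n_genes=40,
    chrom_lengths={"chr1": 600_000, "chr2": 600_000, "chr3": 600_000},
    background_coefs=BackgroundCoefs(intercept=-9.5),
    driver_spec=[DriverSpec(region="promoter:G00003", multiplier=12.0,
                            concentration=0.6)])
paths, truth = generate_cohort(cfg, tempfile.mkdtemp())

maf, rejected = filter_variant_frame(pd.read_csv(paths["snvs"], sep="\t"))
tracks = rec.CovariateTracks.from_tracks(
    rec.read_track(paths["reptime"]), rec.read_track(paths["coverage"]),
    rec.read_track(paths["refclass"]))
tss = pd.read_csv(paths["tss"], sep="\t")
promoters = define_promoters(tss, cfg.chrom_lengths)
tumors = sorted(maf["tumor_id"].unique())

model = rec.fit_background(maf, tracks, promoters, kind="promoter",
                           tumor_ids=tumors)
print("fitted background model (log-odds per unit covariate):")
print(f"  intercept {model.intercept:.2f}, ref A/T {model.beta_ref_class:.3f},"
      f" replication timing {model.beta_reptime:.3f},"
      f" coverage {model.beta_coverage:.3f}")

res = rec.run_recurrence(promoters, maf, model, tracks, tumors,
                         n_perm=10_000, seed=23)
top = res.sort_values("q").head(3)
print("\ntop regions (m = mutations, x = mutated tumors, u = distinct sites):")
print(top.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print(f"\ntrue driver: {list(truth.driver_regions)[0]}")
print("a small q on that region means the scan recovered the spiked driver;"
      "\nnull promoters should sit at q near 1.")
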