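"""Mutational signatures and AID motif classification.

Computes the 96-channel trinucleotide spectrum of a cohort's SNVs, refits
per-cohort signature exposures against the shipped catalog by non-negative
least squares (weights under 0.06 zeroed), and classifies each mutation as
canonical AID (C>T/G in WRCY), non-canonical AID (A>C/G in WA) or other.
"""

import tempfile

import pandas as pd

from regdriver import GeneratorConfig, generate_cohort
from regdriver.signatures import (
    SignatureCatalog,
    classify_aid,
    refit_exposures,
    trinucleotide_spectrum,
)

cfg = GeneratorConfig(seed=4, n_tumors=25, n_genes=30,
                      chrom_lengths={"chr1": 500_000},
                      signature_mix={"S1": 0.5, "S2": 0.3, "S3": 0.2})
paths, truth = generate_cohort(cfg, tempfile.mkdtemp())

maf = pd.read_csv(paths["snvs"], sep="\t")
catalog = SignatureCatalog.read(paths["catalog"])

spectrum = trinucleotide_spectrum(maf)
print(f"spectrum over {spectrum.sum()} SNVs; "
      f"busiest channel holds {spectrum.max()} mutations")

profile = refit_exposures(spectrum, catalog, sample_id="cohort")
weights = profile.weights[profile.weights > 0]
print("refit exposures (fraction of mutations attributed per signature):")
for sig_id, w in weights.items():
    print(f"  {sig_id}: {w:.3f}")
print(f"residual {profile.residual:.4f}; configured truth was "
      f"{cfg.signature_mix} (channel sampling is conditioned on the local"
      "\nbase class, so recovered weights are approximate)")

labels = classify_aid(maf)
counts = labels.value_counts()
print("\nAID motif classification:")
for lab in ("canonical_AID", "noncanonical_AID", "other"):
    print(f"  {lab}: {counts.get(lab, 0)}")
print("an excess of WRCY/WA-motif mutations in a B-cell regulatory region"
      "\nis the fingerprint of on/off-target AID activity.")
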