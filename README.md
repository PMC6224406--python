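# regdriver

Recurrence testing and expression-effect analysis of **non-coding
regulatory mutations** in tumor cohorts.

Most cancer driver searches look at protein-coding exons. `regdriver`
implements the complementary analysis for whole-genome cohorts: restrict
the non-coding search space to gene promoters and the cis-regulatory
elements (CREs) that physically contact them (promoter capture Hi-C
interactions), test each region for more mutations and more positional
clustering than a covariate-aware background model predicts, and then ask
whether mutation or copy-number change of a significant region actually
shifts its target gene's expression. It was built with multiple-myeloma
cohorts in mind (hyperdiploid/translocation karyotypes, APOBEC and AID
mutational signatures) but the machinery is generic. Because real
patient-level data cannot ship with code, the package includes a
first-class synthetic cohort generator with known ground truth, which all
calibration and recovery studies run against.

Intended users: statistical-genomics researchers and bioinformaticians
analyzing tumor WGS + RNA-seq + copy-number cohorts from Python.

## The model

For every testable base *k* of a regulatory region and tumor *t*, the
background mutation probability comes from a logistic regression

&nbsp;&nbsp;logit *p₍t,k₎* = β₀ + β₁·refclass(k) + β₂·reptime(k) + β₃·coverage(k) + αₜ

with covariates reference-base class (A/T vs G/C), replication timing and
sequencing coverage, and a per-tumor effect αₜ (promoters and CREs are fit
separately). A region of *s* testable bases is mutated in tumor *t* with
probability

&nbsp;&nbsp;*q*ₜ = 1 − ∏ₖ (1 − *p₍t,k₎*),

so the number of mutated tumors *X* is Poisson-binomial over tumors and
the background P-value is the exact tail P(X ≥ x_obs), computed by
dynamic-programming convolution. Positional clustering is scored by
S = m − u (m mutations, u distinct positions) against 10,000 uniform
permutations over the region's testable bases, with add-one smoothing.
The two P-values are combined by Fisher's method (χ², 4 df) and BH-adjusted
per batch; regions with Q < 0.05 are recurrently mutated.

Downstream, expression effects are tested with an exact-style two-group
negative-binomial test (TMM library factors, conditional-ML common
dispersion, conditioning on the pooled count total; candidates need fold
change ≥ 1.2 or ≤ 0.8 and Q < 0.1), CNV effects at CREs with the same test
on focal-event groups (|log₂ ratio| ≥ 0.1613, < 3 Mb, groups of ≥ 7),
karyotypes with the ≥ 90%-amplified / ≥ 2-autosome hyperdiploidy rule, and
mutational etiology with 96-channel signature refitting (NNLS with a 0.06
exposure floor) and AID motif classification (canonical C>T/G in WRCY,
non-canonical A>C/G in WA).

## Worked example

`examples/02_recurrence_scan.py` simulates a 60-tumor cohort with one
spiked promoter driver (12× mutation rate, 60% of its mutations on one
hotspot base), fits the background model and runs the recurrence scan:

```
fitted background model (log-odds per unit covariate):
  intercept -9.19, ref A/T -0.118, replication timing 0.191, coverage 0.411

top regions (m = mutations, x = mutated tumors, u = distinct sites):
                  region_id  m  x  u  p_background  p_cluster  p_combined        q
promoter:G00003:chr1:200051 14 13  8      0.000102     0.0001    1.98e-07 7.93e-06
   promoter:G00000:chr1:365  4  4  4         0.186          1       0.498        1
 promoter:G00001:chr1:66840  1  1  1         0.886        NaN       0.886        1
```

The spiked driver is mutated in 13 of 60 tumors where the background
expects ~2 (Poisson-binomial p = 1.0e-4), and 14 mutations hit only 8
distinct sites (clustering p = 1.0e-4); combined and BH-adjusted it is the
only call at Q < 0.05. Null promoters sit at q ≈ 1, and a region with
fewer than three mutations gets no clustering test (`p_cluster = NaN`,
background P passed through). Running the full pipeline on the same cohort
(`examples/03_pipeline_expression.py`) then flags the driver's expression
effect: fold change 0.249 at Q = 5.8e-8 against the spiked 4.6-fold
knock-down, after excluding CNV-bearing samples.

The other examples cover cohort simulation (01), CNV calling, karyotyping
and translocation enrichment (04), and signature refitting plus AID motifs
(05); each prints the numbers it computes and what they mean.

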