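# Methods

## Scope and shape

`regdriver` is a library for discovering non-coding driver mutations in
tumor cohorts by recurrence testing of promoters and promoter-interacting
cis-regulatory elements (CREs), coupled to expression-effect testing,
CNV/karyotype statistics, and mutational-signature/AID-motif analysis.
Its public face is the importable API plus `examples/`; a thin `mmreg` CLI
wraps cohort simulation and end-to-end runs. All coordinates are 0-based
half-open internally; MAF-like variant tables and TSS tables are 1-based
inclusive and converted at I/O boundaries.

## Region definition

Promoter windows span 400 bp upstream to 250 bp downstream of each
annotated TSS in gene orientation — 651 bp including the TSS base itself.
Overlapping windows of the same gene are merged; windows are clipped at
chromosome ends. CRE fragments come from a promoter-interaction table and
are retained when the interaction score is ≥ 5 and the TSS-to-nearest-edge
distance is ≤ 1 Mb (both inclusive), and when ≥ 95% of fragment bases are
covered by the well-mapped track (a fragment without any coverage counts
as 0% and is dropped with a log entry). For CREs, open reading frames
padded by 5 bp (splice sites) and UTRs are removed from the testable mask;
promoter windows keep their full span but ORF-overlapping mutations are
excluded when mutations are assigned to regions. Where "upstream",
merge rules, or the distance anchor were underdetermined, the choices here
(strand-aware windows, merge-overlapping, TSS-to-edge) are deliberate
design decisions, documented so tests are stable.

## Variant QC

Record-level filters retain SNVs with ≥ 1 alternative read on each strand,
mean Phred base quality strictly > 26, mean mapping quality ≥ 50, and
alignability exactly 1.0. Rejection counts attribute each removed record
to the first failed rule in the fixed order strand → bq → mq →
alignability. QC metrics are consumed from table columns; the package
never opens read-level data. WGS sensitivity against a high-coverage
call set is the fraction of exome variants with alternate allele ratio
> 0.2 (matched on chrom/pos/ref/alt) recovered by the genome calls,
reported per sample and as an unweighted cohort mean; an empty clonal set
yields a missing value, not zero.

## Background mutation model

Per-base mutation probability is logistic in reference-base class (A/T vs
G/C), replication timing, and coverage, with tumor identity as a rate
offset; promoters and CREs are fitted separately. Covariates are
piecewise constant over 1-kb windows, so per-(tumor, window) binomial
aggregation is an exact representation of the per-base Bernoulli model and
keeps the GLM design at (tumors × windows) rows. Tumor effects use a
two-pass scheme: per-tumor offsets are set from marginal mutation loads
(logit of the tumor's crude rate relative to the pooled rate, with a +0.5
smoothing count), then the four shared coefficients are fitted by a
binomial GLM with those offsets fixed. Because every tumor is exposed to
the same covariate tracks, tumor load is independent of the covariate
effects and the shared coefficients are estimated without bias; the
acceptance study verifies 95%-CI coverage of the replication-timing
coefficient across 20 simulated cohorts. Optional case-control thinning
of unmutated observations (negative sampling) corrects the intercept by
ln(fraction). Non-convergence raises with the covariate list rather than
returning a partial fit.

## Recurrence statistics

The printed form of the region probability in the source method equals the
probability of *no* mutation; the per-tumor success probability used here
is the complement, q_t = 1 − ∏(1 − p_k) over the region's testable bases.
The count of mutated tumors is then Poisson-binomial; P(X ≥ x_obs) is
computed by exact O(T²) convolution up to 5,000 tumors and by a
skewness-corrected (refined-normal) approximation beyond, with the tail
summed smallest-term-first and clamped to [0, 1] against accumulated
rounding. Multiple mutations of one tumor at one base count once toward
both x and m.

Clustering uses S = m − u (mutations minus distinct positions). Regions
with fewer than three mutations are not tested and their combined value is
the background P alone. The null draws m positions uniformly with
replacement over the region's testable bases; the P-value is
(r + 1)/(n_perm + 1) with n_perm = 10,000, which avoids exact zeros that
would break the log-based combination. Because the null depends only on
(m, s), cohort-level runs cache one permutation table per (m, s) pair,
each on its own deterministic substream — statistically equivalent for
marginal inference and roughly the number-of-distinct-m-values times
cheaper. Fisher's combination uses the χ² 4-df upper tail; BH adjustment
runs separately for promoters and CREs, and ties resolve by the standard
cumulative-minimum step-up.

**Conservatism of the combined test.** Fisher's method presumes
continuous uniform inputs. Both components here are discrete — the
Poisson-binomial tail takes at most T + 1 values and the clustering P has
most of its null mass at exactly 1.0 (S = 0) — so the combined test is
valid but conservative. A design study over baseline rates
(logit⁻¹ −9.5 … −5.0) and per-tumor spread found the attained size at
nominal 0.05 peaks near 0.024 when the expected mutated-tumor count is
15–22 of 50 and falls off on both sides (Poisson-binomial coarseness at
low counts, saturation near T at high counts). The packaged null
calibration reports the measured fraction (≈ 0.02 at the default design)
rather than forcing it to nominal; the companion FDR study confirms the
Q < 0.05 call set on null cohorts is (almost always) empty. The published
method inherits the same conservatism; it costs power, never validity.

## Expression effects

Library scaling uses trimmed-mean-of-M-values factors (30% M-trim, 5%
A-trim, reference = sample with upper quartile closest to the mean),
normalized to geometric mean 1. Counts are scaled to the geometric-mean
effective library and rounded only inside the conditional test; fold
changes use the unrounded normalized means with a display-only prior count
of 0.5. A common dispersion is estimated by conditional maximum
likelihood on the adjusted counts (bounded search on log φ; the Poisson
limit φ = 0 is accepted when it fits at least as well). The two-group
test conditions on the pooled adjusted total: the group-1 sum given the
total follows the NB analogue of the hypergeometric with sizes n·r
(r = 1/φ), and the two-sided P doubles the smaller tail (observed point
included), capped at 1. At φ = 0 with equal libraries this reduces
exactly to the conditional binomial test (verified to 1e-10).

Sample selection excludes tumors with a copy-number event (|log₂| ≥
0.1613, aneuploidy included) over the region or the target gene, excludes
tumors mutated in more than one recurrent CRE of the same promoter, and
compares against tumors unmutated in every such CRE; fewer than three
mutated samples makes the pair untestable. Gene "bodies" for CNV overlap
are TSS ± 1 kb, matching the synthetic annotation's resolution. Pairs are
BH-adjusted per run; candidates need fold change ≥ 1.2 or ≤ 0.8 and
Q < 0.1. CNV-at-CRE tests group samples by focal amplification/deletion
over the CRE against copy-neutral samples, drop samples whose gene itself
carries an event (including single events spanning both), and skip groups
under 7 samples.

## CNVs, karyotype, signatures, cohort statistics

Events require |log₂ ratio| ≥ 0.1613; focal events additionally < 3 Mb.
A chromosome is amplified when ≥ 90% of its base-pair length is covered by
the union of amplification events (base pairs, not cytobands — a
documented choice); hyperdiploidy needs ≥ 2 amplified autosomes.
Mutation-burden comparisons per karyotype use the two-sided rank-sum test,
exact when the smaller side has ≤ 25 samples and no ties, otherwise the
tie-corrected normal approximation. Enrichment claims use one-sided
Fisher tests uniformly; term enrichment is an upper-tail hypergeometric at
the level of promoter/CRE-promoter interactions (so promiscuous promoters
do not dominate), with the term list supplied as configuration.

Spectra use the 96 pyrimidine-centered trinucleotide channels with
purine-reference mutations reverse-complemented. Exposure refitting is
non-negative least squares of the normalized spectrum on the catalog,
iteratively zeroing weights under the 0.06 floor (the conventional default
of refitting tools) and renormalizing only if the sum exceeds 1; signature
presence is a post-threshold weight > 0. AID classification is
strand-symmetric, canonical (mutated C of a WRCY, alt T/G) checked before
non-canonical (W-preceded A, alt C/G), with missing context mapped to
"other"; the implementation is verified against a brute-force regex oracle
over the full 5-mer × substitution enumeration.

## Synthetic cohorts

The generator emits every input the analysis consumes — TSS table,
interaction table (scores straddling 5, distances straddling 1 Mb),
replication-timing/coverage/ref-class tracks, mappability BED with
sub-95% holes in ~8% of fragments, MAF-like SNV table with QC columns (2%
of records failing one rule each), SEG file, count matrix, sample
metadata, and a synthetic signature catalog — plus a truth object. One
integer seed drives named substreams, so outputs are byte-identical across
runs.

What it emulates, and deliberate departures from patient data:

- **Accelerated mutation rate.** The default per-base rate
  (logit⁻¹(−7) ≈ 9×10⁻⁴ per tumor) is orders of magnitude above a
  patient genome's. Cohorts here are 30–60 tumors on megabase genomes;
  the rate is set so per-region counts give the discrete recurrence
  statistics the resolution they have at population scale (chosen from
  the attained-size design study above, fixed before any calibration was
  run). Fixtures that exercise the expression stage use a lower baseline
  (logit⁻¹(−9.5)) so driver regions stay mutated in a minority of tumors
  and a comparison group survives.
- **Smooth covariates.** Replication timing and coverage are stationary
  AR(1) fields over 1-kb windows (ρ = 0.99, ~100-kb correlation length,
  N(0,1) marginals), mimicking the smoothness of real tracks; base
  composition is drawn independently per window. Jagged covariate fields
  would put real rate heterogeneity inside single fragments, which the
  uniform clustering null would (correctly, but unrealistically) flag.
- **Desk-scale CNVs.** Focal sizes are exponential with 50-kb mean and
  hyperdiploid gains cover 97% of a chromosome, so CNV exclusions thin
  rather than erase expression comparison groups on a megabase genome.
- **Signature-conditioned alleles.** Each SNV's channel is drawn from the
  configured signature mixture restricted to the window's base class,
  then placed on either strand; contexts are emitted in the MAF, so
  spectrum/refit analyses run without a reference FASTA. The class
  conditioning slightly distorts the realized mixture, which is why
  mixture-recovery checks on generated cohorts are loose while the
  refitting acceptance tests use directly constructed spectra.
- Drivers are spiked as rate multipliers plus a hotspot step that moves a
  fixed fraction of a region's mutations onto one shared base; expression
  effects multiply the NB mean of mutated samples. Truth records only
  specs that actually alter the data (multiplier > 1, concentration > 0,
  or fold change ≠ 1).

Passing tests on these cohorts demonstrate calibration and recovery under
the model's own assumptions; they do not demonstrate robustness to
misspecified covariates, subclonal architecture, mappability artifacts, or
expression batch effects, none of which the generator simulates.

## Worked-example statistics

The cohort-scale findings the pipeline is built around (e.g. enrichment of
translocations among tumors with amplified CREs of a target oncogene;
APOBEC-signature enrichment in specific translocation groups) reduce to
one-sided Fisher tests on published cohort counts, which
`scripts/acceptance.py` recomputes. Two of the four tables are fully
determined by the published counts and reproduce the published p-values at
printed precision (30/31 of 765 → 1.2e-15; 7/9 → 4.1e-3). For the other
two, the published text fixes only the group counts (34/51 against 209 of
765; 46/93 against 230 of 765); the margins reconstructed from those
totals give 1.3e-9 and 2.1e-5, which differ from the published 1.2e-11 and
1.1e-5 — the original tables evidently used additional sample filtering
that is not stated. The package reports the values its reconstructed
tables actually produce.

## Numerical choices

- Poisson-binomial DP in float64; far tails summed smallest-first and the
  total clamped to 1; the > 5,000-tumor path uses the refined normal
  approximation with a half-count continuity correction.
- Permutation draws in chunks of ~2×10⁶ integers to bound memory.
- All-zero count rows are skipped (logged) by the dispersion estimator;
  degenerate inputs (empty regions, p ≥ 1 rates, zero-length regions,
  negative distances) raise rather than return sentinel values.
- BH uses `statsmodels.multipletests`; p-values are floored at 1e-300
  before adjustment to avoid log underflow in combination steps.
- Run outputs carry a 12-hex config hash over analysis parameters (paths
  excluded) so mixed-config outputs are detectable; identical seed and
  inputs give byte-identical reports.

## Known limitations

- The combined recurrence test is conservative (see above); at desk scale
  its attained size is ~0.02 at nominal 0.05.
- At extreme mutation densities (m approaching the region length) both
  component statistics saturate: every tumor is mutated under background
  too, and the per-(tumor, position) deduplication caps a hotspot's
  contribution at one count per tumor while background collisions grow —
  so the very strongest spiked drivers can become *less* detectable than
  moderate ones. Patient-scale densities are far below this regime.
- The two-pass tumor-offset scheme slightly understates intercept
  uncertainty; coefficient CIs for the shared covariates are verified by
  simulation, the intercept's is not guaranteed nominal.
- Count adjustment to a common library rounds to integers inside the
  conditional NB test; with strongly unequal libraries this is an
  approximation (exactness is only claimed, and tested, for equal
  libraries).
- The generator does not simulate indels, structural-variant breakpoints,
  read-level artifacts, or subclonality; sensitivity analysis against a
  high-coverage call set is exercised on constructed call sets only.
- Signature "presence" percentages of a real cohort are not reproducible
  from synthetic data and are out of scope.
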