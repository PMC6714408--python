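# Methods

This note documents the models behind `cnvresp`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions that make results reproducible.

## Copy-number HMM

The caller decodes a hidden copy-number state CN ∈ {0,1,2,3,4} along each
chromosome from two per-probe summaries of SNP-array fluorescence: the Log R
Ratio (LRR), a log-scale normalized total intensity proportional to local
copy number, and the B-allele frequency (BAF), the fraction of signal
attributable to the B allele.

**Emissions.** LRR | CN ~ Normal(μ_CN, σ_CN) with default means
(−3.5, −0.66, 0, 0.40, 0.68) and SDs (1.30, 0.28, 0.18, 0.21, 0.24) — the
values in wide use for Illumina-style arrays; both are configurable on
`HmmModel`. BAF | CN is a mixture over allelic compositions: with k copies
and j B alleles the cluster mean is j/k, weighted by Binomial(k, PFB) where
PFB is the probe's population B-allele frequency. Every cluster, including
the homozygous clusters at 0 and 1, is a Normal of common width
`baf_sd = 0.04` truncated to [0,1]; truncation roughly doubles the density
at the boundaries and avoids mixing discrete point masses with continuous
densities. CN=0 has no allelic signal and emits BAF uniformly. All standard
deviations are floored at 1e−3 and the mixture density at 1e−300, so the
log-likelihood is finite for any input.

**Transitions.** At inter-probe distance d the off-diagonal mass is
`p₀ (1 − exp(−d/D))` with `p₀ = 0.01` and `D = 100 kb`, split equally over
the four other states; the diagonal takes the remainder, so every row sums
to one at every distance. Nearby probes therefore almost never switch state
while distant probes approach a constant switch rate — the qualitative
behaviour of distance-aware array CNV callers.

**Decoding and calls.** Viterbi decoding in log space starts from
P(CN=2) = 0.99 (remainder uniform). Chromosomes are decoded independently;
sex chromosomes are simply never supplied (the analysis is autosomal).
Maximal runs with CN ≠ 2 become calls spanning the first to last probe of
the run; runs supported by fewer than four probes (i.e. not "more than
three") are dropped. Samples with more than 100 calls are excluded as
likely array-quality failures; exactly 100 is kept.

Deliberately out of scope relative to full-featured callers: no
loss-of-heterozygosity state, no GC-wave correction, no per-call confidence
score, no family-based calling.

## Boundary segmentation

Coordinates are 1-based inclusive throughout (length = end − start + 1);
conversion to BED's 0-based half-open convention happens only in the BED
writer. For each chromosome, the distinct call start positions and
(end + 1) positions are cut points; the union of call footprints is
partitioned into maximal intervals between consecutive cut points. Each
segment records every sample's copy number, defaulting to the diploid 2 when
no call overlaps — every patient appears in every segment's genotype column.
Within one sample, overlapping calls with conflicting copy number are a hard
error (the caller emits maximal runs, so a conflict means corrupt input);
overlapping calls that agree are tolerated.

This rule makes segments tile the covered genome exactly (no gaps, no
overlaps), makes every call a union of whole segments, and is idempotent:
re-segmenting the segments reproduces them. Printed regions that share an
endpoint (e.g. adjacent segments listed as …–129,458,197 and
129,458,197–…) abut without internal overlap under the (end + 1) cut
convention.

**Classification and filters.** A segment is deletion-only if all abnormal
copy numbers are < 2, duplication-only if all are > 2, multi-class
otherwise. The carrier frequency is the fraction of samples with CN ≠ 2.
Single-class segments are tested for Hardy–Weinberg equilibrium by mapping
CN 2/1/0 (deletions) or CN 2/3/4 (duplications) to the
reference-homozygote/heterozygote/variant-homozygote genotypes of a
biallelic CNV allele; the default test is the exact conditional test (sum of
probabilities of heterozygote counts no more probable than the observed one,
given the allele counts), with a 1-df chi-square variant available for
speed. The exact test is the default because observed variant-homozygote
counts can be as small as 0 or 1 at the frequencies of interest. Segments
are kept for association when carrier frequency ≥ 5% and, for single-class
segments, HWE p > 0.05 (p ≤ 0.05 excludes). Multi-class segments are not
reducible to one biallelic genotype and skip the HWE screen; a reporting
variant that drops duplication carriers and tests the deletion allele is
available but not part of the filter.

## Disease activity and response

DAS28-ESR = 0.56·√TJC28 + 0.28·√SJC28 + 0.70·ln(ESR) + 0.014·GH with
tender/swollen 28-joint counts in 0–28, ESR ≥ 1 mm/h, and general health on
a 0–100 mm VAS (the 0.014 weight presumes the 0–100 scale).
CDAI = TJC28 + SJC28 + PtGA + PhGA with the global assessments on 0–10,
giving the documented 0–76 range. Both indexes are computed at baseline and
month 6; Δ = baseline − month 6 for both, so improvement is positive — the
only orientation under which a ΔCDAI range extending to ~+70 is reachable
on a 0–76 scale.

The EULAR class is a function of (ΔDAS28, attained month-6 DAS28): good iff
Δ > 1.2 and attained ≤ 3.2; no response iff Δ ≤ 0.6, or Δ ≤ 1.2 with
attained > 5.1; moderate otherwise. Boundary conventions (strict > 1.2 for
good, ≤ 0.6 for none, inclusive 3.2 and 5.1 on the attained axis) follow
the published decision matrix and are asserted cell by cell in the tests.
Responders are good + moderate. A patient missing either visit is skipped
with a logged warning and reported; duplicate visits are an error.

## Association model

Per segment, the predictor is the deletion-carrier indicator (CN ≤ 1), with
duplication carriers kept in the reference class — deletions are the
hypothesis and single duplication carriers tabulate with non-carriers. A
duplication-only segment has no deletion carriers, so the driver switches to
the duplication-carrier indicator there and records the coding used.

The logistic model regresses EULAR non-response (1 = "none") on the carrier
indicator plus baseline DAS28, BMI, sex, methotrexate use, blocker
indicators (reference etanercept, the most frequent blocker; indicators only
for categories observed in the cohort), and the first 5 genetic principal
components (configurable; PCs are consumed as provided covariates, never
computed). The linear model regresses ΔCDAI on the same covariates with
baseline CDAI in place of baseline DAS28. The ΔCDAI orientation is
configurable (default improvement = baseline − month 6); flipping it only
negates the coefficient.

**Inference.** The general-purpose fitter is Newton/IRLS maximum likelihood
with Wald z-tests, refitting with Firth's penalized likelihood when the fit
is quasi-separated. For the per-segment test the default is the sparse-cell
rule: when any cell of the carrier × outcome 2×2 table holds fewer than five
samples, the segment is fitted with Firth penalization outright, because
unpenalized Wald intervals are unreliable at such counts — at n = 357 with
~9% non-responders and ~5.6% carriers the expected carrier∩non-responder
cell is ~1.8, so penalization is the norm rather than the exception. With
this rule the per-segment test is well calibrated in simulation (empirical
type-I ≈ 0.04 at nominal 0.05 over 2,000 null segments; p-values
KS-consistent with uniformity over 500 null segments). Well-populated
tables and large-n fits use the plain MLE, whose covariate-free segment OR
reduces exactly to the contingency-table cross-product ratio.

Multiple testing is controlled per model by Benjamini–Hochberg step-up FDR
at q = 0.05 across all tested segments. Crude (unadjusted) odds ratios with
Woolf confidence intervals and the Haldane–Anscombe 0.5 correction for zero
cells are provided as a diagnostic, as is the SNP↔CNV tagging diagnostic:
squared Pearson correlation between SNP dosage and deletion dosage for SNPs
within 1 Mb, monomorphic SNPs reported as r² = 0 with a flag.

## Synthetic cohorts

The generator emulates the study conditions the pipeline is designed for:
357 patients, baseline DAS28 ~ N(6.24, 0.89) (clipped to [4.2, 9.2]),
~9% non-responders with the responder split ~36% good / ~64% moderate,
blockers at 72.8/16.8/5.3/5.0% (etanercept/adalimumab/golimumab/infliximab),
70% methotrexate use, 85% female, BMI ~ N(23, 3.2), and 5 standard-normal
genetic PCs.

**Outcome model.** Non-response is drawn from
logit P = logit(0.09) + ln(8.44)·carrier + centered covariate effects.
The covariate effects (BMI 0.03 per kg/m², sex 0.2, MTX −0.2, baseline
DAS28 0.1, blocker 0.10–0.15, PCs 0.05 per unit, all on the logit scale) are
small non-zero defaults whose only purpose is to exercise confounder
adjustment without dominating the planted effect; no empirical estimates of
them exist to emulate. Because generation and analysis share the same
linear-logistic form, the adjusted refit is consistent for the planted
log-OR — the large-n recovery check exploits exactly this.

**Causal locus.** The planted deletion occupies a 3.8-kb region on
chromosome 2 and is planted at the configured *realized* carrier fraction
(default 5.6%): round(n·f) carriers assigned by permutation, homozygous
deletions among carriers at the conditional HWE probability q/(2 − q) with
q = 1 − √(1 − f). The locus emulates a segment the study design ascertains
as common — a locus drawn i.i.d. Binomial would fall below its own ≥5%
carrier filter in a sizeable fraction of cohorts and the planted-effect
test would silently test nothing. Carriers receive a call at
CN = 2 − (allele count).

**Background CNVs and boundaries.** Background comes from two sources: a
deterministic panel (default 40 loci) of recurrent polymorphic CNV loci with
per-locus carrier frequencies U(0.05, 0.30), CN ∈ {0,1,3,4}, lognormal
lengths (median ~4 kb) placed length-proportionally on the autosomes; plus
per-sample Poisson(8) singleton CNVs placed uniformly. The panel supplies
the common null segments the FDR and calibration machinery needs; the
singletons supply realistic rare clutter. 40 loci is a deliberate
scale-down of the ~286 common segments of a full 2.5M-probe study, keeping
default runs fast while preserving every stage's behaviour. Neither source
overlaps the causal region by default, keeping planted-effect recovery
unconfounded. All boundaries are jittered per sample by
Normal(0, 250 bp) *quantized to whole probe-spacing steps* (default
800 bp) — array call boundaries can only fall on probes, which is why real
cohorts show only ~3% more segments than calls; unquantized jitter would
make every carrier's boundaries unique and explode the segment count.

**Clinical components.** Components are constructed to land on a target
DAS28: the target score is allocated across GH, ln(ESR), and the two joint
counts with random fractions, integer rounding of the joint counts is
compensated through the continuous ESR term, and the global assessments
track severity with noise. Month-6 targets are drawn inside the EULAR cell
of the drawn class with a small buffer from every boundary; the class
recomputed from the stored (rounded) components is verified to equal the
drawn label for every patient, with resampling on the rare mismatch. This
construction-plus-verification is cheaper and more robust than pure
rejection sampling from unconditioned component distributions. Resulting
baseline CDAI is ~N(32, 9) and corr(ΔDAS28, ΔCDAI) ≈ 0.80, consistent with
treated-RA cohorts.

**Reproducibility.** All randomness flows from `SimConfig.seed` through
fixed named substreams (genotypes, covariates, outcome, clinical, cnv,
loci, signal), so identical configurations are byte-identical and stages
can be regenerated independently. The package default seed is 2019.

**What the generator does not emulate.** No linkage disequilibrium between
the CNV and SNPs beyond the optional tagging diagnostic's inputs; no
haplotypes or pedigrees; no array batch effects, GC waves, or probe-level
intensity artifacts (the signal module draws directly from the caller's
emission model, so caller tests on synthetic signal check decoding, not
robustness to real-array noise); covariate effect sizes are invented.
Passing tests therefore demonstrate correctness of the algorithms and
calibration under the assumed generative model, not performance on real
array data.

## Problem sizes and statistical behaviour of the default run

Default end-to-end runs use n = 357, ~5,200–5,700 calls, ~3,000 segments
and ~45–70 common segments; the suite's calibration checks use 2,000 null
segments (20 cohorts × 100) and recovery checks use n = 10⁵. At the planted
conditions (OR 8.44, 5.6% carriers, n = 357) the adjusted test's power to
clear the 5% BH-FDR is high but not unity — 19 of 20 seeds flag the planted
locus; the honest sampling variability of a barely-genome-wide-significant
effect at this sample size. The linear ΔCDAI model is less powerful under
this generator (the carrier effect on ΔCDAI arises only through the
response-class pathway) and flags the locus in a minority of seeds.

## Known limitations

- The HMM is a simplified caller: fixed emission constants, no GC
  correction, no confidence scores; it is adequate for probe-quantized
  synthetic signal, not a PennCNV replacement on production array data.
- The exact HWE test assumes a biallelic CNV allele; multi-class segments
  are screened only by carrier frequency.
- Wald-type intervals are reported even for Firth fits; penalized-likelihood
  profile intervals are not implemented.
- The segment tests treat segments as independent in the FDR step, while
  boundary-split siblings of one region are strongly correlated —
  Benjamini–Hochberg remains valid under that positive dependence but is
  conservative.
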