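# Methods

`strqc` post-processes short-tandem-repeat (STR) genotype calls from
short-read sequencing and tests STR–disease associations. This note records
the models, the parameters that matter, the numerical choices, what the
synthetic-data generator does and does not emulate, and the design decisions
taken where the design was genuinely open.

## Read consistency

An STR genotype is a pair of allele sizes (one for hemizygous X-linked male
calls), in repeat units. Reads are classified against the called genotype:

- a **spanning** read covers the whole repeat and pins a size exactly, so it
  is consistent iff its size equals one of the alleles;
- **flanking** and **in-repeat** reads only lower-bound the size, so they are
  consistent iff their size does not exceed the longest allele.

Counts are attributed per allele: a consistent read adds its count to every
allele it is individually consistent with (spanning: equality; bounded types:
less-or-equal), and a non-consistent read counts against both alleles. The
paper-style rule does not specify the dual-consistency case; counting a read
for both alleles is deterministic and conservative, since it can only raise
the consistent-read fraction.

## Quality parameters and flags

Per allele, with allelic depth defined as the total reads attributed to the
allele (the only per-allele depth derivable from the genotyper output):

| parameter | formula | range |
|---|---|---|
| Q_depth | min(d_a, d̄)/max(d_a, d̄) | [0, 1] |
| Q_ci | exp(−4·(CI width)/size) | (0, 1] |
| Q_con | consistent/total | [0, 1] |
| Q_non | exp(−4·non-consistent/total) | (0, 1] |

"Confidence interval" in Q_ci is read as the CI **width** (high − low): only a
width makes sense as a ratio to the size. Degenerate inputs: size 0 gives
Q_ci = 1 if the width is 0 and 0 otherwise (the width-dominated limit);
an allele with zero attributed reads gets Q_con = 0 and is marked
*unsupported* — such calls carry no evidence and are always routed to the
failure path. The exponential form makes both penalty parameters strictly
decreasing and bounded, so they can enter a linear predictor without
transformation.

Seven binary flags mark suspect calls: (i) flanking-read support,
(ii) both alleles in-repeat-supported, (iii) fragment-length-limited —
operationalized as size × motif length ≥ fragment length − motif length,
since reported sizes saturate one motif short of the fragment; (iv) allelic
depth more than 5× above or below the sample average; (v) CI width greater
than the size; (vi) exactly one consistent read (J1C); (vii) fewer consistent
than non-consistent reads (LCTNC). The support type of an allele is inferred
(the genotyper does not report it): spanning if a spanning read matches the
size exactly, in-repeat if the allele is at least as long as the read length
and in-repeat reads exist, flanking otherwise.

## Genotyping-failure model

A *failure* is a call whose true size falls outside the reported confidence
interval — the adjudication a human reviewer makes from read-alignment
images. Labels come from a stratified inspection manifest per locus: up to 10
random alleles per binary flag, the 25 largest calls, the 10 smallest, and
10 random calls from each of repeat-size quintiles 2–4 (deterministic given a
seed; strata smaller than their quota are taken whole).

Training uses a temporal split on sequencing date (default cutoff
2018-01-01, ISO dates compared lexicographically; samples with no date go to
training so they can never leak into evaluation). One logistic GLM per read
type — spanning alleles use Q_depth, Q_ci, Q_non; flanking and in-repeat
alleles use Q_ci, Q_con, Q_non — with fail coded 1. Zero-variance features
are dropped from the optimization and reported with zero slope, so a fully
constant design degenerates to intercept = logit(fail rate). A read type
whose labels are single-class cannot support its own GLM; it reuses a fitted
model with the same feature set (flanking ↔ in-repeat) or, if every label is
`fail`, a constant always-fail model.

The probability cutoff is the **largest** predicted probability at which the
captured fraction of labelled training failures is at least the target
sensitivity (default 0.90): concretely, the k-th largest fail score with
k = ⌈target · n_fail⌉, searched over the finite set of predicted
probabilities. Predicted failures are set to missing before any association
analysis; unsupported alleles fail unconditionally.

Locus exclusion: a locus leaves the study if its predicted failure frequency
over all alleles exceeds 5%, or if observed failures among inspected alleles
significantly exceed the model's expectation. The expected count is the sum
of predicted probabilities over inspected alleles; the test is a 1-df
goodness of fit on the fail/pass totals, Bonferroni-corrected over the loci
in the run, and fires only in the observed > expected direction (the
two-sided statistic would also flag loci the model *over*-predicts, which is
not a reason to distrust their genotypes). Observed-vs-expected is computed
only over alleles whose read type has a fitted model.

## Association analyses

Three views per locus, for three outcomes. All models adjust for sex,
country (fixed-effect indicators, first level as reference; constant columns
are dropped with a warning) and 10 ancestry principal components.

- **Susceptibility** — Firth bias-reduced logistic regression. Carrier
  counts at pathogenic thresholds are tiny and often separated (e.g. zero
  expanded controls); the Jeffreys-prior penalty ℓ(β) + ½ log det I(β)
  keeps estimates finite. Inference is Wald (deterministic and cheap;
  profile-penalized intervals are a documented possible extension).
- **Survival** — Cox proportional hazards on months from onset, with death
  as the event and Efron tie handling; proportionality is checkable via
  scaled Schoenfeld residuals against event-time rank.
- **Age at onset** — ordinary least squares with t inference.

Progression analyses first filter the cases: onset below 18 years, invalid
or incomplete survival records, and whole countries in which fewer than 30%
of cases are deceased (a signature of systematic misdiagnosis) are removed.
Thresholds with fewer than five observations in either carrier category are
not tested for survival or onset.

**Literature thresholds.** Carrier coding honours the inheritance mode:
dominant (AD) needs one allele in range; recessive (AR) needs both; X-linked
recessive (XR) needs the single hemizygous allele in males and both alleles
in females. A sample whose determination depends on a failure-missing allele
is coded missing. Premutation ranges are [premutation, pathogenic);
samples carrying a pathogenic allele are excluded from premutation carriers
so the two categories stay disjoint. Fragment-length-limited alleles are
treated as at least pathogenic-sized (their true length exceeds the cap); a
switch disables this. Bonferroni spans the (locus × threshold) tests per
outcome. A sensitivity mode recodes every locus as AD.

**Best-threshold scan.** Every observed allele size t is a candidate; the
predictor is the additive allelic dosage (number of non-missing alleles ≥ t:
0/1/2, 0/1 hemizygous). Correction order: BH-FDR across thresholds within a
locus, then Bonferroni across loci. The per-locus best is the minimum
corrected p, ties resolved toward the smaller raw p and then the smaller
threshold. Susceptibility significance is read at corrected p < 0.05;
survival and onset at p < 0.01, because the Cox and linear fits are
sensitive to extreme repeat sizes.

**Distribution analysis.** Max and sum of the allele sizes per sample (sum
requires every called allele observed; for hemizygous genotypes it equals
the single allele). Susceptibility uses a plain binomial GLM of status on
the size statistic (the Firth penalty is unnecessary for a continuous
predictor); survival and onset as above. The log transform is
log(1 + size), admitting zero-size alleles.

**External panel comparison.** Carrier frequencies of an internal control
panel versus an external reference panel, Firth logistic regression of panel
membership on carrier status adjusting for sex, Bonferroni over the
(locus × threshold) tests.

**Motif changes.** Per-motif in-repeat read counts restricted to regions
overlapping catalog loci; motifs of a single repeated nucleotide are
excluded as artefacts. Firth regression of case status on read count with
the standard covariates, Bonferroni over motifs; samples without a record
count zero.

## Synthetic cohorts

The generator produces what the analyses assume, with the ground truth
recorded beside it.

*Genotypes.* Allele sizes are a mixture of a common-size core (a rounded,
clipped normal) and a geometric expansion tail starting at the locus
threshold and capped at the fragment length in repeat units. The default
panel mirrors a large ALS case-control study: a GGCCCC locus with wild-type
alleles of at most ~11 units, 0.47% control carriers at ≥30 units and a
planted carrier OR of 16, HR of 1.51, and 2.4-year earlier onset; a CAG
locus with a planted OR of 3.0 from 29 units; a recessive AAGGG locus and an
X-linked CAG locus with no planted effects. Cohort defaults are 5237 cases
and 1746 controls, 150 bp reads, 450 bp fragments, ~35× depth, and
sequencing dates drawn 81%/19% around 2018-01-01.

*Status.* Case/control sampling is retrospective: given a control carrier
frequency f0 and planted OR, the case frequency is
f1/(1−f1) = OR · f0/(1−f0); per-allele expansion probabilities are derived
so per-sample carrier frequencies hit these targets. Under case-control
sampling the planted OR is exactly the estimand of the logistic analysis
model, with no rejection loop that could stall at extreme ORs.

*Survival and onset.* Case survival is exponential with hazard
(ln 2 / 30 months) · HR^carrier, administratively censored
Uniform(6, 120 months), event = death before censoring (~70% deceased under
the defaults). Onset is Normal(61, 12²) years plus the planted carrier
shift.

*Reads.* Spanning reads are generated at the true size for alleles short
enough to span (Poisson, ~half the sample depth); longer alleles get
flanking reads bounded by the size and in-repeat reads once size × motif ≥
read length. Clean calls carry mild noise — occasional CI widening and
sporadic stray reads — so quality is a gradient rather than a step.

*Planted failures.* A failed allele's reported size overshoots its true size
by max(3, 0.6·size) with a realistically wide CI that still excludes the
truth, so the ground-truth fail label coincides exactly with the
out-of-CI definition the inspection labels use. Four modes add the
characteristic read-level signature: excess non-consistent reads, an
oversized CI, a depth imbalance, and unsupported calls with no attributable
reads; half of the excess/depth failures also get a misaligned read pile at
the wrong reported size, which makes them spanning-called so every read-type
model sees failures. Inspection labels equal the ground truth, optionally
with symmetric label noise.

*What is not emulated:* alignment-level artefacts (the dominant failure mode
of real loci with degenerate motifs), motif interruptions and mosaicism,
linkage between loci, ancestry structure in the PCs (independent standard
normals by default), and population stratification confounding. Passing
tests therefore demonstrate that the statistical machinery recovers planted
truth under the stated noise models — not that the failure predictor would
reach the same operating characteristics on real read alignments.

## Numerical choices

- Firth: Newton iterations on the modified score with step-halving; the
  halving acceptance tolerance (10⁻¹³ relative) sits below the cycle
  amplitude of an overshooting Newton step but above floating-point noise,
  which is what prevents a two-point limit cycle near the optimum.
  Convergence at max |score| < 10⁻⁹, cap 100 iterations; rank-deficient
  designs are rejected with the collinear columns named.
- Cox fits run to a partial-likelihood precision of 10⁻¹⁰ so small-sample
  estimates agree with direct maximization to ~10⁻⁴; zero events and
  non-positive times are rejected; monotone likelihoods surface as a
  convergence error naming the usual cause.
- Exact-tie handling in the cutoff search uses ≥ comparisons on the finite
  score set, which breaks ties toward higher sensitivity.
- The acceptance script and test suite run simulations at reduced sizes
  (e.g. 2000-sample QC cohorts, 10,000 alleles per locus for the exclusion
  boundary, 100–500 replicates for recovery and error-rate studies), chosen
  so the expected behaviour is several binomial standard deviations away
  from the pass/fail boundaries.

## Known limitations

Wald inference everywhere (no profile-penalized CIs for Firth, no robust
variances); no BAM/CRAM-level re-genotyping or realignment; the support-type
inference rule is a reconstruction, since genotyper output does not state
which read type determined an allele; premutation carrier counting excludes
pathogenic-allele carriers by design, which is one of several defensible
conventions; flexible parametric (spline) survival models are out of scope.
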