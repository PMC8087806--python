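# Methods

## The measurement model

The target is a short editing island: a ~225-bp intronic region in which
ADAR enzymes deaminate several adenosines on the same transcript. Targeted
amplicon sequencing reads the whole island on every read, so the data
support two levels of description:

* the **site level** — for each reference A position, the percentage of
  reads carrying G, computed as `G / (G + A) × 100`. Reads with C, T or N
  at the position are excluded from numerator and denominator alike; a
  position with `A + G = 0` is reported missing, never as 0 %.
* the **molecule level** — each read is classified by the set of called
  sites at which it carries G (its co-editing pattern, called an "isoform"
  here); `NonEdited` is the empty set. Relative proportions are percentages
  of classified reads and sum to 100 before any threshold. By construction
  a site's level equals the sum of proportions of all patterns containing
  it; this identity is asserted throughout the test suite.

Site calling uses a strict threshold: a candidate A position is a site when
its G-percentage exceeds 0.1 % (a value at exactly 0.1 % does not pass).
Patterns below a 0.1 % relative proportion are flagged below-threshold but
retained in output tables; positions whose signal stays under ~0.05 % are
indistinguishable from sequencing error at realistic error rates and are
annotated accordingly.

Alignment is anchored and ungapped: every read covers the full amplicon at
offset 0, and a read is accepted when its Hamming distance to the reference
*outside* candidate positions is ≤ 5 (configurable). Candidate positions
never count as mismatches, so heavily edited molecules are not penalised.
There is no quality trimming (simulated qualities are constant Q37); a
pass-through hook exists for real data. The amplicon is defined on the
sense strand and editing is observed as A→G only.

### Ambiguities resolved

Two behaviours are not fixed by the measurement definition and are exposed
as options, with these defaults:

* **Feature space across a cohort**: the analysis site set is defined by
  applying the 0.1 % threshold to the *control-group mean* site levels, so
  every sample shares one feature space; per-sample pass flags are also
  reported.
* **Replicate aggregation**: the five technical replicates per sample are
  combined as the unweighted mean of proportions, not by pooling reads —
  replicates are independent library preparations and pooling would weight
  them by depth. Averaging reduces the whole-profile error (standardised
  Euclidean distance to truth) below that of every individual replicate in
  ≳ 80 % of simulated samples; this is verified by a Monte-Carlo test.
  (For a single scalar site the mean beats a given replicate only ~75 % of
  the time — the variance-reduction claim is a statement about the whole
  profile.)
* Reads carrying C/T/N at any *called* site are excluded from pattern
  classification (and counted), keeping the molecule-level denominator
  consistent with the site-level formula.

## The synthetic cohort generator

The generator emulates the study design the analysis assumes: three groups
(healthy controls, depressed non-attempters DEP, suicide attempters SA),
five technical replicates per subject, deep amplicon sequencing per
replicate, and two correlated clinician severity scales.

* **Control pattern table** (shipped default): `NonEdited` 80 %, `{B}`
  18.4 %, `{B,C}` 0.6 %, `{B,E}` 0.45 %, `{B,F}` 0.3 %, `{B,D}` 0.25 %.
  Implied site levels: B = 20 %, C–F between 0.2 and 0.6 %; the other nine
  candidate positions are unedited in truth, so their observed signal comes
  only from the error rate. Every multi-site pattern contains the dominant
  site B.
* **Group effects**: the mass of every edited pattern is multiplied by 0.7
  (DEP) and 0.6 (SA), the freed mass moving to `NonEdited` — decreases in
  editing are mirrored by a rise of the fully unedited molecule. The
  magnitudes are configurable; only direction and ordering are treated as
  fixed features of the design.
* **Subject variability** has two components. A shared per-subject
  *editing propensity* factor (log-normal, mean 1, σ = 0.12) multiplies all
  edited-pattern mass: editing across an island is co-regulated by the same
  enzymatic activity, and this shared factor is what makes *all* pairwise
  site levels positively correlated across subjects. A Dirichlet draw
  around the propensity-scaled group mean (concentration 30,000) adds
  residual per-pattern variability. A pure Dirichlet cannot serve alone:
  its components are negatively correlated, which would push minor-site
  pairs to r ≈ 0 or below, contradicting the strongly positive inter-site
  correlations the analysis is meant to exhibit. With these defaults the
  subject-level SD of site B is ≈ 2.4 percentage points (CV ≈ 12 %).
* **Reads**: each replicate is an independent multinomial draw over the
  subject's pattern table, followed by independent per-base substitution
  error (default 4 × 10⁻⁴, uniform over the three alternative bases). Reads
  are full-length with constant Q37 qualities; no indels, PCR duplicates or
  chimeras are modelled. FASTQ output is byte-identical for identical
  seeds (gzip header timestamp and name are pinned).
* **Severity scores**: bivariate normal per group (defaults match the
  study cohort's group means/SDs), with correlation √0.90 between MADRS
  and IDS-C30, rounded to integers and clipped at 0. Controls score near
  zero. Across patients the empirical squared correlation averages ≈ 0.88
  over seeds — the clip-and-round step attenuates the 0.90 target slightly,
  within the tolerance the tests assert.
* **Depth**: the number of reads per replicate is a free design parameter
  (default 10,000), chosen so that the 0.1 % detection threshold is well
  resolved after replicate aggregation (≥ 50,000 informative reads per
  sample).

Because the generator is an idealisation, passing tests demonstrate
correctness of the *pipeline* under the stated model, not properties of
real blood data: real amplicon data add quality heterogeneity, indels, PCR
artefacts, SNP/editing confusion and batch effects that are out of scope
here.

## Statistics

Group comparisons report both the Wilcoxon rank-sum test (exact enumeration
for small untied samples, tie-corrected normal approximation otherwise) and
Welch's *t* (Satterthwaite df; also computable from summary statistics).
Benjamini–Hochberg adjustment is applied per comparison across its feature
family, separately for each test; the significance flag uses the adjusted
rank-sum p at 0.05, as the minor-pattern proportions are strongly skewed.
Degenerate inputs are defined rather than fatal: constant pooled data give
p = 1 with a warning (rank-sum), and two zero-variance groups give t = 0,
p = 1 when their means agree (|t| = ∞, p = 0 otherwise) — rare patterns can
be absent from one group and must not abort a cohort table.

Severity binning takes MADRS precedence (IDS-C30 only when MADRS is
missing), resolving the contradictory "and/or" joint definition
deterministically. The analysis-set filter keeps patients with MADRS ≥ 20
or IDS-C30 ≥ 24 — inclusive boundaries, consistent with the moderate bin
starting at 20/24 and with the published analysis group sizes
(82 DEP + 76 SA = 158) given the printed severity breakdowns.

## Classifier

A bagged decision-tree ensemble (scikit-learn `RandomForestClassifier`,
1000 trees, 2 candidate features per split) discriminates SA from Ctrl.
The split is stratified at 2/3 (per-class round-half-up, largest class
adjusted to preserve the total); feature selection (BH-adjusted p < 0.05,
SA vs Ctrl) runs on the training subjects only, so test labels cannot leak
into the model — a property the suite checks by verifying that pure-noise
features cannot lift the held-out AUC above chance. Evaluation reports the
test-set ROC, trapezoid AUC, a 95 % CI from a stratified bootstrap (2000
resamples), and sensitivity/specificity at the maximum-Youden operating
point (a fixed-specificity mode is also provided, since a published
operating point's threshold rule is generally unknown). `mtry` is clamped
to the number of selected features when fewer than `mtry` survive
selection; an optional stratified 10-fold CV grid search tunes it.

The stratified 2/3 rule gives 117/58 for a 99 + 76 cohort; published split
sizes of 125/50 for a 175-subject cohort are not reachable by any exact
stratified 2/3 split, so the fraction is configurable and the rounding rule
documented.

## Problem sizes in tests

Monte-Carlo tests and the end-to-end check run at reduced scale, chosen as
the package's own trade-off between statistical resolution and runtime:
null-calibration runs use 150–1000 repetitions; the end-to-end
discrimination check uses 45 Ctrl + 40 SA subjects at 5 × 2,000 reads over
10 seeds (held-out AUC ≥ 0.985 on every seed under the shipped effect);
parameter-recovery runs use 5 × 50,000 reads. The acceptance script uses
the full 5 × 50,000-read design.

## Known limitations

* The shipped amplicon sequence is a synthetic stand-in; only the labelled
  A positions matter downstream.
* No SNP/editing disambiguation (no genomic DNA track exists in the
  design), no hyper-editing detection, no genome-scale alignment.
* The generator's group effects and dispersion are stylised: they
  reproduce directions, orderings and correlation structure, not exact
  published effect sizes, so classifier performance on synthetic cohorts
  is an upper bound relative to real data.
* Treatment, inflammation and substance-use covariates exist only as inert
  metadata; no covariate adjustment is implemented.
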