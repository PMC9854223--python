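# Methods

This note records the models, conventions and design choices behind
`radiomethyl`, in the spirit of a statistical-software methods appendix:
what is computed, under which assumptions, and what the synthetic
benchmarks do and do not demonstrate.

## Restriction-signature methylation calling

A CCCGGG (SmaI) site carries one CpG. SmaI cuts only unmethylated sites,
bluntly, between the C and G triplets; XmaI cuts regardless of
methylation, leaving a 4-base 5' overhang. After sequential digestion a
sequencing read starting at a cut therefore begins `GGG` (blunt, site
was unmethylated) or `CCGGG` (sticky, site was methylated). The
classifier is exactly this prefix rule; anything else is `invalid` and
retained in the QC table. The methylation fraction of a (site, sample)
pair is `n_meth / (n_meth + n_unmeth)`, defined only at a minimum
classified depth (`min_depth`, default 20 reads — the standard error of
a fraction at that depth is at most ~0.11). Reads carry provenance site
ids in the synthetic setting; without provenance they are resolved by
exact match of the sequence 3' of the signature against the site
catalog, because read mapping proper is out of scope. Reads resolving to
no site are counted as unmapped, never dropped silently.

**Differential filter.** Group means of per-sample fractions are
compared per site; a site passes when |Δ| > 5 percentage points AND
p < 0.1. The significance test is configurable because the historical
analyses of this kind do not state one: the default is a two-sided
pooled-variance t on per-sample fractions (the design has biological
replicates, 8 per group); Fisher's exact test on group-pooled counts is
the alternative. Sites with fewer than two defined fractions in a group
are reported as untested. Sites whose cut position falls in a repeat
interval (LINE/Alu stand-ins) are excluded before testing.

## CpG islands and promoter windows

Islands use the classical compositional definition: GC fraction
(N bases excluded from numerator and denominator) and
observed/expected CpG ratio `#CpG × L / (#C × #G)` both strictly above
0.6 over 200-bp windows. The detected islands are the merged union of
all qualifying windows scanned at single-base steps; the implementation
uses prefix sums and is property-tested against a brute-force
per-window string-counting oracle. All three thresholds are
configuration keys, not constants. Note the two published phrasings of
"a region all of whose windows qualify" versus "the union of qualifying
windows" differ when a single failing window separates two overlapping
runs; this package implements the union-merge semantics.

Promoter distances are signed along the direction of transcription
(negative = upstream), and the ±1000 bp window is inclusive at the
boundary. The narrowing step keeps a passing differential tag when its
cut-site start coordinate lies inside an island AND within the window
of some TSS (conjunction; a disjunction variant is available by flag
since the published criterion is not fully explicit). A site near
several TSSs yields one annotated row per gene.

## Marker evaluation

A gene's methylation in one assay is the arithmetic mean over its
pyrosequenced CpG positions. The positivity rule keeps a gene only when
its specimen-class mean exceeds 5% (strict) in every class; per-specimen
strictness is available by option since "all tested" could mean either.
Genes with missing cells are reported non-evaluable rather than
silently dropped. Tissue contrasts use the paired t test (same-donor
non-plaque vs plaque intima) and one-way ANOVA (≥3 specimen classes);
an exactly constant paired shift has divergent t and is reported with
undefined p rather than a fabricated value.

## Cohort statistics

Continuous variables: two-sided independent Student's t with pooled
variance (the named test of such risk-factor tables); Welch is a
toggle. The summary-statistics variant computes the identical quantity
from (n, mean, SD) triples, which allows re-checking published
mean ± SD rows; a property test asserts raw/summary equivalence on
random vectors. Categorical risk factors: Pearson chi-square without
continuity correction (togglable), appropriate at these margins. No
multiple-testing correction is applied across the table — deliberately
mirroring how such univariate tables are conventionally reported.

Re-computing the reference MTNR1B row (n=50: 25.4 ± 8.7 vs n=334:
22.7 ± 6.7) from the printed summaries gives p = 0.0112 by pooled t,
whereas the published table prints 0.009; rounding of the printed means
and SDs plausibly explains the gap, and the package documents rather
than "fixes" it.

## Risk model

Maximum-likelihood logistic regression (statsmodels Newton, relative
tolerance 1e-8, 100 iterations; BFGS fallback when the Hessian goes
singular on badly scaled designs — the Wald covariance always comes
from the analytic Hessian at the optimum). Zero-variance predictors are
dropped; complete separation is detected (optimizer warning or runaway
coefficients beyond |β| = 50) and flagged instead of returning
divergent estimates as if they were fine.

**Selection.** Backward elimination on Wald p: repeatedly drop the
largest-p variable until all retained p < 0.1 (threshold chosen so that
borderline variables around p ≈ 0.09 survive, matching how such models
are reported); exact ties drop the later-listed variable. Forward and
keep-all modes exist. An SPSS-style likelihood-ratio elimination was
prototyped and not adopted (no measurable benefit at 4× cost).

**Split and cross-validation.** Stratified 70/30 split; stratified
fivefold CV on the training part re-runs selection per fold; the final
model is selected and refit on the full training part and evaluated
exactly once on the untouched 30%. Everything derives from one seed.

**Importance.** A variable's raw importance is its mean |Wald z| across
the five fold models, counting 0 in folds that eliminated it, linearly
rescaled so the top score is 100. This deliberately blends effect
strength with selection stability: a variable that is occasionally
significant but usually eliminated scores low. The alternative
(mean |z| over full-candidate fold fits, no selection) is available by
calling `importance_scores` on keep-all fold models.

**Metrics.** The class conventions are hard-coded into field names to
prevent silent swaps: *sensitivity* is the correct-classification rate
of the minority no-stenosis class, *specificity* that of the majority
stenosis class; accuracy is their prevalence-weighted mean (asserted as
an identity in tests). AUC is the rank (Mann–Whitney) formulation with
midranks for ties, stenosis as the positive direction; a constant score
gives 0.5. Classification threshold 0.5 by default, configurable.

## The synthetic-data generator

The generator defines the study conditions; its defaults are not tuned.

*Genome*: AT-rich background (GC ≈ 0.40) with planted CCCGGG sites,
CpG-rich island blocks (~45% CG dinucleotide content, so every 200-bp
window clears both 0.6 thresholds), tandem-repeat intervals, and TSSs
placed half near sites (within 1 kb) and half isolated (≥2 kb away,
sampled exactly from the complement of site neighbourhoods), so
promoter annotation always has positive and negative cases. Feasibility
is checked; infeasible packings raise.

*Reads*: per (site, sample), `depth` reads are emitted, each methylated
with probability equal to the planted fraction, symmetric signature
flips at `error_rate`. Depth is a free parameter (no canonical value
exists for this assay family); benchmarks use 1000×, at which the
binomial standard error of a fraction is ≤ 0.016.

*Cohort*: one record per patient from group-wise marginal descriptors —
normal draws clipped at a lower bound for most labs; moment-matched
lognormal for the canonically right-skewed ones (CRP, lipoprotein (a),
triglycerides), because a normal marginal with a 4.5× SD ratio between
groups puts the group tails on disjoint support and makes single labs
implausibly diagnostic; Bernoulli for yes/no factors. A Gaussian copula
supplies the joint structure; binary variables join it through latent
thresholding, which preserves their marginal prevalence exactly. The
default reference cohort (50 no-stenosis vs 334 stenosis) encodes
standard clinical clusters: the lipid panel (TC–LDL 0.9, HDL–ApoA 0.8,
LDL–ApoB 0.85, …), the glycemic panel including diabetes status, the
two stroke-severity scores, age–creatinine–hypertension comorbidity,
WBC–CRP inflammation, male–smoking, and an age-related methylation
drift of r = 0.30 between age and each marker gene (markers mutually
0.15). The drift term matters: it creates the suppression structure in
which age-adjusted MTNR1B hypomethylation is a stronger predictor than
its raw group difference — the defining phenomenon of this analysis.
Stroke-severity scores and stenosis counts are generated for the cohort
table but never offered to the model (severity is a consequence of the
event, and the counts define the label).

*What passing benchmarks do and do not show.* The synthetic cohort
reproduces marginal summaries and a plausible correlation skeleton; it
does not model measurement error, missingness, batch effects, cellular
heterogeneity of the buffy coat, or non-Gaussian dependence. Recovery
and power results therefore certify the pipeline's correctness, not
field performance on real patients. In particular, the importance rank
of MTNR1B under these conditions is variable: with the encoded effect
size (≈0.4 SD) its expected multivariable |z| ≈ 2.6 sits fifth to
sixth among 28 candidates behind age, hypertension, diabetes and
lipoprotein (a), and it reaches the top four in roughly a third of
seeds rather than a majority — the acceptance benchmark reports the
measured fraction.

## Numerical conventions

Coordinates are 0-based half-open everywhere in memory and in BED;
1-based only in rendered text. One TSV dialect (tab, UTF-8, header,
"." for missing) and fixed float formatting make artifacts
byte-reproducible; `run_all` writes a manifest of SHA-256 hashes and
re-running with the same config and seed reproduces every hash. One
master seed is split into per-component streams via
`SeedSequence([seed, k])` with fixed k per component. Degenerate inputs
(all-N windows, zero-variance groups, empty candidate sets, missing
classes) return explicitly undefined results or raise named errors —
never silent NaN propagation.

Benchmark problem sizes (100 replicate seeds at 20 sites × 16 samples ×
depth 1000; 20 cohort seeds for the model benchmarks; 100 refits for CI
coverage) were chosen to keep the full validation run to a couple of
minutes on a single CPU while leaving Monte-Carlo error well below the
margins being tested.
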