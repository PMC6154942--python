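# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the limits of what the package's tests demonstrate.

## Diagnosis and cohort summary

MetS is diagnosed from five components (central obesity, elevated blood
pressure, elevated triglycerides, low HDL, elevated fasting glucose) with
inclusive upper thresholds and a strict lower HDL threshold
(waist ≥ 90/85 cm by gender, SBP ≥ 130 or DBP ≥ 85 mmHg, TG ≥ 1.7 mmol/L,
HDL < 1.04 mmol/L, FBG ≥ 6.1 mmol/L). Epidemiological sources differ on the
combining rule; we adopt the harmonised "any 3 of 5" criterion and expose it
as `min_components`. Survey-style summaries report counts with one-decimal
percentages, rounded half away from zero; group comparisons use Welch's
(unequal-variance) t for age and Pearson chi-square without continuity
correction for the binary components — at survey sample sizes the Yates
correction is needlessly conservative, but a flag provides it.

## Core statistics

Wilcoxon rank-sum, chi-square, Spearman and Benjamini–Hochberg are
implemented in-package so their tie handling and small-sample behaviour are
fully specified; scipy/statsmodels appear in the test suite only as
independent oracles. The rank-sum test uses midranks; for a combined sample
size up to 25 the exact two-sided p-value is computed by a dynamic programme
over the (doubled, hence integer) midranks — equivalent to enumerating all
C(N, n₁) group assignments — and beyond that a normal approximation with tie
and continuity corrections. Two-sided exact p is twice the smaller tail,
capped at one. Spearman is the Pearson correlation of midranks with a
t-approximation p-value. BH is the standard step-up; q-values are clipped to
q ≥ p to guard against floating-point inversion at ties.

## Diversity

Shannon entropy defaults to base 2 and Faith's PD includes the stem path
from the subtree to the root, matching the classic QIIME-1 toolchain whose
outputs this analysis style grew from; a `base` switch gives nats.
Rarefaction subsamples without replacement via the multivariate
hypergeometric distribution; samples below depth are dropped and reported,
never padded. Bray–Curtis comes from scipy's `pdist`. PD is computed by
accumulating, for each observed tip, the not-yet-visited ancestor edges;
the final sum runs in a fixed tree-traversal order so results are
bit-reproducible (summing over an unordered set is not).

## PERMANOVA and the saturation procedure

The pseudo-F uses the standard among/within partition of squared distances;
permutations are evaluated in vectorised batches via the quadratic form
1_g'D²1_g, which makes the 2000-replication null calibration run in
seconds. The p-value uses the +1 correction so it is bounded below by
1/(n_perm+1); the default is 999 permutations and α = 0.05. The saturation
procedure subsamples *stratified by group* — the group ratio is preserved
and degenerate draws are impossible by construction (the proportional
targets are settled to the exact subsample size with a bounded adjustment
loop, erroring only if a group cannot keep ≥ 2 members). Distances are
computed once and sliced per subsample; for Bray–Curtis the two orders of
operation are identical.

## Association engine

The design matrix per factor is: intercept, the standardised factor, then
confounders (age and Bristol standardised, gender as a dummy, region as
dummy-coded fixed effects). Diagnostic factors enter as their binary
component flags (standardised), matching how survey tables present them;
continuous modelling is available by passing custom factor columns.
Aliased covariates are dropped with a warning (rank check via QR-free
column elimination); a factor is skipped entirely when n < 10 + #covariates.
Because the design matrix is shared by all OTUs within a factor, the OLS
coefficients, standard errors and two-sided t-tests for every OTU are
computed in one batched linear solve — this is what keeps the
1000-OTU × 9-factor scenario at well under a second, where per-OTU model
objects would take minutes. The batched fit is validated in the tests
against statsmodels OLS coefficient by coefficient.

The optional `selection="boosted"` screen runs 100 rounds of componentwise
least-squares boosting (step 0.1) per OTU and drops covariates never
selected; the default is `selection="none"` because the confounder set here
is small and deliberately forced — dropping a known confounder because a
greedy screen ignored it is exactly the failure mode confounder adjustment
exists to prevent. BH families are per factor across OTUs (each factor its
own multiple-testing family); a `bh_family="global"` switch pools all pairs.

Directional bookkeeping counts significant records by modelled sign per
factor; aggregate totals and per-taxon counts flip the HDL sign (low HDL is
the disorder, so a positive HDL association is protective). Records missing
taxonomy are counted under "Unassigned".

## MetS index

w_i = sign(β)·|β|·(−log₁₀ q), summed over the significant factors of an OTU
after the HDL flip; I_s = Σ r_si·w_i, z-standardised. The weighting is one
defensible reading of "abundance weighted by coefficient and significance";
it is isolated in `MetsIndexScorer` with `weight_mode` alternatives
(`beta`, `logq`) precisely because the choice is not canonical.
Standardisation makes the index scale-free (doubling all weights changes
nothing) and lets quartile cut-offs be cohort-relative.

## Risk stratification

Quartiles cut at the 25/50/75 empirical percentiles with midpoint
interpolation; ties go to the lower quartile; a constant vector is a
degenerate-input error. The 16-cell grid reports n, MetS count and
prevalence per cell, all 120 pairwise 2×2 chi-squares with BH, and
per-spending-level occupancy grids. Cell marginals reproduce the single-axis
quartile prevalences exactly by construction.

## Synthetic cohort generator

The generator is the package's study bench; its defaults are the study
conditions, fixed once.

*Cohort.* A latent metabolic risk score (standard normal) loads on
standardised age (0.25), sedentary time (0.25) and log spending (0.15);
each diagnostic is sqrt(0.30)·risk + independent noise (SBP/DBP share an
extra 0.25 of variance), with means back-solved so each component's
exceedance rate matches survey-typical values per gender. The 0.30 shared
loading was calibrated once so the realised MetS rate sits near 20% at
large n (measured 20.2–20.5%). Economics are log-normal with spending
tertile-like groups in proportions 0.251/0.513/0.236; sedentary time
correlates with spending at 0.3 (Gaussian copula), vegetables and fruit at
+0.25, grain at −0.25, meat uncoupled; smoking is male-dominated and
decreases with spending. Zero SDs are allowed (degenerate but valid, e.g.
an all-healthy fixed cohort); negative SDs are config errors.

*OTU counts.* Baseline log-abundances are N(0, 2.0) over the community;
counts are Dirichlet-multinomial with precision 100 at depth 10,000, which
reproduces realistic zero-inflation: at full community scale
(17,083 OTUs) roughly 850–900 OTUs survive a 10% prevalence filter.
Planted effects shift log-composition by `effect` per SD of the
standardised factor. Crucially, when the planted set contains both enriched
and depleted taxa, the shift *redistributes abundance within the planted set
at fixed per-sample share*: enriched taxa grow at the expense of depleted
ones and non-planted OTUs remain exactly null in relative abundance. Plain
softmax renormalisation instead leaks the compositional complement into
every null OTU — measured at ~0.50 empirical FDR at survey scale, which is
real compositional behaviour but makes "null taxon" ground truth
meaningless. A one-sided planted set has no within-set counterweight and
falls back to whole-community renormalisation. Confounder effects (age,
gender, Bristol: ±0.15 on a random 20% of OTUs; region: N(0, 0.15) offsets)
apply community-wide; they are functions of modelled covariates, so linear
adjustment removes their closure leak. Planted OTUs get baselines floored
at the community's 55th→85th percentile (they must be detectable at all),
and disorder-positive OTUs get an extra baseline boost (default 0.75 log
units) so dysbiosis concentrates abundance — the mechanism that makes
Shannon and PD lower in MetS subjects. Directions are assigned by family
priors (e.g. Ruminococcaceae and Bacteroidetes families negative,
Lachnospiraceae and Proteobacteria families positive) with 90% consistency,
emulating phylogenetic conservation of the association signal. An optional
spending leak moves each planted OTU along its disorder profile
(scaled to one effective factor channel) per SD of log spending, planting a
weak index–economics correlation; an optional profile-noise latent does the
same with pure noise, bounding how well any abundance index can track the
phenotype.

*Tree.* Random bifurcating rooted topology by iterative joining with
exponential(1)+0.05 branch lengths; deterministic per seed.

## Named scenarios and problem sizes

The test suite and `scripts/acceptance.py` use fixed scenarios
(`gutmets.scenarios`), sized to recover their planted structure clearly in
seconds to a few minutes on one CPU:

- *association*: n = 3000, 1000 OTUs, 200 planted at 0.3–0.6. Measured:
  empirical FDR ≈ 0.03 at q ≤ 0.05 (false positive = significant record on
  an OTU with no planted effect on any factor — planted OTUs genuinely
  associate with several correlated diagnostics, so per-pair scoring would
  miscount those), sensitivity ≈ 0.96, sign agreement ≈ 97%.
- *coupling*: n = 5000, spending→risk path off, profile leak −0.06; the
  recovered non-MetS Spearman rho lands around −0.04…−0.07 (measurement
  noise in the index attenuates the planted value slightly).
- *grid*: n = 4000, 300 OTUs, 60 planted at 0.15–0.3, profile-noise SD 3.0,
  sedentary risk weight 0.35. With the strong association scenario the
  index nearly classifies MetS and the low-index cells hit 0% prevalence;
  the moderate scenario reproduces the graded additive pattern
  (high/high ≈ 50–60%, low/low ≈ 3–5%).
- *saturation*: n = 600, 30 weak effects (0.12–0.22) so PERMANOVA power
  climbs visibly over subsample sizes 50→400.
- *diversity*: n = 1000 with a 1.5 log-unit positive-OTU boost so the
  concentration mechanism dominates.
- PERMANOVA null calibration: 2000 replications at n = 40 (100 fresh null
  tables × 20 label draws), 199 permutations.

## What the synthetic results do and do not show

Passing tests demonstrate that the pipeline recovers planted structure with
calibrated error control *under the generator's assumptions*: log-linear
factor effects, Dirichlet-multinomial sampling, exactly-null non-planted
taxa, Gaussian-copula lifestyle couplings. Real surveys violate all of
these to some degree — taxon covariance is ecological rather than purely
compositional, effects are not log-linear, confounding is richer — so the
measured FDR/sensitivity are properties of the bench, not guarantees about
field data. The index-weight formula is one choice among close variants,
and the per-factor BH family is a convention; both are isolated behind
parameters.

## Known limitations

- One-way PERMANOVA only; no multi-factor Adonis or strata/blocking.
- The boosting screen is a simplified componentwise-L2 stand-in for
  gradient-boosted selection, provided for completeness rather than as the
  recommended path.
- No zero-inflated or interaction models; no UniFrac; no Fisher exact
  tests.
- The generator emulates statistical structure, not a real taxon inventory
  or strain-level biology; raw sequence processing is out of scope.
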