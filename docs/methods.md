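# Methods

This note documents the statistical machinery, the modelling choices that
were genuinely open, and what the synthetic-data tests do and do not show.

## Approximate adjusted fractional Bayes factors

The engine evaluates informative hypotheses — conjunctions of equality and
order constraints on model parameters — against a multivariate-normal
approximation to the posterior of those parameters, g(γ | data) ≈ N(γ̂, Σ),
where γ̂ and Σ are the fixed-effect estimates and their covariance from a
fitted model. The prior is the *adjusted fractional prior*
h(γ) ≈ N(0, Σ/(f·b)): the posterior covariance inflated by 1/(f·b), centred
at the constraint boundary (the zero vector — all study constraints are
contrasts with boundary 0, and a non-zero boundary is rejected with an error
rather than silently mis-centred). Here

* **b = J/n_eff**, with J the number of *independent* constraint rows of
  the hypothesis (duplicate rows are deduplicated and J is the rank of the
  stacked constraint matrix), and
* **n_eff = n / (1 + (n_cluster − 1)·ICC)** the effective sample size of
  the clustered data, with ICC = s²_int/(s²_int + s²_res) from the model's
  variance components. For unbalanced clusters n_cluster is the mean
  cluster size (the design is balanced at 13 trials per participant, so no
  unbalanced rule is prescribed elsewhere).
* **f ∈ {1, 2, 3}** sets conservatism; f = 2 is the default and
  `sensitivity_over_fractions` re-evaluates a hypothesis set at f = 1 and
  f = 3 with identical seeds so the comparison is paired.

b is computed per hypothesis (b_i = J_i/n_eff); a shared-J override pools
the maximum J over a set for users who prefer one common fraction.

For each hypothesis the **fit** is the posterior probability (inequality
constraints) times the posterior density at the boundary (equality
constraints), and the **complexity** is the same functional under the prior.
Equality parts are closed-form marginal normal densities; inequality parts
are seeded Monte-Carlo orthant probabilities (default 10⁵ draws, minimum
10⁴), conditioned exactly on the equality block via the normal conditional
distribution when a hypothesis mixes both. Every sampled probability
carries its standard error √(p(1−p)/draws).

Bayes factors: BF_iu = fit/complexity against the unconstrained model;
BF_ic = (fit/complexity) / ((1−fit)/(1−complexity)) against the complement,
formed from the probability-valued inequality parts. For an equality-only
hypothesis the complement of a measure-zero set *is* the unconstrained
model, so BF_ic := BF_iu there. Posterior model probabilities are
PostP_i ∝ w_i·BF_iu with equal default weights; the fail-safe hypothesis is
by default the **complement of the union** of the mutually exclusive
pure-inequality hypotheses (fit_c = 1 − Σ fit_i, complexity_c = 1 − Σ c_i;
equality hypotheses are measure-zero in the union and contribute nothing),
with an alternative "unconstrained, BF = 1" mode behind a flag. A negative
complement beyond three combined Monte-Carlo standard errors raises an
error, because it means the hypothesis set is not mutually exclusive.

A fit or complexity of exactly 1 yields an infinite (or zero) BF_ic,
reported as such rather than raised — at 10⁴ draws an estimated probability
of 1 means the complement region received no mass at Monte-Carlo
resolution.

## Multilevel models

Every analysis model is a Gaussian random-intercept model fitted by REML
(ML behind a flag), through statsmodels MixedLM. Group × condition
analyses use the cell-means parameterization (no global intercept) so each
coefficient *is* a named cell mean and hypothesis strings read like the
theory ("dys_positive < non_positive & …"). The detail–affect regression
uses group dummies (group1 = 1 for the dysphoric group), the grand-mean
centred participant mean of episodic detail crossed with the dummies
(between-person slopes), and the participant-mean centred detail crossed
with the dummies (within-person slopes). The grand mean is the mean of
participant means, so each person counts once regardless of trial count;
within- and between-person regressors are orthogonal by construction.
Participants contributing a single trial get a structurally zero
within-person term and are flagged.

Numerical choices: outcomes are internally rescaled to unit variance before
optimization and the results rescaled back (the likelihood is invariant but
the optimizers are not); optimizers are tried in the order lbfgs → powell →
cg, and a candidate is rejected if it reports convergence from a degenerate
boundary point with a non-finite or exploded fixed-effect covariance
(observed with lbfgs when the intercept variance estimate collapses to 0);
posterior covariances are symmetrized and tiny negative eigenvalues from
optimizer round-off are clipped to zero. A boundary estimate s²_int = 0 is
legitimate and yields ICC = 0, n_eff = n.

## EMG preprocessing

Raw traces (1000 S/s, 4 s baseline before cue onset, 60 s recall or the
movie duration) are high-pass filtered at 20 Hz (4th-order Butterworth),
notch-filtered at 50 and 100 Hz (2nd-order band-stop sections, 4 poles,
48–52 and 98–102 Hz), all zero-phase; then full-wave rectified and smoothed
by a first-order exponential filter with τ = 25 ms — a digital contour
follower realized functionally, not electrically. Windows are half-open
[start, end) in whole seconds with cue onset at t = 0 and baseline [−4, 0).
Each 1000 ms segment becomes one bin (mean amplitude; any non-finite sample
marks the bin missing).

Artifact rejection is a **single pass**: within participant × muscle ×
session × condition (baselines: across conditions), the mean and *sample*
SD (ddof = 1) are computed once on the original bins and every bin with
|z| ≥ 3 becomes missing. Statistics are never recomputed after removal; a
group SD of 0 rejects nothing. A consequence worth knowing: the largest
attainable sample z in a group of n bins is (n−1)/√n, so groups of ≤ 10
bins can never trigger the rule — baselines (4 bins × few trials) are
effectively protected, which is why the baseline grouping pools across
conditions. A high artifact *rate* also defeats the rule by inflating the
pooled SD; the single pass is deliberate (one rejection step, not
iteration).

Trials lose their response when more than 50 % of event segments or more
than 50 % of baseline segments are missing (strictly more: 31/60 excludes,
30/60 retains), or when the baseline mean is zero (degenerate). The
standardized response is the mean percent change of the retained event bins
from the baseline mean — invariant to amplitude gain. The unstandardized
recall/baseline bin means are exported alongside, because the manipulation
checks run on raw amplitudes (aggregated to trial means; the aggregation
level was an open choice).

## Synthetic data

The generator emulates the study design: two groups (dysphoric /
non-dysphoric), 13 memory trials each (5 positive, 5 negative, 3 neutral;
movies: 2/2/1), participant random intercepts sized from an ICC target
(default 0.3), and trial-level Gaussian residuals. Scenario sign patterns
on the dysphoric-minus-non-dysphoric shift: overgeneral (−, −), negativity
(−, +), positive attenuation (−, 0), null (0, 0), applied per outcome with
unit magnitudes of 2.5 details, 8 valence points, 80 zygomaticus and 15
corrugator percent-change points, times an `effect_scale` (1 ≈ study-sized,
3 = "large" in the identifiability studies). Non-dysphoric cell means and
residual SDs are set to realistic magnitudes for this kind of data (e.g.
zygomaticus ≈ +175 % on positive memories with SD ≈ 120). Valence is
truncated to [0, 100] (truncation, not resampling, preserves effect
monotonicity); detail counts are rounded Gaussians by default (mean and
variance independently controllable) with a Poisson mode behind a flag.
One global seed expands into per-participant substreams
(SeedSequence spawn keys), so enlarging the sample never perturbs earlier
participants — the sequential design depends on this.

What the generator does **not** emulate: realistic EMG spectra beyond
broadband noise with amplitude bursts, muscle cross-talk, skewed
percent-change distributions, missing-data mechanisms other than planted
spikes, or any correlation between detail counts and affect beyond the
optional planted slope. Passing tests therefore certify the machinery and
its calibration under the stated generative model, not the behaviour of the
pipeline on real recordings.

## Study battery and sign conventions

A *stronger* emotional response means: more zygomaticus activity on
positive trials, more corrugator activity on negative trials, higher
valence ratings on positive trials and **lower** valence ratings on
negative trials. All hypothesis strings are expressed on raw means with
these directions.

Test 2A's fEMG outcome assigns zygomaticus percent change to positive
trials and corrugator percent change to negative trials. The two muscles'
scales have very different residual variances (≈ 120 vs ≈ 30 SD in the
generator, and similarly lopsided spreads in real data), so the default
fits **one model per muscle** and joins the two cell-mean posteriors
block-diagonally (the blocks come from disjoint trials), averaging the two
models' effective sample sizes. A single pooled-variance cell-means model
— which understates the zygomaticus standard errors and inflates false
directional verdicts under the null — remains available via
`combined_model=True`. Test 2B and the attenuation comparison use the same
per-muscle posterior.

Test 2B is conditional: it runs the directional pattern Test 2A favoured
against its complement, and is skipped with a recorded reason when 2A
favoured the null or the fail-safe, mirroring the registered decision
table. The habituation tests model only the five same-valence trials
(their ordinal position within valence, not the global trial index).
Symptom-severity and affect-questionnaire analyses are participant-level
regressions where n_eff reduces to the participant count.

The sequential design evaluates Tests 1 and 2A at N = 40 and after each
balanced step of 10 (5 per group, participants in arrival order), stopping
when **both** leading posterior model probabilities reach 0.80, else at
N = 80 with reason `max_N`.

## Operating characteristics and limitations

Simulation sizes used by the test suite and `scripts/acceptance.py`:
Monte-Carlo oracle checks at 10⁵ draws; ordering complexities at 2·10⁵;
parameter recovery over 200 replications (80 participants × 13 trials,
ICC 0.3); identifiability over 100 simulated studies per scenario at
N = 80 with effect_scale 3 and 10⁴ evidence draws.

Measured identifiability: the directional scenarios (overgeneral,
negativity) are recovered essentially always; positive attenuation ≈ 93 %
and the null scenario ≈ 89 % (both primary tests jointly picking the
equality hypothesis). The shortfall from certainty is not an
implementation artifact but a property of the evidence measure at this
design's effective sample size (n_eff ≈ 200) and fraction f = 2: a truly
equal contrast produces a ≈ 2.3 σ directional fluke in roughly 5 % of
tests, which is enough to hand the verdict to a directional or fail-safe
hypothesis, and the null scenario compounds two such tests. Under the null
the sequential design's early directional stops inherit the same rate; it
is monitored as a reported statistic, not bounded.

Known limitations: no interval ("about-equality") constraints, no
heterogeneous-variance priors beyond the per-muscle block construction, no
Bayes factors for non-normal posteriors, no random slopes or crossed random
effects, and no modelling of the verbal-recall coding process (episodic
detail counts are inputs).
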