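# Methods

## Model

The package models a simplified adverse outcome pathway for developmental
neurotoxicity as a fixed directed chain of four Bernoulli nodes: reduction of
BDNF (molecular key event), decrease of synaptogenesis, decrease of neural
network formation, and the adverse outcome DNT.  Each key event k carries a
coefficient vector beta_k over its predictor block X_k; the linear predictors
accumulate along the chain (theta of a node adds to the next node's linear
predictor), and the DNT predictor is the sum of the three key-event
predictors — equivalently 3·c1 + 2·c2 + c3 in the per-block contributions
c_k = beta_k·X_k.  All coefficients are partially pooled through a single
hyperprior pair mu ~ Normal(0, 0.1), sigma ~ HalfNormal(1) (second Normal
parameter is a standard deviation throughout).

The Bernoulli probability is the inverse logit of theta.  The theta chain is
formally a linear predictor on the logit scale, and a Bernoulli parameter
must lie in [0, 1]; generator and fitter import the link from one module
(`qaop._link`) so they cannot diverge.

Assumptions worth keeping in mind: causal effects between key events are
linear on the logit scale; the chain is the only causal structure (no
molecular initiating events, no feedback); predictors act only on their own
key event; all coefficients are exchangeable under one global hyperprior.

## Predictor assignment and preprocessing

There is no single canonical mapping of evidence columns to key events, so
the default assignment follows the biological levels: chemical/ADMET
properties (LogD, BBB, Cbrain/Cblood, three P-gp indicators) feed the
molecular event; each in vitro assay's viability and effective concentrations
feed its own key event.  Each block gets an intercept column (constant 1,
never standardized) because the binary outcomes have non-trivial base rates;
its coefficient is pooled like any other.  Both choices are config-overridable
(`PredictorAssignment`), including an intercept-free literal mode.

Continuous predictors are z-scored over observed entries with the sample
(n−1) standard deviation; EC30/EC50 columns (µM, spanning orders of
magnitude) are log10-transformed first; binary predictors stay 0/1.  The
location/scale pairs are stored for exact round-tripping.  Empty CSV cells
are the sole missingness encoding; "inactive in assay implies missing" is an
upstream data-preparation rule, not re-applied here.

## Missing data

Missing predictor cells are masked, never filled by the reader.  In the model
each missing cell is a latent value with prior Normal(mu_miss, sigma_miss),
one weakly-informative hyperprior pair (Normal(0, 0.1), HalfNormal(1)) per
block that has gaps; binary predictors are imputed on the same continuous
standardized scale as continuous ones (one imputation scheme for all X).
Missing outcome labels contribute no likelihood term (marginalization — for
a Bernoulli node this is exact) and are imputed from the posterior predictive
as per-draw Bernoulli draws, which the `PosteriorSamples` object exposes.
The adverse-outcome label is mandatory: every compound carries an in vivo
classification, and observed DNT labels condition the fit through the Y_DNT
likelihood even though theta_DNT has no coefficient block of its own.

## Sampling

The posterior is sampled by an in-package No-U-Turn sampler (slice-based
tree doubling, max depth 10) with analytic gradients of the log joint,
dual-averaging step-size adaptation (target acceptance 0.9) and windowed
diagonal mass-matrix estimation.  Energy errors above 1000 nats mark a
transition divergent; post-warmup divergences are reported per chain and the
caller is expected to act on them.  Half-normal scales are sampled on the log
scale with the Jacobian correction; coefficients and latent predictor cells
are sampled non-centered (beta = mu + sigma·raw with raw ~ N(0,1)), which
leaves the posterior unchanged but removes the funnel geometry that otherwise
produces divergences in hierarchical models.  Defaults: 4 chains × 1000
warmup × 1000 kept draws, sequential chains, one child seed per chain from a
`SeedSequence`; a fixed seed reproduces draws bit-for-bit.

The natural-parameter log joint (`log_joint_density`) is exposed separately
so that tests can check the sampler against exhaustive grid integration on
reduced models (ModelSpec.frozen pins any subset of parameters);
sigma ≤ 0 returns −inf by contract.

## Diagnostics

R-hat is the rank-normalized split variant; ESS is the autocorrelation-based
bulk estimate (both via ArviZ); MCSE is sd/√ESS by definition.  Constant
chains return NaN (undefined), never 1.  WAIC uses the sample-variance
penalty (the R `loo` convention) and is reported on the deviance (−2×) scale
with the elpd scale also exposed; PSIS-LOO smooths importance ratios with
ArviZ's generalized-Pareto fitter, flags points with k > 0.7, and assigns
k = 0 to points whose weights are exactly uniform (no tail to fit).  Brier
scores are computed per node from posterior-predictive mean probabilities
against observed labels, skipping compounds whose label is missing.

The hyperprior sensitivity analysis refits under alternative
weakly-informative settings — by default the pooled-coefficient HalfNormal
scale × {0.5, 1, 2}, a symmetric halving/doubling around the default — and
tabulates elpd_loo, WAIC, Brier scores and
the pairwise max absolute difference of per-compound predictive means.

## Prediction outputs

The 95% interval is equal-tailed (2.5th/97.5th percentiles) by default —
the convention that defines the interval by its tail quantiles — with a true
highest-density interval behind a flag.  Hazard classes use two thresholds,
by default the empirical tertiles of the per-node predicted means (a
data-derived convention chosen here; fixed thresholds are accepted); the
boundary is inclusive on the upper class side (mean = t_low is medium,
mean = t_high is high).  Performance metrics binarize at 0.5 (the natural
probability cutoff, configurable) and report sensitivity, specificity,
accuracy and
balanced accuracy, with undefined values flagged as None rather than 0.

## Synthetic data

The generator draws raw predictors on natural scales (LogD ~ N(2, 2); brain/
blood ratio and ECs log-normal spanning the low/medium/high absorption and
µM ranges; viabilities ~ N(70–75, 20) percent of control; binary ADMET flags
Bernoulli(0.5) flags), builds the same standardized design matrices the fitter
uses, evaluates the theta chain with true coefficients (drawn from
Normal(0, 0.5) by default, so true effects sit inside the weakly-informative
prior's plausible range), and draws all four labels.  Missingness is MCAR
per column; the default rates emulate a realistic evidence base (BDNF labels
55% missing, in silico columns 8%, assay columns 10–12%) — chosen once as
the package's study conditions, since real screening collections do not
publish per-column missingness rates.  The generator does not
emulate chemistry-aware feature correlations, assay concentration–response
designs, or MNAR mechanisms; passing tests therefore demonstrate statistical
correctness of the machinery, not predictive validity on real compounds —
on self-generated data the model is well-specified, which is why synthetic
DNT accuracy (~98% at n = 88) is far above what heterogeneous real evidence
can support.

## Problem sizes and numerical choices

Test and acceptance computations use sizes chosen to make their statistical
checks stable: the parameter-recovery experiment uses n = 300 compounds
(20 seeds in the test suite, 6 in the acceptance script) with 2 chains × 300
warmup/300 kept draws; the interval-width contrast uses n = 200 with 30%
MCAR key-event labels on top of the default predictor missingness, because
with complete predictors the label-only effect on per-compound interval
width is second-order (theta is deterministic given beta and X) and the
widening mechanism — the contrast between fully characterized and data-poor
compounds — runs through predictor imputation;
the default study fit uses the full 4 × 1000/1000 sampler settings.
Standardization tolerances are 1e-9; gradient correctness is verified against
central finite differences; tie-breaks (equal predicted means) make tertile
thresholds degenerate and raise an error advising fixed thresholds.

## Known limitations

`count_parameters` reports the census of the actual model graph — named
blocks, imputation blocks, free scalars — which depends on the dataset's
missingness pattern, so counts are only comparable across fits of the same
data.  Published per-compound DNT probabilities for specific reference
chemicals depend on curated evidence that is not redistributable, so they
serve only as qualitative anchors for the synthetic studies here.  Cyclic
AOP networks, variational inference, MNAR missingness and kinetic/PBK
extensions are out of scope.
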