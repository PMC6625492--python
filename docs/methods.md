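# Methods

`solvoptim` implements a hybrid mechanistic–machine-learning workflow for
choosing reaction solvents: physically meaningful molecular descriptors make
the discrete solvent choice continuous, Gaussian-process (GP) surrogates
learn the descriptor → outcome map from a handful of experiments, and
Thompson-sampling multi-objective optimisation proposes the next experiments.
This note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic benchmarks do and do not show.

## Descriptors and features

A solvent is described by 17 tabulated quantities: 14 scalar
physico-chemical properties (molecular weight, density, molar volume,
refractive index, molecular refractive power, dielectric constant, dipole
moment, melting and boiling points, viscosity, ln P(octanol–water), vapour
pressure, Henry's constant of H₂, and ln γ of the substrate) plus the areas
of the COSMO screening-charge-density profile p(σ) split into three segments
σ̄₁–σ̄₃ at σ = −0.010 and +0.010 e Å⁻².  A five-segment split σ₁–σ₅ (cuts at
−0.015, −0.005, +0.005, +0.015 e Å⁻²) is carried alongside; the wings of the
profile encode hydrogen-bond donor/acceptor character, the centre the apolar
surface.

Segment areas are trapezoidal integrals on the native grid with the density
linearly interpolated at each cut, so the segments always sum exactly to the
total profile area; segments are half-open [left, right) with the last
closed, a pure tie-breaking convention since interpolated cuts make the
integral itself unambiguous.  Mixture profiles are volume-fraction-weighted
sums of re-gridded pure profiles, hence segment descriptors of a mixture are
the same weighted sums of the pure descriptors — the linearity that lets
pure-solvent models score mixtures.

Principal components t₁–t₄ of the autoscaled (z-scored, ddof = 1)
17-descriptor block provide the low-dimensional feature sets.  Autoscaling
is forced because the descriptors carry incommensurate units; the loading
sign is fixed by making each loading's largest-magnitude element positive.
Six canonical feature sets are exposed: model 1 = σ₁–σ₅, model 2 = σ̄₁–σ̄₃,
models 3–6 = t₁–t₄, t₁–t₃, t₁–t₂, t₁.  Rows with missing descriptors are
excluded from the PCA fit but can still be transformed when their own
features are complete.

Diastereomeric excess interconverts with the transition-state free-energy
difference via ΔΔG‡ = R·T·ln((1+de)/(1−de)) (kJ mol⁻¹, positive for the
major diastereomer); both d.e. and ΔΔG‡ are accepted as regression targets —
the default is d.e. directly.

## GP surrogates

One independent GP per objective (conversion %, d.e. %).  Kernel: Matérn 5/2
with automatic relevance determination (ARD, one length scale per feature);
a squared-exponential is available by configuration.  Inputs are z-scored
per column and targets standardised; hyperparameters (log length scales,
log signal variance, log noise variance) maximise the log marginal
likelihood by L-BFGS-B from 10 seeded restarts (default start plus 9 random
draws), with analytic gradients.  Cholesky factorisations escalate jitter
from 10⁻⁸ by decades up to 10⁻⁴ before raising a conditioning error with a
remedy hint.  A noise floor of 10⁻⁶ (standardised variance) keeps
interpolation stable on noise-free toys.  Predictive variance optionally
includes the noise term; replicate experiments are averaged to one training
point before fitting.

Smaller ARD length scale ⇒ stronger influence of that input, which is the
basis of the relevance ranking (ties keep input order).  On data generated
from a known ARD kernel with length scales separated 4× (n = 60), the fitted
ordering is recovered in ≳90% of seeded replicates — the computational
justification for reading length-scale tables as variable-importance tables.

Leave-one-out q² is computed honestly: hyperparameters are re-optimised in
every fold (small-sample optimism otherwise), and q² = 1 − PRESS/TSS with
TSS about the full-sample mean.  The squared-Pearson variant is available
behind a flag because the convention is not universal; the two differ
slightly in exactly the situations where published tables and text disagree
at the second decimal.

## Thompson sampling

Posterior *functions* are drawn with random Fourier features plus Matheron's
pathwise update: a prior sample f₀(x) = √(2σ_f²/M) Σ w_i cos(ω_iᵀx + b_i)
(ω from the kernel's spectral density — Student-t with 5 degrees of freedom
for Matérn 5/2, Gaussian for the squared-exponential; M = 256 by default,
512 in consistency tests) is corrected by
f = f₀ + k(·, X)(K + σ_n²I)⁻¹(y − f₀(X) − ε).  Each sample is a cheap
deterministic function; ensemble means are exactly unbiased for the
posterior mean, ensemble variances match to O(1/M).

Discrete suggestion: per repeat, one sample per objective is evaluated at
every untested solvent (exhaustive enumeration — with a few hundred
candidates no inner genetic algorithm is needed) and the candidate with the
largest hypervolume improvement over the observed front gets a vote; votes
over (default 100) repeats rank the candidates, which biases pure Thompson
sampling towards exploitation.  Ties break by mean hypervolume improvement,
then lexicographic id.  Sampled candidates falling below the reference point
contribute zero improvement.

The hypervolume reference point defaults to the component-wise observed
minimum minus 10% of the observed range.  Campaign logs instead use the
fixed objective-space corner (0, −100) so the hypervolume trajectory of the
growing archive is monotone by construction and comparable across
iterations.

## Mixtures and batches

Mixture campaigns optimise (x₁, x₂, x₃, T) with the fourth solvent as
balance, subject to Σ₁³xᵢ ≤ 1.  The inner search is an in-package NSGA-II
(simulated binary crossover η = 15, polynomial mutation η = 20 at rate 1/d,
feasibility-dominated tournaments; constraint by feasibility dominance, not
penalty).  Batches follow the two-step rule imposed by parallel reactors
sharing one temperature: recipe 1 is selected with temperature free and
fixes the batch temperature; recipes 2..B are selected at that temperature,
each after conditioning the surrogates on the *sampled* (fantasised) outcome
of the previous recipe with hyperparameters held fixed — the standard
batch-sequential device.

## Amplify–classify loop

Ten measured points are amplified to 100 rows by evaluating the
per-objective GPs (model 4 features for conversion, model 1 for d.e.) at
untested solvents drawn uniformly without replacement; posterior means by
default, posterior samples optionally to propagate uncertainty.  Rows are
labelled high/low at 80% conversion and 65% d.e. (strict inequalities; the
joint label requires both).  A bounded template search — {none, z-scaling} ×
{none, top-k univariate selection} × {logistic regression, RBF-SVC, random
forest, k-NN} with small per-family grids, scored by stratified 5-fold
balanced accuracy — stands in for genetic pipeline optimisers; it is
exhaustive by default with an optional small genetic search over the same
grid.  Class weights are balanced because positives are rare by
construction.  If an amplified label set is single-class the loop falls back
to ranking untested solvents by the GP joint exceedance probability rather
than stalling.  The top-scored predicted-'high' untested solvents (4 per
iteration) are measured, appended, and the GPs refit.

## Synthetic data

The generator defines the study conditions. The descriptor library
prescribes the *exact* eigenstructure of its sample correlation matrix:
orthonormal centred score columns are combined with a random correlation
matrix constructed to have the requested spectrum.  The default spectrum
puts 32/17/13/8% of the variance on the first four components (cumulative
0.32, 0.49, 0.62, 0.70) — the concentration typical of curated solvent
tables — with the residual 30% spread evenly.  Standardised columns map to
realistic units per descriptor; σ-segment columns are then re-derived from
constructed mixture-of-Gaussians profiles so that both segmentations are
exactly consistent with one integration rule (this re-derivation, plus rare
clipping at physical positivity floors, is the only deviation from the
prescribed eigenstructure, and it is well inside the ±0.02 tolerance used in
the checks).

The reaction oracle mimics an asymmetric hydrogenation.  Conversion is a
logistic response in a latent axis u₁ (a random direction in the library's
top-PC factor subspace — reactivity responds to the dominant
physico-chemical axes) with a positive temperature coefficient; selectivity
comes from ΔΔG‡ linear in a second axis u₂ anchored on the σ-profile wing
contrast σ̄₁+σ̄₃ (profile extremes carry the stereochemical information) and
correlated 0.8 with u₁ by default; de = tanh(ΔΔG‡/2RT) keeps |d.e.| < 100
and makes selectivity fall with temperature, giving the
reactivity/selectivity trade-off in T.  Observation noise defaults to 2%
(conversion) and 3% (d.e.) SD, the scale of replicate scatter in small-batch
autoclave screening.  Intercepts are calibrated per library (a monotone
shift, so the Pareto ordering is untouched) to pin the noiseless joint-high
prevalence at 10% with a 25% conversion-high marginal.

Under this structure σ-profile features predict d.e. well but conversion
poorly, and PC features predict conversion best — the qualitative pattern
the method exploits.

The *benchmark* landscape used for campaign evaluation raises the latent
correlation to 0.95: strongly aligned objectives mean one or two solvents
dominate, the regime in which a designated best solvent exists and in which
undirected screening of 35 out of 200 candidates only rarely finds it (the
hypergeometric identity ties the random hit rate directly to the true front
size).

What the synthetic benchmarks do **not** show: real descriptor tables have
heavy-tailed, clustered, missing-data-ridden columns rather than a clean
factor model; real reaction landscapes are rougher and higher-dimensional
than a monotone response in one or two latent axes, so real campaigns should
be expected to need more data than the synthetic ones; and the σ-profiles
are statistical stand-ins, not quantum-chemical objects.  In particular the
smoothness of the synthetic landscape means a GP trained on just 10 points
is already informative, so early-iteration performance of the
amplify–classify loop is better than the near-uninformed start the loop
anticipates on hard real systems — its pick precision rises in the mean
across iterations, but not strictly in nearly every run.

## Numerical and degenerate-input conventions

Boundaries outside a profile's grid contribute zero area; non-monotone cut
lists, negative densities, fraction vectors off the simplex, k above the
data rank, zero-variance q² targets, single-class pipeline labels, and
exhausted libraries all raise typed errors rather than warnings.  All
randomness flows from `numpy` `SeedSequence` trees rooted at a single seed;
refits, sample draws, searches and whole campaigns are bit-reproducible for
a fixed seed.  Cross-validation never scores a model on data used to fit it
within a fold; folds that lose a class score zero rather than NaN.

## Problem sizes

The standard evaluation uses 459-solvent libraries for the variance-structure
check (seconds), 200-solvent landscapes with 20 campaign replicates for the
optimisation benchmark and 10 replicates of the 3-iteration amplify loop,
2000 posterior draws for the Thompson-sampling consistency check, and
10⁶-sample Monte-Carlo rejection for the hypervolume oracle — sizes at which
every reported rate has a Monte-Carlo error of a few percent and a full
evaluation completes in minutes on one CPU.
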