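# Methods

## Generative model

Cortical activity is represented at `n_v` lumped thalamocortical generators
("vertices"). Each generator hosts up to two independent, zero-mean,
weakly stationary Gaussian processes: a broadband aperiodic component and a
rhythmic alpha component. Their power spectral densities are generalized
Lorentzians

    psi(omega | A, B, E, F) = A / (1 + B (omega - F)^2)^E,

with amplitude `A` (linear power density; decibels are a display choice
only), bandwidth `B` in s² (a peak's FWHM is `2 sqrt((2^(1/E) - 1)/B)` Hz),
spectral exponent `E > 1/2` controlling tail decay and process smoothness,
and center frequency `F` in Hz (0 for the aperiodic component; inside the
alpha band, default 7–13 Hz, for the rhythmic one). A real-valued rhythm
requires an even spectrum, so the alpha PSD is the symmetrized
`(psi(omega - F) + psi(omega + F))/2`.

The matching time-domain autocovariance is the cosine-modulated Matérn
kernel

    cos(2 pi F tau) * M(tau),
    M(tau) = (2 sqrt(pi) A)/(sqrt(B) Gamma(E)) (pi|tau|/sqrt(B))^(E-1/2)
             K_{E-1/2}(2 pi |tau| / sqrt(B)).

Under the convention `S(omega) = \int M(tau) e^{-2 pi i omega tau} dtau`
(omega in Hz) this pair is an *exact* Fourier pair for every `E > 1/2`; the
package verifies this numerically and, at `E = 1` where `M` is the
exponential kernel `(pi A/sqrt(B)) e^{-2 pi |tau|/sqrt(B)}`, in closed
form. `M(0)` is evaluated from the small-argument Bessel limit
`sqrt(pi) A Gamma(E - 1/2)/(sqrt(B) Gamma(E))`, never by calling
`K_nu` at 0; lags below a nu-dependent threshold return that limit
(relative error < 1e-12) and the far tail underflows to exactly 0.

Generators interact through a delayed MVAR kernel factorized as a Hadamard
product of a coupling matrix and a Dirac delay kernel,
`A_tau = C (.) delta(tau - D)`, with `C = w_C Cbar` and `D = w_D Dbar`
scaled from population-level priors. `Cbar` is normalized to unit spectral
radius at construction so `w_C` reads as a global coupling gain. In the
frequency domain the delay kernel is the exact phase factor

    A_omega = C (.) exp(-2 pi i omega D),

with no discretization (delays are only rounded in the time-domain
simulator). The Green function `G_omega = (I - A_omega)^{-1}` propagates
locally generated power across the network; the per-component transfer
function is `H_omega = G_omega diag(sqrt(s_omega))` and the component
source cross-spectrum `S_omega = H_omega H_omega^dagger`. Sensors observe
`Sigma_omega = K S_omega K^dagger + sigma_n^2 I` through a lead field `K`.
Weak stationarity is enforced by requiring the spectral radius of
`A_omega` to stay below `1 - 0.02` over the analysis grid (and at DC); for
nonnegative `C` the bound `rho(A_omega) <= rho(C)` makes a single
eigencomputation on `C` a sufficient test, which the weight search
exploits.

Default analysis grid: 47 bins, 1.17–19.11 Hz in 0.39 Hz steps — the
standard derived-cross-spectrum layout for 19-channel quantitative EEG.

## Synthetic scenes

`make_scene` generates the complete study configuration deterministically
from a seed: quasi-uniform vertices on a 70 mm sphere (y is the
posterior–anterior axis); a sparse connectome with symmetric support and
asymmetric weights; conduction delays = Euclidean distance / 6 m/s with
15% lognormal jitter, clamped to 1–100 ms; smooth lead-field columns
(Gaussian sensor–vertex kernel, 40 mm length scale) so neighboring sources
project similarly; alpha-active generators clustered posteriorly and
aperiodic generators spread uniformly; a coordinate-based parcellation
whose per-parcel hierarchy gradient rises anteriorly. Sensor noise
defaults to 5% of mean signal power. Alpha bandwidths default to
`B in [0.5, 2]` s² (FWHM ≈ 1–2 Hz), matching empirical resting-state peak
widths and resolvable at 0.39 Hz resolution; amplitudes, exponents and
peak frequencies are drawn from physiologically plausible ranges stated in
the code.

What the scenes deliberately do not emulate: realistic head-model lead
fields (no BEM/FEM), inter-subject anatomical variability, nonstationary
dynamics, artifacts, or volume-conduction asymmetries. Passing recovery
tests therefore demonstrates correctness of the estimator under the
model's own assumptions plus finite-trial noise — not robustness to the
full mismatch of real recordings. The neural-mass benchmark below is the
designated mismatch probe.

Three data routes:

* **Complex-Wishart sampling** — finite-trial sample cross-spectra
  `(1/m) sum z z^dagger` with circular complex Gaussian trials, the exact
  sampling distribution of averaged periodograms.
* **Time-domain simulation** — innovations synthesized spectrally
  (circulant embedding: exact stationary realizations up to circular
  wrap), network recursion with delays rounded to the nearest sample
  (clamped to ≥1 lag with a warning), sensors via the lead field plus
  white noise. Consistency measurements run at 499.2 Hz so Welch bins with
  1280-sample segments land exactly on the 0.39 Hz grid and delay rounding
  is ≤1 ms. At 10 minutes of data the median relative Frobenius error
  against the analytic spectra has a statistical floor near 9% for 19
  correlated channels — the 10% consistency bound is tight by design, not
  slack.
* **Neural-mass benchmark** — delay-coupled stochastically driven damped
  oscillators (second-order units, semi-implicit Euler in the damping so
  the overdamped limit is stable), intentionally *not* the model
  likelihood, for inverse-crime-free comparisons. Its parameters are
  configuration, not calibration: the role is qualitative mismatch.

## Inversion

The data term is the Whittle / complex-Wishart negative log-likelihood
`m sum_omega [log det Sigma(omega) + tr(Sigma^{-1}(omega) S_hat(omega))]`.
Because the two components enter only through the summed per-generator PSD
`s = xi + alpha`, the model spectrum is `Kt diag(s) Kt^dagger + sigma^2 I`
with `Kt = K G` precomputed per frequency once per structural candidate;
the gradient w.r.t. `s` is `m Re diag(Kt^dagger (Sigma^{-1} - Sigma^{-1}
S_hat Sigma^{-1}) Kt)`, chained analytically to the Lorentzian parameters.
The analytic score is verified against central finite differences to
1e-9 relative.

Sparsity is a group lasso with one group per (generator, component) over
scaled coordinates `(A, B, E - 1/2)` and `(A, B, E - 1/2, F - F0)`
(scales 3, 1, 1, 2; group weights `sqrt(group size)`), so a whole
component dies or survives jointly. Optimization is monotone FISTA with
Nesterov momentum, backtracking line search, box projection of surviving
groups to their parameter bounds (A ≤ 30, B in [0.05, 10], E in [0.6, 6],
F in the alpha band), optional stochastic frequency minibatches (full-grid
evaluation is the default and is what all reported experiments use), and
a monotone-restart safeguard, run from one data-driven initialization
(beamformer-style backprojection of the data spectrum; alpha peak seeded
at the in-band argmax) plus `n_starts - 1` random initializations. After
each descent a blockwise sweep zeroes any group whose removal does not
increase the penalized objective — an exact prox step that removes
near-dead groups whose shape coordinates the likelihood no longer senses
(their gradient is proportional to the vanishing amplitude, so plain
proximal iterations shrink them only geometrically). Every accepted step,
including the sweep, decreases the objective, preserving the monotone
trace invariant.

Structural weights `(w_C, w_D)` are profiled out first: each candidate
runs a reduced spectral fit (1 start, 30–45 iterations) and the profiled
penalized objective is minimized over the log-box `w_C in [0.05, 0.95]`,
`w_D in [0.5, 2]`. The objective's geometry — a deep needle in `w_D` over
a flat noisy background, visible only at non-negligible coupling — forces
several departures from textbook GP-EI optimization. Initialization is a
designed scan along `log w_D` at two moderate coupling probes, each probe
scanned in increasing `w_D` order with *warm-start continuation*: the
inner fit starts from the neighboring level's solution, which makes every
profile evaluation both cheaper and far better converged, so the needle
contrast is not buried in inner-fit truncation noise (full-grid inner
fits throughout; stochastic minibatches were evaluated and rejected here
because they halve the contrast). The GP for the expected-improvement
phase is fitted to normal scores (ranks) of the objective, which keeps
its length scales from collapsing on the skewed raw values. The run ends
with a coordinate refinement (delay, coupling, delay rounds) at 1.5x
inner budget, warm-started from the incumbent's solution and with the
incumbent re-evaluated on equal terms, so truncation noise cannot favor a
lucky earlier evaluation. The `w_C` floor of 0.05 encodes the
physiological prior that cortico-cortical coupling is present but
subcritical.

Model complexity uses `BIC = 2 L + k_active log(m n_omega)`; ties prefer
fewer active parameters. The regularization weight is tuned after the
structural weights (two-step profile strategy); `select_bic` consumes fits
over a lambda path.

Uncertainty is a Laplace approximation at the MAP: the Hessian of the
unpenalized objective restricted to active coordinates by central finite
differences of the analytic score (relative step 1e-4), standard errors
from the inverse (Moore–Penrose with a flag if indefinite), two-sided
normal Wald p-values, Benjamini–Hochberg across parameters, and optional
parcel-level mean |z| summaries. Doubling the trial count doubles the
curvature (SEs shrink by sqrt 2) and raising sensor noise variance flattens
it — both verified in the test suite.

## Spectral Granger causality

Each component defines its own directed structure. Pairwise causality uses
the 2x2 *reduced* cross-spectrum of a vertex pair: reduction of a network
to two nodes introduces moving-average terms, so the pair spectrum is
refactorized with Wilson's canonical spectral matrix factorization (Newton
iteration with the causal plus-operator; the zero-lag gauge is the
upper-triangular half, which pins the unique minimum-phase factor) and the
bivariate Geweke measure is evaluated from `(H~, Sigma~)`. A parametric
shortcut evaluates the same formula directly from the model transfer
function with unit innovations; it equals the Wilson route when that
factorization is already canonical (flat innovation spectra) and serves as
the built-in cross-check (agreement ≤ 1e-3, in practice ~1e-10).

Two numerical facts shape the implementation. First, a continuous
conduction delay is a fractional-sample delay on any factorization grid
and hence non-causal in discrete time; Wilson's iteration then provably
cannot converge to the model factor. Delays are therefore snapped to the
factorization sample period (<2 ms at the default 256 Hz rate / 513-point
half grid, 0.25 Hz resolution). Second, Lorentzian spectra span ~8 decades
over the factorization band, so the iteration plateaus near 1e-6 relative
change from rounding noise; the convergence test accepts plateaus below
1e-5, where Geweke values are already stable to 8 decimals.

Ordered pairs with no directed anatomical path have an exactly vanishing
transfer entry, are skipped, and report exactly 0. Causality is evaluated
at the component's peak frequency (alpha: in-band argmax of the mean alpha
PSD; aperiodic: its 1–4 Hz maximum; bands configurable), and vertex pairs
aggregate to parcel pairs by the mean.

The directional asymmetry index is
`DAI = (G_{j->i} - G_{i->j})/(G_{j->i} + G_{i->j})` in [-1, 1],
antisymmetric in raw form; when a hierarchy gradient is supplied each
entry is oriented by the sign of the gradient difference so positive means
feedforward (toward higher hierarchy). Pairs silent in both directions are
NaN-masked. The direction test compares mean causality over feedforward
and feedback ordered edges against a null built by jointly permuting the
gradient's parcel labels (a generic label permutation — weaker than a
surface-based spatial null, which needs geometry this package does not
model), with one-sided `p = (1 + #{null >= obs})/(1 + n_perm)`.

## Benchmarks

The linearized inverse without sparsity is the Bayesian minimum-norm
operator `T = Gamma K^T (K Gamma K^T + sigma^2 I)^{-1}`; `R = T K` holds
point-spread functions in its columns. "Priors ON" builds `Gamma` by
propagating unit source variances through the Green function at a 10 Hz
reference (`Re{G G^dagger}`); "priors OFF" is `Gamma = I`. The ON/OFF
contrast is the tested contract; the specific `Gamma` is one reasonable
linearization. Metrics per column: PLE (distance to the |PSF| peak, ties
resolved to the candidate nearest the truth), SD (energy-weighted RMS
distance from the peak), RSA (energy fraction beyond 30 mm — the radius is
a configurable convention, reported with results). All three vanish on the
identity matrix and are invariant to column rescaling, and denser montages
(19 → 120 sensors) must not worsen their medians across random scenes
(one-sided sign test).

ICC(3,1) is the two-way mixed-effects consistency estimator
`(BMS - EMS)/(BMS + (k-1) EMS)`; it matches an independent implementation
to machine precision. Inference: percentile bootstrap over subjects, and a
floor test of `H0: ICC <= 0.40` whose null is built parametrically by
simulating same-shape tables with population ICC exactly 0.40 (plain
session-label shuffling can only test the zero floor — an interpretation
choice, documented); BH FDR across (parameter × network) cells.

## Lifespan statistics

Group-lasso zeros are structural, so per-vertex parameters across subjects
follow a zero-inflated Gaussian: logit of the zero probability linear in
age, conditional mean quadratic in age. Because the continuous part has no
mass at 0, maximum likelihood separates exactly into a logistic fit on the
zero indicator and a Gaussian quadratic fit on the nonzero subset; the
variance is taken constant per vertex (no age model for it is imposed).
Wald 95% intervals for the inflation slope and the curvature achieve
92–98% coverage at n = 500 in the validation suite. Degenerate inputs
(all zeros / no zeros) collapse to the single-part model with a flag.

Cortical-average trajectories: robust quadratic regression (IRLS,
bisquare) reporting weighted `R^2`, Cohen's `f^2 = R^2/(1 - R^2)` and a
robust-covariance Wald p for the curvature; and penalized cubic B-spline
fits with exactly 8 basis functions (4 uniform interior knots), a
second-difference coefficient penalty, and the smoothing level chosen by
`AIC = n log(RSS/n) + 2 edf` over a fixed lambda grid. The analytic first
derivative of the spline tracks maturation rates; the zero crossing of a
planted inverted-U derivative is recovered within ±2 years at n = 500.

The myelination proxy is `1/<tau>^2` with `<tau>` the mean delay over
connected tracts (mean rather than the printed double sum — the two differ
by a subject-invariant constant under a fixed connectome support and the
mean keeps units interpretable); it is z-scored across subjects before
trajectory modeling. The probability atlas is a Nadaraya–Watson estimate:
Gaussian kernel in vertex coordinates (Silverman bandwidth by default)
applied to subject amplitude fields, normalized to a probability over
vertices per component and frequency.

## Problem sizes and reproduction

The validation experiments (`connspectra.validation`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) run at: 50 random
networks (≤30 vertices) for the power identity; a 30-vertex/19-channel
scene with 10 minutes of simulated data for spectral consistency; 50
vertices / 19 channels / 200 trials for recovery, with 20 repeated
delay-scale estimations in the test suite and 10 in the script; 20 (test)
or 12 (script) 80-vertex scenes for the montage contrast; 300 calibration
and 60 power replicates for the ICC floor test; 200 replicates at n = 500
for ZIG coverage; n = 500 for trajectories. These sizes are chosen so the
full suite completes in minutes on a single CPU while keeping Monte-Carlo
error well inside each asserted tolerance.

## Known limitations

Linear dynamics only (no nonlinear activation, no explicit thalamus);
Dirac delays (no dispersion); stationary segments only; two spectral
components (no beta/gamma); generic spherical geometry rather than
realistic head models; the BO profile search estimates two global scales,
not edge-wise structure; the spatial null for direction tests permutes
labels rather than rotating a surface. The Wilson route requires on-grid
delays, so reported causality refers to the delay-snapped model (≤2 ms
perturbation at defaults).
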