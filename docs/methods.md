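# Methods

## Physical model

A four-pulse DEER experiment on an isolated pair of electron spins at
distance r produces an echo modulation at the dipolar frequency

    nu_dd(r) = D / r^3,    D = (mu0 / 4 pi) g_e^2 mu_B^2 / h,

evaluated from CODATA constants as D = 52041 MHz·Å³ (52.04 MHz·nm³); the
point-dipole approximation with free-electron g values is used for both
the flavin semiquinone and the nitroxide. Averaging over the isotropic
powder distribution of inter-spin vector orientations gives the kernel

    K(t, r) = ∫₀¹ cos[(3x² − 1) · 2π nu_dd(r) t] dx,

the forward operator mapping a distance distribution P(r) onto the
intramolecular form factor. A full trace adds the modulation depth λ
(fraction of echo amplitude modulated by pumped partner spins) and a
stretched-exponential intermolecular background:

    V(t) = [(1 − λ) + λ (K P)(t)] · exp(−k t^(d/3)),   V(0) = 1.

Orientation selection and finite pump/observer excitation bandwidths are
deliberately ignored: pumping is treated as complete and
orientation-independent, the same assumption made by the standard
distance-reconstruction tools this package mirrors. ESEEM artifacts,
multispin effects and relaxation-induced depth changes are out of scope.

Internal units are Å, µs and MHz throughout; nm appears only in
user-facing summaries of long distances.

## Numerical evaluation of the kernel

K is evaluated through the Fresnel-integral closed form

    K = sqrt(pi / (6 phi)) [cos(phi) C(z) + sin(phi) S(z)],
    z = sqrt(6 phi / pi),  phi = 2 pi nu_dd t.

For phi < 1e-3 the prefactor and Fresnel terms cancel catastrophically,
so the code switches to 8-point Gauss–Legendre quadrature of the defining
integral; the two branches agree with brute-force quadrature (1e5 nodes)
to better than 1e-9 across the switchover. The discretized kernel matrix
folds in the rectangle-rule weight Δr, so `K @ density` of a normalized
distribution is the form factor and the t = 0 row sums any density to 1.

## Distance grids and components

The default grid spans 15–80 Å with 256 points — wide enough that the
docked (29.3 Å) and undocked (39.5 Å) components both complete more than
one dipolar oscillation on a 3 µs trace, and comfortably containing both
Gaussians. Components are truncated to the grid and renormalized;
truncation moves the component means by < 0.05 Å. A two-state mixture
combines the two *individually renormalized* components, so the mixing
fraction f equals the undocked probability mass exactly even after
truncation. All "width" parameters are Gaussian standard deviations σ,
not FWHM — this matches the ⟨R⟩/σ parameterization the component values
were quoted in, and is stated here prominently because the FWHM reading
would change the widths by 2.355×.

The packaged registry (`deermix/data/variants.json`) carries the study
conditions: docked 29.3/2.0 Å, undocked 39.5/6.7 Å, the His378 variant
undocked fractions (0.81, 0.91, 0.95 for the ASQ-forming single variants;
0.47, 0.57, 0.63 for the NSQ-forming triple variants), and iLOV as a
single broad component (44/12 Å).

## Synthetic data generator

Defaults: λ = 0.3, no background (k = 0), SNR = 50 (per-point Gaussian
noise of sd V(0)/50), traces of 256 points over 0–3 µs (0–4 µs for the
longer iLOV distance), seeds 1–10 for seed-averaged quantities. The
acquisition parameters of the original measurements were never published,
so these are this package's explicit, configurable choices — typical for
Q-band DEER on doubly labelled proteins at this concentration scale.

What the generator emulates: dipolar oscillations from one- and
two-component Gaussian mixtures, modulation depth, optional stretched
exponential background, white Gaussian noise. What it does not emulate:
orientation selection, ESEEM nuclear modulation, phase noise, drifting
baselines, exchange between sub-states, and non-Gaussian distribution
shapes. Passing recovery tests therefore demonstrates the correctness and
statistical calibration of the estimators under the stated model, not
robustness to every artifact of measured data.

## Background and noise estimation

`fit_background` fits (1 − λ) exp(−k t^(d/3)) to the final half of the
trace (d fixed, default 3). The half-trace window is a deliberate choice:
with a shorter (30 %) tail the joint (λ, k) exponential fit is nearly
degenerate at SNR 50 and the depth estimate scatters by ±0.05; the longer
lever arm recovers λ to ±0.02 at the cost of a small bias from residual
form-factor decay (< 0.01 for the broad undocked component). When a trace
carries no noise level, the sd of residuals after a 2nd-order
Savitzky–Golay smooth of the last 25 % of the trace is used.

## Truncated-SVD inversion

`tsvd_solve` inverts a background-corrected form factor by truncating the
SVD of the kernel. Rank selection uses the discrepancy principle: the
smallest rank whose reduced chi-square against the noise level is ≤ 1.1;
if no rank reaches it (e.g. noiseless input, where the noise floor is
clamped to 1e-7), the best-fitting rank is used. Nonnegativity is imposed
after truncation by clipping and renormalizing — simple and deterministic;
an NNLS option on the rank-filtered kernel exists for cross-checks. Phase
correction and zero-time determination are not implemented: synthetic
traces are ideal-phase by construction, and import of raw experimental
data is a non-goal. No Tikhonov L-curve machinery or uncertainty bands on
P(r) are provided.

## Mixture fitting and the two-state decomposition

`fit_gaussians` minimizes the noise-weighted residual with bounded
trust-region least squares (scipy `least_squares`, TRF), parameters being
component means and widths, mixture fractions, the modulation depth, an
amplitude nuisance (bounded to [0.8, 1.2] around the normalized V(0) = 1)
and optionally a background rate. Five seeded starts guard against local
minima; the winner is the lowest reduced chi-square, ties broken by the
lowest first fraction. Parameter uncertainties come from the
Jacobian-based covariance scaled by the reduced chi-square. Degenerate
requests fail loudly: identical two-state components, more parameters
than points, fractions outside the simplex.

`two_state_fit` holds both components fixed and varies only the undocked
fraction a ∈ [0, 1] (plus λ and amplitude). On the default study
conditions the estimator has |bias| < 0.01 and RMSE < 0.03 across the
fraction range, and its 1-SD interval covers the truth for ~70 % of
draws. The uncertainty-propagation method behind the originally reported
population errors was never described, so the scaled-covariance errors
here are validated for ordering and coverage only, not for equality with
any published error column. With free (unconstrained) two-component fits
on mid-fraction variants, the recovered components agree with the
generating ones within ~1.5 Å seed-averaged, but the undocked width is
weakly identified in any single trace at SNR 50: the optimizer can trade
a larger mean against a smaller width along a shallow ridge, so
single-trace component parameters should be read together with their
reported uncertainties.

`lincomb_fit` is the model-free cross-check: the target trace is fit as
c·[a·V_undocked + (1 − a)·V_docked] by nonnegative linear least squares
(exact, no iteration), with basis traces interpolated onto the target
axis. The two population routes agree within 5 percentage points on all
synthetic panels, and typically within 1.

## Determinism and problem sizes

Every stochastic step takes an explicit integer seed; the panel runner
derives per-trace seeds from one root seed and produces byte-identical
JSON reports for identical configurations. Seed-averaged quantities in
the tests and the acceptance script use 10 traces per condition, and the
calibration sweep uses 5 fractions × 20 seeds — sizes at which all
estimator checks resolve well below their tolerances while the whole
suite runs in well under a minute.
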