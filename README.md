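# deermix

Simulation, inversion and two-state population analysis of four-pulse
DEER (double electron-electron resonance) dipolar traces.

## The problem

Pulsed dipolar ESR spectroscopy measures the distance between two unpaired
electron spins — here a photoreduced flavin semiquinone radical and a
nitroxide spin label attached to the C-terminal tail (CTT) of *Drosophila*
cryptochrome. In the dark the CTT docks against the flavin pocket
(flavin–label distance ⟨R⟩ ≈ 29.3 Å, σ ≈ 2.0 Å); on blue-light
photoreduction to the anionic semiquinone the tail releases and extends by
about 1 nm (⟨R⟩ ≈ 39.5 Å, σ ≈ 6.7 Å). Variants at His378 partition
between the two conformations, and the fraction of undocked protein is the
biologically meaningful readout.

`deermix` implements the analysis chain needed to extract that fraction
from 4P-DEER time traces, and a seeded synthetic-data generator so the
whole chain is testable without measured data:

- **Forward model** (`deermix.forward`) — powder-averaged dipolar kernel
  K(t, r) = ∫₀¹ cos[(3x² − 1)·2π·D t / r³] dx (Fresnel closed form,
  D ≈ 52.04 MHz·nm³), trace simulation
  V(t) = [(1 − λ) + λ·(K·P)(t)]·exp(−k·t^(d/3)).
- **Synthetic data** (`deermix.synthetic`) — Gaussian distance components,
  two-state mixtures P(r) = (1 − f)·N(⟨R⟩_d, σ_d) + f·N(⟨R⟩_u, σ_u), a
  packaged variant registry, seeded Gaussian noise at a stated SNR.
- **Inversion** (`deermix.inversion`) — tail background/modulation-depth
  fitting and model-free P(r) recovery by truncated SVD with
  discrepancy-principle rank selection.
- **Mixture fitting** (`deermix.mixture`) — time-domain Gaussian-component
  fits, the fixed-component two-state fit for the undocked fraction *a*,
  a linear-combination cross-check on basis traces, and the reduced
  chi-square χ²_ν = 1/(N − q) Σᵢ [V(tᵢ) − F(tᵢ)]²/sᵢ² (values ≲ 2 indicate
  a good fit).
- **Pipeline** (`deermix.io`, `deermix.panel`, `deermix.cli`) — two-column
  ASCII trace files, a deterministic panel runner, and a `deermix` CLI
  with `simulate`, `fit`, `panel` and `variants` verbs.

## Worked example

Simulate a light-state wild-type trace (pure undocked component, SNR 50)
and fit a single Gaussian component with the modulation depth free:

```sh
$ deermix simulate --variant WT_light --seed 1 --out wt.dat
$ deermix fit wt.dat
     amp =  1.0056 +/- 0.0074
 bg_rate =  0.0000 +/- 0.0000
  lambda =  0.3061 +/- 0.0053
   mean1 =  39.2597 +/- 0.3590
  sigma1 =  6.8518 +/- 0.3923
chi2_nu  = 0.840  (q = 4)
```

The fitted mean distance (39.26 ± 0.36 Å) and width (6.85 ± 0.39 Å)
recover the generating undocked component (39.5 Å / 6.7 Å) within one
standard error, and χ²_ν < 2 marks the fit as good.

Run the six-variant His378 panel (10 noisy traces per variant, fixed
docked/undocked components, only the population fitted):

```sh
$ deermix panel table_config.json --out-dir report/
      variant radical  n_traces  pct_undocked  pct_undocked_sd  pct_undocked_lincomb  chi2_nu  fraction_generating
  H378R_light     ASQ        10     79.416275         2.701445             80.143163 0.985737                 0.81
  H378K_light     ASQ        10     89.330543         2.886972             90.154218 0.985737                 0.91
  H378N_light     ASQ        10     93.296248         2.963990             94.158640 0.985737                 0.95
H378R_EN_dark     NSQ        10     45.707765         2.175419             46.105575 0.985737                 0.47
H378K_EN_dark     NSQ        10     55.622033         2.309327             56.116630 0.985737                 0.57
H378N_EN_dark     NSQ        10     61.570593         2.398938             62.123263 0.985737                 0.63
```

with `table_config.json` listing the variant names (all other settings
default). `pct_undocked` is the seed-averaged two-state estimate; it
tracks the generating fraction within ~1.5 percentage points, and the
independent linear-combination estimate (`pct_undocked_lincomb`) agrees
within 1 point.

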