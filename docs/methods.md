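# Methods

## The model

`rootmech` implements a one-parameter constitutive model for the pre-peak
tensile response of a single root. Normalising strain and stress by their
values at the peak, x = ε/ε_p and y = σ/σ_p, the model is the unique
two-term linear-plus-power curve

    y(x) = E·x − (E − 1)·x^(E/(E−1)),        0 ≤ x ≤ 1,

satisfying the four boundary conditions observed in typical single-root
tensile tests:

1. y(0) = 0 — the curve passes through the origin;
2. y′(0) = E — the initial slope equals the dimensionless elastic modulus;
3. y(1) = 1 — peak stress occurs at peak strain;
4. y′(1) = 0 — the slope vanishes at the peak.

Here E = E₀/E_p > 1 is the **dimensionless elastic modulus**: the ratio of
the linear elastic modulus E₀ (secant slope in the near-linear regime, MPa)
to the peak secant modulus E_p = σ_p/ε_p (MPa). Starting from the general
ansatz y = a·x + b·x^c + d, the boundary conditions force d = 0, a = E,
b = 1 − E and c = E/(E − 1); the test suite re-derives this numerically from
the boundary-condition system as an independent oracle. The second
derivative,

    y″(x) = −(E/(E−1))·x^((2−E)/(E−1)),

is strictly negative on (0, 1] for every E > 1, so the curve is concave
down for all admissible specimens — including those with E < 1.5, which a
cubic-polynomial ansatz could not accommodate. For E > 2 the curvature
diverges at the origin; x = 0 is therefore excluded from `curvature`'s
domain rather than mapped to a sentinel. As E → 1⁺ the model tends to pure
linear elasticity y = x; since the model requires E > 1 strictly, values of
E ≤ 1 + 1e−9 are rejected rather than switched to the limit form.

The model ends at x = 1 by construction. Post-peak softening (necking, seen
in a minority of tests) and rate dependence are out of scope; x = 1 marks
the strain at peak stress, not necessarily the largest strain recorded.

## Parameter estimation

Given a sampled stress–strain curve, `fit_curve` proceeds as the original
measurement pipeline does:

- **Peak.** σ_p is the maximum stress; ε_p the strain at the *first* index
  attaining it, so necking tails cannot shift the peak.
- **E₀.** The secant modulus at a stress fraction q of the peak (default
  q = 0.4, applied uniformly across species but configurable): the first
  pre-peak crossing of q·σ_p is located by linear interpolation between the
  bracketing samples, giving ε_q, and E₀ = q·σ_p/ε_q. Interpolating makes
  the estimate grid-independent; taking the first monotone crossing guards
  against noise-induced multiple crossings.
- **E_p and E.** E_p = σ_p/ε_p and E = E₀/E_p. A curve whose estimate does
  not exceed 1 (convex or purely linear) is flagged invalid with its
  diagnostics retained.
- **Critical point.** x_e solves y(x_e, E) = q by bisection (tolerance
  1e−10, at most 200 iterations — derivative-free so the contract holds for
  E arbitrarily close to 1). A data-based alternative, the strain ratio at
  the interpolated crossing (`x_e_data`), is reported alongside for
  comparison.
- **Residuals.** On the dimensionless scale, over pre-peak points only:
  r_i = y_i − y(x_i, E). We report the mean of |r_i| (published per-group
  residual summaries are all positive, which a signed mean of a fitted
  curve would not be) and the unbiased (n−1) sample variance; the `ddof`
  is exposed because the convention is not fixed by the source material.

**Self-consistency bias.** Because y(x) ≤ E·x with equality only at the
origin, the secant at any q > 0 underestimates the initial tangent: on
noiseless model data the estimator converges to q/x_q(E_true) < E_true.
`plug_in_modulus_ratio` computes this plug-in limit, which is the correct
reference when validating the estimator on synthetic data. A corollary is
that refitting residuals against the *estimated* E are strictly positive
even for noise-free model curves (for E_true = 2 the mean absolute residual
is ≈ 0.015, comparable to published per-group values); residuals vanish
identically only against the generating modulus. The pipeline does not
least-squares-refit E to the whole curve — E is fixed by the two moduli by
design.

## Units and I/O

Traces are (displacement mm, force N) pairs from a universal tester,
comma-delimited with a header (dialect configurable; export formats vary by
instrument). Engineering stress uses the nominal initial diameter,
σ = 4F/(πd²) (MPa), and strain is elongation over the gauge length,
ε = Δl/L₀, with L₀ = 50 mm by default — the standardised grip spacing.
Percentages in sample-accounting tables are rounded half-up to 2 decimals;
two aggregate conventions are reported because pooled datasets use the
ratio of summed counts while per-gauge columns use the mean of per-class
percentages.

## Synthetic data generator

The generator uses the model itself as the kernel: a uniform strain grid on
[0, ε_p] (default 200 points, a typical effective sampling density for a
tensile pull at these strains), model stress at each strain, then noise.

- **Noise model.** Multiplicative Gaussian on stress, default relative SD
  0.005 — load-cell error scales with load and the relevant tester class is
  rated at ±0.5 % of reading. An additive variant (SD expressed in units of
  σ_p) is exposed.
- **Peak convention.** The exact peak sample (ε_p, σ_p) is always included
  noise-free, and every other sample is capped strictly below σ_p. Near the
  peak the curve is flat, so uncapped noise would routinely push samples
  above σ_p and migrate the detected peak (at 1 % noise this inflates E_p
  by ≈ 6 %); the cap keeps the peak exactly identifiable so estimator bias
  can be studied separately from peak-detection error. This is a generator
  convention, not a claim about real data: on laboratory curves the
  detected peak is itself noisy.
- **Necking mode.** Optionally appends a post-peak tail extending strain to
  ε_p·(1 + tail_fraction) at stresses held strictly below σ_p (a 5 % linear
  decay plus noise). Only the tail's existence matters — it exercises the
  truncation rules — and pre-peak samples are bit-identical across modes
  for a given seed.
- **Determinism.** One `numpy` Generator per curve, seeded from the config;
  replicate r of configuration i in `recovery_experiment` uses seed
  `seed + 100000·i + r`.
- **Presets.** The twelve published (species, diameter) groups ship as
  parameter presets with their E₀ and E_p values. Their peak stress and
  strain were not published, so presets adopt σ_p = 30 MPa with
  ε_p = σ_p/E_p — an arbitrary dimensional scale that leaves every
  dimensionless quantity unchanged.

What passing tests on synthetic data do **not** show: real root curves
deviate from the model family (that is what the residual columns measure),
their peaks are noisy, diameters vary along the specimen, and grip slippage
or early breakage produce artefacts the generator does not emulate.
Synthetic validation establishes the pipeline's correctness and its
inherent estimator bias, not field accuracy.

## Numerical choices and degenerate inputs

- Boundary comparisons use absolute tolerance 1e−12; interior comparisons
  1e−9; inversion 1e−10.
- Strictly: `E ≤ 1 + 1e−9`, non-positive geometry, all-zero stress series,
  and unbracketed secant crossings (first sample already above q·σ_p) are
  errors, not silent fallbacks.
- Ties at the peak break to the first attaining index.
- For E near 1 the curvature magnitude underflows to zero at small x even
  though it is analytically negative; concavity checks sample x bounded
  away from 0.

## Known limitations

- The model is pre-peak only; fitted results say nothing about post-peak
  energy absorption.
- The secant-at-q estimator's first-crossing rule interacts with noise:
  denser sampling raises the chance of a noise-induced early crossing, so
  its RMSE against the plug-in reference is not monotone in the number of
  samples at high noise (it is at instrument-level noise).
- The published per-group critical-point values around 0.55–0.63 are not
  reproduced by y(x_e) = q under this model (which yields ≈ 0.40–0.43 for
  the published moduli); the package reports both the model-based and the
  data-based critical point so users can compare conventions.
- q = 0.4 is a species-independent convention carried over from work on
  *Pinus tabulaeformis*; whether it transfers across species is untested
  here, which is why it is a parameter.
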