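# Methods

## Field model

In the sensing volume the coil fields are source-free, so each field is the
gradient of a harmonic scalar potential and is expanded in gradients of
regular real solid harmonics,

    B(r) = Σ_{l=1}^{lmax} Σ_{m=-l}^{l} β_lm w_lm(r),
    w_lm(r) = ∇( r^l Y_lm(θ, φ) ) / N_l .

The `Y_lm` are real, orthonormal over the unit sphere, without the
Condon–Shortley phase; θ is the polar angle from +z and φ the azimuth from
+x. Components are ordered by degree `l` ascending and order `m` from `-l`
to `l`, giving `C = lmax(lmax+2)` coefficients (35 at the default
`lmax = 5`). Degree-1 basis fields are exactly the Cartesian unit fields
(ŷ, ẑ, x̂ for m = −1, 0, 1); degree-2 fields are the five independent
first-order gradients.

Each Cartesian component of `w_lm` is a homogeneous polynomial of degree
`l − 1`. The polynomials are generated symbolically once per `lmax`
(associated-Legendre body times `Re/Im[(x+iy)^m]`), differentiated exactly,
and cached as monomial tables, so evaluation is a single matrix product and
the divergence- and curl-free constraints hold to machine precision. The
basis agrees with the external signal-space-separation basis used in MEG
preprocessing up to the (irrelevant) per-component scaling; a test verifies
that the two span the same column space.

**Normalization.** Every basis field is scaled to unit RMS magnitude over a
reference sphere (default radius 0.1 m, the scale of the sensor-array
region). For orthonormal `Y_lm` the constant is analytic,
`N_l = R^{l−1} √(l(2l+1)/4π)`. All estimators below involve only
pseudo-inverses of matrices whose columns are fixed per-component rescalings
of one another under a change of normalization, so the estimated sensor
parameters are invariant to this convention (a gauge-consistency test
refits the same data under two reference radii and checks the estimates
agree). Coefficients carry units of tesla — or T/A when fitted from
per-unit-current maps.

## Fitting and synthesis

Coefficients are the least-squares solution `β = S⁺ m` of the basis design
matrix against the stacked field map (triaxial vectors by default;
single-axis projected rows are also supported). The pseudo-inverse uses an
SVD with relative singular-value cutoff 1e-10; numerical rank below `C`
raises a warning carrying the achieved rank. The expansion origin defaults
to the centroid of the mapping positions, which places the zero crossings
of the gradient fields inside the mapped volume. Fit quality is the RMS
residual over all scalar components divided by the RMS of the data (NRMSE).

Currents that excite a target coefficient vector are `i = B⁺ β̃` with
`B = [β_1 … β_N]` (minimum-norm among exact solutions). Diagnostics report
the condition number and rank of `B` — optionally restricted to degrees
≤ 2 — and the achieved/requested ratio per component; ratios below 0.5
(heuristic, configurable) trigger a warning. An optional uniform-step
current quantizer emulates DAC bit resolution; it is off by default and in
every pipeline.

## Calibration

The channel forward model is `b_i = g B_i(r)·n`. The pipeline:

1. **Linear stage.** From the three synthesized homogeneous fields,
   `g n = H⁺ b_H` where row i of `H` is the *achieved* uniform part of the
   superposed model (extracted from the fitted models, not the requested
   target). From the five gradient fields, `r = G⁺(b_G − H_G g n)` where
   row i of `G` is `(gn)ᵀ G_i` — the first-order Taylor expansion of the
   forward model about the origin — with `G_i` the model's gradient tensor
   and `H_G` its homogeneous part. Rank below 3 in either system (e.g.
   only diagonal gradients available, which span just two independent
   components) raises an explicit error.
2. **Fine-tune.** Nelder–Mead minimization of the SSE against the full
   `lmax = 5` models of the eight superposed fields jointly.
3. **Final.** The same minimization against the individually driven coils,
   each per-ampere model scaled by its drive current.

The optimizer parametrizes a channel as the 6-vector `(r, g n)` — no unit
norm constraint — and a dual-axis sensor jointly as the 9-vector
`(r, g_x n_x, g_y n_y)` with a shared position. Variables are scaled by
5 mm and 5% of |g n|, which also sets the initial simplex; the start point
is a simplex vertex, so the result never has a larger objective than the
initialization. Tolerances: relative objective 1e-10, scaled parameters
1e-8, at most 5000 iterations (best-so-far returned with a flag on
non-convergence). Positions are reported relative to the VSH origin; a
warning is emitted if a refined position leaves the fitted models' validity
sphere (the largest mapped radius).

Whether the fine-tune uses the eight superposed responses jointly or
sequentially was an open choice; they are used jointly (one objective, all
eight residuals), which is the natural SSE formulation.

## Dipole localization

Phantom sources are ideal point magnetic dipoles,
`B = μ0/4π · [3(m·r̂)r̂ − m]/d³`, with a 1-mm singularity guard. Because
the forward amplitudes are linear in the moment, fitting is separable: at
every candidate position the moment is solved by 3-parameter least squares
and the residual scored. Stage 1 scans a uniform grid (default 5-mm
spacing in a 12 × 12 × 6 cm box below the array; ties broken by first
index); stage 2 refines the best node's position with Nelder–Mead,
re-solving the moment at each evaluation. The grid extent and spacing are
package choices — fine enough that every dipole has a node within half a
spacing, coarse enough to keep the scan a single vectorized lead-field
evaluation. Channels are pre-filtered by the maximum normalized
cross-correlation with the excitation reference over lags within ± one
reference period; channels below 0.9 are discarded (in hardware such
channels suffer phase errors from cross-axis response; the reference is
taken to be the excitation current waveform).

Estimated positions are compared to reference positions after a unit-scale
rigid Umeyama alignment (closed form, reflections disallowed), i.e. the
score is relative geometry, matching how sensor and phantom positions are
compared against CAD references in practice. Correspondences are by index;
no matching problem is solved.

## Synthetic scenarios

The simulator emulates a person-sized cylindrical shield with 16
rectangular coils (8 azimuths × 2 height rows, tangent to a 0.85-m
cylinder) and 2 circular end coils, one coil flagged with a broken
connector so 17 are usable. True coil dimensions and placements of the
emulated hardware are not published; these are plausible inventions chosen
so that the arrangement surrounds the array region and spans the eight
degree-≤2 components — the same design requirement the physical coil set
satisfies. Ground-truth fields are exact finite-segment Biot–Savart sums
(the robust `(r1×r2)(|r1|+|r2|) / (|r1||r2|(|r1||r2|+r1·r2))` form);
circular loops are 72-segment polygons.

The field maps sample a 6 × 6 × 3 lattice over the 0.2-m array region —
108 triaxial locations, 324 scalar samples per coil — and are noiseless
(the mapping sensor is treated as exact). Fluxgate mode provides 18
single-axis channels: six probe placements, each a triad of orthogonal
channels spaced 2 cm along the probe axis, gains 0.1 V/µT with 0.5%
scatter and ±0.5° orthogonality perturbation. OPM mode provides 48
channels: six sensors × four channels in a flat patch, two tangential
orientations per position with ~1° non-orthogonality, gains 2.7 V/nT with
5% scatter, plus a phantom of nine 140-nAm² dipoles with seeded random
moment directions 3–6 cm below the array.

Excitations are 20-Hz sinusoids sampled at 1 kHz in 1-s blocks; drive
currents are rescaled so the peak mapped field is 12.5 nT (fluxgate) or
0.5 nT (OPM; a ±1-nT linear-range clip guards the OPM response). Responses
carry white Gaussian noise. The SNR is the controlled quantity — the ratio
of the maximum lock-in amplitude to the lock-in amplitude error, default
1900 (fluxgate) and 1e4 (OPM) — realized by setting the time-series noise
to `σ_t = σ_A √(N/2)`; the corresponding noise density is `σ_t √(2/fs)`.
Amplitudes are read out by complex demodulation over an integer number of
reference periods (`2/N Σ v e^{−i2πf0t}`; exact for a pure sinusoid,
DC-invariant). All randomness derives from the scenario seed, with each
stage drawing from a (seed, stage-index) generator so reruns are
byte-identical.

**What the generator does not emulate** — and what passing tests therefore
do not establish about hardware: mapping-sensor errors and drift, coil
non-idealities and shield polarization (fields are exactly Biot–Savart),
amplitude nonlinearity between the fluxgate and OPM drive regimes, OPM
cross-axis projection errors and phase offsets (the correlation filter is
exercised but rejects nothing in clean simulations), DAC quantization of
the synthesized currents, and any geometric mismatch between a CAD
reference and the magnetic channel center. The synthetic studies bound
what the *method* contributes to the error budget at a given SNR, not what
a physical system will achieve.

## Validation studies

The acceptance script and tests run two studies end to end at the default
conditions: (i) fluxgate validation — 18 channels calibrated through the
full pipeline at amplitude SNR ~1900, RMS position/orientation/gain errors
averaged over ten seeded runs; (ii) phantom validation — the 48-channel
array jointly calibrated at SNR ~1e4, then the nine dipoles localized with
the calibrated (not true) parameters, mean position error over five runs;
plus the worst-case NRMSE of the `lmax = 5` fits across all 18 coils.
Problem sizes (10 and 5 repetitions, 1-s blocks) keep each study to a
couple of minutes on one CPU while leaving the Monte-Carlo means stable to
a few percent.

## Known limitations

* The linear stage assumes the synthesized fields are dominantly
  degree ≤ 2; with strong higher-order content it is only a first-order
  initialization (the refinement stages correct this, as the noiseless
  stage-shrink test demonstrates).
* In the idealized noise-limited setting the noisy *position* error is
  statistically flat between the linear and final stages — the synthesized
  gradients already encode position near-optimally — while orientation and
  gain improve; on hardware, systematic model errors make the refinement
  matter more.
* Nelder–Mead is local; it relies on the linear stage landing in the
  correct basin. Poorly conditioned coil arrangements (see the synthesis
  diagnostics) can defeat it.
* Time series are simulated at the amplitude level (sinusoid + white
  noise); colored noise, drift and interference are out of scope.
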