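# Methods

## Degradation model

Protein stability is treated with the two-state picture
native ⇌ unfolded → irreversibly lost. Once the folding/unfolding
reaction is at equilibrium the overall loss of assay-detectable protein
is pseudo-first order, `ln N(t) = ln N₀ − k·t`, so `k` is estimated as
the negative slope of an OLS fit of `ln C` on `t` and `t½ = ln 2 / k`.

Freshly reconstituted protein is not at equilibrium: the first hours show
a faster apparent loss. This is handled purely through the fit window —
default 8–96 h, inclusive on both ends — rather than by fitting a
multi-exponential model. Fits are per replicate and then aggregated
(mean, sample SD with n−1); a fit-of-the-mean-curve mode exists behind an
explicit flag for comparison but is not the default, because averaging
before the log transform biases the slope under multiplicative noise.

Degenerate inputs are reported, not hidden: a flat window yields `k = 0`,
`r² = 0` and an infinite-half-life sentinel; a growing signal yields
`k < 0` with a `positive_slope` flag and the same sentinel. Aggregation
refuses infinite half-lives by name so a bad replicate is an explicit
decision, not a silent drop. Aliquots in the degradation assay are taken
without volume replacement; the shrinking well volume is ignored because
the model is concentration-based — an assumption, stated here.

All kinetics are in hours, ng/mL, mL and cm²; day-unit columns are
converted at the I/O boundary.

## Release correction and power-law fit

Each sampling-with-replacement aliquot reflects only the interval since
the previous sampling, and protein released at time `s` inside the
interval decays for `t_i − s` before collection. Under a constant
within-interval release rate the attenuation integrates exactly to
`(1 − e^{−kΔt})/(kΔt)`, so the correction multiplies each measured
amount by `kΔt/(1 − e^{−kΔt})`. This factor is ≥ 1, continuous at
`k = 0` (handled as the analytic limit, not a division), and approaches
`kΔt` for long intervals. The cruder midpoint variant `e^{kΔt/2}` is
available behind a flag for sensitivity analysis; it agrees to first
order for small `kΔt`.

The default correction half-life is 22.75 h — the ELISA-detectable FGF2
half-life in PBS at the higher assay concentration, chosen for its low
relative standard deviation — and is always overridable, including with
a freshly fitted value when the pipeline runs end to end.

The corrected cumulative curve is fitted to `M_t/M_∞ = K·tⁿ` by OLS of
`ln(M_t/M_∞)` on `ln t` (t = 0 is excluded by construction; zero-release
points are log-undefined and dropped). `M_∞` is the final corrected
cumulative release plus the acid–base wash recovery, so the fitted
fractions are ≤ 1 by construction for self-consistent inputs; a fraction
above 1 raises an error rather than clamping. A nonlinear least-squares
mode on the untransformed fractions is available behind a flag, seeded
from the log–log estimate, since either convention is defensible.
Replicates are corrected and fitted independently and condition-level
constants reported as mean ± SD.

## Concentration simulation

The well concentration under an eluting source solves
`dC/dt = R′(t)/V − k·C` with `R(t) = A·M_∞·min(1, K·tⁿ)` the cumulative
mass released into the well (source normalized per cm² of its study
substrate, then scaled by the coated area `A`; default geometry
1.9 cm² under 0.6 mL). The discretization is an exponential integrator:

    C_{i+1} = C_i·e^{−kΔt} + (ΔR_i/V)·e^{−kΔt/2}

with `ΔR_i` the release increment over the step, decayed for half a step
(midpoint rule). The scheme is unconditionally stable, second-order
accurate, and absorbs the `n < 1` power law's infinite initial rate
because increments are finite. Default `dt = 0.05 h`; at that step the
profile agrees with a high-resolution quadrature of the convolution
integral to about 0.01% and halving the step changes it by under 0.01%,
comfortably inside the 0.1% convergence budget the tests enforce.

Bolus dosing needs no integration: between doses
`C(t) = C(t_d⁺)·e^{−k(t−t_d)}`, and each dose is an instantaneous,
volume-preserving concentration jump. Both one-sided values at a dose
time are stored; tables read the pre-dose (trough) value by convention.
Superposition across schedules holds exactly (the ODE is linear) and is
asserted in tests. No media-replacement events are modeled in the
default 4-day run, matching supplementation without total media
replacement; a media change can be represented by composing profiles.

Reported tables round half-up to 2 decimals only at the render layer;
data outputs keep full precision. `population_doublings` is the log2
ratio of two cell counts.

## QCM-D

The Sauerbrey relation for rigid films is implemented in its standard
dimensional form `Δm = −C·Δf/n` with `C = 17.7 ng cm⁻² Hz⁻¹` for 5 MHz
sensors and `n` the (odd) overtone, default 3 — the overtone that best
reflects the bulk film. (The relation is sometimes typeset with `nΔf` in
a denominator; that form is dimensionally inconsistent with `C` in
ng cm⁻² Hz⁻¹ and is not what is computed here.)

End-of-step masses are taken as the mean Sauerbrey mass over the final
30 s of each wash step — noise-robust compared to a single last sample;
the window is configurable. Increments telescope exactly to the final
mass, and a wash that strips below the previous plateau yields a
negative increment rather than an error, since stripping is a real
regime of layer-by-layer assembly near neutral pH.

Rigidity is screened, not modeled: the ratio `ΔD/(−Δf/n)` must be stable
across overtones (relative spread below 20%) and small (below
0.4×10⁻⁶ per Hz). The result is advisory; no viscoelastic modeling is
attempted.

## Synthetic data

The generators produce data with exactly the statistical structure the
analysis assumes, with known ground truth:

- **Degradation assay** — `c(t) = c₀[(1−b)e^{−kt} + b·e^{−k_burst t}]`:
  a second, faster exponential is the simplest mechanism that reproduces
  a non-first-order early phase while leaving the 8–96 h window clean
  (defaults: c₀ = 500 ng/mL, t½ = 22.75 h, b = 0.3, k_burst = 0.5 h⁻¹ —
  the burst is below 0.6% of signal by 8 h). Sampling grid
  {1, 2, 4, 8, 24, 48, 72, 96} h: a 1 h first point and a 4-day span are
  the study design; the intermediate points are a plausible choice and
  are recorded in output metadata. 5 replicates at 10% CV.
- **Release study** — true cumulative `M_∞·K·tⁿ` differenced on the
  sampling grid {1, 4, 8, 24, 48, 72, 96} h; measured aliquots are
  attenuated by the same within-interval factor the correction inverts;
  wash recovery is `M_∞(1 − K·t_lastⁿ)`, noiseless. Defaults
  (K = 0.105, n = 0.3, M_∞ = 11.41 ng on 1 cm² in 1 mL) emulate the
  most-releasing coating condition: ≈4.7 ng released over 4 days with
  ≈6.7 ng left for the wash.
- **QCM-D trace** — programmed plateau masses with exponential approach
  (τ = 2 min) during 15 min adsorption steps, 10 min washes, Sauerbrey
  frequency shifts per odd overtone 3–13 plus white noise, and a
  rigid-film dissipation signature.

Noise is multiplicative lognormal parameterized by CV (concentrations
are positive and immunoassay error roughly proportional to signal),
normalized to unit mean; an additive-Gaussian mode exists behind a flag.
Replicate noise is single-level: within-plate vs between-vial structure
of real assays is not emulated, so passing recovery tests demonstrates
estimator correctness under the assumed noise model, not robustness to
hierarchical assay error. Generators are pure functions of (spec, seed).

## Problem sizes and checks

The test suite runs the parameter-recovery experiment at 5 replicates ×
8 time points × 10 seeds, the noise-monotonicity check at 20 seeds × 4
CV levels, and the simulator validation on a 96 h horizon at dt = 0.05 h
against `scipy.integrate.quad` applied to the integration-by-parts form
`C(t) = [R(t) − k∫₀ᵗ R(s)e^{−k(t−s)}ds]/V`, which avoids the integrable
singularity of `R′`. These sizes keep the full suite around a second
while leaving the statistical assertions well-powered.

## Known limitations

- The degradation correction assumes a constant release rate within each
  interval; for intervals much longer than the half-life the factor
  approaches `kΔt` and amplifies aliquot noise proportionally.
- `M_∞` from cumulative-plus-wash is itself an estimate; errors in the
  wash recovery shift `K` (not `n`) in the log–log fit.
- The simulator has no sink terms (cell uptake, receptor binding,
  adsorption to plasticware) and no media-change events by default.
- The Sauerbrey route is invalid for soft films; the rigidity screen
  flags but does not correct viscoelasticity.
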