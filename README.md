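# gfelute

Kinetic modeling of growth-factor release and degradation in cell culture.

Growth-factor–eluting coatings (for example polyelectrolyte multilayers
loaded with basic fibroblast growth factor, FGF2) are widely used to
improve cell outcomes, but the concentration a cell actually experiences
is rarely known: the protein degrades while it is being released, so
neither the release study nor the dosing schedule alone gives the
real-time concentration. `gfelute` is a small toolkit for practitioners
who run ELISA-based stability and release studies and want defensible
concentration-versus-time curves out of them.

## What it computes

**First-order half-life from ELISA timecourses.** At folding/unfolding
equilibrium, loss of immunoassay-detectable protein is pseudo-first
order, `ln N(t) = ln N₀ − k·t`. `fit_first_order` fits `ln C` vs `t` by
OLS per replicate inside an equilibration-aware window (default 8–96 h,
excluding the early burst phase), and `summarize_fits` reports the
condition mean ± SD of `t½ = ln 2 / k`.

**Degradation-corrected release.** In a sampling-with-replacement release
study each aliquot measures only the release since the previous sampling,
attenuated by within-interval degradation. Assuming a constant release
rate within the interval, the exact inflation factor is
`k·Δt / (1 − e^{−k·Δt})`; `degradation_correct` applies it per interval
and accumulates the true release curve.

**Power-law (Korsmeyer–Peppas) release kinetics.** The corrected
cumulative curve is fitted to `M_t / M_∞ = K·tⁿ` by log–log OLS, with
`M_∞` taken as the final cumulative release plus the protein recovered by
an acid–base wash of the substrate.

**Well-concentration simulation.** `simulate_eluting` couples the fitted
release law with first-order degradation,
`C(t) = (1/V)·∫₀ᵗ R′(s)·e^{−k(t−s)} ds`, via an exponential-integrator
scheme; `simulate_exogenous` solves bolus-dosing schedules in closed
form, retaining pre- and post-dose values at each dose time.

**QCM-D layer masses.** Frequency shifts of a quartz crystal
microbalance are converted to areal mass with the Sauerbrey relation
`Δm = −C·Δf/n` (C = 17.7 ng cm⁻² Hz⁻¹ for 5 MHz sensors), with a
rigidity screen and per-layer mass increments for layer-by-layer
assembly.

A synthetic-data module generates degradation assays, release studies and
QCM-D traces with known ground truth, so the whole pipeline is testable
without any experimental download.

## Worked example

```python
import gfelute as g

k = g.rate_from_half_life(22.75)          # 0.030468 per hour
system = g.CultureSystem(surface_area=1.9, media_volume=0.6)
cfg = g.SimulationConfig(k=k, t_end=96.0, dt=0.05)

doses = [g.DoseEvent(0.0, 16.0), g.DoseEvent(48.0, 16.0)]
profile = g.simulate_exogenous(doses, system, cfg)
print(round(profile.value_at(48.0, side="pre"), 2))   # 3.71
print(round(profile.value_at(48.0, side="post"), 2))  # 19.71
```

A 16 ng/mL supplement added at day 0 and day 2 decays to a trough of
3.71 ng/mL just before the second dose and peaks at 19.71 ng/mL just
after it — a five-fold swing that an eluting coating avoids.

The numbered scripts under `analysis/` run the full synthetic workflow
(generate assay → fit half-life → correct release and fit the power law →
simulate concentration profiles → QCM-D layer masses) and write their
tables under `results/analysis/`. For example `analysis/02_fit_half_life.py`
prints:

```
mean half-life 23.14 ± 0.85 h (truth 22.75 h, n = 5)
```

and `analysis/04_concentration_profiles.py` reports the eluting coating
holding 2.35–6.05 ng/mL after the first hour while the bolus schedules
swing between their troughs and peaks.

The same stages are available from the shell via the `gfelute` console
script (`fit-halflife`, `correct-release`, `fit-powerlaw`, `simulate`,
`dose-table`, `qcmd-mass`, `gen-synthetic`, `run`).

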