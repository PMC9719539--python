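# tgtquant

Quantitative analysis of **tension gauge tether (TGT)** rupture imaging and
integrin mechanics.

A TGT is a surface-anchored DNA duplex linking an adhesion ligand to the
substrate. It ruptures irreversibly when the force transmitted through a
single receptor–ligand bond exceeds its tension tolerance `T_tol` (~12 pN in
unzipping geometry up to ~54 pN in shear). In the quenched variant (qTGT),
rupture separates a fluorophore from its quencher, so **each rupture turns on
exactly one fluorophore**: a time-lapse TIRF movie of a spreading cell becomes
a countable record of every high-force event a cell transmitted through
single integrins. This package turns such movies — and the companion RICM,
nucleus-tracking, actin-flow and Fab-exchange measurements — into calibrated,
drift-corrected molecule counts and biophysical parameters.

It is written for single-molecule biophysicists and mechanobiologists who
want an inspectable, fully tested reimplementation of this analysis that runs
end to end on synthetic data with known ground truth.

## What it computes

**Single-fluorophore calibration** (`tgtquant.calibration`). The integrated
intensity `I1` of one fluorophore, estimated from stepwise
photobleaching/binding traces by exact penalized change-point segmentation;
`I1` divides integrated signal to give molecule counts. At least 40 step
events are required per calibration.

**Rupture mapping** (`tgtquant.rupture`). Fiducial-marker drift tracking and
sub-pixel registration; pixelwise turn-on increments with a temporal median
filter (window N = 3) against defocus transients; cumulative molecule-count
maps `counts = ΔI / I1`; ray-normalized radial rupture-density profiles; and
per-cell rupture-rate time series (cells above 200,000 cumulative ruptures
are excluded from rate summaries).

**Morphology and motility** (`tgtquant.morphology`). RICM segmentation of
close-contact footprints (enclosed area, second-moment aspect ratio), spread
classification, nucleus blob tracking with greedy nearest-neighbor linking,
and ensemble MSD power-law fits `MSD = A·τ^α` (α ≈ 1.7 for directed
migration, α = 1 for diffusive motion).

**Flow and Fab kinetics** (`tgtquant.kinetics`). Actin retrograde-flow speed
from linear fits to kymograph ridges; mono-exponential Fab binding/washout
kinetics (`k_obs = k_on·C + k_off`); bound-Fab (activated-integrin) counting
against the same `I1` contract; and the derived ruptures-per-activated-
integrin-per-minute statistic.

**Closed-form models** (`tgtquant.biophys`):

- de Gennes duplex tension tolerance
  `T_tol = 2 f_c [κ⁻¹ tanh(κ l / 2)]` with `f_c = 3.9 pN`, `κ⁻¹ = 6.8 bp`;
- two-state bent-closed (BC) ↔ extended-open (EO) integrin activation under
  force, `p_EO = 1 / (1 + exp((ΔG − F·Δx)/kT))`, and its exact inverse
  `F = (ΔG + kT·ln(p/(1−p)))/Δx` with ΔG ≈ 2.5–4 kcal/mol, Δx ≈ 14.5 nm;
- Fab-competition occupancy `P_unbound = 1/(1 + Σᵢ Cᵢ/K_d,i)` (a literal
  per-Fab-sum variant is available behind `mode="as_printed"`).

**Synthetic data** (`tgtquant.synth`). Seeded generators for every input:
turn-on rupture stacks with growing cell footprints, drifting fiducials and a
Poisson+read-noise camera; bleaching-step traces; RICM images; kymographs;
fractional-Brownian-motion nucleus tracks; Fab wash traces — all with
serialized ground truth.

## Worked example

```python
import numpy as np
from scipy import ndimage
import tgtquant as tq

params = tq.AcquisitionParams(seed=1)
scenario = tq.SpreadingScenario(n_events=500)   # circular cell, edge-streak hazard
stack, truth = tq.simulate_rupture_stack(params, scenario)

traces, _ = tq.simulate_bleaching_traces(60, params, noise_sd=25.0)
calib = tq.calibrate_traces(traces)

drift = tq.track_fiducials(stack)
registered = tq.register_stack(stack, drift)

roi = ndimage.binary_dilation(truth.footprint_mask_series[-1], iterations=2)
rmap = tq.cumulative_rupture_map(registered, calib, roi)
rates = tq.rupture_rate_timeseries(registered, calib, [roi])

model = tq.TwoStateIntegrinModel(delta_G=2.5)

print(f"I1 = {calib.single_fluor_intensity:.1f} counts from "
      f"{calib.n_events} steps (CV {calib.dispersion:.3f})")
print(f"fiducial tracking residual = {drift.residual:.3f} px")
print(f"total ruptures = {rmap.total_count:.1f} molecules "
      f"(ground truth: {len(truth.rupture_events)})")
print(f"peak rupture rate = {rates.mean.max():.1f} molecules/min")
print(f"F(50% EO, dG = 2.5 kcal/mol) = {tq.force_for_occupancy(model, 0.5):.1f} pN")
print(f"T_tol(18 bp shear duplex) = "
      f"{tq.degennes_tension_tolerance(tq.TGTGeometry(18)):.1f} pN")
```

Output:

```
I1 = 799.6 counts from 60 steps (CV 0.008)
fiducial tracking residual = 0.014 px
total ruptures = 491.8 molecules (ground truth: 500)
peak rupture rate = 15.7 molecules/min
F(50% EO, dG = 2.5 kcal/mol) = 1.2 pN
T_tol(18 bp shear duplex) = 46.0 pN
```

Reading: the calibration recovered the generator's single-fluorophore
intensity (800 counts) to 0.05%; after drift correction the 500 simulated
rupture events were counted to within 1.6%; a 1.2 pN force suffices to hold
half of a ΔG = 2.5 kcal/mol integrin population in the extended-open state;
and an 18-bp duplex loaded in shear tolerates ~46 pN.

## Command line

Every stage is a subcommand of `tgtquant`:

```bash
tgtquant simulate --out run/ --seed 1
tgtquant calibrate --traces run/traces.csv --out run/calibration.json
tgtquant map-ruptures --stack run/stack.tif --calibration run/calibration.json --out run/
tgtquant morphology --ricm run/ricm.tif --pixel-size 0.16 --out run/morph.csv
tgtquant motility --tracks run/tracks.csv --out run/msd.json
tgtquant flow --kymograph kymo.tif --pixel-size 0.16 --frame-interval 3 --out flow.json
tgtquant models --out models.csv
tgtquant run --config config.yaml --out run/ --seed 1   # config-driven pipeline
```

`tgtquant run` writes the fully resolved configuration and a checksummed
product summary into the run directory; identical config + seed reproduces
identical checksums.

## Layout

```
src/tgtquant/      biophys, synth, calibration, rupture, morphology,
                   kinetics, cli
tests/             unit, property and acceptance tests (all synthetic)
docs/methods.md    models, estimators, parameter choices, limitations
scripts/           acceptance.py
```
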