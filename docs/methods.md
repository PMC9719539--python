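# Methods

This note documents the models, estimators and numerical choices behind
`tgtquant`, the assumptions they rest on, and what the synthetic-data tests
do and do not establish about real microscopy data.

## Physical models

### Duplex tension tolerance

A DNA duplex loaded in shear distributes stress over a characteristic
adjustment length, giving the de Gennes form

    T_tol = 2 f_c [κ⁻¹ tanh(κ l / 2)],

with `f_c = 3.9 pN` per base pair and `κ⁻¹ = 6.8 bp` (defaults of
`TGTGeometry`), `l` the number of duplexed base pairs. The curve is monotone
in `l` and saturates at `2 f_c κ⁻¹ = 53.0 pN`; the 18-bp duplex used in
shear-geometry TGTs evaluates to 46.0 pN. Two caveats are inherent to the
model and inherited here: rupture force depends on loading rate, so `T_tol`
values are approximations valid at slow loading, and the nominal tolerance
class of a construct (12/23/33/43/54 pN) also depends on where the anchor
enters the duplex — geometry the formula does not parameterize. The package
therefore treats nominal tolerances as configuration labels
(`TGTGeometry.nominal_label`), never as outputs. Loading-rate-dependent
kinetic models (Bell/Dudko) are out of scope.

### Two-state integrin activation

Integrin activation is modelled as a two-state equilibrium between the
bent-closed (BC) and extended-open (EO) conformations. Tension `F` applied
between the ligand-binding site and the β-subunit tail performs work
`F·Δx` on the BC→EO transition (`Δx ≈ 14.5 nm`), tilting the zero-force
free-energy difference `ΔG`:

    p_EO(F) = 1 / (1 + exp((ΔG − F·Δx) / kT)),
    F(p)    = (ΔG + kT·ln(p/(1−p))) / Δx.

`ΔG` is taken in kcal/mol at the API surface (measured range 2.5–4 kcal/mol
for β1 integrins on cells) and converted with
1 kcal/mol = 6.9477 pN·nm (4184 J per kcal, Avogadro 6.02214×10²³/mol);
`kT(310 K) = 4.280 pN·nm` with `k_B = 1.380649×10⁻²³ J/K`. Temperature
defaults to 310 K — the model describes live-cell experiments at 37 °C, and
this choice reproduces the quoted one-decimal thresholds (2.6 and 3.3 pN at
99%), which 298 K does not. The two functions are exact inverses; the test
suite checks the round trip at 10⁻⁹ relative tolerance. One quoted value,
the 1.9 pN lower bound for 90% occupancy at ΔG = 2.5 kcal/mol, evaluates to
≈1.85 pN and appears to be a rounding artifact; it is not used as a
reference point. The model ignores the intermediate extended-closed state
and any force dependence of Δx.

### Fab competition occupancy

The fraction of an integrin subtype left unbound by a panel of inhibitory
Fabs is, treating the Fabs as competitors for one site,

    P_unbound = 1 / (1 + Σᵢ Cᵢ / K_d,i),

which is bounded in [0, 1] for any panel and is the package default
(`mode="competitive"`). The per-Fab sum `Σᵢ 1/(1 + Cᵢ/K_d,i)` is also in
circulation for such panels; it agrees exactly for a single Fab but exceeds
1 for several dilute Fabs, so it is exposed only behind
`mode="as_printed"`. Fabs lacking a `K_d` for the queried subtype are
treated as non-binding and excluded. Panels load from CSV
(`fab_name, concentration_nM, K_d_nM_<subtype>…`; empty cell = non-binding).

## Estimators

### Single-fluorophore intensity (I1)

Steps are found by exact penalized least-squares change-point segmentation
(O(n²) dynamic program over cumulative sums; equivalent to what a PELT-type
segmenter returns at these trace lengths). The penalty is
`10 σ² ln n / sensitivity`, with σ the robust noise sd from successive
differences (MAD/√2·1.4826); step magnitudes below 5σ are discarded, so flat
traces yield no events at default sensitivity. Magnitude is the difference
of adjacent segment *medians*, and I1 is the *median* absolute magnitude
over ≥ 40 events — both medians chosen for robustness to unresolved double
steps (tests verify < 10% shift under 20% doubled magnitudes). Dispersion is
reported as 1.4826·MAD/median. Calibration refuses mixed channel labels;
traces recorded at a different exposure time must be rescaled by the caller.

### Drift correction

Fiducial markers are followed frame to frame (brightest pixel within a
5 px gate of the previous position, refined to a background-subtracted
intensity centroid in an 11×11 window); the drift offset is the
across-marker mean displacement from the reference frame, and the reported
residual is the rms inter-marker disagreement. A marker that dims below 30%
of its initial brightness or jumps beyond the gate raises an error naming
the frame. Registration translates each frame by the negated offset with
bilinear interpolation, which preserves flux away from borders; on synthetic
data the post-registration fiducial motion is below 0.05 px RMS, well inside
the 0.2 px requirement.

### Turn-on counting

The stack is median-filtered in time (window N = 3, odd windows enforced) to
suppress single-frame defocus transients; the median preserves step edges,
so a turn-on event survives at full amplitude. Counting is
**detect-then-integrate**:

1. a difference image (late-window mean minus early-background mean for the
   cumulative map) is standardized by a per-pixel shot-noise proxy
   (intensity/window at unit camera gain) — without this, pixels over
   already-ruptured bright regions cross any global threshold on noise
   alone;
2. pixels above `threshold_sigmas = 4` robust noise units form event cores,
   dilated by 2 px to capture PSF tails;
3. the (unstandardized) difference is clipped at 0 and integrated over
   support components, divided by I1. Components touching the cell ROI are
   counted in full, so edge-straddling spots keep their mass.

Setting `threshold_sigmas = 0` recovers a plain clipped difference. The
naive alternative — clipping the raw per-pixel difference at zero and
summing over the ROI — accumulates the one-sided noise expectation
`E[max(0, N(0,σ))] ≈ 0.4σ` over ~10⁴ cell pixels and would overwhelm the
signal at realistic SNR; restricting integration to detected support is
what makes per-pixel clipping harmless. Background defaults to the mean of
the first 5 frames (the generator lands the cell at frame 5); the late
window is 3 frames so that events near the end of acquisition lose little
of their amplitude to window averaging.

The rate time series exploits that summation over a fixed support commutes
with frame differencing: the per-cell molecule trajectory `C(t)` is the
background-subtracted intensity of frame `t` integrated over the support
components touching the cell, and the rate is `diff(C)` per minute. This is
pixelwise frame differencing in aggregated form, but it is robust to
per-pixel noise splitting one event's step across two adjacent increments
(which defeats per-frame re-detection), and it carries no clipping bias —
conservation between summed increments and the cumulative count holds
exactly on clean data and to a few percent at default noise. Individual
rate samples may dip slightly below zero on noise; they are left unclipped
to keep sums unbiased. Cells whose cumulative count reaches 200,000
molecules are excluded from rate summaries (`max_total`), matching the
inclusion rule used for rupture-rate statistics.

Per-pixel noise scales (97.5%-quantile based for frame differences, MAD for
window means) differ because differences of *overlapping* temporal-median
windows are exactly zero at most pixels, which deflates a central MAD.

### Radial profiles

Each ROI pixel gets a normalized radius `r = d_centroid / d_boundary(θ)`
along its own ray, so elongated footprints are handled ray-wise (an edge
ring peaks in the same bin for a circle and a 3:1 ellipse). Boundary
distance comes from the ROI contour binned into 180 angular sectors (max
radius per sector, circular nearest-neighbor fill). Default profiles are
per-unit-area densities (molecules/µm² per bin) before max-normalization —
raw per-bin counts are available via `per_area=False` — and the peak value
before normalization is retained (`max_raw`), mirroring how such profiles
are annotated.

### Morphology and motility

RICM segmentation: Gaussian smoothing (σ = 1 px), Otsu threshold on the dark
side (optional fixed offset), binary closing (radius 2), hole filling —
"enclosed area" semantics, so a bright patch inside a footprint belongs to
the cell — and a 20 µm² minimum size. A guard rejects the Otsu split when
the dark class is not at least 5 noise-sd darker than the background, so
blank or saturated images return no cells rather than noise speckle.
Aspect ratio is the major/minor axis ratio of the second-moment ellipse,
with the minor axis floored at 0.5 px so line-like regions give a large
finite ratio. The spread/not-spread threshold defaults to 500 µm²
(configurable; chosen to match the area floor used when aspect ratios of
spread cells are tabulated).

Nucleus tracking is Gaussian-blob detection (smoothing at the nucleus
scale, local maxima, centroid refinement) plus greedy nearest-neighbor
linking under a 5 px/frame gate, shortest distances first; ambiguous
candidates are logged and resolved by distance, and fragmentation is
preferred over wrong links (global assignment is unnecessary at ~30
cells/mm² densities). MSD is time-averaged per track with overlapping
pairs, then ensemble-averaged with pair-count weights (making concatenation
exactly equivalent to weighted averaging); lags run to 1/4 of the track
length. The power law is fit by least squares on log–log axes, excluding
non-positive MSD values. Whether to time- or ensemble-average, and over
which lag window, are free choices in this kind of analysis; the defaults
above are stated so results are reproducible against them.

### Kymographs and kinetics

Kymographs are sampled along a line at unit-pixel spacing, averaged across
a width band (noise falls ~√width). Ridges are per-row sub-pixel local
maxima (3-point parabolic refinement) linked under a 3 px gate with ≤ 2-row
dropouts; each ridge with ≥ 10 rows is fit by least squares and the slope
converted to nm/s via pixel size and frame interval. Speeds are magnitudes;
the estimator is invariant to intensity scaling and to modest time-axis
cropping. This deliberately mirrors the manual kymograph-plus-linear-fit
practice rather than Radon or Fourier flow estimators, staying inspectable
per ridge.

Fab kinetics: the injection epoch follows `A(1 − e^{−k_obs t})` with
`k_obs = k_on·C + k_off`, the washout epoch `B e^{−k_off t}`. Per-epoch
fits seed a joint fit of the whole trace with shared amplitude; `k_on`
follows as `(k_obs − k_off)/C`. Note the conditioning: when `k_on·C ≪
k_off`, `k_on` is a small difference of two fitted rates and no estimator
resolves it well; recovery tests therefore use concentrations where binding
at least matches dissociation. A non-converging fit returns a flagged
result with diagnostics. Bound-Fab counting integrates background-
subtracted ROI intensity over I1 (bound-Fab densities exceed single-spot
resolvability, so spot detection would undercount); it shares the I1
contract with rupture counting and rejects channel mismatches.

## Synthetic data: what it emulates, and what it does not

The generators emulate the *structure* of the real measurements with known
ground truth: persistent one-fluorophore turn-on spots (2-D Gaussians
truncated at 5σ and renormalized, so integrated intensity is exactly I1)
gated by a growing elliptical footprint; edge-ring versus interior event
placement with optional inward translation (centripetally maturing
adhesions) and early/late hazard peaks; rigid lateral drift
(linear 0.05–0.2 px/frame plus Gaussian jitter, applied by flux-preserving
bilinear shift of the accumulated clean image); bright persistent
fiducials; a Poisson shot-noise + Gaussian read-noise camera at unit gain;
stepwise bleaching/binding traces with exponential step times (conditioned
to the observable window); dark-footprint RICM images with multiplicative
speckle; kymographs with linearly translating Gaussian ridges; exact
fractional-Brownian-motion tracks (Davies–Harte circulant embedding,
`H = α/2`, ballistic `α = 2` handled as the degenerate limit); and
two-epoch Fab wash traces.

Defaults define the simulated study conditions: 256×256 px at 0.16 µm/px,
60 frames at 1-min intervals, PSF σ = 1.1 px, I1 = 800 counts,
200 counts/px background, 5 counts read noise, TGT density 1500 µm⁻²,
700 µm² circular footprints (elongated 3:1 footprints need a
proportionally larger field of view or smaller area). Camera gain and SNR
are not constrained by the source experiments; these defaults put a single
fluorophore at ~7× the background noise — detectable but not trivially so —
and every recovery tolerance in the tests is stated at these defaults.

Not modelled: RICM interference fringes, cytoskeletal mechanics, cell-shape
dynamics beyond the parametric ellipse, fluorophore blinking and
photobleaching of turned-on probes, spatially varying illumination, and
camera gain structure. Passing tests therefore demonstrate that the
estimators are unbiased and within tolerance under this noise and drift
model — not that they are robust to every artifact of real microscopy
(out-of-focus drift, rupture of pre-quenched probes, autofluorescence).

## Problem sizes and determinism

Test and acceptance simulations use the default 256²×60 stacks with
300–500 events, 10 seeds for the end-to-end recovery check, 150 tracks ×
180 steps for MSD exponents, and 3×3 rate grids for kinetics — sizes at
which every statistical tolerance above holds with margin while the whole
suite stays fast. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give bit-identical stacks,
and a pipeline run (`tgtquant run`) writes a resolved config and sha256
product checksums that reproduce exactly for identical config + seed.

## Known limitations

- Counting accuracy degrades once per-pixel cumulative signal approaches
  the dynamic range where shot noise swamps a single fluorophore
  (≫10³ molecules/µm² at defaults); the real assay runs into the same
  physics near full monolayer rupture.
- `force_for_occupancy` can return a (physically meaningless) negative
  force for very small `p` at small ΔG; callers asking for occupancies the
  zero-force equilibrium already exceeds should interpret the sign.
- The greedy linker will swap identities of two nuclei that pass within
  the detection merge radius; tracks fragment rather than silently bridge.
- `as_printed` Fab fractions are reported exactly as defined even where
  they exceed 1; the competitive mode is the physically meaningful default.
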