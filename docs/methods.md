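# Methods

`vasomet` reimplements, as a tested pipeline, the image-analysis chain used
to quantify cerebrovascular structure and blood–brain-barrier (BBB)
permeability from in vivo two-photon angiography: maximal-intensity
projection (MIP) of thin z-stacks, vessel segmentation, average-outward-flux
(AOF) medial-axis skeletonization, Euclidean-distance-transform (EDT)
diameters, vascular and branch-point densities, the outside/inside (O/I)
leakage ratio with its 5→60 min delta, and the group statistics used to
compare genotype cohorts. Raw in vivo angiography of this kind is rarely
shared, so a synthetic vascular-phantom generator supplies inputs with full
ground truth; every pipeline stage is validated against that truth.

## Acquisition model the phantom emulates

One imaging session is a time series of two-channel z-stacks: 512×512
frames, five layers at 1 µm spacing, one stack every 5 min for 1 h,
acquired after injecting a mixture of FITC-conjugated 40 kDa dextran and
TRITC-conjugated 70 kDa dextran. The pixel size is a required user input:
the hardware (a 16×/0.8 NA water objective) does not determine it without
the scan zoom, so the loader refuses stacks without physical calibration.
Phantoms default to 1 µm/px.

### Vascular network

`phantom.build_network` grows gently meandering, quasi-planar vessels
(superficial cortical vessels are nearly flat over a 5 µm stack). Trunks
start at golden-ratio-stratified vertical positions so the field is covered
the way well-separated surface vessels cover a projection; with probability
`branch_prob` a segment instead branches off an existing vessel, creating a
degree-3 junction node. Each edge carries a constant radius (default
3–8 µm) and a wall permeability (default 0.005–0.02 min⁻¹). Ground truth
recorded per volume: polyline centerlines, total length, degree-≥3 node
count, per-point diameters. Deterministic constructors (`straight_tube_graph`,
`parallel_tubes_graph`, `grid_graph`, `y_junction_graph`) provide phantoms
with closed-form truth for unit tests and oracles.

### Rasterization

A voxel is vessel iff its center lies within the local radius of the
nearest centerline point, with exact point-to-segment distances in µm;
overlapping vessels are unions. The pixel-center rule means a radius-r tube
at 1 µm/px has a (2r+1)-pixel cross-section, i.e. an effective half-width of
r + 0.5 px; tests that compare digital areas to analytic capsule areas use
that effective radius.

### Leakage kinetics (simulation convention, not a claim about biology)

The analysis itself needs no kinetic model; the phantom uses the minimal
model that reproduces the phenomenology seen in such experiments (fast initial
rise, slow ongoing leak, renal clearance):

- intravascular: plasma concentration `C_p(t) = C_0·exp(−k_c·t)` with
  clearance `k_c = 0.02 min⁻¹` by default. Plasma is an undepleted
  recirculating reservoir — brain extravasation does not feed back on it.
- extravascular: a perivascular shell (default 3 µm) fills by first-order
  exchange `dC_e/dt = P_eff·(C_p − C_e)` with
  `P_eff = edge permeability × channel scale`, then spreads by one Gaussian
  kernel (default σ = 1 µm) per 1-min step. The default channel scales are
  1.0 for the 40 kDa tracer and 0.0 for the 70 kDa tracer, encoding a
  barrier permeable only to the smaller dextran.
- the diffusion operator conserves extravascular mass under the default
  `closed` (reflecting) boundary and only loses it under `open`
  (absorbing); because plasma is a reservoir, total intra+extravascular
  signal is *not* conserved — the conservation property is tested on the
  diffusion operator, where it holds.

The noise-free ground-truth O/I curve is computed before blur and noise,
with the same guard-band definition as the measurement (below). Frames are
then blurred by the PSF, degraded by Poisson–Gaussian noise, and quantized
to 16-bit counts (default amplitude 1000 counts).

PSF: the effective two-photon PSF of a 0.8 NA water objective at 860 nm is
approximately diffraction-limited with lateral FWHM ≈ 0.24 µm and axial
FWHM ≈ 1.2 µm; the defaults are the corresponding Gaussian sigmas (0.1 µm
lateral, 0.5 µm axial).

All randomness flows from one `numpy` generator seeded by the spec;
identical (spec, seed) produce bit-identical outputs.

## Measurement pipeline

**MIP.** All 2D analysis runs on the pointwise maximum over z of each
stack; no registration or photobleaching correction is applied.

**Segmentation.** Protocols of this kind typically segment with a trained
network whose weights are not distributable, so this package honors only
the mask contract: masks can be imported from any external segmenter (nonzero =
vessel), and two classical baselines are provided. The default,
`otsu_hysteresis`, seeds at an Otsu threshold refined by intermeans
(isodata) iterations — on angiography MIPs the background is a huge
near-zero mode with a faint perivascular halo of leaked tracer, a regime
where raw Otsu's objective is nearly flat across two decades of threshold
and can land inside the halo — and grows regions down to half that
threshold. Small objects (<25 px) are removed and interior holes (<50 px)
filled so tube interiors stay solid for the EDT. Segmentation runs on the
first (5-min) timepoint of the 40 kDa channel, where vessels are brightest
and leaked tracer minimal; that mask is held fixed for the whole session
(re-segmenting later frames would absorb leaked tracer into "vessel" and
bias the O/I ratio downward).

**AOF skeletonization.** The distance transform is the exact EDT. The AOF
field is `AOF(x) = (1/n)·Σᵢ ⟨g(x+ε·n̂ᵢ), n̂ᵢ⟩` over n = 32 unit directions
with ε = 1 px, where g is the unit gradient of the EDT (central
differences, bilinear sampling, mirrored borders); it is ≈ 0 off the medial
axis and strongly negative on it. Skeletons are extracted by flux-ordered
homotopic thinning: simple pixels (8-connected foreground, 4-connected
background; 256-entry lookup table) are removed in increasing EDT order,
and a curve endpoint with AOF < τ is anchored. τ = −0.25 was calibrated
once on straight-tube phantoms (radii 3–12 px, orientations 0–45°,
sub-pixel offsets): more than 99.9% of true centerline pixels — including
the weaker end-cap tips — carry AOF below it, while non-medial flux stays
near zero. Remaining spurs that end at a junction are pruned when shorter
than `max(5 px, local radius + 2)`; the radius-aware part matters because a
two-pixel boundary bump on a radius-r vessel spawns a medial spur of about
r pixels, so no fixed cutoff separates noise spurs from true side branches
across calibers. Topology (component and hole counts) is preserved by
construction and asserted in tests.

**Diameters.** One sample per skeleton pixel, `2·(D − 0.5)·pixel size`. The
half-pixel correction accounts for the EDT measuring to the nearest
background pixel *center*, half a pixel beyond the vessel boundary; without
it every diameter is overestimated by one pixel. Skeleton pixels closer to
the image border than their own local radius are excluded (truncated
distances), and diameter pooling is per-pixel, i.e. length-weighted.

**Length and densities.** Skeleton length uses branch decomposition plus
polyline resampling (every 5 pixels): exact on straight horizontal and
diagonal runs and free of the staircase bias that inflates chain-code
length by `cos θ + (√2−1)·sin θ − 1` (up to +8.2% at 22.5°) on tilted
vessels. The classic chain-code estimator (1 per orthogonal step, √2 per
diagonal) remains available as `estimator="chain"` and is cross-checked in
tests. Vascular density is length over imaged area (reported in mm/mm²);
branch points are skeleton pixels with ≥3 skeleton neighbors, 8-connected
clusters merged to one junction each, reported per mm².

**Permeability.** O/I = mean intensity over the complement of the mask
dilated by a 2 px guard band, divided by mean intensity over the mask;
"average" is the arithmetic mean. The guard band keeps PSF-blurred vessel
rims out of "outside". The ratio is invariant to global gain and to the
multiplicative signal loss from renal clearance — the reason a ratio is
used at all — and this invariance is asserted to machine precision. The
leakage delta is O/I(60 min) − O/I(5 min), requiring both timepoints within
0.5 min. One known nuisance is quantified rather than hidden: the MIP of
clipped sensor noise adds a small uniform background which, divided by a
clearance-decaying inside mean, produces a systematic positive delta in
*any* channel (~0.005 under default noise). The size-exclusion checks
therefore compare each channel's delta to a noise floor estimated from
matched negative controls: re-simulations of the same phantom with every
channel impermeable.

## Statistics

Groups of per-volume metrics are compared with Kruskal–Wallis (midrank tie
correction, χ² p on k−1 df; all-identical data gives H = 0, p = 1) followed
by the Conover–Iman all-pairs rank t-test,
`t_ij = (R̄_i − R̄_j)/√(S²·((N−1−H)/(N−k))·(1/n_i + 1/n_j))` on N−k df,
unadjusted by default (Holm and Bonferroni available). Two-way ANOVA uses
type-II sums of squares with optional Tukey HSD. The two-way
repeated-measures (split-plot) ANOVA — one between-subject factor, one
within-subject factor — is implemented directly in numpy (needed for
Monte-Carlo calibration at thousands of fits) and cross-checked against
`pingouin.mixed_anova` in tests; Greenhouse–Geisser correction is applied
by default, with ε from the double-centered pooled within-group covariance.
The analytic ε of a compound-symmetric covariance is exactly 1; the sample
estimate is biased downward by roughly (k−1)/n, which the tests account
for. Wilcoxon signed-rank drops zero differences and uses the exact null
for n ≤ 25 without ties. Relative qPCR quantification averages technical
replicates per biological sample, then ΔCt = Ct_target − Ct_reference,
ΔΔCt = mean ΔCt(group) − mean ΔCt(calibrator), RQ = 2^(−ΔΔCt), with −ΔΔCt
reported alongside.

Kruskal–Wallis, Wilcoxon, two-way ANOVA and Tukey are delegated to
scipy/statsmodels; Conover–Iman and the split-plot ANOVA are implemented
here (no installed package provides the former; the latter is hand-rolled
for speed and checked against pingouin).

## What the phantoms do and do not establish

Phantoms share the acquisition geometry, tracer kinetics phenomenology,
photon-limited noise, and the ground-truth structure needed to verify every
stage. They do not contain motion, breathing artifacts, depth-dependent
scattering, dural vessels, autofluorescence, segmentation-hostile contrast
variation, or real biological variability in vessel morphology — so passing
tests certify the *computations* (skeletonization, diameters, densities,
ratios, statistics), not the field performance of the classical
segmentation baselines on real angiograms. On real data the intended route
is importing masks from a trained segmenter and running the identical
downstream chain.

## Problem sizes and reproducibility

The planted-effect study runs 4 groups × 24 volumes per seed at 128×128×5
with timepoints {5, 60} min (the leakage delta needs only those two), over
20 cohort seeds — sizes chosen so the whole study runs in minutes on one
core while keeping realistic group sizes (such studies image 20–31
volumes per genotype). The analysis scripts use 8 volumes per group
for a quick narrative run. Monte-Carlo calibration of the repeated-measures
interaction test uses 1000 null simulations at 20 subjects × 4 timepoints.
Every random quantity is derived from an explicit seed; cohort volumes draw
child seeds from a single `SeedSequence`, and re-running a persisted
configuration reproduces outputs byte-for-byte.

## Known limitations

- 2D morphometry on MIPs, as in the emulated protocol; no 3D
  skeletonization.
- The leakage model is compartmental, not a PDE; absolute O/I magnitudes
  depend on the shell width and spreading kernel and are smaller than
  typical in vivo values because the far field stays empty. Ordering and
  invariance properties, which the analyses rely on, are insensitive to
  this.
- Overlapping vessels merge in the mask (as in real projections); diameters
  near junctions reflect the merged geometry.
- Classical segmentation baselines assume bright vessels on dark background
  (an `invert` flag handles the reverse polarity) and are not a substitute
  for a trained segmenter on real data.
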