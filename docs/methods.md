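# Methods

`tmsmap` implements prospective, E-field-informed motor mapping for
transcranial magnetic stimulation (TMS): candidate coil configurations are
selected *before* stimulation by the dissimilarity of the |E| maps they
induce in a cortical region of interest (ROI), using farthest point
sampling (FPS).  The package contains everything needed to study the
method end to end on synthetic data — geometry, field model, MEP
simulation, map estimation, and the sampling-efficiency experiments —
plus import paths so FEM-derived |E| matrices and experimental MEP tables
can replace the synthetic components without code changes.

## The mapping model

The ROI surface is discretized into K compartments (surface triangles).
For coil configuration c (position x, y on the scalp tangent plane,
orientation α ∈ [0°, 180°)), the induced field-magnitude map is the
vector E_c ∈ R^K (V/m).

**Muscle representation (MGM).**  A spatially restricted muscle
representation centred at the most excitable compartment k_max is modelled
as a geodesic Gaussian,

    m_k = (1 / σ√(2π)) · exp(−d(k, k_max)² / 2σ²),

with d the geodesic distance along the cortical surface and σ (mm) the
spatial extent.  The Gaussian density is applied literally per compartment
and not renormalised after discretization; the resulting overall scale is
absorbed by the calibration of the sigmoid turning point (below).

**MEP generation.**  The stimulation strength of configuration c is the
inner product x = ⟨M, E_c⟩.  The clean motor-evoked-potential (MEP)
amplitude follows a sigmoid input–output curve

    y(x) = y_max / (1 + e^{−k (x − x0)}),   ψ = {x0, y_max, k},

and the observed amplitude adds sigmoid-modulated heteroscedastic Gaussian
noise, clamped at zero after the noise is added (peak-to-peak amplitudes
are non-negative; the clean y is already positive):

    ỹ = max(0, y + ε),   ε ~ [P / (1 + e^{−k(x − x0)})] · N(0, 1).

The noise standard deviation therefore rises with stimulation strength and
saturates at P — matching the empirical observation that strong stimuli
yield more variable MEPs.  MEP waveform morphology and latency are not
modelled.

**Map estimation.**  Given n sampled configurations and their MEPs, a
sigmoid is fitted per compartment (predictor: that compartment's |E|
across the n stimulations; response: the MEP amplitudes) with a
Levenberg–Marquardt least-squares solver.  The per-compartment coefficients
of determination form the R² map, read as the estimated muscle
representation.  R² is defined as 1 − SS_res/SS_tot, floored at 0;
degenerate data (constant response) and invalid fits are flagged failed
and carry R² = 0, preserving the [0, 1] map contract.

**Map comparison.**  Two non-negative maps are compared with the fitting
score — their inner product after l2-normalisation (cosine similarity);
1 is perfect overlap, 0 the lower bound.  Localisation error is the
geodesic distance between map peaks (argmax, smallest-index tie-break).
Sample efficiency is n95: the smallest evaluated sample count whose map
exceeds a 0.95 score against the reference map, censored at the sampling
budget when never reached (censored runs enter summaries at the budget
value, flagged).

## Farthest point sampling

FPS greedily selects, at each step, the candidate whose minimum Euclidean
distance to the already-selected |E| maps is maximal:

    s_n = argmax_{E_c ∈ C \ S} min_{E_j ∈ S} ‖E_c − E_j‖.

The first sample is uniform-random (seeded) or forced.  The incremental
implementation maintains each candidate's current min-distance to the
selected set (O(N_c·K) per step) and is exactly equivalent — same
floating-point comparisons, same smallest-index tie-break — to the
brute-force re-evaluation oracle shipped for verification.  The
min-distance trace of the selected samples is non-increasing from step 2
onward (classic greedy max-min property); both properties are asserted in
the test suite.  The ordering produced by FPS is invariant to a global
positive rescaling of the maps, so whether candidate maps are expressed at
the 1%-MSO reference or at mapping intensity does not change the
selection.  The baseline is uniform random sampling without replacement —
the finite candidate grid and the mapping protocol (a fixed number of
distinct configurations) imply distinct draws.

## Synthetic study conditions

Real deployments obtain E_c from FEM simulations on individual head
models; those inputs are out of scope here and replaced by a parametric
stand-in with the features that drive the sampling problem.

**Geometry.**  A disc-shaped cortical patch (default radius 30 mm) with a
sinusoidal fold, height z = A·sin(2π y/λ) (default amplitude A = 6 mm,
wavelength λ = 12 mm), triangulated from a lightly jittered lattice
(seeded, deterministic).  Compartment depth is the drop of the analytic
height field below the crown envelope, giving crown (≤25% of max depth),
wall, and fundus (≥75%) bands.  Analysis is restricted to a vertical
cylindrical ROI of radius 20 mm (closed boundary) while coils may sit
anywhere within the 30 mm search radius — the larger coil radius
accentuates |E| differences between ROI centre and edge.

**Geodesics.**  Shortest paths between compartment centroids on a
vertex-sharing k-ring graph (default ring = 2) with chord-length edge
weights (Dijkstra).  On a flat test disc this approximation stays within
~1.5% of the Euclidean distance (worst pair), and graph distances can
never undercut the straight-line distance.  The backend is pluggable
(`ring`, `adjacency='vertex'|'edge'`); exact polyhedral geodesics are
unnecessary at the accuracy the mapping metrics need.  A metric-MDS
flattening (classical-MDS initialisation + SMACOF) is provided for
visualisation only.

**Field model.**  For a coil at (x, y) with orientation α,

    E_k = A · [(1 − η_k) e^{−ρ_k²/2λ_f²} (1 + β cos 2(α − φ_k))
               + η_k g(x, y)] · e^{−(depth_k + standoff)/δ},

clipped at 0, with ρ_k the tangent-plane distance to compartment k,
g(x, y) = e^{−(x²+y²)/2λ_g²} the global coil-proximity mode (no
orientation sensitivity — it represents volume-conducted current), and
η_k = η_max / (1 + e^{−(depth_k − d_0)/w}) the share of that mode,
switching on sigmoidally in the sulcal depths.  Defaults: peak amplitude
A = 1 V/m at the 1%-MSO reference, footprint λ_f = 14 mm, depth decay
δ = 15 mm, anisotropy β = 0.3 with preferred direction φ_k along the
local fold contour, shadowing onset d_0 = 8 mm (two thirds of the default
fold's maximum depth) with width w = 1.5 mm and ceiling η_max = 0.9,
global spread λ_g = 20 mm.

The shadowing term encodes the property of FEM fields that matters most
for mapping: superficial and mid-depth compartments see focal fields
whose pattern across coil configurations identifies them individually,
whereas compartments in the sulcal depths see volume-conducted fields
whose configuration-to-configuration variation is dominated by a single
global mode — nearly co-linear across the whole fold floor.  A purely
local separable model (Gaussian footprint × per-compartment depth
attenuation) cannot reproduce the depth dependence of mapping quality at
all: per-compartment attenuation factors cancel out of every predictor
correlation, and on a sinusoidal fold the crown and fundus are mirror
images of each other, so their R² profiles are provably identical.  With
shadowing, R² maps of deep muscle representations delocalise along the
fold (R² is high wherever the global mode predicts the MEPs), which is
what drives the low fundus scores in the placement sweep; confining the
collapse to the deepest band keeps the reference maps structured enough
that subset-map overlap grows gradually with the sample count, so the
samples-to-criterion measure discriminates between samplers.

The cos 2(·) term gives the required 180° periodicity of the field
magnitude in coil rotation.  With shadowing disabled (η_max = 0) the
model is strictly monotone in ρ and in depth; with shadowing,
monotonicity is deliberately given up for deep compartments (their
pattern follows the global mode).  The field is continuous in the
configuration — nearby configurations give nearby maps, the property
that motivates FPS.  Intensity scaling is linear in percent MSO (FEM
fields are linear in the coil-current rate of change).

**Default experiment scale.**  Mesh of ≈2,200 triangles on the 30 mm
patch, ≈980 compartments inside the 20 mm ROI; coil grid of 5 mm spacing
and 10° orientation steps inside 30 mm → 2,034 candidates at mapping
intensity 50% MSO.  These sizes keep a full 3-placement × 50-paired-run
comparison to a few minutes on one CPU while preserving the regime of
interest (candidates ≫ budget ≫ sigmoid parameters).  The production-scale
grid (3 mm / 5° → 11,412 candidates) and the high-resolution reference
grid (2 mm / 10° → 12,762) are available through the same API and are
checked by count in the tests.

**MEP model defaults.**  σ = 5 mm; y_max = 1 mV; P = 0.1 mV (10% of
saturation); x0 calibrated to the median stimulation strength of a
noise-free sweep over the full candidate set, and the slope to
6/(q90 − q10) of that strength distribution so the central 80% of
candidates span the rising phase of the sigmoid.  The calibration is part
of the generative model, not of the estimator: it only ensures the
candidate set actually exercises the sigmoid's dynamic range, as a
threshold-referenced stimulation intensity does in practice.

## Experiments

**Placement sweep.**  The MGM is placed at every ROI compartment in turn;
one noisy MEP per candidate of the dense grid is simulated, the R² map
fitted, and its score against the generating MGM recorded.  On the folded
fixture, fundus-band scores fall below crown- and wall-band scores — deep
compartments see volume-conducted fields dominated by the global
proximity mode, so their R² maps delocalise along the fold — while crown
and wall differ little and a flat fixture shows no depth contrast at all.

**Subsampling comparison.**  For each placement (crown-centre,
wall-centre, crown-edge) and each (sampling seed × noise seed) pair, FPS
and random orders of 150 configurations are drawn from the same candidate
set.  Noise is drawn once per candidate index per noise seed, so both
samplers see identical noise for identical configurations (paired-run
variance reduction; asserted in the tests).  Score and peak-distance
curves are evaluated every 2nd sample (the budget itself is always
evaluated); evaluation stops once the score exceeds the threshold, which
fixes n95 — points beyond the crossing cannot change it.  The default
reference map is the all-samples R² map fitted on the full candidate set
with the same noise stream, so the score measures convergence to the
full-data answer and reaches 1 by construction in the noise-free
exhaustion limit; the generating MGM or a high-resolution-grid map can be
selected instead.

Summaries report mean, std, median, and 5th/95th percentiles of n95 per
method × placement (linear interpolation between closest ranks), with
censored runs included at the budget and counted.

## Numerical choices

* Sigmoid fits: scalar path uses scipy `least_squares(method='lm')` with
  tight tolerances; the batched path is a hand-vectorised
  Levenberg–Marquardt (damped normal equations, per-problem λ adaptation)
  that solves all K compartments simultaneously and is verified against
  the scalar path.  Initialisation: y_max⁰ = max(y), x0⁰ = y-weighted
  median of x, slope⁰ = 4·y_max⁰/range(x).  Validity (checked after the
  unconstrained solve): finite parameters, 0 < y_max ≤ 2·max(y),
  slope > 0; violations are failed fits with R² = 0.
* Curve evaluations warm-start each fit from the previous evaluation's
  parameters, keeping a warm start only where it beats the default
  initialisation in residual cost; the final (budget) evaluation is
  cold-started so a full-set evaluation reproduces a reference map fitted
  by the same procedure.
* Ties (FPS argmax/min, map peaks) break to the smallest index for
  cross-platform determinism.  All randomness flows through explicit
  integer seeds; no global RNG state is used.
* Cylinder membership uses a closed boundary (≤ radius); the coil lattice
  is axis-aligned and origin-anchored.

## What the synthetic conditions do and do not show

The generator reproduces the structural features that make prospective
sampling useful: smooth configuration→field dependence, depth-attenuated
and orientation-sensitive fields over a folded surface, sigmoid MEP
recruitment with intensity-dependent noise.  It does not model real head
anatomy, vector field direction, conductivity anisotropy, coil-specific
field shapes, device intensity units, MEP morphology/latency, or
trial-to-trial brain-state dynamics.  Passing tests therefore demonstrate
the correctness of the algorithms and the qualitative sample-efficiency
ordering under controlled conditions — not quantitative agreement with
any individual's motor map.  Known limitations carried over from the
method itself: FPS favours high-|E| (crown) regions because field
differences are largest there, and the R² map assumes a single
anatomically restricted generator, so multi-modal representations can
yield inconclusive maps.
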