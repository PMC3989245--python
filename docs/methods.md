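# Methods

## Model

A wormlike chain confined to (or equilibrated in) two dimensions has a
tangent angle θ(s) that performs Brownian motion along the contour with
variance rate 1/Lp. Three equivalent statistics encode Lp, and the
package implements all three so they can cross-check each other:

* tangent-angle cosine correlation C(s) = A·exp(−s/2Lp);
* mean square end-to-end distance
  ⟨R²⟩(L) = 4·Lp·L − 8·Lp²·(1 − e^(−L/2Lp));
* equipartition of cosine bending modes, var(aₙ) = (1/Lp)(L/nπ)².

The factor 2 in the exponent is the 2D convention (shape fluctuations in
a plane); a `convention="3d"` flag switches the cosine model to
exp(−s/Lp) for users analysing projections of 3D fluctuations. The
flexural rigidity is reported as κ = Lp·kT (default T = 298.15 K). Twist
and twist–bend coupling are outside the model: the reported κ is the
effective bending rigidity only.

The cosine amplitude A is deliberately a free fit parameter.
Relative-angle determination carries noise ε; since cos is even and
bounded by 1, ±ε map to the same cosine and E[cos(ε)] = e^(−σ²/2) < 1
for Gaussian noise. Constraining A = 1 would therefore force the decay
to absorb the noise and bias Lp downward. The fitted A is itself a
useful diagnostic of angle noise (A ≈ e^(−σ²/2)); values slightly above
1 occur on very clean data because spline smoothing suppresses
short-scale decorrelation.

## Tracking

Input skeletons are binary, nominally 1-pixel-wide and 8-connected
(standard thinning output). Coordinates are 0-based (row, col) with
row 0 at the top; the scan for filament ends starts at the bottom left,
reads each row left to right, and proceeds bottom to top.

A pixel is an endpoint when (i) its on-neighbours at Chebyshev radius 1
are a single pixel or two mutually adjacent pixels, and (ii) all
on-pixels within Chebyshev radius 2 lie strictly inside a half-plane
through the pixel. Condition (ii) is what distinguishes a true end from
the boundary pixel of a small gap, which has on-pixels on both sides at
radius 2. Radius is Chebyshev throughout.

Tracing steps to the unvisited neighbour most collinear with the running
direction (mean of the last three unit steps); ties break by smaller
turn against the last step, then by scan order. Maximal collinearity is
what carries the trace straight through short spurs and filament
crossings — with the known failure mode that two crossing filaments can
be joined into one trace; frames whose skeletons contain more than 2%
branch pixels trigger a warning for that reason. When no adjacent pixel
exists, rings of Chebyshev radius 2 … gap_skip+1 are searched within
±45° of the running direction, so gaps of up to `gap_skip` missing
pixels (default 2) are crossed and counted; larger gaps terminate the
trace and split the filament. Traces shorter than `min_pixels`
(minimum 4 — below that a backbone shows no resolvable curvature, and a
cubic reconstruction needs 4 points) are discarded with a signal and
their pixels released for re-tracing; a review hook can accept or reject
each candidate trace (default: accept all), replacing interactive
screening.

## Shape reconstruction

Raw pixel chains alternate their direction in 45° steps and would
dominate any tangent statistic. Reconstruction proceeds as:

1. point-reflect the backbone by one window length beyond each end, so
   end windows are not fit on one-sided data;
2. fit a cubic (third-order Bézier-equivalent) parametric curve over
   every sliding window of w = 7 pixels (chord-length parameter) and
   average all window evaluations at each pixel;
3. pass a chord-parameterized cubic *smoothing* spline through the
   averaged points, with residual budget (0.35 px)² per point — the
   quantization error left after averaging;
4. resample the spline at uniform arc steps (default 0.5 × pixel size)
   over the unpadded span; tangent angles come from the analytic spline
   derivative and are unwrapped.

On rasterized test curves this leaves < 0.25 px RMS position error,
recovers a 50 px-radius quarter circle's curvature within 5% and its
contour length within 1%. Known limitation: the tangent angle at the
extreme ends is only determined to a few hundredths of a radian by a
1-px-wide raster, and its error varies with the filament's orientation
on the lattice; statistics that average over the filament (correlation,
modes) are insensitive to this.

## Ensemble statistics

The cosine correlation accumulates cos(θ(s₂) − θ(s₁)) into bins of
s₂ − s₁ (default bin width 2 × sample step). The default `all_pairs`
pairing uses every ordered pair of sample points — computed per filament
in O(N log N) via FFT autocorrelation of e^(iθ) — which minimizes
variance; `from_origin` (reference angle at the filament end only) is
retained for convention comparisons, and both converge to the same
expectation. Bin occupancies are reported so users can judge the
within-filament correlation of samples; bins with fewer than 10 samples
are flagged low-confidence, and empty bins are absent rather than zero.
Fits weight bins with σ ∝ 1/√count.

When no fit range is given, the cosine fit finds the semiflexible window
[0, 8·L̂p] iteratively, starting from a log-slope estimate over the
first tenth of the positive bins: beyond roughly eight persistence
lengths the correlation is noise around zero. Initialization is
derivative-free (A₀ from the smallest-s bin, Lp₀ from the bin nearest
the median s); optimization is bounded least squares with 1e−8 relative
tolerance, at most 500 evaluations, and a non-converged fit returns an
explicit failure result (lp = NaN, diagnostics attached) rather than any
default. The end-to-end fit bins per-filament (L, R²) records
(~√N bins) and rejects geometrically impossible records (R² > L²),
sub-minimal samples (< 10 filaments) and degenerate designs (all L
equal). The combined mode estimate averages the per-mode Lp values —
each mode's variance estimate has the same relative chi-square error for
a given frame count — and reports the standard error of that mean.

Mode amplitudes use the discrete midpoint rule
aₙ = √(2/L)·Σ θ(s̄ₖ)·cos(nπ·s̄ₖ/L)·Δsₖ with each frame's mean angle
subtracted (free filament, no imposed boundary orientation). Frames
whose contour length deviates more than 5% from the median are rejected
with a warning: a blurred or out-of-focus filament end changes the
apparent length and corrupts every mode variance.

## Synthetic data

The generator draws tangent increments Δθ ~ Normal(0, step/Lp) (step
defaults to L/500, keeping increments ≪ 1 rad), which makes
⟨cos Δθ(s)⟩ = e^(−s/2Lp) exact at every separation. Fluctuating-filament
time series are independent equilibrium conformations of fixed L — the
mode analysis needs only equilibrium variances, so no temporal dynamics
are modelled and frame-to-frame correlation of real video data is not
emulated. Rasterization marches the curve with Bresenham lines, prunes
the pixel chain to a minimal 8-connected path, and then applies
configured artifacts: gaps (n consecutive pixels off at a fractional
position), spurs (short false branches) and per-segment angle noise.
The default study conditions used throughout the validation are
Lp* = 10 µm, 300 chains with contour lengths uniform in 5–40 µm,
0.1 µm pixels, and 2000 frames of a 15 µm filament for mode analysis —
a filament count and L/Lp window typical of fluorescence measurements on
actin. All randomness flows from explicit seeds and runs are
bit-reproducible.

What passing the synthetic validation does **not** show: performance
under real point-spread blur, uneven labelling, out-of-plane excursions,
filament crossings at high density, or temporally correlated frames.
The pre-processing chain (morphological background subtraction, Gaussian
smoothing, contrast normalization, global threshold, thinning) is a
deliberately simple reference implementation: a cutoff set too high
fragments dim filaments, one set too low lets noise sprout spurious
branches, and both failure modes are exercised in the tests on rendered
synthetic micrographs.

## Configuration semantics

`min_pixels < 4` and `max_filaments < 1` are rejected with explicit
messages; a physically absurd pixel size only warns, because no software
can know the instrument's true magnification — results scale with it.
Every run writes its fully resolved configuration next to the outputs,
selected traces are persisted before analysis begins, and a re-analysis
from cached traces is bit-identical to the original run.
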