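# Methods

This note documents the models, conventions and numerical choices behind
`nucdyn`: what each metric computes, what the synthetic generator does and
does not emulate, and where the design was genuinely open.

## Measurement pipeline

### Segmentation and shape descriptors

Frames are smoothed with a Gaussian (σ = 1 px) and thresholded globally
with Otsu's method; the largest connected component is kept and interior
holes are filled. A fixed-threshold override exists for reproducibility
studies. The threshold-selection rule is a documented choice — grayscale
thresholding admits many rules and Otsu is the standard parameter-free
one. Exactly one nucleus per movie is assumed (high-magnification
single-cell fields); a frame with no foreground, or fewer than 9 px of it,
is a per-frame segmentation failure that excludes (and counts) the cell at
the pipeline level.

Per-frame descriptors: area = pixel count × pixel_size²; centroid = mean
foreground position (x = column, y = row, origin top-left, physical =
index × pixel_size); major axis from the ellipse with matching normalized
second central moments; circularity **R = 4·area/(π·major_axis²)** — the
best-fit-ellipse definition, *not* the perimeter-based 4πA/P² (the two
disagree off-ellipse; the ellipse form is used consistently because it
reduces exactly to b/a and is insensitive to perimeter rasterization
noise); solidity = area / convex-hull area (reported, unused downstream).

### Fluctuation amplitude

The area series is fitted with a least-squares cubic on a time axis
rescaled to [−1, 1] (conditioning only; the fit is analytically
identical). Percentage residuals are residual/trend × 100; the amplitude
is their **sample (n − 1) SD**, and the variance form is exactly its
square. Sample SDs are used everywhere in the package. Amplitude is
scale-free (invariant to area rescaling) and insensitive to any added
cubic drift in raw-residual terms. A trend crossing zero is rejected as a
malformed upstream segmentation.

Circularity fluctuation is the coefficient of variation in percent,
S = σ/μ × 100. Edge fluctuations use lag 1 by default with centroid
alignment ON (the later mask is shifted by the integer-rounded centroid
displacement first), so the ratio reports boundary motion rather than
migration; both the lag and the alignment switch are exposed and echoed in
output metadata, since translation removal is a modelling decision, not a
mathematical necessity.

### Registration

Translation-only, integer-pixel alignment to frame 0, via
amplitude-weighted (non-phase-normalized) cross-correlation: phase
whitening over-weights high-frequency noise on smooth microscopy frames
and was observed to misregister fields whose only sharp features are the
moving cells themselves. Translation is deliberately the only motion
model — drift removal is all the downstream metrics need, and sub-pixel
interpolation would smooth texture and bias the intensity correlation.
Out-of-frame pixels are filled with the median border intensity. Constant
frames cannot be registered and are flagged, not shifted.

### Intensity correlation coefficient

Each frame is divided by its summed in-nucleus intensity (removing
photobleaching and expression-level scale), a fixed window — 100 × 100 px
centred on the time-averaged centroid, clamped to the image — is cropped
from every frame of the registered series, and each later frame n is
scored by the pixelwise Pearson correlation against frame 1 with
population SDs over the window:

    C_n = Σᵢⱼ (x1ᵢⱼ − x̄1)(xnᵢⱼ − x̄n) / (N·σ1·σn),   C = mean over n = 2..end.

This per-frame-Pearson-averaged reading is the only normalization under
which the coefficient is bounded in [−1, 1]; negative values are
mathematically possible and reported as computed. Frames with zero pixel
variance are skipped with a flag. Note that a window containing the
nucleus boundary and background carries a static shape term that keeps C
high regardless of texture dynamics; texture-dynamics validation therefore
uses a window interior to the nucleus, while the 100 px default matches
the acquisition-scale protocol for real movies. A manual window override
exists for parity with hand-cropped analyses.

### Migration

Centroid trajectories join consecutive frame centroids with straight
lines; length is the polyline length in μm. If per-frame field offsets
from a registered paired bright-field movie are supplied they are
subtracted first and the result flagged drift-corrected; otherwise the
trajectory is flagged uncorrected (it then also contains field drift and
small-scale attachment/spreading motion).

Time-projection streaks: the aligned bright-field movie is min-projected
per pixel; dark regions below a global Otsu threshold are hole-filled,
skeletonized, and each region is measured as the **geodesic diameter of
its skeleton** (8-neighbour pixel graph, edge weights 1/√2, double
Dijkstra sweep — exact on tree-shaped skeletons). Because the filled
streak of an outlined cell swept along its path is, to good approximation,
the Minkowski sum of the path with the cell disc, the medial axis is the
path itself and the geodesic length estimates the path length directly —
no cell-diameter subtraction is applied (verified on generator movies:
mean 57.2 μm measured vs 57.3 μm truth over 32 cells). Regions shorter
than `min_length` (default 15 μm, a cell-body scale automating the
"too short to be migration" exclusion) are discarded, and skeletons with
more than 4 endpoints (crossing or tangled streaks a manual tracer would
reject) are excluded as unmeasurable. Both parameters are exposed.

### Cytoskeletal intensity

Per channel, a global 3-D Otsu threshold over all voxels delineates the
stained structure (a per-stack threshold; whether delineation should be
per-cell or global is an open choice — a fixed threshold can be supplied);
volume = voxel count × pixel_size² × z_step; the metric is total in-mask
intensity per unit volume. It is invariant to padding with empty planes
and covariant in z-step. Percent difference is (test − ref)/ref × 100 with
the exact asymmetry pd(a,b) = −pd(b,a)·b/a. The manual type-1/type-2
process-dominance classification is out of scope; only the continuous
metric is automated.

### Statistics

One-way ANOVA plus all pairwise two-sample t tests with Bonferroni
multiplication (×k, capped at 1). The outlier rule before correlation is
**one-sided and single-pass**: thresholds mean + 2·(sample SD) per axis
are computed once on the full input and points above either are removed,
with no low-side removal and no re-iteration — matching the stated removal
of high extreme points; order-invariance holds by construction,
idempotence is only claimed in this single-pass sense. Gaussian histogram
fits are least squares on counts with free amplitude (as plotting software
fits), Freedman–Diaconis bin width by default; degenerate or
non-convergent fits are flagged and the raw histogram returned.

## Synthetic generator

The generator produces the three modalities with exact truth records.

**Nucleus movies.** The boundary is star-convex,
r(θ,t) = R₀·s(t)·(1 + Σₖ aₖ cos(kθ+φₖ)), with static modes k = 2..5
(defaults giving circularity ≈ 0.9) — the simplest family with
controllable area and circularity. Area breathing enters through
s(t) = exp(σ·z(t)) with z a stationary AR(1) (persistence 0.8). σ is
calibrated per cell by a bracketed root find so that the percentage-residual
SD of the *realized analytic* area series about its own cubic trend equals
the target exactly (to 10⁻¹⁰ %), removing Monte-Carlo slack from recovery
tests. The interior carries a chromatin-like granular texture: smoothed
white noise (grain 0.8 μm) living in nucleus-local coordinates (so it
advects with the centroid), evolving as an AR(1) field whose per-frame
innovation fraction is `texture_turnover` (0 = frozen, 1 = fully fresh);
the texture amplitude tapers to zero at the rim so granularity never
modulates the segmented envelope. The centroid follows an equal-step
persistent random walk reflected off an interior margin box; the truth
trajectory length is always re-measured from the emitted polyline. Optics
are a single Gaussian blur (σ = 1 px); the camera applies Poisson shot
noise at `noise_gain` photons/unit plus Gaussian read noise — defaults
(gain 1, read SD 2 on a 150-unit nucleus over a 10-unit background) give a
realistic but benign SNR. Pixel calibration (0.16 μm/px, 256², 60 frames
at 30 s) is an assumed typical high-magnification confocal setting; the
acquisition cadence is known but detector calibration is not, so these are
assumptions, not reproduced facts.

**Populations.** Per-cell (amplitude, trajectory length) pairs come from a
bivariate log-normal: one standard-normal latent pair with correlation
`coupling_rho` (default 0.63, the empirically reported amplitude–motility
association) pushed through mean·exp(σ·u − σ²/2) per axis with CVs 0.25
(amplitude) and 0.35 (trajectory) — moderate single-cell heterogeneity
chosen once as realistic. The latent correlation is controlled in closed
form; the observable Pearson correlation is slightly attenuated by the
log-normal marginals (≈ 0.62 at these CVs). Child seeds derive from
`SeedSequence([master, index])`, so any cell is reproducible independent of
generation order.

**Bright-field movies.** Cells are dark rings (radius 7.5 μm, 1.6 μm
thick, 80 on a 200 background) on a static smooth illumination mottle
(σ = 4 px, SD 6 units) that anchors registration, with Gaussian camera
noise. Each cell walks persistently (persistence 0.96 — gentle arcs that
yield traceable streaks) inside its own grid tile (reflecting walls), so
synthetic streaks never cross; per-cell path lengths are log-normal around
the condition mean (CV 0.35). Calibration 0.8 μm/px, 512², 100 frames at
36 s (an assumed low-magnification setting).

**Z-stacks.** Each channel fills a random ellipsoid with uniform voxel
intensity density × voxel-volume over a 2% background, plus Gaussian noise
(SD 0.2 units ≈ 10% of a typical voxel level); total/volume recovers the
density to ≈ 0.2%. Densities are condition parameters (unstrained tubulin
100, strained 24 h 170; unstrained actin 140 at 24 h, strained 119 —
arbitrary units encoding the +70%/−15% relations, with F-actin rising from
1 h to 24 h in both arms).

**Condition presets.** Amplitudes: 3% at 1 h in both arms; 2% in strained
cells at 24 h and 48 h; unstrained cells reach 2% only at 48 h. Whole-cell
migration: 60 μm/h unstrained and 30 μm/h strained at 1 h; the 24/48 h
migration means and all nuclear-trajectory means (16 μm/30 min unstrained
1 h, declining with time and strain) encode the qualitative reported
trends and are documented assumptions, not reported values.

### What the generator does not emulate

No point-spread-function optics beyond one Gaussian blur, no multi-nucleus
fluorescence fields, no apoptotic bleb morphologies, no cell divisions or
collisions (tile confinement), no focus drift, no photobleaching (the
normalization step is exercised by scale-invariance tests instead).
Passing recovery tests therefore demonstrates correctness of the
measurement chain under controlled imaging physics — not robustness to
every artifact of real microscopy.

## Validation design and problem sizes

The recovery benchmarks (`nucdyn.validation`) use 35–40 cells per
amplitude condition, 40–101 bright-field cells per migration arm, an
87-cell pooled population for the amplitude–trajectory correlation, and 20
z-stack pairs per condition — single-CPU-friendly sizes at which the
population means determine the recovered values to a few percent. The
statistical-calibration check runs 300 replicate equal-preset two-group
comparisons at the truth level (no rendering), since it calibrates the
statistical layer, not the imaging chain; its rejection rate at α = 0.05
is verified to sit near 5%. The n = 87 correlation has an intrinsic
sampling SE of ≈ 0.065 on r, so single-seed values scatter accordingly
around the coupling value.

## Degenerate inputs and tie-breaks

Constant frames: unregistrable (flagged), unsegmentable (error). Zero
in-mask intensity: normalization refused. Equal-size components in
segmentation: first-labelled wins (deterministic). Zero-variance crop
windows: skipped with a flag, C averaged over the rest. Empty streak
projections: empty list, not an error. All-identical stats groups: F = 0,
p = 1 reported explicitly rather than NaN.
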