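# Methods

## The model in brief

A scene is a hyperspectral image L(u, v; λ) on a 400–720 nm grid sampled at
10 nm (33 bands), with an isotropic angular scale (deg/pixel).  Cone
excitations are rectangular-sum integrals of radiance against the L-, M-,
S-cone fundamentals, q = Σ_λ L(λ) S(λ) Δλ with Δλ = 10 nm.  Gaze is a
sequence of angular positions at 20 ms intervals; at each position the
retina sees a 5°-diameter disc (about the size of the fovea) whose blur
grows with eccentricity.

Two statistics are computed from this input stream.

**Diet convergence.**  For each end frame n, the log₁₀ cone excitations of
the first n foveal samples are histogrammed with a bin count given by the
Freedman–Diaconis rule (h = 2·IQR·n^(−1/3), bins = ⌈range/h⌉, type-7
quartiles) and correlated (Pearson) with the histogram of all scene pixels
on the *same* bin edges.  Both histograms are relative frequencies; the bin
edges span the union of the local and global ranges so support is shared.
The default end-frame range 50…15,000 in steps of 1 gives 14,951
coefficients per cone class.  The curve is computed incrementally with a
sorted prefix, but every value is provably identical to a from-scratch
recomputation at that end frame (tested).

**Local vs. global adaptation.**  The scene reflectance is relit with a CIE
daylight SPD (default correlated color temperature 4,000 K, reconstructed
from the S0/S1/S2 components).  Per-pixel XYZ (normalized so a perfect
reflector under the illuminant has Y = 100) is mapped to cone-like RGB by
the fixed 3×3 matrix M16.  At evaluation frame n the local adaptation state
of each retinal position is the exponentially weighted mean of the RGB it
has seen over frames 1…n (weights ∝ exp(−(t_n − t_k)/τ), normalized); its
reciprocal gives the spatially varying diagonal (von Kries) gains, applied
to the retinal frame at t_{n+1}.  The global correction divides the same
frame by the scene-wide mean RGB.  The two corrected patches are compared
pixelwise in CAM16-UCS, and the median ΔE over the 5° disc is reported at
six log-spaced evaluation frames from frame 3 to the penultimate frame.
Full adaptation is assumed throughout (no degree-of-adaptation factor), and
CAM16's own chromatic-adaptation stage is skipped: the diagonal corrections
*are* the adaptation, so the corrected RGB enters the model at the
post-adaptation response-compression stage.  Because both corrections of the
same frame share every later stage, any monotone stage cancels to first
order and the statistic isolates the spatial inhomogeneity of the local
gains.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| wavelength grid | 400–720 nm, 10 nm | nm | acquisition convention of the source imagery; all spectra resampled to it |
| sampling interval | 0.02 | s | 50 Hz eye-tracker cadence |
| speed exclusion | 5.0 | deg/s | shifts faster than this exceed the cone-pathway temporal response; applied to *recorded* traces only (model observers are constructed at their nominal speeds; the random-gaze model would otherwise lose every sample) |
| walk step speed | 2.3 (also 0.77, 6.9) | deg/s | recorded modal gaze speed and ⅓×/3× variants |
| local-feature disc | 0.5 | deg diameter | walk confinement around the max-chroma 5×5-pixel window |
| patch diameter | 5.0 | deg | foveal extent; diameter in pixels is rounded (forced odd so a center pixel exists) |
| foveal blur σ₀ | 1.0 | px | ≈1 arcmin at the native scale, the minimum angle of resolution |
| density profile | (1 + e/1°)⁻² | – | smooth inverse-square stand-in for foveal cone-density falloff; σ(e) = σ₀/d(e), capped at 8 px; pluggable (CSV) |
| σ quantization | 0.5 | px | blur realized as a small stack of fixed-σ Gaussians (truncate 4σ); the center level is exactly σ₀, so foveal samples are exact |
| adaptation τ | 1 and 10 | s | bracketing reported cone-adaptation time constants |
| illuminant change | 5,571 K → 4,000 K | K | mean measured scene illumination vs. a setting-sun daylight |
| CAM16 viewing conditions | average surround, L_A 20 cd/m², Y_b 20, white = (100,100,100) after correction | – | CIE defaults; the analysis never states them, and ΔE differences are insensitive to the exact choice because both images share them |
| UCS jnd | 2.46 | ΔE | configured reference threshold (from a CIELAB jnd of ≈2.2) |
| log floor | 10⁻⁶ × global max | – | guards log₁₀ of exactly zero excitations in synthetic scenes |
| FD bin cap | 1000 (curve path only) | bins | near-degenerate local samples (tiny IQR, wide union range) otherwise request 10⁴⁺ bins; the bare `fd_bin_count` op is uncapped |

## Numerical and design choices

* **M16 precision.**  The matrix is stored at its printed 3-significant-
  figure precision; at this precision a daylight white maps to near-equal
  cone-like responses (≈97–108), the defining property of the transform.
* **Blur-then-weight order.**  The eccentricity blur is applied to the
  cone/RGB fields before history weighting; the weighted history is then a
  linear functional of the blurred field and is evaluated exactly by FFT
  cross-correlation of the blur stack with the per-pixel weight map
  (verified against a direct weighted sum of gathered patches to 1e−9).
* **Mirror padding** (`numpy` "symmetric") extends the scene by its own
  reflection so every gaze position yields a full patch and the center never
  samples more points than the rim; padding wider than the image tiles the
  reflection with a warning.
* **Gaze→pixel mapping**: pixel centers at half-integer angular positions;
  the foveal sample is the nearest pixel center.  Retinal image inversion is
  ignored (a relabeling that affects no statistic).
* **Velocity attribution**: the speed of a sample pair is attributed to the
  later sample; excluded samples are dropped, never interpolated (a
  robustness re-analysis with the exclusion disabled is one flag away:
  `vmax = inf`).
* **Walk boundaries**: directions are rejection-resampled, never clamped, so
  the step length stays exactly constant.
* **Ties and degenerate inputs**: the max-chroma window tie-breaks to the
  first in row-major order; constant samples give one histogram bin;
  zero-variance histograms yield NaN correlations that propagate as missing
  (excluded from averages, reported as null in manifests); adaptation gains
  are epsilon-floored at 10⁻⁶ of the per-channel maximum before inversion.
* **Evaluation times** are geometric from frame 3 to frame N−1, rounded with
  duplicate-bumping; each estimate corrects the *next* frame, which is why
  the last usable index is N−1.
* **CCT** is estimated by bounded scalar minimization of CIE 1960 uv
  distance to a Planckian locus computed with the same truncated 400–720 nm
  integration as all other spectra, keeping the daylight round trip within
  ±50 K over 4,000–10,000 K (measured maximum ≈37 K).
* **Uncorrected baseline**: the un-adapted comparison renders the scene
  under the original and test illuminants with a *shared* XYZ normalization
  (the original illuminant's), so the full photometric and chromatic shift
  is retained.

## What the synthetic data does and does not emulate

`synthetic_data` generates: Voronoi-tessellated reflectance scenes whose
region spectra are clipped sums of six raised-cosine bumps (smooth in
wavelength, values in [0, 1], chromatic variance set by one spread
parameter); CIE daylight illuminants at any CCT in [4,000, 25,000] K; and
drift/saccade gaze traces whose drift speeds follow a scaled Beta
distribution bounded below 5 deg/s with mode 2.3 deg/s, mixed with ~60 deg/s
saccades so that the sub-5 deg/s fraction hits its 0.8 target exactly in
expectation.

It does **not** emulate: the 1/f spatial statistics, shadows, or specular
structure of natural scenes; photoreceptor noise; saccadic main-sequence
kinematics; or salience-driven fixation clustering.  Consequently, passing
tests show that the *machinery* is correct and that the qualitative
orderings (uniform sampling ≥ walk ≥ confined feature; τ = 10 s ≤ τ = 1 s;
ΔE grows with CCT gap) hold under controlled conditions — they do not
reproduce the numerical correlation or ΔE levels of human observers on real
hyperspectral scenes.  A replay mode (cube + gaze CSV inputs through the
same pipeline) supports such data when available.

## Problem sizes

The test suite and the reproduction script run on 64×84-pixel scenes
spanning ≈6.9°×5.3° (0.082 deg/px, 61-px retinal patches).  The script uses
full 5-minute traces (15,000 frames) for the observer comparison and the
adaptation minima; the suite uses 3,000-frame traces for the stochastic
fixtures.  At these sizes the full reproduction completes in under a minute
on one CPU; the blur-stack and FFT machinery scales directly to the
336×256 analysis resolution of real acquisitions.

## Known limitations

* The default cone fundamentals are a constructed stand-in (a published
  linear transform of the CIE 1931 CMFs, peak-normalized), not the CVRL
  tabulation; supply tabulated curves via CSV for colorimetric fidelity.
  All shipped statistics compare local against global responses computed
  with the same fundamentals, so no result in this package depends on the
  difference.
* The spatially varying blur quantizes σ(e) to 0.5-px levels and caps it at
  8 px at the patch rim.
* Confined, repetitive sampling can make the Freedman–Diaconis rule
  degenerate (see the bin cap above); correlation values in that regime
  depend on the cap and should be read qualitatively.
* The exponential adaptation model is first-order: no higher-order temporal
  filtering, photoreceptor noise, cone-mosaic structure, or post-receptoral
  pooling.
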