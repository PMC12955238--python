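# gazediet

How do eye movements shape the "spectral diet" of a single foveal cone
photoreceptor — and is that diet rich enough for purely *local* retinal
adaptation to behave like *global* adaptation to the scene mean?

`gazediet` simulates the cone input a fovea receives while a human (or a
model observer) views a hyperspectral scene, and quantifies two things:

1. **Diet convergence.** At the foveal center, L-, M- and S-cone excitations
   q = ∫ L(λ) S(λ) dλ are accumulated frame by frame (50 Hz).  For every end
   frame n, the histogram of log₁₀ excitations over the first n samples is
   compared (Pearson r, matched Freedman–Diaconis bins) with the histogram
   over *all* pixels of the scene.  The curve r(n) measures how quickly the
   local diet comes to resemble the global scene statistics.
2. **Local vs. global von Kries adaptation.**  The scene is relit by a
   4,000 K CIE daylight illuminant.  Each retinal location estimates its
   adaptation state as an exponentially weighted mean (time constant τ) of
   the cone-like CAM16 responses it has seen, and corrects by the diagonal
   (von Kries) transform `diag(1/R̄ᵢⱼ, 1/Ḡᵢⱼ, 1/B̄ᵢⱼ)`; the global correction
   uses one diagonal built from the scene-wide means.  The gap between the
   two corrections is the median color difference ΔE in CAM16-UCS over a
   5°-diameter, eccentricity-blurred retinal patch, tracked over viewing
   time and compared against a just-noticeable difference of 2.46.

The package is aimed at computational color-vision researchers: every stage
(spectral integration, daylight model, CAM16 post-adaptation stages, retinal
blur, gaze models, histogram statistics) is an importable, tested function,
and a synthetic-data module generates scenes, illuminants and gaze traces
with the statistical structure the analysis assumes, so the full pipeline
runs without any external data.

## Structure

| module                | contents |
|-----------------------|----------|
| `spectral_core`       | spectra, cone excitations, CIE daylight SPDs, XYZ, the M16 cone-like transform, CAM16-UCS coordinates and ΔE, CCT, CIELAB chroma |
| `hyperspectral_io`    | HDF5/ENVI cubes, radiance → effective reflectance, block downsampling |
| `gaze_models`         | gaze traces, velocity filtering (5 deg/s exclusion), random-gaze / random-walk / local-feature observers |
| `retinal_sampling`    | mirror padding, eccentricity-dependent Gaussian blur, 5° retinal frames, foveal time series |
| `diet_analysis`       | Freedman–Diaconis binning, matched histograms, correlation curves |
| `adaptation_analysis` | exponential adaptation weighting, local/global diagonal corrections, median-ΔE time courses |
| `synthetic_data`      | seeded generators for scenes, illuminants and gaze traces |
| `pipeline` / `cli`    | YAML-configured experiment runs; `gazediet` command-line entry point |

## Worked example

```python
import numpy as np
from gazediet.synthetic_data import SceneSpec, make_scene
from gazediet.spectral_core import apply_illuminant, cone_excitations, daylight_spd
from gazediet.retinal_sampling import sigma0_blurred
from gazediet.gaze_models import WalkConfig, simulate_random_walk
from gazediet.pipeline import foveal_series_from_blurred
from gazediet.diet_analysis import correlation_curve
from gazediet import adaptation_analysis as ad

scene = make_scene(SceneSpec(n_patches=24, chroma_spread=0.25, seed=0))
cone = sigma0_blurred(cone_excitations(apply_illuminant(scene, daylight_spd(5571.0))))
trace = simulate_random_walk(WalkConfig(step_speed_degps=2.3, duration_s=300.0,
                                        bounds=scene.angular_extent_deg, seed=0))
series = foveal_series_from_blurred(cone, trace)
curve = correlation_curve(series, cone)
print("curve points per cone class:", curve.r.shape[0])
print("asymptotic r (L, M, S):", np.round(np.nanmedian(curve.r[-100:], axis=0), 3))

tc = ad.adaptation_timecourse(scene, trace, illuminant_cct=4000.0, tau_s=10.0)
print("median dE (tau=10 s):", np.round(tc.median_dE, 2))
print("uncorrected median dE:",
      round(ad.uncorrected_delta_e(scene, daylight_spd(5571.0), 4000.0), 2))
```

prints

```
curve points per cone class: 14951
asymptotic r (L, M, S): [0.614 0.584 0.598]
median dE (tau=10 s): [20.53 20.17 20.9  19.91 13.9  14.82]
uncorrected median dE: 10.48
```

Reading: over 5 minutes the random-walk observer's foveal diet reaches
r ≈ 0.6 with the global statistics of this synthetic scene (14,951 end
frames, 50…15,000 in steps of 1).  Under the 4,000 K relighting, the local
von Kries correction starts about 20 ΔE away from the global correction and
closes to about 14 ΔE as the adaptation history accumulates (times are
log-spaced from frame 3 to the penultimate frame).  The uncorrected
illuminant shift itself is about 10 ΔE on this scene — local adaptation on a
partially explored scene can still sit farther from the global correction
than the raw shift, which is why sampling breadth matters.

The same experiments run from a YAML config:

```sh
gazediet make-fixtures --seed 1 --out fixtures
gazediet run config.yaml          # writes diet_curves.csv, adaptation_curves.csv + manifests
```

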