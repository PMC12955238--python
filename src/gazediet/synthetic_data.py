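"""Synthetic scenes, illuminants, and gaze traces.

The generators target the *structure* the analysis assumes rather than
photometric naturalness: piecewise-constant (Voronoi) reflectance regions
built from smooth nonnegative spectral basis functions, daylight illuminants
from the CIE model, and gaze traces with a drift/saccade mixture whose
sub-5 deg/s fraction is controlled (about 80% of recorded gaze shifts are
slower than 5 deg/s).

Scene geometry defaults to the source imagery's camera angle, about
6.9 x 5.3 degrees, so retinal-patch code paths run at realistic angular
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gaze_models import GazeTrace, WalkConfig, simulate_local_feature, \
    simulate_random_gaze, simulate_random_walk
from .hyperspectral_io import SpectralImage
from .spectral_core import CANONICAL_WAVELENGTHS, Spectrum, daylight_spd

__all__ = [
    "SceneSpec",
    "GazeSpec",
    "FixtureSet",
    "spectral_basis",
    "make_scene",
    "make_two_region_scene",
    "make_gaze",
    "make_fixture_set",
]


@dataclass(frozen=True)
class SceneSpec:
    """Specification of a synthetic reflectance scene."""

    height: int = 64
    width: int = 84
    n_patches: int = 12
    basis_dim: int = 6
    chroma_spread: float = 0.15
    seed: int = 0
    span_deg: float = 6.9  # horizontal angular span

    def __post_init__(self):
        if self.height < 8 or self.width < 8:
            raise ValueError("scene dimensions must be at least 8 x 8")
        if self.basis_dim < 3:
            raise ValueError("basis_dim must be at least 3")
        if self.n_patches < 1:
            raise ValueError("n_patches must be positive")
        if self.chroma_spread < 0:
            raise ValueError("chroma_spread must be nonnegative")


@dataclass(frozen=True)
class GazeSpec:
    """Specification of a synthetic gaze trace.

    ``slow_fraction`` is the target fraction of inter-sample speeds below
    5 deg/s; drift speeds are drawn from a scaled Beta distribution bounded
    below 5 deg/s with mode ``slow_speed_scale``, saccade speeds from a
    normal distribution around ``saccade_speed_scale``.
    """

    duration_s: float = 300.0
    interval_s: float = 0.02
    slow_fraction: float = 0.8
    slow_speed_scale: float = 2.3
    saccade_speed_scale: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.slow_fraction < 1.0 or self.saccade_speed_scale == 0.0):
            raise ValueError("slow_fraction must lie in (0, 1)")
        n = self.duration_s / self.interval_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s must be an integral number of intervals")
        if not (0.0 < self.slow_speed_scale < 5.0):
            raise ValueError("slow_speed_scale must lie in (0, 5) deg/s "
                             "(drift speeds are bounded below the 5 deg/s cut)")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.interval_s))


def spectral_basis(basis_dim: int = 6, grid=None) -> np.ndarray:
    """Raised-cosine bumps centered 420–700 nm; shape (basis_dim, bands)."""
    grid = CANONICAL_WAVELENGTHS if grid is None else np.asarray(grid, float)
    centers = np.linspace(420.0, 700.0, basis_dim)
    width = 1.3 * (centers[1] - centers[0])
    d = (grid[None, :] - centers[:, None]) / width
    return np.where(np.abs(d) < 1.0, 0.5 * (1.0 + np.cos(np.pi * d)), 0.0)


def _region_reflectances(n: int, basis_dim: int, chroma_spread: float,
                         rng: np.random.Generator) -> np.ndarray:
    basis = spectral_basis(basis_dim)
    coeff = rng.normal(0.0, chroma_spread, size=(n, basis_dim))
    refl = 0.5 + coeff @ basis
    return np.clip(refl, 0.02, 1.0)


def make_scene(spec: SceneSpec) -> SpectralImage:
    """Voronoi-tessellated reflectance scene (seed-deterministic).

    ``chroma_spread = 0`` degenerates to a spatially uniform gray scene.
    """
    rng = np.random.default_rng(spec.seed)
    seeds = rng.uniform([0, 0], [spec.height, spec.width], size=(spec.n_patches, 2))
    rows, cols = np.mgrid[0:spec.height, 0:spec.width]
    d2 = ((rows[..., None] - seeds[:, 0]) ** 2
          + (cols[..., None] - seeds[:, 1]) ** 2)
    labels = np.argmin(d2, axis=-1)
    refl = _region_reflectances(spec.n_patches, spec.basis_dim,
                                spec.chroma_spread, rng)
    data = refl[labels]  # (H, W, bands)
    return SpectralImage(
        data=data,
        wavelengths_nm=CANONICAL_WAVELENGTHS,
        kind="reflectance",
        degrees_per_pixel=spec.span_deg / spec.width,
    )


def make_two_region_scene(height: int = 64, width: int = 84,
                          span_deg: float = 6.9) -> SpectralImage:
    """Left/right two-region scene: a long-wavelength-reflecting half and a
    middle-wavelength-reflecting half; useful for bimodality fixtures."""
    grid = CANONICAL_WAVELENGTHS
    reddish = np.clip(0.15 + 0.75 * spectral_basis(6, grid)[4], 0.0, 1.0)
    greenish = np.clip(0.15 + 0.75 * spectral_basis(6, grid)[2], 0.0, 1.0)
    data = np.empty((height, width, grid.size))
    data[:, : width // 2, :] = reddish
    data[:, width // 2:, :] = greenish
    return SpectralImage(data=data, wavelengths_nm=grid, kind="reflectance",
                         degrees_per_pixel=span_deg / width)


def make_gaze(spec: GazeSpec, bounds: tuple[float, float]) -> GazeTrace:
    """Drift/saccade mixture gaze trace within ``bounds`` (width, height deg).

    Drift speeds follow ``5 * Beta(3, b)`` with the Beta parameter chosen so
    the mode equals ``slow_speed_scale``; they never exceed 5 deg/s, so the
    expected sub-5 deg/s fraction equals ``slow_fraction`` exactly.
    ``saccade_speed_scale = 0`` degenerates to an all-slow trace.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    w, h = bounds
    vmax = 5.0
    a = 3.0
    b = (a - 1.0) * vmax / spec.slow_speed_scale - a + 2.0

    p_saccade = 0.0 if spec.saccade_speed_scale == 0.0 else 1.0 - spec.slow_fraction
    saccade = rng.random(n - 1) < p_saccade
    speeds = np.where(
        saccade,
        np.abs(rng.normal(spec.saccade_speed_scale,
                          0.25 * max(spec.saccade_speed_scale, 1e-9), n - 1)),
        vmax * rng.beta(a, b, n - 1),
    )
    steps = speeds * spec.interval_s

    pos = np.empty((n, 2))
    pos[0] = rng.uniform([0.0, 0.0], [w, h])
    p = pos[0].copy()
    for i in range(1, n):
        step = min(steps[i - 1], 0.99 * min(w, h))
        for _ in range(10000):
            theta = rng.uniform(0.0, 2.0 * np.pi)
            cand = p + step * np.array([np.cos(theta), np.sin(theta)])
            if 0.0 <= cand[0] <= w and 0.0 <= cand[1] <= h:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not place an in-bounds gaze step")
        p = cand
        pos[i] = p
    times = np.arange(n) * spec.interval_s
    return GazeTrace(times, pos[:, 0], pos[:, 1], np.ones(n, dtype=bool))


@dataclass(frozen=True)
class FixtureSet:
    """Canonical synthetic bundle used throughout the test suite."""

    scenes: dict
    illuminants: dict
    traces: dict
    seed: int


def make_fixture_set(seed: int = 0, n_frames: int = 3000,
                     height: int = 64, width: int = 84) -> FixtureSet:
    """Uniform, two-region and high-variance scenes; 4,000 K test and
    5,571 K reference daylights; one trace per gaze model.

    Traces are simulated over the high-variance scene's angular bounds.
    """
    duration = n_frames * 0.02
    scenes = {
        "uniform": make_scene(SceneSpec(height=height, width=width,
                                        chroma_spread=0.0, seed=seed)),
        "two_region": make_two_region_scene(height, width),
        "high_variance": make_scene(SceneSpec(height=height, width=width,
                                              n_patches=24, chroma_spread=0.25,
                                              seed=seed + 1)),
    }
    illuminants = {
        "test_4000k": daylight_spd(4000.0),
        "reference_5571k": daylight_spd(5571.0),
    }
    scene = scenes["high_variance"]
    bounds = scene.angular_extent_deg
    base = WalkConfig(duration_s=duration, bounds=bounds, seed=seed + 10)
    traces = {
        "random": simulate_random_gaze(base),
        "walk": simulate_random_walk(base),
        "feature": simulate_local_feature(
            scene, WalkConfig(step_speed_degps=0.77, duration_s=duration,
                              bounds=bounds, seed=seed + 10)),
    }
    return FixtureSet(scenes=scenes, illuminants=illuminants, traces=traces,
                      seed=seed)
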