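"""Gaze traces, velocity filtering, and simulated observers.

Gaze positions are expressed in scene-angular coordinates: origin at the
top-left corner of the image, x increasing rightward and y downward, in
degrees.  Traces are sampled at a fixed interval, 20 ms (50 Hz) by default,
matching the temporal resolution of the source eye-tracking recordings.

Three simulated observers are provided:

* **random gaze** — an i.i.d. uniform position in every frame; the upper
  bound on how well any gaze strategy can sample a scene.
* **random walk** — a fixed angular step in a uniformly random direction
  each frame (directions are re-drawn when a step would leave the image);
  step speeds of interest are the recorded modal speed 2.3 deg/s and 1/3
  and 3 times that mode (0.77 and 6.9 deg/s).
* **local feature** — a walk confined to a 0.5-deg-diameter disc around the
  5 x 5-pixel region of maximum CIELAB chroma, modelling gaze captured by a
  single chromatically salient feature.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace

import numpy as np

from .spectral_core import Spectrum, lab_chroma, spd_to_xyz, xyz_image

__all__ = [
    "GazeTrace",
    "WalkConfig",
    "MODE_SPEED_DEGPS",
    "gaze_speeds",
    "filter_speed",
    "cumulative_speed_fraction",
    "simulate_random_gaze",
    "simulate_random_walk",
    "simulate_local_feature",
    "read_gaze_csv",
    "write_gaze_csv",
]

#: Modal angular speed of the recorded gaze shifts (deg/s); a configuration
#: default for the random-walk observer, not recomputed from data.
MODE_SPEED_DEGPS = 2.3


@dataclass(frozen=True)
class GazeTrace:
    """Timestamped angular gaze positions at a fixed sampling interval."""

    times_s: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        x = np.asarray(self.x_deg, dtype=float)
        y = np.asarray(self.y_deg, dtype=float)
        v = np.asarray(self.valid, dtype=bool)
        if not (t.shape == x.shape == y.shape == v.shape) or t.ndim != 1:
            raise ValueError("times, positions and validity must be equal-length 1-D")
        if t.size >= 2:
            steps = np.diff(t)
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
                raise ValueError("gaze timestamps must be uniformly spaced")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "x_deg", x)
        object.__setattr__(self, "y_deg", y)
        object.__setattr__(self, "valid", v)

    def __len__(self) -> int:
        return self.times_s.size

    @property
    def interval_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])


@dataclass(frozen=True)
class WalkConfig:
    """Configuration for simulated observers.

    ``bounds`` is the image angular extent (width_deg, height_deg);
    positions live in [0, width_deg] x [0, height_deg].
    """

    step_speed_degps: float = MODE_SPEED_DEGPS
    duration_s: float = 300.0
    interval_s: float = 0.02
    bounds: tuple[float, float] = (6.9, 5.3)
    seed: int = 0
    start: tuple[float, float] | None = None

    def __post_init__(self):
        if self.step_speed_degps <= 0:
            raise ValueError("step_speed_degps must be positive")
        n = self.duration_s / self.interval_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s must be an integral number of intervals")
        if min(self.bounds) <= 0:
            raise ValueError("bounds must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.interval_s))


def gaze_speeds(trace: GazeTrace) -> np.ndarray:
    """Angular speed (deg/s) between consecutive samples; length n - 1."""
    if len(trace) < 2:
        raise ValueError("need at least 2 samples to compute speeds")
    dt = np.diff(trace.times_s)
    return np.hypot(np.diff(trace.x_deg), np.diff(trace.y_deg)) / dt


def filter_speed(trace: GazeTrace, vmax: float = 5.0) -> GazeTrace:
    """Invalidate samples reached by a gaze shift faster than ``vmax`` deg/s.

    The speed of each consecutive pair is attributed to the later sample;
    the first sample is always valid.  Invalid samples are skipped (never
    interpolated) by downstream accumulation.  ``vmax = inf`` disables the
    exclusion (the robustness re-analysis).
    """
    if vmax <= 0:
        raise ValueError("vmax must be positive")
    valid = trace.valid.copy()
    if len(trace) >= 2:
        fast = gaze_speeds(trace) > vmax
        valid[1:] &= ~fast
    valid[0] = True
    return replace(trace, valid=valid)


def cumulative_speed_fraction(trace: GazeTrace, v: float) -> float:
    """Fraction of inter-sample speeds at or below ``v`` deg/s."""
    speeds = gaze_speeds(trace)
    return float(np.mean(speeds <= v))


def _make_times(config: WalkConfig) -> np.ndarray:
    return np.arange(config.n_frames) * config.interval_s


def _start_position(config: WalkConfig, rng: np.random.Generator) -> np.ndarray:
    if config.start is not None:
        return np.asarray(config.start, dtype=float)
    w, h = config.bounds
    return rng.uniform([0.0, 0.0], [w, h])


def simulate_random_gaze(config: WalkConfig) -> GazeTrace:
    """I.i.d. uniform gaze positions within the image bounds (seeded)."""
    rng = np.random.default_rng(config.seed)
    start = _start_position(config, rng)
    w, h = config.bounds
    n = config.n_frames
    pos = rng.uniform([0.0, 0.0], [w, h], size=(n, 2))
    pos[0] = start
    return GazeTrace(_make_times(config), pos[:, 0], pos[:, 1],
                     np.ones(n, dtype=bool))


def _bounded_walk(n: int, start: np.ndarray, step: float,
                  lo: np.ndarray, hi: np.ndarray,
                  rng: np.random.Generator,
                  center: np.ndarray | None = None,
                  radius: float | None = None) -> np.ndarray:
    """Fixed-step walk; directions re-drawn until the step stays inside the
    rectangle [lo, hi] (and optionally the disc of ``radius`` about
    ``center``)."""
    pos = np.empty((n, 2))
    pos[0] = start
    p = start.copy()
    for i in range(1, n):
        for _ in range(10000):
            theta = rng.uniform(0.0, 2.0 * np.pi)
            cand = p + step * np.array([np.cos(theta), np.sin(theta)])
            if np.all(cand >= lo) and np.all(cand <= hi) and (
                radius is None or np.hypot(*(cand - center)) <= radius
            ):
                break
        else:  # pragma: no cover - only reachable with a degenerate geometry
            raise RuntimeError("could not find an in-bounds step")
        p = cand
        pos[i] = p
    return pos


def simulate_random_walk(config: WalkConfig) -> GazeTrace:
    """Random walk: fixed angular step, uniformly random direction each frame."""
    step = config.step_speed_degps * config.interval_s
    w, h = config.bounds
    if step >= min(w, h):
        raise ValueError("step size exceeds the image bounds")
    rng = np.random.default_rng(config.seed)
    start = _start_position(config, rng)
    pos = _bounded_walk(config.n_frames, start, step,
                        np.array([0.0, 0.0]), np.array([w, h]), rng)
    return GazeTrace(_make_times(config), pos[:, 0], pos[:, 1],
                     np.ones(config.n_frames, dtype=bool))


def max_chroma_center(scene, white=None) -> tuple[float, float]:
    """Angular position of the center of the 5 x 5-pixel window with the
    highest mean CIELAB chroma (ties broken first-in-row-major-order).

    ``white`` defaults to the XYZ of a unit spectrum on the scene grid
    (equal-energy white for reflectance cubes).
    """
    if scene.height < 5 or scene.width < 5:
        raise ValueError("scene must be at least 5 x 5 pixels")
    xyz = xyz_image(scene)
    if white is None:
        white = spd_to_xyz(Spectrum(scene.wavelengths_nm,
                                    np.ones_like(scene.wavelengths_nm)))
    chroma = lab_chroma(xyz, white)
    # mean chroma over all 5x5 windows via a separable box filter
    from scipy.ndimage import uniform_filter

    mean5 = uniform_filter(chroma, size=5, mode="constant")
    interior = mean5[2:-2, 2:-2]
    idx = np.unravel_index(np.argmax(interior), interior.shape)
    row, col = idx[0] + 2, idx[1] + 2
    dpp = scene.degrees_per_pixel
    return ((col + 0.5) * dpp, (row + 0.5) * dpp)  # (x_deg, y_deg)


def simulate_local_feature(scene, config: WalkConfig,
                           diameter_deg: float = 0.5) -> GazeTrace:
    """Local-feature observer: a fixed-step walk confined to a
    ``diameter_deg`` disc centered on the maximum-chroma 5 x 5 window.

    The default step speed follows the one-third-of-mode convention
    (0.77 deg/s); pass a config with that speed explicitly when comparing
    observers.
    """
    cx, cy = max_chroma_center(scene)
    center = np.array([cx, cy])
    radius = diameter_deg / 2.0
    step = config.step_speed_degps * config.interval_s
    w, h = config.bounds
    rng = np.random.default_rng(config.seed)
    pos = _bounded_walk(config.n_frames, center.copy(), step,
                        np.array([0.0, 0.0]), np.array([w, h]), rng,
                        center=center, radius=radius)
    return GazeTrace(_make_times(config), pos[:, 0], pos[:, 1],
                     np.ones(config.n_frames, dtype=bool))


# --------------------------------------------------------------------------
# CSV dialect: time_s,x_deg,y_deg,valid
# --------------------------------------------------------------------------

def write_gaze_csv(trace: GazeTrace, path) -> str:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "x_deg", "y_deg", "valid"])
        for t, x, y, v in zip(trace.times_s, trace.x_deg, trace.y_deg, trace.valid):
            w.writerow([f"{t:.6f}", f"{x:.6f}", f"{y:.6f}", int(v)])
    return str(path)


def read_gaze_csv(path) -> GazeTrace:
    times, xs, ys, vs = [], [], [], []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            times.append(float(row["time_s"]))
            xs.append(float(row["x_deg"]))
            ys.append(float(row["y_deg"]))
            vs.append(bool(int(row.get("valid", 1))))
    return GazeTrace(np.array(times), np.array(xs), np.array(ys),
                     np.array(vs, dtype=bool))
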