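"""Local vs. global von Kries adaptation under a global illuminant change.

The question: if each retinal location scales its cone-like response by the
reciprocal of its own exponentially weighted stimulus history (local
diagonal transform), how close does the result come to scaling every
location by the reciprocal of the global scene mean (global diagonal
transform)?  Closeness is measured as the median CAM16-UCS color difference
over the 5-degree foveal patch, tracked over viewing time while the scene is
relit by a 4,000 K daylight illuminant.

The degree-of-adaptation factor of colorimetric adaptation models is fixed
at complete adaptation throughout, and CAM16's own chromatic-adaptation
stage is skipped (the diagonal corrections here replace it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gaze_models import GazeTrace
from .hyperspectral_io import SpectralImage
from .retinal_sampling import DensityProfile, RetinalSampler
from .spectral_core import (
    Spectrum,
    ViewingConditions,
    apply_illuminant,
    cam16_ucs_coords,
    daylight_spd,
    delta_e_ucs,
    illuminant_xyz_scale,
    xyz_image,
    xyz_to_cam16_rgb,
)

__all__ = [
    "AdaptationField",
    "GlobalGains",
    "DeltaESummary",
    "UCS_JND",
    "exponential_weights",
    "local_adaptation_field",
    "diagonal_correct_local",
    "diagonal_correct_global",
    "global_gains_of",
    "median_delta_e",
    "evaluation_times",
    "adaptation_timecourse",
    "uncorrected_delta_e",
]

#: Reference just-noticeable difference in CAM16-UCS (configured constant,
#: transformed from a CIELAB jnd of about 2.2).
UCS_JND = 2.46


@dataclass(frozen=True)
class AdaptationField:
    """Per-pixel diagonal gains over the retinal patch."""

    gains: np.ndarray  # (side, side, 3), strictly positive
    tau_s: float
    t_index: int = 0

    def __post_init__(self):
        g = np.asarray(self.gains, dtype=float)
        if g.ndim != 3 or g.shape[-1] != 3:
            raise ValueError("gains must be (side, side, 3)")
        if not np.all(np.isfinite(g)) or np.any(g <= 0):
            raise ValueError("gains must be finite and positive")
        object.__setattr__(self, "gains", g)


@dataclass(frozen=True)
class GlobalGains:
    """Scene-wide diagonal gains (reciprocal global mean responses)."""

    a: float
    b: float
    c: float

    def __post_init__(self):
        v = np.array([self.a, self.b, self.c], dtype=float)
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("global gains must be finite and positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])


@dataclass(frozen=True)
class DeltaESummary:
    """Median CAM16-UCS color difference time course."""

    times_s: np.ndarray
    median_dE: np.ndarray
    tau_s: float
    eval_indices: np.ndarray = field(default_factory=lambda: np.array([], int))
    jnd: float = UCS_JND


def exponential_weights(frame_times, now: float, tau_s: float) -> np.ndarray:
    """Normalized weights exp(-(now - t_k) / tau), largest for the most recent."""
    t = np.asarray(frame_times, dtype=float)
    if t.size == 0:
        raise ValueError("frame history is empty")
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    if np.any(t > now + 1e-12):
        raise ValueError("frame times must not lie in the future")
    w = np.exp(-(now - t) / tau_s)
    return w / w.sum()


def _floor_positive(x: np.ndarray, frac: float = 1e-6) -> np.ndarray:
    """Epsilon-floor per channel at ``frac`` of the channel maximum."""
    out = np.array(x, dtype=float, copy=True)
    for c in range(out.shape[-1]):
        ch = out[..., c]
        top = np.max(np.abs(ch))
        floor = frac * top if top > 0 else frac
        out[..., c] = np.maximum(ch, floor)
    return out


def local_adaptation_field(history, now: float, tau_s: float,
                           floor_frac: float = 1e-6) -> AdaptationField:
    """Estimate the local adaptation gains from a history of retinal frames.

    ``history`` is a list of :class:`~gazediet.retinal_sampling.RetinalFrame`
    (their patches interpreted as cone-like RGB fields) or of raw
    (side, side, 3) arrays with associated times; gains are the reciprocals
    of the exponentially weighted mean response, epsilon-floored.
    """
    if not history:
        raise ValueError("frame history is empty")
    if hasattr(history[0], "patch"):
        patches = [f.patch.as_stack() for f in history]
        times = [f.time_s for f in history]
    else:
        patches, times = zip(*history)
        patches = [np.asarray(p, dtype=float) for p in patches]
    shape = patches[0].shape
    if any(p.shape != shape for p in patches):
        raise ValueError("history frames must share one patch grid")
    w = exponential_weights(times, now, tau_s)
    mean = np.tensordot(w, np.stack(patches), axes=1)
    gains = 1.0 / _floor_positive(mean, floor_frac)
    return AdaptationField(gains=gains, tau_s=tau_s, t_index=len(history))


def diagonal_correct_local(frame_rgb: np.ndarray, fld: AdaptationField) -> np.ndarray:
    """Pixelwise diagonal (von Kries) correction with spatially varying gains."""
    frame_rgb = np.asarray(frame_rgb, dtype=float)
    if frame_rgb.shape != fld.gains.shape:
        raise ValueError("frame and adaptation field shapes differ")
    return frame_rgb * fld.gains


def global_gains_of(rgb_image: np.ndarray, floor_frac: float = 1e-6) -> GlobalGains:
    """Reciprocal global spatial means of a cone-like RGB image."""
    rgb_image = np.asarray(rgb_image, dtype=float)
    mean = _floor_positive(rgb_image.reshape(-1, 3).mean(axis=0), floor_frac)
    if np.any(mean <= 0):
        raise ValueError("global mean response must be positive")
    inv = 1.0 / mean
    return GlobalGains(*inv)


def diagonal_correct_global(frame_rgb: np.ndarray, gains: GlobalGains) -> np.ndarray:
    """One diagonal transform applied to every pixel."""
    return np.asarray(frame_rgb, dtype=float) * gains.as_array()


def median_delta_e(local_img: np.ndarray, global_img: np.ndarray,
                   vc: ViewingConditions | None = None,
                   mask: np.ndarray | None = None,
                   rgb_scale: float = 100.0) -> float:
    """Median per-pixel CAM16-UCS color difference between two RGB images.

    ``rgb_scale`` lifts corrected responses (near 1 after a diagonal
    correction) onto the model's nominal 0–100 range where the reference
    white of ``vc`` lives.
    """
    local_img = np.asarray(local_img, dtype=float)
    global_img = np.asarray(global_img, dtype=float)
    if local_img.shape != global_img.shape:
        raise ValueError("image shapes differ")
    vc = vc or ViewingConditions()
    p = cam16_ucs_coords(local_img * rgb_scale, vc)
    q = cam16_ucs_coords(global_img * rgb_scale, vc)
    dE = delta_e_ucs(p, q)
    if mask is not None:
        dE = dE[mask]
    return float(np.median(dE))


def evaluation_times(n_frames: int = 15000, count: int = 6,
                     first_index: int = 3) -> np.ndarray:
    """Roughly geometrically spaced 1-based frame indices from ``first_index``
    to ``n_frames - 1`` inclusive (each estimate corrects the next frame, so
    the last usable index is ``n_frames - 1``)."""
    if count < 2:
        raise ValueError("count must be >= 2")
    last = n_frames - 1
    if first_index < 1 or last <= first_index:
        raise ValueError("count/range of evaluation indices is infeasible")
    if count > last - first_index + 1:
        raise ValueError("count exceeds the available index range")
    idx = np.round(np.geomspace(first_index, last, count)).astype(int)
    for i in range(1, count):  # deduplicate while preserving the count
        if idx[i] <= idx[i - 1]:
            idx[i] = idx[i - 1] + 1
    idx[0], idx[-1] = first_index, last
    return idx


def _weight_map(trace: GazeTrace, n: int, tau_s: float,
                dpp: float, shape: tuple[int, int]) -> np.ndarray:
    """Scatter normalized exponential weights of valid samples 1..n onto the
    scene pixel grid."""
    valid = trace.valid[:n]
    if not np.any(valid):
        raise ValueError("no valid gaze samples in the history window")
    times = trace.times_s[:n][valid]
    now = trace.times_s[n - 1]
    w = exponential_weights(times, now, tau_s)
    cols = np.clip(np.floor(trace.x_deg[:n][valid] / dpp).astype(int), 0, shape[1] - 1)
    rows = np.clip(np.floor(trace.y_deg[:n][valid] / dpp).astype(int), 0, shape[0] - 1)
    wmap = np.zeros(shape)
    np.add.at(wmap, (rows, cols), w)
    return wmap


def scene_cam16_rgb(scene_reflectance: SpectralImage,
                    illuminant: Spectrum) -> np.ndarray:
    """Per-pixel CAM16 cone-like RGB of the relit scene.

    XYZ is normalized so a perfect reflector under the illuminant has
    Y = 100.
    """
    relit = apply_illuminant(scene_reflectance, illuminant)
    xyz = xyz_image(relit, illuminant=illuminant)
    return xyz_to_cam16_rgb(xyz)


def adaptation_timecourse(scene_reflectance: SpectralImage, trace: GazeTrace,
                          illuminant_cct: float = 4000.0,
                          tau_s: float = 1.0,
                          vc: ViewingConditions | None = None,
                          profile: DensityProfile | None = None,
                          eval_indices: np.ndarray | None = None,
                          n_times: int = 6,
                          sampler: RetinalSampler | None = None,
                          floor_frac: float = 1e-6) -> DeltaESummary:
    """Median local-vs-global correction difference over viewing time.

    The reflectance scene is relit at ``illuminant_cct``; at each evaluation
    index n the local adaptation field is estimated from the exponentially
    weighted history of retinal frames f_1..f_n and applied to the frame at
    t_{n+1}; the same frame is corrected by the global scene-mean gains; the
    median CAM16-UCS difference over the 5-degree disc is recorded.

    A prebuilt ``sampler`` over the relit scene RGB may be passed to share
    work across time constants.
    """
    vc = vc or ViewingConditions()
    if sampler is None:
        rgb = scene_cam16_rgb(scene_reflectance, daylight_spd(illuminant_cct))
        sampler = RetinalSampler(rgb, scene_reflectance.degrees_per_pixel,
                                 profile=profile)
        scene_rgb = rgb
    else:
        pad = sampler.pad
        scene_rgb = sampler.stack[0, pad:-pad, pad:-pad, :]
    g_gains = global_gains_of(scene_rgb, floor_frac)

    if eval_indices is None:
        eval_indices = evaluation_times(len(trace), count=n_times)
    eval_indices = np.asarray(eval_indices, dtype=int)
    if eval_indices.max() + 1 > len(trace):
        raise ValueError("trace too short for the requested evaluation indices")

    med = np.empty(eval_indices.size)
    for i, n in enumerate(eval_indices):
        wmap = _weight_map(trace, int(n), tau_s, sampler.dpp, sampler.shape)
        adapt = sampler.weighted_history_patch(wmap)
        gains = 1.0 / _floor_positive(adapt, floor_frac)
        fld = AdaptationField(gains=gains, tau_s=tau_s, t_index=int(n))
        frame = sampler.patch_at(trace.x_deg[n], trace.y_deg[n])
        local_corr = diagonal_correct_local(frame, fld)
        global_corr = diagonal_correct_global(frame, g_gains)
        med[i] = median_delta_e(local_corr, global_corr, vc, mask=sampler.mask)
    return DeltaESummary(
        times_s=trace.times_s[eval_indices - 1],
        median_dE=med,
        tau_s=tau_s,
        eval_indices=eval_indices,
    )


def uncorrected_delta_e(scene_reflectance: SpectralImage,
                        original_illuminant: Spectrum,
                        test_cct: float = 4000.0,
                        vc: ViewingConditions | None = None) -> float:
    """Median color shift introduced by the test illuminant with no correction.

    Both renderings share the original illuminant's XYZ normalization so the
    full photometric and chromatic shift of the relighting is retained.
    """
    vc = vc or ViewingConditions()
    k = illuminant_xyz_scale(original_illuminant, scene_reflectance.wavelengths_nm)
    rgb_orig = xyz_to_cam16_rgb(
        xyz_image(apply_illuminant(scene_reflectance, original_illuminant), k=k))
    test = daylight_spd(test_cct)
    rgb_test = xyz_to_cam16_rgb(
        xyz_image(apply_illuminant(scene_reflectance, test), k=k))
    return median_delta_e(rgb_orig, rgb_test, vc, rgb_scale=1.0)
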