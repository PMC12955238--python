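"""Retinal sampling: eccentricity-blurred 5-degree foveal patches.

At each gaze position the scene's cone-excitation image is sampled through a
model retina: a disc of 5 degrees diameter (roughly the fovea) whose spatial
resolution falls with eccentricity.  Blur is Gaussian with standard
deviation ``sigma0_px`` (default 1 px, about 1 arcmin) at the patch center,
growing as the reciprocal of relative cone density with eccentricity and
capped for tractability.  The scene is padded with its own mirror image so
every gaze position yields a full, equally sized patch.

Implementation note: the spatially varying blur is realized by quantizing
sigma(e) into a small set of levels, blurring the padded image once per
level, and assembling each patch from the per-pixel level map.  At the patch
center the level is exactly ``sigma0_px``, so foveal samples are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .gaze_models import GazeTrace
from .spectral_core import ConeTriple

__all__ = [
    "ConeImage",
    "DensityProfile",
    "RetinalFrame",
    "RetinalSampler",
    "mirror_pad",
    "make_retinal_frame",
    "foveal_series",
    "sigma0_blurred",
]


@dataclass(frozen=True)
class ConeImage:
    """Per-pixel (qL, qM, qS) cone excitations with angular metadata."""

    qL: np.ndarray
    qM: np.ndarray
    qS: np.ndarray
    degrees_per_pixel: float

    def __post_init__(self):
        for name in ("qL", "qM", "qS"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != np.shape(self.qL):
                raise ValueError("cone channels must share one shape")
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{name} must be finite and nonnegative")
            object.__setattr__(self, name, v)
        if self.degrees_per_pixel <= 0:
            raise ValueError("degrees_per_pixel must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.qL.shape

    def as_stack(self) -> np.ndarray:
        """(H, W, 3) view of the three channels."""
        return np.stack([self.qL, self.qM, self.qS], axis=-1)

    @classmethod
    def from_stack(cls, stack: np.ndarray, degrees_per_pixel: float) -> "ConeImage":
        return cls(stack[..., 0], stack[..., 1], stack[..., 2], degrees_per_pixel)


@dataclass(frozen=True)
class DensityProfile:
    """Relative cone density d(e)/d(0) as a function of eccentricity (deg).

    The default is a smooth inverse-square falloff
    ``d(e)/d(0) = (1 + e / e_half)**-2`` with ``e_half = 1`` deg, standing in
    for tabulated foveal cone-density data; a tabulated profile can be
    supplied via :meth:`from_table`.
    """

    e_half_deg: float = 1.0
    table: tuple | None = None  # (eccentricities, relative densities)

    def relative_density(self, e):
        e = np.asarray(e, dtype=float)
        if self.table is not None:
            ecc, dens = self.table
            return np.interp(e, ecc, dens)
        return (1.0 + e / self.e_half_deg) ** -2.0

    @classmethod
    def flat(cls) -> "DensityProfile":
        """Uniform density (constant-sigma blur); used by oracle tests."""
        return cls(table=(np.array([0.0, 100.0]), np.array([1.0, 1.0])))

    @classmethod
    def from_table(cls, eccentricity_deg, relative_density) -> "DensityProfile":
        ecc = np.asarray(eccentricity_deg, dtype=float)
        dens = np.asarray(relative_density, dtype=float)
        if dens[0] != 1.0:
            raise ValueError("relative density must be 1 at eccentricity 0")
        if np.any(np.diff(dens[ecc <= 2.5]) > 0):
            raise ValueError("relative density must be non-increasing over the fovea")
        return cls(table=(ecc, dens))

    @classmethod
    def from_csv(cls, path) -> "DensityProfile":
        import csv as _csv

        ecc, dens = [], []
        with open(path) as fh:
            for row in _csv.DictReader(fh):
                ecc.append(float(row["eccentricity_deg"]))
                dens.append(float(row["relative_density"]))
        return cls.from_table(np.array(ecc), np.array(dens))


@dataclass(frozen=True)
class RetinalFrame:
    """One eccentricity-blurred retinal patch and its foveal-center sample."""

    patch: ConeImage           # square patch (side x side)
    mask: np.ndarray           # boolean disc of 5 deg diameter
    fovea: ConeTriple
    gaze: tuple[float, float]  # (x_deg, y_deg)
    time_s: float


def mirror_pad(image: ConeImage, pad_deg: float) -> ConeImage:
    """Reflect the image into a border of ``pad_deg`` degrees on all sides.

    Padding wider than the image itself falls back to repeated reflection
    (tiling) with a warning.
    """
    pad_px = int(np.ceil(pad_deg / image.degrees_per_pixel))
    h, w = image.shape
    if pad_px > min(h, w):
        warnings.warn("padding exceeds image size; reflection is tiled", stacklevel=2)
    stack = image.as_stack()
    padded = np.pad(stack, ((pad_px, pad_px), (pad_px, pad_px), (0, 0)),
                    mode="symmetric")
    return ConeImage.from_stack(padded, image.degrees_per_pixel)


def _gaze_to_pixel(x_deg: float, y_deg: float, dpp: float,
                   shape: tuple[int, int]) -> tuple[int, int]:
    """Nearest pixel center to an angular gaze position (row, col)."""
    col = int(np.clip(np.floor(x_deg / dpp), 0, shape[1] - 1))
    row = int(np.clip(np.floor(y_deg / dpp), 0, shape[0] - 1))
    return row, col


class RetinalSampler:
    """Precomputed blur stack for repeated retinal sampling of one scene.

    Parameters
    ----------
    image : ConeImage or (H, W, C) array of per-pixel fields to be sampled
        (cone excitations or CAM16 RGB).
    profile : DensityProfile
    sigma0_px : foveal blur standard deviation in pixels.
    patch_diameter_deg : angular diameter of the retinal patch.
    sigma_cap_px : upper bound on sigma(e) for tractability.
    level_step_px : quantization step for the sigma levels.
    """

    def __init__(self, image, degrees_per_pixel: float | None = None,
                 profile: DensityProfile | None = None,
                 sigma0_px: float = 1.0,
                 patch_diameter_deg: float = 5.0,
                 sigma_cap_px: float = 8.0,
                 level_step_px: float = 0.5,
                 truncate: float = 4.0):
        if isinstance(image, ConeImage):
            fields = image.as_stack()
            degrees_per_pixel = image.degrees_per_pixel
        else:
            fields = np.asarray(image, dtype=float)
            if degrees_per_pixel is None:
                raise ValueError("degrees_per_pixel required for array input")
        if fields.ndim != 3:
            raise ValueError("sampler fields must be (H, W, C)")
        self.dpp = float(degrees_per_pixel)
        self.profile = profile or DensityProfile()
        self.sigma0 = float(sigma0_px)
        self.truncate = float(truncate)
        self.shape = fields.shape[:2]

        side = int(round(patch_diameter_deg / self.dpp))
        if side % 2 == 0:
            side += 1  # odd side so the patch has a center pixel
        self.side = side
        r = side // 2
        self.radius_px = r

        # eccentricity, sigma and level maps over the patch
        di = np.arange(-r, r + 1)
        ecc = np.hypot(di[:, None], di[None, :]) * self.dpp
        self.mask = ecc <= patch_diameter_deg / 2.0
        dens = self.profile.relative_density(np.minimum(ecc, patch_diameter_deg / 2.0))
        sigma = np.minimum(self.sigma0 / dens, sigma_cap_px)
        quant = self.sigma0 + np.round((sigma - self.sigma0) / level_step_px) * level_step_px
        self.levels = np.unique(quant)
        self.level_map = np.searchsorted(self.levels, quant)

        max_radius = int(self.truncate * self.levels.max() + 0.5)
        self.pad = r + max_radius
        padded = np.pad(fields, ((self.pad, self.pad), (self.pad, self.pad), (0, 0)),
                        mode="symmetric")
        self.stack = np.stack(
            [gaussian_filter(padded, (lvl, lvl, 0), truncate=self.truncate)
             for lvl in self.levels]
        )
        # gather indices for patch assembly
        self._pi = self.level_map
        self._pr = di[:, None] + np.zeros_like(di)[None, :]
        self._pc = di[None, :] + np.zeros_like(di)[:, None]

    @property
    def foveal_image(self) -> np.ndarray:
        """The sigma0-blurred full field (padded); exact at the patch center."""
        i0 = int(np.searchsorted(self.levels, self.sigma0))
        return self.stack[i0]

    def patch_at(self, x_deg: float, y_deg: float) -> np.ndarray:
        """(side, side, C) eccentricity-blurred patch centered at the gaze."""
        row, col = _gaze_to_pixel(x_deg, y_deg, self.dpp, self.shape)
        return self.stack[self._pi, row + self.pad + self._pr,
                          col + self.pad + self._pc, :]

    def fovea_at(self, x_deg: float, y_deg: float) -> np.ndarray:
        row, col = _gaze_to_pixel(x_deg, y_deg, self.dpp, self.shape)
        return self.foveal_image[row + self.pad, col + self.pad, :]

    def weighted_history_patch(self, weight_map: np.ndarray) -> np.ndarray:
        """Weighted sum over gaze history of the patches at each visited pixel.

        ``weight_map`` is an (H, W) array of per-pixel accumulated weights
        (typically summing to 1).  Returns the (side, side, C) weighted mean
        patch, computed exactly via FFT cross-correlation with the blur
        stack — equivalent to, but far cheaper than, summing the individual
        patches.
        """
        from scipy.signal import fftconvolve

        if weight_map.shape != self.shape:
            raise ValueError("weight map must match the scene shape")
        kernel = weight_map[::-1, ::-1]
        corr = np.empty((len(self.levels), 2 * self.pad + 1, 2 * self.pad + 1,
                         self.stack.shape[-1]))
        for li in range(len(self.levels)):
            for c in range(self.stack.shape[-1]):
                corr[li, :, :, c] = fftconvolve(self.stack[li, :, :, c], kernel,
                                                mode="valid")
        return corr[self._pi, self._pr + self.pad, self._pc + self.pad, :]

    def frame(self, x_deg: float, y_deg: float, time_s: float = 0.0) -> RetinalFrame:
        patch = self.patch_at(x_deg, y_deg)
        fov = self.fovea_at(x_deg, y_deg)
        return RetinalFrame(
            patch=ConeImage.from_stack(np.clip(patch, 0.0, None), self.dpp),
            mask=self.mask,
            fovea=ConeTriple(*fov),
            gaze=(x_deg, y_deg),
            time_s=time_s,
        )


def make_retinal_frame(image: ConeImage, gaze: tuple[float, float],
                       profile: DensityProfile | None = None,
                       sigma0_px: float = 1.0,
                       patch_diameter_deg: float = 5.0,
                       **kwargs) -> RetinalFrame:
    """Build a single eccentricity-blurred retinal frame at ``gaze``.

    Convenience wrapper around :class:`RetinalSampler`; for many frames from
    one scene construct the sampler once.
    """
    w_deg = image.shape[1] * image.degrees_per_pixel
    h_deg = image.shape[0] * image.degrees_per_pixel
    if not (0.0 <= gaze[0] <= w_deg and 0.0 <= gaze[1] <= h_deg):
        raise ValueError("gaze position outside the image bounds")
    sampler = RetinalSampler(image, profile=profile, sigma0_px=sigma0_px,
                             patch_diameter_deg=patch_diameter_deg, **kwargs)
    return sampler.frame(gaze[0], gaze[1])


def foveal_series(image: ConeImage, trace: GazeTrace,
                  profile: DensityProfile | None = None,
                  sigma0_px: float = 1.0) -> np.ndarray:
    """Time series of foveal-center cone excitations along a gaze trace.

    Invalid samples are omitted.  Returns an (n_valid, 3) array of
    (qL, qM, qS) in time order.
    """
    if not np.any(trace.valid):
        raise ValueError("gaze trace has no valid samples")
    blurred = sigma0_blurred(image, sigma0_px)
    dpp = image.degrees_per_pixel
    x = trace.x_deg[trace.valid]
    y = trace.y_deg[trace.valid]
    cols = np.clip(np.floor(x / dpp).astype(int), 0, image.shape[1] - 1)
    rows = np.clip(np.floor(y / dpp).astype(int), 0, image.shape[0] - 1)
    return blurred.as_stack()[rows, cols, :]


def sigma0_blurred(image: ConeImage, sigma0_px: float = 1.0) -> ConeImage:
    """Foveal-resolution view of the scene: the sigma0 Gaussian blur applied
    under mirror padding, cropped back to the original extent.

    This is the field both the foveal samples and (for consistency) the
    global diet statistics are drawn from.
    """
    pad = int(4.0 * sigma0_px + 0.5) + 1
    padded = np.pad(image.as_stack(), ((pad, pad), (pad, pad), (0, 0)),
                    mode="symmetric")
    blurred = gaussian_filter(padded, (sigma0_px, sigma0_px, 0), truncate=4.0)
    return ConeImage.from_stack(np.clip(blurred[pad:-pad, pad:-pad, :], 0.0, None),
                                image.degrees_per_pixel)
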