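"""Hyperspectral cube container and I/O.

The canonical on-disk container is HDF5 with a ``data`` dataset of shape
(height, width, bands) and attributes ``wavelengths_nm``, ``kind``
(``radiance`` or ``reflectance``) and ``degrees_per_pixel``.  ENVI
header/``.dat`` pairs are accepted read-only (BSQ/BIL/BIP interleaves).

Angular scale follows the acquisition geometry of the source imagery:
1344 x 1024 px spanning about 6.9 x 5.3 degrees, i.e. ~0.00513 deg/px
native, four times that after the standard 4x block-mean downsampling to
336 x 256 px.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from .spectral_core import GridError, Spectrum, _as_grid

__all__ = [
    "SpectralImage",
    "read_cube",
    "write_cube",
    "radiance_to_reflectance",
    "block_downsample",
    "NATIVE_DEGREES_PER_PIXEL",
]

#: 6.9 degrees over 1344 native pixels.
NATIVE_DEGREES_PER_PIXEL = 6.9 / 1344


class FormatError(ValueError):
    """Malformed or unsupported cube file."""


@dataclass(frozen=True)
class SpectralImage:
    """A wavelength-sampled image cube with angular-extent metadata.

    data: (height, width, bands), finite and nonnegative.
    kind: "radiance" or "reflectance"; reflectance values may exceed 1
    slightly (specular pixels) but are validated against gross violations.
    degrees_per_pixel: isotropic angular scale, > 0.
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    kind: str
    degrees_per_pixel: float

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        grid = _as_grid(self.wavelengths_nm)
        if data.ndim != 3:
            raise FormatError("cube data must be (height, width, bands)")
        if data.shape[2] != grid.size:
            raise FormatError(
                f"cube has {data.shape[2]} bands but the grid has {grid.size} entries"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("cube data must be finite")
        if np.any(data < 0):
            raise ValueError("cube data must be nonnegative")
        if self.kind not in ("radiance", "reflectance"):
            raise ValueError("kind must be 'radiance' or 'reflectance'")
        if self.kind == "reflectance" and np.any(data > 5.0):
            raise ValueError("reflectance values grossly exceed 1; wrong kind?")
        if self.degrees_per_pixel <= 0:
            raise ValueError("degrees_per_pixel must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "wavelengths_nm", grid)

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def angular_extent_deg(self) -> tuple[float, float]:
        """(width_deg, height_deg) of the imaged field."""
        return (self.width * self.degrees_per_pixel,
                self.height * self.degrees_per_pixel)

    def mean_spectrum(self) -> Spectrum:
        return Spectrum(self.wavelengths_nm, self.data.mean(axis=(0, 1)))


def write_cube(image: SpectralImage, path) -> str:
    """Write a cube to HDF5 (lossless round trip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=image.data)
        f.attrs["wavelengths_nm"] = image.wavelengths_nm
        f.attrs["kind"] = image.kind
        f.attrs["degrees_per_pixel"] = image.degrees_per_pixel
    return str(path)


def _read_hdf5(path) -> SpectralImage:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise FormatError("HDF5 cube is missing the 'data' dataset")
        if "wavelengths_nm" not in f.attrs:
            raise FormatError("HDF5 cube is missing wavelength metadata")
        data = f["data"][()]
        if np.any(~np.isfinite(data)):
            raise ValueError("cube contains NaN or infinite values")
        return SpectralImage(
            data=data,
            wavelengths_nm=np.asarray(f.attrs["wavelengths_nm"], dtype=float),
            kind=str(f.attrs.get("kind", "radiance")),
            degrees_per_pixel=float(
                f.attrs.get("degrees_per_pixel", NATIVE_DEGREES_PER_PIXEL)
            ),
        )


def _read_envi(path) -> SpectralImage:
    """Read an ENVI header/.dat pair (read-only support)."""
    hdr_path = path if str(path).endswith(".hdr") else str(path) + ".hdr"
    if not os.path.exists(hdr_path):
        base, _ = os.path.splitext(str(path))
        hdr_path = base + ".hdr"
    if not os.path.exists(hdr_path):
        raise FormatError(f"no ENVI header found for {path}")

    fields: dict[str, str] = {}
    with open(hdr_path) as fh:
        text = fh.read()
    # join {...} blocks, then parse key = value lines
    text = text.replace("\n", " \n")
    import re

    for m in re.finditer(r"(?m)^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", text):
        fields[m.group(1).strip().lower()] = m.group(2).strip()

    def _num(key, default=None):
        if key not in fields:
            if default is None:
                raise FormatError(f"ENVI header missing '{key}'")
            return default
        return int(float(fields[key]))

    samples, lines, bands = _num("samples"), _num("lines"), _num("bands")
    interleave = fields.get("interleave", "bsq").lower()
    dtype_map = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
    dtype = dtype_map.get(_num("data type", 4))
    if "wavelength" not in fields:
        raise FormatError("ENVI header missing wavelength metadata")
    wavelengths = np.array(
        [float(v) for v in fields["wavelength"].strip("{}").split(",") if v.strip()]
    )

    dat_path = None
    for ext in ("", ".dat", ".img", ".raw"):
        cand = os.path.splitext(hdr_path)[0] + ext
        if os.path.exists(cand) and not cand.endswith(".hdr"):
            dat_path = cand
            break
    if dat_path is None:
        raise FormatError(f"no ENVI data file found next to {hdr_path}")

    raw = np.fromfile(dat_path, dtype=dtype)
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise FormatError(f"unsupported ENVI interleave '{interleave}'")
    return SpectralImage(
        data=np.ascontiguousarray(data, dtype=float),
        wavelengths_nm=wavelengths,
        kind=fields.get("kind", "radiance"),
        degrees_per_pixel=float(fields.get("degrees_per_pixel",
                                           NATIVE_DEGREES_PER_PIXEL)),
    )


def read_cube(path, format: str | None = None) -> SpectralImage:
    """Read a cube from HDF5 (canonical) or ENVI (read-only)."""
    if format is None:
        s = str(path)
        format = "envi" if s.endswith((".hdr", ".dat", ".img", ".raw")) else "hdf5"
    if format == "hdf5":
        return _read_hdf5(path)
    if format == "envi":
        return _read_envi(path)
    raise FormatError(f"unsupported format '{format}'")


def radiance_to_reflectance(cube: SpectralImage, reference: Spectrum) -> SpectralImage:
    """Effective reflectance: pixelwise division by the direct-illumination
    spectrum recorded from a neutral reference surface.

    Specular pixels may exceed 1; a warning is emitted but values are not
    clipped.
    """
    if cube.kind != "radiance":
        raise ValueError("cube must be a radiance image")
    ref = reference.resample(cube.wavelengths_nm)
    if np.any(ref.values <= 0):
        raise ZeroDivisionError("reference spectrum must be strictly positive on all bands")
    data = cube.data / ref.values
    if np.any(data > 1.0 + 1e-9):
        warnings.warn("reflectance exceeds 1 for some pixels (specular highlights?)",
                      stacklevel=2)
    return SpectralImage(
        data=data,
        wavelengths_nm=cube.wavelengths_nm,
        kind="reflectance",
        degrees_per_pixel=cube.degrees_per_pixel,
    )


def block_downsample(cube: SpectralImage, factor: int) -> SpectralImage:
    """Spatial averaging over non-overlapping factor x factor blocks.

    Dimensions not divisible by ``factor`` are reflect-padded up to the next
    multiple first.  The angular scale grows by ``factor`` and the global
    per-band mean is preserved (exactly, for divisible dimensions).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return cube
    data = cube.data
    h, w, b = data.shape
    pad_h = (-h) % factor
    pad_w = (-w) % factor
    if pad_h or pad_w:
        data = np.pad(data, ((0, pad_h), (0, pad_w), (0, 0)), mode="symmetric")
        h, w = data.shape[:2]
    out = data.reshape(h // factor, factor, w // factor, factor, b).mean(axis=(1, 3))
    return SpectralImage(
        data=out,
        wavelengths_nm=cube.wavelengths_nm,
        kind=cube.kind,
        degrees_per_pixel=cube.degrees_per_pixel * factor,
    )
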