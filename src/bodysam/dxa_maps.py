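"""Dual-energy attenuation images -> body thickness, leanness and R-value maps.

A whole-body densitometer records, per pixel, the attenuation of a low- and a
high-energy X-ray beam through the body.  Under the linearized two-material
model, those two measurements solve for the projected thickness (cm of tissue
along the beam) of fat and of lean soft tissue at each pixel.  From the solved
thicknesses this module derives the three working images of the pipeline:

1. total thickness  -- fat + lean path length (cm), the X-ray's path through
   the body excluding air cavities;
2. leanness         -- fat-free fraction, lean / (fat + lean), in [0, 1];
3. R-value          -- ratio of low- to high-energy attenuation, sensitive to
   soft-tissue composition.

It also owns the raster plumbing shared downstream: anisotropic-to-square
pixel upscaling, 8-bit quantization for annotation-software export, masked
histogram equalization for display, and TIFF + JSON-sidecar file IO.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .config import (NO_DATA, CalibrationTable, DEFAULT_CALIBRATION,
                     round_half_away)

__all__ = [
    "AttenuationPair", "CompositionMaps", "DegeneratePixelError",
    "compute_rvalue", "decompose_tissue", "total_thickness", "leanness",
    "compose_maps", "forward_simulate", "upscale_y", "downscale_y",
    "export_8bit", "histogram_equalize", "body_mask_from_high",
    "save_raster", "load_raster",
]


class DegeneratePixelError(ValueError):
    """A pixel inside the body mask violates a precondition; names coordinates."""

    def __init__(self, message: str, coords: np.ndarray):
        coords = np.asarray(coords)
        preview = ", ".join(f"(y={y}, x={x})" for y, x in coords[:5])
        more = "" if len(coords) <= 5 else f" and {len(coords) - 5} more"
        super().__init__(f"{message} at {preview}{more}")
        self.coords = coords


# ---------------------------------------------------------------------------
# Domain containers


@dataclass
class AttenuationPair:
    """Registered low/high-energy attenuation rasters with pixel geometry."""

    low: np.ndarray
    high: np.ndarray
    pixel_size: tuple[float, float] = (2.0, 13.0)  # (width mm, height mm)
    body_mask: np.ndarray | None = None
    calibration: CalibrationTable = field(default_factory=lambda: DEFAULT_CALIBRATION)

    def __post_init__(self) -> None:
        self.low = np.asarray(self.low, dtype=float)
        self.high = np.asarray(self.high, dtype=float)
        if self.low.shape != self.high.shape:
            raise ValueError(
                f"low {self.low.shape} and high {self.high.shape} shapes differ")
        if self.pixel_size[0] <= 0 or self.pixel_size[1] <= 0:
            raise ValueError("pixel_size components must be > 0")
        if self.body_mask is None:
            self.body_mask = body_mask_from_high(self.high)
        self.body_mask = np.asarray(self.body_mask, dtype=bool)
        if self.body_mask.shape != self.low.shape:
            raise ValueError("body_mask shape differs from images")

    @property
    def shape(self) -> tuple[int, int]:
        return self.low.shape


@dataclass
class CompositionMaps:
    """Per-pixel total thickness (cm), leanness fraction and R-value."""

    thickness: np.ndarray
    leanness: np.ndarray
    rvalue: np.ndarray
    body_mask: np.ndarray
    pixel_size: tuple[float, float] = (2.0, 13.0)

    def __post_init__(self) -> None:
        self.thickness = np.asarray(self.thickness, dtype=float)
        self.leanness = np.asarray(self.leanness, dtype=float)
        self.rvalue = np.asarray(self.rvalue, dtype=float)
        self.body_mask = np.asarray(self.body_mask, dtype=bool)
        shapes = {self.thickness.shape, self.leanness.shape,
                  self.rvalue.shape, self.body_mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent raster shapes: {shapes}")


# ---------------------------------------------------------------------------
# Core decomposition


def compute_rvalue(pair: AttenuationPair) -> np.ndarray:
    """Ratio of low- to high-energy attenuation on the body mask.

    Off-mask pixels carry the no-data value.  An on-mask pixel with zero
    high-energy attenuation has no defined ratio and raises
    :class:`DegeneratePixelError`.
    """
    mask = pair.body_mask
    bad = mask & (pair.high == 0)
    if bad.any():
        raise DegeneratePixelError("zero high-energy attenuation on body mask",
                                   np.argwhere(bad))
    out = np.full(pair.shape, NO_DATA)
    out[mask] = pair.low[mask] / pair.high[mask]
    return out


def decompose_tissue(pair: AttenuationPair,
                     calib: CalibrationTable | None = None,
                     ) -> tuple[np.ndarray, np.ndarray, int]:
    """Solve the 2x2 two-material system per on-mask pixel.

    Returns ``(fat_thickness_cm, lean_thickness_cm, n_clamped)``: negative
    solutions (attenuation pairs outside the physical cone of the two basis
    materials) are clamped to 0 and counted.  Off-mask pixels are 0.
    """
    calib = pair.calibration if calib is None else calib
    inv = np.linalg.inv(calib.matrix)  # raises on exact singularity
    mask = pair.body_mask
    a = np.stack([pair.low[mask], pair.high[mask]])  # (2, n)
    tf_tl = inv @ a
    n_clamped = int(np.count_nonzero((tf_tl < 0).any(axis=0)))
    tf_tl = np.clip(tf_tl, 0.0, None)
    fat = np.zeros(pair.shape)
    lean = np.zeros(pair.shape)
    fat[mask] = tf_tl[0]
    lean[mask] = tf_tl[1]
    return fat, lean, n_clamped


def total_thickness(fat_thickness: np.ndarray,
                    lean_thickness: np.ndarray) -> np.ndarray:
    """Total projected tissue thickness: fat + lean, per pixel.

    Bone, when simulated, is folded into the lean channel upstream, so the
    two-channel sum is the full path length through tissue.
    """
    fat = np.asarray(fat_thickness, dtype=float)
    lean = np.asarray(lean_thickness, dtype=float)
    if fat.shape != lean.shape:
        raise ValueError(f"shape mismatch: {fat.shape} vs {lean.shape}")
    return fat + lean


def leanness(fat_thickness: np.ndarray, lean_thickness: np.ndarray,
             body_mask: np.ndarray | None = None) -> np.ndarray:
    """Fat-free fraction lean/(fat+lean) in [0, 1] on the mask, no-data off it."""
    fat = np.asarray(fat_thickness, dtype=float)
    lean = np.asarray(lean_thickness, dtype=float)
    if fat.shape != lean.shape:
        raise ValueError(f"shape mismatch: {fat.shape} vs {lean.shape}")
    total = fat + lean
    if body_mask is None:
        body_mask = total > 0
    body_mask = np.asarray(body_mask, dtype=bool)
    zero = body_mask & (total == 0)
    if zero.any():
        raise DegeneratePixelError("zero total thickness on body mask",
                                   np.argwhere(zero))
    out = np.full(fat.shape, NO_DATA)
    out[body_mask] = lean[body_mask] / total[body_mask]
    return out


def compose_maps(pair: AttenuationPair,
                 calib: CalibrationTable | None = None) -> CompositionMaps:
    """Full per-pixel decomposition of a pair into the three working maps."""
    fat, lean, _ = decompose_tissue(pair, calib)
    thick = total_thickness(fat, lean)
    thick[~pair.body_mask] = 0.0
    return CompositionMaps(
        thickness=thick,
        leanness=leanness(fat, lean, pair.body_mask),
        rvalue=compute_rvalue(pair),
        body_mask=pair.body_mask,
        pixel_size=pair.pixel_size,
    )


def forward_simulate(fat_thickness: np.ndarray, lean_thickness: np.ndarray,
                     calib: CalibrationTable | None = None,
                     pixel_size: tuple[float, float] = (2.0, 13.0),
                     noise_sd: float = 0.0,
                     rng: np.random.Generator | None = None,
                     ) -> AttenuationPair:
    """Simulate the attenuation pair a scanner would record for known tissue maps.

    The exact linear-model adjoint of :func:`decompose_tissue`; the round trip
    is lossless for nonnegative inputs in the noise-free case.
    """
    calib = DEFAULT_CALIBRATION if calib is None else calib
    fat = np.asarray(fat_thickness, dtype=float)
    lean = np.asarray(lean_thickness, dtype=float)
    if fat.shape != lean.shape:
        raise ValueError(f"shape mismatch: {fat.shape} vs {lean.shape}")
    if (fat < 0).any() or (lean < 0).any():
        raise ValueError("tissue thickness must be >= 0")
    low = calib.mu_fat_low * fat + calib.mu_lean_low * lean
    high = calib.mu_fat_high * fat + calib.mu_lean_high * lean
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        low = np.clip(low + rng.normal(0, noise_sd, low.shape), 0, None)
        high = np.clip(high + rng.normal(0, noise_sd, high.shape), 0, None)
    mask = (fat + lean) > 0
    return AttenuationPair(low=low, high=high, pixel_size=pixel_size,
                           body_mask=mask, calibration=calib)


# ---------------------------------------------------------------------------
# Resampling / quantization / display


def upscale_y(raster: np.ndarray, factor: float,
              interpolation: str = "linear") -> np.ndarray:
    """Resample along y so anisotropic pixels become square.

    ``factor * rows`` must be integral (tolerance 1e-9).  Endpoint-aligned
    sampling: output row j reads input coordinate ``j*(rows-1)/(rows_out-1)``,
    so constants are preserved exactly and a linear ramp is reproduced exactly.
    The caller divides the pixel height by ``factor``.
    """
    raster = np.asarray(raster, dtype=float)
    if factor <= 0:
        raise ValueError("factor must be > 0")
    rows, _ = raster.shape
    out_rows_f = rows * factor
    out_rows = round(out_rows_f)
    if abs(out_rows_f - out_rows) > 1e-9:
        raise ValueError(
            f"factor {factor} x {rows} rows = {out_rows_f}, not integral")
    if factor == 1:
        return raster.copy()
    if out_rows == 1 or rows == 1:
        return np.repeat(raster[:1], out_rows, axis=0)
    src = np.arange(out_rows) * (rows - 1) / (out_rows - 1)
    if interpolation == "nearest":
        return raster[round_half_away(src).astype(int)]
    if interpolation != "linear":
        raise ValueError(f"unknown interpolation {interpolation!r}")
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, rows - 1)
    w = (src - lo)[:, None]
    # a + w*(b - a) rather than (1-w)*a + w*b: exact for constant rasters
    base = raster[lo]
    return base + w * (raster[hi] - base)


def downscale_y(raster: np.ndarray, factor: float) -> np.ndarray:
    """Inverse-direction resample (same endpoint-aligned linear convention)."""
    rows = raster.shape[0]
    if rows == 1:
        return np.asarray(raster, dtype=float).copy()
    out_rows_f = rows / factor
    out_rows = round(out_rows_f)
    if abs(out_rows_f - out_rows) > 1e-6:
        raise ValueError("rows not divisible by factor")
    return upscale_y(raster, out_rows / rows)


def export_8bit(raster: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Linear [lo, hi] -> [0, 255] quantization with clipping.

    Rounds half away from zero; values outside [lo, hi] clip to the endpoints.
    No-data (nan) pixels export as 0.
    """
    if hi <= lo:
        raise ValueError(f"hi ({hi}) must exceed lo ({lo})")
    raster = np.asarray(raster, dtype=float)
    scaled = (raster - lo) / (hi - lo) * 255.0
    scaled = np.where(np.isnan(scaled), 0.0, np.clip(scaled, 0.0, 255.0))
    return round_half_away(scaled).astype(np.uint8)


def histogram_equalize(raster: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Rank-based histogram equalization over mask pixels only.

    On-mask output is the inclusive empirical CDF of the on-mask values,
    in (0, 1]; off-mask pixels are passed through untouched.
    """
    raster = np.asarray(raster, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    values = raster[mask]
    order = np.sort(values)
    # inclusive CDF with ties sharing the highest rank of their value
    cdf = np.searchsorted(order, values, side="right") / n
    out = raster.copy()
    out[mask] = cdf
    return out


def body_mask_from_high(high: np.ndarray, threshold: float = 1e-6) -> np.ndarray:
    """Threshold the high-energy image, keep the largest connected component."""
    mask = np.asarray(high, dtype=float) > threshold
    if not mask.any():
        return mask
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    return mask


# ---------------------------------------------------------------------------
# File IO: 16-bit single-channel TIFF + sidecar JSON header; 8-bit PNG export.


def save_raster(path, raster: np.ndarray,
                pixel_size: tuple[float, float],
                mask: np.ndarray | None = None,
                value_range: tuple[float, float] | None = None,
                meta: dict | None = None) -> None:
    """Write a float raster as 16-bit TIFF with a JSON sidecar.

    The sidecar records the linear value range used for quantization, the
    pixel geometry and the mask encoding (mask pixels are raster > 0 unless a
    mask raster is written alongside).
    """
    import tifffile

    path = Path(path)
    raster = np.asarray(raster, dtype=float)
    finite = raster[np.isfinite(raster)]
    if value_range is None:
        lo = float(finite.min()) if finite.size else 0.0
        hi = float(finite.max()) if finite.size else 1.0
        if hi <= lo:
            hi = lo + 1.0
    else:
        lo, hi = value_range
    scaled = (np.where(np.isfinite(raster), raster, lo) - lo) / (hi - lo)
    data16 = round_half_away(np.clip(scaled, 0, 1) * 65535).astype(np.uint16)
    tifffile.imwrite(path, data16)
    header = {
        "format": "bodysam-raster",
        "version": 1,
        "value_range": [lo, hi],
        "pixel_size_mm": list(pixel_size),
        "mask_encoding": "sidecar" if mask is not None else "nonzero",
        "meta": meta or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=2))
    if mask is not None:
        tifffile.imwrite(path.with_suffix(".mask" + path.suffix),
                         np.asarray(mask, dtype=np.uint8) * 255)


def load_raster(path) -> tuple[np.ndarray, tuple[float, float], np.ndarray | None, dict]:
    """Read a raster written by :func:`save_raster`.

    Returns ``(raster, pixel_size, mask_or_None, meta)``.
    """
    import tifffile

    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    lo, hi = header["value_range"]
    data16 = tifffile.imread(path).astype(float)
    raster = data16 / 65535.0 * (hi - lo) + lo
    mask = None
    if header["mask_encoding"] == "sidecar":
        mask = tifffile.imread(path.with_suffix(".mask" + path.suffix)) > 0
    return raster, tuple(header["pixel_size_mm"]), mask, header.get("meta", {})
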