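"""Shared configuration: grid geometry, calibration, no-data convention, seeding, logging.

Conventions used throughout the package
---------------------------------------
* Rasters are numpy arrays indexed ``[row, col]``; x = column index, y = row
  index, origin at the top-left, 0-based, half-open pixel boxes.
* Floating rasters use ``numpy.nan`` as the no-data value; integer exports use 0.
* All quantization rounds half away from zero (``round_half_away``).
* Every source of randomness derives from one integer seed through named
  substreams (``substream``); no hidden global state.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, asdict

import numpy as np

# ---------------------------------------------------------------------------
# Native raster geometry of the whole-body scan pathway.
# The scanner grid is 150 rows x 327 columns with anisotropic 2 mm x 13 mm
# pixels; images are upscaled by 6.5 along y to a square-pixel 975 x 327 grid.
NATIVE_SHAPE = (150, 327)          # (rows, cols)
NATIVE_PIXEL_SIZE = (2.0, 13.0)    # (width mm, height mm)
Y_UPSCALE_FACTOR = 6.5
UPSCALED_SHAPE = (975, 327)
SQUARE_PIXEL_SIZE = (2.0, 2.0)

NO_DATA = np.nan


def round_half_away(values: np.ndarray) -> np.ndarray:
    """Round half away from zero (0.5 -> 1, -0.5 -> -1).

    This is the single quantization rule used everywhere; numpy's default
    banker's rounding is deliberately not used.
    """
    values = np.asarray(values, dtype=float)
    return np.sign(values) * np.floor(np.abs(values) + 0.5)


# ---------------------------------------------------------------------------
# Calibration


@dataclass(frozen=True)
class CalibrationTable:
    """Effective linear attenuation coefficients (per cm of tissue) and densities.

    The two-material model is linear (monochromatic, linearized): at each pixel

        A_low  = mu_fat_low  * t_fat + mu_lean_low  * t_lean
        A_high = mu_fat_high * t_fat + mu_lean_high * t_lean

    with thicknesses in cm.  The defaults are physically plausible values for
    adipose and lean soft tissue at the two effective beam energies of a
    fan-beam densitometer (~40 and ~70 keV equivalent): lean tissue attenuates
    more, and more so at low energy, so the low/high ratio (R-value) of lean
    tissue exceeds that of fat.
    """

    mu_fat_low: float = 0.218
    mu_fat_high: float = 0.182
    mu_lean_low: float = 0.262
    mu_lean_high: float = 0.192
    density_fat: float = 0.92   # g/cm^3
    density_lean: float = 1.05  # g/cm^3

    def __post_init__(self) -> None:
        coeffs = (self.mu_fat_low, self.mu_fat_high,
                  self.mu_lean_low, self.mu_lean_high,
                  self.density_fat, self.density_lean)
        if any(c <= 0 for c in coeffs):
            raise ValueError("all calibration coefficients must be > 0")
        if abs(self.determinant) < 1e-12:
            raise ValueError("singular calibration: "
                             "mu_fat_low*mu_lean_high == mu_fat_high*mu_lean_low")

    @property
    def determinant(self) -> float:
        return (self.mu_fat_low * self.mu_lean_high
                - self.mu_fat_high * self.mu_lean_low)

    @property
    def matrix(self) -> np.ndarray:
        """2x2 system matrix mapping (t_fat, t_lean) -> (A_low, A_high)."""
        return np.array([[self.mu_fat_low, self.mu_lean_low],
                         [self.mu_fat_high, self.mu_lean_high]])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationTable":
        return cls(**{k: float(v) for k, v in d.items()})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "CalibrationTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


DEFAULT_CALIBRATION = CalibrationTable()


# ---------------------------------------------------------------------------
# Seeding: one root seed, named substreams, no global state.

def substream(seed: int, name: str) -> np.random.Generator:
    """Derive an independent, reproducible generator for a named stage."""
    digest = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def substream_seed(seed: int, name: str) -> int:
    """A derived scalar seed (< 2**31) for APIs that take an integer."""
    digest = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


# ---------------------------------------------------------------------------
# Logging: one machine-parseable record per line.

_LOG_FORMAT = "%(asctime)s\t%(name)s\t%(levelname)s\t%(message)s"


def get_logger(stage: str) -> logging.Logger:
    logger = logging.getLogger(f"bodysam.{stage}")
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        handler.formatter.converter = time.gmtime
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.propagate = False
    return logger


def config_hash(config: dict) -> str:
    """Stable digest of a configuration mapping, for provenance records."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
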