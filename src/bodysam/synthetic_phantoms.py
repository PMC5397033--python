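"""Seeded populations of 2D body phantoms with exact ground truth.

Every phantom is a stylized body (circular head, tapered torso, capsule
limbs) whose fat and lean projected-thickness fields and 82 landmark
positions all have closed forms, so each downstream operation has an exact
oracle.  The paired low/high-energy attenuation images are forward-simulated
through the same linearized two-material model the decomposition inverts, on
the native anisotropic scanner grid (150 x 327 pixels of 2 mm x 13 mm),
optionally with additive Gaussian pixel noise.

Cohorts draw per-subject parameters from three generative factors — overall
scale, torso width and trunk fat fraction — plus per-limb pose jitter, and
can superpose binary group effects expressed in SD units of any factor
(emulating, e.g., a sex-like difference in width and composition).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _body
from .annotation import PointSet, scheme_82
from .config import (NATIVE_PIXEL_SIZE, NATIVE_SHAPE, UPSCALED_SHAPE,
                     CalibrationTable, DEFAULT_CALIBRATION, substream)
from .dxa_maps import AttenuationPair, CompositionMaps, forward_simulate

__all__ = ["PhantomSpec", "CohortSpec", "Phantom", "make_phantom",
           "sample_cohort", "FACTOR_SDS", "POSE_JITTER_SD"]

# generative factor spreads (the cohort's "population")
FACTOR_SDS = {"scale": 0.04, "width": 0.05, "fat": 0.06}
FACTOR_BASE = {"scale": 1.0, "width": 1.0, "fat": 0.32}
# pose jitter SDs in degrees, per joint angle
POSE_JITTER_SD = {"arm_angle": 1.5, "forearm_angle": 1.0,
                  "leg_angle": 1.0, "shank_angle": 0.8}
_MAX_RESAMPLE = 20


@dataclass(frozen=True)
class PhantomSpec:
    """One body: geometry/pose/composition parameters plus imaging noise."""

    body: _body.BodyShapeParams = field(default_factory=_body.BodyShapeParams)
    noise_sd: float = 0.0
    seed: int = 0
    calibration: CalibrationTable = field(default_factory=lambda: DEFAULT_CALIBRATION)
    grid: str = "native"   # "native": 150x327 anisotropic scanner grid, the
                           # realistic pathway; "square": sample the analytic
                           # fields directly at 975x327 (no resampling aliasing)


@dataclass(frozen=True)
class CohortSpec:
    """A seeded population with optional binary group effects.

    ``group_effects`` maps an outcome name to per-factor effect sizes in SD
    units of that factor; subjects in the positive group get +delta/2 SD and
    the rest -delta/2 SD, so overall factor means are unchanged.
    """

    n: int = 60
    seed: int = 0
    factor_sds: dict = field(default_factory=lambda: dict(FACTOR_SDS))
    pose_jitter_sd: dict = field(default_factory=lambda: dict(POSE_JITTER_SD))
    noise_sd: float = 0.0
    grid: str = "native"
    group_effects: dict = field(default_factory=dict)
    group_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort needs n >= 2")
        for effects in self.group_effects.values():
            if not all(np.isfinite(list(effects.values()))):
                raise ValueError("effect sizes must be finite")


@dataclass
class Phantom:
    """A generated subject: spec, attenuation pair, ground truth, landmarks.

    ``pair``/``truth`` are None for label-only draws (render=False)."""

    spec: PhantomSpec
    pair: AttenuationPair | None           # native grid (150 x 327)
    truth: CompositionMaps | None          # same grid, noise-free
    points: PointSet                       # 82 landmarks, square-pixel frame
    factors: dict = field(default_factory=dict)


def _native_grid() -> tuple[np.ndarray, np.ndarray]:
    """Square-frame coordinates of native pixel centers.

    Native row r maps to square-frame y = r*(rows_up-1)/(rows_native-1), the
    same endpoint-aligned convention the y-upscaler uses, so the upscaled
    image and the square-frame landmarks are mutually consistent.
    """
    rows, cols = NATIVE_SHAPE
    rows_up = UPSCALED_SHAPE[0]
    ys = np.arange(rows) * (rows_up - 1) / (rows - 1)
    xs = np.arange(cols, dtype=float)
    return np.meshgrid(xs, ys)


def _integrated_fields(params, xx, yy, dx: float, dy: float,
                       n_sub: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-area-integrated thickness fields (midpoint rule, n_sub x n_sub).

    A detector pixel integrates over its footprint rather than point-sampling;
    averaging over subpixel offsets models that and removes the edge-phase
    aliasing a point sample would imprint on the steep sqrt profile at part
    rims.  The linear forward model commutes with the averaging, so the
    decomposition round trip against these same fields stays exact.
    """
    offsets = (np.arange(n_sub) - (n_sub - 1) / 2) / n_sub
    fat = 0.0
    lean = 0.0
    for ox in offsets:
        for oy in offsets:
            f, l = _body.thickness_fields(params, xx + ox * dx, yy + oy * dy)
            fat = fat + f
            lean = lean + l
    return fat / n_sub ** 2, lean / n_sub ** 2


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Forward-simulate one phantom; bit-identical under a fixed seed."""
    params = spec.body.resolved()
    if not _body.fits_grid(params):
        raise ValueError("phantom exceeds the native grid; "
                         "reduce scale/width or pose angles")
    if spec.grid == "native":
        xx, yy = _native_grid()
        pixel_size = NATIVE_PIXEL_SIZE
        dy = (UPSCALED_SHAPE[0] - 1) / (NATIVE_SHAPE[0] - 1)
    elif spec.grid == "square":
        rows, cols = UPSCALED_SHAPE
        xx, yy = np.meshgrid(np.arange(cols, dtype=float),
                             np.arange(rows, dtype=float))
        pixel_size = (NATIVE_PIXEL_SIZE[0], NATIVE_PIXEL_SIZE[0])
        dy = 1.0
    else:
        raise ValueError(f"unknown grid {spec.grid!r}")
    fat, lean = _integrated_fields(params, xx, yy, dx=1.0, dy=dy)
    rng = substream(spec.seed, "phantom-noise") if spec.noise_sd > 0 else None
    pair = forward_simulate(fat, lean, spec.calibration,
                            pixel_size=pixel_size,
                            noise_sd=spec.noise_sd, rng=rng)
    mask = (fat + lean) > 0
    thickness = fat + lean
    leanness = np.full(mask.shape, np.nan)
    leanness[mask] = lean[mask] / thickness[mask]
    c = spec.calibration
    rvalue = np.full(mask.shape, np.nan)
    num = c.mu_fat_low * fat + c.mu_lean_low * lean
    den = c.mu_fat_high * fat + c.mu_lean_high * lean
    rvalue[mask] = num[mask] / den[mask]
    truth = CompositionMaps(thickness=thickness, leanness=leanness,
                            rvalue=rvalue, body_mask=mask,
                            pixel_size=pixel_size)
    points = PointSet(_body.landmark_positions(params), scheme_82().scheme_id)
    return Phantom(spec, pair, truth, points)


def _draw_subject(base_factors: dict, cohort: CohortSpec,
                  rng: np.random.Generator) -> _body.BodyShapeParams:
    """One subject's body parameters from factor values plus pose jitter."""
    fat_trunk = float(np.clip(base_factors["fat"], 0.08, 0.60))
    upd = dict(scale=float(base_factors["scale"]),
               width_factor=float(base_factors["width"]),
               fat_trunk=fat_trunk,
               fat_arm=0.78 * fat_trunk,
               fat_leg=0.875 * fat_trunk)
    defaults = _body.BodyShapeParams()
    for angle, sd in cohort.pose_jitter_sd.items():
        for side in ("l", "r"):
            name = f"{angle}_{side}"
            upd[name] = getattr(defaults, name) + (rng.normal(0, sd) if sd > 0 else 0.0)
    return replace(defaults, **upd)


def sample_cohort(cohort: CohortSpec, render: bool = True,
                  ) -> tuple[list[Phantom], pd.DataFrame]:
    """Generate a seeded cohort and its labels table.

    Returns the phantoms and a DataFrame with one row per subject: ``id``,
    one binary 0/1 column per group effect, and the realized generative
    factor values as continuous covariates.  Deterministic under the seed;
    ``render=False`` skips image simulation (landmarks and labels only),
    drawing the identical population.
    """
    rng = substream(cohort.seed, "cohort")
    rows = []
    phantoms = []
    group_names = list(cohort.group_effects)
    # balanced permuted assignment per group, mirroring a case-control design
    assignment = {}
    for g in group_names:
        n_pos = int(round(cohort.group_fraction * cohort.n))
        arr = np.zeros(cohort.n, dtype=int)
        arr[:n_pos] = 1
        assignment[g] = rng.permutation(arr)
    for i in range(cohort.n):
        groups = {g: int(assignment[g][i]) for g in group_names}
        phantom = None
        for _attempt in range(_MAX_RESAMPLE):
            factors = {f: FACTOR_BASE[f] + rng.normal(0, sd)
                       for f, sd in cohort.factor_sds.items()}
            for g, effects in cohort.group_effects.items():
                sign = 0.5 if groups[g] else -0.5
                for f, delta in effects.items():
                    factors[f] += sign * delta * cohort.factor_sds[f]
            body = _draw_subject(factors, cohort, rng)
            spec = PhantomSpec(body=body, noise_sd=cohort.noise_sd,
                               seed=int(rng.integers(2 ** 31)),
                               grid=cohort.grid)
            if not _body.fits_grid(body.resolved()):
                continue
            if render:
                phantom = make_phantom(spec)
            else:
                points = PointSet(_body.landmark_positions(body.resolved()),
                                  scheme_82().scheme_id)
                phantom = Phantom(spec, None, None, points)
            phantom.factors = dict(factors)
            break
        if phantom is None:
            raise ValueError(f"subject {i}: could not draw a phantom that "
                             f"fits the grid in {_MAX_RESAMPLE} attempts")
        phantoms.append(phantom)
        row = {"id": f"subj{i:04d}", **groups,
               **{f"factor_{k}": v for k, v in phantom.factors.items()}}
        rows.append(row)
    return phantoms, pd.DataFrame(rows)
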