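"""Parametric stylized 2D body: closed-form landmarks and tissue-thickness fields.

Shared by :mod:`bodysam.annotation` (which derives the landmark schemes, the
template shape and the triangle meshes from the default body) and
:mod:`bodysam.synthetic_phantoms` (which varies the parameters to generate
cohorts).  The body is a union of analytically simple parts — a circular head,
capsule limbs, a tapered torso — so that every landmark coordinate and every
per-pixel fat/lean thickness value has a closed form and downstream tests have
exact oracles.

All geometry lives in the square-pixel frame (975 rows x 327 columns, 2 mm
pixels, x = column, y = row, origin top-left).  Thickness amplitudes are in
cm of tissue along the beam; each part's cross-section along the beam is
elliptic, so thickness falls off as sqrt(1 - (d/w)^2) from the part axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

FRAME_SHAPE = (975, 327)  # square-pixel (rows, cols)


@dataclass(frozen=True)
class BodyShapeParams:
    """Geometry (square pixels), pose (degrees) and composition of one body."""

    cx: float = 163.0            # body axis column; (327-1)/2 so a zero-pose
                                 # body is mirror-symmetric about the pixel grid
    head_top: float = 40.0       # y of the top of the head

    head_radius: float = 40.0
    neck_len: float = 22.0
    neck_hw: float = 16.0        # hw = half-width

    torso_len: float = 270.0
    torso_end_round: float = 30.0   # elliptic rounding length of the torso ends
    shoulder_hw: float = 90.0
    waist_hw: float = 72.0
    hip_hw: float = 82.0
    waist_frac: float = 0.60     # waist position along the torso

    shoulder_joint_dx: float = 78.0
    shoulder_joint_dy: float = 14.0
    upper_arm_len: float = 155.0
    forearm_len: float = 140.0
    hand_len: float = 35.0
    arm_hw: float = 17.0
    forearm_hw: float = 12.0
    wrist_hw: float = 9.0

    hip_joint_dx: float = 42.0
    thigh_len: float = 210.0
    shank_len: float = 200.0
    foot_len: float = 45.0
    thigh_hw: float = 30.0
    knee_hw: float = 20.0
    calf_hw: float = 17.0
    ankle_hw: float = 10.0

    # pose: angles from vertical (downward), positive = outward, degrees;
    # forearm/shank angles are relative to their parent segment
    arm_angle_l: float = 7.0
    arm_angle_r: float = 7.0
    forearm_angle_l: float = 2.0
    forearm_angle_r: float = 2.0
    leg_angle_l: float = 6.0
    leg_angle_r: float = 6.0
    shank_angle_l: float = -2.0
    shank_angle_r: float = -2.0

    # sagittal thickness amplitudes (cm) at each part's axis
    t_torso: float = 22.0
    t_head: float = 17.0
    t_neck: float = 10.0
    t_upper_arm: float = 8.0
    t_forearm: float = 6.0
    t_thigh: float = 13.0
    t_shank: float = 9.0
    spine_hw: float = 9.0
    t_spine: float = 4.0         # lean-only column folded into the lean channel

    # fat fraction of each part's thickness
    fat_head: float = 0.08
    fat_neck: float = 0.15
    fat_trunk: float = 0.32
    fat_arm: float = 0.25
    fat_leg: float = 0.28

    # cohort-level multiplicative factors
    scale: float = 1.0           # global geometric scale about (cx, head_top)
    width_factor: float = 1.0    # extra scaling of transverse half-widths

    def resolved(self) -> "BodyShapeParams":
        """Apply scale/width_factor to the raw dimensions, returning factors of 1."""
        s, w = self.scale, self.width_factor
        if s == 1.0 and w == 1.0:
            return self
        upd = {}
        lengths = ("head_radius", "neck_len", "torso_len", "torso_end_round",
                   "shoulder_joint_dy", "upper_arm_len", "forearm_len",
                   "hand_len", "thigh_len", "shank_len", "foot_len")
        widths = ("neck_hw", "shoulder_hw", "waist_hw", "hip_hw",
                  "shoulder_joint_dx", "arm_hw", "forearm_hw", "wrist_hw",
                  "hip_joint_dx", "thigh_hw", "knee_hw", "calf_hw", "ankle_hw",
                  "spine_hw")
        for name in lengths:
            upd[name] = getattr(self, name) * s
        for name in widths:
            upd[name] = getattr(self, name) * s * w
        upd["scale"] = 1.0
        upd["width_factor"] = 1.0
        return replace(self, **upd)


# ---------------------------------------------------------------------------
# Derived joint geometry


def _rad(deg: float) -> float:
    return float(np.deg2rad(deg))


def _limb_axes(p: BodyShapeParams) -> dict:
    """Joint positions and segment endpoints for both sides (side -1 = viewer left)."""
    out = {}
    y_neck_base = p.head_top + 2 * p.head_radius + p.neck_len
    y_sh = y_neck_base
    y_hip = y_sh + p.torso_len
    for side, tag in ((-1, "l"), (+1, "r")):
        a1 = _rad(getattr(p, f"arm_angle_{tag}"))
        a2 = a1 + _rad(getattr(p, f"forearm_angle_{tag}"))
        g1 = _rad(getattr(p, f"leg_angle_{tag}"))
        g2 = g1 + _rad(getattr(p, f"shank_angle_{tag}"))
        sh = np.array([p.cx + side * p.shoulder_joint_dx, y_sh + p.shoulder_joint_dy])
        u_ua = np.array([side * np.sin(a1), np.cos(a1)])
        elbow = sh + p.upper_arm_len * u_ua
        u_fa = np.array([side * np.sin(a2), np.cos(a2)])
        wrist = elbow + p.forearm_len * u_fa
        hand_tip = wrist + p.hand_len * u_fa
        hip = np.array([p.cx + side * p.hip_joint_dx, y_hip])
        u_th = np.array([side * np.sin(g1), np.cos(g1)])
        knee = hip + p.thigh_len * u_th
        u_sk = np.array([side * np.sin(g2), np.cos(g2)])
        ankle = knee + p.shank_len * u_sk
        foot_tip = ankle + p.foot_len * u_sk
        out[tag] = dict(shoulder=sh, elbow=elbow, wrist=wrist,
                        hand_tip=hand_tip, hip=hip, knee=knee, ankle=ankle,
                        foot_tip=foot_tip, u_ua=u_ua, u_fa=u_fa,
                        u_th=u_th, u_sk=u_sk, side=side)
    out["y_neck_base"] = y_neck_base
    out["y_shoulder"] = y_sh
    out["y_hip"] = y_hip
    return out


def _torso_halfwidth(p: BodyShapeParams, y: np.ndarray) -> np.ndarray:
    """Piecewise-linear torso half-width: shoulder -> waist -> hip."""
    ax = _limb_axes(p)
    y_sh, y_hip = ax["y_shoulder"], ax["y_hip"]
    y_waist = y_sh + p.waist_frac * p.torso_len
    return np.interp(y, [y_sh, y_waist, y_hip],
                     [p.shoulder_hw, p.waist_hw, p.hip_hw])


# ---------------------------------------------------------------------------
# Landmarks: the 82-point scheme layout.
#
# Entries in anatomical top-down order; "M" is a single midline point, "P" a
# left/right pair (left index precedes right).  The torso subset keeps the
# torso, upper arms and upper legs and drops the head and forelimbs.

SCHEME_LAYOUT: list[tuple[str, str, bool]] = [
    # (name, kind M/P, in_torso_subset)
    ("head_top", "M", False),
    ("head_upper", "P", False),
    ("head_mid", "P", False),
    ("head_lower", "P", False),
    ("chin", "M", False),
    ("neck_upper", "P", False),
    ("neck_base", "P", True),
    ("sternum", "M", True),
    ("clavicle", "P", True),
    ("shoulder_tip", "P", True),
    ("shoulder_joint", "P", True),
    ("armpit", "P", True),
    ("arm_outer_mid", "P", True),
    ("elbow_outer", "P", True),
    ("elbow_inner", "P", True),
    ("forearm_outer_mid", "P", False),
    ("wrist_outer", "P", False),
    ("hand_tip", "P", False),
    ("wrist_inner", "P", False),
    ("forearm_inner_mid", "P", False),
    ("arm_inner_mid", "P", True),
    ("lung_apex", "P", True),
    ("chest_upper", "P", True),
    ("chest_outer", "P", True),
    ("lung_base", "P", True),
    ("rib_lower", "P", True),
    ("waist", "P", True),
    ("abdomen", "P", True),
    ("pelvis_brim", "P", True),
    ("hip", "P", True),
    ("femoral_head", "P", True),
    ("crotch", "M", True),
    ("groin", "P", True),
    ("hip_outer", "P", True),
    ("thigh_outer_mid", "P", True),
    ("thigh_inner_mid", "P", True),
    ("knee_outer", "P", True),
    ("knee_inner", "P", True),
    ("calf_outer", "P", False),
    ("calf_inner", "P", False),
    ("ankle_outer", "P", False),
    ("ankle_inner", "P", False),
    ("foot_tip", "P", False),
]


def landmark_positions(params: BodyShapeParams) -> np.ndarray:
    """All 82 landmark coordinates, (n, 2) array of (x, y), in scheme order."""
    p = params.resolved()
    ax = _limb_axes(p)
    y_sh, y_hip = ax["y_shoulder"], ax["y_hip"]
    L = p.torso_len
    head_c = np.array([p.cx, p.head_top + p.head_radius])
    y_chin = p.head_top + 2 * p.head_radius

    def outline(y):
        return _torso_halfwidth(p, np.asarray(y)).item()

    def sided(tag):
        """Coordinates of every paired landmark for one side, keyed by name."""
        a = ax[tag]
        s = a["side"]
        perp_ua = np.array([s * a["u_ua"][1], -a["u_ua"][0] * s]) * s
        # outward perpendicular of a limb axis (points away from the body axis)
        def outward(u):
            cand = np.array([u[1], -u[0]])
            return cand if cand[0] * s > 0 else -cand
        o_ua, o_fa = outward(a["u_ua"]), outward(a["u_fa"])
        o_th, o_sk = outward(a["u_th"]), outward(a["u_sk"])
        th45 = _rad(45.0)
        pts = {
            "head_upper": head_c + p.head_radius * np.array([s * np.sin(th45), -np.cos(th45)]),
            "head_mid": head_c + np.array([s * p.head_radius, 0.0]),
            "head_lower": head_c + p.head_radius * np.array([s * np.sin(th45), np.cos(th45)]),
            "neck_upper": np.array([p.cx + s * p.neck_hw, y_chin + 0.25 * p.neck_len]),
            "neck_base": np.array([p.cx + s * p.neck_hw, ax["y_neck_base"]]),
            "clavicle": np.array([p.cx + s * 0.5 * p.shoulder_joint_dx, y_sh + 10.0]),
            "shoulder_tip": np.array([p.cx + s * p.shoulder_hw, y_sh + 4.0]),
            "shoulder_joint": a["shoulder"],
            "armpit": a["shoulder"] + 0.22 * p.upper_arm_len * a["u_ua"] - o_ua * p.arm_hw,
            "arm_outer_mid": a["shoulder"] + 0.5 * p.upper_arm_len * a["u_ua"] + o_ua * p.arm_hw,
            "elbow_outer": a["elbow"] + o_ua * 0.9 * p.arm_hw,
            "elbow_inner": a["elbow"] - o_ua * 0.9 * p.arm_hw,
            "forearm_outer_mid": a["elbow"] + 0.5 * p.forearm_len * a["u_fa"] + o_fa * p.forearm_hw,
            "wrist_outer": a["wrist"] + o_fa * p.wrist_hw,
            "hand_tip": a["hand_tip"],
            "wrist_inner": a["wrist"] - o_fa * p.wrist_hw,
            "forearm_inner_mid": a["elbow"] + 0.5 * p.forearm_len * a["u_fa"] - o_fa * p.forearm_hw,
            "arm_inner_mid": a["shoulder"] + 0.55 * p.upper_arm_len * a["u_ua"] - o_ua * p.arm_hw,
            "lung_apex": np.array([p.cx + s * 0.42 * p.shoulder_hw, y_sh + 0.11 * L]),
            "chest_upper": np.array([p.cx + s * outline(y_sh + 0.18 * L), y_sh + 0.18 * L]),
            "chest_outer": np.array([p.cx + s * outline(y_sh + 0.38 * L), y_sh + 0.38 * L]),
            "lung_base": np.array([p.cx + s * 0.48 * p.waist_hw, y_sh + 0.40 * L]),
            "rib_lower": np.array([p.cx + s * 0.75 * outline(y_sh + 0.5 * L), y_sh + 0.5 * L]),
            "waist": np.array([p.cx + s * p.waist_hw, y_sh + p.waist_frac * L]),
            "abdomen": np.array([p.cx + s * outline(y_sh + 0.78 * L), y_sh + 0.78 * L]),
            "pelvis_brim": np.array([p.cx + s * 0.58 * p.hip_hw, y_sh + 0.88 * L]),
            "hip": np.array([p.cx + s * p.hip_hw, y_hip]),
            "femoral_head": np.array([p.cx + s * p.hip_joint_dx, y_hip - 8.0]),
            "groin": a["hip"] + 0.12 * p.thigh_len * a["u_th"] - o_th * p.thigh_hw,
            "hip_outer": a["hip"] + 0.08 * p.thigh_len * a["u_th"] + o_th * p.thigh_hw,
            "thigh_outer_mid": a["hip"] + 0.5 * p.thigh_len * a["u_th"] + o_th * p.thigh_hw,
            "thigh_inner_mid": a["hip"] + 0.5 * p.thigh_len * a["u_th"] - o_th * p.thigh_hw,
            "knee_outer": a["knee"] + o_th * p.knee_hw,
            "knee_inner": a["knee"] - o_th * p.knee_hw,
            "calf_outer": a["knee"] + 0.5 * p.shank_len * a["u_sk"] + o_sk * p.calf_hw,
            "calf_inner": a["knee"] + 0.5 * p.shank_len * a["u_sk"] - o_sk * p.calf_hw,
            "ankle_outer": a["ankle"] + o_sk * p.ankle_hw,
            "ankle_inner": a["ankle"] - o_sk * p.ankle_hw,
            "foot_tip": a["foot_tip"],
        }
        return pts

    mid = {
        "head_top": np.array([p.cx, p.head_top]),
        "chin": np.array([p.cx, y_chin]),
        "sternum": np.array([p.cx, y_sh + 6.0]),
        "crotch": np.array([p.cx, y_hip]),
    }
    left, right = sided("l"), sided("r")
    coords = []
    for name, kind, _ in SCHEME_LAYOUT:
        if kind == "M":
            coords.append(mid[name])
        else:
            coords.append(left[name])
            coords.append(right[name])
    return np.array(coords, dtype=float)


# ---------------------------------------------------------------------------
# Thickness fields


def _capsule_thickness(xx, yy, a, b, hw, amp):
    """Elliptic-chord thickness of a capsule (segment a->b, half-width hw)."""
    ab = b - a
    length2 = float(ab @ ab)
    px = xx - a[0]
    py = yy - a[1]
    t = np.clip((px * ab[0] + py * ab[1]) / length2, 0.0, 1.0) if length2 > 0 else 0.0
    dx = px - t * ab[0]
    dy = py - t * ab[1]
    d2 = (dx * dx + dy * dy) / (hw * hw)
    return amp * np.sqrt(np.clip(1.0 - d2, 0.0, None))


def _separable_axes(xx: np.ndarray, yy: np.ndarray):
    """1D (x, y) axes when the coordinate arrays form a meshgrid, else None.

    A meshgrid with monotone axes lets each part be evaluated only inside its
    bounding-box window, which cuts the field evaluation cost several-fold.
    """
    if xx.ndim != 2 or yy.ndim != 2 or xx.shape != yy.shape:
        return None
    x_axis = xx[0]
    y_axis = yy[:, 0]
    if not (np.all(xx == x_axis[None, :]) and np.all(yy == y_axis[:, None])):
        return None
    if np.any(np.diff(x_axis) <= 0) or np.any(np.diff(y_axis) <= 0):
        return None
    return x_axis, y_axis


class _FieldAccum:
    """Accumulates per-part thickness into fat/lean planes, windowed when possible."""

    def __init__(self, xx: np.ndarray, yy: np.ndarray):
        self.xx, self.yy = xx, yy
        self.shape = np.broadcast_shapes(xx.shape, yy.shape)
        self.fat = np.zeros(self.shape)
        self.lean = np.zeros(self.shape)
        self.axes = _separable_axes(np.broadcast_to(xx, self.shape),
                                    np.broadcast_to(yy, self.shape))             if xx.ndim == 2 else None

    def _window(self, x0, x1, y0, y1):
        x_axis, y_axis = self.axes
        c0 = int(np.searchsorted(x_axis, x0, side="left"))
        c1 = int(np.searchsorted(x_axis, x1, side="right"))
        r0 = int(np.searchsorted(y_axis, y0, side="left"))
        r1 = int(np.searchsorted(y_axis, y1, side="right"))
        return (slice(r0, r1), slice(c0, c1))

    def add(self, fn, bbox, frac):
        """fn(xx, yy) -> thickness; bbox = (x0, x1, y0, y1); frac = fat share."""
        if self.axes is None:
            t = fn(np.broadcast_to(self.xx, self.shape),
                   np.broadcast_to(self.yy, self.shape))
            self.fat += frac * t
            self.lean += (1.0 - frac) * t
            return
        win = self._window(*bbox)
        xxw = np.broadcast_to(self.xx, self.shape)[win]
        yyw = np.broadcast_to(self.yy, self.shape)[win]
        t = fn(xxw, yyw)
        self.fat[win] += frac * t
        self.lean[win] += (1.0 - frac) * t


def thickness_fields(params: BodyShapeParams,
                     xx: np.ndarray, yy: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate fat and lean thickness (cm) at square-frame coordinates.

    ``xx``/``yy`` are broadcastable coordinate arrays (x = column, y = row in
    the square-pixel frame).  Overlapping parts add, which yields plausible
    soft ridges at the joints.  The spine column contributes to the lean
    channel only, standing in for bone, which is folded into fat-free tissue.
    """
    p = params.resolved()
    ax = _limb_axes(p)
    xx = np.asarray(xx, dtype=float)
    yy = np.asarray(yy, dtype=float)
    acc = _FieldAccum(xx, yy)

    head_c = np.array([p.cx, p.head_top + p.head_radius])

    def head(gx, gy):
        d2 = ((gx - head_c[0]) ** 2 + (gy - head_c[1]) ** 2) / p.head_radius ** 2
        return p.t_head * np.sqrt(np.clip(1.0 - d2, 0.0, None))

    acc.add(head, (head_c[0] - p.head_radius, head_c[0] + p.head_radius,
                   head_c[1] - p.head_radius, head_c[1] + p.head_radius),
            p.fat_head)

    y_chin = p.head_top + 2 * p.head_radius
    neck_a = np.array([p.cx, y_chin - 2.0])
    neck_b = np.array([p.cx, ax["y_neck_base"] + 4.0])
    acc.add(lambda gx, gy: _capsule_thickness(gx, gy, neck_a, neck_b,
                                              p.neck_hw, p.t_neck),
            _capsule_bbox(neck_a, neck_b, p.neck_hw), p.fat_neck)

    y_sh, y_hip = ax["y_shoulder"], ax["y_hip"]

    def end_envelope(gy):
        # smooth elliptic roll-off at the torso's top and bottom: bodies have
        # sloping shoulders and hips, not flat cuts, and a thickness
        # discontinuity would dominate registration residuals
        r = max(p.torso_end_round, 1e-9)
        u = np.clip((gy - y_sh) / r, 0.0, 1.0)
        v = np.clip((y_hip - gy) / r, 0.0, 1.0)
        top = np.sqrt(np.clip(2 * u - u * u, 0.0, None))
        bot = np.sqrt(np.clip(2 * v - v * v, 0.0, None))
        return np.where((gy >= y_sh) & (gy <= y_hip), top * bot, 0.0)

    def torso(gx, gy):
        hw = _torso_halfwidth(p, gy)
        dx2 = (gx - p.cx) ** 2 / np.maximum(hw, 1e-9) ** 2
        return (p.t_torso * end_envelope(gy)
                * np.sqrt(np.clip(1.0 - dx2, 0.0, None)))

    acc.add(torso, (p.cx - p.shoulder_hw, p.cx + p.shoulder_hw, y_sh, y_hip),
            p.fat_trunk)

    spine_a = np.array([p.cx, y_sh])
    spine_b = np.array([p.cx, y_hip])

    def spine(gx, gy):
        t = _capsule_thickness(gx, gy, spine_a, spine_b, p.spine_hw, p.t_spine)
        return t * end_envelope(gy)

    acc.add(spine, _capsule_bbox(spine_a, spine_b, p.spine_hw), 0.0)

    for tag in ("l", "r"):
        a = ax[tag]
        for seg_a, seg_b, hw, amp, frac in (
                (a["shoulder"], a["elbow"], p.arm_hw, p.t_upper_arm, p.fat_arm),
                (a["elbow"], a["hand_tip"], p.forearm_hw, p.t_forearm, p.fat_arm),
                (a["hip"], a["knee"], p.thigh_hw, p.t_thigh, p.fat_leg),
                (a["knee"], a["ankle"], p.calf_hw, p.t_shank, p.fat_leg),
                (a["ankle"], a["foot_tip"], p.ankle_hw, 0.75 * p.t_shank,
                 p.fat_leg)):
            acc.add(lambda gx, gy, sa=seg_a, sb=seg_b, w=hw, t=amp:
                    _capsule_thickness(gx, gy, sa, sb, w, t),
                    _capsule_bbox(seg_a, seg_b, hw), frac)
    return acc.fat, acc.lean


def _capsule_bbox(a: np.ndarray, b: np.ndarray, hw: float):
    return (min(a[0], b[0]) - hw, max(a[0], b[0]) + hw,
            min(a[1], b[1]) - hw, max(a[1], b[1]) + hw)


def silhouette(params: BodyShapeParams, torso_only: bool = False):
    """Shapely outline of the body (or of the torso-subset region)."""
    from shapely.geometry import LineString, Point, Polygon
    from shapely.ops import unary_union

    p = params.resolved()
    ax = _limb_axes(p)
    y_sh, y_hip = ax["y_shoulder"], ax["y_hip"]
    ys = np.linspace(y_sh, y_hip, 40)
    hws = _torso_halfwidth(p, ys)
    ring = ([(p.cx - h, y) for y, h in zip(ys, hws)]
            + [(p.cx + h, y) for y, h in zip(ys[::-1], hws[::-1])])
    parts = [Polygon(ring)]
    caps = []
    for tag in ("l", "r"):
        a = ax[tag]
        caps.append(LineString([a["shoulder"], a["elbow"]]).buffer(p.arm_hw))
        caps.append(LineString([a["hip"], a["knee"]]).buffer(p.thigh_hw))
        if not torso_only:
            caps.append(LineString([a["elbow"], a["hand_tip"]]).buffer(p.forearm_hw))
            caps.append(LineString([a["knee"], a["ankle"]]).buffer(p.calf_hw))
            caps.append(LineString([a["ankle"], a["foot_tip"]]).buffer(p.ankle_hw))
    if not torso_only:
        parts.append(Point(p.cx, p.head_top + p.head_radius).buffer(p.head_radius))
        y_chin = p.head_top + 2 * p.head_radius
        parts.append(LineString([(p.cx, y_chin - 2.0),
                                 (p.cx, ax["y_neck_base"] + 4.0)]).buffer(p.neck_hw))
    return unary_union(parts + caps)


def fits_grid(params: BodyShapeParams,
              shape: tuple[int, int] = FRAME_SHAPE, margin: float = 2.0) -> bool:
    """True when every landmark (padded by the largest half-width) is in frame."""
    pts = landmark_positions(params)
    pad = margin
    rows, cols = shape
    return bool((pts[:, 0] > pad).all() and (pts[:, 0] < cols - 1 - pad).all()
                and (pts[:, 1] > pad).all() and (pts[:, 1] < rows - 1 - pad).all())
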