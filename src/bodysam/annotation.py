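"""Landmark schemes, point sets, triangle meshes and semi-automatic placement.

Two annotation schemes describe the whole-body images: an 82-point full-body
scheme covering the skin outline plus bony and soft-tissue landmarks, and a
52-point extended-torso subset keeping the torso, upper arms and upper legs
while dropping the head and the forelimbs (whose pose varies most between
scans and carries little composition information).

The schemes, the bilateral symmetry pairing, the torso subset and the triangle
meshes used for piecewise-affine warping are generated from the parametric
template body in :mod:`bodysam._body`, so every fixture is reproducible from
code.  A simplified constrained local search refines landmark positions on an
image: per-point normalized-cross-correlation patch matching alternated with a
hard projection onto the shape-model subspace.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay

from . import _body

__all__ = [
    "LandmarkScheme", "PointSet", "TriangleMesh", "MeshReport",
    "scheme_82", "scheme_52", "get_scheme", "template_points",
    "subset_to_torso", "reflect", "validate_mesh",
    "constrained_local_fit", "make_patch_templates",
    "save_points", "load_points", "save_scheme", "load_scheme",
]


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class LandmarkScheme:
    """An ordered landmark naming with bilateral symmetry structure."""

    scheme_id: str
    point_names: tuple[str, ...]
    symmetry_pairs: tuple[tuple[int, int], ...]  # (left index, right index)
    midline_points: tuple[int, ...]
    torso_subset: tuple[int, ...] = ()           # indices into this scheme

    def __post_init__(self) -> None:
        n = self.count
        paired = [i for pair in self.symmetry_pairs for i in pair]
        if any(i >= n for i in paired + list(self.midline_points)
               + list(self.torso_subset)):
            raise ValueError("landmark index out of range")
        if len(set(paired)) != len(paired):
            raise ValueError("symmetry pairs are not disjoint")
        if set(paired) & set(self.midline_points):
            raise ValueError("a midline point cannot be in a symmetry pair")
        if self.count == 82 and self.torso_subset and len(self.torso_subset) != 52:
            raise ValueError("torso subset of the 82-point scheme must have 52 points")

    @property
    def count(self) -> int:
        return len(self.point_names)

    def partner(self) -> np.ndarray:
        """partner[i] = index of i's mirror landmark (itself for midline)."""
        partner = np.arange(self.count)
        for l, r in self.symmetry_pairs:
            partner[l], partner[r] = r, l
        return partner


@dataclass
class PointSet:
    """Ordered landmark coordinates (x, y) in the image frame."""

    coords: np.ndarray
    scheme_id: str

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")

    @property
    def n(self) -> int:
        return len(self.coords)

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass(frozen=True)
class TriangleMesh:
    """Triangle topology over a landmark scheme, used for piecewise warping."""

    triangles: tuple[tuple[int, int, int], ...]
    scheme_id: str

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.triangles, dtype=int)


@dataclass
class MeshReport:
    degenerate: list[int] = field(default_factory=list)   # triangle indices
    inverted: list[int] = field(default_factory=list)
    uncovered: list[int] = field(default_factory=list)    # landmark indices

    @property
    def ok(self) -> bool:
        return not (self.degenerate or self.inverted or self.uncovered)


# ---------------------------------------------------------------------------
# Scheme construction from the template body

SCHEME_82_ID = "body82"
SCHEME_52_ID = "torso52"


def _build_layout():
    """Expand the per-name layout into flat index structures."""
    names, pairs, midline, subset = [], [], [], []
    for name, kind, in_subset in _body.SCHEME_LAYOUT:
        if kind == "M":
            idx = len(names)
            names.append(name)
            midline.append(idx)
            if in_subset:
                subset.append(idx)
        else:
            li = len(names)
            names.append(f"{name}_l")
            names.append(f"{name}_r")
            pairs.append((li, li + 1))
            if in_subset:
                subset.extend([li, li + 1])
    return names, pairs, midline, subset


@functools.lru_cache(maxsize=1)
def scheme_82() -> LandmarkScheme:
    """The 82-point full-body scheme."""
    names, pairs, midline, subset = _build_layout()
    return LandmarkScheme(SCHEME_82_ID, tuple(names), tuple(pairs),
                          tuple(midline), tuple(subset))


@functools.lru_cache(maxsize=1)
def scheme_52() -> LandmarkScheme:
    """The 52-point extended-torso scheme (subset of the 82-point scheme)."""
    full = scheme_82()
    subset = list(full.torso_subset)
    remap = {old: new for new, old in enumerate(subset)}
    names = tuple(full.point_names[i] for i in subset)
    pairs = tuple((remap[l], remap[r]) for l, r in full.symmetry_pairs
                  if l in remap and r in remap)
    midline = tuple(remap[i] for i in full.midline_points if i in remap)
    return LandmarkScheme(SCHEME_52_ID, names, pairs, midline)


def get_scheme(scheme_id: str) -> LandmarkScheme:
    if scheme_id == SCHEME_82_ID:
        return scheme_82()
    if scheme_id == SCHEME_52_ID:
        return scheme_52()
    raise KeyError(f"unknown scheme {scheme_id!r}")


def template_points(scheme_id: str = SCHEME_82_ID) -> PointSet:
    """Landmarks of the default template body, in the square-pixel frame."""
    pts = _body.landmark_positions(_body.BodyShapeParams())
    if scheme_id == SCHEME_82_ID:
        return PointSet(pts, SCHEME_82_ID)
    if scheme_id == SCHEME_52_ID:
        return PointSet(pts[list(scheme_82().torso_subset)], SCHEME_52_ID)
    raise KeyError(f"unknown scheme {scheme_id!r}")


@functools.lru_cache(maxsize=4)
def default_mesh(scheme_id: str = SCHEME_82_ID) -> TriangleMesh:
    """Delaunay triangulation of the template shape, clipped to the body outline.

    Triangles whose centroid falls outside the (slightly buffered) silhouette
    are dropped so the mesh does not bridge the concave gaps between limbs and
    torso.  Winding is normalized to positive signed area in image coordinates.
    """
    from shapely.geometry import Point

    pts = template_points(scheme_id).coords
    sil = _body.silhouette(_body.BodyShapeParams(),
                           torso_only=(scheme_id == SCHEME_52_ID)).buffer(3.0)
    tri = Delaunay(pts)
    kept = []
    for simplex in tri.simplices:
        c = pts[simplex].mean(axis=0)
        if sil.contains(Point(c[0], c[1])):
            kept.append(tuple(int(i) for i in simplex))
    kept = [_orient(t, pts) for t in kept]
    kept.sort()
    mesh = TriangleMesh(tuple(kept), scheme_id)
    report = validate_mesh(mesh, PointSet(pts, scheme_id))
    if report.uncovered:
        raise RuntimeError(f"template mesh leaves landmarks uncovered: "
                           f"{report.uncovered}")
    return mesh


def _signed_area(tri: tuple[int, int, int], pts: np.ndarray) -> float:
    a, b, c = pts[list(tri)]
    return 0.5 * float((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))


def _orient(tri: tuple[int, int, int], pts: np.ndarray) -> tuple[int, int, int]:
    if _signed_area(tri, pts) < 0:
        return (tri[0], tri[2], tri[1])
    return tri


# ---------------------------------------------------------------------------
# Operations


def subset_to_torso(points: PointSet, scheme: LandmarkScheme | None = None) -> PointSet:
    """Restrict an 82-point set to the 52-point extended-torso scheme."""
    scheme = scheme_82() if scheme is None else scheme
    if points.scheme_id != scheme.scheme_id or not scheme.torso_subset:
        raise ValueError(
            f"expected a {SCHEME_82_ID} point set, got {points.scheme_id!r}")
    if points.n != scheme.count:
        raise ValueError(f"point count {points.n} != scheme count {scheme.count}")
    return PointSet(points.coords[list(scheme.torso_subset)], SCHEME_52_ID)


def reflect(points: PointSet, image_width: int,
            scheme: LandmarkScheme | None = None) -> PointSet:
    """Mirror a point set about the vertical image axis, relabeling left/right.

    Every x becomes ``image_width - 1 - x``; paired landmarks swap labels so
    the output is a valid annotation of the mirrored image.  An exact
    involution: reflecting twice restores the input bit-for-bit.
    """
    scheme = get_scheme(points.scheme_id) if scheme is None else scheme
    if points.n != scheme.count:
        raise ValueError(f"point count {points.n} != scheme count {scheme.count}")
    paired = {i for pair in scheme.symmetry_pairs for i in pair}
    unpaired = set(range(scheme.count)) - paired - set(scheme.midline_points)
    if unpaired:
        raise ValueError(f"non-midline points without a symmetry partner: "
                         f"{sorted(unpaired)}")
    mirrored = points.coords.copy()
    mirrored[:, 0] = image_width - 1 - mirrored[:, 0]
    out = mirrored[scheme.partner()]
    return PointSet(out, points.scheme_id)


def validate_mesh(mesh: TriangleMesh, mean_points: PointSet,
                  eps: float = 1e-9) -> MeshReport:
    """Check a mesh against the shape it will be used on.

    Degenerate triangles (|area| < eps on the mean shape) raise; inverted
    winding and landmarks not used by any triangle are reported as warnings.
    """
    pts = mean_points.coords
    report = MeshReport()
    covered: set[int] = set()
    for t_idx, tri in enumerate(mesh.triangles):
        if len(set(tri)) != 3:
            report.degenerate.append(t_idx)
            continue
        area = _signed_area(tri, pts)
        if abs(area) < eps:
            report.degenerate.append(t_idx)
        elif area < 0:
            report.inverted.append(t_idx)
        covered.update(tri)
    report.uncovered = sorted(set(range(mean_points.n)) - covered)
    if report.degenerate:
        raise ValueError(f"degenerate triangles on the mean shape: "
                         f"{report.degenerate}")
    return report


# ---------------------------------------------------------------------------
# Simplified constrained local search


def make_patch_templates(image: np.ndarray, points: PointSet,
                         patch_size: int = 9) -> np.ndarray:
    """Sample square patches around each landmark to use as match templates."""
    if patch_size % 2 == 0:
        raise ValueError("patch_size must be odd")
    h = patch_size // 2
    img = np.asarray(image, dtype=float)
    padded = np.pad(img, h, mode="edge")
    out = np.empty((points.n, patch_size, patch_size))
    for i, (x, y) in enumerate(points.coords):
        cx, cy = int(round(x)) + h, int(round(y)) + h
        out[i] = padded[cy - h:cy + h + 1, cx - h:cx + h + 1]
    return out


def _ncc_displacement(region: np.ndarray, template: np.ndarray) -> tuple[int, int]:
    """Best (dx, dy) of the template inside the search region by NCC.

    Returns (0, 0) when either the template or every candidate window is
    (numerically) constant — a blank image offers no gradient to follow.
    """
    from skimage.feature import match_template

    if template.std() < 1e-12 or region.std() < 1e-12:
        return 0, 0
    resp = match_template(region, template, pad_input=False)
    if not np.isfinite(resp).any() or resp.max() <= 0:
        return 0, 0
    iy, ix = np.unravel_index(np.argmax(resp), resp.shape)
    half = (region.shape[0] - template.shape[0]) // 2
    return int(ix) - half, int(iy) - half


def constrained_local_fit(image: np.ndarray, init_points: PointSet,
                          shape_model, patch_templates: np.ndarray,
                          search_window: int = 6, max_iter: int = 20,
                          tol: float = 0.25, k_sd: float = 3.0,
                          ) -> tuple[PointSet, bool]:
    """Refine landmark positions: local NCC search + shape-subspace projection.

    Each iteration moves every point to its best normalized-cross-correlation
    match within ``+/-search_window`` pixels, then projects the configuration
    onto the span of ``shape_model`` with mode scores clipped to
    ``+/-k_sd*sqrt(eigenvalue)``.  Stops when the mean per-point displacement
    falls below ``tol`` pixels or after ``max_iter`` iterations; the result is
    always inside the image.  Non-convergence is reported via the flag, not
    raised.
    """
    img = np.asarray(image, dtype=float)
    img = np.where(np.isfinite(img), img, 0.0)
    n_pts, p, _ = patch_templates.shape
    if n_pts != init_points.n:
        raise ValueError("templates and points have different schemes")
    h = p // 2 + search_window
    padded = np.pad(img, h, mode="edge")
    rows, cols = img.shape
    coords = init_points.coords.copy()
    coords[:, 0] = np.clip(coords[:, 0], 0, cols - 1)
    coords[:, 1] = np.clip(coords[:, 1], 0, rows - 1)
    converged = False
    for _ in range(max_iter):
        moved = coords.copy()
        for i in range(n_pts):
            cx = int(round(coords[i, 0])) + h
            cy = int(round(coords[i, 1])) + h
            region = padded[cy - h:cy + h + 1, cx - h:cx + h + 1]
            dx, dy = _ncc_displacement(region, patch_templates[i])
            moved[i, 0] += dx
            moved[i, 1] += dy
        new = _project_to_shape(moved, shape_model, k_sd)
        new[:, 0] = np.clip(new[:, 0], 0, cols - 1)
        new[:, 1] = np.clip(new[:, 1], 0, rows - 1)
        delta = float(np.linalg.norm(new - coords, axis=1).mean())
        coords = new
        if delta < tol:
            converged = True
            break
    return PointSet(coords, init_points.scheme_id), converged


def _project_to_shape(coords: np.ndarray, shape_model, k_sd: float) -> np.ndarray:
    """Project a configuration onto the shape span with clipped mode scores."""
    centroid = coords.mean(axis=0)
    x = (coords - centroid).ravel()
    b = shape_model.modes.T @ (x - shape_model.mean_shape)
    lim = k_sd * np.sqrt(np.maximum(shape_model.eigenvalues, 0.0))
    b = np.clip(b, -lim, lim)
    x_proj = shape_model.mean_shape + shape_model.modes @ b
    return x_proj.reshape(-1, 2) + centroid


# ---------------------------------------------------------------------------
# File formats: plain-text points, JSON scheme + mesh documents


def save_points(path, points: PointSet) -> None:
    """Plain text: one header line ``bodysam-points <scheme> <n>``, then
    ``index x y`` per line (0-based, floating-point pixels)."""
    lines = [f"bodysam-points {points.scheme_id} {points.n}"]
    for i, (x, y) in enumerate(points.coords):
        lines.append(f"{i} {float(x)!r} {float(y)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_points(path) -> PointSet:
    lines = Path(path).read_text().strip().splitlines()
    tag, scheme_id, n_str = lines[0].split()
    if tag != "bodysam-points":
        raise ValueError(f"{path}: not a points file")
    n = int(n_str)
    coords = np.empty((n, 2))
    for line in lines[1:1 + n]:
        idx_s, x_s, y_s = line.split()
        coords[int(idx_s)] = (float(x_s), float(y_s))
    return PointSet(coords, scheme_id)


def save_scheme(path, scheme: LandmarkScheme, mesh: TriangleMesh | None = None) -> None:
    doc = {
        "format": "bodysam-scheme",
        "version": 1,
        "scheme_id": scheme.scheme_id,
        "point_names": list(scheme.point_names),
        "symmetry_pairs": [list(p) for p in scheme.symmetry_pairs],
        "midline_points": list(scheme.midline_points),
        "torso_subset": list(scheme.torso_subset),
        "triangles": [list(t) for t in mesh.triangles] if mesh else None,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_scheme(path) -> tuple[LandmarkScheme, TriangleMesh | None]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "bodysam-scheme":
        raise ValueError(f"{path}: not a scheme file")
    scheme = LandmarkScheme(
        doc["scheme_id"], tuple(doc["point_names"]),
        tuple(tuple(p) for p in doc["symmetry_pairs"]),
        tuple(doc["midline_points"]), tuple(doc.get("torso_subset") or ()))
    mesh = None
    if doc.get("triangles"):
        mesh = TriangleMesh(tuple(tuple(t) for t in doc["triangles"]),
                            scheme.scheme_id)
    return scheme, mesh
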