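"""Piecewise-affine warping into the mean-shape reference frame.

Shape variation is removed from the images by deforming each one onto a common
raster whose geometry is the mean body shape: for every output pixel inside
the triangulated mean shape, the pixel's barycentric coordinates in its
reference triangle identify the corresponding location in the subject's
triangle, and the source image is sampled there bilinearly.  The map is affine
within each triangle and continuous across shared edges.

The module also computes population mean images under three registration
levels of increasing strength — translation only, global affine, and the full
piecewise warp — whose increasing sharpness is the classic visual argument
for shape normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .annotation import PointSet, TriangleMesh

__all__ = ["ReferenceFrame", "DegenerateTriangleError", "build_frame",
           "warp_image", "warp_to_reference", "affine_fit", "mean_image",
           "gradient_energy"]

_BARY_EPS = 1e-9


class DegenerateTriangleError(ValueError):
    def __init__(self, triangle_index: int, vertices):
        super().__init__(f"degenerate source triangle {triangle_index} "
                         f"with vertices {vertices}")
        self.triangle_index = triangle_index


# ---------------------------------------------------------------------------
# Triangle rasterization helpers


def _bary_matrix(verts: np.ndarray) -> np.ndarray | None:
    """Inverse mapping (x, y, 1) -> barycentric weights; None when degenerate."""
    m = np.column_stack([verts, np.ones(3)]).T  # rows: x, y, 1
    det = np.linalg.det(m)
    if abs(det) < 1e-12:
        return None
    return np.linalg.inv(m)


def rasterize_mesh(points: np.ndarray, mesh: TriangleMesh,
                   shape: tuple[int, int]) -> np.ndarray:
    """Per-pixel triangle assignment: index of the containing triangle, -1 outside.

    Pixels on shared edges go to the lowest-indexed containing triangle — the
    deterministic tie-break that makes warps bit-reproducible.
    """
    rows, cols = shape
    tri_index = np.full(shape, -1, dtype=np.int32)
    tris = mesh.as_array()
    for t, tri in enumerate(tris):
        verts = points[tri]
        inv = _bary_matrix(verts)
        if inv is None:
            continue  # zero-area reference triangle covers no pixels
        x0 = max(int(np.floor(verts[:, 0].min())), 0)
        x1 = min(int(np.ceil(verts[:, 0].max())), cols - 1)
        y0 = max(int(np.floor(verts[:, 1].min())), 0)
        y1 = min(int(np.ceil(verts[:, 1].max())), rows - 1)
        if x1 < x0 or y1 < y0:
            continue
        xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        coords = np.stack([xs.ravel(), ys.ravel(), np.ones(xs.size)])
        bary = inv @ coords
        inside = (bary >= -_BARY_EPS).all(axis=0)
        sub = tri_index[y0:y1 + 1, x0:x1 + 1].ravel()
        take = inside & (sub == -1)
        sub[take] = t
        tri_index[y0:y1 + 1, x0:x1 + 1] = sub.reshape(ys.shape)
    return tri_index


@dataclass
class ReferenceFrame:
    """Mean shape placed on a raster grid, with its mesh and pixel-triangle map."""

    points: np.ndarray                  # (n, 2) reference landmark coordinates
    mesh: TriangleMesh
    shape: tuple[int, int]              # raster (rows, cols)
    tri_index: np.ndarray = field(repr=False, default=None)
    output_scale: float = 1.0           # frame pixels per source-image pixel

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        rows, cols = self.shape
        if ((self.points[:, 0] < 0).any() or (self.points[:, 0] > cols - 1).any()
                or (self.points[:, 1] < 0).any() or (self.points[:, 1] > rows - 1).any()):
            raise ValueError("reference points fall outside the raster")
        if self.tri_index is None:
            self.tri_index = rasterize_mesh(self.points, self.mesh, self.shape)

    @property
    def mask(self) -> np.ndarray:
        return self.tri_index >= 0

    @property
    def n_mask_pixels(self) -> int:
        return int(self.mask.sum())


def build_frame(mean_points: PointSet, mesh: TriangleMesh,
                margin: float = 0.05, output_scale: float = 1.0) -> ReferenceFrame:
    """Place a mean shape into a fresh raster with a proportional margin.

    ``output_scale`` shrinks the frame raster (and hence the texture vector
    length) without changing the geometry; 1.0 keeps source resolution.
    """
    pts = mean_points.coords
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = hi - lo
    pad = margin * span
    ref = (pts - lo + pad) * output_scale
    dims = np.ceil((span + 2 * pad) * output_scale).astype(int) + 1
    shape = (int(dims[1]), int(dims[0]))  # (rows, cols)
    return ReferenceFrame(ref, mesh, shape, output_scale=output_scale)


# ---------------------------------------------------------------------------
# Warping


def _sample_bilinear(image: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    img = np.where(np.isfinite(img), img, 0.0)  # no-data contributes as 0
    return ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")


def warp_image(image: np.ndarray, source_points: np.ndarray,
               dest_points: np.ndarray, mesh: TriangleMesh,
               out_shape: tuple[int, int],
               tri_index: np.ndarray | None = None) -> np.ndarray:
    """Piecewise-affine warp: image annotated by ``source_points`` rendered on
    the raster where the landmarks sit at ``dest_points``.

    Output pixels outside the destination mesh carry nan (no-data).
    """
    source_points = np.asarray(source_points, dtype=float)
    dest_points = np.asarray(dest_points, dtype=float)
    if tri_index is None:
        tri_index = rasterize_mesh(dest_points, mesh, out_shape)
    out = np.full(out_shape, np.nan)
    tris = mesh.as_array()
    ys_all, xs_all = np.nonzero(tri_index >= 0)
    t_all = tri_index[ys_all, xs_all]
    order = np.argsort(t_all, kind="stable")
    ys_all, xs_all, t_all = ys_all[order], xs_all[order], t_all[order]
    bounds = np.searchsorted(t_all, np.arange(len(tris) + 1))
    for t in range(len(tris)):
        a, b = bounds[t], bounds[t + 1]
        if a == b:
            continue
        tri = tris[t]
        dst_verts = dest_points[tri]
        src_verts = source_points[tri]
        inv = _bary_matrix(dst_verts)
        if inv is None:
            raise DegenerateTriangleError(t, dst_verts.tolist())
        if abs(np.linalg.det(np.column_stack([src_verts, np.ones(3)]))) < 1e-12:
            raise DegenerateTriangleError(t, src_verts.tolist())
        xs, ys = xs_all[a:b], ys_all[a:b]
        coords = np.stack([xs, ys, np.ones(xs.size)])
        bary = inv @ coords                     # (3, m)
        src = src_verts.T @ bary                # (2, m): x, y
        out[ys, xs] = _sample_bilinear(image, src[0], src[1])
    return out


def warp_to_reference(image: np.ndarray, source_points: PointSet,
                      frame: ReferenceFrame) -> np.ndarray:
    """Warp a subject image into the mean-shape reference frame."""
    if len(source_points.coords) != len(frame.points):
        raise ValueError("source points do not match the frame scheme")
    return warp_image(image, source_points.coords, frame.points, frame.mesh,
                      frame.shape, tri_index=frame.tri_index)


def affine_fit(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Unweighted least-squares 6-parameter affine map src -> dst (3x2 matrix).

    Rows of the returned matrix are applied as ``[x, y, 1] @ A``.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    design = np.column_stack([src, np.ones(len(src))])
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return coef


# ---------------------------------------------------------------------------
# Mean images


def mean_image(images: list[np.ndarray], pointsets: list[PointSet],
               frame: ReferenceFrame, level: str = "piecewise") -> np.ndarray:
    """Pixelwise mean of registered images at the requested alignment level.

    * ``translation`` — shift each image so its landmark centroid coincides
      with the frame centroid;
    * ``affine`` — unweighted least-squares 6-parameter fit of the landmarks
      to the frame points;
    * ``piecewise`` — full triangle-wise warp into the frame.

    Only non-no-data contributions are counted at each pixel.
    """
    if not images:
        raise ValueError("need at least one image")
    if level not in ("translation", "affine", "piecewise"):
        raise ValueError(f"unknown level {level!r}")
    rows, cols = frame.shape
    xs, ys = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    total = np.zeros(frame.shape)
    count = np.zeros(frame.shape)
    frame_centroid = frame.points.mean(axis=0)
    for img, ps in zip(images, pointsets):
        if level == "translation":
            offset = frame_centroid - ps.centroid()
            src_x = xs - offset[0]
            src_y = ys - offset[1]
            warped = _sample_outside_nan(img, src_x, src_y)
        elif level == "affine":
            inv_map = affine_fit(frame.points, ps.coords)  # frame -> subject
            src = np.stack([xs.ravel(), ys.ravel(), np.ones(xs.size)], axis=1) @ inv_map
            warped = _sample_outside_nan(img, src[:, 0].reshape(xs.shape),
                                         src[:, 1].reshape(ys.shape))
        else:
            warped = warp_to_reference(img, ps, frame)
        good = np.isfinite(warped)
        total[good] += warped[good]
        count[good] += 1
    out = np.full(frame.shape, np.nan)
    seen = count > 0
    out[seen] = total[seen] / count[seen]
    return out


def _sample_outside_nan(image: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Bilinear sampling that returns nan outside the source raster."""
    img = np.asarray(image, dtype=float)
    img = np.where(np.isfinite(img), img, 0.0)
    rows, cols = img.shape
    vals = ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")
    outside = (xs < 0) | (xs > cols - 1) | (ys < 0) | (ys > rows - 1)
    vals = np.where(outside, np.nan, vals)
    return vals


def _signed_areas(points: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    """Signed area of every mesh triangle on a configuration (y-down frame)."""
    tris = mesh.as_array()
    a = points[tris[:, 0]]
    b = points[tris[:, 1]]
    c = points[tris[:, 2]]
    return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                  - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))


def gradient_energy(image: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean squared spatial gradient over valid pixels; a sharpness score."""
    img = np.asarray(image, dtype=float)
    valid = np.isfinite(img) if mask is None else (mask & np.isfinite(img))
    filled = np.where(valid, img, 0.0)
    gy, gx = np.gradient(filled)
    # count only pixels whose full neighborhood is valid
    core = valid & ndimage.binary_erosion(valid, structure=np.ones((3, 3)))
    if not core.any():
        return 0.0
    return float((gx[core] ** 2 + gy[core] ** 2).mean())
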