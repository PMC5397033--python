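"""Combined appearance model: joint PCA of shape and texture parameters.

Shape and texture mode scores are correlated across subjects (a wider body is
also a thicker one), so a third PCA over the concatenated score vectors

    [ w_s * b_shape ; b_texture ]

captures both together in one parameter vector c.  The scalar shape weight
w_s commensurates pixel-unit shape variance with physical-unit texture
variance; the default balances the two blocks' total variance,
w_s = sqrt(sum(lambda_g) / sum(lambda_s)).

Because shape and texture scores are projections of centered data, the
combined vectors have zero mean by construction, and synthesis/encoding are
exact linear round trips within the model span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import PointSet
from .piecewise_warp import warp_image, warp_to_reference, _signed_areas
from .shape_model import (ShapeModel, fit_pca, params_from_shape,
                          shape_from_params)
from .texture_model import (TextureModel, paint_texture,
                            params_from_texture, sample_texture,
                            texture_from_params)

__all__ = ["AppearanceModel", "SynthesisResult", "build_appearance",
           "synthesize", "encode_image", "mode_visualization",
           "FoldedTriangleError"]


@dataclass
class SynthesisResult:
    """A synthesized subject: landmarks, rendered images, model-space texture.

    ``images`` are the channels warped onto the synthesized shape (for
    display); ``frame_channels`` are the same texture in the reference frame,
    the model's own domain — encoding them reproduces c exactly, while
    re-encoding the rendered images costs one warp interpolation.
    Iterates as (points, images) for tuple-style unpacking.
    """

    points: PointSet
    images: list
    frame_channels: list

    def __iter__(self):
        return iter((self.points, self.images))

    def __getitem__(self, i):
        return (self.points, self.images)[i]


class FoldedTriangleError(ValueError):
    def __init__(self, triangle_index: int):
        super().__init__(f"synthesized shape folds triangle {triangle_index} "
                         "(negative area)")
        self.triangle_index = triangle_index


@dataclass
class AppearanceModel:
    """Linked shape+texture PCA with a combined parameter space."""

    shape_model: ShapeModel
    texture_model: TextureModel
    shape_weight: float              # w_s > 0
    modes: np.ndarray                # (k_s + k_g, k_c) orthonormal columns
    eigenvalues: np.ndarray
    variance_threshold: float
    total_variance: float

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def n_shape_modes(self) -> int:
        return self.shape_model.n_modes

    def split_blocks(self, combined: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split a combined-space vector into (b_shape, b_texture), unweighted."""
        k_s = self.n_shape_modes
        return combined[:k_s] / self.shape_weight, combined[k_s:]


def build_appearance(shape_model: ShapeModel, texture_model: TextureModel,
                     shape_params: np.ndarray, texture_params: np.ndarray,
                     variance_threshold: float = 0.95,
                     shape_weight: float | None = None) -> AppearanceModel:
    """Joint PCA over per-subject concatenated (weighted) score vectors.

    ``shape_params`` is (n_subjects, k_s), ``texture_params`` (n_subjects,
    k_g), row-paired by subject.  When ``shape_weight`` is None it is chosen
    so the weighted shape block and the texture block carry equal total
    variance.
    """
    shape_params = np.asarray(shape_params, dtype=float)
    texture_params = np.asarray(texture_params, dtype=float)
    if shape_params.shape[0] != texture_params.shape[0]:
        raise ValueError("unpaired inputs: "
                         f"{shape_params.shape[0]} shape rows vs "
                         f"{texture_params.shape[0]} texture rows")
    if shape_weight is None:
        var_s = float(shape_params.var(axis=0, ddof=1).sum())
        var_g = float(texture_params.var(axis=0, ddof=1).sum())
        shape_weight = float(np.sqrt(var_g / var_s)) if var_s > 0 and var_g > 0 else 1.0
    if shape_weight <= 0:
        raise ValueError("shape_weight must be > 0")
    combined = np.hstack([shape_weight * shape_params, texture_params])
    pca = fit_pca(combined, variance_threshold)
    return AppearanceModel(shape_model, texture_model, shape_weight,
                           pca.modes, pca.eigenvalues, variance_threshold,
                           pca.total_variance)


def _combined_from_params(model: AppearanceModel, c: np.ndarray) -> np.ndarray:
    c = np.atleast_1d(np.asarray(c, dtype=float))
    if c.size > model.n_modes:
        raise ValueError(f"{c.size} params but only {model.n_modes} modes")
    full = np.zeros(model.n_modes)
    full[:c.size] = c
    return model.modes @ full


def synthesize(model: AppearanceModel, c: np.ndarray,
               out_shape: tuple[int, int] | None = None,
               ) -> SynthesisResult:
    """Generate (shape, rendered channel images) from appearance parameters.

    The combined vector is split into blocks; the shape block synthesizes
    landmark positions, the texture block synthesizes intensities in the
    reference frame, and the texture is warped from the frame onto the
    synthesized shape.  The shape is placed at the frame centroid for
    rendering.  A synthesized shape that folds a mesh triangle (negative
    area) raises :class:`FoldedTriangleError`.
    """
    b_s, b_g = model.split_blocks(_combined_from_params(model, c))
    shape = shape_from_params(model.shape_model, b_s)         # centered coords
    frame = model.texture_model.frame
    # render at source-image scale: the frame raster may be a scaled-down
    # grid, but synthesized subjects live in full-scale image coordinates
    placed = shape.coords + frame.points.mean(axis=0) / frame.output_scale
    areas = _signed_areas(placed, frame.mesh)
    folded = np.nonzero(areas <= 0)[0]
    if folded.size:
        raise FoldedTriangleError(int(folded[0]))
    g = texture_from_params(model.texture_model, b_g)
    channel_rasters = paint_texture(g, frame, model.texture_model.layout)
    if out_shape is None:
        out_shape = (int(np.ceil(frame.shape[0] / frame.output_scale)) + 1,
                     int(np.ceil(frame.shape[1] / frame.output_scale)) + 1)
    rendered = [warp_image(raster, frame.points, placed, frame.mesh, out_shape)
                for raster in channel_rasters]
    return SynthesisResult(PointSet(placed, shape.scheme_id), rendered,
                           channel_rasters)


def encode_image(model: AppearanceModel, warped_channels,
                 points: PointSet) -> np.ndarray:
    """Project an annotated subject into appearance parameters.

    ``warped_channels`` are the channel rasters already warped into the
    reference frame (or raw rasters plus points; see
    :func:`encode_from_image`).  Returns c = Q_c^T [w_s b_s ; b_g], the
    least-squares optimal parameters within the linear model.
    """
    centered = PointSet(points.coords - points.centroid(), points.scheme_id)
    b_s = params_from_shape(model.shape_model, centered)
    g = sample_texture(warped_channels, model.texture_model.frame,
                       model.texture_model.layout)
    b_g = params_from_texture(model.texture_model, g)
    combined = np.concatenate([model.shape_weight * b_s, b_g])
    return model.modes.T @ combined


def encode_from_image(model: AppearanceModel, channels,
                      points: PointSet) -> np.ndarray:
    """Encode raw (unwarped) channel rasters: warp to the frame, then encode."""
    if isinstance(channels, np.ndarray) and channels.ndim == 2:
        channels = [channels]
    frame = model.texture_model.frame
    warped = [warp_to_reference(ch, points, frame) for ch in channels]
    return encode_image(model, warped, points)


def mode_visualization(model: AppearanceModel, mode: int, k_sd: float = 3.0,
                       ) -> tuple[tuple[PointSet, list[np.ndarray]],
                                  tuple[PointSet, list[np.ndarray]]]:
    """Synthesize the -k_sd and +k_sd extremes of one appearance mode.

    Returns the (minus, plus) pair in that fixed order — minus conventionally
    displayed on the left.
    """
    if not (0 <= mode < model.n_modes):
        raise ValueError(f"mode {mode} out of range (0..{model.n_modes - 1})")
    sd = float(np.sqrt(model.eigenvalues[mode]))
    c = np.zeros(model.n_modes)
    c[mode] = -k_sd * sd
    minus = synthesize(model, c)
    c[mode] = +k_sd * sd
    plus = synthesize(model, c)
    return minus, plus
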