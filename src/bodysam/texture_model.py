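"""Texture model: PCA over shape-normalized pixel intensities.

After every image is warped into the mean-shape reference frame, the remaining
variation is purely "texture" — per-pixel intensity differences reflecting the
distribution of tissue rather than body outline.  Texture vectors collect the
in-mask pixels of the warped image in a fixed row-major scan order (channels
interleaved per pixel for multi-channel layouts) and are decomposed as

    g = g_mean + Q_g c .

Intensities are modeled in physical units (cm of thickness, leanness
fraction); 8-bit conversion exists only for display and export, so
quantization noise never enters the covariance.  A two-channel layout pairs
thickness and leanness, matching the RGB hybrid display where thickness is
the green channel and leanness the red.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dxa_maps import export_8bit
from .piecewise_warp import ReferenceFrame
from .shape_model import fit_pca

__all__ = ["TextureLayout", "TextureModel", "sample_texture", "paint_texture",
           "encode_rgb", "fit_texture_pca", "texture_from_params",
           "params_from_texture"]


@dataclass(frozen=True)
class TextureLayout:
    """Channel layout of a texture vector: names in interleaving order."""

    channels: tuple[str, ...] = ("rvalue",)

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass
class TextureModel:
    """PCA model of texture vectors sampled in a reference frame."""

    mean_texture: np.ndarray
    modes: np.ndarray
    eigenvalues: np.ndarray
    layout: TextureLayout
    frame: ReferenceFrame
    variance_threshold: float
    total_variance: float

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def __post_init__(self) -> None:
        expected = self.frame.n_mask_pixels * self.layout.n_channels
        if self.mean_texture.size != expected:
            raise ValueError(
                f"mean texture length {self.mean_texture.size} != "
                f"mask pixels x channels = {expected}")


def sample_texture(warped, frame: ReferenceFrame,
                   layout: TextureLayout | None = None) -> np.ndarray:
    """Collect in-mask pixels of warped channel image(s) into a texture vector.

    ``warped`` is one raster or a sequence of rasters (one per layout
    channel), all already in the frame.  Scan order is row-major over the
    mask with channels interleaved per pixel.
    """
    if isinstance(warped, np.ndarray) and warped.ndim == 2:
        warped = [warped]
    layout = layout or TextureLayout(tuple(f"ch{i}" for i in range(len(warped))))
    if len(warped) != layout.n_channels:
        raise ValueError(f"{len(warped)} rasters but layout has "
                         f"{layout.n_channels} channels")
    mask = frame.mask
    stacked = []
    for ch in warped:
        ch = np.asarray(ch, dtype=float)
        if ch.shape != frame.shape:
            raise ValueError(f"raster shape {ch.shape} != frame {frame.shape}; "
                             "warp to the frame first")
        stacked.append(ch[mask])
    return np.stack(stacked, axis=1).ravel()  # interleaved per pixel


def paint_texture(vector: np.ndarray, frame: ReferenceFrame,
                  layout: TextureLayout | None = None) -> list[np.ndarray]:
    """Inverse of :func:`sample_texture`: paint a vector back into frame rasters."""
    n_mask = frame.n_mask_pixels
    if layout is None:
        n_ch = vector.size // n_mask
        layout = TextureLayout(tuple(f"ch{i}" for i in range(n_ch)))
    per_pixel = vector.reshape(n_mask, layout.n_channels)
    out = []
    for c in range(layout.n_channels):
        img = np.full(frame.shape, np.nan)
        img[frame.mask] = per_pixel[:, c]
        out.append(img)
    return out


def encode_rgb(thickness: np.ndarray, leanness: np.ndarray,
               thickness_range: tuple[float, float] | None = None,
               leanness_range: tuple[float, float] = (0.0, 1.0)) -> np.ndarray:
    """Hybrid display encoding: thickness -> green, leanness -> red, blue unused.

    Both channels are linearly scaled into 0..255; no-data pixels are black.
    """
    thickness = np.asarray(thickness, dtype=float)
    leanness = np.asarray(leanness, dtype=float)
    if thickness.shape != leanness.shape:
        raise ValueError("thickness and leanness masks/shapes differ")
    if thickness_range is None:
        finite = thickness[np.isfinite(thickness)]
        hi = float(finite.max()) if finite.size and finite.max() > 0 else 1.0
        thickness_range = (0.0, hi)
    rgb = np.zeros(thickness.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = export_8bit(leanness, *leanness_range)
    rgb[..., 1] = export_8bit(thickness, *thickness_range)
    return rgb


def fit_texture_pca(vectors: np.ndarray, frame: ReferenceFrame,
                    layout: TextureLayout,
                    variance_threshold: float = 0.95) -> TextureModel:
    """PCA over texture vectors with threshold mode retention."""
    pca = fit_pca(np.asarray(vectors, dtype=float), variance_threshold)
    return TextureModel(pca.mean, pca.modes, pca.eigenvalues, layout, frame,
                        variance_threshold, pca.total_variance)


def texture_from_params(model: TextureModel, params: np.ndarray) -> np.ndarray:
    """Linear synthesis g = g_mean + Q_g c; trailing params default to 0."""
    params = np.atleast_1d(np.asarray(params, dtype=float))
    if params.size > model.n_modes:
        raise ValueError(
            f"{params.size} params but only {model.n_modes} retained modes")
    full = np.zeros(model.n_modes)
    full[:params.size] = params
    return model.mean_texture + model.modes @ full


def params_from_texture(model: TextureModel, vector: np.ndarray) -> np.ndarray:
    """Orthogonal projection c = Q_g^T (g - g_mean)."""
    vector = np.asarray(vector, dtype=float)
    if vector.size != model.mean_texture.size:
        raise ValueError(f"vector length {vector.size} != texture length "
                         f"{model.mean_texture.size}")
    return model.modes.T @ (vector - model.mean_texture)
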