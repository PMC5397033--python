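"""Versioned single-file model container (HDF5).

One archive holds everything needed to reuse a fitted model: the landmark
scheme and mesh, the shape model, the texture model with its reference frame
and channel layout, the combined appearance model with its shape weight, and
provenance (tool version, configuration hash, seed).  Loading reproduces
every array bit-exactly; files written by a future major format version are
refused with a clear error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import __version__ as _tool_version
from .annotation import LandmarkScheme, TriangleMesh
from .appearance_model import AppearanceModel
from .piecewise_warp import ReferenceFrame
from .shape_model import ShapeModel
from .texture_model import TextureLayout, TextureModel

__all__ = ["ModelContainer", "ModelIOError", "save_model", "load_model",
           "FORMAT_MAJOR", "FORMAT_MINOR"]

FORMAT_MAJOR = 1
FORMAT_MINOR = 0


class ModelIOError(RuntimeError):
    pass


@dataclass
class ModelContainer:
    scheme: LandmarkScheme
    mesh: TriangleMesh
    appearance: AppearanceModel
    provenance: dict

    @property
    def shape_model(self) -> ShapeModel:
        return self.appearance.shape_model

    @property
    def texture_model(self) -> TextureModel:
        return self.appearance.texture_model


def save_model(path, container: ModelContainer) -> None:
    import h5py

    app = container.appearance
    shp = app.shape_model
    tex = app.texture_model
    frame = tex.frame
    try:
        with h5py.File(path, "w") as f:
            f.attrs["format"] = "bodysam-model"
            f.attrs["format_major"] = FORMAT_MAJOR
            f.attrs["format_minor"] = FORMAT_MINOR
            prov = f.create_group("provenance")
            prov.attrs["tool_version"] = _tool_version
            for k, v in container.provenance.items():
                prov.attrs[str(k)] = v
            g = f.create_group("scheme")
            g.attrs["scheme_id"] = container.scheme.scheme_id
            g.create_dataset("point_names",
                             data=np.array(container.scheme.point_names, dtype="S"))
            g.create_dataset("symmetry_pairs",
                             data=np.asarray(container.scheme.symmetry_pairs,
                                             dtype=int).reshape(-1, 2))
            g.create_dataset("midline_points",
                             data=np.asarray(container.scheme.midline_points, dtype=int))
            g.create_dataset("torso_subset",
                             data=np.asarray(container.scheme.torso_subset, dtype=int))
            g.create_dataset("triangles", data=container.mesh.as_array())
            g = f.create_group("shape")
            g.create_dataset("mean", data=shp.mean_shape)
            g.create_dataset("modes", data=shp.modes)
            g.create_dataset("eigenvalues", data=shp.eigenvalues)
            g.attrs["n_points"] = shp.n_points
            g.attrs["variance_threshold"] = shp.variance_threshold
            g.attrs["total_variance"] = shp.total_variance
            g = f.create_group("texture")
            g.create_dataset("mean", data=tex.mean_texture)
            g.create_dataset("modes", data=tex.modes)
            g.create_dataset("eigenvalues", data=tex.eigenvalues)
            g.attrs["variance_threshold"] = tex.variance_threshold
            g.attrs["total_variance"] = tex.total_variance
            g.create_dataset("channels", data=np.array(tex.layout.channels, dtype="S"))
            g.create_dataset("frame_points", data=frame.points)
            g.create_dataset("frame_tri_index", data=frame.tri_index)
            g.attrs["frame_shape"] = frame.shape
            g.attrs["frame_output_scale"] = frame.output_scale
            g = f.create_group("appearance")
            g.create_dataset("modes", data=app.modes)
            g.create_dataset("eigenvalues", data=app.eigenvalues)
            g.attrs["shape_weight"] = app.shape_weight
            g.attrs["variance_threshold"] = app.variance_threshold
            g.attrs["total_variance"] = app.total_variance
    except OSError as exc:
        raise ModelIOError(f"cannot write model to {path}: {exc}") from exc


def load_model(path) -> ModelContainer:
    import h5py

    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != "bodysam-model":
                raise ModelIOError(f"{path}: not a model container")
            major = int(f.attrs.get("format_major", -1))
            if major > FORMAT_MAJOR:
                raise ModelIOError(
                    f"{path}: container format version {major} is newer than "
                    f"this build supports ({FORMAT_MAJOR}); upgrade to read it")
            g = f["scheme"]
            scheme = LandmarkScheme(
                scheme_id=str(g.attrs["scheme_id"]),
                point_names=tuple(n.decode() for n in g["point_names"][()]),
                symmetry_pairs=tuple(map(tuple, g["symmetry_pairs"][()].tolist())),
                midline_points=tuple(g["midline_points"][()].tolist()),
                torso_subset=tuple(g["torso_subset"][()].tolist()),
            )
            mesh = TriangleMesh(tuple(map(tuple, g["triangles"][()].tolist())),
                                scheme.scheme_id)
            g = f["shape"]
            shp = ShapeModel(
                mean_shape=g["mean"][()], modes=g["modes"][()],
                eigenvalues=g["eigenvalues"][()],
                n_points=int(g.attrs["n_points"]),
                variance_threshold=float(g.attrs["variance_threshold"]),
                scheme_id=scheme.scheme_id,
                total_variance=float(g.attrs["total_variance"]),
            )
            g = f["texture"]
            frame = ReferenceFrame(
                points=g["frame_points"][()], mesh=mesh,
                shape=tuple(int(v) for v in g.attrs["frame_shape"]),
                tri_index=g["frame_tri_index"][()],
                output_scale=float(g.attrs.get("frame_output_scale", 1.0)),
            )
            tex = TextureModel(
                mean_texture=g["mean"][()], modes=g["modes"][()],
                eigenvalues=g["eigenvalues"][()],
                layout=TextureLayout(tuple(c.decode() for c in g["channels"][()])),
                frame=frame,
                variance_threshold=float(g.attrs["variance_threshold"]),
                total_variance=float(g.attrs["total_variance"]),
            )
            g = f["appearance"]
            app = AppearanceModel(
                shape_model=shp, texture_model=tex,
                shape_weight=float(g.attrs["shape_weight"]),
                modes=g["modes"][()], eigenvalues=g["eigenvalues"][()],
                variance_threshold=float(g.attrs["variance_threshold"]),
                total_variance=float(g.attrs["total_variance"]),
            )
            prov = dict(f["provenance"].attrs)
            prov = {k: (v.item() if hasattr(v, "item") else v)
                    for k, v in prov.items()}
    except OSError as exc:
        raise ModelIOError(f"cannot read model container {path}: "
                           f"corrupt or not an HDF5 file ({exc})") from exc
    return ModelContainer(scheme, mesh, app, prov)
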