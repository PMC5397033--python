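"""End-to-end pipeline: simulate -> maps -> annotate -> build-model -> encode -> stats.

One hierarchical configuration document drives the whole run; every stage
logs its parameters and the SHA-256 digests of its outputs, and an identical
configuration plus seed reproduces identical digests.  The pipeline is the
programmatic core behind ``bodysam run``.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np

from . import annotation, shape_model as sm, texture_model as tm
from .annotation import default_mesh, reflect, subset_to_torso
from .appearance_model import build_appearance, encode_image
from .config import (Y_UPSCALE_FACTOR, config_hash, get_logger, substream_seed)
from .dxa_maps import decompose_tissue, upscale_y
from .model_io import ModelContainer
from .piecewise_warp import build_frame, warp_to_reference
from .stats_regression import auc, predict_prob, stepwise_logistic
from .synthetic_phantoms import (CohortSpec, POSE_JITTER_SD,
                                 sample_cohort)

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 17,
    "cohort": {
        "n": 60,
        "noise_sd": 0.003,
        "group_effects": {"sexlike": {"width": 2.5, "fat": -2.0}},
    },
    "scheme": "torso52",
    "channels": ["thickness", "leanness"],
    "reflect": True,
    "variance_threshold": 0.95,
    "frame": {"margin": 0.05, "output_scale": 0.5},
    "annotate": {"method": "truth"},
    "stats": {"outcomes": ["sexlike"], "p_enter": 0.05, "p_stay": 0.05},
}

_REQUIRED_KEYS = ("seed", "cohort", "channels", "scheme")
_CHANNELS = ("thickness", "leanness", "rvalue")


def validate_config(config: dict) -> dict:
    """Fill defaults and fail fast on missing or invalid required keys."""
    for key in _REQUIRED_KEYS:
        if key not in config:
            raise KeyError(f"config is missing required key {key!r}")
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    def deep_update(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                deep_update(dst[k], v)
            else:
                dst[k] = v
    deep_update(merged, config)
    if "n" not in config["cohort"]:
        raise KeyError("config is missing required key 'cohort.n'")
    for ch in merged["channels"]:
        if ch not in _CHANNELS:
            raise ValueError(f"unknown channel {ch!r}; choose from {_CHANNELS}")
    if merged["scheme"] not in ("body82", "torso52"):
        raise ValueError(f"unknown scheme {merged['scheme']!r}")
    return merged


def _digest(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(np.asarray(a))
        h.update(str(a.shape).encode())
        h.update(a.tobytes())
    return h.hexdigest()[:16]


def _subject_channels(phantom, wanted: list[str]) -> list[np.ndarray]:
    """Decompose one attenuation pair and upscale the requested maps.

    Pairs already on the square grid need no y-upscaling."""
    fat, lean, _ = decompose_tissue(phantom.pair)
    needs_upscale = phantom.pair.pixel_size[1] != phantom.pair.pixel_size[0]
    out = []
    for name in wanted:
        if name == "thickness":
            native = fat + lean
        elif name == "leanness":
            total = fat + lean
            native = np.where(total > 0, lean / np.where(total > 0, total, 1.0), 0.0)
        else:  # rvalue
            native = np.where(phantom.pair.body_mask,
                              np.where(phantom.pair.high > 0,
                                       phantom.pair.low
                                       / np.where(phantom.pair.high > 0,
                                                  phantom.pair.high, 1.0), 0.0),
                              0.0)
        out.append(upscale_y(native, Y_UPSCALE_FACTOR) if needs_upscale
                   else native)
    return out


def run_pipeline(config: dict) -> dict:
    """Execute the full pipeline; returns artifacts and per-stage digests."""
    cfg = validate_config(config)
    log = get_logger("pipeline")
    seed = int(cfg["seed"])
    chash = config_hash(cfg)
    log.info("start\tconfig_hash=%s\tseed=%d", chash, seed)
    digests: dict[str, str] = {}

    # --- simulate ---------------------------------------------------------
    cohort_cfg = cfg["cohort"]
    cohort = CohortSpec(n=int(cohort_cfg["n"]),
                        seed=substream_seed(seed, "cohort"),
                        noise_sd=float(cohort_cfg.get("noise_sd", 0.0)),
                        grid=cohort_cfg.get("grid", "native"),
                        pose_jitter_sd=cohort_cfg.get("pose_jitter_sd",
                                                      dict(POSE_JITTER_SD)),
                        group_effects=cohort_cfg.get("group_effects", {}))
    phantoms, labels = sample_cohort(cohort)
    digests["simulate"] = _digest(*[p.pair.low for p in phantoms])
    log.info("simulate\tn=%d\tdigest=%s", len(phantoms), digests["simulate"])

    # --- maps -------------------------------------------------------------
    channels = [_subject_channels(p, cfg["channels"]) for p in phantoms]
    digests["maps"] = _digest(*[c for chs in channels for c in chs])
    log.info("maps\tchannels=%s\tdigest=%s", ",".join(cfg["channels"]),
             digests["maps"])

    # --- annotate ---------------------------------------------------------
    method = cfg["annotate"]["method"]
    if method not in ("truth", "clm"):
        raise ValueError(f"unknown annotation method {method!r}")
    points82 = [p.points for p in phantoms]
    if method == "clm":
        aligned = sm.align_translation(points82)
        guide = sm.fit_shape_pca(aligned, 0.98)
        templates = annotation.make_patch_templates(channels[0][0], points82[0])
        points82 = [annotation.constrained_local_fit(chs[0], pts, guide,
                                                     templates)[0]
                    for chs, pts in zip(channels, points82)]
    digests["annotate"] = _digest(*[p.coords for p in points82])
    log.info("annotate\tmethod=%s\tdigest=%s", method, digests["annotate"])

    # --- build-model ------------------------------------------------------
    if cfg["scheme"] == "torso52":
        points = [subset_to_torso(p) for p in points82]
    else:
        points = points82
    mesh = default_mesh(cfg["scheme"])
    width = phantoms[0].pair.shape[1]
    images, pointsets = list(channels), list(points)
    if cfg["reflect"]:
        images += [[ch[:, ::-1] for ch in chs] for chs in channels]
        pointsets += [reflect(p, width) for p in points]
    aligned = sm.align_translation(pointsets)
    thr = float(cfg["variance_threshold"])
    shape_pca = sm.fit_shape_pca(aligned, thr)
    frame = build_frame(shape_pca.mean_pointset(), mesh,
                        margin=float(cfg["frame"]["margin"]),
                        output_scale=float(cfg["frame"]["output_scale"]))
    layout = tm.TextureLayout(tuple(cfg["channels"]))
    warped_all = [[warp_to_reference(ch, ps, frame) for ch in chs]
                  for chs, ps in zip(images, pointsets)]
    vectors = np.stack([tm.sample_texture(w, frame, layout) for w in warped_all])
    texture_pca = tm.fit_texture_pca(vectors, frame, layout, thr)
    b_s = np.stack([sm.params_from_shape(shape_pca, a) for a in aligned])
    b_g = np.stack([tm.params_from_texture(texture_pca, v) for v in vectors])
    appearance = build_appearance(shape_pca, texture_pca, b_s, b_g, thr)
    container = ModelContainer(
        scheme=annotation.get_scheme(cfg["scheme"]), mesh=mesh,
        appearance=appearance,
        provenance={"config_hash": chash, "seed": seed,
                    "n_training": len(pointsets)})
    digests["model"] = _digest(shape_pca.mean_shape, shape_pca.modes,
                               texture_pca.mean_texture, texture_pca.modes,
                               appearance.modes)
    log.info("build-model\tmodes=%d/%d/%d\tsamples=%d\tdigest=%s",
             shape_pca.n_modes, texture_pca.n_modes, appearance.n_modes,
             len(pointsets), digests["model"])

    # --- encode -----------------------------------------------------------
    n = len(phantoms)
    scores = np.stack([encode_image(appearance, warped_all[i], pointsets[i])
                       for i in range(n)])
    digests["encode"] = _digest(scores)
    log.info("encode\tn=%d\tk=%d\tdigest=%s", n, scores.shape[1],
             digests["encode"])

    # --- stats ------------------------------------------------------------
    stats_out = {}
    for outcome in cfg["stats"]["outcomes"]:
        y = labels[outcome].to_numpy()
        # stratified alternating split: both halves carry both classes
        order = np.argsort(y, kind="stable")
        train, valid = order[0::2], order[1::2]
        if len(np.unique(y[train])) < 2 or len(np.unique(y[valid])) < 2:
            raise ValueError(f"outcome {outcome!r}: a split lacks both classes")
        model = stepwise_logistic(scores[train], y[train],
                                  p_enter=float(cfg["stats"]["p_enter"]),
                                  p_stay=float(cfg["stats"]["p_stay"]),
                                  outcome=outcome)
        train_auc = auc(predict_prob(model, scores[train]), y[train]) \
            if model.coefficients else 0.5
        valid_auc = auc(predict_prob(model, scores[valid]), y[valid]) \
            if model.coefficients else 0.5
        stats_out[outcome] = {
            "equation": model.equation(),
            "intercept": model.intercept,
            "coefficients": {str(k): v for k, v in model.coefficients.items()},
            "train_auc": train_auc,
            "validation_auc": valid_auc,
        }
        log.info("stats\toutcome=%s\tmodes=%s\ttrain_auc=%.3f\tvalid_auc=%.3f",
                 outcome, sorted(model.coefficients), train_auc, valid_auc)
    digests["stats"] = hashlib.sha256(
        json.dumps(stats_out, sort_keys=True).encode()).hexdigest()[:16]
    log.info("done\tdigest=%s", digests["stats"])

    return {"config": cfg, "config_hash": chash, "labels": labels,
            "phantoms": phantoms, "channels": channels, "model": container,
            "scores": scores, "stats": stats_out, "digests": digests,
            "frame": frame}
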