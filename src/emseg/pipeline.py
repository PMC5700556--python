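"""End-to-end brain tissue segmentation.

The pipeline chains: anisotropic-diffusion denoising -> skull stripping ->
brain-only intensity histogram -> EMO search for the m thresholds that
maximise the Otsu (or Kapur) criterion -> pixel labelling -> tissue
assignment.  With m = 2 the three intensity classes are ranked by mean
intensity and mapped, ascending, to CSF / GM / WM (T1 contrast).

The histogram deliberately excludes off-mask pixels: after stripping, the
background zeros would otherwise dominate the between-class variance and
waste a threshold separating background from head.  All randomness flows
from a single seed recorded in the result's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .emo import EMOParams, emo_optimize
from .labels import BG, CSF, GM, WM
from .objectives import (NormalizedHistogram, compute_histogram,
                         kapur_objective, otsu_objective)
from .preprocess import BrainMask, DiffusionParams, anisotropic_diffuse, strip_skull

__all__ = ["SegmentationConfig", "SegmentationResult", "classify_pixels",
           "map_classes_to_tissues", "segment_image", "make_threshold_objective"]


@dataclass
class SegmentationConfig:
    """Everything a segmentation run needs, with field-standard defaults."""

    objective: str = "otsu"          # or "kapur"
    m: int = 2                       # thresholds -> m + 1 classes
    L: int = 256
    seed: int = 0
    skip_strip: bool = False
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    r_open: int = 2
    r_erode: int = 6
    r_dilate: int = 8
    emo_n_pop: int = 30
    emo_k_max: int = 100
    emo_k_local: int = 10
    emo_lambda_local: float = 0.25
    emo_perturb: bool = False


@dataclass
class SegmentationResult:
    thresholds: np.ndarray           # sorted integer cut-points, length m
    label_map: np.ndarray            # class index per pixel, -1 off-mask
    tissue_map: Optional[np.ndarray]  # BG/CSF/GM/WM codes (m = 2 only)
    objective_value: float
    mask: BrainMask
    params_used: dict


def make_threshold_objective(hist: NormalizedHistogram, objective: str = "otsu"):
    """Objective over integer threshold vectors for the EMO search.

    Returns a closure equivalent to ``otsu_objective(hist, th)`` /
    ``kapur_objective(hist, th)`` but built on per-histogram prefix sums,
    since the optimizer evaluates it tens of thousands of times per run.
    """
    p = hist.probs
    L = hist.L
    cp = np.concatenate(([0.0], np.cumsum(p))).tolist()

    if objective == "otsu":
        cip = np.concatenate(
            ([0.0], np.cumsum(np.arange(L) * p))).tolist()
        mu_T = cip[-1]

        def fn(th):
            edges = [0, *map(int, th), L]
            s = 0.0
            for a, b in zip(edges[:-1], edges[1:]):
                w = cp[b] - cp[a]
                if w > 0.0:
                    d = (cip[b] - cip[a]) / w - mu_T
                    s += w * d * d
            return s

        return fn

    if objective == "kapur":
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        cplp = np.concatenate(([0.0], np.cumsum(plogp))).tolist()

        def fn(th):
            edges = [0, *map(int, th), L]
            s = 0.0
            for a, b in zip(edges[:-1], edges[1:]):
                w = cp[b] - cp[a]
                if w > 0.0:
                    # class entropy: ln w - (1/w) sum p ln p
                    s += np.log(w) - (cplp[b] - cplp[a]) / w
            return float(s)

        return fn

    raise ValueError(f"unknown objective {objective!r}; use 'otsu' or 'kapur'")


def classify_pixels(image, mask, TH) -> np.ndarray:
    """Assign each in-mask pixel its intensity-bin index.

    Bins are half-open: a pixel exactly at a threshold joins the class
    above it.  Off-mask pixels get -1.
    """
    img = np.asarray(image)
    th = np.asarray(TH).ravel()
    labels = np.digitize(img, th).astype(np.int64)
    if mask is not None:
        labels[~np.asarray(mask, dtype=bool)] = -1
    return labels


def map_classes_to_tissues(label_map, image) -> np.ndarray:
    """Rank the three intensity classes by mean and name them CSF/GM/WM.

    On T1 contrast CSF is darkest and WM brightest, so the ascending rank
    of in-mask class mean intensities fixes the tissue identity regardless
    of label order.  Requires exactly 3 populated in-mask classes (m = 2).
    """
    lab = np.asarray(label_map)
    img = np.asarray(image, dtype=float)
    classes = np.unique(lab[lab >= 0])
    if classes.size != 3:
        raise ValueError(
            f"expected 3 in-mask classes (m=2), found {classes.size}")
    means = np.array([img[lab == c].mean() for c in classes])
    if np.unique(means).size != means.size:
        raise ValueError("class mean intensities are tied; cannot rank tissues")
    order = classes[np.argsort(means)]
    tissue = np.full(lab.shape, BG, dtype=np.int64)
    for cls, code in zip(order, (CSF, GM, WM)):
        tissue[lab == cls] = code
    return tissue


def segment_image(image, config: SegmentationConfig = None) -> SegmentationResult:
    """Run the full pipeline on a 2-D grayscale slice.

    Deterministic for a fixed config seed.  The returned objective value is
    the criterion recomputed at the chosen thresholds on the same masked
    histogram.
    """
    cfg = config or SegmentationConfig()
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")

    smoothed = anisotropic_diffuse(img, cfg.diffusion)
    quantized = np.clip(np.rint(smoothed), 0, cfg.L - 1).astype(np.int64)

    if cfg.skip_strip:
        mask = BrainMask(mask=np.ones(img.shape, dtype=bool),
                         provenance={"skipped": True})
    else:
        _, mask = strip_skull(smoothed, r_open=cfg.r_open,
                              r_erode=cfg.r_erode, r_dilate=cfg.r_dilate)

    hist = compute_histogram(quantized, mask.mask, L=cfg.L)
    objective = make_threshold_objective(hist, cfg.objective)
    params = EMOParams(
        bounds=np.tile([1.0, float(cfg.L - 1)], (cfg.m, 1)),
        n_pop=cfg.emo_n_pop, k_max=cfg.emo_k_max, k_local=cfg.emo_k_local,
        lambda_local=cfg.emo_lambda_local, integer=True,
        perturb=cfg.emo_perturb, seed=cfg.seed)
    result = emo_optimize(objective, params)
    thresholds = np.asarray(result.best_point, dtype=np.int64)

    label_map = classify_pixels(quantized, mask.mask, thresholds)
    tissue_map = (map_classes_to_tissues(label_map, quantized)
                  if cfg.m == 2 else None)

    params_used = {"config": _config_record(cfg),
                   "strip": mask.provenance,
                   "emo_trace_final": float(result.trace_scores[-1])}
    return SegmentationResult(
        thresholds=thresholds, label_map=label_map, tissue_map=tissue_map,
        objective_value=float(objective(thresholds)), mask=mask,
        params_used=params_used)


def _config_record(cfg: SegmentationConfig) -> dict:
    rec = asdict(cfg)
    rec["diffusion"] = asdict(cfg.diffusion)
    return rec
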