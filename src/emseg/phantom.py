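"""Synthetic T1-weighted head-slice phantom with pixel-wise ground truth.

The phantom emulates the structures a thresholding pipeline must cope with
on an axial T1 slice: a dark background, a bright elliptical skull ring, a
thin dark gap between skull and brain, and a brain made of a white-matter
core, a gray-matter cortical band, paired ventricles and randomized CSF
pockets.  On T1 contrast the tissue means are ordered CSF < GM < WM, with
the skull brighter still.  Intensities are the tissue means, optionally
modulated by a smooth multiplicative bias field, plus additive Gaussian
(optionally Rician) noise, clipped to [0, 255] and quantized.  Ground-truth
labels are the pre-noise assignments, so every stage of the segmentation
pipeline can be scored pixel-wise without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Tuple

import numpy as np

from .labels import BG, SKULL, CSF, GM, WM

__all__ = ["PhantomSpec", "generate_phantom"]

_FULL_SCALE = 255.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise of the synthetic head slice.

    Intensity means are on the 0-255 scale and must satisfy
    background < CSF < GM < WM.  ``noise_sigma`` is the additive Gaussian
    noise SD as a fraction of full scale (0.03 = 3%).  ``bias_amplitude``
    scales a smooth low-order polynomial multiplicative field (0 disables
    it).  Ring/band thicknesses are in pixels.
    """

    size: Tuple[int, int] = (256, 256)
    csf_mean: float = 50.0
    gm_mean: float = 110.0
    wm_mean: float = 200.0
    skull_mean: float = 230.0
    background_mean: float = 5.0
    noise_sigma: float = 0.03
    rician: bool = False
    bias_amplitude: float = 0.0
    include_skull: bool = True
    skull_thickness: int = 5
    gap_thickness: int = 4
    gm_thickness: int = 10
    n_csf_pockets: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.background_mean < self.csf_mean < self.gm_mean
                < self.wm_mean):
            raise ValueError("tissue means must satisfy BG < CSF < GM < WM")
        for v in (self.csf_mean, self.gm_mean, self.wm_mean, self.skull_mean,
                  self.background_mean):
            if not (0 <= v <= 255):
                raise ValueError("intensity means must lie in [0, 255]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if min(self.size) < 64:
            raise ValueError("phantom must be at least 64x64")

    def to_dict(self) -> dict:
        return asdict(self)


def _ellipse(shape, center, ry, rx) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - center[0]) / ry) ** 2 + ((xx - center[1]) / rx) ** 2 <= 1.0


def _bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    if amplitude == 0.0:
        return np.ones(shape)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    u = 2.0 * xx / (shape[1] - 1) - 1.0
    v = 2.0 * yy / (shape[0] - 1) - 1.0
    coef = rng.uniform(-1.0, 1.0, size=5)
    poly = coef[0] * u + coef[1] * v + coef[2] * u * v \
        + coef[3] * u**2 + coef[4] * v**2
    poly /= max(np.abs(poly).max(), 1e-12)
    return 1.0 + amplitude * poly


def generate_phantom(spec: PhantomSpec = PhantomSpec()):
    """Render the phantom.

    Returns
    -------
    image : ndarray of uint8
        The noisy T1-like slice.
    truth : ndarray of int
        Per-pixel labels BG/SKULL/CSF/GM/WM (pre-noise assignments).
    brain_mask : ndarray of bool
        CSF ∪ GM ∪ WM.
    """
    h, w = spec.size
    cy, cx = h / 2.0, w / 2.0
    outer_ry, outer_rx = 0.42 * h, 0.36 * w

    inner_ry = outer_ry - spec.skull_thickness
    inner_rx = outer_rx - spec.skull_thickness
    brain_ry = inner_ry - spec.gap_thickness
    brain_rx = inner_rx - spec.gap_thickness
    core_ry = brain_ry - spec.gm_thickness
    core_rx = brain_rx - spec.gm_thickness
    if min(brain_ry, brain_rx, core_ry, core_rx) <= 4:
        raise ValueError("degenerate geometry: ring thicker than radius")

    rng = np.random.default_rng(spec.seed)
    truth = np.full(spec.size, BG, dtype=np.int64)

    if spec.include_skull:
        outer = _ellipse(spec.size, (cy, cx), outer_ry, outer_rx)
        inner = _ellipse(spec.size, (cy, cx), inner_ry, inner_rx)
        truth[outer & ~inner] = SKULL

    brain = _ellipse(spec.size, (cy, cx), brain_ry, brain_rx)
    core = _ellipse(spec.size, (cy, cx), core_ry, core_rx)
    truth[brain & ~core] = GM
    truth[core] = WM

    # paired lateral ventricles (CSF), mirrored about the midline
    vent_ry, vent_rx = 0.10 * h, 0.035 * w
    for dx in (-0.07 * w, 0.07 * w):
        vent = _ellipse(spec.size, (cy - 0.02 * h, cx + dx), vent_ry, vent_rx)
        truth[vent & core] = CSF

    # randomized CSF pockets inside the WM core
    for _ in range(spec.n_csf_pockets):
        py = cy + rng.uniform(-0.55, 0.55) * core_ry
        px = cx + rng.uniform(-0.55, 0.55) * core_rx
        pr = rng.uniform(3.0, 7.0)
        pocket = _ellipse(spec.size, (py, px), pr, pr)
        truth[pocket & core] = CSF

    means = np.zeros(5)
    means[BG] = spec.background_mean
    means[SKULL] = spec.skull_mean
    means[CSF] = spec.csf_mean
    means[GM] = spec.gm_mean
    means[WM] = spec.wm_mean
    clean = means[truth] * _bias_field(spec.size, spec.bias_amplitude, rng)

    sigma = spec.noise_sigma * _FULL_SCALE
    if sigma > 0:
        if spec.rician:
            n1 = rng.normal(0.0, sigma, spec.size)
            n2 = rng.normal(0.0, sigma, spec.size)
            noisy = np.hypot(clean + n1, n2)
        else:
            noisy = clean + rng.normal(0.0, sigma, spec.size)
    else:
        noisy = clean

    image = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    brain_mask = (truth == CSF) | (truth == GM) | (truth == WM)
    return image, truth, brain_mask
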