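"""Synthetic data with exact ground truth.

Two families of generators make the whole package testable without any
external data:

* :func:`generate_pad` renders a scanned-pad look-alike — a rounded
  rectangle of pink/blue indicator pixels on a near-white scanner bed —
  with a per-pixel label map and an exactly known pink fraction.
* :func:`generate_cohort` simulates subject cohorts in which a single
  latent neuropathy-severity factor drives all measures, giving
  controllable separability between the disease and control groups.
* :func:`generate_paired_scores` draws paired diagnostic scores with
  prescribed binormal AUCs and within-class correlation, the standard
  fixture for correlated-ROC methods.

All generators are pure functions of their configuration, including the
seed: the same config yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from scipy.special import ndtri
from skimage.color import hsv2rgb

from .errors import ConfigError
from .pad_quant import MM_PER_INCH, PadMask, PadScan

LABEL_BACKGROUND = 0
LABEL_BLUE = 1
LABEL_PINK = 2

PATTERNS = ("uniform-mix", "reaction-front", "patchy-blobs")


@dataclass(frozen=True)
class PadSceneConfig:
    """Geometry, colouring and degradation model for one synthetic scan.

    Lengths are millimetres; the defaults mimic a ~1 cm square indicator
    pad scanned at 600 dpi.  ``noise_sigma`` is the per-channel Gaussian
    sensor noise on the [0, 1] intensity scale; ``salt_density`` the
    probability of a saturated white pixel; ``illumination_amplitude`` the
    relative amplitude of a linear left-right illumination ramp.
    """

    pad_width_mm: float = 12.0
    pad_height_mm: float = 12.0
    corner_radius_mm: float = 2.0
    margin_mm: float = 3.0
    true_pink_fraction: float = 0.5
    pattern: str = "uniform-mix"
    noise_sigma: float = 8.0 / 255.0
    salt_density: float = 1e-3
    illumination_amplitude: float = 0.10
    dpi: float = 600.0
    seed: int = 0
    # reference indicator colours (hue degrees / saturation / value)
    pink_hue_deg: float = 330.0
    blue_hue_deg: float = 225.0
    hue_sd_deg: float = 6.0
    sat_mean: float = 0.5
    sat_sd: float = 0.08
    value_mean: float = 0.85
    value_sd: float = 0.04
    background_value: float = 0.96

    def noise_free(self) -> "PadSceneConfig":
        """Copy with all degradation switched off."""
        return replace(
            self, noise_sigma=0.0, salt_density=0.0, illumination_amplitude=0.0
        )


@dataclass(frozen=True)
class LabelledPad:
    """A rendered scan plus its exact ground truth."""

    scan: PadScan
    truth_mask: PadMask
    pixel_labels: np.ndarray  # uint8, LABEL_* constants
    true_pink_fraction_realized: float


def _rounded_rect_mask(cfg: PadSceneConfig) -> np.ndarray:
    px_per_mm = cfg.dpi / MM_PER_INCH
    w = int(round(cfg.pad_width_mm * px_per_mm))
    h = int(round(cfg.pad_height_mm * px_per_mm))
    m = int(round(cfg.margin_mm * px_per_mm))
    r = cfg.corner_radius_mm * px_per_mm
    H, W = h + 2 * m, w + 2 * m
    yy, xx = np.mgrid[0:H, 0:W]
    # distance from the pixel centre to the shrunken (by r) pad rectangle
    cx0, cx1 = m + r, m + w - 1 - r
    cy0, cy1 = m + r, m + h - 1 - r
    dx = np.maximum(np.maximum(cx0 - xx, xx - cx1), 0.0)
    dy = np.maximum(np.maximum(cy0 - yy, yy - cy1), 0.0)
    return dx**2 + dy**2 <= r**2


def _assign_pink(cfg: PadSceneConfig, pad: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Choose exactly round(fraction * area) pad pixels to be pink."""
    idx = np.flatnonzero(pad.ravel())
    area = idx.size
    k = int(round(cfg.true_pink_fraction * area))
    pink_flat = np.zeros(pad.size, dtype=bool)
    if k == 0:
        return pink_flat.reshape(pad.shape)
    if cfg.pattern == "uniform-mix":
        chosen = rng.permutation(idx)[:k]
    elif cfg.pattern == "reaction-front":
        # pink advances inward from the pad edge
        dist = ndimage.distance_transform_edt(pad).ravel()[idx]
        keys = dist + rng.uniform(0.0, 1e-6, size=area)
        chosen = idx[np.argsort(keys)[:k]]
    elif cfg.pattern == "patchy-blobs":
        field_img = rng.standard_normal(pad.shape)
        sigma_px = 0.8 * cfg.dpi / MM_PER_INCH
        smooth = ndimage.gaussian_filter(field_img, sigma=sigma_px).ravel()[idx]
        chosen = idx[np.argsort(-smooth)[:k]]
    else:
        raise ConfigError(f"unknown pattern {cfg.pattern!r}; valid: {PATTERNS}")
    pink_flat[chosen] = True
    return pink_flat.reshape(pad.shape)


def generate_pad(cfg: PadSceneConfig | None = None) -> LabelledPad:
    """Render a synthetic scanned pad with exact per-pixel ground truth.

    The realized pink fraction equals the requested one to within half a
    pixel's worth of mass (the count is rounded to the nearest pixel).
    Degradations are applied in scan order: illumination ramp, Gaussian
    sensor noise, salt pixels, then 8-bit quantization — so the returned
    scan is exactly what would be read back from the written PNG.
    """
    cfg = cfg or PadSceneConfig()
    if not (0.0 <= cfg.true_pink_fraction <= 1.0):
        raise ConfigError(
            f"true_pink_fraction must be in [0, 1], got {cfg.true_pink_fraction}"
        )
    if cfg.dpi <= 0:
        raise ConfigError("dpi must be > 0")
    if min(cfg.noise_sigma, cfg.salt_density) < 0 or cfg.illumination_amplitude < 0:
        raise ConfigError("noise amplitudes must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    pad = _rounded_rect_mask(cfg)
    pink = _assign_pink(cfg, pad, rng)
    blue = pad & ~pink

    H, W = pad.shape
    hsv = np.empty((H, W, 3))
    hsv[..., 0] = 0.1  # background hue is irrelevant at near-zero saturation
    hsv[..., 1] = 0.02
    hsv[..., 2] = cfg.background_value
    for sel, centre in ((pink, cfg.pink_hue_deg), (blue, cfg.blue_hue_deg)):
        n = int(sel.sum())
        if n == 0:
            continue
        hue = (centre + rng.normal(0.0, cfg.hue_sd_deg, n)) % 360.0
        # saturation/value kept well clear of the whitish-pixel regime so
        # that, absent noise, every generated pixel is unambiguous
        hsv[..., 0][sel] = hue / 360.0
        hsv[..., 1][sel] = np.clip(rng.normal(cfg.sat_mean, cfg.sat_sd, n), 0.2, 0.9)
        hsv[..., 2][sel] = np.clip(rng.normal(cfg.value_mean, cfg.value_sd, n), 0.5, 0.99)
    rgb = hsv2rgb(hsv)

    if cfg.illumination_amplitude > 0:
        ramp = 1.0 + cfg.illumination_amplitude * (2.0 * np.arange(W) / max(W - 1, 1) - 1.0)
        rgb = rgb * ramp[None, :, None]
    if cfg.noise_sigma > 0:
        rgb = rgb + rng.normal(0.0, cfg.noise_sigma, rgb.shape)
    if cfg.salt_density > 0:
        salt = rng.random((H, W)) < cfg.salt_density
        rgb[salt] = 1.0
    rgb8 = np.round(np.clip(rgb, 0.0, 1.0) * 255.0).astype(np.uint8)

    labels = np.zeros((H, W), dtype=np.uint8)
    labels[blue] = LABEL_BLUE
    labels[pink] = LABEL_PINK
    area = int(pad.sum())
    scan = PadScan(
        pixels=rgb8.astype(np.float64) / 255.0,
        dpi=cfg.dpi,
        source_id=f"synthetic-pad-seed{cfg.seed}",
    )
    truth = PadMask(membership=pad, threshold_used=float("nan"), n_components_before_cleanup=1)
    return LabelledPad(
        scan=scan,
        truth_mask=truth,
        pixel_labels=labels,
        true_pink_fraction_realized=float(pink.sum()) / area,
    )


def write_pad_png(pad: LabelledPad, path: str | Path) -> None:
    """Write the rendered scan as an 8-bit PNG carrying its dpi metadata."""
    arr = np.round(pad.scan.pixels * 255.0).astype(np.uint8)
    Image.fromarray(arr).save(Path(path), dpi=(pad.scan.dpi, pad.scan.dpi))


# ---------------------------------------------------------------------------
# cohort simulation


#: (control median, disease median, direction) anchors for each measure; the
#: medians place simulated values in clinically plausible ranges and set the
#: sign of the disease effect.  Scenery only — no distributional fidelity to
#: any real cohort is claimed.
MEASURE_ANCHORS: dict[str, tuple[float, float]] = {
    "NDS": (0.5, 5.5),
    "VPT": (6.3, 21.8),
    "SNAP": (13.0, 4.9),
    "SNCV": (43.8, 39.5),
    "PMNAP": (4.6, 1.8),
    "PMNCV": (44.1, 39.3),
    "IENFD": (6.8, 3.5),
    "CNFD": (30.0, 21.4),
    "CNBD": (90.1, 62.5),
    "CNFL": (25.0, 19.6),
    "DB_HRV": (25.0, 10.0),
    "WPT": (38.5, 42.0),
    "neuropad_percent": (61.5, 18.0),
}


@dataclass(frozen=True)
class CohortSimConfig:
    """Latent-factor cohort model.

    Each subject carries a latent severity ``z`` (standard normal within
    group; the disease group's mean is shifted up by ``latent_effect``).
    Every measure is an affine transform of ``loading * z + noise`` with
    the sign implied by its anchors, so measures are mutually correlated
    through the latent factor alone.  ``latent_severity`` itself is
    emitted as a unit-variance score whose group separation equals
    ``latent_effect`` exactly.
    """

    n_per_group: tuple[int, int] = (64, 46)  # (control, disease)
    latent_effect: float = 1.5
    loading: float = 0.8
    noise_sd: float = 0.6
    loadings: dict[str, float] = field(default_factory=dict)  # per-measure override
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 2:
            raise ConfigError("n_per_group must be >= 2 in both groups")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")


def generate_cohort(cfg: CohortSimConfig | None = None) -> pd.DataFrame:
    """Simulate a cohort as a DataFrame, one row per subject.

    Columns: ``subject_id``, ``group`` ('no-DPN' / 'DPN'), ``dpn`` (0/1),
    ``latent_severity``, every measure in :data:`MEASURE_ANCHORS` and
    ``neuropad_percent`` (clamped to [0, 100]; the clamp leaves mass at
    the floor/ceiling, mimicking the bounded read-out of a real pad).
    NDS is rounded to an integer in [0, 10].
    """
    cfg = cfg or CohortSimConfig()
    rng = np.random.default_rng(cfg.seed)
    n_ctrl, n_dis = cfg.n_per_group
    n = n_ctrl + n_dis
    dpn = np.concatenate([np.zeros(n_ctrl, dtype=int), np.ones(n_dis, dtype=int)])
    z = rng.standard_normal(n) + cfg.latent_effect * dpn
    data: dict[str, np.ndarray] = {
        "subject_id": np.array([f"S{i + 1:04d}" for i in range(n)]),
        "group": np.where(dpn == 1, "DPN", "no-DPN"),
        "dpn": dpn,
        "latent_severity": z,
    }
    d = cfg.latent_effect if cfg.latent_effect != 0 else 1.0
    for name, (m0, m1) in MEASURE_ANCHORS.items():
        lam = cfg.loadings.get(name, cfg.loading)
        score = lam * z + rng.normal(0.0, cfg.noise_sd, n)
        values = m0 + (m1 - m0) * score / (lam * d)
        values = np.maximum(values, 0.0)
        if name == "NDS":
            values = np.clip(np.round(values), 0, 10)
        if name == "neuropad_percent":
            values = np.clip(values, 0.0, 100.0)
        data[name] = values
    return pd.DataFrame(data)


def generate_paired_scores(
    n_pos: int,
    n_neg: int,
    auc1: float,
    auc2: float,
    rho: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw paired diagnostic scores with prescribed binormal AUCs.

    Within each class the two scores are bivariate normal with unit
    variances and correlation ``rho``; the positive-class means are
    ``sqrt(2) * Phi^{-1}(auc)`` so each score's population AUC (higher
    score = disease) equals its target.  Returns
    ``(scores1, scores2, labels)`` with labels 1 for the positive class.
    """
    for a in (auc1, auc2):
        if not (0.0 < a < 1.0):
            raise ConfigError(f"AUC {a} infeasible; must lie strictly in (0, 1)")
    if not abs(rho) < 1.0:
        raise ConfigError(f"|rho| must be < 1, got {rho}")
    if min(n_pos, n_neg) < 1:
        raise ConfigError("need at least one subject per class")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    neg = rng.standard_normal((n_neg, 2)) @ chol.T
    pos = rng.standard_normal((n_pos, 2)) @ chol.T
    pos += np.sqrt(2.0) * np.array([ndtri(auc1), ndtri(auc2)])
    scores = np.vstack([neg, pos])
    labels = np.concatenate([np.zeros(n_neg, dtype=int), np.ones(n_pos, dtype=int)])
    return scores[:, 0], scores[:, 1], labels
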