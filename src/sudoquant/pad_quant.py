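"""Automated quantification of scanned sweat-indicator pads.

The indicator pad contains a cobalt(II) salt that turns from blue to pink on
contact with sweat.  A flatbed scan of the removed pad is reduced to a single
continuous number — the percentage of the pad area that has turned pink —
through a fixed, deterministic pipeline:

1.  :func:`load_scan` — decode the image, normalize intensities to [0, 1].
2.  :func:`segment_pad` — separate pad from scanner background with a
    per-image (Otsu) threshold; no fixed global constant is used.
3.  :func:`refine_mask` — morphological opening/closing with a physical-unit
    structuring element, largest-component retention and hole filling.
4.  :func:`colour_histogram` — per-pixel hue/saturation classification of
    masked pixels into pink, blue or other, plus a hue histogram.
5.  :func:`pink_percentage` / :func:`categorize` — the continuous output and
    its mapping onto the three-level visual read-out.

:func:`quantify` composes the stages.  There is no randomness anywhere in
this module: identical input bytes give bit-identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from skimage.color import rgb2gray, rgb2hsv
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing as morph_closing
from skimage.morphology import disk
from skimage.morphology import opening as morph_opening

from .config import (
    CategoryConfig,
    ColourConfig,
    MorphologyConfig,
    RunConfig,
    SegmentationConfig,
)
from .errors import (
    EmptyRegionError,
    ConfigError,
    InputError,
    SegmentationFailure,
    UnsupportedImageError,
)

logger = logging.getLogger(__name__)

MM_PER_INCH = 25.4

CATEGORIES = ("normal", "intermediate", "abnormal")


@dataclass(frozen=True)
class PadScan:
    """An RGB raster of a scanned indicator pad.

    ``pixels`` is H x W x 3 float64 in [0, 1]; ``dpi`` is the scan
    resolution in dots per inch; ``source_id`` is a free-text provenance
    label (usually the file name).
    """

    pixels: np.ndarray
    dpi: float = 600.0
    source_id: str = ""

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3:
            raise UnsupportedImageError(
                f"scan must be H x W x 3, got shape {px.shape}"
            )
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise InputError(f"scan too small: {px.shape[0]} x {px.shape[1]} < 16 x 16")
        if px.dtype != np.float64:
            raise InputError("scan pixels must be float64 in [0, 1]")
        if float(px.min()) < 0.0 or float(px.max()) > 1.0:
            raise InputError("scan intensities outside declared range [0, 1]")
        if not self.dpi > 0:
            raise InputError(f"dpi must be > 0, got {self.dpi}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class PadMask:
    """Boolean pad-membership map with segmentation diagnostics."""

    membership: np.ndarray
    threshold_used: float
    n_components_before_cleanup: int

    def __post_init__(self) -> None:
        if self.membership.ndim != 2 or self.membership.dtype != bool:
            raise InputError("mask membership must be a 2-D boolean array")

    @property
    def area_px(self) -> int:
        return int(self.membership.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.membership.shape


@dataclass(frozen=True)
class ColourHistogram:
    """Hue histogram and pink/blue/other classification over masked pixels.

    Invariants: ``sum(counts) == area_px`` and
    ``n_pink + n_blue + n_other == area_px``.
    """

    bin_edges: np.ndarray  # degrees, len n_bins + 1, covering [0, 360]
    counts: np.ndarray
    n_pink: int
    n_blue: int
    n_other: int

    @property
    def area_px(self) -> int:
        return self.n_pink + self.n_blue + self.n_other

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.area_px:
            raise InputError("histogram counts do not sum to the masked area")
        if min(self.n_pink, self.n_blue, self.n_other) < 0:
            raise InputError("negative class count")


@dataclass(frozen=True)
class QuantResult:
    """Final per-image result: continuous percentage plus diagnostics."""

    source_id: str
    pink_percent: float
    category: str
    pad_area_mm2: float
    mask: PadMask
    histogram: ColourHistogram

    def to_row(self) -> dict[str, object]:
        """One CSV row: the stable tabular serialization of a result."""
        return {
            "source_id": self.source_id,
            "pink_percent": self.pink_percent,
            "category": self.category,
            "pad_area_mm2": self.pad_area_mm2,
            "threshold_used": self.mask.threshold_used,
            "area_px": self.mask.area_px,
        }


def _normalize_array(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:  # unusual float encoding on a 0-255 scale
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def load_scan(
    path: str | Path, declared_dpi: float | None = None
) -> PadScan:
    """Decode an image file into a :class:`PadScan`.

    RGBA input is accepted (alpha discarded); greyscale and paletted
    single-channel images are rejected.  The dpi is taken from
    ``declared_dpi`` if given, else from file metadata, else defaults to
    600 (the standard protocol resolution) with a logged warning.
    """
    path = Path(path)
    try:
        with Image.open(path) as img:
            img.load()
            meta_dpi = img.info.get("dpi")
            arr = np.asarray(img)
    except (UnidentifiedImageError, OSError) as exc:
        raise InputError(f"cannot decode image file {path}: {exc}") from exc
    if arr.ndim == 2:
        raise UnsupportedImageError(
            f"{path}: single-channel greyscale images are not supported; "
            "the pipeline needs colour information"
        )
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise UnsupportedImageError(
            f"{path}: expected 3 or 4 channels, got {arr.shape[2]}"
        )
    if declared_dpi is not None:
        dpi = float(declared_dpi)
    elif meta_dpi:
        dpi = float(meta_dpi[0])
    else:
        logger.warning("%s: no dpi metadata; assuming protocol default 600", path)
        dpi = 600.0
    if dpi <= 0:
        raise InputError(f"{path}: non-positive dpi {dpi}")
    return PadScan(pixels=_normalize_array(arr), dpi=dpi, source_id=path.name)


def _scalar_channel(scan: PadScan, channel: str) -> tuple[np.ndarray, bool]:
    """Return (channel image, foreground_is_high)."""
    if channel == "saturation":
        return rgb2hsv(scan.pixels)[:, :, 1], True
    if channel == "luminance":
        return rgb2gray(scan.pixels), False
    raise ConfigError(f"unknown segmentation channel {channel!r}")


def segment_pad(scan: PadScan, cfg: SegmentationConfig | None = None) -> PadMask:
    """Segment the pad from the scanner background.

    The threshold is recomputed for every image (Otsu's method on the
    configured scalar channel), so it adapts to per-scan illumination and
    exposure.  A two-sided sanity check guards against degenerate images:
    the foreground must occupy at least ``foreground_floor`` of the frame
    and the foreground/background channel means must differ by at least
    ``min_contrast``.
    """
    cfg = cfg or SegmentationConfig()
    channel, fg_high = _scalar_channel(scan, cfg.channel)
    try:
        thr = float(threshold_otsu(channel))
    except ValueError as exc:  # constant image
        raise SegmentationFailure(
            f"{scan.source_id}: channel is constant, no threshold exists"
        ) from exc
    fg = channel > thr if fg_high else channel < thr
    frac = fg.mean()
    if frac < cfg.foreground_floor:
        raise SegmentationFailure(
            f"{scan.source_id}: foreground fraction {frac:.4f} below floor "
            f"{cfg.foreground_floor} at threshold {thr:.4f}"
        )
    contrast = abs(float(channel[fg].mean()) - float(channel[~fg].mean()))
    if contrast < cfg.min_contrast:
        raise SegmentationFailure(
            f"{scan.source_id}: foreground/background contrast {contrast:.4f} "
            f"below {cfg.min_contrast} at threshold {thr:.4f}; image looks "
            "uniform (no pad found)"
        )
    n_comp = int(cc_label(fg, connectivity=2).max())
    return PadMask(membership=fg, threshold_used=thr, n_components_before_cleanup=n_comp)


def refine_mask(
    mask: PadMask, scan: PadScan, cfg: MorphologyConfig | None = None
) -> PadMask:
    """Morphological cleanup: remove background noise, solidify the pad.

    Binary opening then closing with a disc whose radius is given in
    millimetres and converted to pixels via the scan dpi, followed by
    largest-connected-component retention and interior hole filling.
    Interior holes are filled *before* the opening as well: otherwise a
    single dropped pixel inside the pad (a salt speck) would be eroded
    into a crater of the structuring-element radius.  The result always
    has exactly one connected component and no holes.
    """
    cfg = cfg or MorphologyConfig()
    if mask.shape != scan.shape:
        raise InputError(
            f"mask shape {mask.shape} does not match scan shape {scan.shape}"
        )
    radius_px = max(1, int(round(cfg.radius_mm * scan.dpi / MM_PER_INCH)))
    selem = disk(radius_px)
    solid_in = ndimage.binary_fill_holes(mask.membership)
    opened = morph_opening(solid_in, selem)
    if not opened.any():
        raise SegmentationFailure(
            f"{scan.source_id}: mask empty after opening with radius "
            f"{cfg.radius_mm} mm ({radius_px} px)"
        )
    closed = morph_closing(opened, selem)
    labels = cc_label(closed, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    solid = ndimage.binary_fill_holes(labels == largest)
    return PadMask(
        membership=solid,
        threshold_used=mask.threshold_used,
        n_components_before_cleanup=mask.n_components_before_cleanup,
    )


def _in_intervals(hue_deg: np.ndarray, intervals: Sequence[tuple[float, float]]) -> np.ndarray:
    out = np.zeros(hue_deg.shape, dtype=bool)
    for lo, hi in intervals:
        out |= (hue_deg >= lo) & (hue_deg < hi)
    return out


def colour_histogram(
    scan: PadScan, mask: PadMask, cfg: ColourConfig | None = None
) -> ColourHistogram:
    """Hue histogram and pink/blue/other classification of pad pixels.

    Masked pixels are converted to hue/saturation/value.  Every masked
    pixel lands in exactly one hue bin (count conservation).  A pixel is
    classified pink or blue when its hue falls in the configured interval
    *and* its saturation passes the gate; unsaturated (whitish) or
    off-hue pixels count as "other" but remain in the denominator.
    """
    cfg = cfg or ColourConfig()
    if mask.shape != scan.shape:
        raise InputError("mask shape does not match scan shape")
    if mask.area_px == 0:
        raise EmptyRegionError("cannot compute a colour histogram on an empty mask")
    hsv = rgb2hsv(scan.pixels)
    hue = hsv[:, :, 0][mask.membership] * 360.0
    sat = hsv[:, :, 1][mask.membership]
    edges = np.linspace(0.0, 360.0, cfg.n_bins + 1)
    counts, _ = np.histogram(hue, bins=edges)
    saturated = sat >= cfg.saturation_gate
    pink = saturated & _in_intervals(hue, cfg.pink_hue)
    blue = saturated & _in_intervals(hue, cfg.blue_hue) & ~pink
    n_pink = int(pink.sum())
    n_blue = int(blue.sum())
    return ColourHistogram(
        bin_edges=edges,
        counts=counts,
        n_pink=n_pink,
        n_blue=n_blue,
        n_other=mask.area_px - n_pink - n_blue,
    )


def pink_percentage(hist: ColourHistogram) -> float:
    """Percentage of the whole pad area classified pink, in [0, 100].

    The denominator is the full pad area (pink + blue + other), not just
    the classified pixels.
    """
    if hist.area_px == 0:
        raise EmptyRegionError("zero-area histogram")
    return 100.0 * hist.n_pink / hist.area_px


def categorize(pink_percent: float, cfg: CategoryConfig | None = None) -> str:
    """Map the continuous percentage to normal / intermediate / abnormal.

    Boundaries are inclusive toward the less-diseased category: a value
    exactly at ``t_normal`` is normal, exactly at ``t_abnormal`` is
    abnormal.
    """
    cfg = cfg or CategoryConfig()
    if not cfg.t_abnormal < cfg.t_normal:
        raise ConfigError(
            f"category thresholds inverted: t_abnormal={cfg.t_abnormal} must be "
            f"< t_normal={cfg.t_normal}"
        )
    if not (0.0 <= pink_percent <= 100.0):
        raise InputError(f"pink_percent {pink_percent} outside [0, 100]")
    if pink_percent >= cfg.t_normal:
        return "normal"
    if pink_percent <= cfg.t_abnormal:
        return "abnormal"
    return "intermediate"


def quantify_scan(scan: PadScan, cfg: RunConfig | None = None) -> QuantResult:
    """Run segmentation -> cleanup -> histogram -> percentage on a scan
    already in memory."""
    cfg = cfg or RunConfig()
    mask = segment_pad(scan, cfg.segmentation)
    mask = refine_mask(mask, scan, cfg.morphology)
    hist = colour_histogram(scan, mask, cfg.colour)
    pct = pink_percentage(hist)
    mm_per_px = MM_PER_INCH / scan.dpi
    return QuantResult(
        source_id=scan.source_id,
        pink_percent=pct,
        category=categorize(pct, cfg.categories),
        pad_area_mm2=mask.area_px * mm_per_px**2,
        mask=mask,
        histogram=hist,
    )


def quantify(
    path: str | Path,
    cfg: RunConfig | None = None,
    declared_dpi: float | None = None,
) -> QuantResult:
    """Full pipeline on an image file: the automated analogue of the visual
    pad reading, returning the continuous percentage plus diagnostics."""
    scan = load_scan(path, declared_dpi=declared_dpi)
    return quantify_scan(scan, cfg)
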