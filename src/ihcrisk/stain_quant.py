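"""Dual-stain image quantification: OD transform, unmixing, PPEA/AEI.

The pipeline mirrors a digital-pathology positive-pixel workflow for a
dual-chromogen immunostain:

1. convert 8-bit RGB to per-channel optical density (OD),
2. classify tissue vs blank by mean-channel OD (> 0.08),
3. unmix the OD image into per-stain concentrations with a stain basis,
4. call a pixel marker-positive when its deconvolved stain concentration
   exceeds 0.15 OD,
5. summarise each marker as PPEA (positive / tissue pixel count) and AEI
   (mean concentration over positive pixels), and score a subject as
   ln(PPEA x AEI) pooled over all annotated regions.

Thresholds are strict (>).  "Overall staining OD" for the tissue mask is
the mean of the three channel ODs.  Positivity is assessed on the
deconvolved stain channel rather than raw colour because the two
chromogens overlap spectrally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .synth_histology import StainBasis, build_default_stain_basis

__all__ = [
    "QuantConfig",
    "MarkerQuant",
    "FormatError",
    "NoTissueError",
    "UndefinedExpressionError",
    "rgb_to_od",
    "tissue_mask",
    "deconvolve",
    "quantify_marker",
    "subject_expression",
    "quantify_image",
    "read_rgb",
]

BROWN, BLUE, COUNTERSTAIN = 0, 1, 2


class FormatError(ValueError):
    """Input raster is not 8-bit 3-channel RGB."""


class NoTissueError(ValueError):
    """No analyzable tissue pixels (maps to the study's exclusion rule)."""


class UndefinedExpressionError(ValueError):
    """PPEA is zero, so ln(PPEA x AEI) is undefined for this subject."""


@dataclass(frozen=True)
class QuantConfig:
    """Thresholds and stain basis for quantification.

    ``tissue_od_threshold``: mean-channel OD above which a pixel is
    tissue (default 0.08).  ``marker_od_threshold``: per-marker
    deconvolved OD above which a tissue pixel is positive (default 0.15
    for both chromogens).
    """

    tissue_od_threshold: float = 0.08
    marker_od_threshold: dict[int, float] = field(
        default_factory=lambda: {BROWN: 0.15, BLUE: 0.15}
    )
    basis: StainBasis = field(default_factory=build_default_stain_basis)

    def __post_init__(self) -> None:
        if self.tissue_od_threshold <= 0:
            raise ValueError("tissue_od_threshold must be > 0")
        if any(t <= 0 for t in self.marker_od_threshold.values()):
            raise ValueError("marker_od_threshold values must be > 0")


@dataclass(frozen=True)
class MarkerQuant:
    """Per-region quantification of one marker.

    ``aei`` and ``expression_level`` are NaN when no pixel is positive.
    """

    ppea: float
    aei: float
    expression_level: float
    n_tissue_pixels: int
    n_positive_pixels: int


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Per-channel optical density: OD_c = -log10(max(I_c, 1) / 255)."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise FormatError(f"expected an (H, W, 3) RGB raster, got shape {rgb.shape}")
    intensity = np.maximum(rgb.astype(float), 1.0)
    return -np.log10(intensity / 255.0)


def tissue_mask(od: np.ndarray, cfg: QuantConfig) -> np.ndarray:
    """Tissue pixels: mean of the three channel ODs strictly above threshold."""
    return od.mean(axis=-1) > cfg.tissue_od_threshold


def deconvolve(od: np.ndarray, basis: StainBasis) -> np.ndarray:
    """Unmix per-pixel OD into per-stain concentrations.

    Solves ``basis^T c = od`` for each pixel and clamps negative
    components to zero.  Returns an array of shape (3, H, W) in OD units
    along each stain vector.
    """
    try:
        inv = np.linalg.inv(basis.vectors)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "stain basis is singular; provide linearly independent stain vectors"
        ) from exc
    h, w = od.shape[:2]
    conc = od.reshape(-1, 3) @ inv  # od_row = conc_row @ basis
    return np.clip(conc, 0.0, None).T.reshape(3, h, w)


def quantify_marker(
    conc: np.ndarray, stain_index: int, tissue: np.ndarray, cfg: QuantConfig
) -> MarkerQuant:
    """PPEA and AEI for one stain channel restricted to tissue pixels."""
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise NoTissueError("no analyzable tissue pixels in region")
    values = conc[stain_index][tissue]
    threshold = cfg.marker_od_threshold[stain_index]
    positive = values > threshold
    n_pos = int(positive.sum())
    ppea = n_pos / n_tissue
    if n_pos == 0:
        return MarkerQuant(ppea, float("nan"), float("nan"), n_tissue, 0)
    aei = float(values[positive].mean())
    return MarkerQuant(ppea, aei, float(np.log(ppea * aei)), n_tissue, n_pos)


def subject_expression(quants: list[MarkerQuant]) -> float:
    """Subject-level expression: ln(PPEA x AEI) pooled over regions.

    Pixel pooling: pooled PPEA = total positive / total tissue pixels;
    pooled AEI = positive-pixel-weighted mean of region AEIs.  This is
    the unique aggregation invariant to how regions are partitioned.
    """
    if not quants:
        raise NoTissueError("no regions with tissue")
    tot_tissue = sum(q.n_tissue_pixels for q in quants)
    tot_pos = sum(q.n_positive_pixels for q in quants)
    if tot_tissue == 0:
        raise NoTissueError("no analyzable tissue pixels across regions")
    if tot_pos == 0:
        raise UndefinedExpressionError("pooled PPEA is zero; expression undefined")
    ppea = tot_pos / tot_tissue
    aei = sum(q.aei * q.n_positive_pixels for q in quants if q.n_positive_pixels) / tot_pos
    return float(np.log(ppea * aei))


def quantify_image(
    rgb: np.ndarray,
    cfg: QuantConfig | None = None,
    region_mask: np.ndarray | None = None,
) -> dict[int, MarkerQuant]:
    """Full quantification of one image: both markers in one call.

    ``region_mask`` optionally restricts analysis to annotated regions
    (emulating manual gland annotation).
    """
    cfg = cfg or QuantConfig()
    od = rgb_to_od(rgb)
    tissue = tissue_mask(od, cfg)
    if region_mask is not None:
        tissue = tissue & region_mask.astype(bool)
    conc = deconvolve(od, cfg.basis)
    return {s: quantify_marker(conc, s, tissue, cfg) for s in (BROWN, BLUE)}


def read_rgb(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as (H, W, 3) uint8, dropping any alpha channel."""
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[-1] == 4:
        img = img[..., :3]
    if img.ndim != 3 or img.shape[-1] != 3:
        raise FormatError(f"{path}: expected an RGB image, got shape {img.shape}")
    return img
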