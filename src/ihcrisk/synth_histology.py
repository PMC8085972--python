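"""Synthetic dual-stained tissue phantoms with exact ground truth.

Renders small RGB images that mimic a dual-chromogen immunostain of
prostate glandular tissue: a brown chromogen (DAB, horseradish-peroxidase
substrate), a blue chromogen (Ferangi Blue, alkaline-phosphatase
substrate) and a hematoxylin counterstain, mixed per pixel by
Beer-Lambert absorbance.  Every phantom carries its ground truth — the
tissue/positive masks, per-stain concentration maps, and the true
positive-area fraction (PPEA) and mean positive intensity (AEI) — so the
quantification stage can be validated without any real slide.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import stats

__all__ = [
    "StainBasis",
    "PhantomSpec",
    "GroundTruth",
    "InvalidSpecError",
    "build_default_stain_basis",
    "render_phantom",
    "write_phantom",
]

# Published absorbance direction for DAB (brown) and hematoxylin
# (counterstain).  The Ferangi Blue vector is NOT published anywhere; the
# default below is a documented, configurable choice that absorbs mostly
# red/green (hence looks blue) and sits > 30 degrees away from DAB so the
# two chromogens unmix stably.  Users with a calibrated basis should pass
# their own.
_DAB = (0.268, 0.570, 0.776)
_FERANGI_BLUE = (0.850, 0.500, 0.170)
_HEMATOXYLIN = (0.650, 0.704, 0.286)


class InvalidSpecError(ValueError):
    """Raised when a phantom specification is internally inconsistent."""


@dataclass(frozen=True)
class StainBasis:
    """Unit absorbance vectors for the three stains.

    ``vectors`` is a 3x3 matrix; rows are (brown chromogen, blue
    chromogen, counterstain), columns are (R, G, B) optical density.
    Each row has unit Euclidean norm and nonnegative entries.
    """

    vectors: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise ValueError(f"stain basis must be 3x3, got {v.shape}")
        if np.any(v < 0):
            raise ValueError("stain basis entries must be nonnegative")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("stain basis rows must have unit norm")
        if not np.isfinite(np.linalg.cond(v)) or np.linalg.cond(v) > 1e8:
            raise ValueError("stain basis rows are (near-)linearly dependent")
        object.__setattr__(self, "vectors", v)

    @property
    def brown(self) -> np.ndarray:
        return self.vectors[0]

    @property
    def blue(self) -> np.ndarray:
        return self.vectors[1]

    @property
    def counterstain(self) -> np.ndarray:
        return self.vectors[2]


def build_default_stain_basis() -> StainBasis:
    """Return the package's default stain basis (deterministic).

    Row order: brown chromogen (DAB direction), blue chromogen
    (synthetic Ferangi-Blue default), hematoxylin counterstain.
    """
    raw = np.array([_DAB, _FERANGI_BLUE, _HEMATOXYLIN], dtype=float)
    raw /= np.linalg.norm(raw, axis=1, keepdims=True)
    return StainBasis(raw)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one rendered phantom.

    Fractions are proportions of *tissue* pixels; mean ODs are the
    target per-pixel stain concentrations in optical-density units.
    One integer ``seed`` fully determines the phantom.
    """

    width: int = 128
    height: int = 128
    gland_count: int = 6
    gland_radius: float = 18.0
    brown_positive_fraction: float = 0.25
    blue_positive_fraction: float = 0.25
    brown_mean_od: float = 0.40
    blue_mean_od: float = 0.40
    counterstain_mean_od: float = 0.30
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 16 or self.height < 16:
            raise InvalidSpecError("phantom dimensions must be >= 16 pixels")
        for name in ("brown_positive_fraction", "blue_positive_fraction"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise InvalidSpecError(f"{name} must be in [0, 1], got {f}")
        if self.brown_positive_fraction + self.blue_positive_fraction > 1.0 + 1e-9:
            raise InvalidSpecError(
                "brown and blue positive fractions must sum to <= 1 "
                "(positive regions are disjoint)"
            )
        for name in ("brown_mean_od", "blue_mean_od", "counterstain_mean_od"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if self.gland_count < 1:
            raise InvalidSpecError("gland_count must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Exact truth accompanying a rendered phantom."""

    tissue_mask: np.ndarray
    brown_mask: np.ndarray
    blue_mask: np.ndarray
    true_ppea_brown: float
    true_ppea_blue: float
    true_aei_brown: float  # NaN when the brown mask is empty
    true_aei_blue: float
    concentration_maps: np.ndarray  # (3, H, W): brown, blue, counterstain


def _gland_tissue_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Union of randomly placed disks emulating glandular regions."""
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    r = spec.gland_radius
    for _ in range(spec.gland_count):
        cy = rng.uniform(r, max(spec.height - r, r))
        cx = rng.uniform(r, max(spec.width - r, r))
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    if not mask.any():  # pathological spec (huge radius, tiny image)
        mask[spec.height // 2, spec.width // 2] = True
    return mask


def _truncated_normal(
    mean: float, rng: np.random.Generator, size: int, rel_sd: float = 0.15
) -> np.ndarray:
    """Stain concentrations: normal(mean, 0.15*mean) truncated to +-1.5 sd.

    The truncation keeps every positive pixel's concentration above
    0.775*mean, so with mean OD >= 0.2 positives stay safely above the
    0.15 positivity threshold and the rendered mask matches the truth.
    """
    if mean == 0.0:
        return np.zeros(size)
    sd = rel_sd * mean
    return stats.truncnorm.rvs(-1.5, 1.5, loc=mean, scale=sd, size=size, random_state=rng)


def render_phantom(
    spec: PhantomSpec, basis: StainBasis | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Render a dual-stained phantom and its ground truth.

    Pixel intensities follow Beer-Lambert transmission:
    ``I_c = round(255 * 10**(-sum_s basis[s, c] * conc[s]))`` clipped to
    [0, 255].  Background (non-tissue) is pure white (OD 0) before noise.
    Identical ``(spec, basis)`` give byte-identical images.
    """
    if basis is None:
        basis = build_default_stain_basis()
    rng = np.random.default_rng(spec.seed)

    tissue = _gland_tissue_mask(spec, rng)
    tissue_idx = np.flatnonzero(tissue.ravel())
    n_tissue = tissue_idx.size

    k_brown = int(round(spec.brown_positive_fraction * n_tissue))
    k_blue = int(round(spec.blue_positive_fraction * n_tissue))
    if k_brown + k_blue > n_tissue:
        raise InvalidSpecError("requested positive pixels exceed tissue area")
    perm = rng.permutation(n_tissue)
    brown_idx = tissue_idx[perm[:k_brown]]
    blue_idx = tissue_idx[perm[k_brown : k_brown + k_blue]]

    h, w = spec.height, spec.width
    conc = np.zeros((3, h * w))
    conc[0, brown_idx] = _truncated_normal(spec.brown_mean_od, rng, k_brown)
    conc[1, blue_idx] = _truncated_normal(spec.blue_mean_od, rng, k_blue)
    conc[2, tissue_idx] = _truncated_normal(spec.counterstain_mean_od, rng, n_tissue)

    od = conc.T @ basis.vectors  # (H*W, 3) per-channel OD
    if spec.noise_sd > 0:
        od = np.clip(od + rng.normal(0.0, spec.noise_sd, od.shape), 0.0, None)
    rgb = np.clip(np.round(255.0 * 10.0 ** (-od)), 0, 255).astype(np.uint8)
    rgb = rgb.reshape(h, w, 3)

    brown_mask = np.zeros(h * w, dtype=bool)
    brown_mask[brown_idx] = True
    blue_mask = np.zeros(h * w, dtype=bool)
    blue_mask[blue_idx] = True

    truth = GroundTruth(
        tissue_mask=tissue,
        brown_mask=brown_mask.reshape(h, w),
        blue_mask=blue_mask.reshape(h, w),
        true_ppea_brown=k_brown / n_tissue,
        true_ppea_blue=k_blue / n_tissue,
        true_aei_brown=float(conc[0, brown_idx].mean()) if k_brown else float("nan"),
        true_aei_blue=float(conc[1, blue_idx].mean()) if k_blue else float("nan"),
        concentration_maps=conc.reshape(3, h, w),
    )
    return rgb, truth


def write_phantom(
    out_dir: str | Path,
    stem: str,
    rgb: np.ndarray,
    truth: GroundTruth,
    spec: PhantomSpec,
) -> None:
    """Write image + masks as PNG and ground truth as a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / f"{stem}.png", rgb)
    for name in ("tissue_mask", "brown_mask", "blue_mask"):
        mask = getattr(truth, name).astype(np.uint8) * 255
        iio.imwrite(out / f"{stem}_{name}.png", mask)
    sidecar = {
        "spec": dataclasses.asdict(spec),
        "true_ppea_brown": truth.true_ppea_brown,
        "true_ppea_blue": truth.true_ppea_blue,
        "true_aei_brown": truth.true_aei_brown,
        "true_aei_blue": truth.true_aei_blue,
    }
    (out / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
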