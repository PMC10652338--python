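"""COC matrix permeability (PEA) and HA staining (HABP) quantification.

Images are multi-channel, optionally z-stacked (DNA, actin, particles or
HABP).  The particle-exclusion readouts are percent porosity (area
infiltrated by nanoparticles over the whole COC area) and nanoparticle
mean fluorescent intensity per pixel of the COC.  HABP intensity is the
mean signal per pixel within equal-sized cellular and intercellular
regions of interest, averaged as the mean of per-ROI means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

__all__ = [
    "CocImage",
    "CocMask",
    "PorosityResult",
    "Roi",
    "RoiSet",
    "HabpResult",
    "segment_coc",
    "porosity",
    "habp_intensity",
    "place_rois",
]


def _as_zyx(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        return arr[None, ...]
    if arr.ndim == 3:
        return arr
    raise ValueError("channel arrays must be 2D (y, x) or 3D (z, y, x)")


@dataclass(frozen=True)
class CocImage:
    """Named intensity channels sharing one (z, y, x) shape and pixel scale."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    coc_id: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.channels:
            raise ValueError("at least one channel required")
        stacked = {k: _as_zyx(v) for k, v in self.channels.items()}
        shapes = {v.shape for v in stacked.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        object.__setattr__(self, "channels", stacked)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def z_count(self) -> int:
        return self.shape[0]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not in {sorted(self.channels)}"
            ) from None


@dataclass(frozen=True)
class CocMask:
    """Binary 2D region of the whole COC."""

    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if not m.any():
            raise ValueError("mask is empty")
        object.__setattr__(self, "mask", m)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_mm2(self) -> float:
        return self.area_px * (self.pixel_size_um * 1e-3) ** 2


@dataclass(frozen=True)
class PorosityResult:
    percent_porosity: float
    mean_intensity_per_pixel: float
    per_z_percent: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_porosity <= 100.0):
            raise ValueError("percent_porosity outside [0, 100]")
        if self.mean_intensity_per_pixel < 0:
            raise ValueError("mean intensity must be non-negative")


@dataclass(frozen=True)
class Roi:
    """Square ROI: top-left corner, side length, category and z-plane."""

    row: int
    col: int
    size: int
    category: Literal["cellular", "intercellular"]
    z: int = 0

    def pixels(self, arr: np.ndarray) -> np.ndarray:
        if (
            self.row < 0
            or self.col < 0
            or self.row + self.size > arr.shape[-2]
            or self.col + self.size > arr.shape[-1]
        ):
            raise ValueError("ROI extends outside the image")
        if arr.ndim == 3:
            if not (0 <= self.z < arr.shape[0]):
                raise ValueError("ROI z-plane outside the stack")
            return arr[self.z, self.row : self.row + self.size,
                       self.col : self.col + self.size]
        return arr[self.row : self.row + self.size, self.col : self.col + self.size]


@dataclass(frozen=True)
class RoiSet:
    rois: tuple[Roi, ...]

    def by_category(self, category: str) -> list[Roi]:
        return [r for r in self.rois if r.category == category]


@dataclass(frozen=True)
class HabpResult:
    cellular_mean: float
    intercellular_mean: float

    def __post_init__(self) -> None:
        if self.cellular_mean < 0 or self.intercellular_mean < 0:
            raise ValueError("intensities must be non-negative")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def segment_coc(
    image: CocImage, structural_channel: str = "actin"
) -> CocMask:
    """Segment the whole-COC region from a structural channel.

    Max-projects over z, Otsu-thresholds, applies morphological closing
    and hole filling, and keeps the largest connected component.
    """
    chan = image.channel(structural_channel)
    proj = chan.max(axis=0)
    if np.ptp(proj) == 0:
        raise ValueError("structural channel is constant: nothing to segment")
    thr = filters.threshold_otsu(proj)
    fg = proj > thr
    fg = ndimage.binary_closing(fg, structure=morphology.disk(3))
    fg = ndimage.binary_fill_holes(fg)
    labels = measure.label(fg)
    if labels.max() == 0:
        raise ValueError("empty foreground after thresholding")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = labels == sizes.argmax()
    return CocMask(mask=keep, pixel_size_um=image.pixel_size_um)


def porosity(
    image: CocImage,
    mask: CocMask,
    particle_threshold: float | Literal["otsu"] = "otsu",
    particle_channel: str = "particles",
) -> PorosityResult:
    """Percent porosity and nanoparticle mean intensity per pixel.

    Per z-plane, infiltrated pixels are those within the COC mask whose
    particle signal exceeds the threshold (Otsu computed within the mask
    by default, or a fixed value); percent porosity is 100 x infiltrated
    area / COC area, averaged across planes.  Mean intensity is the total
    particle intensity over the mask divided by the mask pixel count,
    averaged across planes.
    """
    chan = image.channel(particle_channel)
    m = mask.mask
    if m.shape != chan.shape[1:]:
        raise ValueError("mask shape does not match image planes")

    per_z_pct: list[float] = []
    per_z_int: list[float] = []
    for z in range(chan.shape[0]):
        plane = chan[z]
        inside = plane[m]
        if particle_threshold == "otsu":
            if np.ptp(inside) == 0:
                thr = float(inside.max())  # constant: nothing distinguishable
            else:
                thr = float(filters.threshold_otsu(inside))
        else:
            thr = float(particle_threshold)
        per_z_pct.append(100.0 * float(np.mean(inside > thr)))
        per_z_int.append(float(inside.sum()) / mask.area_px)

    return PorosityResult(
        percent_porosity=float(np.mean(per_z_pct)),
        mean_intensity_per_pixel=float(np.mean(per_z_int)),
        per_z_percent=tuple(per_z_pct),
    )


def habp_intensity(
    image: CocImage, rois: RoiSet, signal_channel: str = "habp"
) -> HabpResult:
    """Mean HABP signal per pixel in cellular and intercellular ROIs.

    The category value is the mean of per-ROI mean intensities (not a
    pixel-pooled mean), matching per-ROI assessment across z-planes.
    """
    chan = image.channel(signal_channel)
    means: dict[str, list[float]] = {"cellular": [], "intercellular": []}
    for roi in rois.rois:
        means[roi.category].append(float(roi.pixels(chan).mean()))
    for cat, vals in means.items():
        if not vals:
            raise ValueError(f"no {cat} ROIs supplied")
    return HabpResult(
        cellular_mean=float(np.mean(means["cellular"])),
        intercellular_mean=float(np.mean(means["intercellular"])),
    )


def place_rois(
    mask: CocMask,
    dna: np.ndarray,
    n_rois: int = 9,
    n_z: int = 3,
    roi_size_px: int = 15,
    seed: int = 0,
) -> RoiSet:
    """Deterministic equal-sized ROI placement within the COC mask.

    Cellular ROIs are centred on high DNA-density loci (a proxy for
    clusters of adjacent cumulus cells) and intercellular ROIs on low
    DNA-density regions; both categories use the same ROI size.  The
    same candidate ranking is applied per z-plane, so the set is a pure
    function of (mask, dna, seed).
    """
    dna = _as_zyx(dna)
    if n_z > dna.shape[0]:
        raise ValueError(f"requested {n_z} z-planes but stack has {dna.shape[0]}")
    rng = np.random.default_rng(seed)
    half = roi_size_px // 2

    # candidate centres whose full ROI fits inside the mask
    eroded = ndimage.binary_erosion(
        mask.mask, structure=np.ones((roi_size_px, roi_size_px))
    )
    cand = np.argwhere(eroded)
    if cand.shape[0] < 2 * n_rois:
        raise ValueError("mask too small for the requested ROI layout")

    rois: list[Roi] = []
    for z in range(n_z):
        density = ndimage.gaussian_filter(dna[z], sigma=roi_size_px / 2.0)
        scores = density[cand[:, 0], cand[:, 1]]
        jitter = rng.random(scores.size) * 1e-9  # stable tie-break
        order = np.argsort(scores + jitter)
        chosen = {"cellular": order[::-1], "intercellular": order}
        for category, pool in chosen.items():
            picked: list[int] = []
            for idx in pool:
                r, c = cand[idx]
                if all(
                    abs(r - cand[j][0]) >= roi_size_px
                    or abs(c - cand[j][1]) >= roi_size_px
                    for j in picked
                ):
                    picked.append(idx)
                if len(picked) == n_rois:
                    break
            if len(picked) < n_rois:
                raise ValueError("could not place non-overlapping ROIs")
            for idx in picked:
                r, c = cand[idx]
                rois.append(
                    Roi(row=int(r - half), col=int(c - half), size=roi_size_px,
                        category=category, z=z)
                )
    return RoiSet(rois=tuple(rois))
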