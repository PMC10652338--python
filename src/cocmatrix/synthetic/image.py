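"""Synthetic multi-channel COC images with ground-truth masks.

The complex is a disk (cumulus annulus around an oocyte disk).  The
particles channel is nonzero only on a truth "infiltrated" mask inside
the COC plus everywhere outside it; the infiltrated area fraction is set
by thresholding a smoothed noise field at the exact quantile of the
requested porosity, so the truth fraction matches the spec to within a
pixel-counting error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from cocmatrix.imaging import CocImage
from cocmatrix.synthetic.specs import CocImageSpec

__all__ = ["CocImageTruth", "gen_coc_image"]


@dataclass(frozen=True)
class CocImageTruth:
    """Ground truth for one generated image."""

    coc_mask: np.ndarray  # 2D bool
    oocyte_mask: np.ndarray  # 2D bool
    infiltrated: np.ndarray  # (z, y, x) bool, subset of coc_mask per plane
    porosity_fraction: float

    def fraction(self, z: int = 0) -> float:
        return float(self.infiltrated[z][self.coc_mask].mean())


def _disk(shape: tuple[int, int], center: tuple[float, float], radius: float
          ) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _infiltration_mask(
    coc: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Subset of ``coc`` with area fraction ``fraction`` (quantile-exact)."""
    if fraction <= 0.0:
        return np.zeros_like(coc)
    if fraction >= 1.0:
        return coc.copy()
    field = ndimage.gaussian_filter(rng.standard_normal(coc.shape), sigma=4.0)
    inside = field[coc]
    thr = np.quantile(inside, 1.0 - fraction)
    out = np.zeros_like(coc)
    out[coc] = inside > thr
    return out


def gen_coc_image(spec: CocImageSpec) -> tuple[CocImage, CocImageTruth]:
    """Generate a (DNA, actin, particles) image stack plus truth masks."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape_px
    center = spec.center

    coc = _disk(shape, center, spec.coc_radius_px)
    oocyte = _disk(shape, center, spec.oocyte_radius_px)
    annulus = coc & ~oocyte
    exterior = ~coc

    n_nuclei = max(12, int(annulus.sum() / 2500))
    cand = np.argwhere(annulus)
    nuclei_idx = rng.choice(cand.shape[0], size=n_nuclei, replace=False)

    dna_planes, actin_planes, part_planes, infil_planes = [], [], [], []
    for _ in range(spec.n_z):
        # DNA: gaussian nuclei blobs in the cumulus annulus
        dna = np.zeros(shape)
        for r, c in cand[nuclei_idx]:
            dna[r, c] = 1.0
        dna = ndimage.gaussian_filter(dna, sigma=3.0)
        peak = dna.max() if dna.max() > 0 else 1.0
        dna = spec.background + spec.cell_intensity * dna / peak
        dna += np.abs(rng.normal(0, 0.05 * spec.background + 1e-9, shape))

        # actin: bright over the whole complex, dim background
        actin = np.where(coc, spec.cell_intensity, spec.background).astype(float)
        actin += np.abs(rng.normal(0, 0.1 * spec.background + 1e-9, shape))

        # particles: exterior plus infiltrated truth region only
        infil = _infiltration_mask(coc, spec.porosity_fraction, rng)
        particles = np.zeros(shape)
        region = infil | exterior
        texture = 1.0 + 0.1 * rng.standard_normal(shape)  # Poisson-like CV
        particles[region] = spec.particle_intensity * np.clip(
            texture[region], 0.2, None
        )

        dna_planes.append(dna)
        actin_planes.append(actin)
        part_planes.append(particles)
        infil_planes.append(infil)

    image = CocImage(
        channels={
            "dna": np.stack(dna_planes),
            "actin": np.stack(actin_planes),
            "particles": np.stack(part_planes),
        },
        pixel_size_um=spec.pixel_size_um,
        coc_id=f"synthetic-seed{spec.seed}",
    )
    truth = CocImageTruth(
        coc_mask=coc,
        oocyte_mask=oocyte,
        infiltrated=np.stack(infil_planes),
        porosity_fraction=spec.porosity_fraction,
    )
    return image, truth
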