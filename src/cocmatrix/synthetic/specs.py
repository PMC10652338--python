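"""Validated parameter specs for the synthetic generators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


class GenerationError(RuntimeError):
    """Raised when a spec is satisfiable in principle but not in practice
    (e.g. an event rate too high for non-overlapping placement)."""


@dataclass(frozen=True)
class MwDistributionSpec:
    """Mixture of log-normal molecular-weight components, truncated to bounds.

    ``components`` is a list of (weight, median_kda, sigma_log) triples;
    weights must sum to one.  The default two-component mixture (150 kDa
    and 800 kDa medians) emulates a fluid in which sub-300 kDa hyaluronan
    predominates.
    """

    components: tuple[tuple[float, float, float], ...] = (
        (0.65, 150.0, 0.5),
        (0.35, 800.0, 0.5),
    )
    mw_bounds_kda: tuple[float, float] = (50.0, 8000.0)

    def __post_init__(self) -> None:
        w = sum(c[0] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {w}")
        for weight, median, sigma in self.components:
            if weight < 0 or median <= 0 or sigma <= 0:
                raise ValueError("weights non-negative; medians and sigmas positive")
        lo, hi = self.mw_bounds_kda
        if not (0 < lo < hi):
            raise ValueError("need 0 < min_kda < max_kda")

    def _component_mass_below(self, cutoff: float) -> np.ndarray:
        """Per-component P(MW < cutoff) before truncation."""
        return np.array(
            [
                sps.norm.cdf((np.log(cutoff) - np.log(med)) / sig)
                for _, med, sig in self.components
            ]
        )

    def fraction_below(self, cutoff_kda: float) -> float:
        """Analytic mixture P(MW < cutoff) under bound truncation."""
        lo, hi = self.mw_bounds_kda
        cutoff = float(np.clip(cutoff_kda, lo, hi))
        w = np.array([c[0] for c in self.components])
        p_lo = self._component_mass_below(lo)
        p_hi = self._component_mass_below(hi)
        p_c = self._component_mass_below(cutoff)
        inside = p_hi - p_lo
        total = float(np.sum(w * inside))
        if total <= 0:
            raise ValueError("bounds exclude all mixture mass")
        return float(np.sum(w * (p_c - p_lo)) / total)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` molecular weights (kDa), rejecting outside the bounds."""
        lo, hi = self.mw_bounds_kda
        w = np.array([c[0] for c in self.components])
        medians = np.array([c[1] for c in self.components])
        sigmas = np.array([c[2] for c in self.components])
        out = np.empty(0)
        while out.size < n:
            k = max(n - out.size, 16)
            comp = rng.choice(len(w), size=2 * k, p=w / w.sum())
            draw = np.exp(np.log(medians[comp]) + sigmas[comp] * rng.standard_normal(2 * k))
            draw = draw[(draw >= lo) & (draw <= hi)]
            out = np.concatenate([out, draw])
        return out[:n]


@dataclass(frozen=True)
class TraceSpec:
    """Parameters of one synthetic ionic-current acquisition."""

    baseline_pa: float = 4000.0
    noise_sd_pa: float = 10.0
    sampling_hz: float = 200_000.0
    acq_filter_hz: float = 100_000.0  # 4-pole Bessel corner, causal
    duration_s: float = 5.0
    event_rate_hz: float = 20.0
    mw_spec: MwDistributionSpec = field(default_factory=MwDistributionSpec)
    voltage_mv: float = 250.0
    seed: int = 0
    min_depth_pa: float | None = None  # optional SNR floor on dip depth
    min_gap_s: float = 2e-3  # enforced spacing between events

    def __post_init__(self) -> None:
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if self.noise_sd_pa <= 0:
            raise ValueError("noise_sd_pa must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.baseline_pa <= 0:
            raise ValueError("baseline_pa must be positive")
        if self.event_rate_hz < 0:
            raise ValueError("event_rate_hz must be non-negative")


@dataclass(frozen=True)
class CocImageSpec:
    """Geometry and intensity parameters of a synthetic COC image."""

    shape_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 1.5
    coc_center_px: tuple[float, float] | None = None  # default: image centre
    coc_radius_px: float = 180.0
    oocyte_radius_px: float = 40.0
    porosity_fraction: float = 0.25
    particle_intensity: float = 200.0
    cell_intensity: float = 120.0
    intercellular_intensity: float = 30.0
    background: float = 5.0
    n_z: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.porosity_fraction <= 1.0):
            raise ValueError("porosity_fraction must lie in [0, 1]")
        if not (0 < self.oocyte_radius_px < self.coc_radius_px):
            raise ValueError("need 0 < oocyte_radius_px < coc_radius_px")
        if self.coc_radius_px >= min(self.shape_px) / 2:
            raise ValueError("COC disk must fit inside the image")
        if self.pixel_size_um <= 0 or self.n_z < 1:
            raise ValueError("pixel_size_um must be positive and n_z >= 1")

    @property
    def center(self) -> tuple[float, float]:
        if self.coc_center_px is not None:
            return self.coc_center_px
        return (self.shape_px[0] / 2.0, self.shape_px[1] / 2.0)


@dataclass(frozen=True)
class TimelapseSpec:
    """Logistic cumulus-expansion time course sampled hourly."""

    d_max_um: float = 75.0
    t_mid_h: float = 8.0
    rate_per_h: float = 0.6
    interval_h: float = 1.0
    horizon_h: float = 16.0
    noise_sd_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_max_um <= 0:
            raise ValueError("d_max_um must be positive")
        if not (self.horizon_h >= self.interval_h > 0):
            raise ValueError("need horizon_h >= interval_h > 0")
        if self.noise_sd_um < 0:
            raise ValueError("noise_sd_um must be non-negative")


@dataclass(frozen=True)
class CtTableSpec:
    """Synthetic gene x sample Ct table with specified ddCt effects.

    ``ddct_effects`` maps target genes to the Ct shift applied to the old
    group (so the downstream fold change is 2^-effect); housekeeping
    genes must carry a zero effect.
    """

    genes: tuple[str, ...]
    hkgs: tuple[str, ...] = ("Gusb", "Actb", "Gapdh", "B2m", "Hsp90ab1")
    n_young: int = 2
    n_old: int = 2
    hkg_ct_mean: float = 20.0
    hkg_ct_sd: float = 0.5
    target_ct_mean: float = 26.0
    ddct_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        all_genes = tuple(self.genes)
        for h in self.hkgs:
            if h not in all_genes:
                object.__setattr__(self, "genes", all_genes + (h,))
                all_genes = self.genes
        for name, mean in (("hkg_ct_mean", self.hkg_ct_mean),
                           ("target_ct_mean", self.target_ct_mean)):
            if not (0 < mean < 45):
                raise ValueError(f"{name} must lie in (0, 45)")
        if self.n_young < 1 or self.n_old < 1:
            raise ValueError("need at least one sample per group")
        for hkg in self.hkgs:
            if self.ddct_effects.get(hkg, 0.0) != 0.0:
                raise ValueError("housekeeping genes must have zero ddCt effect")
        unknown = set(self.ddct_effects) - set(self.genes)
        if unknown:
            raise ValueError(f"ddct_effects for unknown genes: {sorted(unknown)}")
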