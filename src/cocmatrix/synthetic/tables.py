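"""Synthetic expansion time courses and Ct tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from cocmatrix.kinetics import DistanceSeries
from cocmatrix.qpcr import CtTable
from cocmatrix.synthetic.specs import CtTableSpec, TimelapseSpec

__all__ = ["gen_timelapse", "gen_ct_table", "logistic_distance"]


def logistic_distance(t_h, spec: TimelapseSpec) -> np.ndarray:
    """Noiseless logistic expansion d(t) = d_max / (1 + exp(-rate (t - t_mid)))."""
    t_h = np.asarray(t_h, dtype=float)
    return spec.d_max_um / (1.0 + np.exp(-spec.rate_per_h * (t_h - spec.t_mid_h)))


def gen_timelapse(spec: TimelapseSpec, coc_id: str = "synthetic") -> DistanceSeries:
    """Hourly (by default) distance series on a logistic expansion curve."""
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, spec.horizon_h + 1e-9, spec.interval_h)
    d = logistic_distance(times, spec)
    if spec.noise_sd_um > 0:
        d = d + rng.normal(0.0, spec.noise_sd_um, size=times.size)
    return DistanceSeries(coc_id=coc_id, times_h=times, distances_um=d)


def gen_ct_table(spec: CtTableSpec) -> CtTable:
    """Gene x sample Ct table with specified ddCt effects in the old group.

    Samples are paired into replicate experiments (young_i with old_i);
    per gene, the old group's Ct is shifted by its ddCt effect, so the
    noiseless table recovers FC = 2^-effect downstream exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n_rep = max(spec.n_young, spec.n_old)

    samples, groups, reps = [], [], []
    for i in range(spec.n_young):
        samples.append(f"young_{i + 1}")
        groups.append("young")
        reps.append(min(i + 1, n_rep))
    for i in range(spec.n_old):
        samples.append(f"old_{i + 1}")
        groups.append("old")
        reps.append(min(i + 1, n_rep))

    rows = {}
    for gene in spec.genes:
        is_hkg = gene in spec.hkgs
        base = spec.hkg_ct_mean if is_hkg else spec.target_ct_mean
        # fixed per-gene offset so genes are distinguishable yet deterministic
        base = base + (0.0 if is_hkg else rng.normal(0.0, spec.hkg_ct_sd))
        effect = spec.ddct_effects.get(gene, 0.0)
        ct = np.full(len(samples), base)
        ct += np.where(np.array(groups) == "old", effect, 0.0)
        if spec.noise_sd > 0:
            ct += rng.normal(0.0, spec.noise_sd, size=len(samples))
        rows[gene] = np.clip(ct, 1.0, 45.0)

    ct_df = pd.DataFrame(rows, index=samples).T
    meta = pd.DataFrame({"group": groups, "replicate": reps}, index=samples)
    return CtTable(ct=ct_df, sample_meta=meta, hkgs=spec.hkgs)
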