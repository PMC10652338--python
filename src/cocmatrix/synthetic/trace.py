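"""Synthetic ionic-current traces with known translocation events.

Events are rectangular conductance dips before acquisition filtering (so
their areas are exact); a causal 4-pole Bessel low-pass emulates the
recording hardware.  The dip area of each event equals the calibration
curve's area for its true molecular weight, making the generator the
exact inverse of the sizing chain up to noise and filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from cocmatrix.nanopore import CalibrationCurve, CurrentTrace
from cocmatrix.synthetic.specs import GenerationError, TraceSpec

__all__ = ["EventTruth", "gen_trace"]

DURATION_RANGE_S = (50e-6, 2e-3)  # analyzable window with margin
MAX_DEPTH_FRACTION = 0.5  # dips never exceed half the open-pore current


@dataclass(frozen=True)
class EventTruth:
    """Ground-truth sidecar for one injected event."""

    onset_s: float
    duration_s: float
    depth_pa: float
    true_mw_kda: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.depth_pa <= 0:
            raise ValueError("duration and depth must be positive")

    @property
    def area_pa_s(self) -> float:
        return self.depth_pa * self.duration_s


def _depth_duration(
    areas: np.ndarray, spec: TraceSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split each target area into (depth, duration).

    Duration is drawn log-uniform in the analyzable window and depth is
    area/duration; depths are clipped into [min_depth_pa, 0.5*baseline]
    with duration re-derived so the area is preserved exactly.
    """
    lo, hi = DURATION_RANGE_S
    dur = np.exp(rng.uniform(np.log(lo), np.log(hi), size=areas.size))
    depth = areas / dur
    if spec.min_depth_pa is not None:
        shallow = depth < spec.min_depth_pa
        depth[shallow] = spec.min_depth_pa
        dur[shallow] = areas[shallow] / spec.min_depth_pa
    cap = MAX_DEPTH_FRACTION * spec.baseline_pa
    deep = depth > cap
    depth[deep] = cap
    dur[deep] = areas[deep] / cap
    return depth, dur


def _place(
    lengths: np.ndarray, n_total: int, gap: int, rng: np.random.Generator
) -> np.ndarray:
    """Non-overlapping start samples with at least ``gap`` between events."""
    k = lengths.size
    required = int(lengths.sum()) + (k + 1) * gap
    if required > n_total:
        raise GenerationError(
            "event rate too high for non-overlapping placement: "
            f"need {required} samples, trace has {n_total}"
        )
    slack = n_total - required
    offsets = np.sort(rng.integers(0, slack + 1, size=k))
    starts = gap + offsets + np.concatenate(([0], np.cumsum(lengths[:-1] + gap)))
    return starts.astype(int)


def gen_trace(
    spec: TraceSpec, calibration: CalibrationCurve
) -> tuple[CurrentTrace, list[EventTruth]]:
    """Generate a current trace plus its sorted event-truth sidecar.

    Event count is Poisson(event_rate * duration); each event's
    depth x duration equals ``calibration.area_for_mw(true_mw)`` exactly
    (before noise/filtering).  Identical specs give identical traces.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_hz
    n = int(round(spec.duration_s * fs))

    n_events = int(rng.poisson(spec.event_rate_hz * spec.duration_s))
    current = np.full(n, spec.baseline_pa)
    truths: list[EventTruth] = []
    if n_events > 0:
        mws = spec.mw_spec.sample(rng, n_events)
        areas = np.asarray(calibration.area_for_mw(mws), dtype=float)
        depths, durs = _depth_duration(areas, spec, rng)
        # quantise to whole samples, re-deriving depth to keep areas exact;
        # round up where rounding would push the depth past the cap
        cap = MAX_DEPTH_FRACTION * spec.baseline_pa
        len_samp = np.maximum.reduce([
            np.round(durs * fs).astype(int),
            np.ceil(areas * fs / cap).astype(int),
            np.ones(areas.size, dtype=int),
        ])
        durs = len_samp / fs
        depths = areas / durs
        gap = max(1, int(round(spec.min_gap_s * fs)))
        starts = _place(len_samp, n, gap, rng)
        order = np.argsort(starts)
        for i in order:
            s, ln = int(starts[i]), int(len_samp[i])
            current[s : s + ln] -= depths[i]
            truths.append(
                EventTruth(
                    onset_s=s / fs,
                    duration_s=float(durs[i]),
                    depth_pa=float(depths[i]),
                    true_mw_kda=float(mws[i]),
                )
            )

    current = current + rng.normal(0.0, spec.noise_sd_pa, size=n)

    # causal acquisition filter, as in hardware; a corner at/above Nyquist
    # (the 100 kHz Bessel sampled at 200 kHz) is a no-op digitally
    if spec.acq_filter_hz < 0.99 * fs / 2.0:
        sos = signal.bessel(4, spec.acq_filter_hz, btype="low", fs=fs,
                            output="sos", norm="mag")
        current = signal.sosfilt(sos, current)

    trace = CurrentTrace(
        samples=current,
        sampling_hz=fs,
        voltage_mv=spec.voltage_mv,
        acq_filter_hz=spec.acq_filter_hz,
        source_id=f"synthetic-seed{spec.seed}",
    )
    return trace, truths
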