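"""File formats for traces, images, tables and result reports.

Traces travel as raw little-endian float32 sample files with a JSON
metadata sidecar (or single-column CSV); images as multi-page TIFF with a
JSON sidecar carrying pixel size and channel names; tables as headered
CSV; truth sidecars and reports as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from cocmatrix.imaging import CocImage
from cocmatrix.kinetics import DistanceSeries
from cocmatrix.nanopore import (
    CalibrationCurve,
    CurrentTrace,
    PolydispersityResult,
    SizedEvent,
)
from cocmatrix.qpcr import CtTable, FoldChangeResult

__all__ = [
    "write_trace",
    "read_trace",
    "write_trace_csv",
    "read_trace_csv",
    "read_calibration_csv",
    "write_calibration_csv",
    "write_coc_image",
    "read_coc_image",
    "write_events_csv",
    "read_ct_csv",
    "write_fold_change_csv",
    "read_distance_series_csv",
    "polydispersity_report",
    "dump_json",
]


def dump_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def write_trace(trace: CurrentTrace, path: str | Path) -> None:
    """Raw little-endian float32 samples at ``path`` + ``<path>.json`` sidecar."""
    path = Path(path)
    trace.samples.astype("<f4").tofile(path)
    dump_json(
        {
            "sampling_hz": trace.sampling_hz,
            "voltage_mv": trace.voltage_mv,
            "acq_filter_hz": trace.acq_filter_hz,
            "source_id": trace.source_id,
            "n_samples": int(trace.samples.size),
            "dtype": "<f4",
        },
        path.with_suffix(path.suffix + ".json"),
    )


def read_trace(path: str | Path) -> CurrentTrace:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    samples = np.fromfile(path, dtype=meta.get("dtype", "<f4"))
    return CurrentTrace(
        samples=samples.astype(float),
        sampling_hz=meta["sampling_hz"],
        voltage_mv=meta.get("voltage_mv"),
        acq_filter_hz=meta.get("acq_filter_hz"),
        source_id=meta.get("source_id", ""),
    )


def write_trace_csv(trace: CurrentTrace, path: str | Path) -> None:
    pd.DataFrame({"current_pa": trace.samples}).to_csv(path, index=False)
    dump_json(
        {"sampling_hz": trace.sampling_hz, "voltage_mv": trace.voltage_mv,
         "acq_filter_hz": trace.acq_filter_hz, "source_id": trace.source_id},
        Path(path).with_suffix(Path(path).suffix + ".json"),
    )


def read_trace_csv(path: str | Path) -> CurrentTrace:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    df = pd.read_csv(path)
    return CurrentTrace(
        samples=df["current_pa"].to_numpy(float),
        sampling_hz=meta["sampling_hz"],
        voltage_mv=meta.get("voltage_mv"),
        acq_filter_hz=meta.get("acq_filter_hz"),
        source_id=meta.get("source_id", ""),
    )


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def read_calibration_csv(path: str | Path) -> CalibrationCurve:
    df = pd.read_csv(path)
    return CalibrationCurve(
        areas_pa_s=df["area_pa_s"].to_numpy(float),
        mw_kda=df["mw_kda"].to_numpy(float),
    )


def write_calibration_csv(cal: CalibrationCurve, path: str | Path) -> None:
    pd.DataFrame({"area_pa_s": cal.areas_pa_s, "mw_kda": cal.mw_kda}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def write_coc_image(image: CocImage, path: str | Path) -> None:
    """Multi-page TIFF ordered (z, channel, y, x) + JSON sidecar."""
    path = Path(path)
    names = sorted(image.channels)
    stack = np.stack([image.channels[n] for n in names], axis=1)  # z,c,y,x
    tifffile.imwrite(path, stack.astype(np.float32), photometric="minisblack")
    dump_json(
        {"pixel_size_um": image.pixel_size_um, "channels": names,
         "coc_id": image.coc_id, "axes": "ZCYX"},
        path.with_suffix(path.suffix + ".json"),
    )


def read_coc_image(path: str | Path) -> CocImage:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    stack = tifffile.imread(path)
    if stack.ndim == 3:  # single z collapsed by the writer
        stack = stack[None, ...]
    names = meta["channels"]
    channels = {n: stack[:, i].astype(float) for i, n in enumerate(names)}
    return CocImage(channels=channels, pixel_size_um=meta["pixel_size_um"],
                    coc_id=meta.get("coc_id", ""))


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_events_csv(sized: Sequence[SizedEvent], path: str | Path) -> None:
    rows = [
        {
            "onset_s": s.event.onset_s,
            "duration_s": s.event.duration_s,
            "mean_depth_pa": s.event.mean_depth_pa,
            "area_pa_s": s.event.area_pa_s,
            "mw_kda": s.mw_kda,
            "flag": s.flag,
        }
        for s in sized
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ct_csv(ct_path: str | Path, sample_sheet_path: str | Path,
                hkgs: tuple[str, ...] | None = None) -> CtTable:
    """Long-format Ct CSV (gene, sample, ct) + sample sheet (sample, group,
    replicate)."""
    long = pd.read_csv(ct_path)
    ct = long.pivot(index="gene", columns="sample", values="ct")
    ct.columns.name = None
    meta = pd.read_csv(sample_sheet_path).set_index("sample")
    kwargs = {} if hkgs is None else {"hkgs": tuple(hkgs)}
    return CtTable(ct=ct, sample_meta=meta, **kwargs)


def write_fold_change_csv(result: FoldChangeResult, path: str | Path) -> None:
    result.table.to_csv(path)


def read_distance_series_csv(path: str | Path) -> list[DistanceSeries]:
    """Long format: coc_id, time_h, distance_um [, mouse_id]."""
    df = pd.read_csv(path)
    out = []
    for coc_id, sub in df.groupby("coc_id", sort=True):
        sub = sub.sort_values("time_h")
        mouse = str(sub["mouse_id"].iloc[0]) if "mouse_id" in sub else ""
        out.append(
            DistanceSeries(
                coc_id=str(coc_id),
                times_h=sub["time_h"].to_numpy(float),
                distances_um=sub["distance_um"].to_numpy(float),
                mouse_id=mouse,
            )
        )
    return out


def polydispersity_report(result: PolydispersityResult) -> dict:
    """JSON-ready polydispersity summary."""
    return {
        "n_events": result.n_events,
        "qc_pass": result.qc_pass,
        "min_events": result.min_events,
        "weighted_avg_mw_kda": result.weighted_avg_mw_kda,
        "number_avg_mw_kda": result.number_avg_mw_kda,
        "fraction_below": {str(int(k)): v for k, v in result.fraction_below.items()},
        "histogram": {
            "edges_kda": result.histogram_edges_kda.tolist(),
            "fraction": result.histogram_fraction.tolist(),
        },
    }
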