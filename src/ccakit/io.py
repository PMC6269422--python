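"""Trace file IO (OME-TIFF and raw binary), configuration, and exports.

Instrument traces arrive as OME-TIFF (T x C planes, channel = detector
element, sampling time in the OME ``TimeIncrement`` attribute) or as raw
little-endian 16-bit unsigned binary, channel-major per timepoint, with the
layout declared in the config file.  Correlation curves and fit results are
exported as CSV/JSON.
"""

from __future__ import annotations

import configparser
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .correlator import CorrelationCurve, TimeTrace

__all__ = [
    "read_trace",
    "write_trace_ome_tiff",
    "write_trace_raw",
    "read_config",
    "default_config",
    "curve_to_frame",
    "write_curves_csv",
]


class TraceFormatError(ValueError):
    pass


def write_trace_ome_tiff(path, trace: TimeTrace) -> None:
    """Write a trace as OME-TIFF, one T x C image, uint16.

    Values are rounded and clipped to the 16-bit range (the instrument's own
    bit depth); the sampling time is stored as the OME TimeIncrement.
    """
    data = np.clip(np.rint(trace.values), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        data[:, :, np.newaxis, np.newaxis],  # axes T, C, Y=1, X=1
        photometric="minisblack",
        metadata={
            "axes": "TCYX",
            "TimeIncrement": trace.t_sample,
            "TimeIncrementUnit": "s",
        },
        ome=True,
    )


def _ome_time_increment(xml: str) -> float | None:
    m = re.search(r'TimeIncrement="([0-9eE.+-]+)"', xml or "")
    return float(m.group(1)) if m else None


def read_trace(
    path,
    format: str | None = None,
    n_channels: int = 32,
    t_sample: float | None = None,
) -> TimeTrace:
    """Read a trace from OME-TIFF or raw binary.

    ``format`` is inferred from the suffix when omitted.  For raw binary the
    layout is little-endian uint16, channel-major per timepoint, and both
    ``n_channels`` and ``t_sample`` must be supplied (typically from the
    config file).  A channel-count mismatch raises a format error; a missing
    sampling time must be provided explicitly.
    """
    path = Path(path)
    if format is None:
        format = "ome-tiff" if path.suffix.lower() in (".tif", ".tiff") else "raw"
    if format == "ome-tiff":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            ts = _ome_time_increment(tf.ome_metadata)
        data = np.asarray(data, dtype=np.float64).reshape(data.shape[0], -1)
        if data.shape[1] != n_channels:
            raise TraceFormatError(
                f"{path} has {data.shape[1]} channels, expected {n_channels}"
            )
        ts = t_sample if t_sample is not None else ts
        if ts is None:
            raise TraceFormatError(
                "sampling time not in OME metadata; pass t_sample explicitly"
            )
        return TimeTrace(data, ts, {"source": str(path)})
    if format == "raw":
        if t_sample is None:
            raise TraceFormatError("raw traces require an explicit t_sample")
        flat = np.fromfile(path, dtype="<u2")
        if flat.size % n_channels:
            raise TraceFormatError(
                f"{path}: {flat.size} samples not divisible by "
                f"{n_channels} channels"
            )
        data = flat.reshape(-1, n_channels).astype(np.float64)
        return TimeTrace(data, t_sample, {"source": str(path)})
    raise TraceFormatError(f"unknown trace format {format!r}")


def write_trace_raw(path, trace: TimeTrace) -> None:
    """Write a trace as raw little-endian uint16, channel-major per timepoint."""
    data = np.clip(np.rint(trace.values), 0, 65535).astype("<u2")
    data.tofile(path)


_DEFAULTS = {
    "detector": {
        "pitch_nm": "50.0",
        "w0_nm": "144.0",
        "waist_slope": "",  # empty = package default
        "aspect_ratio_A": "2.97",
        "channel_map": "",  # comma-separated file-channel order, optional
    },
    "correlator": {
        "points_per_cascade": "16",
        "lag_cap_s": "",
        "n_segments": "8",
    },
    "fits": {
        "gamma": "0.35355339",
        "fit_lo_s": "",
        "fit_hi_s": "",
    },
    "simulation": {
        "D_um2_s": "30.0",
        "n_particles": "100",
        "box_um": "1.0,1.0,2.0",
        "brightness": "0.2",
        "t_sample_s": "2.46e-6",
        "n_steps": "250000",
        "gain": "750.0",
        "offset": "200.0",
        "dark_sigma": "20.0",
    },
}


def default_config() -> configparser.ConfigParser:
    cp = configparser.ConfigParser()
    cp.read_dict(_DEFAULTS)
    return cp


def read_config(path=None) -> configparser.ConfigParser:
    """Config file (INI sections [detector], [correlator], [fits],
    [simulation]) merged over package defaults."""
    cp = default_config()
    if path is not None:
        read = cp.read(path)
        if not read:
            raise FileNotFoundError(f"config file {path} not found")
    return cp


def curve_to_frame(curve: CorrelationCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lag_s": curve.lags,
            "G": curve.values,
            "stderr": curve.stderr,
            "corrected": curve.corrected,
            "kind": curve.kind,
            "channels": str(curve.channel_spec),
        }
    )


def write_curves_csv(path, curves) -> None:
    pd.concat([curve_to_frame(c) for c in curves], ignore_index=True).to_csv(
        path, index=False
    )


def write_json(path, obj) -> None:
    def convert(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=convert))
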