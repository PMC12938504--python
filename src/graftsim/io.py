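"""Trace, frame and report serialization.

Traces travel as CSV files with columns ``time_s, value, units`` plus a
JSON sidecar carrying provenance (sampling rate, kind, seed, config
hash).  Frame stacks are written as multi-page TIFF or a directory of
PNGs, with a JSON sidecar holding fps, calibration and any synthetic
ground truth.  Analysis results are emitted as JSON reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import FrameStack
from .waveforms import SignalTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_frames",
    "read_frames",
    "write_report",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_trace(
    trace: SignalTrace, path: str | Path, seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    """Write a trace as CSV (time_s, value, units) with a metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trace.times,
            "value": trace.samples,
            "units": trace.units,
        }
    )
    df.to_csv(path, index=False)
    meta = {
        "sampling_rate_hz": trace.sampling_rate,
        "start_time_s": trace.start_time,
        "kind": trace.kind,
        "units": trace.units,
        "n_samples": len(trace),
        "seed": seed,
        "config_hash": config_hash,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_trace(path: str | Path) -> SignalTrace:
    """Read a trace CSV written by :func:`write_trace`.

    Falls back to inferring the sampling rate from the time column when
    no sidecar is present.
    """
    path = Path(path)
    df = pd.read_csv(path)
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        rate = meta["sampling_rate_hz"]
        kind = meta.get("kind", "pressure")
        units = meta.get("units", "mmHg")
        start = meta.get("start_time_s", 0.0)
    else:
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise ValueError("cannot infer sampling rate from a single sample")
        rate = 1.0 / float(np.median(np.diff(t)))
        units = str(df["units"].iloc[0]) if "units" in df else "mmHg"
        kind = "flow" if "ml" in units.lower() else "pressure"
        start = float(t[0])
    return SignalTrace(
        df["value"].to_numpy(), rate, start_time=start, kind=kind, units=units
    )


def write_frames(stack: FrameStack, path: str | Path, fmt: str = "tiff") -> None:
    """Write a frame stack as multi-page TIFF (or a PNG directory)."""
    path = Path(path)
    meta = {
        "frame_rate_fps": stack.frame_rate,
        "mm_per_pixel": stack.mm_per_pixel,
        "start_time_s": stack.start_time,
        "n_frames": len(stack),
        **{
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in stack.metadata.items()
        },
    }
    if fmt == "tiff":
        import tifffile

        tifffile.imwrite(path, stack.frames, photometric="minisblack")
        _sidecar(path).write_text(json.dumps(meta, indent=2))
    elif fmt == "png":
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(stack.frames):
            iio.imwrite(path / f"frame_{i:05d}.png", frame)
        (path / "meta.json").write_text(json.dumps(meta, indent=2))
    else:
        raise ValueError(f"unsupported frame format {fmt!r}")


def read_frames(path: str | Path) -> FrameStack:
    """Read a frame stack written by :func:`write_frames`."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(path.glob("frame_*.png"))
        frames = np.stack([iio.imread(f) for f in files])
        meta = json.loads((path / "meta.json").read_text())
    else:
        import tifffile

        frames = tifffile.imread(path)
        meta = json.loads(_sidecar(path).read_text())
    extra = {
        k: v
        for k, v in meta.items()
        if k not in ("frame_rate_fps", "mm_per_pixel", "start_time_s", "n_frames")
    }
    return FrameStack(
        frames=frames,
        frame_rate=meta["frame_rate_fps"],
        mm_per_pixel=meta["mm_per_pixel"],
        start_time=meta.get("start_time_s", 0.0),
        metadata=extra,
    )


def write_report(data: dict, path: str | Path) -> None:
    """Write an analysis report as indented JSON."""
    Path(path).write_text(json.dumps(data, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return str(obj)
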