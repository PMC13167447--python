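"""Frame-stack, ROI and result-table input/output.

Frame sequences are exchanged as multi-page grayscale TIFF stacks with a
JSON sidecar carrying the acquisition metadata (frame rate, channel,
stimulus times, session time).  ROI specifications are small CSV/JSON
tables; quantification results are emitted as a tidy CSV with one row per
(slice, ROI, channel, pulse, metric).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

#: sidecar keys that must be present to interpret a stack
REQUIRED_SIDECAR_KEYS = ("frame_rate_hz", "pulse_times_ms", "channel")

CHANNELS = ("vm", "ca")


@dataclass
class FrameSequence:
    """A time-lapse fluorescence recording: frames x rows x cols.

    ``data`` holds integer camera counts (or float counts for noise-free
    renders); ``channel`` is ``"vm"`` (voltage dye, depolarization lowers
    counts) or ``"ca"`` (Ca2+ indicator, influx raises counts).
    """

    data: np.ndarray
    frame_rate: float  # Hz
    channel: str
    pulse_times: tuple[float, ...] = ()  # ms
    bit_depth: int = 8
    session_time: float = 0.0  # minutes since first recording
    seed: int | None = None
    saturated: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"frame data must be 3-D (t, y, x), got ndim={self.data.ndim}")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if np.issubdtype(self.data.dtype, np.integer):
            hi = 2**self.bit_depth - 1
            if self.data.min() < 0 or self.data.max() > hi:
                raise ValueError(f"integer counts outside [0, {hi}]")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def duration_ms(self) -> float:
        return self.n_frames / self.frame_rate * 1000.0

    @property
    def times_ms(self) -> np.ndarray:
        """Frame timestamps (start of exposure), in ms."""
        return np.arange(self.n_frames) / self.frame_rate * 1000.0


@dataclass(frozen=True)
class RoiSpec:
    """Square region of interest given by its center pixel and side length.

    The pixel block is ``rows [r - side//2, r - side//2 + side)`` and
    likewise for columns (left/top-biased for even sides), matching the
    convention used by the synthetic generator.
    """

    name: str
    center: tuple[int, int]  # (row, col)
    side: int = 50

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError(f"ROI {self.name!r}: side must be positive")

    @property
    def row_slice(self) -> slice:
        r0 = self.center[0] - self.side // 2
        return slice(r0, r0 + self.side)

    @property
    def col_slice(self) -> slice:
        c0 = self.center[1] - self.side // 2
        return slice(c0, c0 + self.side)

    def check_bounds(self, n_rows: int, n_cols: int) -> None:
        rs, cs = self.row_slice, self.col_slice
        if rs.start < 0 or rs.stop > n_rows or cs.start < 0 or cs.stop > n_cols:
            raise ValueError(
                f"ROI {self.name!r} (center={self.center}, side={self.side}) "
                f"falls outside the {n_rows}x{n_cols} field"
            )


def write_frames(seq: FrameSequence, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = seq.data
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError("write_frames expects integer counts; quantize first")
    tifffile.imwrite(path, data.astype(np.uint8 if seq.bit_depth <= 8 else np.uint16))
    sidecar = {
        "frame_rate_hz": seq.frame_rate,
        "pulse_times_ms": list(seq.pulse_times),
        "channel": seq.channel,
        "bit_depth": seq.bit_depth,
        "session_time_min": seq.session_time,
        "seed": seq.seed,
        "saturated": seq.saturated,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_frames(path: str | Path) -> FrameSequence:
    """Read a TIFF stack written by :func:`write_frames` (lossless round-trip)."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_path.name}; required keys: "
            + ", ".join(REQUIRED_SIDECAR_KEYS)
        )
    meta = json.loads(sidecar_path.read_text())
    missing = [k for k in REQUIRED_SIDECAR_KEYS if k not in meta]
    if missing:
        raise KeyError(f"sidecar {sidecar_path.name} missing required keys: {', '.join(missing)}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return FrameSequence(
        data=data,
        frame_rate=float(meta["frame_rate_hz"]),
        channel=meta["channel"],
        pulse_times=tuple(meta["pulse_times_ms"]),
        bit_depth=int(meta.get("bit_depth", 8)),
        session_time=float(meta.get("session_time_min", 0.0)),
        seed=meta.get("seed"),
        saturated=bool(meta.get("saturated", False)),
    )


def read_roi_spec(path: str | Path, field_shape: tuple[int, int] | None = None) -> list[RoiSpec]:
    """Read ROI definitions from CSV (name, center_row, center_col, side) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path).to_dict("records")
    rois = []
    for rec in records:
        roi = RoiSpec(
            name=str(rec["name"]),
            center=(int(rec["center_row"]), int(rec["center_col"])),
            side=int(rec.get("side", 50)),
        )
        if field_shape is not None:
            roi.check_bounds(*field_shape)
        rois.append(roi)
    return rois


def write_roi_spec(rois: Sequence[RoiSpec], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {"name": r.name, "center_row": r.center[0], "center_col": r.center[1], "side": r.side}
            for r in rois
        ]
    ).to_csv(path, index=False)
    return path


def write_results(
    result,
    path: str | Path,
    slice_id: str = "slice",
    diagnostics: bool = False,
) -> Path:
    """Write a SliceResult as tidy CSV: slice_id, roi, channel, pulse_index, metric, value.

    The default output contains exactly the core quantification parameters
    (one row each); ``diagnostics=True`` appends per-pulse peak amplitudes
    and times.
    """
    path = Path(path)
    df = result.to_frame(slice_id=slice_id, diagnostics=diagnostics)
    df.to_csv(path, index=False)
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_activity_map(amap, out_dir: str | Path, prefix: str = "map") -> list[Path]:
    """Export an ActivityMap as one float32 TIFF image per instant."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for image, t in zip(amap.images, amap.instants_ms):
        path = out_dir / f"{prefix}_{amap.channel}_{t:g}ms.tif"
        tifffile.imwrite(path, image.astype(np.float32))
        paths.append(path)
    return paths


def results_to_frame(rows: Mapping[str, float], slice_id: str = "slice") -> pd.DataFrame:
    """Convert a flat {parameter: value} mapping to the tidy result schema."""
    records = []
    for key, value in rows.items():
        roi, channel, metric, pulse = _split_parameter_key(key)
        records.append(
            {
                "slice_id": slice_id,
                "roi": roi,
                "channel": channel,
                "pulse_index": pulse,
                "metric": metric,
                "value": value,
            }
        )
    return pd.DataFrame(records)


def _split_parameter_key(key: str):
    # canonical parameter keys look like "roi2_vm_ppr" or "roi1_ca_dt1"
    roi, channel, metric = key.split("_", 2)
    pulse: int | None = None
    if metric.endswith(("1", "2")):
        pulse = int(metric[-1])
        metric = metric[:-1]
    return roi, channel, metric, pulse
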