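"""Read/write multi-timepoint, multi-channel z-stacks and compute MIPs.

Two on-disk dialects are supported:

* a single OME-TIFF with TCZYX axes and physical pixel sizes in the OME
  metadata, or
* a directory of plain multi-page TIFFs named ``t{minutes:03d}_ch{label}.tif``
  plus a ``metadata.yaml`` sidecar carrying the acquisition metadata.

Physical calibration (pixel size, timepoints) is never defaulted silently:
loading fails hard when it is absent, because every downstream morphometric
quantity is reported in micrometers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml


class StackIOError(ValueError):
    """Raised for unreadable, inconsistent, or under-specified stacks."""


@dataclass
class TimeSeriesStack:
    """Ordered multi-timepoint, multi-channel z-stacks with physical metadata.

    ``data`` has axes (T, C, Z, Y, X). Timepoints are minutes post tracer
    injection and must be strictly increasing; all frames share one shape and
    channel set by construction.
    """

    data: np.ndarray
    timepoints_min: tuple[float, ...]
    channel_labels: tuple[str, ...]
    pixel_size_um: float
    layer_spacing_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise StackIOError("data must have (T, C, Z, Y, X) axes")
        if self.data.shape[0] != len(self.timepoints_min):
            raise StackIOError("timepoint count does not match data")
        if self.data.shape[1] != len(self.channel_labels):
            raise StackIOError("channel count does not match data")
        tp = np.asarray(self.timepoints_min, dtype=float)
        if tp.size and np.any(np.diff(tp) <= 0):
            raise StackIOError("timepoints must be strictly increasing")
        if self.pixel_size_um <= 0 or self.layer_spacing_um <= 0:
            raise StackIOError("physical spacings must be positive")
        if np.issubdtype(self.data.dtype, np.floating) and np.any(self.data < 0):
            raise StackIOError("intensities must be >= 0")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[-2:]

    @property
    def n_layers(self) -> int:
        return self.data.shape[2]

    def volume(self, timepoint_min: float, channel: str) -> np.ndarray:
        """The (Z, Y, X) volume for one timepoint and channel."""
        try:
            ci = self.channel_labels.index(channel)
        except ValueError:
            raise StackIOError(
                f"channel {channel!r} not in {self.channel_labels}") from None
        ti = int(np.argmin(np.abs(np.asarray(self.timepoints_min) - timepoint_min)))
        if abs(self.timepoints_min[ti] - timepoint_min) > 0.5:
            raise StackIOError(f"no timepoint within 0.5 min of {timepoint_min}")
        return self.data[ti, ci]


@dataclass
class ProjectedImage:
    """Maximal-intensity projection of one volume: each pixel is the maximum
    over z of the source stack at that (y, x)."""

    image: np.ndarray
    timepoint_min: float
    channel: str
    pixel_size_um: float


def max_project(volume: np.ndarray, timepoint_min: float = 0.0,
                channel: str = "", pixel_size_um: float = 1.0) -> ProjectedImage:
    """Pointwise maximum over z of a (Z, Y, X) volume."""
    volume = np.asarray(volume)
    if volume.ndim != 3 or volume.shape[0] < 1:
        raise StackIOError("volume must be (Z, Y, X) with >= 1 layer")
    return ProjectedImage(image=volume.max(axis=0),
                          timepoint_min=timepoint_min, channel=channel,
                          pixel_size_um=pixel_size_um)


_FNAME_RE = re.compile(r"^t(\d+)_ch(.+)\.tiff?$")


def save_timeseries(stack: TimeSeriesStack, path: str | Path,
                    dialect: str = "ome") -> Path:
    """Write a stack as one OME-TIFF ('ome') or a per-timepoint-per-channel
    TIFF directory with a metadata.yaml sidecar ('dir')."""
    path = Path(path)
    if dialect == "ome":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(
            path, stack.data, photometric="minisblack",
            metadata={
                "axes": "TCZYX",
                "PhysicalSizeX": stack.pixel_size_um,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": stack.pixel_size_um,
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeZ": stack.layer_spacing_um,
                "PhysicalSizeZUnit": "µm",
                "Channel": {"Name": list(stack.channel_labels)},
                "TimeIncrementUnit": "min",
                "TimepointsMin": list(stack.timepoints_min),
            })
        return path
    if dialect == "dir":
        path.mkdir(parents=True, exist_ok=True)
        for ti, t in enumerate(stack.timepoints_min):
            for ci, ch in enumerate(stack.channel_labels):
                tifffile.imwrite(path / f"t{int(round(t)):03d}_ch{ch}.tif",
                                 stack.data[ti, ci],
                                 photometric="minisblack")
        meta = {
            "pixel_size_um": float(stack.pixel_size_um),
            "layer_spacing_um": float(stack.layer_spacing_um),
            "timepoints_min": [float(t) for t in stack.timepoints_min],
            "channel_labels": list(stack.channel_labels),
        }
        (path / "metadata.yaml").write_text(yaml.safe_dump(meta))
        return path
    raise StackIOError(f"unknown dialect {dialect!r}")


def load_timeseries(path: str | Path) -> TimeSeriesStack:
    """Load a time series written by :func:`save_timeseries`.

    A file path is read as OME-TIFF; a directory is scanned for the
    ``t{mm}_ch{label}.tif`` pattern and requires the metadata sidecar.
    Missing physical metadata is a hard error.
    """
    path = Path(path)
    if path.is_dir():
        return _load_dir(path)
    if not path.exists():
        raise StackIOError(f"no such stack: {path}")
    return _load_ome(path)


def _load_ome(path: Path) -> TimeSeriesStack:
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if not meta and tf.ome_metadata:
            meta = {}
    order = {ax: i for i, ax in enumerate(axes)}
    missing = set("TCZYX") - set(order)
    if missing:
        raise StackIOError(f"OME-TIFF axes {axes!r} lack {sorted(missing)}")
    data = np.transpose(data, [order[a] for a in "TCZYX"])
    px = meta.get("PhysicalSizeX")
    dz = meta.get("PhysicalSizeZ")
    tps = meta.get("TimepointsMin")
    chans = meta.get("Channel", {}).get("Name") if isinstance(meta.get("Channel"), dict) else None
    if px is None or dz is None:
        raise StackIOError("pixel size / layer spacing missing from OME metadata")
    if tps is None:
        raise StackIOError("timepoints missing from OME metadata")
    if chans is None:
        chans = [f"ch{i}" for i in range(data.shape[1])]
    return TimeSeriesStack(data=data, timepoints_min=tuple(float(t) for t in tps),
                           channel_labels=tuple(chans),
                           pixel_size_um=float(px), layer_spacing_um=float(dz))


def _load_dir(path: Path) -> TimeSeriesStack:
    meta_path = path / "metadata.yaml"
    if not meta_path.exists():
        raise StackIOError(f"metadata.yaml sidecar missing in {path}")
    meta = yaml.safe_load(meta_path.read_text())
    for key in ("pixel_size_um", "layer_spacing_um", "timepoints_min",
                "channel_labels"):
        if key not in meta:
            raise StackIOError(f"metadata.yaml lacks required key {key!r}")
    tps = [float(t) for t in meta["timepoints_min"]]
    chans = [str(c) for c in meta["channel_labels"]]
    frames = []
    shape = None
    for t in tps:
        per_chan = []
        for ch in chans:
            f = path / f"t{int(round(t)):03d}_ch{ch}.tif"
            if not f.exists():
                raise StackIOError(f"missing frame file {f.name}")
            arr = tifffile.imread(f)
            if arr.ndim == 2:
                arr = arr[None]
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise StackIOError(
                    f"frame shape mismatch: {f.name} has {arr.shape}, "
                    f"expected {shape}")
            per_chan.append(arr)
        frames.append(per_chan)
    data = np.asarray(frames)
    return TimeSeriesStack(data=data, timepoints_min=tuple(tps),
                           channel_labels=tuple(chans),
                           pixel_size_um=float(meta["pixel_size_um"]),
                           layer_spacing_um=float(meta["layer_spacing_um"]))
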