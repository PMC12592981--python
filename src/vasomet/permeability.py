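"""Blood-brain-barrier leakage from tracer fluorescence time series.

Leakage is quantified as the outside/inside (O/I) ratio: mean extravascular
fluorescence divided by mean intravascular fluorescence on each timepoint's
maximal-intensity projection, using one fixed vessel mask for the whole
session. The ratio is dimensionless and invariant to global gain and to the
multiplicative signal loss from renal tracer clearance — which is why it is
used instead of raw intensities. The summary statistic is the leakage delta,
O/I at 60 min minus O/I at 5 min post injection.

A perivascular guard band (mask dilation excluded from both regions, default
2 px) keeps PSF-blurred vessel edges out of the "outside" estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from vasomet.segmentation import VesselMask
from vasomet.stack_io import ProjectedImage, TimeSeriesStack, max_project

_S8 = ndimage.generate_binary_structure(2, 2)


class PermeabilityError(ValueError):
    """Raised for undefined ratios or missing timepoints/channels."""


@dataclass
class OITrace:
    """Outside/inside ratio per timepoint for one channel."""

    channel: str
    timepoints_min: tuple[float, ...]
    oi_ratios: tuple[float, ...]
    guard_band_px: int = 2
    mask_provenance: dict | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timepoint_min": self.timepoints_min,
                             "oi_ratio": self.oi_ratios,
                             "channel": self.channel})


@dataclass
class LeakageDelta:
    """O/I(late) - O/I(early); the session's summary permeability value."""

    channel: str
    value: float
    t_early_min: float = 5.0
    t_late_min: float = 60.0


def oi_ratio(image: ProjectedImage | np.ndarray, mask: VesselMask | np.ndarray,
             guard_band_px: int = 2, min_region_px: int = 100) -> float:
    """Mean extravascular / mean intravascular fluorescence.

    Inside is the mean over the mask; outside is the mean over the complement
    of the mask dilated by ``guard_band_px``. Both regions must hold at least
    ``min_region_px`` pixels and the inside mean must be positive.
    """
    img = np.asarray(image.image if isinstance(image, ProjectedImage) else image,
                     dtype=float)
    m = np.asarray(mask.mask if isinstance(mask, VesselMask) else mask,
                   dtype=bool)
    if img.shape != m.shape:
        raise PermeabilityError(
            f"image shape {img.shape} does not match mask {m.shape}")
    if guard_band_px > 0:
        guarded = ndimage.binary_dilation(m, structure=_S8,
                                          iterations=guard_band_px)
    else:
        guarded = m
    outside = ~guarded
    if m.sum() < min_region_px or outside.sum() < min_region_px:
        raise PermeabilityError(
            f"need >= {min_region_px} px inside and outside "
            f"(got {int(m.sum())} / {int(outside.sum())})")
    inside_mean = img[m].mean()
    if inside_mean == 0:
        raise PermeabilityError("inside mean is zero: O/I undefined")
    return float(img[outside].mean() / inside_mean)


def oi_timeseries(ts: TimeSeriesStack, mask: VesselMask, channel: str,
                  guard_band_px: int = 2) -> OITrace:
    """O/I per timepoint with one fixed mask (MIP computed per timepoint).

    The mask is taken from the earliest frame and held fixed: re-segmenting
    later frames would absorb leaked tracer into "vessel" and bias the ratio
    downward.
    """
    if channel not in ts.channel_labels:
        raise PermeabilityError(
            f"channel {channel!r} not in {ts.channel_labels}")
    ratios = []
    for t in ts.timepoints_min:
        proj = max_project(ts.volume(t, channel), t, channel, ts.pixel_size_um)
        ratios.append(oi_ratio(proj, mask, guard_band_px))
    return OITrace(channel=channel, timepoints_min=tuple(ts.timepoints_min),
                   oi_ratios=tuple(ratios), guard_band_px=guard_band_px,
                   mask_provenance=dict(mask.provenance))


def leakage_delta(trace: OITrace, t_early_min: float = 5.0,
                  t_late_min: float = 60.0,
                  tolerance_min: float = 0.5) -> LeakageDelta:
    """O/I at the late timepoint minus O/I at the early timepoint."""
    tp = np.asarray(trace.timepoints_min, dtype=float)

    def _pick(t: float) -> float:
        i = int(np.argmin(np.abs(tp - t)))
        if abs(tp[i] - t) > tolerance_min:
            raise PermeabilityError(
                f"no timepoint within {tolerance_min} min of {t} min")
        return trace.oi_ratios[i]

    return LeakageDelta(channel=trace.channel,
                        value=float(_pick(t_late_min) - _pick(t_early_min)),
                        t_early_min=t_early_min, t_late_min=t_late_min)
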