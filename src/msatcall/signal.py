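"""Fluorescence signal processing: peak delineation, baseline
subtraction and inter-channel crosstalk flagging.

Peaks are delineated directly on the raw trace — no smoothing filter is
applied; the prominence requirement is what rejects noise.  Crosstalk
("pull-up") is flagged, never subtracted: the source channel's signal is
left untouched and flagged peaks are simply ignored downstream by the
ladder matcher and the allele caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .abif import Chromatogram

__all__ = [
    "Peak",
    "detect_peaks",
    "subtract_baseline",
    "flag_crosstalk",
    "DEFAULT_MIN_HEIGHT",
    "DEFAULT_MIN_PROMINENCE_RATIO",
    "DEFAULT_APEX_TOLERANCE",
    "DEFAULT_SHAPE_SIMILARITY_MIN",
    "DEFAULT_HEIGHT_RATIO_MAX",
]

DEFAULT_MIN_HEIGHT = 20
DEFAULT_MIN_PROMINENCE_RATIO = 0.5
DEFAULT_APEX_TOLERANCE = 3
DEFAULT_SHAPE_SIMILARITY_MIN = 0.9
DEFAULT_HEIGHT_RATIO_MAX = 0.2


@dataclass
class Peak:
    """A delineated fluorescence peak on one channel.

    ``start_scan``/``end_scan`` are the flanking minima bounding the
    peak; ``apex_scan`` the local maximum between them.  ``height`` is
    the apex fluorescence, ``area`` the summed fluorescence over the
    peak's scan range.  ``saturated_width`` (scans) stands in for height
    when the camera clipped the apex.  ``size`` in base pairs is filled
    in once a sizing fit exists.
    """

    channel: int
    start_scan: int
    apex_scan: int
    end_scan: int
    height: float
    area: float
    saturated: bool = False
    saturated_width: int = 0
    crosstalk: bool = False
    crosstalk_source: int | None = None
    size: float | None = None

    def __post_init__(self) -> None:
        if not self.start_scan <= self.apex_scan <= self.end_scan:
            raise ValueError("peak scans out of order")


def detect_peaks(
    trace,
    min_height: float = DEFAULT_MIN_HEIGHT,
    min_prominence_ratio: float = DEFAULT_MIN_PROMINENCE_RATIO,
    channel: int = 0,
    saturation_regions: list[tuple[int, int, int]] | None = None,
) -> list[Peak]:
    """Delineate peaks in a single fluorescence trace.

    A scan qualifies as an apex when it is a local maximum whose level
    is at least ``min_height`` absolute units AND exceeds both flanking
    minima by at least ``min_prominence_ratio`` times its own level.
    The peak extends from the left flanking minimum to the right one;
    returned peaks are sorted by apex and have non-overlapping interiors.

    ``saturation_regions`` (``(channel, start, end)`` half-open tuples)
    mark peaks whose apex range was clipped by the camera; such peaks
    carry the clipped width in ``saturated_width``.
    """
    arr = np.asarray(trace, dtype=float)
    if arr.size == 0:
        raise ValueError("empty trace")
    if min_height <= 0:
        raise ValueError("min_height must be positive")
    n = arr.size

    # candidate apexes: strict rise before, non-rise after (plateau apexes
    # resolve to the first scan of the plateau top)
    peaks: list[Peak] = []
    sat = [
        (s, e) for (c, s, e) in (saturation_regions or []) if c == channel
    ]

    i = 1
    last_end = 0
    while i < n - 1:
        if arr[i] >= arr[i - 1] and arr[i] >= arr[i + 1] and arr[i] >= min_height:
            # extend over a flat top
            j = i
            while j + 1 < n and arr[j + 1] == arr[i]:
                j += 1
            if j + 1 < n and arr[j + 1] > arr[i]:
                i = j + 1
                continue
            apex = (i + j) // 2
            level = arr[apex]
            # walk to flanking minima
            left = i
            while left > last_end and arr[left - 1] <= arr[left]:
                left -= 1
            right = j
            while right < n - 1 and arr[right + 1] <= arr[right]:
                right += 1
            elev = level - max(arr[left], arr[right])
            if elev >= min_prominence_ratio * level:
                height = float(level)
                area = float(arr[left : right + 1].sum())
                sat_width = 0
                for s, e in sat:
                    if s <= apex < e or (left <= s and e <= right + 1):
                        sat_width = max(sat_width, e - s)
                peaks.append(
                    Peak(
                        channel=channel,
                        start_scan=int(left),
                        apex_scan=int(apex),
                        end_scan=int(right),
                        height=height,
                        area=area,
                        saturated=sat_width > 0,
                        saturated_width=sat_width,
                    )
                )
                last_end = right
                i = right + 1
                continue
            i = j + 1
        else:
            i += 1
    return peaks


def subtract_baseline(trace, peaks: list[Peak], mode: str = "relative-elevation"):
    """Subtract the piecewise baseline anchored at peak start/end points.

    The baseline runs linearly from each peak's start level to its end
    level, so both anchor points land at level zero in the output.  Two
    modes exist:

    * ``"absolute-height"`` — each apex keeps its original fluorescence
      value (the in-peak residual signal is rescaled accordingly);
    * ``"relative-elevation"`` — each apex keeps its elevation above the
      local baseline (plain subtraction).

    Between peaks the output is zero.  Signals too faint to contain any
    peak are returned unchanged.  Negative values are clamped to zero.
    """
    if mode not in ("absolute-height", "relative-elevation"):
        raise ValueError(f"unknown baseline mode: {mode}")
    arr = np.asarray(trace, dtype=float)
    if not peaks:
        return arr.copy()
    out = np.zeros_like(arr)
    for p in peaks:
        s, e = p.start_scan, p.end_scan
        if e <= s:
            continue
        xs = np.arange(s, e + 1)
        base = np.interp(xs, [s, e], [arr[s], arr[e]])
        seg = arr[s : e + 1] - base
        if mode == "absolute-height":
            apex_val = arr[p.apex_scan]
            apex_resid = apex_val - base[p.apex_scan - s]
            if apex_resid > 0 and apex_val > 0:
                seg = seg * (apex_val / apex_resid)
        out[s : e + 1] = np.maximum(seg, 0.0)
    return out


def _shape_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two co-located peak windows."""
    if a.size < 3 or b.size < 3:
        return 0.0
    n = min(a.size, b.size)
    a, b = a[:n].astype(float), b[:n].astype(float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _intensity_rank(peak: Peak) -> tuple[int, float]:
    # saturated peaks rank above all unsaturated ones, ordered by the
    # width of the clipped region (height no longer reflects DNA amount)
    if peak.saturated:
        return (1, float(peak.saturated_width))
    return (0, float(peak.height))


def flag_crosstalk(
    chromatogram: Chromatogram,
    peaks_per_channel: list[list[Peak]],
    apex_tolerance: int = DEFAULT_APEX_TOLERANCE,
    shape_similarity_min: float = DEFAULT_SHAPE_SIMILARITY_MIN,
    height_ratio_max: float = DEFAULT_HEIGHT_RATIO_MAX,
) -> list[list[Peak]]:
    """Flag peaks caused by spectral bleed from another channel.

    A peak P on channel c is flagged with source c' when a co-located
    peak Q on channel c' (apexes within ``apex_tolerance`` scans) exists
    such that P is small relative to Q (height ratio at most
    ``height_ratio_max``), the two peak windows correlate in shape at
    least ``shape_similarity_min``, and Q is the dominant peak at that
    position across all channels.  Saturated candidates are ranked by
    saturated width rather than clipped height.  Flags are written in
    place; the source peak is never altered.
    """
    all_peaks = [p for ch in peaks_per_channel for p in ch]
    for c, plist in enumerate(peaks_per_channel):
        for p in plist:
            # co-located peaks on other channels
            coloc = [
                q
                for q in all_peaks
                if q.channel != c and abs(q.apex_scan - p.apex_scan) <= apex_tolerance
            ]
            if not coloc:
                continue
            dominant = max(coloc + [p], key=_intensity_rank)
            if dominant is p:
                continue  # the tallest co-located peak is never flagged
            q = dominant
            if q.saturated:
                ratio_ok = True  # clipped height cannot be trusted; width already dominates
            else:
                ratio_ok = p.height / q.height <= height_ratio_max
            if not ratio_ok:
                continue
            s = min(p.start_scan, q.start_scan)
            e = max(p.end_scan, q.end_scan)
            wa = np.asarray(chromatogram.channels[c][s : e + 1], dtype=float)
            wb = np.asarray(chromatogram.channels[q.channel][s : e + 1], dtype=float)
            if _shape_correlation(wa, wb) >= shape_similarity_min:
                p.crosstalk = True
                p.crosstalk_source = q.channel
    return peaks_per_channel


def noise_threshold(trace, k: float = 8.0) -> float:
    """Absolute fluorescence level a peak must clear to beat the noise.

    Robustly estimated as median + k * sigma, with sigma from the median
    absolute deviation.  Chromatogram background is a roughly constant
    baseline plus sensor noise, both of which the median/MAD capture
    while ignoring the sparse peaks.
    """
    arr = np.asarray(trace, dtype=float)
    med = float(np.median(arr))
    sigma = 1.4826 * float(np.median(np.abs(arr - med)))
    return med + k * sigma


def detect_all_channels(
    chromatogram: Chromatogram,
    min_height: float = DEFAULT_MIN_HEIGHT,
    min_prominence_ratio: float = DEFAULT_MIN_PROMINENCE_RATIO,
    apex_tolerance: int = DEFAULT_APEX_TOLERANCE,
    shape_similarity_min: float = DEFAULT_SHAPE_SIMILARITY_MIN,
    height_ratio_max: float = DEFAULT_HEIGHT_RATIO_MAX,
) -> list[list[Peak]]:
    """Detect peaks on every channel and flag crosstalk between them.

    The absolute-level threshold per channel is the larger of
    ``min_height`` and the channel's estimated noise ceiling, so a
    non-zero baseline does not drown detection in noise bumps.
    """
    per_channel = [
        detect_peaks(
            chromatogram.channels[c],
            min_height=max(min_height, noise_threshold(chromatogram.channels[c])),
            min_prominence_ratio=min_prominence_ratio,
            channel=c,
            saturation_regions=chromatogram.saturation_regions,
        )
        for c in range(chromatogram.n_channels)
    ]
    return flag_crosstalk(
        chromatogram,
        per_channel,
        apex_tolerance=apex_tolerance,
        shape_similarity_min=shape_similarity_min,
        height_ratio_max=height_ratio_max,
    )
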