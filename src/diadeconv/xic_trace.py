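"""Extracted-ion-chromatogram tracing across retention time.

Per-merged-frame :class:`~diadeconv.feature_detect.Peak2D` lists are linked
frame to frame into :class:`XICFeature` traces, each trace is bounded around
its apex so the chromatogram is bell-shaped, and traces whose endpoints were
never found (``extended_flag``) are segmented into separate peaks with
Savitzky-Golay smoothing followed by rolling Z-score peak detection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .feature_detect import Peak2D

__all__ = ["XICFeature", "trace", "bound", "zscore_segment", "zscore_signals"]


@dataclass
class XICFeature:
    """A traced signal: 2D peak attributes frozen at the apex frame plus an
    RT intensity trace with apex and boundaries."""

    mz: float
    im: float
    mz_range: tuple[float, float]
    im_range: tuple[float, float]
    rt_trace: list[tuple[int, float, float]]  # (frame_id, rt_seconds, intensity)
    apex_index: int
    rt_start: float
    rt_end: float
    apex_intensity: float
    area: float
    ms_level: int
    window_id: Optional[int] = None
    extended_flag: bool = False

    @property
    def apex_rt(self) -> float:
        return self.rt_trace[self.apex_index][1]

    @property
    def intensities(self) -> np.ndarray:
        return np.array([e[2] for e in self.rt_trace])

    @property
    def rts(self) -> np.ndarray:
        return np.array([e[1] for e in self.rt_trace])


def _area(entries: Sequence[tuple[int, float, float]]) -> float:
    if len(entries) < 2:
        return float(entries[0][2]) if entries else 0.0
    rts = np.array([e[1] for e in entries])
    ys = np.array([e[2] for e in entries])
    return float(np.trapezoid(ys, rts))


def _make_feature(entries: list[tuple[int, float, float]], apex_peak: Peak2D,
                  ms_level: int, window_id: Optional[int],
                  extended: bool = False) -> XICFeature:
    ys = [e[2] for e in entries]
    apex_idx = int(np.argmax(ys))  # argmax takes the earliest of equal maxima
    return XICFeature(
        mz=apex_peak.mz_center,
        im=apex_peak.im_center,
        mz_range=apex_peak.mz_range,
        im_range=apex_peak.im_range,
        rt_trace=entries,
        apex_index=apex_idx,
        rt_start=entries[0][1],
        rt_end=entries[-1][1],
        apex_intensity=float(ys[apex_idx]),
        area=_area(entries),
        ms_level=ms_level,
        window_id=window_id,
        extended_flag=extended,
    )


# ---------------------------------------------------------------------------
# linking


class _Active:
    __slots__ = ("entries", "peaks", "gap", "last_peak")

    def __init__(self, frame_idx: int, peak: Peak2D):
        self.entries: list[tuple[int, Peak2D | None]] = [(frame_idx, peak)]
        self.gap = 0
        self.last_peak = peak


def trace(peaks_by_frame: Sequence[Sequence[Peak2D]],
          mz_tol_ppm: float = 10.0,
          im_tol: float = 0.01,
          gap_max: int = 1,
          frame_meta: Optional[Sequence[tuple[int, float]]] = None,
          ms_level: int = 1,
          window_id: Optional[int] = None,
          min_trace_len: int = 1) -> list[XICFeature]:
    """Greedily link peaks of consecutive merged frames into XIC traces.

    A trace claims at most one peak per frame: the unclaimed peak nearest in
    m/z among those within ``mz_tol_ppm`` (of the trace's current m/z) and
    ``im_tol``.  A trace ends after ``gap_max`` consecutive unmatched frames;
    skipped frames inside a trace contribute zero-intensity entries.  The
    result does not depend on the ordering of peaks inside a frame list.
    """
    if frame_meta is None:
        frame_meta = []
        for idx, peaks in enumerate(peaks_by_frame):
            if peaks:
                p = peaks[0]
                frame_meta.append((p.center_frame_id, p.rt_seconds))
            else:
                frame_meta.append((-(idx + 1), float(idx)))

    active: list[_Active] = []
    done: list[_Active] = []
    for fidx, peaks in enumerate(peaks_by_frame):
        pool = sorted(peaks, key=lambda p: (p.mz_center, p.im_center))
        claimed = [False] * len(pool)
        still: list[_Active] = []
        for tr in active:
            ref = tr.last_peak
            tol_mz = ref.mz_center * mz_tol_ppm * 1e-6
            best, best_d = -1, None
            for k, p in enumerate(pool):
                if claimed[k]:
                    continue
                d = abs(p.mz_center - ref.mz_center)
                if d <= tol_mz and abs(p.im_center - ref.im_center) <= im_tol:
                    if best_d is None or d < best_d:
                        best, best_d = k, d
            if best >= 0:
                claimed[best] = True
                tr.entries.append((fidx, pool[best]))
                tr.last_peak = pool[best]
                tr.gap = 0
                still.append(tr)
            else:
                tr.gap += 1
                if tr.gap > gap_max:
                    done.append(tr)
                else:
                    still.append(tr)
        active = still
        for k, p in enumerate(pool):
            if not claimed[k]:
                active.append(_Active(fidx, p))
    done.extend(active)

    out: list[XICFeature] = []
    for tr in done:
        first = tr.entries[0][0]
        last = tr.entries[-1][0]
        by_frame = {fi: p for fi, p in tr.entries}
        entries: list[tuple[int, float, float]] = []
        for fi in range(first, last + 1):
            fid, rt = frame_meta[fi]
            p = by_frame.get(fi)
            entries.append((fid, rt, p.summed_intensity if p is not None else 0.0))
        if len(entries) < min_trace_len:
            continue
        ys = [e[2] for e in entries]
        apex_rel = int(np.argmax(ys))
        apex_peak = by_frame[sorted(by_frame)[0]]
        # freeze attributes at the apex frame (fall back to nearest linked frame)
        apex_fi = first + apex_rel
        if apex_fi in by_frame:
            apex_peak = by_frame[apex_fi]
        else:
            nearest = min(by_frame, key=lambda fi: (abs(fi - apex_fi), fi))
            apex_peak = by_frame[nearest]
        out.append(_make_feature(entries, apex_peak, ms_level, window_id))
    out.sort(key=lambda f: (f.rt_trace[0][1], f.mz, f.im))
    return out


# ---------------------------------------------------------------------------
# apex boundaries


def bound(xic: XICFeature, valley_frac: float = 0.1) -> XICFeature:
    """Walk outward from the apex to the first sub-threshold point or valley.

    Each side stops at the first intensity below ``valley_frac *
    apex_intensity`` (that point is kept as the boundary) or at a local
    valley (intensity rising again; the valley point is the boundary).  A
    side that reaches the end of the trace without either marks the feature
    extended on that side.
    """
    ys = xic.intensities
    n = len(ys)
    if n == 0:
        raise ValueError("empty trace")
    apex = xic.apex_index
    thresh = valley_frac * ys[apex]

    right, ext_right = n - 1, True
    for j in range(apex + 1, n):
        if ys[j] < thresh:
            right, ext_right = j, False
            break
        if ys[j] > ys[j - 1]:
            right, ext_right = j - 1, False
            break
    left, ext_left = 0, True
    for j in range(apex - 1, -1, -1):
        if ys[j] < thresh:
            left, ext_left = j, False
            break
        if ys[j] > ys[j + 1]:
            left, ext_left = j + 1, False
            break
    entries = xic.rt_trace[left : right + 1]
    new = replace(
        xic,
        rt_trace=entries,
        apex_index=apex - left,
        rt_start=entries[0][1],
        rt_end=entries[-1][1],
        area=_area(entries),
        extended_flag=bool(ext_left or ext_right),
    )
    return new


# ---------------------------------------------------------------------------
# elongated-peak segmentation


def zscore_signals(y: np.ndarray, lag: int, threshold: float,
                   influence: float) -> np.ndarray:
    """Rolling-statistics Z-score peak detector (positive excursions only).

    Marks position ``i`` as signal when ``y[i]`` exceeds the rolling mean of
    the influence-filtered series by more than ``threshold`` rolling standard
    deviations.  Returns a 0/1 array of the same length as ``y``.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    signals = np.zeros(n, dtype=np.int64)
    if n <= lag:
        return signals
    filt = y.copy()
    avg = float(np.mean(y[:lag]))
    std = float(np.std(y[:lag]))
    for i in range(lag, n):
        if std > 0 and y[i] - avg > threshold * std:
            signals[i] = 1
            filt[i] = influence * y[i] + (1.0 - influence) * filt[i - 1]
        else:
            filt[i] = y[i]
        window = filt[i - lag + 1 : i + 1]
        avg = float(np.mean(window))
        std = float(np.std(window))
    return signals


def zscore_segment(xic: XICFeature, sg_window: int = 5, sg_order: int = 2,
                   lag: int = 5, z_threshold: float = 3.0,
                   influence: float = 0.5,
                   valley_frac: float = 0.1) -> list[XICFeature]:
    """Split an elongated trace into separate bell-shaped sub-features.

    The trace is Savitzky-Golay smoothed and scanned with
    :func:`zscore_signals`; each contiguous above-threshold region becomes a
    sub-feature re-bounded with :func:`bound`.  Traces too short to smooth,
    or with no detected region, are returned unchanged (as a single-element
    list).
    """
    ys = xic.intensities
    if len(ys) <= sg_window:
        return [xic]
    smoothed = savgol_filter(ys, sg_window, sg_order)
    sig = zscore_signals(smoothed, lag, z_threshold, influence)
    regions: list[tuple[int, int]] = []
    start = None
    for i, s in enumerate(sig):
        if s and start is None:
            start = i
        elif not s and start is not None:
            regions.append((start, i - 1))
            start = None
    if start is not None:
        regions.append((start, len(sig) - 1))
    if not regions:
        return [xic]

    out = []
    for a, b in regions:
        entries = xic.rt_trace[a : b + 1]
        sub_ys = [e[2] for e in entries]
        apex = int(np.argmax(sub_ys))
        sub = replace(
            xic,
            rt_trace=entries,
            apex_index=apex,
            rt_start=entries[0][1],
            rt_end=entries[-1][1],
            apex_intensity=float(sub_ys[apex]),
            area=_area(entries),
            extended_flag=False,
        )
        out.append(bound(sub, valley_frac))
    return out
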