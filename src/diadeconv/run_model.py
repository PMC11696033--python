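"""In-memory model of a diaPASEF-style run and its on-disk fixture format.

A run is a sequence of :class:`MobilityFrame` objects (one TIMS ramp each,
holding a sparse point cloud of ``(m/z, 1/K0, intensity)``), a set of
:class:`DiaWindow` isolation windows bounded in both m/z and ion mobility,
and a small block of instrument-like metadata (:class:`RunMeta`).

Conventions
-----------
* m/z in Thomson, ion mobility as inverse reduced mobility 1/K0 (Vs/cm2),
  retention time in seconds.
* All intervals are half-open ``[low, high)``.
* Physical 1/K0 values are stored directly; any scan-index mapping is the
  concern of whatever produced the fixture.

The fixture format is a single versioned, line-oriented UTF-8 text file with
four record types (``#meta``, ``W`` windows, ``F`` frames, ``P`` points); see
:func:`write_fixture`.  Floats are serialized with ``repr`` so that a
read/write round trip is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Protocol, Sequence

import numpy as np

FORMAT_NAME = "diadeconv-fixture"
FORMAT_VERSION = 1

__all__ = [
    "MobilityFrame",
    "DiaWindow",
    "RunMeta",
    "RunFixture",
    "FrameSource",
    "FixtureValidationError",
    "FixtureIOError",
    "read_fixture",
    "write_fixture",
    "window_of",
    "validate_run",
]


class FixtureValidationError(ValueError):
    """A run or fixture file violates a structural invariant."""


class FixtureIOError(OSError):
    """The fixture file is missing, unreadable or unwritable."""


@dataclass
class MobilityFrame:
    """One TIMS ramp at a single retention time.

    ``points`` is an ``(n, 3)`` float64 array with columns
    ``(mz, inv_k0, intensity)``, sorted by ``(inv_k0, mz)``.
    ``window_segments`` is a list of ``(im_low, im_high, window_id)`` for
    MS2 frames (empty for MS1); segment intervals are half-open in 1/K0.
    """

    frame_id: int
    rt_seconds: float
    ms_level: int
    points: np.ndarray
    window_segments: list[tuple[float, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = np.empty((0, 3), dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise FixtureValidationError(
                f"frame {self.frame_id}: points must be an (n, 3) array"
            )
        self.points = pts

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    @property
    def mz(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def inv_k0(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def intensity(self) -> np.ndarray:
        return self.points[:, 2]

    def __eq__(self, other: object) -> bool:  # array-aware equality
        if not isinstance(other, MobilityFrame):
            return NotImplemented
        return (
            self.frame_id == other.frame_id
            and self.rt_seconds == other.rt_seconds
            and self.ms_level == other.ms_level
            and self.window_segments == other.window_segments
            and np.array_equal(self.points, other.points)
        )


@dataclass(frozen=True)
class DiaWindow:
    """An isolation window bounded in m/z and in ion mobility."""

    window_id: int
    mz_low: float
    mz_high: float
    im_low: float
    im_high: float
    cycle_position: int

    def contains(self, mz: float, im: float) -> bool:
        return (
            self.mz_low <= mz < self.mz_high and self.im_low <= im < self.im_high
        )


@dataclass
class RunMeta:
    """Instrument-like resolution constants plus optional extent hints.

    ``mz_step`` / ``im_step`` are the smallest resolvable differences between
    two signals; they define the binning granularity downstream.  The extent
    fields bound the MS1 grid and the MS2 fragment m/z grid; when absent they
    are derived from the window table / observed points.
    """

    mz_step: float = 0.01
    im_step: float = 0.001
    label: str = ""
    ms1_mz_min: Optional[float] = None
    ms1_mz_max: Optional[float] = None
    ms1_im_min: Optional[float] = None
    ms1_im_max: Optional[float] = None
    ms2_mz_min: Optional[float] = None
    ms2_mz_max: Optional[float] = None
    seed: Optional[int] = None


@dataclass
class RunFixture:
    """A full run: ordered frames, the window scheme, and metadata."""

    frames: list[MobilityFrame]
    windows: list[DiaWindow]
    meta: RunMeta = field(default_factory=RunMeta)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RunFixture):
            return NotImplemented
        return (
            self.frames == other.frames
            and self.windows == other.windows
            and self.meta == other.meta
        )

    def frame_by_id(self, frame_id: int) -> MobilityFrame:
        try:
            return self._frame_index()[frame_id]
        except KeyError:
            raise KeyError(f"unknown frame_id {frame_id}") from None

    def _frame_index(self) -> dict[int, MobilityFrame]:
        idx = getattr(self, "_fidx", None)
        if idx is None or len(idx) != len(self.frames):
            idx = {f.frame_id: f for f in self.frames}
            object.__setattr__(self, "_fidx", idx)
        return idx

    def window_by_id(self, window_id: int) -> DiaWindow:
        for w in self.windows:
            if w.window_id == window_id:
                return w
        raise KeyError(f"unknown window_id {window_id}")

    def ms1_frames(self) -> list[MobilityFrame]:
        return [f for f in self.frames if f.ms_level == 1]

    def ms2_frames_of_window(self, window_id: int) -> list[MobilityFrame]:
        out = []
        for f in self.frames:
            if f.ms_level != 2:
                continue
            if any(wid == window_id for _, _, wid in f.window_segments):
                out.append(f)
        return out

    def points_in_window(self, frame: MobilityFrame, window_id: int) -> np.ndarray:
        """Points of ``frame`` whose 1/K0 lies in the segment of ``window_id``."""
        for lo, hi, wid in frame.window_segments:
            if wid == window_id:
                im = frame.inv_k0
                mask = (im >= lo) & (im < hi)
                return frame.points[mask]
        return np.empty((0, 3), dtype=np.float64)


class FrameSource(Protocol):
    """Backend interface for pluggable raw readers (e.g. a vendor adapter).

    Implementations enumerate frame headers and fetch point clouds lazily;
    :func:`as_run_fixture` materializes them into a :class:`RunFixture`.
    """

    def enumerate_frames(self) -> Iterable[MobilityFrame]:
        """Yield frames with empty point arrays (headers only)."""
        ...

    def fetch_points(self, frame_id: int) -> np.ndarray:
        """Return the (n, 3) point array of one frame."""
        ...


def as_run_fixture(
    source: FrameSource, windows: Sequence[DiaWindow], meta: RunMeta
) -> RunFixture:
    frames = []
    for header in source.enumerate_frames():
        frames.append(replace(header, points=source.fetch_points(header.frame_id)))
    run = RunFixture(frames=frames, windows=list(windows), meta=meta)
    validate_run(run)
    return run


# ---------------------------------------------------------------------------
# validation


def _points_sorted(points: np.ndarray) -> bool:
    if points.shape[0] < 2:
        return True
    im, mz = points[:, 1], points[:, 0]
    d_im = np.diff(im)
    if np.any(d_im < 0):
        return False
    same = d_im == 0
    return not np.any(np.diff(mz)[same] < 0)


def validate_run(run: RunFixture) -> None:
    """Check every structural invariant; raise naming the first offender."""
    meta = run.meta
    if not (meta.mz_step > 0) or not (meta.im_step > 0):
        raise FixtureValidationError("meta: resolution steps must be positive")

    seen_ids = set()
    for w in run.windows:
        if w.window_id in seen_ids:
            raise FixtureValidationError(f"window {w.window_id}: duplicate id")
        seen_ids.add(w.window_id)
        if not (w.mz_low < w.mz_high):
            raise FixtureValidationError(f"window {w.window_id}: mz_low >= mz_high")
        if not (w.im_low < w.im_high):
            raise FixtureValidationError(f"window {w.window_id}: im_low >= im_high")

    prev_id, prev_rt = None, None
    for f in run.frames:
        tag = f"frame {f.frame_id}"
        if f.frame_id <= 0:
            raise FixtureValidationError(f"{tag}: frame_id must be positive")
        if prev_id is not None and f.frame_id <= prev_id:
            raise FixtureValidationError(f"{tag}: frame_id not strictly increasing")
        if prev_rt is not None and not (f.rt_seconds > prev_rt):
            raise FixtureValidationError(f"{tag}: rt_seconds not strictly increasing")
        prev_id, prev_rt = f.frame_id, f.rt_seconds
        if f.ms_level not in (1, 2):
            raise FixtureValidationError(f"{tag}: ms_level must be 1 or 2")
        if f.ms_level == 1 and f.window_segments:
            raise FixtureValidationError(f"{tag}: MS1 frame carries window segments")
        if f.ms_level == 2 and not f.window_segments:
            raise FixtureValidationError(f"{tag}: MS2 frame without window segments")
        pts = f.points
        if pts.size and not np.all(np.isfinite(pts)):
            raise FixtureValidationError(f"{tag}: non-finite point values")
        if pts.size and np.any(pts[:, 2] <= 0):
            raise FixtureValidationError(f"{tag}: non-positive intensity stored")
        if not _points_sorted(pts):
            raise FixtureValidationError(f"{tag}: points not sorted by (inv_k0, mz)")
        if f.ms_level == 2:
            segs = sorted(f.window_segments)
            for (lo, hi, wid) in segs:
                if not (lo < hi):
                    raise FixtureValidationError(f"{tag}: empty segment for window {wid}")
                if wid not in seen_ids:
                    raise FixtureValidationError(f"{tag}: segment references unknown window {wid}")
            for (_, hi_a, _), (lo_b, _, _) in zip(segs, segs[1:]):
                if lo_b < hi_a:
                    raise FixtureValidationError(f"{tag}: overlapping window segments")
            if pts.shape[0]:
                im = pts[:, 1]
                covered = np.zeros(pts.shape[0], dtype=np.int64)
                for lo, hi, _ in segs:
                    covered += (im >= lo) & (im < hi)
                if np.any(covered != 1):
                    bad = int(np.flatnonzero(covered != 1)[0])
                    raise FixtureValidationError(
                        f"{tag}: point {bad} (1/K0={im[bad]!r}) not inside exactly one segment"
                    )

    _validate_cycle(run)


def _validate_cycle(run: RunFixture) -> None:
    """Every full MS1-led cycle must present the same window-id sequence."""
    if not any(f.ms_level == 2 for f in run.frames):
        return
    if run.frames and run.frames[0].ms_level != 1:
        raise FixtureValidationError("frame cycle must start with an MS1 frame")
    cycles: list[tuple] = []
    current: list[tuple] = []
    for f in run.frames:
        if f.ms_level == 1:
            if current:
                cycles.append(tuple(current))
            current = []
        else:
            current.append(tuple(wid for _, _, wid in f.window_segments))
    if current:
        cycles.append(tuple(current))
    full = [c for c in cycles[:-1]] if len(cycles) > 1 else cycles
    pattern = full[0] if full else cycles[0]
    for i, c in enumerate(full):
        if c != pattern:
            raise FixtureValidationError(f"cycle {i}: window sequence differs from cycle 0")
    if len(cycles) > 1 and cycles[-1] != pattern:
        # trailing cycle may be truncated but must be a prefix of the pattern
        if cycles[-1] != pattern[: len(cycles[-1])]:
            raise FixtureValidationError("trailing cycle is not a prefix of the window pattern")


# ---------------------------------------------------------------------------
# window lookup


def window_of(run: RunFixture, frame_id: int, inv_k0: float) -> Optional[DiaWindow]:
    """The window whose IM segment contains ``inv_k0`` on an MS2 frame.

    Returns ``None`` for MS1 frames or a mobility outside every segment.
    Segment intervals are half-open, so a probe exactly on a boundary belongs
    to the segment whose ``im_low`` it equals.
    """
    frame = run.frame_by_id(frame_id)
    if frame.ms_level == 1:
        return None
    for lo, hi, wid in frame.window_segments:
        if lo <= inv_k0 < hi:
            return run.window_by_id(wid)
    return None


def window_containing(run: RunFixture, mz: float, im: float) -> Optional[DiaWindow]:
    """The lowest-id window whose (m/z, IM) rectangle contains the point."""
    hits = [w for w in run.windows if w.contains(mz, im)]
    if not hits:
        return None
    return min(hits, key=lambda w: w.window_id)


# ---------------------------------------------------------------------------
# serialization

_META_FLOAT_KEYS = (
    "mz_step",
    "im_step",
    "ms1_mz_min",
    "ms1_mz_max",
    "ms1_im_min",
    "ms1_im_max",
    "ms2_mz_min",
    "ms2_mz_max",
)


def write_fixture(run: RunFixture, path) -> None:
    """Serialize ``run`` to a single text file readable by :func:`read_fixture`.

    The run is validated first; nothing is written for an invalid run.
    """
    validate_run(run)
    try:
        fh = open(path, "w", encoding="utf-8", newline="\n")
    except OSError as exc:
        raise FixtureIOError(f"cannot write fixture: {exc}") from exc
    with fh:
        fh.write(f"#{FORMAT_NAME}\t{FORMAT_VERSION}\n")
        m = run.meta
        for key in _META_FLOAT_KEYS:
            val = getattr(m, key)
            if val is not None:
                fh.write(f"#meta\t{key}\t{val!r}\n")
        if m.label:
            fh.write(f"#meta\tlabel\t{m.label}\n")
        if m.seed is not None:
            fh.write(f"#meta\tseed\t{m.seed}\n")
        for w in run.windows:
            fh.write(
                f"W\t{w.window_id}\t{float(w.mz_low)!r}\t{float(w.mz_high)!r}"
                f"\t{float(w.im_low)!r}\t{float(w.im_high)!r}\t{w.cycle_position}\n"
            )
        for f in run.frames:
            segs = ";".join(
                f"{float(lo)!r}:{float(hi)!r}:{wid}" for lo, hi, wid in f.window_segments
            )
            fh.write(f"F\t{f.frame_id}\t{float(f.rt_seconds)!r}\t{f.ms_level}\t{segs}\n")
        for f in run.frames:
            fid = f.frame_id
            for mz, im, inten in f.points.tolist():
                fh.write(f"P\t{fid}\t{mz!r}\t{im!r}\t{inten!r}\n")


def read_fixture(path) -> RunFixture:
    """Parse a fixture file and return a validated :class:`RunFixture`."""
    try:
        fh = open(path, "r", encoding="utf-8")
    except OSError as exc:
        raise FixtureIOError(f"cannot read fixture: {exc}") from exc
    meta = RunMeta()
    windows: list[DiaWindow] = []
    frame_rows: list[tuple[int, float, int, list[tuple[float, float, int]]]] = []
    points_by_frame: dict[int, list[tuple[float, float, float]]] = {}
    with fh:
        header = fh.readline().rstrip("\n")
        parts = header.split("\t")
        if len(parts) != 2 or parts[0] != f"#{FORMAT_NAME}":
            raise FixtureValidationError(f"not a {FORMAT_NAME} file: bad header")
        if int(parts[1]) != FORMAT_VERSION:
            raise FixtureValidationError(f"unsupported fixture version {parts[1]}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            tag = cols[0]
            try:
                if tag == "#meta":
                    key, val = cols[1], cols[2]
                    if key in _META_FLOAT_KEYS:
                        setattr(meta, key, float(val))
                    elif key == "label":
                        meta.label = val
                    elif key == "seed":
                        meta.seed = int(val)
                    else:
                        raise FixtureValidationError(f"line {lineno}: unknown meta key {key!r}")
                elif tag == "W":
                    windows.append(
                        DiaWindow(
                            window_id=int(cols[1]),
                            mz_low=float(cols[2]),
                            mz_high=float(cols[3]),
                            im_low=float(cols[4]),
                            im_high=float(cols[5]),
                            cycle_position=int(cols[6]),
                        )
                    )
                elif tag == "F":
                    segs = []
                    if len(cols) > 4 and cols[4]:
                        for chunk in cols[4].split(";"):
                            lo, hi, wid = chunk.split(":")
                            segs.append((float(lo), float(hi), int(wid)))
                    frame_rows.append((int(cols[1]), float(cols[2]), int(cols[3]), segs))
                elif tag == "P":
                    fid = int(cols[1])
                    points_by_frame.setdefault(fid, []).append(
                        (float(cols[2]), float(cols[3]), float(cols[4]))
                    )
                else:
                    raise FixtureValidationError(f"line {lineno}: unknown record tag {tag!r}")
            except (IndexError, ValueError) as exc:
                if isinstance(exc, FixtureValidationError):
                    raise
                raise FixtureValidationError(f"line {lineno}: malformed record ({exc})") from exc

    frames = []
    for fid, rt, level, segs in frame_rows:
        pts = points_by_frame.pop(fid, [])
        arr = np.asarray(pts, dtype=np.float64) if pts else np.empty((0, 3))
        frames.append(
            MobilityFrame(frame_id=fid, rt_seconds=rt, ms_level=level, points=arr, window_segments=segs)
        )
    if points_by_frame:
        orphan = sorted(points_by_frame)[0]
        raise FixtureValidationError(f"points reference unknown frame {orphan}")
    run = RunFixture(frames=frames, windows=windows, meta=meta)
    validate_run(run)
    return run
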