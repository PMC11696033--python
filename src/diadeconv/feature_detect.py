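"""Per-merged-frame 2D peak detection in the (m/z, ion mobility) plane.

One isolation window (or the MS1 stream) is processed frame by frame:
points are binned onto an N x W grid (N m/z bins, W mobility bins, steps
taken from the run metadata), adjacent retention-time frames are aggregated
by summing, sparse cells without enough nonzero neighbors are removed, the
grid is smoothed with a truncated 2D Gaussian kernel, local maxima seed
separable Gaussian fits, and each fit yields a :class:`Peak2D`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
from scipy import ndimage

from .run_model import FixtureValidationError, MobilityFrame, RunFixture

__all__ = [
    "BinnedMatrix",
    "Peak2D",
    "DetectConfig",
    "DegeneratePeakError",
    "bin_frame",
    "aggregate_frames",
    "denoise",
    "smooth2d",
    "find_seeds",
    "fit_peak",
    "detect_stream",
]


class DegeneratePeakError(ValueError):
    """The patch around a seed carries no usable signal."""


# Fraction of nonzero cells below which the row-run fast path kicks in for
# denoise/smooth2d.  The fast path is exact (see _row_runs), so this is purely
# a performance knob.
_SPARSE_FRACTION = 0.02
_SPARSE_MIN_SIZE = 100_000


def _row_runs(values: np.ndarray, radius: int) -> list[tuple[int, int, int, int]]:
    """Merged (row0, row1, col0, col1) bounding boxes of nonzero row runs.

    Rows with any nonzero cell are dilated by ``radius`` and merged into
    disjoint intervals; each interval gets a column bounding box, also
    expanded by ``radius``.  Convolving each box independently (margins are
    all-zero by construction) reproduces the full-grid convolution exactly.
    """
    rows = np.flatnonzero(values.any(axis=1))
    if rows.size == 0:
        return []
    n = values.shape[0]
    breaks = np.flatnonzero(np.diff(rows) > 2 * radius)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [rows.size - 1]])
    out = []
    for s, e in zip(starts, ends):
        r0 = max(0, rows[s] - radius)
        r1 = min(n, rows[e] + radius + 1)
        cols = np.flatnonzero(values[r0:r1].any(axis=0))
        c0 = max(0, cols[0] - radius)
        c1 = min(values.shape[1], cols[-1] + radius + 1)
        out.append((int(r0), int(r1), int(c0), int(c1)))
    return out


@dataclass
class BinnedMatrix:
    """Dense N x W intensity grid for one merged frame of one stream.

    Rows index m/z bins, columns index ion-mobility bins.  ``mz_axis`` /
    ``im_axis`` hold bin centers; bin ``i`` covers the half-open interval
    ``[low + i*step, low + (i+1)*step)``.
    """

    values: np.ndarray
    mz_low: float
    mz_step: float
    im_low: float
    im_step: float
    source_frame_group: tuple[int, int]
    center_frame_id: int
    rt_seconds: float
    window_id: Optional[int] = None  # None marks the MS1 stream

    @property
    def n_mz(self) -> int:
        return self.values.shape[0]

    @property
    def n_im(self) -> int:
        return self.values.shape[1]

    @property
    def mz_axis(self) -> np.ndarray:
        return self.mz_low + (np.arange(self.n_mz) + 0.5) * self.mz_step

    @property
    def im_axis(self) -> np.ndarray:
        return self.im_low + (np.arange(self.n_im) + 0.5) * self.im_step

    def replace_values(self, values: np.ndarray) -> "BinnedMatrix":
        out = BinnedMatrix(
            values=values,
            mz_low=self.mz_low,
            mz_step=self.mz_step,
            im_low=self.im_low,
            im_step=self.im_step,
            source_frame_group=self.source_frame_group,
            center_frame_id=self.center_frame_id,
            rt_seconds=self.rt_seconds,
            window_id=self.window_id,
        )
        return out


@dataclass
class Peak2D:
    """One fitted 2D peak of a merged frame."""

    mz_center: float
    im_center: float
    mz_range: tuple[float, float]
    im_range: tuple[float, float]
    amplitude: float
    sigma_mz: float
    sigma_im: float
    frame_group: tuple[int, int]
    summed_intensity: float
    center_frame_id: int = 0
    rt_seconds: float = 0.0


@dataclass
class DetectConfig:
    """Detection parameters; MS2 streams use the relaxed neighbor count."""

    half_width: int = 2
    denoise_radius: tuple[int, int] = (1, 1)
    min_neighbors_ms1: int = 2
    min_neighbors_ms2: int = 1
    smooth_sigma: tuple[float, float] = (1.0, 1.5)
    min_seed_intensity: float = 0.0
    patch_radius: tuple[int, int] = (6, 6)
    range_k: float = 2.0


# ---------------------------------------------------------------------------
# grids & binning


def _grid_spec(run: RunFixture, window_id: Optional[int]):
    """(mz_low, mz_high, im_low, im_high) of the stream's binning grid."""
    meta = run.meta
    if window_id is None:
        mz_lo = meta.ms1_mz_min
        mz_hi = meta.ms1_mz_max
        im_lo = meta.ms1_im_min
        im_hi = meta.ms1_im_max
        if None in (mz_lo, mz_hi, im_lo, im_hi):
            pts = [f.points for f in run.ms1_frames() if f.n_points]
            if not pts:
                raise FixtureValidationError("MS1 grid extent unknown and no points to derive it")
            allp = np.concatenate(pts)
            mz_lo = float(allp[:, 0].min()) if mz_lo is None else mz_lo
            mz_hi = float(np.nextafter(allp[:, 0].max(), np.inf)) if mz_hi is None else mz_hi
            im_lo = float(allp[:, 1].min()) if im_lo is None else im_lo
            im_hi = float(np.nextafter(allp[:, 1].max(), np.inf)) if im_hi is None else im_hi
    else:
        w = run.window_by_id(window_id)
        mz_lo, mz_hi = meta.ms2_mz_min, meta.ms2_mz_max
        if mz_lo is None or mz_hi is None:
            pts = [run.points_in_window(f, window_id)
                   for f in run.ms2_frames_of_window(window_id)]
            pts = [p for p in pts if p.size]
            if not pts:
                mz_lo, mz_hi = w.mz_low, w.mz_high
            else:
                allp = np.concatenate(pts)
                mz_lo = float(allp[:, 0].min())
                mz_hi = float(np.nextafter(allp[:, 0].max(), np.inf))
        im_lo, im_hi = w.im_low, w.im_high
    return float(mz_lo), float(mz_hi), float(im_lo), float(im_hi)


def bin_frame(run: RunFixture, frame: MobilityFrame,
              window_id: Optional[int]) -> np.ndarray:
    """Sum the frame's points (of one stream) onto the stream's dense grid."""
    mz_lo, mz_hi, im_lo, im_hi = _grid_spec(run, window_id)
    step_mz, step_im = run.meta.mz_step, run.meta.im_step
    n = int(np.ceil((mz_hi - mz_lo) / step_mz))
    w = int(np.ceil((im_hi - im_lo) / step_im))
    grid = np.zeros((n, w), dtype=np.float64)
    pts = frame.points if window_id is None else run.points_in_window(frame, window_id)
    if pts.shape[0] == 0:
        return grid
    mz, im, inten = pts[:, 0], pts[:, 1], pts[:, 2]
    inside = (mz >= mz_lo) & (mz < mz_hi) & (im >= im_lo) & (im < im_hi)
    if not np.all(inside):
        bad = int(np.flatnonzero(~inside)[0])
        raise FixtureValidationError(
            f"frame {frame.frame_id}: point {bad} outside the binning grid"
        )
    i = np.minimum((mz - mz_lo) / step_mz, n - 1).astype(np.int64)
    j = np.minimum((im - im_lo) / step_im, w - 1).astype(np.int64)
    np.add.at(grid, (i, j), inten)
    return grid


def _stream_frames(run: RunFixture, window_id: Optional[int]) -> list[MobilityFrame]:
    if window_id is None:
        return run.ms1_frames()
    run.window_by_id(window_id)  # raises for unknown windows
    return run.ms2_frames_of_window(window_id)


def aggregate_frames(run: RunFixture, window_id: Optional[int],
                     half_width: int) -> Iterator[BinnedMatrix]:
    """Yield one aggregated matrix per central frame of the stream.

    Each cell is the sum of that cell over the frames
    ``[c - half_width, c + half_width]`` clipped to the run; edge frames use
    whatever neighbors exist.  ``window_id=None`` selects the MS1 stream.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    frames = _stream_frames(run, window_id)
    if not frames:
        return
    mz_lo, _, im_lo, _ = _grid_spec(run, window_id)
    cache: dict[int, np.ndarray] = {}

    def binned(idx: int) -> np.ndarray:
        if idx not in cache:
            cache[idx] = bin_frame(run, frames[idx], window_id)
        return cache[idx]

    for c in range(len(frames)):
        lo = max(0, c - half_width)
        hi = min(len(frames) - 1, c + half_width)
        total = binned(lo).copy()
        for k in range(lo + 1, hi + 1):
            total += binned(k)
        for k in list(cache):
            if k < c - half_width + 1:
                del cache[k]
        yield BinnedMatrix(
            values=total,
            mz_low=mz_lo,
            mz_step=run.meta.mz_step,
            im_low=im_lo,
            im_step=run.meta.im_step,
            source_frame_group=(frames[lo].frame_id, frames[hi].frame_id),
            center_frame_id=frames[c].frame_id,
            rt_seconds=frames[c].rt_seconds,
            window_id=window_id,
        )


# ---------------------------------------------------------------------------
# denoising / smoothing / seeding


def denoise(matrix: BinnedMatrix, radius_bins: tuple[int, int] = (1, 1),
            min_neighbors: int = 1) -> BinnedMatrix:
    """Zero cells with fewer than ``min_neighbors`` nonzero neighbors.

    The neighborhood is the ``(2*dmz+1) x (2*dim+1)`` box around the cell,
    excluding the cell itself; cells outside the grid count as empty.
    A single pass: neighbor counts are taken on the input matrix, and the
    surviving cells keep their original values.
    """
    dmz, dim = radius_bins
    if dmz < 1 or dim < 1:
        raise ValueError("radius must be at least (1, 1)")
    v = matrix.values

    def box_counts(arr: np.ndarray) -> np.ndarray:
        occ = (arr > 0).astype(np.float64)
        # separable box sum of 0/1 cells: exact in float64
        c = ndimage.correlate1d(occ, np.ones(2 * dmz + 1), axis=0,
                                mode="constant", cval=0.0)
        c = ndimage.correlate1d(c, np.ones(2 * dim + 1), axis=1,
                                mode="constant", cval=0.0)
        return c - occ  # exclude self

    nnz = np.count_nonzero(v)
    if v.size > _SPARSE_MIN_SIZE and nnz < _SPARSE_FRACTION * v.size:
        out = np.zeros_like(v)
        for r0, r1, c0, c1 in _row_runs(v, max(dmz, dim)):
            sub = v[r0:r1, c0:c1]
            counts = box_counts(sub)
            out[r0:r1, c0:c1] = np.where(
                (sub > 0) & (counts < min_neighbors), 0.0, sub
            )
        return matrix.replace_values(out)

    counts = box_counts(v)
    out = np.where((v > 0) & (counts < min_neighbors), 0.0, v)
    return matrix.replace_values(out)


def _gauss_kernel1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth2d(matrix: BinnedMatrix,
             sigma_bins: tuple[float, float] = (1.0, 1.0)) -> BinnedMatrix:
    """Convolve with a normalized truncated (4 sigma) Gaussian, reflect padding."""
    smz, sim = sigma_bins
    if smz <= 0 or sim <= 0:
        raise ValueError("smoothing sigmas must be positive")
    v = matrix.values
    kmz, kim = _gauss_kernel1d(smz), _gauss_kernel1d(sim)

    def smooth(arr: np.ndarray) -> np.ndarray:
        # the outer-product kernel is separable; reflect padding commutes
        # with per-axis application, so two 1D passes equal the full 2D
        # convolution
        out = ndimage.correlate1d(arr, kmz, axis=0, mode="reflect")
        return ndimage.correlate1d(out, kim, axis=1, mode="reflect")

    radius = max(kmz.size, kim.size) // 2
    nnz = np.count_nonzero(v)
    if v.size > _SPARSE_MIN_SIZE and nnz < _SPARSE_FRACTION * v.size:
        out = np.zeros_like(v)
        for r0, r1, c0, c1 in _row_runs(v, radius):
            out[r0:r1, c0:c1] = smooth(v[r0:r1, c0:c1])
        return matrix.replace_values(out)
    return matrix.replace_values(smooth(v))


def find_seeds(matrix: BinnedMatrix,
               min_intensity: float = 0.0) -> list[tuple[tuple[int, int], float]]:
    """Cells strictly greater than all 8 neighbors and >= ``min_intensity``.

    Ordered by descending value; equal values break toward the lower m/z bin
    then the lower IM bin.
    """
    v = matrix.values
    if v.size == 0:
        return []

    def local_maxima(arr: np.ndarray) -> np.ndarray:
        padded = np.full((arr.shape[0] + 2, arr.shape[1] + 2), -np.inf)
        padded[1:-1, 1:-1] = arr
        neighbor_max = np.full_like(arr, -np.inf)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                shifted = padded[1 + di : padded.shape[0] - 1 + di,
                                 1 + dj : padded.shape[1] - 1 + dj]
                np.maximum(neighbor_max, shifted, out=neighbor_max)
        return (arr > neighbor_max) & (arr >= min_intensity) & (arr > 0)

    nnz = np.count_nonzero(v)
    rows_i: list[np.ndarray] = []
    rows_j: list[np.ndarray] = []
    if v.size > _SPARSE_MIN_SIZE and nnz < _SPARSE_FRACTION * v.size:
        # each nonzero cell's 8-neighborhood lies inside its (radius-1) crop,
        # so per-crop maxima equal full-grid maxima
        for r0, r1, c0, c1 in _row_runs(v, 1):
            mi, mj = np.nonzero(local_maxima(v[r0:r1, c0:c1]))
            rows_i.append(mi + r0)
            rows_j.append(mj + c0)
        ii = np.concatenate(rows_i) if rows_i else np.empty(0, dtype=np.int64)
        jj = np.concatenate(rows_j) if rows_j else np.empty(0, dtype=np.int64)
    else:
        ii, jj = np.nonzero(local_maxima(v))
    vals = v[ii, jj]
    order = np.lexsort((jj, ii, -vals))
    return [((int(ii[k]), int(jj[k])), float(vals[k])) for k in order]


# ---------------------------------------------------------------------------
# Gaussian fitting


def _fit_gauss1d(x: np.ndarray, y: np.ndarray) -> Optional[tuple[float, float, float]]:
    """Least-squares Gaussian fit via the weighted log-parabola (Guo's method).

    Returns (center, sigma, amplitude) or None when no concave parabola fits.
    """
    good = y > 0
    if good.sum() < 3:
        return None
    xg, yg = x[good], y[good]
    w = yg * yg
    ly = np.log(yg)
    # weighted quadratic LS: ly ~ a + b x + c x^2
    A = np.stack([np.ones_like(xg), xg, xg * xg], axis=1)
    Aw = A * w[:, None]
    try:
        coef, *_ = np.linalg.lstsq(Aw, ly * w, rcond=None)
    except np.linalg.LinAlgError:
        return None
    a, b, c = coef
    if not np.isfinite(c) or c >= 0:
        return None
    sigma = float(np.sqrt(-1.0 / (2.0 * c)))
    center = float(-b / (2.0 * c))
    log_amp = a - b * b / (4.0 * c)
    if log_amp > 700.0:  # exp would overflow; reject as a failed fit
        return None
    amp = float(np.exp(log_amp))
    if not (np.isfinite(sigma) and np.isfinite(center) and np.isfinite(amp)):
        return None
    return center, sigma, amp


def fit_peak(matrix: BinnedMatrix, seed: tuple[int, int],
             cfg: Optional[DetectConfig] = None) -> Peak2D:
    """Fit a separable 2D Gaussian on a patch around a seeded local maximum.

    Two 1D fits are run along the seed's m/z column and IM row; on failure the
    peak falls back to the intensity-weighted centroid of the patch, with
    ranges from the contiguous above-half-max region through the seed.
    """
    cfg = cfg or DetectConfig()
    i0, j0 = seed
    v = matrix.values
    pr_mz, pr_im = cfg.patch_radius
    ilo, ihi = max(0, i0 - pr_mz), min(v.shape[0], i0 + pr_mz + 1)
    jlo, jhi = max(0, j0 - pr_im), min(v.shape[1], j0 + pr_im + 1)
    patch = v[ilo:ihi, jlo:jhi]
    if patch.size == 0 or patch.max() <= 0:
        raise DegeneratePeakError(f"patch around seed {seed} carries no signal")

    mz_prof = v[ilo:ihi, j0]
    im_prof = v[i0, jlo:jhi]
    mz_bins = np.arange(ilo, ihi, dtype=np.float64)
    im_bins = np.arange(jlo, jhi, dtype=np.float64)

    fit_mz = _fit_gauss1d(mz_bins, mz_prof)
    fit_im = _fit_gauss1d(im_bins, im_prof)

    def phys_mz(bin_f: float) -> float:
        return matrix.mz_low + (bin_f + 0.5) * matrix.mz_step

    def phys_im(bin_f: float) -> float:
        return matrix.im_low + (bin_f + 0.5) * matrix.im_step

    patch_mz = (phys_mz(ilo - 0.5), phys_mz(ihi - 0.5))
    patch_im = (phys_im(jlo - 0.5), phys_im(jhi - 0.5))

    ok = (
        fit_mz is not None and fit_im is not None
        and ilo <= fit_mz[0] < ihi and jlo <= fit_im[0] < jhi
        and fit_mz[1] > 0 and fit_im[1] > 0
    )
    if ok:
        c_mz, s_mz_bins, _ = fit_mz
        c_im, s_im_bins, _ = fit_im
        mz_center = phys_mz(c_mz)
        im_center = phys_im(c_im)
        sigma_mz = s_mz_bins * matrix.mz_step
        sigma_im = s_im_bins * matrix.im_step
        k = cfg.range_k
        mz_range = (max(mz_center - k * sigma_mz, patch_mz[0]),
                    min(mz_center + k * sigma_mz, patch_mz[1]))
        im_range = (max(im_center - k * sigma_im, patch_im[0]),
                    min(im_center + k * sigma_im, patch_im[1]))
    else:
        total = patch.sum()
        gi, gj = np.meshgrid(mz_bins, im_bins, indexing="ij")
        c_mz = float((gi * patch).sum() / total)
        c_im = float((gj * patch).sum() / total)
        mz_center = phys_mz(c_mz)
        im_center = phys_im(c_im)
        half = v[i0, j0] / 2.0
        a = i0
        while a > ilo and v[a - 1, j0] >= half:
            a -= 1
        b = i0
        while b < ihi - 1 and v[b + 1, j0] >= half:
            b += 1
        mz_range = (phys_mz(a - 0.5), phys_mz(b + 0.5))
        a = j0
        while a > jlo and v[i0, a - 1] >= half:
            a -= 1
        b = j0
        while b < jhi - 1 and v[i0, b + 1] >= half:
            b += 1
        im_range = (phys_im(a - 0.5), phys_im(b + 0.5))
        sigma_mz = max((mz_range[1] - mz_range[0]) / 2.355, matrix.mz_step / 2)
        sigma_im = max((im_range[1] - im_range[0]) / 2.355, matrix.im_step / 2)
        mz_center = float(np.clip(mz_center, mz_range[0],
                                  np.nextafter(mz_range[1], -np.inf)))
        im_center = float(np.clip(im_center, im_range[0],
                                  np.nextafter(im_range[1], -np.inf)))

    # summed intensity over the signal-range rectangle of the input matrix
    ri0 = max(0, int(np.floor((mz_range[0] - matrix.mz_low) / matrix.mz_step)))
    ri1 = min(v.shape[0], int(np.ceil((mz_range[1] - matrix.mz_low) / matrix.mz_step)))
    rj0 = max(0, int(np.floor((im_range[0] - matrix.im_low) / matrix.im_step)))
    rj1 = min(v.shape[1], int(np.ceil((im_range[1] - matrix.im_low) / matrix.im_step)))
    ri1 = max(ri1, ri0 + 1)
    rj1 = max(rj1, rj0 + 1)
    summed = float(v[ri0:ri1, rj0:rj1].sum())
    amplitude = float(v[i0, j0])
    summed = max(summed, amplitude)

    return Peak2D(
        mz_center=float(mz_center),
        im_center=float(im_center),
        mz_range=(float(mz_range[0]), float(mz_range[1])),
        im_range=(float(im_range[0]), float(im_range[1])),
        amplitude=amplitude,
        sigma_mz=float(sigma_mz),
        sigma_im=float(sigma_im),
        frame_group=matrix.source_frame_group,
        summed_intensity=summed,
        center_frame_id=matrix.center_frame_id,
        rt_seconds=matrix.rt_seconds,
    )


def detect_stream(
    run: RunFixture, window_id: Optional[int],
    cfg: Optional[DetectConfig] = None,
) -> tuple[list[list[Peak2D]], list[tuple[int, float]]]:
    """Full detection for one stream.

    Returns one Peak2D list per merged frame plus the aligned
    ``(center_frame_id, rt_seconds)`` metadata used for XIC tracing.
    """
    cfg = cfg or DetectConfig()
    min_nb = cfg.min_neighbors_ms1 if window_id is None else cfg.min_neighbors_ms2
    out: list[list[Peak2D]] = []
    meta: list[tuple[int, float]] = []
    for mat in aggregate_frames(run, window_id, cfg.half_width):
        den = denoise(mat, cfg.denoise_radius, min_nb)
        smo = smooth2d(den, cfg.smooth_sigma)
        peaks = []
        for cell, _val in find_seeds(smo, cfg.min_seed_intensity):
            try:
                peaks.append(fit_peak(smo, cell, cfg))
            except DegeneratePeakError:
                continue
        out.append(peaks)
        meta.append((mat.center_frame_id, mat.rt_seconds))
    return out, meta
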