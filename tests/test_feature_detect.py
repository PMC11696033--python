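"""Feature detection: binning, aggregation, denoise, smoothing, seeding,
Gaussian fitting — each checked against an exhaustive oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diadeconv.feature_detect import (
    BinnedMatrix,
    DegeneratePeakError,
    DetectConfig,
    aggregate_frames,
    bin_frame,
    denoise,
    find_seeds,
    fit_peak,
    smooth2d,
    _gauss_kernel1d,
)
from diadeconv.run_model import MobilityFrame, RunFixture, RunMeta

from conftest import small_sim_config
from diadeconv import pasef_sim


def make_matrix(values: np.ndarray, mz_low: float = 400.0,
                mz_step: float = 0.02, im_low: float = 0.7,
                im_step: float = 0.002) -> BinnedMatrix:
    return BinnedMatrix(
        values=np.asarray(values, dtype=np.float64),
        mz_low=mz_low, mz_step=mz_step, im_low=im_low, im_step=im_step,
        source_frame_group=(1, 1), center_frame_id=1, rt_seconds=0.0,
    )


# ---------------------------------------------------------------------------
# oracles


def oracle_denoise(values, dmz, dim, min_neighbors):
    """Exhaustive per-cell neighborhood count."""
    out = values.copy()
    n, w = values.shape
    for i in range(n):
        for j in range(w):
            if values[i, j] <= 0:
                continue
            count = 0
            for a in range(max(0, i - dmz), min(n, i + dmz + 1)):
                for b in range(max(0, j - dim), min(w, j + dim + 1)):
                    if (a, b) != (i, j) and values[a, b] > 0:
                        count += 1
            if count < min_neighbors:
                out[i, j] = 0.0
    return out


def oracle_smooth(values, smz, sim):
    """Naive double-loop 2D convolution with the normalized truncated kernel,
    reflect padding applied explicitly."""
    kmz = _gauss_kernel1d(smz)
    kim = _gauss_kernel1d(sim)
    kernel = np.outer(kmz, kim)
    rm, ri = kmz.size // 2, kim.size // 2
    padded = np.pad(values, ((rm, rm), (ri, ri)), mode="symmetric")
    n, w = values.shape
    out = np.zeros_like(values)
    for i in range(n):
        for j in range(w):
            acc = 0.0
            for a in range(kernel.shape[0]):
                for b in range(kernel.shape[1]):
                    acc += kernel[a, b] * padded[i + a, j + b]
            out[i, j] = acc
    return out


def oracle_seeds(values, min_intensity):
    """Exhaustive 8-neighborhood scan."""
    n, w = values.shape
    hits = []
    for i in range(n):
        for j in range(w):
            v = values[i, j]
            if v <= 0 or v < min_intensity:
                continue
            is_max = True
            for a in range(max(0, i - 1), min(n, i + 2)):
                for b in range(max(0, j - 1), min(w, j + 2)):
                    if (a, b) != (i, j) and values[a, b] >= v:
                        is_max = False
            if is_max:
                hits.append(((i, j), float(v)))
    hits.sort(key=lambda t: (-t[1], t[0][0], t[0][1]))
    return hits


# ---------------------------------------------------------------------------
# binning & aggregation


class TestAggregation:
    def _tiny_run(self, frame_points, mz_rng=(400.0, 401.0), im_rng=(0.7, 0.8)):
        frames = []
        for k, pts in enumerate(frame_points):
            pts = np.asarray(pts, dtype=np.float64).reshape(-1, 3)
            if pts.size:
                pts = pts[np.lexsort((pts[:, 0], pts[:, 1]))]
            frames.append(MobilityFrame(k + 1, float(k), 1, pts))
        meta = RunMeta(mz_step=0.1, im_step=0.01,
                       ms1_mz_min=mz_rng[0], ms1_mz_max=mz_rng[1],
                       ms1_im_min=im_rng[0], ms1_im_max=im_rng[1])
        return RunFixture(frames=frames, windows=[], meta=meta)

    def test_half_width_zero_is_identity(self):
        run = self._tiny_run([
            [[400.05, 0.705, 10.0]],
            [[400.15, 0.715, 20.0]],
        ])
        mats = list(aggregate_frames(run, None, 0))
        for mat, frame in zip(mats, run.frames):
            np.testing.assert_array_equal(mat.values,
                                          bin_frame(run, frame, None))

    def test_three_constant_frames_middle_is_triple(self):
        pts = [[400.05, 0.705, 10.0], [400.35, 0.755, 4.0]]
        run = self._tiny_run([pts, pts, pts])
        mats = list(aggregate_frames(run, None, 1))
        single = bin_frame(run, run.frames[0], None)
        np.testing.assert_allclose(mats[1].values, 3 * single)
        np.testing.assert_allclose(mats[0].values, 2 * single)  # edge clip
        np.testing.assert_allclose(mats[2].values, 2 * single)

    def test_random_frames_vs_exhaustive_resummation(self):
        rng = np.random.default_rng(4)
        frame_points = []
        for _ in range(7):
            n = rng.integers(0, 20)
            pts = np.column_stack([
                rng.uniform(400.0, 401.0, n),
                rng.uniform(0.70, 0.80, n),
                rng.integers(1, 50, n).astype(float),
            ])
            frame_points.append(pts)
        run = self._tiny_run(frame_points)
        half_width = 2
        mats = list(aggregate_frames(run, None, half_width))
        for c, mat in enumerate(mats):
            lo = max(0, c - half_width)
            hi = min(len(run.frames) - 1, c + half_width)
            expected = np.zeros_like(mat.values)
            for k in range(lo, hi + 1):  # brute-force re-sum over raw points
                for mz, im, inten in run.frames[k].points:
                    i = min(int((mz - 400.0) / 0.1), expected.shape[0] - 1)
                    j = min(int((im - 0.70) / 0.01), expected.shape[1] - 1)
                    expected[i, j] += inten
            np.testing.assert_allclose(mat.values, expected)

    def test_binning_conserves_integer_intensity(self):
        rng = np.random.default_rng(5)
        pts = np.column_stack([
            rng.uniform(400.0, 401.0, 200),
            rng.uniform(0.70, 0.80, 200),
            rng.integers(1, 1000, 200).astype(float),
        ])
        run = self._tiny_run([pts])
        grid = bin_frame(run, run.frames[0], None)
        assert grid.sum() == pts[:, 2].sum()  # exact for integer inputs

    def test_unknown_window_raises(self, small_run):
        run, _ = small_run
        with pytest.raises(KeyError):
            list(aggregate_frames(run, 99, 1))

    def test_negative_half_width_rejected(self, small_run):
        run, _ = small_run
        with pytest.raises(ValueError):
            list(aggregate_frames(run, None, -1))


# ---------------------------------------------------------------------------
# denoise


class TestDenoise:
    def test_isolated_cell_zeroed(self):
        v = np.zeros((9, 9))
        v[4, 4] = 5.0
        out = denoise(make_matrix(v), (1, 1), 1)
        assert out.values[4, 4] == 0.0

    def test_dense_matrix_unchanged(self):
        v = np.ones((8, 8))
        out = denoise(make_matrix(v), (1, 1), 2)
        np.testing.assert_array_equal(out.values, v)

    def test_random_sparse_vs_oracle(self):
        rng = np.random.default_rng(6)
        v = np.where(rng.random((50, 50)) < 0.08,
                     rng.uniform(1, 100, (50, 50)), 0.0)
        got = denoise(make_matrix(v), (1, 1), 2).values
        np.testing.assert_array_equal(got, oracle_denoise(v, 1, 1, 2))

    @given(density=st.floats(0.02, 0.3), min_nb=st.integers(1, 4),
           seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_oracle_equivalence_property(self, density, min_nb, seed):
        rng = np.random.default_rng(seed)
        v = np.where(rng.random((20, 20)) < density,
                     rng.uniform(1, 10, (20, 20)), 0.0)
        got = denoise(make_matrix(v), (2, 1), min_nb).values
        np.testing.assert_array_equal(got, oracle_denoise(v, 2, 1, min_nb))

    def test_second_pass_only_removes(self):
        # a single pass is the contract (neighbor counts are taken on the
        # input); a second pass may zero more cells but never changes or
        # restores surviving values
        rng = np.random.default_rng(7)
        v = np.where(rng.random((40, 40)) < 0.1,
                     rng.uniform(1, 100, (40, 40)), 0.0)
        once = denoise(make_matrix(v), (1, 1), 2)
        twice = denoise(once, (1, 1), 2)
        surviving = twice.values > 0
        np.testing.assert_array_equal(twice.values[surviving],
                                      once.values[surviving])
        assert np.all(once.values[~surviving & (once.values > 0)] >= 0)

    def test_idempotent_on_clustered_signal(self):
        # for blob-like signal (every nonzero cell keeps its neighbors) the
        # pass is a fixpoint
        v = np.zeros((30, 30))
        v[10:15, 10:15] = 3.0
        once = denoise(make_matrix(v), (1, 1), 2)
        twice = denoise(once, (1, 1), 2)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_sparse_fast_path_matches_oracle(self):
        # large, very sparse matrix triggers the row-run fast path
        rng = np.random.default_rng(8)
        v = np.zeros((600, 400))
        idx = rng.integers(0, 600 * 400, 500)
        v.flat[idx] = rng.uniform(1, 50, idx.size)
        clusters = rng.integers(0, 550, 10)
        for c in clusters:
            v[c : c + 3, 100:103] = 5.0
        got = denoise(make_matrix(v), (1, 1), 2).values
        np.testing.assert_array_equal(got, oracle_denoise(v, 1, 1, 2))

    def test_radius_validation(self):
        with pytest.raises(ValueError):
            denoise(make_matrix(np.ones((4, 4))), (0, 1), 1)


# ---------------------------------------------------------------------------
# smoothing


class TestSmooth2D:
    def test_unit_impulse_gives_normalized_kernel(self):
        v = np.zeros((21, 21))
        v[10, 10] = 1.0
        out = smooth2d(make_matrix(v), (1.0, 1.0)).values
        kernel = np.outer(_gauss_kernel1d(1.0), _gauss_kernel1d(1.0))
        r = kernel.shape[0] // 2
        np.testing.assert_allclose(out[10 - r : 10 + r + 1, 10 - r : 10 + r + 1],
                                   kernel, atol=1e-15)
        assert out.sum() == pytest.approx(1.0)

    def test_constant_matrix_unchanged(self):
        v = np.full((15, 15), 7.0)
        out = smooth2d(make_matrix(v), (1.0, 1.5)).values
        np.testing.assert_allclose(out, v, rtol=1e-12)

    def test_random_matrix_vs_naive_convolution(self):
        rng = np.random.default_rng(9)
        v = rng.uniform(0, 100, (24, 18))
        got = smooth2d(make_matrix(v), (1.0, 1.0)).values
        np.testing.assert_allclose(got, oracle_smooth(v, 1.0, 1.0), atol=1e-10)

    @given(seed=st.integers(0, 10_000),
           smz=st.floats(0.5, 2.0), sim=st.floats(0.5, 2.0))
    @settings(max_examples=15, deadline=None)
    def test_oracle_equivalence_property(self, seed, smz, sim):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 10, (15, 12))
        got = smooth2d(make_matrix(v), (smz, sim)).values
        np.testing.assert_allclose(got, oracle_smooth(v, smz, sim), atol=1e-10)

    def test_total_intensity_preserved_interior(self):
        rng = np.random.default_rng(10)
        v = np.zeros((40, 40))
        v[10:30, 10:30] = rng.uniform(0, 50, (20, 20))  # away from edges
        out = smooth2d(make_matrix(v), (1.0, 1.0)).values
        assert out.sum() == pytest.approx(v.sum(), rel=1e-9)

    def test_sparse_fast_path_matches_dense(self):
        rng = np.random.default_rng(11)
        v = np.zeros((800, 300))
        for _ in range(12):
            i, j = rng.integers(5, 790), rng.integers(5, 290)
            v[i : i + 4, j : j + 4] = rng.uniform(1, 100, (4, 4))
        got = smooth2d(make_matrix(v), (1.0, 1.0)).values
        # dense reference via explicit full-grid separable convolution
        from scipy import ndimage
        ref = ndimage.correlate1d(v, _gauss_kernel1d(1.0), axis=0, mode="reflect")
        ref = ndimage.correlate1d(ref, _gauss_kernel1d(1.0), axis=1, mode="reflect")
        np.testing.assert_allclose(got, ref, atol=1e-12)

    def test_sigma_validation(self):
        with pytest.raises(ValueError):
            smooth2d(make_matrix(np.ones((4, 4))), (0.0, 1.0))


# ---------------------------------------------------------------------------
# seeding


class TestFindSeeds:
    def test_single_gaussian_single_seed(self):
        x = np.arange(25)
        g = np.exp(-0.5 * ((x - 12) / 2.5) ** 2)
        v = np.outer(g, g) * 100
        seeds = find_seeds(make_matrix(v), 0.0)
        assert len(seeds) == 1
        assert seeds[0][0] == (12, 12)

    def test_zero_matrix_no_seeds(self):
        assert find_seeds(make_matrix(np.zeros((10, 10))), 0.0) == []

    def test_random_matrix_vs_exhaustive_scan(self):
        rng = np.random.default_rng(12)
        v = rng.uniform(0, 100, (30, 30))
        got = find_seeds(make_matrix(v), 5.0)
        assert got == oracle_seeds(v, 5.0)

    @given(seed=st.integers(0, 10_000), thresh=st.floats(0, 50))
    @settings(max_examples=25, deadline=None)
    def test_oracle_equivalence_property(self, seed, thresh):
        rng = np.random.default_rng(seed)
        v = np.where(rng.random((18, 14)) < 0.5,
                     rng.uniform(0, 100, (18, 14)), 0.0)
        assert find_seeds(make_matrix(v), thresh) == oracle_seeds(v, thresh)

    def test_sparse_fast_path_matches_oracle(self):
        rng = np.random.default_rng(13)
        v = np.zeros((700, 250))
        for _ in range(15):
            i, j = rng.integers(3, 690), rng.integers(3, 240)
            patch = rng.uniform(1, 100, (3, 3))
            v[i : i + 3, j : j + 3] = patch
        assert find_seeds(make_matrix(v), 0.0) == oracle_seeds(v, 0.0)

    def test_ordering_descending_with_tie_break(self):
        v = np.zeros((9, 9))
        v[2, 2] = 10.0
        v[6, 6] = 10.0
        v[4, 4] = 20.0
        seeds = find_seeds(make_matrix(v), 0.0)
        assert [s[0] for s in seeds] == [(4, 4), (2, 2), (6, 6)]


# ---------------------------------------------------------------------------
# Gaussian fitting


class TestFitPeak:
    def _planted(self, mz_c=500.250, im_c=1.020, sigma_mz=0.04,
                 sigma_im=0.006, amp=1000.0,
                 mz_low=500.0, im_low=1.0):
        mz_step, im_step = 0.02, 0.002
        n, w = 25, 20
        mz_axis = mz_low + (np.arange(n) + 0.5) * mz_step
        im_axis = im_low + (np.arange(w) + 0.5) * im_step
        v = amp * np.outer(
            np.exp(-0.5 * ((mz_axis - mz_c) / sigma_mz) ** 2),
            np.exp(-0.5 * ((im_axis - im_c) / sigma_im) ** 2),
        )
        mat = BinnedMatrix(values=v, mz_low=mz_low, mz_step=mz_step,
                           im_low=im_low, im_step=im_step,
                           source_frame_group=(1, 1), center_frame_id=1,
                           rt_seconds=0.0)
        return mat

    def test_noiseless_gaussian_center_recovery(self):
        mat = self._planted()
        seeds = find_seeds(mat, 0.0)
        peak = fit_peak(mat, seeds[0][0])
        assert abs(peak.mz_center - 500.250) <= 1e-3
        assert abs(peak.im_center - 1.020) <= 1e-4

    def test_symmetric_peak_on_bin_center(self):
        # bin centers: 500.0 + (i+0.5)*0.02 -> i=12 is 500.25; im j=9 is 1.019
        mat = self._planted(mz_c=500.0 + 12.5 * 0.02, im_c=1.0 + 9.5 * 0.002)
        seeds = find_seeds(mat, 0.0)
        peak = fit_peak(mat, seeds[0][0])
        assert peak.mz_center == pytest.approx(500.0 + 12.5 * 0.02, abs=1e-9)
        assert peak.im_center == pytest.approx(1.0 + 9.5 * 0.002, abs=1e-10)

    def test_single_cell_fallback_centroid(self):
        v = np.zeros((15, 15))
        v[7, 8] = 42.0
        mat = make_matrix(v)
        peak = fit_peak(mat, (7, 8))
        assert peak.mz_center == pytest.approx(mat.mz_axis[7])
        assert peak.im_center == pytest.approx(mat.im_axis[8])
        assert peak.sigma_mz > 0 and peak.sigma_im > 0

    def test_degenerate_patch_raises(self):
        v = np.zeros((15, 15))
        v[1, 1] = 5.0
        with pytest.raises(DegeneratePeakError):
            fit_peak(make_matrix(v), (13, 13))

    def test_invariants(self):
        mat = self._planted()
        peak = fit_peak(mat, find_seeds(mat, 0.0)[0][0])
        assert peak.mz_range[0] <= peak.mz_center < peak.mz_range[1]
        assert peak.im_range[0] <= peak.im_center < peak.im_range[1]
        assert peak.summed_intensity >= peak.amplitude > 0


class TestSeedUniquenessOnSimulatedData:
    def test_one_seed_per_species_at_apex_frame(self):
        # planted species produce exactly one seed within their RT range in
        # the merged frame nearest the apex (no split seeds after smoothing)
        for seed in range(1, 11):
            cfg = small_sim_config(seed=seed, n_species=3, noise_density=0)
            run, species = pasef_sim.simulate_run(cfg)
            mats = list(aggregate_frames(run, None, 2))
            cfgd = DetectConfig()
            for sp in species:
                mat = min(mats, key=lambda m: abs(m.rt_seconds - sp.rt_apex))
                sm = smooth2d(denoise(mat, cfgd.denoise_radius,
                                      cfgd.min_neighbors_ms1),
                              cfgd.smooth_sigma)
                hits = []
                for (i, j), _val in find_seeds(sm, 30.0):
                    mz = sm.mz_axis[i]
                    im = sm.im_axis[j]
                    if (abs(mz - sp.monoisotopic_mz) < 0.05
                            and abs(im - sp.im_apex) < 0.01):
                        hits.append((i, j))
                assert len(hits) == 1, (seed, sp.species_id, hits)
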