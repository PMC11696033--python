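"""Synthetic diaPASEF run generator with ground truth.

Produces :class:`~diadeconv.run_model.RunFixture` objects containing
peptide-like species: each species contributes a separable 3D Gaussian
intensity profile (retention time x ion mobility x isotope envelope in m/z)
to the MS1 frames, and co-eluting fragment profiles to the MS2 frames of the
isolation window containing its precursor.  Chemical noise is planted as
uniformly distributed points per frame.  Every planted signal is described in
a manifest of :class:`TrueSpecies` so downstream stages can be scored against
ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .run_model import (
    DiaWindow,
    FixtureValidationError,
    MobilityFrame,
    RunFixture,
    RunMeta,
    validate_run,
)

#: m/z spacing of adjacent isotopes for a singly charged ion (C13 - C12).
ISOTOPE_DELTA = 1.0033548

#: Proton mass used to convert between m/z and neutral mass.
PROTON_MASS = 1.00727646688

# Averagine model composition: atoms per 111.1254 Da of peptide.
_AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
_AVERAGINE_MASS = 111.1254

# Aggregated isotope abundance polynomials per element, indexed by nominal
# mass shift (natural abundances).
_ISO_POLY = {
    "C": np.array([0.9893, 0.0107]),
    "H": np.array([0.999885, 0.000115]),
    "N": np.array([0.99636, 0.00364]),
    "O": np.array([0.99757, 0.00038, 0.00205]),
    "S": np.array([0.9499, 0.0075, 0.0425, 0.0001]),
}


def _poly_power(coeffs: np.ndarray, n: int, keep: int) -> np.ndarray:
    """coeffs**n as a polynomial product, truncated to the first ``keep`` terms."""
    result = np.array([1.0])
    base = coeffs.copy()
    while n > 0:
        if n & 1:
            result = np.convolve(result, base)[:keep]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:keep]
    return result


def isotope_envelope(mono_mass: float, n: int) -> np.ndarray:
    """Relative isotope intensities for a peptide-like molecule of ``mono_mass``.

    Uses the averagine composition scaled to ``mono_mass`` (element counts
    rounded to integers) and convolves the per-element natural-abundance
    polynomials.  Returns the first ``n`` nominal-isotope intensities
    normalized so the maximum is 1.  Members are spaced ``1.0033548/z`` apart
    in m/z for a charge-``z`` ion; this function returns intensities only.
    """
    if mono_mass <= 0:
        raise ValueError("mono_mass must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    keep = max(n, 8)
    scale = mono_mass / _AVERAGINE_MASS
    dist = np.array([1.0])
    for el, per_unit in _AVERAGINE.items():
        count = int(round(scale * per_unit))
        if count <= 0:
            continue
        dist = np.convolve(dist, _poly_power(_ISO_POLY[el], count, keep))[:keep]
    out = np.zeros(n)
    m = min(n, dist.size)
    out[:m] = dist[:m]
    peak = out.max()
    if peak > 0:
        out /= peak
    return out


# ---------------------------------------------------------------------------
# ground-truth records


@dataclass(frozen=True)
class FragmentSpec:
    """One planted fragment of a species.

    Non-decoy fragments co-elute with their precursor (apexes inherit the
    precursor apex plus a small jitter); decoys are placed at uncorrelated
    RT/IM inside the same window to model interference.
    """

    mz: float
    rel_intensity: float
    rt_apex: float
    im_apex: float
    is_decoy: bool


@dataclass(frozen=True)
class TrueSpecies:
    species_id: int
    monoisotopic_mz: float
    charge: int
    rt_apex: float
    rt_sigma: float
    im_apex: float
    im_sigma: float
    abundance: float
    n_isotopes: int
    envelope: tuple[float, ...]
    fragments: tuple[FragmentSpec, ...]
    window_id: Optional[int]
    in_window: bool


@dataclass
class SimConfig:
    """All knobs of the simulator; ``rng_seed`` is mandatory."""

    rng_seed: int
    n_species: int = 50
    n_windows: int = 3
    ms1_mz_min: float = 400.0
    ms1_mz_max: float = 560.0
    ms1_im_min: float = 0.75
    ms1_im_max: float = 1.05
    ms2_mz_min: float = 350.0
    ms2_mz_max: float = 650.0
    window_im_width: float = 0.16
    gradient_length_s: float = 90.0
    cycle_time_s: float = 3.0
    mz_step: float = 0.02
    im_step: float = 0.002
    charges: tuple[int, ...] = (1, 2, 3, 4)
    n_isotopes_min: int = 3
    n_isotopes_max: int = 5
    rt_sigma_min: float = 3.0
    rt_sigma_max: float = 6.0
    im_sigma_min: float = 0.004
    im_sigma_max: float = 0.008
    mz_sigma_bins: float = 2.0
    abundance_min: float = 2000.0
    abundance_max: float = 8000.0
    n_fragments: int = 8
    n_decoy_fragments: int = 2
    fragment_rel_min: float = 0.3
    fragment_rel_max: float = 1.0
    fragment_rt_jitter_s: float = 0.3
    fragment_im_jitter: float = 0.002
    noise_density: int = 100
    noise_median_intensity: float = 20.0
    noise_log_sigma: float = 1.0
    intensity_log_sigma: float = 0.1
    intensity_floor: float = 0.5
    out_of_window_species: int = 0
    label: str = "sim"

    def validate(self) -> None:
        if self.rng_seed is None:
            raise ValueError("rng_seed is mandatory")
        for name in ("n_species", "n_windows", "noise_density", "n_fragments",
                     "n_decoy_fragments", "out_of_window_species"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_windows == 0 and self.n_species > 0:
            raise ValueError("need at least one window to place species")
        if not (self.ms1_mz_min < self.ms1_mz_max):
            raise ValueError("ms1 m/z range empty")
        if not (self.ms1_im_min < self.ms1_im_max):
            raise ValueError("ms1 IM range empty")
        if self.mz_step <= 0 or self.im_step <= 0:
            raise ValueError("resolution steps must be positive")


def build_windows(cfg: SimConfig) -> list[DiaWindow]:
    """Tile the MS1 m/z range into ``n_windows`` windows with a sliding IM band."""
    windows = []
    span = cfg.ms1_mz_max - cfg.ms1_mz_min
    w_mz = span / max(cfg.n_windows, 1)
    im_span = cfg.ms1_im_max - cfg.ms1_im_min - cfg.window_im_width
    for i in range(cfg.n_windows):
        if cfg.n_windows > 1:
            im_lo = cfg.ms1_im_min + im_span * i / (cfg.n_windows - 1)
        else:
            im_lo = cfg.ms1_im_min + im_span / 2
        windows.append(
            DiaWindow(
                window_id=i,
                mz_low=cfg.ms1_mz_min + i * w_mz,
                mz_high=cfg.ms1_mz_min + (i + 1) * w_mz,
                im_low=im_lo,
                im_high=im_lo + cfg.window_im_width,
                cycle_position=i,
            )
        )
    return windows


def _sample_offsets(sigma: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Offsets covering +-3 sigma and Gaussian weights normalized to sum 1."""
    x = np.linspace(-3.0, 3.0, n)
    w = np.exp(-0.5 * x * x)
    return x * sigma, w / w.sum()


# sample spacing must stay below the bin width, otherwise binning aliases
# the profile and biases downstream center estimates
_N_IM_SAMPLES = 25
_N_MZ_SAMPLES = 21


def _draw_species(cfg: SimConfig, rng: np.random.Generator,
                  windows: list[DiaWindow]) -> list[TrueSpecies]:
    species = []
    gradient_lo = 0.15 * cfg.gradient_length_s
    gradient_hi = 0.85 * cfg.gradient_length_s
    total = cfg.n_species + cfg.out_of_window_species
    for sid in range(total):
        out_of_window = sid >= cfg.n_species
        w = windows[int(rng.integers(len(windows)))]
        charge = int(rng.choice(cfg.charges))
        n_iso = int(rng.integers(cfg.n_isotopes_min, cfg.n_isotopes_max + 1))
        im_sigma = float(rng.uniform(cfg.im_sigma_min, cfg.im_sigma_max))
        # keep the full envelope and the IM profile inside the window
        mz_margin = n_iso * ISOTOPE_DELTA / charge + 4 * cfg.mz_sigma_bins * cfg.mz_step
        mono_mz = float(rng.uniform(w.mz_low + 0.5, w.mz_high - mz_margin))
        im_margin = 3 * im_sigma + 0.01
        if out_of_window:
            im_apex = cfg.ms1_im_max - 0.002  # above every window band
            if any(win.contains(mono_mz, im_apex) for win in windows):
                im_apex = cfg.ms1_im_min + 0.002
        else:
            im_apex = float(rng.uniform(w.im_low + im_margin, w.im_high - im_margin))
        rt_sigma = float(rng.uniform(cfg.rt_sigma_min, cfg.rt_sigma_max))
        rt_apex = float(rng.uniform(gradient_lo, gradient_hi))
        abundance = float(np.exp(rng.uniform(np.log(cfg.abundance_min),
                                             np.log(cfg.abundance_max))))
        mono_mass = mono_mz * charge - charge * PROTON_MASS
        env = isotope_envelope(mono_mass, n_iso)

        frags = []
        for fi in range(cfg.n_fragments + cfg.n_decoy_fragments):
            is_decoy = fi >= cfg.n_fragments
            fmz = float(rng.uniform(cfg.ms2_mz_min + 1.0, cfg.ms2_mz_max - 1.0))
            rel = float(rng.uniform(cfg.fragment_rel_min, cfg.fragment_rel_max))
            if is_decoy:
                # keep decoys well away from the true apex so they are
                # genuinely uncorrelated interference; cap the exclusion
                # radius so short gradients still leave room to draw
                avoid = min(6 * rt_sigma, 0.35 * (gradient_hi - gradient_lo))
                f_rt = float(rng.uniform(gradient_lo, gradient_hi))
                for _ in range(100):
                    if abs(f_rt - rt_apex) >= avoid:
                        break
                    f_rt = float(rng.uniform(gradient_lo, gradient_hi))
                f_im = float(rng.uniform(w.im_low + im_margin, w.im_high - im_margin))
            else:
                f_rt = rt_apex + float(rng.uniform(-1, 1)) * cfg.fragment_rt_jitter_s
                f_im = im_apex + float(rng.uniform(-1, 1)) * cfg.fragment_im_jitter
                f_im = float(np.clip(f_im, w.im_low + im_margin, w.im_high - im_margin))
            frags.append(FragmentSpec(mz=fmz, rel_intensity=rel, rt_apex=f_rt,
                                      im_apex=f_im, is_decoy=is_decoy))

        in_window = any(win.contains(mono_mz, im_apex) for win in windows)
        species.append(
            TrueSpecies(
                species_id=sid,
                monoisotopic_mz=mono_mz,
                charge=charge,
                rt_apex=rt_apex,
                rt_sigma=rt_sigma,
                im_apex=im_apex,
                im_sigma=im_sigma,
                abundance=abundance,
                n_isotopes=n_iso,
                envelope=tuple(float(v) for v in env),
                fragments=tuple(frags),
                window_id=w.window_id if in_window else None,
                in_window=in_window,
            )
        )
    return species


def _plant_profile(buf: list, rng: np.random.Generator, cfg: SimConfig,
                   mz_center: float, im_center: float, amount: float,
                   im_sigma: float, im_clip: tuple[float, float]) -> None:
    """Append one separable 2D Gaussian sample cloud scaled to ``amount``."""
    im_off, im_w = _sample_offsets(im_sigma, _N_IM_SAMPLES)
    mz_off, mz_w = _sample_offsets(cfg.mz_sigma_bins * cfg.mz_step, _N_MZ_SAMPLES)
    mz = (mz_center + mz_off)[:, None] + np.zeros(_N_IM_SAMPLES)[None, :]
    im = np.zeros(_N_MZ_SAMPLES)[:, None] + (im_center + im_off)[None, :]
    inten = amount * mz_w[:, None] * im_w[None, :]
    mz, im, inten = mz.ravel(), im.ravel(), inten.ravel()
    if cfg.intensity_log_sigma > 0:
        inten = inten * np.exp(rng.normal(0.0, cfg.intensity_log_sigma, inten.size))
    keep = (inten > cfg.intensity_floor) & (im >= im_clip[0]) & (im < im_clip[1])
    if np.any(keep):
        buf.append(np.column_stack([mz[keep], im[keep], inten[keep]]))


def simulate_run(cfg: SimConfig) -> tuple[RunFixture, list[TrueSpecies]]:
    """Generate a run and its ground-truth manifest.

    Deterministic for a fixed ``cfg`` (one named RNG seeded from
    ``cfg.rng_seed``; the seed is recorded in the fixture metadata).
    Species whose precursor falls outside every window raise a warning and
    are flagged ``in_window=False`` in the manifest.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    windows = build_windows(cfg)
    species = _draw_species(cfg, rng, windows)

    for sp in species:
        if not sp.in_window:
            warnings.warn(
                f"species {sp.species_id} falls outside all isolation windows",
                stacklevel=2,
            )

    # frame skeleton: each cycle is one MS1 frame followed by one MS2 frame
    # per window (cycle_position order)
    frames_per_cycle = 1 + cfg.n_windows
    n_cycles = max(int(cfg.gradient_length_s / cfg.cycle_time_s), 1)
    frame_dt = cfg.cycle_time_s / frames_per_cycle
    frame_meta: list[tuple[int, float, int, Optional[DiaWindow]]] = []
    fid = 0
    for c in range(n_cycles):
        t0 = c * cfg.cycle_time_s
        fid += 1
        frame_meta.append((fid, t0, 1, None))
        for w in windows:
            fid += 1
            frame_meta.append((fid, t0 + (w.cycle_position + 1) * frame_dt, 2, w))

    buffers: dict[int, list] = {f[0]: [] for f in frame_meta}
    ms1_ids = [(f[0], f[1]) for f in frame_meta if f[2] == 1]
    ms2_by_window: dict[int, list[tuple[int, float]]] = {}
    for f in frame_meta:
        if f[2] == 2:
            ms2_by_window.setdefault(f[3].window_id, []).append((f[0], f[1]))

    ms1_im_clip = (cfg.ms1_im_min, cfg.ms1_im_max)
    for sp in species:
        for frame_id, rt in ms1_ids:
            z_rt = (rt - sp.rt_apex) / sp.rt_sigma
            if abs(z_rt) > 3.0:
                continue
            w_rt = float(np.exp(-0.5 * z_rt * z_rt))
            for k in range(sp.n_isotopes):
                amount = sp.abundance * w_rt * sp.envelope[k]
                mz_k = sp.monoisotopic_mz + k * ISOTOPE_DELTA / sp.charge
                _plant_profile(buffers[frame_id], rng, cfg, mz_k, sp.im_apex,
                               amount, sp.im_sigma, ms1_im_clip)
        if sp.window_id is None:
            continue
        w = windows[sp.window_id]
        im_clip = (w.im_low, w.im_high)
        for frag in sp.fragments:
            for frame_id, rt in ms2_by_window[sp.window_id]:
                z_rt = (rt - frag.rt_apex) / sp.rt_sigma
                if abs(z_rt) > 3.0:
                    continue
                w_rt = float(np.exp(-0.5 * z_rt * z_rt))
                amount = sp.abundance * frag.rel_intensity * w_rt
                _plant_profile(buffers[frame_id], rng, cfg, frag.mz,
                               frag.im_apex, amount, sp.im_sigma, im_clip)

    # chemical noise: uniform over each frame's (m/z, IM) rectangle
    if cfg.noise_density > 0:
        for frame_id, rt, level, w in frame_meta:
            n = cfg.noise_density
            if level == 1:
                mz = rng.uniform(cfg.ms1_mz_min, cfg.ms1_mz_max, n)
                im = rng.uniform(cfg.ms1_im_min, cfg.ms1_im_max, n)
            else:
                mz = rng.uniform(cfg.ms2_mz_min, cfg.ms2_mz_max, n)
                im = rng.uniform(w.im_low, w.im_high, n)
            inten = cfg.noise_median_intensity * np.exp(
                rng.normal(0.0, cfg.noise_log_sigma, n)
            )
            keep = inten > cfg.intensity_floor
            if np.any(keep):
                buffers[frame_id].append(np.column_stack([mz[keep], im[keep], inten[keep]]))

    frames = []
    for frame_id, rt, level, w in frame_meta:
        chunks = buffers[frame_id]
        if chunks:
            pts = np.concatenate(chunks, axis=0)
            order = np.lexsort((pts[:, 0], pts[:, 1]))
            pts = pts[order]
        else:
            pts = np.empty((0, 3))
        segs = [(w.im_low, w.im_high, w.window_id)] if level == 2 else []
        frames.append(MobilityFrame(frame_id=frame_id, rt_seconds=rt,
                                    ms_level=level, points=pts, window_segments=segs))

    meta = RunMeta(
        mz_step=cfg.mz_step,
        im_step=cfg.im_step,
        label=cfg.label,
        ms1_mz_min=cfg.ms1_mz_min,
        ms1_mz_max=cfg.ms1_mz_max,
        ms1_im_min=cfg.ms1_im_min,
        ms1_im_max=cfg.ms1_im_max,
        ms2_mz_min=cfg.ms2_mz_min,
        ms2_mz_max=cfg.ms2_mz_max,
        seed=cfg.rng_seed,
    )
    run = RunFixture(frames=frames, windows=windows, meta=meta)
    validate_run(run)
    return run, species


# ---------------------------------------------------------------------------
# manifest I/O

_SPECIES_COLS = ("species_id", "monoisotopic_mz", "charge", "rt_apex", "rt_sigma",
                 "im_apex", "im_sigma", "abundance", "n_isotopes", "envelope",
                 "window_id", "in_window")
_FRAG_COLS = ("species_id", "mz", "rel_intensity", "rt_apex", "im_apex", "is_decoy")


def write_manifest(species: Sequence[TrueSpecies], path) -> None:
    """Write the ground-truth manifest as a two-record-type TSV."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#S\t" + "\t".join(_SPECIES_COLS) + "\n")
        fh.write("#G\t" + "\t".join(_FRAG_COLS) + "\n")
        for sp in species:
            env = ",".join(repr(v) for v in sp.envelope)
            wid = "" if sp.window_id is None else str(sp.window_id)
            fh.write(
                f"S\t{sp.species_id}\t{sp.monoisotopic_mz!r}\t{sp.charge}"
                f"\t{sp.rt_apex!r}\t{sp.rt_sigma!r}\t{sp.im_apex!r}\t{sp.im_sigma!r}"
                f"\t{sp.abundance!r}\t{sp.n_isotopes}\t{env}\t{wid}\t{int(sp.in_window)}\n"
            )
            for fr in sp.fragments:
                fh.write(
                    f"G\t{sp.species_id}\t{fr.mz!r}\t{fr.rel_intensity!r}"
                    f"\t{fr.rt_apex!r}\t{fr.im_apex!r}\t{int(fr.is_decoy)}\n"
                )


def read_manifest(path) -> list[TrueSpecies]:
    rows: dict[int, dict] = {}
    frag_rows: dict[int, list[FragmentSpec]] = {}
    order: list[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "S":
                sid = int(cols[1])
                order.append(sid)
                rows[sid] = dict(
                    monoisotopic_mz=float(cols[2]),
                    charge=int(cols[3]),
                    rt_apex=float(cols[4]),
                    rt_sigma=float(cols[5]),
                    im_apex=float(cols[6]),
                    im_sigma=float(cols[7]),
                    abundance=float(cols[8]),
                    n_isotopes=int(cols[9]),
                    envelope=tuple(float(v) for v in cols[10].split(",")),
                    window_id=int(cols[11]) if cols[11] else None,
                    in_window=bool(int(cols[12])),
                )
            elif cols[0] == "G":
                sid = int(cols[1])
                frag_rows.setdefault(sid, []).append(
                    FragmentSpec(
                        mz=float(cols[2]),
                        rel_intensity=float(cols[3]),
                        rt_apex=float(cols[4]),
                        im_apex=float(cols[5]),
                        is_decoy=bool(int(cols[6])),
                    )
                )
            else:
                raise FixtureValidationError(f"unknown manifest record {cols[0]!r}")
    return [
        TrueSpecies(species_id=sid, fragments=tuple(frag_rows.get(sid, [])), **rows[sid])
        for sid in order
    ]
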