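"""Pseudo-MS/MS assembly: pair each precursor with correlated fragments.

For every precursor the candidate fragments are the MS2 XIC features of the
isolation window containing the precursor, within the apex RT and IM
tolerances.  Candidates are gated by the Pearson correlation between the
smoothed monoisotopic precursor XIC and the raw fragment XIC, capped at the
``rf_max`` most intense, and emitted as one DDA-like spectrum per retained
charge state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .isotope_group import PrecursorFeature
from .run_model import DiaWindow
from .xic_trace import XICFeature

__all__ = [
    "PseudoSpectrum",
    "AssemblyConfig",
    "mass_defect_pass",
    "pearson",
    "xic_pearson",
    "assemble",
    "write_sidecar",
]


@dataclass
class PseudoSpectrum:
    """A DDA-like MS/MS record assembled from DIA data.

    ``fragments`` holds ``(mz, intensity, corr)`` sorted by ascending m/z;
    intensities are the fragment XIC apex intensities.
    """

    precursor_mz: float
    charges: list[int]
    rt: float
    im: float
    fragments: list[tuple[float, float, float]]
    precursor_id: int
    window_id: int


@dataclass
class AssemblyConfig:
    delta_apex_im: float = 0.02
    delta_apex_rt: float = 3.0
    corr_threshold: float = 0.3
    rf_max: int = 500
    mass_defect_filter: bool = False
    min_fragments: int = 4
    sg_window: int = 5
    sg_order: int = 2

    def validate(self) -> None:
        if self.delta_apex_im <= 0 or self.delta_apex_rt <= 0:
            raise ValueError("apex tolerances must be positive")
        if self.rf_max < 1:
            raise ValueError("rf_max must be >= 1")


# ---------------------------------------------------------------------------
# fractional-mass (mass defect) filter

_DEFECT_SLOPE = 0.000507
_DEFECT_HALF_WIDTH = 0.15
_DEFECT_WIDEN_PER_100DA = 0.001


def mass_defect_pass(neutral_mass: float, enabled: bool = True) -> bool:
    """True when the fractional mass is inside the tryptic-peptide band.

    The band is centered at ``0.000507 * mass (mod 1)`` with half-width
    ``0.15 + 0.001 per 100 Da``; the distance is circular modulo 1.  With the
    filter disabled every mass passes.
    """
    if not enabled:
        return True
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    center = (_DEFECT_SLOPE * neutral_mass) % 1.0
    frac = neutral_mass % 1.0
    d = abs(frac - center)
    d = min(d, 1.0 - d)
    half_width = _DEFECT_HALF_WIDTH + _DEFECT_WIDEN_PER_100DA * (neutral_mass / 100.0)
    return d <= half_width


# ---------------------------------------------------------------------------
# correlation


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Textbook Pearson r; the undefined (zero-variance) case returns 0."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    if denom == 0:
        return 0.0
    return float((xd * yd).sum() / denom)


def _smooth(y: np.ndarray, window: int, order: int) -> np.ndarray:
    if y.size < 3:
        return y
    w = min(window, y.size if y.size % 2 == 1 else y.size - 1)
    if w < 3:
        return y
    return savgol_filter(y, w, min(order, w - 1))


def xic_pearson(precursor: XICFeature, fragment: XICFeature,
                sg_window: int = 5, sg_order: int = 2) -> float:
    """Correlation of a precursor XIC and a fragment XIC on a shared grid.

    Both traces are resampled onto the precursor's retention-time grid (the
    fragment by linear interpolation of its own trace, zero outside it); the
    precursor trace is Savitzky-Golay smoothed, the fragment used raw.  Fewer
    than 3 grid points supported by the fragment trace returns the sentinel 0.
    """
    rts = precursor.rts
    py = _smooth(precursor.intensities.astype(np.float64), sg_window, sg_order)
    return _corr_prepared(rts, py, fragment)


def _corr_prepared(rts: np.ndarray, smoothed_precursor: np.ndarray,
                   fragment: XICFeature) -> float:
    frts = fragment.rts
    fy = fragment.intensities
    inside = (rts >= frts[0]) & (rts <= frts[-1])
    if int(inside.sum()) < 3:
        return 0.0
    fvals = np.where(inside, np.interp(rts, frts, fy), 0.0)
    return pearson(smoothed_precursor, fvals)


# ---------------------------------------------------------------------------
# assembly


def _locate_window(windows: Sequence[DiaWindow], mz: float,
                   im: float) -> Optional[DiaWindow]:
    hits = [w for w in windows if w.contains(mz, im)]
    return min(hits, key=lambda w: w.window_id) if hits else None


def assemble(precursors: Sequence[PrecursorFeature],
             ms2_by_window: dict[int, Sequence[XICFeature]],
             windows: Sequence[DiaWindow],
             cfg: Optional[AssemblyConfig] = None,
             log=None) -> list[PseudoSpectrum]:
    """Build pseudo-MS/MS spectra for every precursor.

    Fragments may be shared across precursors (no exclusivity).  Precursors
    outside every window are skipped (logged, not an error).  A precursor
    with k retained charges emits k spectra sharing one fragment list.
    """
    cfg = cfg or AssemblyConfig()
    cfg.validate()
    out: list[PseudoSpectrum] = []
    for prec in sorted(precursors, key=lambda p: (p.apex_rt, p.monoisotopic_mz)):
        charges = list(prec.charges)
        if cfg.mass_defect_filter:
            charges = [z for z in charges
                       if mass_defect_pass(prec.neutral_mass(z), True)]
            if not charges:
                continue
        w = _locate_window(windows, prec.monoisotopic_mz, prec.apex_im)
        if w is None:
            if log is not None:
                log(f"precursor {prec.precursor_id} at m/z "
                    f"{prec.monoisotopic_mz:.4f}, 1/K0 {prec.apex_im:.4f} "
                    "outside every isolation window; skipped")
            continue
        mono = prec.mono_xic
        prec_rts = mono.rts
        prec_smoothed = _smooth(mono.intensities.astype(np.float64),
                                cfg.sg_window, cfg.sg_order)
        kept: list[tuple[float, float, float]] = []
        for frag in ms2_by_window.get(w.window_id, ()):  # candidates
            if abs(frag.apex_rt - prec.apex_rt) > cfg.delta_apex_rt:
                continue
            if abs(frag.im - prec.apex_im) > cfg.delta_apex_im:
                continue
            r = _corr_prepared(prec_rts, prec_smoothed, frag)
            if r >= cfg.corr_threshold:
                kept.append((frag.mz, frag.apex_intensity, r))
        if len(kept) > cfg.rf_max:
            kept.sort(key=lambda t: (-t[1], t[0]))
            kept = kept[: cfg.rf_max]
        if len(kept) < cfg.min_fragments:
            continue
        kept.sort(key=lambda t: t[0])
        for z in charges:
            out.append(
                PseudoSpectrum(
                    precursor_mz=prec.monoisotopic_mz,
                    charges=[z],
                    rt=prec.apex_rt,
                    im=prec.apex_im,
                    fragments=list(kept),
                    precursor_id=prec.precursor_id,
                    window_id=w.window_id,
                )
            )
    return out


def write_sidecar(spectra: Sequence[PseudoSpectrum], path) -> None:
    """Provenance TSV: one row per emitted spectrum."""
    cols = ("spectrum_index", "precursor_id", "charge", "window_id",
            "precursor_mz", "rt", "im", "n_fragments", "min_corr", "median_corr")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, s in enumerate(spectra):
            corrs = [c for _mz, _i, c in s.fragments]
            fh.write(
                f"{i}\t{s.precursor_id}\t{s.charges[0]}\t{s.window_id}"
                f"\t{s.precursor_mz!r}\t{s.rt!r}\t{s.im!r}\t{len(s.fragments)}"
                f"\t{min(corrs)!r}\t{float(np.median(corrs))!r}\n"
            )
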