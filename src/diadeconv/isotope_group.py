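"""Isotope clustering and charge assignment for traced MS1 features.

MS1 :class:`~diadeconv.xic_trace.XICFeature` objects are grouped into isotope
envelopes by the C13 spacing rule (adjacent members ``1.0033548/z`` apart in
m/z, co-apexing within RT and IM tolerances).  Clusters are scored by the
Pearson correlation of member intensities against the averagine envelope and
by the mean pairwise correlation of member XICs; confident clusters claim
their members exclusively.  Unclaimed features are retained as
charge-ambiguous singleton precursors.  MS2 features never pass through this
module (fragments are not deisotoped).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .pasef_sim import ISOTOPE_DELTA, PROTON_MASS, isotope_envelope
from .xic_trace import XICFeature

__all__ = [
    "PrecursorFeature",
    "group_isotopes",
    "envelope_corr",
    "xic_corr",
    "assign_charge",
]


@dataclass
class PrecursorFeature:
    """An isotope cluster: monoisotopic coordinates plus quality scores."""

    monoisotopic_mz: float
    charges: list[int]
    members: list[XICFeature]
    envelope_corr: float
    xic_corr: float
    apex_rt: float
    apex_im: float
    intensity: float
    precursor_id: int = -1

    @property
    def mono_xic(self) -> XICFeature:
        return self.members[0]

    def neutral_mass(self, charge: int) -> float:
        return self.monoisotopic_mz * charge - charge * PROTON_MASS


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    if denom == 0:
        return 0.0
    return float((xd * yd).sum() / denom)


def envelope_corr(member_intensities: Sequence[float], mono_mass: float) -> float:
    """Pearson r between member apex intensities and the averagine envelope.

    Singletons return the sentinel 1.0 (nothing to contradict the model);
    zero-variance inputs return the undefined-correlation sentinel 0.
    """
    obs = np.asarray(member_intensities, dtype=np.float64)
    if obs.size < 2:
        return 1.0
    theo = isotope_envelope(mono_mass, obs.size)
    return _pearson(obs, theo)


def xic_corr(members: Sequence[XICFeature]) -> float:
    """Mean pairwise Pearson r of member XIC traces on the union frame grid."""
    if len(members) < 2:
        return 1.0
    traces = []
    for m in members:
        traces.append({fid: inten for fid, _rt, inten in m.rt_trace})
    rs = []
    for a in range(len(traces)):
        for b in range(a + 1, len(traces)):
            fids = sorted(set(traces[a]) | set(traces[b]))
            xa = np.array([traces[a].get(f, 0.0) for f in fids])
            xb = np.array([traces[b].get(f, 0.0) for f in fids])
            rs.append(_pearson(xa, xb))
    return float(np.mean(rs))


def assign_charge(spacings: Sequence[float], iso_ppm: float = 20.0,
                  observed_mz: Optional[float] = None, max_charge: int = 4,
                  default_charges: Sequence[int] = (2, 3)) -> list[int]:
    """Charge states consistent with the observed isotope spacings.

    All ``z`` in ``1..max_charge`` whose theoretical spacing ``1.0033548/z``
    lies within ``iso_ppm`` (relative to ``observed_mz``) of the mean observed
    spacing are returned, ranked by spacing residual.  With no spacings
    (singleton cluster) the configured default charge list is returned.
    """
    spacings = list(spacings)
    if not spacings:
        return list(default_charges)
    if observed_mz is None:
        raise ValueError("observed_mz required when spacings are given")
    mean_sp = float(np.mean(spacings))
    tol = iso_ppm * 1e-6 * observed_mz
    hits = []
    for z in range(1, max_charge + 1):
        resid = abs(mean_sp - ISOTOPE_DELTA / z)
        if resid <= tol:
            hits.append((resid, z))
    hits.sort()
    return [z for _resid, z in hits]


def _build_chain(seed_idx: int, z: int, order: np.ndarray, mzs: np.ndarray,
                 rts: np.ndarray, ims: np.ndarray, available: np.ndarray,
                 iso_ppm: float, rt_tol: float, im_tol: float) -> list[int]:
    """Greedy bidirectional extension of an isotope chain at charge ``z``.

    Returns member indices ordered by ascending m/z (seed included).
    """
    delta = ISOTOPE_DELTA / z
    rt0, im0 = rts[seed_idx], ims[seed_idx]

    def nearest(expected: float, exclude: set[int]) -> int:
        tol = iso_ppm * 1e-6 * expected
        best, best_d = -1, None
        lo = np.searchsorted(mzs[order], expected - tol, side="left")
        hi = np.searchsorted(mzs[order], expected + tol, side="right")
        for k in order[lo:hi]:
            if not available[k] or k in exclude:
                continue
            if abs(rts[k] - rt0) > rt_tol or abs(ims[k] - im0) > im_tol:
                continue
            d = abs(mzs[k] - expected)
            if best_d is None or d < best_d:
                best, best_d = int(k), d
        return best

    chain = [seed_idx]
    used = {seed_idx}
    cur = mzs[seed_idx]
    while True:  # rightward (heavier isotopes)
        nxt = nearest(cur + delta, used)
        if nxt < 0:
            break
        chain.append(nxt)
        used.add(nxt)
        cur = mzs[nxt]
    cur = mzs[seed_idx]
    left = []
    while True:  # leftward, toward the monoisotopic member
        nxt = nearest(cur - delta, used)
        if nxt < 0:
            break
        left.append(nxt)
        used.add(nxt)
        cur = mzs[nxt]
    return list(reversed(left)) + chain


def group_isotopes(ms1_features: Sequence[XICFeature], rt_tol: float,
                   im_tol: float, max_charge: int = 4, iso_ppm: float = 20.0,
                   confidence_env: float = 0.6, confidence_xic: float = 0.6,
                   default_charges: Sequence[int] = (2, 3),
                   min_members: int = 1) -> list[PrecursorFeature]:
    """Cluster MS1 features into isotope envelopes and assign charges.

    Seeding is greedy from the most intense unprocessed feature (ties broken
    by m/z then IM, making the output invariant to input order).  For each
    candidate charge from ``max_charge`` down, the chain of expected isotopes
    is extended within tolerances; the best chain (most members, then highest
    envelope correlation) defines the cluster.  Members are claimed — removed
    from further seeding — only when both correlation scores pass the
    confidence thresholds.  Chains of one feature become charge-ambiguous
    singleton precursors carrying ``default_charges``.
    """
    feats = list(ms1_features)
    n = len(feats)
    if n == 0:
        return []
    mzs = np.array([f.mz for f in feats])
    rts = np.array([f.apex_rt for f in feats])
    ims = np.array([f.im for f in feats])
    intens = np.array([f.apex_intensity for f in feats])
    mz_order = np.argsort(mzs, kind="stable")
    seed_order = sorted(range(n), key=lambda k: (-intens[k], mzs[k], ims[k]))

    available = np.ones(n, dtype=bool)   # claimable by a confident cluster
    seeded = np.zeros(n, dtype=bool)     # already used as a seed
    out: list[PrecursorFeature] = []
    # isotope positions of emitted multi-member clusters: retention rule for
    # singletons (a leftover isotope of an emitted envelope is not a new
    # precursor)
    emitted_positions: list[tuple[float, float, float]] = []  # (mz, rt, im)

    def is_leftover_isotope(k: int) -> bool:
        for mz_e, rt_e, im_e in emitted_positions:
            if (abs(mzs[k] - mz_e) <= iso_ppm * 1e-6 * mz_e
                    and abs(rts[k] - rt_e) <= rt_tol
                    and abs(ims[k] - im_e) <= im_tol):
                return True
        return False

    for seed in seed_order:
        if not available[seed] or seeded[seed]:
            continue
        seeded[seed] = True

        best_chain: list[int] = [seed]
        best_key = None
        best_z = 0
        for z in range(max_charge, 0, -1):
            chain = _build_chain(seed, z, mz_order, mzs, rts, ims, available,
                                 iso_ppm, rt_tol, im_tol)
            if len(chain) < 2:
                continue
            mono_mass = mzs[chain[0]] * z - z * PROTON_MASS
            r = envelope_corr(intens[chain], mono_mass)
            key = (len(chain), r, -z)
            if best_key is None or key > best_key:
                best_key, best_chain, best_z = key, chain, z
        chain = best_chain

        members = [feats[k] for k in chain]
        mono = feats[chain[0]]
        if len(chain) >= 2:
            z = best_z
            spacings = [mzs[b] - mzs[a] for a, b in zip(chain, chain[1:])]
            charges = assign_charge(spacings, iso_ppm, observed_mz=mono.mz,
                                    max_charge=max_charge,
                                    default_charges=default_charges)
            if not charges:
                charges = [z]
            mono_mass = mono.mz * z - z * PROTON_MASS
            env_r = envelope_corr(intens[chain], mono_mass)
            x_r = xic_corr(members)
            if env_r >= confidence_env and x_r >= confidence_xic:
                for k in chain:
                    available[k] = False
            # an emitted chain consumes its members as seeds (they may still
            # be claimed by another cluster, but cannot rebuild this one)
            for k in chain:
                seeded[k] = True
            emitted_positions.extend(
                (mzs[k], rts[k], ims[k]) for k in chain
            )
        else:
            charges = list(default_charges)
            env_r, x_r = 1.0, 1.0
            if is_leftover_isotope(seed):
                continue
        if len(chain) < min_members:
            continue
        out.append(
            PrecursorFeature(
                monoisotopic_mz=float(mono.mz),
                charges=list(charges),
                members=members,
                envelope_corr=float(env_r),
                xic_corr=float(x_r),
                apex_rt=float(mono.apex_rt),
                apex_im=float(mono.im),
                intensity=float(intens[chain].sum()),
            )
        )

    out.sort(key=lambda p: (p.apex_rt, p.monoisotopic_mz))
    for i, p in enumerate(out):
        p.precursor_id = i
    return out
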