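"""End-to-end unit tracking across sessions.

For a pair of sessions the pipeline is: localize included units (KSgood,
peak ptp > 60 µV) -> extract waveform patches -> stage-1 EMD on the
combined cost -> estimate rigid z-drift as the mode of matched
z-displacements -> shift the second session's unit depths -> rebuild the
location distances (waveform distances are drift-tolerant and unchanged)
-> stage-2 EMD -> flag pairs by the z-distance threshold.

Pairs passing the threshold feed two further products: performance metrics
against a reference set (recovery rate: fraction of reference pairs that
the assignment reproduces; accuracy: among threshold-passing assignments
of reference units, the fraction agreeing with the reference), and chains:
units traced through >= 3 consecutive sessions, classified by how much
receptive-field information their members carry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drift_threshold import (DEFAULT_Z_THRESHOLD, DriftEstimate,
                              ThresholdFit, apply_drift_correction,
                              estimate_rigid_drift, fit_z_distribution,
                              select_threshold)
from .emd_core import DEFAULT_OMEGA, build_cost_matrix, solve_transport
from .io_formats import RawSessionBundle
from .localization import (MIN_PEAK_PTP_UV, UnitRecord, channel_ptp,
                           compute_ptp_amplitudes, estimate_unit_location)
from .waveform_metric import WaveformPatch, select_waveform_channels

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["unit1", "unit2", "d_loc", "d_wf", "distance",
                "z_distance", "passes_threshold"]


@dataclass
class MatchResult:
    """EMD assignment between two sessions with distances and flags."""

    session1: str
    session2: str
    pairs: pd.DataFrame                   # PAIR_COLUMNS; z_distance signed
    drift: DriftEstimate
    threshold: float                      # µm on |z_distance|
    total_cost_pre: float
    total_cost_post: float
    omega: float
    threshold_fit: ThresholdFit | None = None
    per_shank_drift: dict[int, float] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def passing_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["passes_threshold"]]

    def assignment(self) -> dict[int, int]:
        return dict(zip(self.pairs["unit1"].astype(int),
                        self.pairs["unit2"].astype(int)))

    def metadata(self) -> dict:
        meta = {
            "session1": self.session1,
            "session2": self.session2,
            "omega": self.omega,
            "z_threshold": self.threshold,
            "drift_mode": self.drift.z_mode,
            "drift_bandwidth": self.drift.bandwidth,
            "drift_n_pairs": self.drift.n_pairs,
            "total_cost_pre_correction": self.total_cost_pre,
            "total_cost_post_correction": self.total_cost_post,
            "n_pairs": self.n_pairs,
            "n_passing": int(self.pairs["passes_threshold"].sum()),
        }
        if self.per_shank_drift:
            meta["per_shank_drift"] = {
                str(k): v for k, v in self.per_shank_drift.items()}
        if self.threshold_fit is not None:
            tf = self.threshold_fit
            meta["threshold_fit"] = {"f": tf.f, "sigma": tf.sigma,
                                     "c": tf.c, "d": tf.d}
        return meta


@dataclass(frozen=True)
class Chain:
    """A unit traced through >= 3 consecutive sessions."""

    members: tuple[tuple[str, int], ...]   # ((session_id, unit_id), ...)
    classification: str = "unclassified"
    fully_trackable: bool = False

    @property
    def length(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# unit preparation
# ---------------------------------------------------------------------------

def prepare_units(bundle: RawSessionBundle, include_mua: bool = False,
                  min_ptp_uv: float = MIN_PEAK_PTP_UV
                  ) -> tuple[list[UnitRecord], list[WaveformPatch]]:
    """Localize and patch every included unit of a session.

    Included units are KSgood (unless ``include_mua``) with raw peak ptp
    above the amplitude filter; units failing either are dropped from
    matching entirely.
    """
    cmap = bundle.channel_map
    units, patches = [], []
    for _, row in bundle.cluster_labels.iterrows():
        cid = int(row["cluster_id"])
        quality = str(row["quality"])
        if quality != "good" and not include_mua:
            continue
        wf = bundle.waveform(cid)
        peak_ptp = float(channel_ptp(wf).max())
        if peak_ptp <= min_ptp_uv:
            continue
        peak_channel, amps, partial = compute_ptp_amplitudes(wf, cmap)
        location, alpha, fallback = estimate_unit_location(
            amps, cmap, peak_channel=peak_channel)
        units.append(UnitRecord(
            unit_id=cid, session_id=bundle.session_id, quality=quality,
            peak_channel=peak_channel,
            shank_id=int(cmap.shank_id[peak_channel]),
            ptp_amplitudes=amps, location=location, alpha=alpha,
            peak_ptp=peak_ptp, firing_rate=bundle.firing_rate(cid),
            included=True, partial_set=partial, fallback=fallback))
        patches.append(select_waveform_channels(wf, cmap, peak_channel,
                                                unit_id=cid))
    return units, patches


# ---------------------------------------------------------------------------
# session pair matching
# ---------------------------------------------------------------------------

def match_sessions(s1: RawSessionBundle, s2: RawSessionBundle,
                   omega: float = DEFAULT_OMEGA,
                   z_threshold: float = DEFAULT_Z_THRESHOLD,
                   threshold_policy: str = "fixed",
                   target_fpr: float = 0.27,
                   include_mua: bool = False,
                   min_drift_pairs: int = 10,
                   per_shank_drift: bool = True,
                   sigma_fixed: float | None = None) -> MatchResult:
    """Run the full two-stage matching pipeline for one session pair.

    ``threshold_policy``: 'fixed' uses ``z_threshold`` directly; 'fit'
    fits the z-distance mixture of the stage-2 matches and selects the
    threshold at ``target_fpr`` (falling back, with a warning, to the
    fixed default when the fit is impossible).  Deterministic given
    identical inputs and configuration.
    """
    units1, patches1 = prepare_units(s1, include_mua=include_mua)
    units2, patches2 = prepare_units(s2, include_mua=include_mua)
    if not units1 or not units2:
        raise ValueError(
            f"no included units ({len(units1)} vs {len(units2)}); "
            "cannot match")

    cost1 = build_cost_matrix(units1, units2, patches1, patches2, omega)
    plan1 = solve_transport(cost1)

    good_pairs = [(i, k) for i, k in plan1.assignment
                  if units1[i].quality == "good"
                  and units2[k].quality == "good"]
    drift, shank_modes = _estimate_drift(units1, units2, good_pairs,
                                         min_drift_pairs, per_shank_drift)

    corrected2 = [u.with_z(u.z - shank_modes.get(u.shank_id, drift.z_mode))
                  for u in units2]
    d_loc2 = _pairwise_dloc(units1, corrected2)
    cost2 = type(cost1)(d_loc=d_loc2, d_wf=cost1.d_wf, omega=omega)
    plan2 = solve_transport(cost2)

    rows = []
    for i, k in plan2.assignment:
        dz = corrected2[k].z - units1[i].z
        rows.append((units1[i].unit_id, corrected2[k].unit_id,
                     cost2.d_loc[i, k], cost2.d_wf[i, k], cost2.D[i, k], dz))
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS[:-1])

    fit = None
    threshold = float(z_threshold)
    if threshold_policy == "fit":
        try:
            fit = fit_z_distribution(np.abs(pairs["z_distance"].to_numpy()),
                                     sigma_fixed=sigma_fixed)
            threshold, _ = select_threshold(fit, target_fpr)
        except Exception as exc:  # fall back to the default operating point
            warnings.warn(
                f"threshold fit failed ({exc}); using the default "
                f"{DEFAULT_Z_THRESHOLD} µm threshold", stacklevel=2)
            threshold = DEFAULT_Z_THRESHOLD
    elif threshold_policy != "fixed":
        raise ValueError(f"unknown threshold policy {threshold_policy!r}")

    pairs["passes_threshold"] = np.abs(pairs["z_distance"]) <= threshold
    return MatchResult(
        session1=s1.session_id, session2=s2.session_id, pairs=pairs,
        drift=drift, threshold=threshold,
        total_cost_pre=plan1.total_cost, total_cost_post=plan2.total_cost,
        omega=omega, threshold_fit=fit, per_shank_drift=shank_modes)


def _pairwise_dloc(units1, units2) -> np.ndarray:
    loc1 = np.array([u.location for u in units1])
    loc2 = np.array([u.location for u in units2])
    diff = loc1[:, None, :] - loc2[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def _estimate_drift(units1, units2, good_pairs, min_pairs,
                    per_shank) -> tuple[DriftEstimate, dict[int, float]]:
    all_z = [(units1[i].z, units2[k].z) for i, k in good_pairs]
    drift = estimate_rigid_drift(all_z, min_pairs=min_pairs)
    shank_modes: dict[int, float] = {}
    if per_shank:
        shanks = {units2[k].shank_id for _, k in good_pairs}
        if len(shanks) > 1:
            for s in sorted(shanks):
                z = [(units1[i].z, units2[k].z) for i, k in good_pairs
                     if units2[k].shank_id == s]
                if len(z) >= min_pairs:
                    shank_modes[s] = estimate_rigid_drift(
                        z, min_pairs=min_pairs).z_mode
                else:
                    logger.info("shank %d has %d pairs (< %d); using the "
                                "global drift mode", s, len(z), min_pairs)
    return drift, shank_modes


def filter_by_z_threshold(result: MatchResult, z_thr: float) -> MatchResult:
    """Re-flag pairs at a new |z| threshold (pairs are unchanged)."""
    pairs = result.pairs.copy()
    pairs["passes_threshold"] = np.abs(pairs["z_distance"]) <= z_thr
    return MatchResult(
        session1=result.session1, session2=result.session2, pairs=pairs,
        drift=result.drift, threshold=float(z_thr),
        total_cost_pre=result.total_cost_pre,
        total_cost_post=result.total_cost_post, omega=result.omega,
        threshold_fit=result.threshold_fit,
        per_shank_drift=result.per_shank_drift)


def match_all(bundles: list[RawSessionBundle], mode: str = "consecutive",
              cost_gate_factor: float = 2.0,
              **kwargs) -> list[MatchResult]:
    """Match a session sequence pairwise.

    ``mode='consecutive'`` matches (1,2), (2,3), ...; ``mode='to-first'``
    matches (1, t) for every later t.  Warns on pairs whose stage-2 total
    cost per pair exceeds ``cost_gate_factor`` × the median across pairs —
    an indicator of very large drift between those sessions.
    """
    if len(bundles) < 2:
        raise ValueError("need at least two sessions")
    if mode == "consecutive":
        pairs = list(zip(bundles[:-1], bundles[1:]))
    elif mode == "to-first":
        pairs = [(bundles[0], b) for b in bundles[1:]]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    results = [match_sessions(a, b, **kwargs) for a, b in pairs]
    per_pair = np.array([r.total_cost_post / max(r.n_pairs, 1)
                         for r in results])
    if len(results) > 1:
        med = np.median(per_pair)
        for r, c in zip(results, per_pair):
            if c > cost_gate_factor * med:
                warnings.warn(
                    f"session pair {r.session1}->{r.session2} has per-pair "
                    f"EMD cost {c:.1f}, over {cost_gate_factor}x the median "
                    f"({med:.1f}); likely very large drift", stacklevel=2)
    return results


# ---------------------------------------------------------------------------
# performance metrics
# ---------------------------------------------------------------------------

def recovery_rate(result: MatchResult,
                  reference_pairs: set[tuple[int, int]] | list) -> float:
    """Fraction of reference pairs reproduced by the assignment."""
    ref = set(map(tuple, reference_pairs))
    if not ref:
        raise ValueError("reference set is empty; recovery rate undefined")
    emd = set(zip(result.pairs["unit1"].astype(int),
                  result.pairs["unit2"].astype(int)))
    return len(emd & ref) / len(ref)


def accuracy(result: MatchResult,
             reference_pairs: set[tuple[int, int]] | list,
             z_thr: float | None = None) -> float:
    """Among threshold-passing assignments of reference units, the
    fraction that agree with the reference pairing."""
    ref = dict((int(a), int(b)) for a, b in reference_pairs)
    if not ref:
        raise ValueError("reference set is empty; accuracy undefined")
    if z_thr is not None:
        result = filter_by_z_threshold(result, z_thr)
    passing = result.passing_pairs()
    sel = passing[passing["unit1"].astype(int).isin(ref)]
    if len(sel) == 0:
        raise ValueError("no reference-unit assignment passes the "
                         "threshold; accuracy undefined")
    agree = sum(ref[int(u1)] == int(u2)
                for u1, u2 in zip(sel["unit1"], sel["unit2"]))
    return agree / len(sel)


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------

MIN_CHAIN_SESSIONS = 3


def trace_chains(results: list[MatchResult],
                 min_length: int = MIN_CHAIN_SESSIONS) -> list[Chain]:
    """Trace threshold-passing links of consecutive matches into chains.

    ``results`` must chain session ids pairwise ((1,2), (2,3), ...).
    Only maximal traces spanning at least ``min_length`` sessions are
    returned; ``fully_trackable`` marks chains spanning every session.
    """
    if not results:
        return []
    for a, b in zip(results[:-1], results[1:]):
        if a.session2 != b.session1:
            raise ValueError(
                f"match results are not consecutive: {a.session2!r} "
                f"followed by {b.session1!r}")
    n_sessions = len(results) + 1
    links = []
    for r in results:
        passing = r.passing_pairs()
        links.append(dict(zip(passing["unit1"].astype(int),
                              passing["unit2"].astype(int))))
    sessions = [results[0].session1] + [r.session2 for r in results]

    chains = []
    continued = [set() for _ in range(n_sessions)]
    for t, mapping in enumerate(links):
        continued[t + 1] = set(mapping.values())
    for t in range(n_sessions - 1):
        for u in sorted(links[t]):
            if u in continued[t]:
                continue  # extended from an earlier session
            members = [(sessions[t], u)]
            cur, s = u, t
            while s < n_sessions - 1 and cur in links[s]:
                cur = links[s][cur]
                s += 1
                members.append((sessions[s], cur))
            if len(members) >= min_length:
                chains.append(Chain(members=tuple(members),
                                    fully_trackable=len(members)
                                    == n_sessions))
    return chains


def classify_chain(chain: Chain,
                   visual_info: set[tuple[str, int]] | dict) -> Chain:
    """reference: info in all sessions; putative: none; mixed: otherwise."""
    if isinstance(visual_info, dict):
        has = [bool(visual_info.get(m, False)) for m in chain.members]
    else:
        has = [m in visual_info for m in chain.members]
    if all(has):
        label = "reference"
    elif not any(has):
        label = "putative"
    else:
        label = "mixed"
    return Chain(members=chain.members, classification=label,
                 fully_trackable=chain.fully_trackable)
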