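"""Visual-response reference set for validating cross-session matches.

Units with reproducible image-evoked responses provide independent ground
truth: if two units in different sessions respond the same way to the same
images, they are very likely the same neuron.  Two response summaries are
computed per unit: the PSTH (1 ms-binned, Gaussian-smoothed histogram of
spikes in a 1800 ms window from 400 ms before to 400 ms after a 1000 ms
presentation) and the visual fingerprint (vfp; mean spike count per image
over the first second after onset, averaged over trials).  The similarity
of two units is the sum of the Pearson correlations of their PSTHs and
vfps, in (−2, 2).

Reference pairs are cross-session pairs with similarity > 1, physical
distance below 30 µm both before and after drift correction, both units
sorter-labeled 'good', and both significantly visually driven
(Kruskal-Wallis across images on the trial-wise vfp counts).  A unit with
several qualifying partners keeps only its highest-similarity one; pairs
are kept when mutual-best, which guarantees a partial matching.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger(__name__)

PSTH_PRE_MS = 400
PSTH_POST_MS = 400
STIM_DURATION_MS = 1000
PSTH_BIN_MS = 1
#: Gaussian smoothing width of the PSTH, ms
PSTH_SMOOTH_SIGMA_MS = 10.0
#: spike-count window after onset for the vfp, s
VFP_WINDOW_S = 1.0

SIMILARITY_THRESHOLD = 1.0
REFERENCE_DISTANCE_UM = 30.0
SIGNIFICANCE_ALPHA = 0.05


@dataclass
class VisualResponse:
    """A unit's stimulus-locked response summaries."""

    psth: np.ndarray          # (n_bins,) smoothed rate per 1 ms bin
    vfp: np.ndarray           # (n_images,) mean count over trials
    vfp_trials: np.ndarray    # (n_trials, n_images) counts
    significant: bool


@dataclass(frozen=True)
class ReferencePair:
    unit1: int
    unit2: int
    similarity: float
    psth_corr: float
    vfp_corr: float
    distance_pre: float
    distance_post: float


def compute_psth(spike_times: np.ndarray, stimulus_onsets: np.ndarray,
                 stim_duration_ms: float = STIM_DURATION_MS,
                 smooth_sigma_ms: float = PSTH_SMOOTH_SIGMA_MS) -> np.ndarray:
    """Trial-averaged smoothed PSTH over [−400, stim+400] ms, 1 ms bins."""
    onsets = np.asarray(stimulus_onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("need at least one stimulus onset")
    n_bins = int(PSTH_PRE_MS + stim_duration_ms + PSTH_POST_MS)
    edges = (np.arange(n_bins + 1) - PSTH_PRE_MS) * 1e-3
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    counts = np.zeros(n_bins)
    if spikes.size:
        lo = np.searchsorted(spikes, onsets + edges[0], side="left")
        hi = np.searchsorted(spikes, onsets + edges[-1], side="left")
        rel = np.concatenate([spikes[a:b] - onset
                              for a, b, onset in zip(lo, hi, onsets)])
        counts = np.histogram(rel, bins=edges)[0].astype(float)
    counts /= onsets.size
    if smooth_sigma_ms > 0:
        counts = gaussian_filter1d(counts, smooth_sigma_ms / PSTH_BIN_MS)
    return counts


def compute_vfp(spike_times: np.ndarray, stimulus_table: pd.DataFrame,
                window_s: float = VFP_WINDOW_S
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-image mean evoked counts and the trial-wise count matrix.

    ``stimulus_table`` columns: image_id, trial, onset_s.  Counts are
    spikes in [onset, onset + window).  Every image must appear in every
    trial.
    """
    required = {"image_id", "trial", "onset_s"}
    if not required <= set(stimulus_table.columns):
        raise ValueError(f"stimulus table needs columns {sorted(required)}")
    images = np.sort(stimulus_table["image_id"].unique())
    trials = np.sort(stimulus_table["trial"].unique())
    presented = stimulus_table.groupby("image_id")["trial"].nunique()
    missing = presented[presented < len(trials)]
    if len(missing) or len(presented) < len(images):
        raise ValueError(
            f"images without presentations in every trial: "
            f"{missing.index.tolist()}")
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    img_pos = {int(v): i for i, v in enumerate(images)}
    trial_pos = {int(v): i for i, v in enumerate(trials)}
    counts = np.zeros((len(trials), len(images)))
    onsets = stimulus_table["onset_s"].to_numpy(dtype=float)
    lo = np.searchsorted(spikes, onsets, side="left")
    hi = np.searchsorted(spikes, onsets + window_s, side="left")
    for (img, trial), n in zip(
            stimulus_table[["image_id", "trial"]].itertuples(index=False),
            hi - lo):
        counts[trial_pos[int(trial)], img_pos[int(img)]] += n
    return counts.mean(axis=0), counts


def response_significance(vfp_trials: np.ndarray,
                          alpha: float = SIGNIFICANCE_ALPHA) -> bool:
    """Kruskal-Wallis across images on trial counts: is the unit driven?"""
    counts = np.asarray(vfp_trials, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("vfp_trials must be (n_trials >= 2, n_images >= 2)")
    groups = [counts[:, j] for j in range(counts.shape[1])]
    if np.ptp(counts) == 0:
        return False
    stat, p = stats.kruskal(*groups)
    return bool(p < alpha)


def build_response(spike_times: np.ndarray,
                   stimulus_table: pd.DataFrame,
                   stim_duration_ms: float = STIM_DURATION_MS,
                   alpha: float = SIGNIFICANCE_ALPHA) -> VisualResponse:
    """PSTH + vfp + significance for one unit."""
    psth = compute_psth(spike_times,
                        stimulus_table["onset_s"].to_numpy(),
                        stim_duration_ms=stim_duration_ms)
    vfp, vfp_trials = compute_vfp(spike_times, stimulus_table)
    return VisualResponse(psth=psth, vfp=vfp, vfp_trials=vfp_trials,
                          significant=response_significance(vfp_trials,
                                                            alpha))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def similarity_score(r1: VisualResponse, r2: VisualResponse
                     ) -> tuple[float, float, float]:
    """(similarity, psth_corr, vfp_corr); similarity = psth_r + vfp_r.

    A zero-variance response leaves the correlation undefined; the score is
    then NaN (flagged invalid) and never qualifies as a reference pair.
    """
    if r1.psth.size != r2.psth.size or r1.vfp.size != r2.vfp.size:
        raise ValueError("responses must share PSTH and vfp lengths")
    pr = _pearson(r1.psth, r2.psth)
    vr = _pearson(r1.vfp, r2.vfp)
    if np.isnan(pr) or np.isnan(vr):
        logger.debug("zero-variance response: similarity flagged invalid")
    return pr + vr, pr, vr


def build_reference_set(
        units1, units2,
        responses1: dict[int, VisualResponse],
        responses2: dict[int, VisualResponse],
        drift_z: float = 0.0,
        max_distance_um: float = REFERENCE_DISTANCE_UM,
        similarity_threshold: float = SIMILARITY_THRESHOLD,
        z_only: bool = False,
) -> list[ReferencePair]:
    """Reference pairs from visual responses and locations.

    ``units1``/``units2`` are UnitRecord lists (uncorrected locations);
    ``drift_z`` is the estimated rigid drift (z2 − z1) used for the
    post-correction distance.  Criteria: similarity > threshold, pre- AND
    post-correction distance < 30 µm, both KSgood, both significant.
    Mutual-best resolution by similarity yields a partial matching.
    """
    cand1 = [u for u in units1
             if u.quality == "good" and u.unit_id in responses1
             and responses1[u.unit_id].significant]
    cand2 = [u for u in units2
             if u.quality == "good" and u.unit_id in responses2
             and responses2[u.unit_id].significant]
    if not cand1 or not cand2:
        warnings.warn("no significant KSgood units on one side; empty "
                      "reference set (large drift or weak responses?)",
                      stacklevel=2)
        return []

    scored: dict[tuple[int, int], ReferencePair] = {}
    for u1 in cand1:
        for u2 in cand2:
            pre = _distance(u1, u2, 0.0, z_only)
            post = _distance(u1, u2, drift_z, z_only)
            if pre >= max_distance_um or post >= max_distance_um:
                continue
            sim, pr, vr = similarity_score(responses1[u1.unit_id],
                                           responses2[u2.unit_id])
            if not np.isfinite(sim) or sim <= similarity_threshold:
                continue
            scored[(u1.unit_id, u2.unit_id)] = ReferencePair(
                unit1=u1.unit_id, unit2=u2.unit_id, similarity=sim,
                psth_corr=pr, vfp_corr=vr,
                distance_pre=pre, distance_post=post)

    best1 = _argmax_by_side(scored, side=0)
    best2 = _argmax_by_side(scored, side=1)
    pairs = [p for (u1, u2), p in sorted(scored.items())
             if best1[u1] == u2 and best2[u2] == u1]
    if not pairs:
        warnings.warn("reference set is empty (large drift or weak "
                      "responses?)", stacklevel=2)
    return pairs


def _distance(u1, u2, drift_z: float, z_only: bool) -> float:
    dz = u1.z - (u2.z - drift_z)
    if z_only:
        return abs(dz)
    return float(np.sqrt((u1.x - u2.x) ** 2 + (u1.y - u2.y) ** 2 + dz ** 2))


def _argmax_by_side(scored: dict[tuple[int, int], ReferencePair],
                    side: int) -> dict[int, int]:
    best: dict[int, tuple[float, int]] = {}
    for (u1, u2), p in sorted(scored.items()):
        key, other = (u1, u2) if side == 0 else (u2, u1)
        if key not in best or p.similarity > best[key][0]:
            best[key] = (p.similarity, other)
    return {k: v[1] for k, v in best.items()}


def reference_pairs_table(pairs: list[ReferencePair]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in pairs])
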