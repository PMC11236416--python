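"""Waveform similarity: per-channel normalized L2 over the peak neighborhood.

A unit's spatial-temporal waveform is summarized on the channels centered at
its peak channel: the peak row plus five rows above and below, across both
columns — 22 channels for an interior peak.  Two units are compared channel
by channel in *peak-relative* coordinates (row offset from each unit's own
peak, column index), which makes the metric tolerant to vertical drift: the
same cell recorded a few rows higher still aligns with itself.

Per aligned channel c the contribution is ||a_c − b_c|| / max(||a_c||,
||b_c||); the distance is the mean over aligned channels, lying in [0, 1]
after clipping (the ratio can reach 2 for anticorrelated waveforms; clips
are logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import ChannelMap

logger = logging.getLogger(__name__)

#: rows above/below the peak row in the similarity patch
K_WF = 5


@dataclass(frozen=True)
class WaveformPatch:
    """Waveform snippet on the peak-channel neighborhood.

    ``offsets`` holds ``(row_offset, column)`` per channel, ordered by
    (row offset, column) so two patches align positionally; ``samples`` is
    the µV array ``(n_patch_channels, n_samples)``.
    """

    unit_id: int
    offsets: tuple[tuple[int, int], ...]
    samples: np.ndarray
    partial: bool = False

    @property
    def n_channels(self) -> int:
        return len(self.offsets)


def select_waveform_channels(waveform: np.ndarray, channel_map: ChannelMap,
                             peak_channel: int, unit_id: int = -1,
                             k_wf: int = K_WF) -> WaveformPatch:
    """Extract the peak-centered patch (±k_wf rows, both columns).

    Near the probe ends only existing rows are kept and the patch is marked
    partial.
    """
    sites = channel_map.sites_in_rows(peak_channel, k_wf)
    peak_row = channel_map.row_index[peak_channel]
    offsets = tuple(
        (int(channel_map.row_index[s] - peak_row),
         int(channel_map.col_index[s]))
        for s in sites)
    n_cols = np.unique(channel_map.col_index[
        channel_map.shank_sites(int(channel_map.shank_id[peak_channel]))]).size
    full = (2 * k_wf + 1) * n_cols
    samples = np.asarray(waveform, dtype=float)[sites]
    return WaveformPatch(unit_id=unit_id, offsets=offsets, samples=samples,
                         partial=len(offsets) < full)


def waveform_distance(a: WaveformPatch, b: WaveformPatch) -> float:
    """Normalized L2 waveform distance in [0, 1].

    Channels are aligned by (row offset, column); the average runs over the
    intersection of the two offset sets.  Conventions: a channel with zero
    energy in both patches contributes 0; per-channel ratios above 1
    (anticorrelated waveforms) are clipped to 1 and logged.
    """
    index_a = {off: i for i, off in enumerate(a.offsets)}
    common = [off for off in b.offsets if off in index_a]
    if not common:
        raise ValueError("waveform patches share no aligned channels")
    index_b = {off: i for i, off in enumerate(b.offsets)}
    ia = np.array([index_a[off] for off in common])
    ib = np.array([index_b[off] for off in common])

    wa = a.samples[ia]
    wb = b.samples[ib]
    na = np.linalg.norm(wa, axis=1)
    nb = np.linalg.norm(wb, axis=1)
    denom = np.maximum(na, nb)
    diff = np.linalg.norm(wa - wb, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom > 0.0, diff / np.where(denom > 0, denom, 1.0),
                         0.0)  # 0/0 convention: identical (empty) channels
    n_clipped = int(np.count_nonzero(ratio > 1.0))
    if n_clipped:
        logger.debug("waveform_distance clipped %d/%d channel ratios at 1",
                     n_clipped, len(common))
        ratio = np.minimum(ratio, 1.0)
    return float(ratio.sum() / len(common))


def pairwise_waveform_distances(patches1: list[WaveformPatch],
                                patches2: list[WaveformPatch]) -> np.ndarray:
    """Dense (len(patches1), len(patches2)) matrix of waveform distances."""
    out = np.empty((len(patches1), len(patches2)))
    for i, a in enumerate(patches1):
        for k, b in enumerate(patches2):
            out[i, k] = waveform_distance(a, b)
    return out
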