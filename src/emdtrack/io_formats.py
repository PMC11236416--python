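"""Read spike-sorter outputs in the phy/Kilosort array-file convention.

A session directory holds:

``channel_positions.npy``
    ``(n_sites, 2)`` float array of (x, z) site coordinates in µm.
``channel_shanks.npy`` (optional)
    ``(n_sites,)`` integer shank assignment; inferred from x-gaps if absent.
``cluster_group.tsv``
    tab-separated table with columns ``cluster_id`` and ``group``
    (``good`` or ``mua``).
``mean_waveforms.npy``
    ``(n_clusters, n_sites, n_samples)`` float array, µV.  Row order follows
    the sorted ``cluster_id`` order of ``cluster_group.tsv``.
``spike_times.npy`` / ``spike_clusters.npy``
    flat arrays of spike times (seconds) and their cluster ids.
``session.json``
    metadata: ``session_id``, ``sample_rate``, ``duration_s`` and optionally
    ``recording_date``.

All coordinates are µm, indices 0-based, times seconds.  Match and chain
tables are written as CSV with a JSON sidecar carrying run parameters.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALLOWED_QUALITY = ("good", "mua")

#: nominal mean-waveform window (ms); n_samples must match within ±1 sample
WAVEFORM_WINDOW_MS = 2.7


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the expected layout."""


# ---------------------------------------------------------------------------
# channel map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelMap:
    """Probe site coordinates with derived row/column/shank structure.

    The origin convention is that the site with minimum z in the leftmost
    column sits at (0, 0): coordinates are shifted on construction so that
    the probe tip of the left column is the origin.
    """

    x: np.ndarray
    z: np.ndarray
    shank_id: np.ndarray
    row_index: np.ndarray
    col_index: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.x.size

    @property
    def z_span(self) -> float:
        return float(self.z.max() - self.z.min())

    @classmethod
    def from_positions(cls, positions: np.ndarray,
                       shank_id: np.ndarray | None = None) -> "ChannelMap":
        positions = np.asarray(positions, dtype=float)
        if positions.ndim != 2 or positions.shape[1] != 2:
            raise FormatError(
                f"channel positions must be (n_sites, 2), got {positions.shape}")
        x = positions[:, 0].copy()
        z = positions[:, 1].copy()
        if shank_id is None:
            shank_id = _infer_shanks(x)
        shank_id = np.asarray(shank_id, dtype=int)
        if shank_id.shape != x.shape:
            raise FormatError("shank vector length does not match positions")

        for key, idx in _group_indices(
                list(zip(shank_id.tolist(), x.tolist(), z.tolist()))).items():
            if len(idx) > 1:
                raise FormatError(
                    f"duplicate site coordinates (shank, x, z)={key} "
                    f"at sites {sorted(idx)}")

        # origin convention: leftmost column, then its lowest site
        x0 = x.min()
        z0 = z[np.isclose(x, x0)].min()
        x = x - x0
        z = z - z0

        row_index = np.zeros(x.size, dtype=int)
        col_index = np.zeros(x.size, dtype=int)
        for s in np.unique(shank_id):
            m = shank_id == s
            col_index[m] = _rank(x[m])
            row_index[m] = _rank(z[m])
        return cls(x=x, z=z, shank_id=shank_id,
                   row_index=row_index, col_index=col_index)

    def sites_in_rows(self, center_site: int, k: int) -> np.ndarray:
        """Site indices on ``center_site``'s shank with row index within ±k.

        Returns sites from both columns, ordered by (row, column).  Near the
        probe ends only existing rows are returned (the caller flags partial
        sets).
        """
        s = self.shank_id[center_site]
        r = self.row_index[center_site]
        mask = (self.shank_id == s) & (np.abs(self.row_index - r) <= k)
        idx = np.nonzero(mask)[0]
        order = np.lexsort((self.col_index[idx], self.row_index[idx]))
        return idx[order]

    def shank_sites(self, shank: int) -> np.ndarray:
        return np.nonzero(self.shank_id == shank)[0]


def _rank(values: np.ndarray) -> np.ndarray:
    """Dense rank of values (0-based), equal values share a rank."""
    uniq = np.unique(values)
    return np.searchsorted(uniq, values)


def _group_indices(keys: list) -> dict:
    out: dict = {}
    for i, k in enumerate(keys):
        out.setdefault(k, []).append(i)
    return out


def _infer_shanks(x: np.ndarray) -> np.ndarray:
    """Group x-columns into shanks split at gaps larger than 3× the median."""
    ux = np.unique(x)
    if ux.size <= 2:
        return np.zeros(x.size, dtype=int)
    gaps = np.diff(ux)
    med = np.median(gaps[gaps > 0]) if np.any(gaps > 0) else 0.0
    shank_of_col = np.concatenate([[0], np.cumsum(gaps > 3 * med)])
    col_shank = dict(zip(ux.tolist(), shank_of_col.tolist()))
    return np.array([col_shank[v] for v in x], dtype=int)


def load_channel_map(path: str | Path) -> ChannelMap:
    """Load ``channel_positions.npy`` (plus optional shank vector).

    ``path`` may be the positions file itself or a session directory.
    """
    path = Path(path)
    if path.is_dir():
        pos_file = path / "channel_positions.npy"
    else:
        pos_file = path
    if not pos_file.exists():
        raise FormatError(f"channel positions file not found: {pos_file}")
    positions = np.load(pos_file)
    shank_file = pos_file.with_name("channel_shanks.npy")
    shank = np.load(shank_file) if shank_file.exists() else None
    return ChannelMap.from_positions(positions, shank)


def save_channel_map(cmap: ChannelMap, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "channel_positions.npy",
            np.column_stack([cmap.x, cmap.z]))
    np.save(directory / "channel_shanks.npy", cmap.shank_id)


# ---------------------------------------------------------------------------
# session bundle
# ---------------------------------------------------------------------------

@dataclass
class RawSessionBundle:
    """One session's sorter output: labels, mean waveforms, spike times."""

    session_id: str
    channel_map: ChannelMap
    cluster_labels: pd.DataFrame          # columns: cluster_id, quality
    mean_waveforms: np.ndarray            # (n_clusters, n_sites, n_samples) µV
    sample_rate: float                    # Hz
    spike_times: dict[int, np.ndarray]    # cluster_id -> seconds
    duration_s: float = float("nan")
    recording_date: str | None = None

    @property
    def cluster_ids(self) -> np.ndarray:
        return self.cluster_labels["cluster_id"].to_numpy()

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_labels)

    def waveform(self, cluster_id: int) -> np.ndarray:
        row = int(np.nonzero(self.cluster_ids == cluster_id)[0][0])
        return self.mean_waveforms[row]

    def quality(self, cluster_id: int) -> str:
        row = self.cluster_labels.set_index("cluster_id")
        return str(row.loc[cluster_id, "quality"])

    def firing_rate(self, cluster_id: int) -> float:
        times = self.spike_times.get(cluster_id, np.empty(0))
        if not np.isfinite(self.duration_s) or self.duration_s <= 0:
            return float("nan")
        return len(times) / self.duration_s

    def validate(self) -> None:
        bad = set(self.cluster_labels["quality"]) - set(ALLOWED_QUALITY)
        if bad:
            raise FormatError(
                f"unknown quality labels {sorted(bad)}; allowed: "
                f"{list(ALLOWED_QUALITY)}")
        if self.mean_waveforms.shape[0] != self.n_clusters:
            raise FormatError(
                f"waveform array has {self.mean_waveforms.shape[0]} clusters "
                f"but cluster table lists {self.n_clusters}")
        if self.n_clusters and (
                self.mean_waveforms.shape[1] != self.channel_map.n_sites):
            raise FormatError(
                f"waveform array covers {self.mean_waveforms.shape[1]} "
                f"channels but the map has {self.channel_map.n_sites} sites")
        expected = WAVEFORM_WINDOW_MS * 1e-3 * self.sample_rate
        n_samples = self.mean_waveforms.shape[2] if self.n_clusters else None
        if n_samples is not None and abs(n_samples - expected) > 1:
            warnings.warn(
                f"waveform window is {n_samples} samples; expected "
                f"~{expected:.0f} ({WAVEFORM_WINDOW_MS} ms at "
                f"{self.sample_rate:g} Hz)", stacklevel=2)


def load_session(directory: str | Path) -> RawSessionBundle:
    """Load a phy-convention session directory into a :class:`RawSessionBundle`."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FormatError(f"session directory not found: {directory}")
    cmap = load_channel_map(directory)

    meta_file = directory / "session.json"
    meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    sample_rate = float(meta.get("sample_rate", 30_000.0))

    group_file = directory / "cluster_group.tsv"
    if not group_file.exists():
        raise FormatError(f"missing cluster_group.tsv in {directory}")
    labels = pd.read_csv(group_file, sep="\t")
    if "group" in labels.columns:
        labels = labels.rename(columns={"group": "quality"})
    labels = labels[["cluster_id", "quality"]].sort_values(
        "cluster_id", kind="stable").reset_index(drop=True)

    if len(labels) == 0:
        logger.warning("session %s has an empty cluster table", directory)
        waveforms = np.empty((0, cmap.n_sites, 0))
        spike_times: dict[int, np.ndarray] = {}
    else:
        wf_file = directory / "mean_waveforms.npy"
        if not wf_file.exists():
            raise FormatError(f"missing mean_waveforms.npy in {directory}")
        waveforms = np.load(wf_file)
        st_file = directory / "spike_times.npy"
        sc_file = directory / "spike_clusters.npy"
        spike_times = {}
        if st_file.exists() and sc_file.exists():
            st = np.load(st_file)
            sc = np.load(sc_file)
            for cid in labels["cluster_id"]:
                spike_times[int(cid)] = np.sort(st[sc == cid])

    bundle = RawSessionBundle(
        session_id=str(meta.get("session_id", directory.name)),
        channel_map=cmap,
        cluster_labels=labels,
        mean_waveforms=waveforms,
        sample_rate=sample_rate,
        spike_times=spike_times,
        duration_s=float(meta.get("duration_s", float("nan"))),
        recording_date=meta.get("recording_date"),
    )
    bundle.validate()
    return bundle


def save_session(bundle: RawSessionBundle, directory: str | Path) -> None:
    """Write a bundle back to the phy-convention directory layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_channel_map(bundle.channel_map, directory)
    bundle.cluster_labels.rename(columns={"quality": "group"}).to_csv(
        directory / "cluster_group.tsv", sep="\t", index=False)
    np.save(directory / "mean_waveforms.npy", bundle.mean_waveforms)
    if bundle.spike_times:
        st = np.concatenate([bundle.spike_times[int(c)]
                             for c in bundle.cluster_ids])
        sc = np.concatenate([
            np.full(len(bundle.spike_times[int(c)]), int(c), dtype=int)
            for c in bundle.cluster_ids])
        order = np.argsort(st, kind="stable")
        np.save(directory / "spike_times.npy", st[order])
        np.save(directory / "spike_clusters.npy", sc[order])
    meta = {
        "session_id": bundle.session_id,
        "sample_rate": bundle.sample_rate,
        "duration_s": bundle.duration_s,
    }
    if bundle.recording_date is not None:
        meta["recording_date"] = bundle.recording_date
    (directory / "session.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# match / chain tables
# ---------------------------------------------------------------------------

MATCH_COLUMNS = ["session1", "session2", "unit1", "unit2",
                 "d_loc", "d_wf", "distance", "z_distance",
                 "passes_threshold"]
CHAIN_COLUMNS = ["chain_id", "classification", "session1", "session2",
                 "unit1", "unit2"]

_FLOAT_FMT = "%.9g"


def save_matches(result, path: str | Path) -> None:
    """Write a MatchResult's pair table as CSV plus a JSON parameter sidecar.

    Output is bit-stable for identical input: floats use a fixed '%.9g'
    format and rows keep the solver's deterministic order.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = result.pairs.copy()
    df.insert(0, "session1", result.session1)
    df.insert(1, "session2", result.session2)
    df[MATCH_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(result.metadata(), indent=2, sort_keys=True)
                       + "\n")


def load_matches(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_chains(chains, path: str | Path) -> None:
    """Write chains as one CSV row per link, sharing a ``chain_id``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for cid, chain in enumerate(chains):
        for (s1, u1), (s2, u2) in zip(chain.members[:-1], chain.members[1:]):
            rows.append((cid, chain.classification, s1, s2, u1, u2))
    pd.DataFrame(rows, columns=CHAIN_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT)
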