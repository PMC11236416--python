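"""Ground-truth simulator for multi-session drifting unit populations.

Emulates the statistics of chronic high-density probe recordings that the
tracking pipeline must cope with: units at 3D positions over a ~720 µm
probe section whose peak-to-peak amplitudes decay as 1/R from a monopole
source, rigid between-session z-drift plus per-unit jitter, ~60% unit
survival with fresh units replacing losses, per-session waveform
perturbation, and (optionally) image-evoked spiking with trial noise.

Sessions are produced in the same in-memory/on-disk layout that real
sorter output is read into, so every pipeline stage can be exercised with
no external data.  A correspondence table records which session-local unit
ids belong to the same ground-truth neuron.

The temporal spike template is a biphasic difference-of-exponentials shape
with per-unit parameter draws; any biphasic template suffices for testing
the matching metrics, no biophysical realism is intended.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import ChannelMap, RawSessionBundle, save_session

#: waveform window: 81 samples = 2.7 ms at 30 kHz
N_SAMPLES = 81
SAMPLE_RATE = 30_000.0

#: units farther than this from every site render as pure noise
RENDER_CUTOFF_UM = 500.0


# ---------------------------------------------------------------------------
# probe
# ---------------------------------------------------------------------------

def generate_probe(n_shanks: int = 4, sites_per_shank: int = 96,
                   x_pitch: float = 32.0, z_pitch: float = 15.0,
                   shank_spacing: float = 250.0) -> ChannelMap:
    """Checkerboard-free 2-column grid per shank, origin at the left tip.

    Defaults give the 4-shank, 384-site layout (96 sites per shank in two
    columns of 48 rows, spanning 720 µm with 15 µm row pitch).
    """
    if n_shanks <= 0 or sites_per_shank <= 0:
        raise ValueError("probe dimensions must be positive")
    if sites_per_shank % 2:
        raise ValueError("sites_per_shank must be even (2 columns)")
    rows = sites_per_shank // 2
    xs, zs, shanks = [], [], []
    for s in range(n_shanks):
        for r in range(rows):
            for c in range(2):
                xs.append(s * shank_spacing + c * x_pitch)
                zs.append(r * z_pitch)
                shanks.append(s)
    return ChannelMap.from_positions(
        np.column_stack([xs, zs]), np.array(shanks))


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Generative conditions for a multi-session recording sequence."""

    seed: int                                   # mandatory
    n_sessions: int = 3
    n_units: int = 60                           # per session
    survival: float = 0.6                       # per-step survival prob.
    drift_per_session: float = 12.0             # µm rigid z-shift per step
    jitter_sigma: float = 3.0                   # µm per-unit z jitter
    amplitude_noise: float = 0.05               # per-channel multiplicative
    background_rms_uv: float = 1.5              # additive sample noise, µV
    mua_fraction: float = 0.1                   # units labeled 'mua'
    duration_s: float = 300.0                   # session length (no stimuli)
    visual_fraction: float = 0.0                # fraction of tuned units
    n_images: int = 112
    n_trials: int = 5
    stim_duration_s: float = 1.0
    inter_stim_s: float = 0.5
    peak_visual_rate_hz: float = 20.0
    representational_noise: float = 0.0         # tuning perturbation fraction
    n_shanks: int = 1
    sites_per_shank: int = 96

    def __post_init__(self):
        if not (0.0 < self.survival <= 1.0):
            raise ValueError("survival must be in (0, 1]")
        for name in ("jitter_sigma", "amplitude_noise", "background_rms_uv",
                     "representational_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruthUnit:
    """One simulated neuron, persistent across sessions in tissue frame."""

    gt_id: int
    x: float                   # µm, probe-frame horizontal
    y: float                   # µm, distance from probe plane
    z_tissue: float            # µm, z in the (moving) tissue frame
    alpha: float               # µV·µm monopole source strength
    quality: str
    base_rate: float           # Hz
    template: np.ndarray       # (N_SAMPLES,) unit-ptp spike shape
    tuning: np.ndarray | None = None   # Hz added per image, or None
    latency_s: float = 0.05    # visual response onset latency
    decay_s: float = 0.3       # visual response decay time constant


def spike_template(rng: np.random.Generator,
                   n_samples: int = N_SAMPLES) -> np.ndarray:
    """Biphasic difference-of-exponentials template, peak-to-peak = 1.

    Trough near 0.9 ms followed by a slower repolarization bump; depth,
    width and repolarization drawn per unit.
    """
    t = np.arange(n_samples) / SAMPLE_RATE * 1e3  # ms
    t0 = 0.5 + rng.uniform(-0.05, 0.05)           # depolarization onset, ms
    tau_r = rng.uniform(0.06, 0.12)               # rise, ms
    tau_f = rng.uniform(0.2, 0.45)                # fall, ms
    repol = rng.uniform(0.25, 0.5)                # relative overshoot
    tau_s = rng.uniform(0.6, 1.2)                 # repolarization decay, ms
    u = np.clip(t - t0, 0.0, None)
    trough = -(np.exp(-u / tau_f) - np.exp(-u / tau_r))
    u2 = np.clip(t - t0 - 0.4, 0.0, None)
    bump = repol * (np.exp(-u2 / tau_s) - np.exp(-u2 / (2 * tau_r)))
    w = trough + bump
    return w / np.ptp(w)


def generate_population(config: SimulationConfig, probe: ChannelMap,
                        rng: np.random.Generator,
                        n_units: int | None = None,
                        start_id: int = 0,
                        session_offset: float = 0.0) -> list[GroundTruthUnit]:
    """Draw fresh ground-truth units uniformly over the probe section.

    Units are placed so their rendered peak ptp exceeds the 60 µV inclusion
    filter (target ptp drawn in [80, 300] µV); ``session_offset`` places
    new units inside the currently visible z-window of a drifted recording.
    """
    n = config.n_units if n_units is None else n_units
    units = []
    for j in range(n):
        shank = int(rng.integers(probe.shank_id.max() + 1))
        sites = probe.shank_sites(shank)
        x = rng.uniform(probe.x[sites].min() - 16.0,
                        probe.x[sites].max() + 16.0)
        z_probe = rng.uniform(probe.z[sites].min(), probe.z[sites].max())
        y = rng.uniform(5.0, 40.0)
        d_nearest = np.sqrt((probe.x[sites] - x) ** 2
                            + (probe.z[sites] - z_probe) ** 2
                            + y ** 2).min()
        ptp_target = rng.uniform(80.0, 300.0)
        quality = "mua" if rng.random() < config.mua_fraction else "good"
        tuned = rng.random() < config.visual_fraction
        tuning = None
        if tuned:
            raw = rng.exponential(1.0, config.n_images) ** 2
            tuning = config.peak_visual_rate_hz * raw / raw.max()
        units.append(GroundTruthUnit(
            gt_id=start_id + j,
            x=float(x), y=float(y),
            z_tissue=float(z_probe - session_offset),
            alpha=float(ptp_target * d_nearest),
            quality=quality,
            base_rate=float(np.exp(rng.normal(np.log(4.0), 0.5))),
            template=spike_template(rng),
            tuning=tuning,
            # per-unit visual dynamics, preserved across sessions: real
            # neurons differ in onset latency and transient decay, which
            # is what makes PSTHs unit-specific rather than generic
            latency_s=float(rng.uniform(0.03, 0.15)),
            decay_s=float(rng.uniform(0.1, 0.6)),
        ))
    return units


def render_waveforms(unit: GroundTruthUnit, probe: ChannelMap,
                     z_probe: float, rng: np.random.Generator,
                     amplitude_noise: float = 0.0,
                     background_rms_uv: float = 0.0) -> np.ndarray:
    """Forward-model the mean waveform: amp_c = α/R_c scaling the template.

    Per-channel multiplicative amplitude jitter emulates session-to-session
    waveform change; additive Gaussian sample noise emulates the residual
    noise floor of a finite-spike average.  A unit beyond the render cutoff
    from every site yields pure noise.
    """
    r = np.sqrt((probe.x - unit.x) ** 2 + (probe.z - z_probe) ** 2
                + unit.y ** 2)
    amps = unit.alpha / np.maximum(r, 1.0)
    if r.min() > RENDER_CUTOFF_UM:
        amps = np.zeros_like(amps)
    if amplitude_noise > 0:
        amps = amps * (1.0 + amplitude_noise
                       * rng.standard_normal(amps.size))
    wf = amps[:, None] * unit.template[None, :]
    if background_rms_uv > 0:
        wf = wf + background_rms_uv * rng.standard_normal(wf.shape)
    return wf


# ---------------------------------------------------------------------------
# session sequence
# ---------------------------------------------------------------------------

def simulate_session_sequence(
        config: SimulationConfig,
        probe: ChannelMap | None = None,
) -> tuple[list[RawSessionBundle], pd.DataFrame]:
    """Simulate drifting sessions and the ground-truth correspondence.

    Session t+1 keeps each unit with probability ``survival``; all units'
    probe-frame depths shift by the rigid drift, survivors additionally get
    per-unit z jitter, and fresh units restore the population count.  The
    returned table has one row per (gt_id, session) appearance with the
    session-local unit id, so true cross-session pairs can be read off.
    """
    rng = np.random.default_rng(config.seed)
    if probe is None:
        probe = generate_probe(n_shanks=config.n_shanks,
                               sites_per_shank=config.sites_per_shank)

    active = generate_population(config, probe, rng)
    next_id = len(active)
    jitter: dict[int, float] = {u.gt_id: 0.0 for u in active}

    bundles: list[RawSessionBundle] = []
    rows = []
    for t in range(config.n_sessions):
        offset = t * config.drift_per_session
        if t > 0:
            survivors = [u for u in active if rng.random() < config.survival]
            for u in survivors:
                jitter[u.gt_id] = jitter.get(u.gt_id, 0.0) + float(
                    rng.normal(0.0, config.jitter_sigma))
            fresh = generate_population(
                config, probe, rng, n_units=config.n_units - len(survivors),
                start_id=next_id, session_offset=offset)
            next_id += len(fresh)
            for u in fresh:
                jitter[u.gt_id] = 0.0
            active = survivors + fresh

        session_id = f"day{t + 1:02d}"
        unit_ids = rng.permutation(len(active))
        order = np.argsort(unit_ids, kind="stable")

        waveforms = np.empty((len(active), probe.n_sites, N_SAMPLES))
        labels = []
        spike_times: dict[int, np.ndarray] = {}
        if config.visual_fraction > 0:
            stim_table = make_stimulus_table(config, rng)
            duration = float(stim_table["onset_s"].iloc[-1]
                             + config.stim_duration_s + config.inter_stim_s)
        else:
            stim_table = None
            duration = config.duration_s
        for row, j in enumerate(order):
            u = active[j]
            uid = int(unit_ids[j])
            z_probe = u.z_tissue + offset + jitter[u.gt_id]
            waveforms[row] = render_waveforms(
                u, probe, z_probe, rng,
                amplitude_noise=config.amplitude_noise if t > 0 else 0.0,
                background_rms_uv=config.background_rms_uv)
            labels.append((uid, u.quality))
            if stim_table is not None:
                spike_times[uid] = simulate_visual_spikes(
                    u, stim_table, config, rng)
            else:
                n_spikes = rng.poisson(u.base_rate * duration)
                spike_times[uid] = np.sort(
                    rng.uniform(0.0, duration, n_spikes))
            rows.append({
                "gt_id": u.gt_id, "session_id": session_id, "unit_id": uid,
                "x": u.x, "y": u.y, "z": z_probe,
                "quality": u.quality, "tuned": u.tuning is not None,
            })
        bundle = RawSessionBundle(
            session_id=session_id,
            channel_map=probe,
            cluster_labels=pd.DataFrame(labels,
                                        columns=["cluster_id", "quality"]
                                        ).sort_values("cluster_id")
                                         .reset_index(drop=True),
            mean_waveforms=waveforms,
            sample_rate=SAMPLE_RATE,
            spike_times=spike_times,
            duration_s=duration,
        )
        if stim_table is not None:
            bundle.stimulus_table = stim_table  # type: ignore[attr-defined]
        bundles.append(bundle)
    truth = pd.DataFrame(rows)
    return bundles, truth


def true_pairs(truth: pd.DataFrame, session1: str, session2: str,
               good_only: bool = False) -> set[tuple[int, int]]:
    """Ground-truth (unit_id1, unit_id2) pairs shared between two sessions.

    ``good_only`` restricts to units the pipeline actually matches
    (sorter label 'good'), the analogue of evaluating on KSgood units.
    """
    sub = truth if not good_only else truth[truth["quality"] == "good"]
    a = sub[sub["session_id"] == session1].set_index("gt_id")["unit_id"]
    b = sub[sub["session_id"] == session2].set_index("gt_id")["unit_id"]
    shared = a.index.intersection(b.index)
    return {(int(a[g]), int(b[g])) for g in shared}


# ---------------------------------------------------------------------------
# visual responses
# ---------------------------------------------------------------------------

def make_stimulus_table(config: SimulationConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Shuffled image presentations: n_trials passes over n_images."""
    rows = []
    t = 5.0  # settle time before the first stimulus
    period = config.stim_duration_s + config.inter_stim_s
    for trial in range(config.n_trials):
        for img in rng.permutation(config.n_images):
            rows.append({"image_id": int(img), "trial": trial, "onset_s": t})
            t += period
    return pd.DataFrame(rows)


def simulate_visual_spikes(unit: GroundTruthUnit, stim_table: pd.DataFrame,
                           config: SimulationConfig,
                           rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson spikes: base rate plus tuning during stimuli."""
    duration = float(stim_table["onset_s"].iloc[-1]
                     + config.stim_duration_s + config.inter_stim_s)
    n_base = rng.poisson(unit.base_rate * duration)
    spikes = [rng.uniform(0.0, duration, n_base)]
    if unit.tuning is not None:
        tuning = unit.tuning
        if config.representational_noise > 0:
            tuning = np.clip(
                tuning * (1.0 + config.representational_noise
                          * rng.standard_normal(tuning.size)), 0.0, None)
        for onset, img in zip(stim_table["onset_s"].to_numpy(),
                              stim_table["image_id"].to_numpy()):
            extra = rng.poisson(tuning[int(img)] * config.stim_duration_s)
            if extra:
                # evoked spikes follow the unit's temporal profile: an
                # exponential transient after the onset latency, truncated
                # to the presentation window
                window = config.stim_duration_s - unit.latency_s
                u = rng.uniform(0.0, 1.0, extra)
                tail = 1.0 - np.exp(-window / unit.decay_s)
                offsets = -unit.decay_s * np.log1p(-u * tail)
                spikes.append(onset + unit.latency_s + offsets)
    return np.sort(np.concatenate(spikes))


def write_simulation(config: SimulationConfig, out_dir: str | Path,
                     probe: ChannelMap | None = None) -> pd.DataFrame:
    """Write one session directory per simulated day plus ground_truth.csv."""
    out_dir = Path(out_dir)
    bundles, truth = simulate_session_sequence(config, probe)
    for bundle in bundles:
        save_session(bundle, out_dir / bundle.session_id)
        stim = getattr(bundle, "stimulus_table", None)
        if stim is not None:
            stim.to_csv(out_dir / bundle.session_id / "stimulus_table.csv",
                        index=False, float_format="%.9g")
    truth.to_csv(out_dir / "ground_truth.csv", index=False,
                 float_format="%.9g")
    return truth
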