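"""Estimate unit positions from mean-waveform peak-to-peak amplitudes.

Each sorted unit is localized in 3D relative to the probe by fitting the
background-subtracted peak-to-peak (ptp) amplitudes on the 10 sites nearest
the peak site with a monopole current-source model: the amplitude on a site
at (x_c, z_c) decays as alpha / R with R the 3D distance from the source at
(x, y, z), y >= 0 being the distance from the probe plane.  Units whose peak
ptp does not exceed 60 µV are excluded from all downstream matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .io_formats import ChannelMap

logger = logging.getLogger(__name__)

#: amplitude filter: units at or below this peak ptp are not localized/matched
MIN_PEAK_PTP_UV = 60.0

#: half-width (in rows) of the localization channel neighborhood
K_LOC = 2

#: half-width (in rows) of the waveform-similarity neighborhood, used here to
#: exclude the spike footprint from the background estimate
K_WF = 5

_DEFAULT_Y0 = 20.0  # µm, initial distance from the probe plane


@dataclass
class UnitRecord:
    """One sorted unit in one session, with its estimated 3D location."""

    unit_id: int
    session_id: str
    quality: str
    peak_channel: int
    shank_id: int
    ptp_amplitudes: dict[int, float]      # site -> background-subtracted µV
    location: tuple[float, float, float]  # (x, y, z) µm
    alpha: float                          # source strength, µV·µm
    peak_ptp: float                       # µV, raw
    firing_rate: float = float("nan")
    included: bool = True
    partial_set: bool = False
    fallback: bool = False

    @property
    def x(self) -> float:
        return self.location[0]

    @property
    def y(self) -> float:
        return self.location[1]

    @property
    def z(self) -> float:
        return self.location[2]

    def with_z(self, z: float) -> "UnitRecord":
        rec = UnitRecord(**{**self.__dict__})
        rec.location = (self.location[0], self.location[1], float(z))
        return rec


def channel_ptp(waveform: np.ndarray) -> np.ndarray:
    """Per-channel peak-to-peak amplitude (max − min over time), µV."""
    wf = np.asarray(waveform, dtype=float)
    return wf.max(axis=-1) - wf.min(axis=-1)


def estimate_background(waveform: np.ndarray, channel_map: ChannelMap,
                        peak_channel: int | None = None) -> float:
    """Median ptp over the peak shank's sites outside the spike footprint.

    The footprint is the waveform neighborhood (rows within ±K_WF of the
    peak row, both columns).  Robust to the spike itself; near 0 for clean
    recordings, near the noise floor otherwise.
    """
    ptp = channel_ptp(waveform)
    if peak_channel is None:
        peak_channel = int(np.argmax(ptp))
    shank = channel_map.shank_id[peak_channel]
    shank_sites = channel_map.shank_sites(int(shank))
    if shank_sites.size < 10:
        raise ValueError(
            f"need at least 10 channels on shank {shank} to estimate "
            f"background, have {shank_sites.size}")
    footprint = set(channel_map.sites_in_rows(peak_channel, K_WF).tolist())
    outside = np.array([s for s in shank_sites if s not in footprint])
    if outside.size == 0:
        return 0.0
    return float(np.median(ptp[outside]))


def compute_ptp_amplitudes(
        waveform: np.ndarray, channel_map: ChannelMap,
        k_loc: int = K_LOC,
        background: float | None = None
) -> tuple[int, dict[int, float], bool]:
    """Background-subtracted ptp amplitudes on the localization channel set.

    Returns ``(peak_channel, {site: amplitude}, partial_set)``.  The set is
    the rows within ±k_loc of the peak row across both columns (10 sites for
    an interior peak with the default geometry); near the probe ends only
    existing rows are used and ``partial_set`` is flagged.  Amplitudes are
    floored at 0 after background subtraction; ``background=None`` estimates
    it from the waveform, an explicit value (e.g. 0) bypasses estimation.
    """
    ptp = channel_ptp(waveform)
    peak_channel = int(np.argmax(ptp))
    if background is None:
        background = estimate_background(waveform, channel_map, peak_channel)
    sites = channel_map.sites_in_rows(peak_channel, k_loc)
    n_cols = np.unique(channel_map.col_index[
        channel_map.shank_sites(int(channel_map.shank_id[peak_channel]))]).size
    full = (2 * k_loc + 1) * n_cols
    partial = sites.size < full
    amps = {int(s): float(max(ptp[s] - background, 0.0)) for s in sites}
    return peak_channel, amps, partial


def _monopole_residuals(params: np.ndarray, xc: np.ndarray, zc: np.ndarray,
                        v: np.ndarray) -> np.ndarray:
    x, y, z, alpha = params
    r = np.sqrt((x - xc) ** 2 + (z - zc) ** 2 + y ** 2)
    return v - alpha / np.maximum(r, 1e-6)


def estimate_unit_location(
        amplitudes: dict[int, float], channel_map: ChannelMap,
        peak_channel: int | None = None,
        n_restarts: int = 3,
) -> tuple[tuple[float, float, float], float, bool]:
    """Fit the monopole model to site amplitudes by bounded least squares.

    Minimizes sum_c (V_c − alpha / sqrt((x−x_c)² + (z−z_c)² + y²))² over
    (x, y, z, alpha) with y ≥ 0.  Returns ``(location, alpha, fallback)``;
    ``fallback=True`` marks degenerate inputs or failed convergence, where
    the peak-site coordinates with a default y are returned instead.
    """
    sites = np.array(sorted(amplitudes), dtype=int)
    v = np.array([amplitudes[int(s)] for s in sites], dtype=float)
    xc = channel_map.x[sites]
    zc = channel_map.z[sites]
    if peak_channel is None:
        peak_channel = int(sites[np.argmax(v)])
    x0, z0 = channel_map.x[peak_channel], channel_map.z[peak_channel]
    vmax = float(v.max())

    positive = v > 0
    degenerate = positive.sum() < 4 or np.ptp(v[positive]) < 1e-9 * vmax
    if vmax <= 0 or degenerate:
        return (float(x0), 100.0, float(z0)), vmax * _DEFAULT_Y0, True

    span_x = np.ptp(channel_map.x) + 100.0
    span_z = np.ptp(channel_map.z) + 100.0
    lo = [channel_map.x.min() - 100.0, 0.0, channel_map.z.min() - 100.0, 0.0]
    hi = [channel_map.x.max() + 100.0, 500.0, channel_map.z.max() + 100.0,
          np.inf]

    best = None
    y0 = _DEFAULT_Y0
    for attempt in range(n_restarts):
        p0 = np.array([x0, y0, z0, vmax * max(y0, 1.0)])
        try:
            res = least_squares(
                _monopole_residuals, p0, args=(xc, zc, v),
                bounds=(lo, hi), ftol=1e-8, xtol=1e-10, gtol=1e-10)
        except Exception:  # pragma: no cover - solver failure is exotic
            res = None
        if res is not None and res.success:
            if best is None or res.cost < best.cost:
                best = res
            if res.cost < 1e-8 * max(1.0, vmax ** 2):
                break
        y0 = _DEFAULT_Y0 * (2.0 + attempt)  # jittered restart

    if best is None:
        logger.warning("localization failed to converge; falling back to "
                       "peak-channel coordinates")
        return (float(x0), _DEFAULT_Y0, float(z0)), vmax * _DEFAULT_Y0, True
    x, y, z, alpha = best.x
    return (float(x), float(y), float(z)), float(alpha), False
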