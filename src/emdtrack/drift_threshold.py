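"""Rigid drift estimation and z-distance threshold calibration.

Between-session drift is predominantly along the probe insertion axis (z).
Because only ~60% of units persist between sessions, the rigid shift must
be read out against a background of spurious matches: it is estimated as
the mode of a Gaussian kernel density over the matched z-displacements,
then subtracted from the second session's unit depths.

After matching, biologically implausible assignments are removed with a
threshold on |Δz|.  The |Δz| distribution of all matched pairs is modeled
as a mixture of a folded Gaussian (correct pairs, width σ = the z-position
estimation error) and an exponential (incorrect pairs, decay c):

    P(z) = d * ( f · N · exp(−z²/2σ²) + (1 − f)/c · exp(−z/c) ),
    N = 2 / (σ √(2π))

with f the fraction of correct pairs and d an amplitude normalization.
Integrating the incorrect-pair component against the total yields the
false-positive rate as a function of the threshold, from which a threshold
achieving a target FPR is selected.  When reference pairs are available
their fitted σ can be fixed in this fit; a free fit slightly
underestimates σ, making the derived FPR conservative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

#: operating-point threshold (µm) used when no mixture fit is requested
DEFAULT_Z_THRESHOLD = 10.0

#: KDE evaluation grid step, µm
MODE_GRID_STEP = 0.1

#: KDE bandwidth floor, µm
MIN_BANDWIDTH = 0.5

#: histogram-fit window and bin width, µm
FIT_RANGE = (0.0, 50.0)
FIT_BIN_WIDTH = 1.0


class DriftEstimationError(RuntimeError):
    pass


class ThresholdFitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# rigid drift
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriftEstimate:
    """Mode-of-z-displacements drift estimate (signed, session2 − session1)."""

    z_mode: float          # µm
    bandwidth: float       # µm
    n_pairs: int
    grid: np.ndarray       # evaluation grid, µm
    density: np.ndarray


def estimate_rigid_drift(matched_z: list[tuple[float, float]] | np.ndarray,
                         min_pairs: int = 10) -> DriftEstimate:
    """Estimate rigid z-drift as the KDE mode of Δz = z2 − z1.

    ``matched_z`` holds (z1, z2) per stage-1 matched pair (KSgood units
    only).  Bandwidth is Silverman's rule with a 0.5 µm floor; the density
    is evaluated on a 0.1 µm grid spanning the observed range.
    """
    pairs = np.asarray(matched_z, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("matched_z must be a sequence of (z1, z2) pairs")
    if pairs.shape[0] < min_pairs:
        raise DriftEstimationError(
            f"only {pairs.shape[0]} matched pairs (< {min_pairs}); supply "
            "the drift manually or lower min_pairs")
    dz = pairs[:, 1] - pairs[:, 0]
    n = dz.size
    std = dz.std(ddof=1)
    if std < 1e-12:
        mode = float(dz[0])
        grid = np.array([mode])
        return DriftEstimate(z_mode=mode, bandwidth=MIN_BANDWIDTH,
                             n_pairs=n, grid=grid, density=np.array([1.0]))
    # Silverman's rule for a Gaussian kernel in 1D, floored
    bw = max(1.06 * std * n ** (-1 / 5), MIN_BANDWIDTH)
    kde = stats.gaussian_kde(dz, bw_method=bw / std)
    grid = np.arange(dz.min() - 3 * bw, dz.max() + 3 * bw + MODE_GRID_STEP,
                     MODE_GRID_STEP)
    density = kde(grid)
    mode = float(grid[np.argmax(density)])
    return DriftEstimate(z_mode=mode, bandwidth=float(bw), n_pairs=n,
                         grid=grid, density=density)


def apply_drift_correction(units, z_mode: float):
    """Return units with z replaced by z − z_mode (x, y untouched)."""
    return [u.with_z(u.z - z_mode) for u in units]


# ---------------------------------------------------------------------------
# mixture model
# ---------------------------------------------------------------------------

def folded_gaussian_pdf(z: np.ndarray, sigma: float) -> np.ndarray:
    """Half-normal density on z ≥ 0: N·exp(−z²/2σ²), N = 2/(σ√(2π))."""
    z = np.asarray(z, dtype=float)
    n = 2.0 / (sigma * np.sqrt(2.0 * np.pi))
    return n * np.exp(-z ** 2 / (2.0 * sigma ** 2))


def mixture_pdf(z: np.ndarray, f: float, sigma: float, c: float) -> np.ndarray:
    """Normalized correct+incorrect mixture density on z ≥ 0."""
    z = np.asarray(z, dtype=float)
    return (f * folded_gaussian_pdf(z, sigma)
            + (1.0 - f) / c * np.exp(-z / c))


@dataclass
class ThresholdFit:
    """Fitted z-distance mixture and the derived FPR curve."""

    f: float               # fraction of correct pairs
    sigma: float           # µm, folded-Gaussian width
    c: float               # µm, exponential decay of incorrect pairs
    d: float               # amplitude normalization (counts × bin width)
    n: int                 # sample size
    sigma_fixed: bool = False
    converged: bool = True
    residual: float = float("nan")
    bin_width: float = FIT_BIN_WIDTH
    fit_range: tuple[float, float] = FIT_RANGE
    warnings_: list[str] = field(default_factory=list)
    chosen_threshold: float | None = None

    def pdf(self, z: np.ndarray) -> np.ndarray:
        return mixture_pdf(z, self.f, self.sigma, self.c)

    def correct_cdf(self, z: np.ndarray) -> np.ndarray:
        """∫₀^z folded-Gaussian = erf(z / (σ√2))."""
        return special.erf(np.asarray(z, dtype=float)
                           / (self.sigma * np.sqrt(2.0)))

    def incorrect_cdf(self, z: np.ndarray) -> np.ndarray:
        return 1.0 - np.exp(-np.asarray(z, dtype=float) / self.c)

    def fpr_curve(self, grid: np.ndarray) -> np.ndarray:
        return np.array([false_positive_rate(self, z) for z in grid])


def fit_z_distribution(z_distances: np.ndarray,
                       sigma_fixed: float | None = None,
                       method: str = "histogram",
                       bin_width: float = FIT_BIN_WIDTH,
                       fit_range: tuple[float, float] = FIT_RANGE,
                       min_n: int = 30) -> ThresholdFit:
    """Fit the folded-Gaussian + exponential mixture to |Δz| distances.

    The default fit is least squares on a 1 µm-binned histogram over
    [0, 50] µm; ``method='mle'`` maximizes the mixture likelihood instead.
    If ``sigma_fixed`` is given (width known from reference pairs), σ is
    held at that value.  Warns when σ̂ > 10 µm or f̂ ≈ 0 — both suggest few
    or no correct matches in the pair of sessions.
    """
    z = np.asarray(z_distances, dtype=float)
    if np.any(z < 0):
        raise ValueError("z_distances must be non-negative (|Δz|)")
    if z.size < min_n:
        raise ThresholdFitError(
            f"need at least {min_n} distances to fit, got {z.size}")

    lo_s, hi_s = 0.1, 20.0
    lo_c, hi_c = 1.0, 500.0
    sigma0 = np.clip(np.std(z[z <= 10.0]) if np.any(z <= 10.0) else 5.0,
                     lo_s + 1e-3, hi_s)
    c0 = np.clip(z.mean(), lo_c + 1e-3, hi_c)

    if method == "mle":
        fit = _fit_mle(z, sigma_fixed, sigma0, c0,
                       (lo_s, hi_s), (lo_c, hi_c))
    elif method == "histogram":
        fit = _fit_histogram(z, sigma_fixed, sigma0, c0,
                             (lo_s, hi_s), (lo_c, hi_c),
                             bin_width, fit_range)
    else:
        raise ValueError(f"unknown fit method {method!r}")

    if fit.sigma > 10.0:
        fit.warnings_.append(
            f"fitted width sigma={fit.sigma:.2f} µm > 10 µm: few or no "
            "correct matches likely")
    if fit.f < 0.05:
        fit.warnings_.append(
            f"fitted correct-pair fraction f={fit.f:.3f} is very small: few "
            "or no correct matches likely")
    for msg in fit.warnings_:
        warnings.warn(msg, stacklevel=2)
    return fit


def _fit_histogram(z, sigma_fixed, sigma0, c0, s_bounds, c_bounds,
                   bin_width, fit_range) -> ThresholdFit:
    edges = np.arange(fit_range[0], fit_range[1] + bin_width, bin_width)
    counts, _ = np.histogram(z, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    d0 = z.size * bin_width

    if sigma_fixed is None:
        def model(p):
            f, s, c, d = p
            return d * mixture_pdf(centers, f, s, c)
        starts = [[f0, sigma0, cc, d0]
                  for f0 in (0.1, 0.5, 0.9) for cc in (c0, max(c0 / 2, 2.0))]
        lo = [0.0, s_bounds[0], c_bounds[0], 1e-9]
        hi = [1.0, s_bounds[1], c_bounds[1], np.inf]
    else:
        def model(p):
            f, c, d = p
            return d * mixture_pdf(centers, f, sigma_fixed, c)
        starts = [[f0, cc, d0]
                  for f0 in (0.1, 0.5, 0.9) for cc in (c0, max(c0 / 2, 2.0))]
        lo = [0.0, c_bounds[0], 1e-9]
        hi = [1.0, c_bounds[1], np.inf]

    # the objective is multimodal (a wide half-normal can mimic a truncated
    # exponential); multi-start and keep the lowest residual
    res = None
    for p0 in starts:
        r = optimize.least_squares(lambda p: model(p) - counts, p0,
                                   bounds=(lo, hi), ftol=1e-12, xtol=1e-12)
        if r.success and (res is None or r.cost < res.cost):
            res = r
    if res is None:
        raise ThresholdFitError("histogram mixture fit did not converge")
    if sigma_fixed is None:
        f, s, c, d = res.x
    else:
        f, c, d = res.x
        s = sigma_fixed
    fit = ThresholdFit(f=float(f), sigma=float(s), c=float(c), d=float(d),
                       n=z.size, sigma_fixed=sigma_fixed is not None,
                       residual=float(np.sqrt(2 * res.cost / counts.size)),
                       bin_width=bin_width, fit_range=tuple(fit_range))
    in_range = counts.sum()
    integral = model(res.x).sum()  # × bin_width / bin_width
    if in_range > 0 and abs(integral - in_range) > 0.02 * in_range:
        fit.warnings_.append(
            f"fitted curve integrates to {integral:.0f} counts vs "
            f"{in_range} observed in the fit window (> 2% off)")
    return fit


def _fit_mle(z, sigma_fixed, sigma0, c0, s_bounds, c_bounds) -> ThresholdFit:
    def nll(p):
        if sigma_fixed is None:
            f, s, c = p
        else:
            f, c = p
            s = sigma_fixed
        pdf = mixture_pdf(z, f, s, c)
        return -np.log(np.maximum(pdf, 1e-300)).sum()

    if sigma_fixed is None:
        p0, bounds = [0.5, sigma0, c0], [(0.0, 1.0), s_bounds, c_bounds]
    else:
        p0, bounds = [0.5, c0], [(0.0, 1.0), c_bounds]
    res = optimize.minimize(nll, p0, bounds=bounds, method="L-BFGS-B")
    if not res.success:
        raise ThresholdFitError(f"MLE mixture fit did not converge: "
                                f"{res.message}")
    if sigma_fixed is None:
        f, s, c = res.x
    else:
        f, c = res.x
        s = sigma_fixed
    return ThresholdFit(f=float(f), sigma=float(s), c=float(c),
                        d=float(z.size), n=z.size,
                        sigma_fixed=sigma_fixed is not None,
                        residual=float(res.fun))


# ---------------------------------------------------------------------------
# false-positive rate and threshold selection
# ---------------------------------------------------------------------------

def false_positive_rate(fit: ThresholdFit, z_thr: float) -> float:
    """FPR(z) = ∫₀^z incorrect density / ∫₀^z total density (closed form)."""
    if z_thr <= 0:
        raise ValueError("z threshold must be positive")
    wrong = (1.0 - fit.f) * fit.incorrect_cdf(z_thr)
    right = fit.f * fit.correct_cdf(z_thr)
    total = wrong + right
    if total == 0.0:
        return 0.0
    return float(wrong / total)


def select_threshold(fit: ThresholdFit, target_fpr: float,
                     grid_step: float = 0.1,
                     grid_max: float | None = None) -> tuple[float, dict]:
    """Largest grid z with FPR(z) ≤ target (FPR is non-decreasing in z).

    Returns ``(threshold, info)``; ``info['capped']`` marks the degenerate
    cases where every grid point satisfies the target (threshold = grid
    max).  Raises when the target is below the minimum achievable FPR.
    """
    if grid_max is None:
        grid_max = fit.fit_range[1]
    grid = np.arange(grid_step, grid_max + grid_step / 2, grid_step)
    fpr = fit.fpr_curve(grid)
    # the curve can dip by ~1e-4 just above 0 (the exponential CDF is
    # slightly concave where the folded-Gaussian CDF is still linear);
    # anything beyond that tolerance indicates a broken fit
    if np.any(np.diff(fpr) < -1e-3):
        raise ThresholdFitError("FPR curve is not monotone on the grid")
    ok = fpr <= target_fpr
    info = {"grid_step": grid_step, "grid_max": float(grid_max),
            "capped": False, "min_achievable_fpr": float(fpr.min())}
    if not ok.any():
        raise ThresholdFitError(
            f"target FPR {target_fpr} unattainable; minimum achievable is "
            f"{fpr.min():.4f}")
    idx = int(np.nonzero(ok)[0][-1])
    if idx == grid.size - 1:
        info["capped"] = True
        logger.info("every grid z meets the FPR target; threshold capped at "
                    "grid max %.1f µm", grid_max)
    thr = float(grid[idx])
    fit.chosen_threshold = thr
    return thr, info
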