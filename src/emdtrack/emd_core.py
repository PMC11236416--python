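"""Earth mover's distance matching between two sessions' unit sets.

Units carry unit mass, so the transport problem

    min_f  sum_ik f_ik D_ik
    s.t.   f_ik in [0, 1],  sum_k f_ik <= 1,  sum_i f_ik <= 1,
           sum_ik f_ik = min(N1, N2)

is a partial assignment: every unit of the smaller session is matched to a
distinct unit of the larger one.  The constraint matrix is totally
unimodular, so an optimal vertex is integral and the problem reduces
exactly to a rectangular linear assignment problem, solved here with a
modified Jonker-Volgenant algorithm (exact; no entropic regularization).

The cost combines physical and waveform space: D = d_loc + omega * d_wf,
where d_loc is the 3D Euclidean distance between estimated unit locations
(µm) and d_wf the normalized waveform distance in [0, 1]; omega (µm per
unit waveform distance, default 1500) trades proximity against waveform
similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .localization import UnitRecord
from .waveform_metric import WaveformPatch, pairwise_waveform_distances

#: default weight of waveform distance in the combined cost (µm per unit
#: d_wf); matching is insensitive to values above this
DEFAULT_OMEGA = 1500.0


@dataclass(frozen=True)
class CostMatrix:
    """Combined pairwise cost between two unit sets: D = d_loc + ω·d_wf."""

    d_loc: np.ndarray   # (N1, N2) µm
    d_wf: np.ndarray    # (N1, N2) unitless, in [0, 1]
    omega: float

    @property
    def D(self) -> np.ndarray:
        return self.d_loc + self.omega * self.d_wf

    @property
    def shape(self) -> tuple[int, int]:
        return self.d_loc.shape

    def validate(self) -> None:
        for name, m in (("d_loc", self.d_loc), ("d_wf", self.d_wf)):
            if not np.all(np.isfinite(m)) or np.any(m < 0):
                raise ValueError(f"{name} must be finite and non-negative")


@dataclass(frozen=True)
class TransportPlan:
    """Integral optimal flow: f_ik ∈ {0, 1}, min(N1, N2) matched pairs."""

    flows: np.ndarray                 # (N1, N2) in {0., 1.}
    total_cost: float
    assignment: tuple[tuple[int, int], ...]   # (i, k) with f_ik = 1

    def validate(self) -> None:
        if np.any((self.flows > 1e-6) & (np.abs(self.flows - 1) > 1e-6)):
            raise AssertionError("transport plan is not integral")
        if np.any(self.flows.sum(axis=0) > 1 + 1e-6) or \
                np.any(self.flows.sum(axis=1) > 1 + 1e-6):
            raise AssertionError("transport plan exceeds unit masses")
        expect = min(self.flows.shape)
        if abs(self.flows.sum() - expect) > 1e-6:
            raise AssertionError(
                f"total flow {self.flows.sum()} != min(N1, N2) = {expect}")


def build_cost_matrix(units1: list[UnitRecord], units2: list[UnitRecord],
                      patches1: list[WaveformPatch],
                      patches2: list[WaveformPatch],
                      omega: float = DEFAULT_OMEGA) -> CostMatrix:
    """Pairwise combined costs between two sessions' included units."""
    if not units1 or not units2:
        raise ValueError("both unit lists must be non-empty")
    loc1 = np.array([u.location for u in units1])
    loc2 = np.array([u.location for u in units2])
    diff = loc1[:, None, :] - loc2[None, :, :]
    d_loc = np.sqrt((diff ** 2).sum(axis=-1))
    d_wf = pairwise_waveform_distances(patches1, patches2)
    return CostMatrix(d_loc=d_loc, d_wf=d_wf, omega=float(omega))


def solve_transport(cost: CostMatrix | np.ndarray) -> TransportPlan:
    """Exact optimal partial assignment for the unit-mass transport problem.

    Ties are broken deterministically by adding a sub-1e-9 lexicographic
    perturbation (1e-9·(i·N2+k)/(N1·N2)) before solving; the reported
    total_cost uses the unperturbed costs.
    """
    if isinstance(cost, CostMatrix):
        cost.validate()
        D = cost.D
    else:
        D = np.asarray(cost, dtype=float)
    n1, n2 = D.shape
    tie = (np.arange(n1)[:, None] * n2 + np.arange(n2)[None, :]) \
        * (1e-9 / (n1 * n2))
    rows, cols = linear_sum_assignment(D + tie)
    flows = np.zeros((n1, n2))
    flows[rows, cols] = 1.0
    order = np.argsort(rows, kind="stable")
    assignment = tuple((int(rows[j]), int(cols[j])) for j in order)
    plan = TransportPlan(flows=flows,
                         total_cost=float(D[rows, cols].sum()),
                         assignment=assignment)
    plan.validate()
    return plan


def total_cost(plan: TransportPlan, cost: CostMatrix | np.ndarray) -> float:
    """Recompute Σ f_ik·D_ik for a plan against a cost matrix."""
    D = cost.D if isinstance(cost, CostMatrix) else np.asarray(cost)
    return float((plan.flows * D).sum())
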