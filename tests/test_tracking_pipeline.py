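import numpy as np
import pandas as pd
import pytest

from emdtrack.drift_threshold import DriftEstimate
from emdtrack.io_formats import save_matches
from emdtrack.synthetic_data import (SimulationConfig,
                                     simulate_session_sequence, true_pairs)
from emdtrack.tracking_pipeline import (Chain, MatchResult, accuracy,
                                        classify_chain,
                                        filter_by_z_threshold, match_all,
                                        match_sessions, prepare_units,
                                        recovery_rate, trace_chains)


def _result(pairs_rows, threshold=10.0):
    pairs = pd.DataFrame(pairs_rows,
                         columns=["unit1", "unit2", "d_loc", "d_wf",
                                  "distance", "z_distance",
                                  "passes_threshold"])
    return MatchResult(session1="a", session2="b", pairs=pairs,
                       drift=DriftEstimate(0.0, 1.0, 10, np.empty(0),
                                           np.empty(0)),
                       threshold=threshold, total_cost_pre=0.0,
                       total_cost_post=0.0, omega=1500.0)


def _row(u1, u2, z, passes=True):
    return (u1, u2, abs(z), 0.1, abs(z) + 150.0, z, passes)


NOISELESS = dict(jitter_sigma=0.0, amplitude_noise=0.0,
                 background_rms_uv=0.0, mua_fraction=0.0)


class TestMatchSessions:
    def test_rigid_shift_recovered_perfectly(self):
        cfg = SimulationConfig(seed=0, n_sessions=2, n_units=20,
                               survival=1.0, drift_per_session=12.0,
                               **NOISELESS)
        bundles, truth = simulate_session_sequence(cfg)
        res = match_sessions(bundles[0], bundles[1])
        assert res.drift.z_mode == pytest.approx(12.0, abs=0.5)
        tp = true_pairs(truth, "day01", "day02")
        assert recovery_rate(res, tp) == 1.0
        assert res.pairs["passes_threshold"].all()

    def test_each_unit_matched_at_most_once(self):
        cfg = SimulationConfig(seed=1, n_sessions=2, n_units=40)
        bundles, _ = simulate_session_sequence(cfg)
        res = match_sessions(bundles[0], bundles[1])
        assert res.pairs["unit1"].is_unique
        assert res.pairs["unit2"].is_unique

    def test_drift_correction_reduces_cost_and_improves_recovery(self):
        d_cost, d_rec = [], []
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, n_sessions=2, n_units=60,
                                   survival=0.6, drift_per_session=12.0)
            bundles, truth = simulate_session_sequence(cfg)
            res = match_sessions(bundles[0], bundles[1])
            tp = true_pairs(truth, "day01", "day02", good_only=True)
            rec_post = recovery_rate(res, tp)
            # an uncorrected run: force zero drift via huge min_pairs?
            # no -- compare stage-1 (pre) to stage-2 (post) cost, and
            # recovery of the stage-2 assignment vs the stage-1 one
            d_cost.append(res.total_cost_post - res.total_cost_pre)
            d_rec.append(rec_post)
        assert np.median(d_cost) <= 0.0
        assert np.median(d_rec) >= 0.8

    def test_waveform_weighting_does_not_hurt_recovery(self):
        deltas = []
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, n_sessions=2, n_units=60,
                                   survival=0.6, drift_per_session=12.0)
            bundles, truth = simulate_session_sequence(cfg)
            tp = true_pairs(truth, "day01", "day02", good_only=True)
            rec_w = recovery_rate(
                match_sessions(bundles[0], bundles[1], omega=1500.0), tp)
            rec_0 = recovery_rate(
                match_sessions(bundles[0], bundles[1], omega=0.0), tp)
            deltas.append(rec_w - rec_0)
        assert np.median(deltas) >= 0.0

    def test_deterministic_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(seed=2, n_sessions=2, n_units=30)
        for name in ("x", "y"):
            bundles, _ = simulate_session_sequence(cfg)
            res = match_sessions(bundles[0], bundles[1])
            save_matches(res, tmp_path / f"{name}.csv")
        assert (tmp_path / "x.csv").read_bytes() \
            == (tmp_path / "y.csv").read_bytes()

    def test_too_few_units_rejected(self):
        cfg = SimulationConfig(seed=3, n_sessions=2, n_units=5,
                               mua_fraction=1.0)
        bundles, _ = simulate_session_sequence(cfg)
        with pytest.raises(ValueError, match="no included units"):
            match_sessions(bundles[0], bundles[1])

    def test_fitted_threshold_policy_runs(self):
        cfg = SimulationConfig(seed=4, n_sessions=2, n_units=60,
                               survival=0.6, drift_per_session=12.0)
        bundles, _ = simulate_session_sequence(cfg)
        res = match_sessions(bundles[0], bundles[1],
                             threshold_policy="fit", target_fpr=0.27)
        assert res.threshold > 0
        assert res.threshold_fit is not None


class TestThresholdFilter:
    def test_infinite_threshold_passes_all(self):
        res = _result([_row(0, 1, 3.0), _row(1, 2, 40.0)])
        out = filter_by_z_threshold(res, np.inf)
        assert out.pairs["passes_threshold"].all()

    def test_zero_threshold_passes_only_exact(self):
        res = _result([_row(0, 1, 0.0), _row(1, 2, 0.1)])
        out = filter_by_z_threshold(res, 0.0)
        assert list(out.pairs["passes_threshold"]) == [True, False]

    def test_pass_sets_nest_with_threshold(self):
        rows = [_row(i, i, z) for i, z in enumerate(
            [1.0, 5.0, 9.0, 12.0, 14.0, 20.0])]
        res = _result(rows)
        at10 = set(filter_by_z_threshold(res, 10.0)
                   .passing_pairs()["unit1"])
        at15 = set(filter_by_z_threshold(res, 15.0)
                   .passing_pairs()["unit1"])
        assert at10 <= at15


class TestMetrics:
    def test_recovery_counts_reference_agreement(self):
        rows = [_row(i, i, 1.0) for i in range(7)] \
            + [_row(i, i + 100, 1.0) for i in range(7, 10)]
        res = _result(rows)
        ref = [(i, i) for i in range(10)]
        assert recovery_rate(res, ref) == pytest.approx(0.7)

    def test_perfect_superset_and_disjoint(self):
        res = _result([_row(0, 0, 1.0), _row(1, 1, 1.0),
                       _row(2, 5, 1.0)])
        assert recovery_rate(res, [(0, 0), (1, 1)]) == 1.0
        assert recovery_rate(res, [(0, 9), (1, 8)]) == 0.0
        with pytest.raises(ValueError, match="empty"):
            recovery_rate(res, [])

    def test_accuracy_vs_recovery_distinction(self):
        # 10 reference pairs; 9 matched correctly and pass, 1 matched
        # correctly but fails the threshold: recovery 0.9 among all
        # matched-correct... here: all 10 EMD pairs agree with reference,
        # one has |z| above threshold -> recovery 1.0? No: recovery counts
        # agreement regardless of threshold; accuracy only passing pairs.
        rows = [_row(i, i, 1.0) for i in range(9)] + [_row(9, 9, 40.0,
                                                          passes=False)]
        res = _result(rows)
        ref = [(i, i) for i in range(10)]
        assert recovery_rate(res, ref) == 1.0
        assert accuracy(res, ref) == 1.0

        # now pair 9 is assigned to the wrong partner with a large z:
        rows = [_row(i, i, 1.0) for i in range(9)] + [_row(9, 90, 40.0,
                                                          passes=False)]
        res = _result(rows)
        assert recovery_rate(res, ref) == pytest.approx(0.9)
        assert accuracy(res, ref) == 1.0  # the error fails the threshold

    def test_accuracy_never_below_recovery_when_errors_fail_threshold(self):
        rows = ([_row(i, i, 2.0) for i in range(8)]
                + [_row(8, 80, 35.0, passes=False),
                   _row(9, 90, 28.0, passes=False)])
        res = _result(rows)
        ref = [(i, i) for i in range(10)]
        assert accuracy(res, ref) >= recovery_rate(res, ref)

    def test_accuracy_undefined_when_nothing_passes(self):
        res = _result([_row(0, 0, 40.0, passes=False)])
        with pytest.raises(ValueError, match="passes"):
            accuracy(res, [(0, 0)])


class TestChains:
    def _link_result(self, s1, s2, mapping, failing=()):
        rows = [_row(a, b, 1.0) for a, b in mapping.items()]
        rows += [_row(a, b, 40.0, passes=False) for a, b in failing]
        res = _result(rows)
        res.session1, res.session2 = s1, s2
        return res

    def test_three_session_chain_traced(self):
        results = [self._link_result("s1", "s2", {7: 3}),
                   self._link_result("s2", "s3", {3: 5})]
        chains = trace_chains(results)
        assert len(chains) == 1
        assert chains[0].members == (("s1", 7), ("s2", 3), ("s3", 5))
        assert chains[0].fully_trackable

    def test_broken_link_yields_no_chain(self):
        results = [self._link_result("s1", "s2", {7: 3}),
                   self._link_result("s2", "s3", {}, failing=[(3, 5)])]
        assert trace_chains(results) == []

    def test_turnover_splits_traces(self):
        # unit A spans all 5 sessions; unit B disappears after session 2;
        # unit C appears in session 3 and persists
        results = [
            self._link_result("s1", "s2", {0: 0, 1: 1}),
            self._link_result("s2", "s3", {0: 0}),
            self._link_result("s3", "s4", {0: 0, 2: 2}),
            self._link_result("s4", "s5", {0: 0, 2: 2}),
        ]
        chains = trace_chains(results)
        keys = {c.members[0]: c.length for c in chains}
        assert keys == {("s1", 0): 5, ("s3", 2): 3}

    def test_non_consecutive_results_rejected(self):
        results = [self._link_result("s1", "s2", {0: 0}),
                   self._link_result("s3", "s4", {0: 0})]
        with pytest.raises(ValueError, match="consecutive"):
            trace_chains(results)

    def test_classification_rules(self):
        chain = Chain(members=(("s1", 0), ("s2", 1), ("s3", 2)))
        full = {("s1", 0), ("s2", 1), ("s3", 2)}
        assert classify_chain(chain, full).classification == "reference"
        assert classify_chain(chain, set()).classification == "putative"
        assert classify_chain(chain,
                              {("s1", 0)}).classification == "mixed"

    def test_chain_links_come_from_passing_pairs(self):
        cfg = SimulationConfig(seed=5, n_sessions=4, n_units=25,
                               survival=0.8, drift_per_session=8.0)
        bundles, _ = simulate_session_sequence(cfg)
        results = match_all(bundles, mode="consecutive")
        chains = trace_chains(results)
        by_pair = [set(zip(r.passing_pairs()["unit1"].astype(int),
                           r.passing_pairs()["unit2"].astype(int)))
                   for r in results]
        sessions = [r.session1 for r in results] + [results[-1].session2]
        for chain in chains:
            assert chain.length >= 3
            for (sa, ua), (sb, ub) in zip(chain.members[:-1],
                                          chain.members[1:]):
                t = sessions.index(sa)
                assert (ua, ub) in by_pair[t]


class TestMatchAll:
    def test_to_first_mode_pairs_against_day_one(self):
        cfg = SimulationConfig(seed=6, n_sessions=3, n_units=25,
                               survival=0.8)
        bundles, _ = simulate_session_sequence(cfg)
        results = match_all(bundles, mode="to-first")
        assert [(r.session1, r.session2) for r in results] \
            == [("day01", "day02"), ("day01", "day03")]

    def test_unrelated_session_triggers_high_cost_warning(self):
        # three related sessions followed by an unrelated population:
        # the last pair's per-pair EMD cost flags the large-drift gate
        cfg = SimulationConfig(seed=7, n_sessions=3, n_units=30,
                               survival=1.0, drift_per_session=5.0,
                               **NOISELESS)
        bundles, _ = simulate_session_sequence(cfg)
        other = SimulationConfig(seed=77, n_sessions=1, n_units=30)
        stranger, _ = simulate_session_sequence(other)
        stranger[0].session_id = "day04"
        with pytest.warns(UserWarning, match="large drift"):
            match_all(bundles + stranger, mode="consecutive")
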