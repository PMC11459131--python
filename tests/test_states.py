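"""State definition, kNN classification, transitions, refolding, stiffness."""

import numpy as np
import pandas as pd
import pytest

from tiplink.containers import PHASE_EXTENSION, PHASE_RELAXATION
from tiplink.mechanics import FitParams, extension_at_force
from tiplink.states import (
    StateModel,
    build_transition_map,
    classify_segment,
    define_states,
    entropic_stiffness_by_state,
    folded_threshold_from_means,
    refolding_summary,
    state_differences,
    tether_statistics,
)

STATE_MEANS = [40.0, 52.0, 82.0, 112.0, 130.0, 202.0]


def _six_state_sample(n_per=100, sigma=3.0, seed=0):
    rng = np.random.default_rng(seed)
    return np.concatenate([rng.normal(m, sigma, n_per) for m in STATE_MEANS])


class TestDefineStates:
    def test_recovers_generating_means(self):
        x = _six_state_sample()
        model = define_states(x)
        for m_true, m_est, sem in zip(STATE_MEANS, model.means, model.sems):
            assert m_est == pytest.approx(m_true, abs=max(3 * sem, 1.0))
        assert np.all(np.diff(model.means) > 0)
        assert model.counts.sum() == len(x)

    def test_order_invariance(self):
        x = _six_state_sample(seed=1)
        a = define_states(x)
        rng = np.random.default_rng(2)
        b = define_states(rng.permutation(x))
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.reference_labels, b.reference_labels)

    def test_identical_values_empty_clusters(self):
        with pytest.raises(ValueError):
            define_states(np.full(100, 50.0))

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            define_states(np.arange(30.0))


class TestClassify:
    @pytest.fixture()
    def model(self):
        return define_states(_six_state_sample())

    def test_reference_point_maps_to_own_state(self, model):
        for i in (0, 100, 300, 599):
            x = model.reference_x[i]
            assert classify_segment(model, x, k=1) == model.reference_labels[i]

    def test_matches_brute_force(self, model):
        # independent oracle: exhaustive sort with the same tie conventions
        def brute(x, k):
            order = sorted(range(len(model.reference_x)),
                           key=lambda i: (abs(model.reference_x[i] - x), model.reference_labels[i]))
            votes = [model.reference_labels[i] for i in order[:k]]
            best = None
            for s in sorted(set(votes)):
                c = votes.count(s)
                if best is None or c > best[1]:
                    best = (s, c)
            return best[0]

        for x in np.linspace(20, 220, 1000):
            assert classify_segment(model, x, k=3) == brute(x, 3)

    def test_vote_tie_breaks_to_lower_state(self):
        model = StateModel(
            means=np.array([10.0, 20.0]),
            sems=np.zeros(2),
            counts=np.array([2, 2]),
            reference_x=np.array([9.0, 11.0, 19.0, 21.0]),
            reference_labels=np.array([1, 1, 2, 2]),
        )
        assert classify_segment(model, 15.0, k=4) == 1

    def test_invalid_k(self, model):
        with pytest.raises(ValueError):
            classify_segment(model, 50.0, k=0)


class TestStateDifferences:
    def test_values_and_propagation(self):
        model = StateModel(
            means=np.array([10.0, 22.0, 50.0]),
            sems=np.array([0.3, 0.4, 1.0]),
            counts=np.array([5, 5, 5]),
            reference_x=np.array([10.0, 22.0, 50.0]),
            reference_labels=np.array([1, 2, 3]),
        )
        diffs = state_differences(model)
        assert diffs[0][0] == pytest.approx(12.0)
        assert diffs[0][1] == pytest.approx(0.5)  # sqrt(0.09 + 0.16)
        assert diffs[1][0] == pytest.approx(28.0)

    def test_recovers_generating_gaps(self):
        model = define_states(_six_state_sample(seed=3))
        for (delta, sem), (a, b) in zip(state_differences(model), zip(STATE_MEANS, STATE_MEANS[1:])):
            assert delta == pytest.approx(b - a, abs=max(3 * sem, 2.0))

    def test_folded_threshold_rule(self):
        assert folded_threshold_from_means([40, 52, 82, 112, 130, 202]) == 2
        assert folded_threshold_from_means([38, 67, 98, 116, 170, 188]) == 1


def _segments_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["dataset_id", "construct", "calcium", "cycle_index", "phase", "ordinal", "state"],
    )


class TestTransitionMap:
    def test_single_state_only_self_transitions(self):
        rows = [("d0", "wild-type", "3 mM", c, PHASE_EXTENSION, o, 1) for c in range(5) for o in (1, 2, 3)]
        tm = build_transition_map(_segments_frame(rows))
        assert set(zip(tm.counts.from_state, tm.counts.to_state)) == {(1, 1)}
        assert tm.occupancy == {1: 1.0}

    def test_deterministic_ladder_counts(self):
        n_cycles = 7
        rows = []
        for c in range(n_cycles):
            for o, s in enumerate([1, 2, 3], start=1):
                rows.append(("d0", "wild-type", "3 mM", c, PHASE_EXTENSION, o, s))
        tm = build_transition_map(_segments_frame(rows))
        for o, frm, to in [(1, 1, 2), (2, 2, 3)]:
            row = tm.counts[(tm.counts.ordinal == o)]
            assert len(row) == 1
            assert row.iloc[0]["count"] == n_cycles
            assert (row.iloc[0].from_state, row.iloc[0].to_state) == (frm, to)

    def test_occupancy_normalized_and_conservation(self):
        rng = np.random.default_rng(0)
        rows = []
        groups = 0
        total = 0
        for c in range(10):
            for phase in (PHASE_EXTENSION, PHASE_RELAXATION):
                n = rng.integers(1, 5)
                groups += 1
                for o in range(1, n + 1):
                    rows.append(("d0", "V507D", "20 uM", c, phase, o, int(rng.integers(1, 7))))
                    total += 1
        tm = build_transition_map(_segments_frame(rows))
        assert sum(tm.occupancy.values()) == pytest.approx(1.0)
        # total transitions = total segments - number of (cycle, phase) groups
        assert tm.counts["count"].sum() == total - groups

    def test_unclassified_segments_rejected(self):
        df = _segments_frame([("d0", "wild-type", "3 mM", 0, PHASE_EXTENSION, 1, np.nan)])
        with pytest.raises(ValueError):
            build_transition_map(df)


class TestRefolding:
    def _frame(self, per_cycle_states, construct="V507D", calcium="0 M EDTA", dataset="d0"):
        rows = []
        for c, (max_state, first_state) in enumerate(per_cycle_states):
            rows.append((dataset, construct, calcium, c, PHASE_EXTENSION, 1, first_state))
            rows.append((dataset, construct, calcium, c, PHASE_EXTENSION, 2, max_state))
        return _segments_frame(rows)

    def test_always_refolds(self):
        df = self._frame([(4, 1), (4, 1), (4, 1), (4, 2)])
        out = refolding_summary(df)
        entry = out[("V507D", "0 M EDTA")]
        assert entry.percent == pytest.approx(100.0)

    def test_never_exceeds_folded_states_is_undefined(self):
        df = self._frame([(2, 1), (1, 1), (2, 2)], construct="wild-type", calcium="3 mM")
        entry = refolding_summary(df)[("wild-type", "3 mM")]
        assert not entry.defined
        assert entry.percent is None

    def test_partial_refolding_counts(self):
        # cycles 0-3 all reach state 4; successors start at 1, 3, 1 -> 2/3
        df = self._frame([(4, 1), (4, 1), (4, 3), (4, 1)])
        entry = refolding_summary(df)[("V507D", "0 M EDTA")]
        assert entry.percent == pytest.approx(100 * 2 / 3)

    def test_monte_carlo_recovery_of_refold_probability(self):
        # every cycle qualifies; each successor starts folded w.p. p
        rng = np.random.default_rng(0)
        p = 0.6
        frames = []
        for d in range(10):
            first = [1] + [1 if rng.uniform() < p else 3 for _ in range(39)]
            frames.append(self._frame([(4, f) for f in first], dataset=f"d{d}"))
        entry = refolding_summary(pd.concat(frames, ignore_index=True))[("V507D", "0 M EDTA")]
        n = 39 * 10
        se = 100 * np.sqrt(p * (1 - p) / n)
        assert entry.percent == pytest.approx(100 * p, abs=2.5 * se)

    def test_mean_sem_over_datasets(self):
        frames = [
            self._frame([(4, 1), (4, 1), (4, 1)], dataset="a"),   # 100%
            self._frame([(4, 3), (4, 3), (4, 3)], dataset="b"),   # 0%
        ]
        entry = refolding_summary(pd.concat(frames, ignore_index=True))[("V507D", "0 M EDTA")]
        assert entry.percent == pytest.approx(50.0)
        assert entry.n_datasets == 2
        assert entry.sem == pytest.approx(50.0)


class TestStateStiffness:
    def test_matches_analytic_derivative_on_model_data(self):
        from tiplink.containers import Dataset, ForceRampCycle

        params = FitParams(60.0, 2.4, 2.5)
        f = np.linspace(1, 60, 2000)
        cyc = ForceRampCycle(
            time=np.arange(len(f)) / 1e3,
            force=f,
            extension=extension_at_force(params, f),
            phase=np.full(len(f), PHASE_EXTENSION, dtype="<U10"),
            dataset_id="m",
        )
        ds = Dataset([cyc], "m", "wild-type", "3 mM")
        segs = pd.DataFrame(
            [
                {
                    "dataset_id": "m",
                    "cycle_index": 0,
                    "phase": PHASE_EXTENSION,
                    "ordinal": 1,
                    "start": 0,
                    "stop": len(f),
                    "state": 1,
                }
            ]
        )
        edges = np.arange(5.0, 60.1, 5.0)
        table = entropic_stiffness_by_state([ds], segs, edges)
        for _, row in table.iterrows():
            fc = row.force_bin_center
            dxdf = params.x_e * params.f_half / (fc + params.f_half) ** 2 + 1 / params.k
            assert row.stiffness == pytest.approx(1 / dxdf, rel=0.08)
        # stiffness rises toward the enthalpic limit with force
        stiff = table.sort_values("force_bin_center").stiffness.to_numpy()
        assert np.all(np.diff(stiff) > 0)
        assert stiff[-1] < params.k

    def test_larger_x_e_is_softer_at_fixed_force(self):
        from tiplink.containers import Dataset, ForceRampCycle

        datasets = []
        seg_rows = []
        for state, x_e in ((1, 40.0), (2, 120.0)):
            f = np.linspace(1, 60, 1500)
            cyc = ForceRampCycle(
                time=np.arange(len(f)) / 1e3,
                force=f,
                extension=extension_at_force(FitParams(x_e, 2.4, 2.5), f),
                phase=np.full(len(f), PHASE_EXTENSION, dtype="<U10"),
            )
            datasets.append(Dataset([cyc], f"d{state}", "wild-type", "3 mM"))
            seg_rows.append(
                {
                    "dataset_id": f"d{state}",
                    "cycle_index": 0,
                    "phase": PHASE_EXTENSION,
                    "ordinal": 1,
                    "start": 0,
                    "stop": len(f),
                    "state": state,
                }
            )
        table = entropic_stiffness_by_state(datasets, pd.DataFrame(seg_rows), [10.0, 15.0])
        soft = table.set_index("state").stiffness
        assert soft.loc[2] < soft.loc[1]

    def test_empty_bins_absent(self):
        from tiplink.containers import Dataset, ForceRampCycle

        f = np.linspace(1, 20, 500)
        cyc = ForceRampCycle(
            time=np.arange(len(f)) / 1e3,
            force=f,
            extension=extension_at_force(FitParams(40.0, 2.0, 2.5), f),
            phase=np.full(len(f), PHASE_EXTENSION, dtype="<U10"),
        )
        ds = Dataset([cyc], "d", "wild-type", "3 mM")
        segs = pd.DataFrame(
            [{"dataset_id": "d", "cycle_index": 0, "phase": PHASE_EXTENSION,
              "ordinal": 1, "start": 0, "stop": len(f), "state": 1}]
        )
        table = entropic_stiffness_by_state([ds], segs, [5.0, 10.0, 40.0, 50.0])
        assert set(table.force_bin_center) <= {7.5, 25.0}  # 40-50 pN bin has no data


class TestTetherStatistics:
    def test_poisson_closed_form(self):
        frac = 1 - np.exp(-1)  # lambda = 1
        assert tether_statistics(10000, int(round(10000 * frac))) == pytest.approx(
            np.exp(-1) / (1 - np.exp(-1)), abs=1e-3
        )

    def test_rare_tethering_limit(self):
        assert tether_statistics(100000, 10) == pytest.approx(1.0, abs=1e-3)

    def test_all_tethered_rejected(self):
        with pytest.raises(ValueError):
            tether_statistics(100, 100)

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            tether_statistics(10, 11)
        with pytest.raises(ValueError):
            tether_statistics(0, 0)
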