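"""Synthetic force-ramp generator: ground truth, kinetics, presets."""

from dataclasses import replace

import numpy as np
import pytest

from tiplink.containers import PHASE_EXTENSION
from tiplink.mechanics import FitParams, KBT_PN_NM
from tiplink.simulate import (
    DomainUnit,
    RampProtocol,
    SimulationConfig,
    condition_presets,
    ground_truth_refolding,
    rate_for_unfold_probability,
    rate_for_unfolding_force,
    simulate_cycle,
    simulate_dataset,
)

from conftest import single_unit_config


class TestProtocol:
    def test_schedule_shape_and_split(self):
        p = RampProtocol(resting_force=1, peak_force=11, loading_rate=10, sample_rate=100)
        t, force, phase = p.schedule()
        n = p.n_half
        assert len(force) == 2 * n + 1
        assert force[0] == pytest.approx(1.0)
        assert force[n] == pytest.approx(11.0)
        assert force[-1] == pytest.approx(1.0)  # symmetric ramp ends back at rest
        assert (phase == PHASE_EXTENSION).sum() == n + 1

    def test_invalid_protocol(self):
        with pytest.raises(ValueError):
            RampProtocol(resting_force=5, peak_force=5)
        with pytest.raises(ValueError):
            RampProtocol(loading_rate=-1)


class TestCycle:
    def test_no_kinetics_no_hysteresis(self):
        cyc = simulate_cycle(single_unit_config(k0=0.0))
        n = len(cyc.force) // 2
        up = cyc.extension[:n]
        down = cyc.extension[n + 1 :][::-1]
        assert np.allclose(up, down, atol=1e-9)
        assert cyc.events == []

    def test_certain_unfolding_logs_programmed_gain(self):
        # huge k0: the unit unfolds immediately; the log records the
        # programmed contour gain and the realized jump at the event force
        cfg = single_unit_config(gain=17.0, k0=1e6, dx_act=0.0)
        cyc = simulate_cycle(cfg)
        assert len(cyc.events) == 1
        ev = cyc.events[0]
        assert ev.contour_gain == 17.0
        expected_jump = 17.0 * ev.force / (ev.force + cfg.base_params.f_half)
        assert ev.observed_step == pytest.approx(expected_jump)
        # instant unfolding at the first sample: the whole noiseless trace
        # follows the model with the enlarged entropic extension
        assert ev.sample_index == 0
        p = cfg.base_params
        expected = (p.x_e + 17.0) * cyc.force / (cyc.force + p.f_half) + cyc.force / p.k
        assert np.allclose(cyc.extension, expected, atol=1e-9)

    def test_mid_ramp_unfolding_steps_by_realized_jump(self):
        # a deterministic mid-ramp event: the extension jump at the event
        # sample equals contour_gain * F / (F + F_half)
        from tiplink.simulate import rate_for_unfolding_force

        k0 = rate_for_unfolding_force(30.0, 0.6)
        cfg = single_unit_config(gain=17.0, k0=k0, dx_act=0.6)
        cyc = simulate_cycle(cfg, rng=np.random.default_rng(0))
        assert len(cyc.events) == 1
        ev = cyc.events[0]
        assert ev.sample_index > 0
        i = ev.sample_index
        jump = cyc.extension[i] - cyc.extension[i - 1]
        drift = cyc.extension[i + 1] - cyc.extension[i]
        assert jump - drift == pytest.approx(ev.observed_step, abs=0.05)

    def test_seeded_reproducibility(self):
        cfg = single_unit_config(k0=0.01, noise_sd=0.3, seed=5)
        a = simulate_cycle(cfg, rng=np.random.default_rng(5))
        b = simulate_cycle(cfg, rng=np.random.default_rng(5))
        assert np.array_equal(a.extension, b.extension)
        assert a.events == b.events

    def test_folded_state_length_checked(self):
        with pytest.raises(ValueError):
            simulate_cycle(single_unit_config(), folded_state=(True, True))

    def test_extension_follows_model_between_steps(self):
        cfg = single_unit_config(k0=0.0, params=FitParams(63.8, 2.4, 2.5))
        cyc = simulate_cycle(cfg)
        expected = 63.8 * cyc.force / (cyc.force + 2.4) + cyc.force / 2.5
        assert np.allclose(cyc.extension, expected, atol=1e-9)


class TestDataset:
    def test_full_refolding_resets_state(self):
        cfg = single_unit_config(k0=0.05, dx_act=0.3, refold=1.0, seed=3)
        ds = simulate_dataset(cfg, 20)
        assert all(cyc.folded_start == (True,) for cyc in ds.cycles)

    def test_irreversible_unfolder_fires_once(self):
        cfg = single_unit_config(k0=0.05, dx_act=0.3, refold=0.0, seed=3)
        ds = simulate_dataset(cfg, 50)
        assert len(ds.all_events()) <= 1

    def test_poor_refolding_extends_baseline(self):
        cfg = replace(condition_presets("V507D", "0 M EDTA"), seed=2)
        ds = simulate_dataset(cfg, 80)
        first = ds.cycles[0].extension[:50].mean()
        late = np.mean([c.extension[:50].mean() for c in ds.cycles[40:]])
        assert late > first + 5.0  # later cycles start visibly extended

    def test_n_cycles_validated(self):
        with pytest.raises(ValueError):
            simulate_dataset(single_unit_config(), 0)


class TestKinetics:
    def test_rate_helpers_invert_correctly(self):
        proto = RampProtocol()
        k0 = rate_for_unfold_probability(0.6, 0.4, proto)
        # Monte Carlo check of the nominal per-cycle unfolding probability
        cfg = single_unit_config(k0=k0, dx_act=0.4, refold=1.0)
        rng = np.random.default_rng(0)
        unfolded = sum(
            bool(simulate_cycle(cfg, rng=rng).events) for _ in range(400)
        )
        assert unfolded / 400 == pytest.approx(0.6, abs=0.07)

    def test_unfolding_force_parametrization(self):
        k0 = rate_for_unfolding_force(40.0, 0.55)
        cfg = single_unit_config(k0=k0, dx_act=0.55, refold=1.0)
        rng = np.random.default_rng(1)
        forces = []
        for _ in range(300):
            cyc = simulate_cycle(cfg, rng=rng)
            if cyc.events:
                forces.append(cyc.events[0].force)
        assert len(forces) > 290  # essentially always unfolds
        assert np.median(forces) == pytest.approx(40.0, abs=4.0)

    def test_mean_unfolding_force_increases_with_loading_rate(self):
        # Bell-Evans: faster ramps give less time at low force, so the
        # typical unfolding force rises with the loading rate.
        forces = {}
        for rate in (5.0, 80.0):
            proto = RampProtocol(loading_rate=rate)
            cfg = single_unit_config(k0=0.02, dx_act=0.5, refold=1.0, protocol=proto)
            rng = np.random.default_rng(7)
            fs = []
            for _ in range(500):
                cyc = simulate_cycle(cfg, rng=rng)
                fs.extend(e.force for e in cyc.events)
            forces[rate] = np.mean(fs)
        assert forces[80.0] > forces[5.0] + 2.0


class TestPresets:
    def test_deterministic(self):
        a = condition_presets("wild-type", "20 uM")
        b = condition_presets("wild-type", "20 uM")
        assert a == b

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            condition_presets("wild-type", "1 mM")
        with pytest.raises(ValueError):
            condition_presets("mutant", "3 mM")

    def test_saturating_calcium_events_are_small(self):
        cfg = replace(condition_presets("wild-type", "3 mM"), seed=1)
        ds = simulate_dataset(cfg, 60)
        events = ds.all_events()
        assert events, "expected some linker events"
        assert all(e.contour_gain < 10.0 for e in events)

    def test_event_totals_increase_as_calcium_decreases(self):
        # Ground-truth event counts, pooled over seeds, ordered by Ca2+ rank
        counts = {}
        unfold = {}
        for ca in ("3 mM", "20 uM", "0 M EDTA"):
            n = 0
            nm = 0.0
            for seed in range(20):
                cfg = replace(condition_presets("wild-type", ca), seed=seed)
                ds = simulate_dataset(cfg, 15)
                evs = ds.all_events()
                n += len(evs)
                nm += sum(e.contour_gain for e in evs)
            counts[ca] = n
            unfold[ca] = nm
        assert counts["3 mM"] < counts["20 uM"] < counts["0 M EDTA"]
        assert unfold["3 mM"] < unfold["20 uM"] < unfold["0 M EDTA"]

    def test_mutant_unfolds_more_and_refolds_less(self):
        for ca in ("20 uM", "0 M EDTA"):
            tot = {}
            ref = {}
            for construct in ("wild-type", "V507D"):
                nm = 0.0
                refs = []
                for seed in range(6):
                    cfg = replace(condition_presets(construct, ca), seed=seed)
                    ds = simulate_dataset(cfg, 40)
                    nm += sum(e.contour_gain for e in ds.all_events())
                    r = ground_truth_refolding(ds)
                    if r is not None:
                        refs.append(r)
                tot[construct] = nm
                ref[construct] = np.mean(refs)
            assert tot["V507D"] > tot["wild-type"]
            assert ref["V507D"] < ref["wild-type"]

    def test_refolding_decreases_as_calcium_decreases(self):
        for construct in ("wild-type", "V507D"):
            means = []
            for ca in ("20 uM", "0 M EDTA"):
                refs = []
                for seed in range(6):
                    cfg = replace(condition_presets(construct, ca), seed=seed)
                    refs.append(ground_truth_refolding(simulate_dataset(cfg, 40)))
                means.append(np.mean([r for r in refs if r is not None]))
            assert means[0] > means[1]

    def test_wild_type_saturating_never_qualifies(self):
        cfg = replace(condition_presets("wild-type", "3 mM"), seed=0)
        assert ground_truth_refolding(simulate_dataset(cfg, 60)) is None

    def test_relaxation_events_fewer_and_smaller(self):
        for construct, ca in (
            ("wild-type", "3 mM"),
            ("wild-type", "0 M EDTA"),
            ("V507D", "20 uM"),
            ("V507D", "0 M EDTA"),
        ):
            ext, rel = [], []
            for seed in range(4):
                cfg = replace(condition_presets(construct, ca), seed=seed)
                for cyc in simulate_dataset(cfg, 60).cycles:
                    for e in cyc.events:
                        (ext if e.phase == PHASE_EXTENSION else rel).append(e.observed_step)
            assert len(rel) < len(ext)
            assert np.mean(rel) < np.mean(ext)
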