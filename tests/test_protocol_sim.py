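"""Schedule structure, signal-model contracts and on-disk output of the simulator."""

import numpy as np
import pytest

import emgshift as es
from emgshift import protocol_sim as ps


class TestSchedule:
    def test_day1_defaults_150_trials_from_con_plus(self):
        cfg = es.ProtocolConfig()
        sched = es.make_schedule(cfg, day=1, seed=0)
        assert len(sched) == 150
        assert {p for p, *_ in sched} == set(es.CON_PLUS)

    def test_day2_uses_con_x(self):
        sched = es.make_schedule(es.ProtocolConfig(), day=2, seed=0)
        assert {p for p, *_ in sched} == set(es.CON_X)

    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_block_structure_and_balance(self, seed):
        cfg = es.ProtocolConfig()
        sched = es.make_schedule(cfg, day=1, seed=seed)
        # consecutive blocks of 5 trials with identical (position, grasp)
        for b in range(30):
            block = sched[5 * b:5 * b + 5]
            assert len({(p, g) for p, g, *_ in block}) == 1
            assert [t for *_, t, _ in block] == list(range(5))
            assert all(bn == b for *_, bn in block)
        # every (position, grasp) pair in exactly one block
        pairs = [(p, g) for p, g, t, _ in sched if t == 0]
        assert len(pairs) == 30 == len(set(pairs))
        # per (grasp, position) count equals trials_per_grasp
        from collections import Counter
        counts = Counter((p, g) for p, g, *_ in sched)
        assert set(counts.values()) == {cfg.trials_per_grasp}

    def test_seed_reproducibility_and_variation(self):
        cfg = es.ProtocolConfig()
        assert es.make_schedule(cfg, 1, 42) == es.make_schedule(cfg, 1, 42)
        orders = {tuple((p, g) for p, g, t, _ in es.make_schedule(cfg, 1, s) if t == 0)
                  for s in range(20)}
        assert len(orders) > 1  # different seeds shuffle block order

    def test_degenerate_single_entry(self):
        cfg = es.ProtocolConfig(trials_per_grasp=1, grasps=(1,), positions_day1=(5,))
        assert es.make_schedule(cfg, 1, 0) == [(5, 1, 0, 0)]

    def test_invalid_day_rejected(self):
        with pytest.raises(ValueError, match="day"):
            es.make_schedule(es.ProtocolConfig(), day=3, seed=0)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            es.ProtocolConfig(grasps=())
        with pytest.raises(ValueError):
            es.ProtocolConfig(positions_day1=())

    def test_default_configurations_share_only_neutral_position(self):
        cfg = es.ProtocolConfig()
        assert set(cfg.positions_day1) & set(cfg.positions_day2) == {5}
        assert cfg.trials_per_session(1) == 150


class TestSimulateTrial:
    def test_contracted_shapes(self):
        rec = es.simulate_trial(es.SimulationParams(), position=5, grasp=1, seed=3)
        assert rec.emg.shape == (16, 10000)
        assert rec.glove.shape == (18, 10000)

    def test_all_stochastic_terms_off_leaves_dc(self):
        sp = es.SimulationParams(amp_profile=np.zeros((6, 16)), powerline_amp=0.0,
                                 shift_magnitude=0.0)
        rec = es.simulate_trial(sp, 5, 1, 0, sampling_rate=1000.0, trial_length=0.5)
        assert np.allclose(rec.emg, sp.dc_offset[:, None])

    def test_deterministic_given_seed(self):
        sp = es.SimulationParams(seed=5)
        a = es.simulate_trial(sp, 4, 2, 99, sampling_rate=1000.0, trial_length=1.0)
        b = es.simulate_trial(sp, 4, 2, 99, sampling_rate=1000.0, trial_length=1.0)
        np.testing.assert_array_equal(a.emg, b.emg)
        np.testing.assert_array_equal(a.glove, b.glove)

    def test_unknown_labels_rejected(self):
        sp = es.SimulationParams()
        with pytest.raises(ValueError, match="grasp"):
            es.simulate_trial(sp, 5, 7, 0)
        with pytest.raises(ValueError, match="position"):
            es.simulate_trial(sp, 12, 1, 0)

    def test_rms_scales_with_multiplicative_shift(self):
        """Channel RMS at delta=0.5 is (1+0.5*u[p,c]) times the delta=0 RMS.

        The postural-tone term is switched off to isolate the multiplicative
        pathway; the band-limited carrier is seed-matched so the ratio is a
        tight Monte-Carlo estimate over 50 seeds.
        """
        base = dict(powerline_amp=0.0, postural_tone=0.0,
                    dc_offset=np.zeros(16))
        sp0 = es.SimulationParams(shift_magnitude=0.0, **base)
        sp5 = es.SimulationParams(shift_magnitude=0.5, **base)
        p = 2
        ratios = []
        for seed in range(50):
            r0 = es.simulate_trial(sp0, p, 1, seed, sampling_rate=1000.0, trial_length=1.0)
            r5 = es.simulate_trial(sp5, p, 1, seed, sampling_rate=1000.0, trial_length=1.0)
            rms0 = np.sqrt((r0.emg ** 2).mean(axis=1))
            rms5 = np.sqrt((r5.emg ** 2).mean(axis=1))
            ratios.append(rms5 / rms0)
        expected = 1.0 + 0.5 * sp0.shift_pattern[p]
        np.testing.assert_allclose(np.mean(ratios, axis=0), expected, rtol=0.05)

    def test_powerline_dominates_neighbouring_bins_before_notch(self):
        """With mains interference on, the 50 Hz periodogram bin towers over
        its neighbours in the raw (un-notched) signal."""
        from scipy.signal import periodogram
        rec = es.simulate_trial(es.SimulationParams(), position=5, grasp=6, seed=1)
        f, pxx = periodogram(rec.emg[0], fs=2000.0)
        bin50 = np.argmin(np.abs(f - 50.0))
        neighbours = np.r_[pxx[bin50 - 5:bin50], pxx[bin50 + 1:bin50 + 6]]
        assert pxx[bin50] > neighbours.max()

    def test_delta_zero_collapses_positions(self):
        """At delta=0 the same seed yields identical signals at any position."""
        sp = es.SimulationParams(shift_magnitude=0.0)
        a = es.simulate_trial(sp, 2, 3, 7, sampling_rate=1000.0, trial_length=0.5)
        b = es.simulate_trial(sp, 9, 3, 7, sampling_rate=1000.0, trial_length=0.5)
        np.testing.assert_array_equal(a.emg, b.emg)


class TestShiftMonotonicity:
    def test_centroid_spread_nondecreasing_in_delta(self, small_cfg):
        """Mean pairwise distance between per-position feature centroids grows
        with the shift magnitude (averaged over 10 seeds)."""
        from emgshift.pipeline import featurize_records
        from emgshift.preprocess import FilterSpec

        fspec = FilterSpec(sampling_rate=1000.0)
        deltas = (0.0, 0.2, 0.5, 1.0)
        mean_dist = []
        for delta in deltas:
            dists = []
            for seed in range(10):
                sp = es.SimulationParams(seed=seed, shift_magnitude=delta)
                cents = []
                for p in es.CON_PLUS:
                    recs = [es.simulate_trial(sp, p, 1, ps.subseed(seed, p, k),
                                              sampling_rate=1000.0, trial_length=1.0)
                            for k in range(2)]
                    df = featurize_records(recs, fspec)
                    cents.append(df[es.feature_columns(16)].mean().to_numpy())
                cents = np.array(cents)
                d = np.linalg.norm(cents[:, None] - cents[None, :], axis=-1)
                dists.append(d[np.triu_indices(len(cents), 1)].mean())
            mean_dist.append(np.mean(dists))
        assert all(a <= b + 1e-9 for a, b in zip(mean_dist, mean_dist[1:]))
        assert mean_dist[0] < mean_dist[-1]


class TestSimulateParticipant:
    def test_writes_four_sessions_with_150_trials(self, small_cfg, tmp_path):
        import pandas as pd
        paths = es.simulate_participant(small_cfg, es.SimulationParams(seed=1), 3, tmp_path)
        assert len(paths) == 4
        names = {p.name for p in paths}
        assert names == {f"participant3_day{d}_session{s}" for d in (1, 2) for s in (1, 2)}
        for p in paths:
            assert len(pd.read_csv(p / "trials.csv")) == 150

    def test_single_session_per_day(self, tmp_path):
        cfg = es.ProtocolConfig(sampling_rate=500.0, trial_length=1.0,
                                trials_per_grasp=1, grasps=(1, 2),
                                positions_day1=(5,), positions_day2=(5,),
                                sessions_per_day=1)
        sp = es.SimulationParams(noise_band=(20.0, 200.0))
        assert len(es.simulate_participant(cfg, sp, 1, tmp_path)) == 2

    def test_roundtrip_matches_memory_records(self, small_cfg, tmp_path):
        sp = es.SimulationParams(seed=4)
        sp_i = ps.participant_params(sp, 2)
        records = es.simulate_session(small_cfg, sp_i, 2, 1, 1)
        es.simulate_participant(small_cfg, sp, 2, tmp_path)
        loaded, params = es.read_session(tmp_path / "participant2_day1_session1")
        assert len(loaded) == len(records)
        assert params.configuration == "+"
        for mem, disk in zip(records, loaded):
            np.testing.assert_array_equal(mem.emg, disk.emg)
            np.testing.assert_array_equal(mem.glove, disk.glove)
            assert (mem.position, mem.grasp, mem.trial_no, mem.block_no) == \
                (disk.position, disk.grasp, disk.trial_no, disk.block_no)

    def test_participants_differ(self, small_cfg):
        sp = es.SimulationParams(seed=0)
        a = ps.participant_params(sp, 1).amp_profile
        b = ps.participant_params(sp, 2).amp_profile
        assert not np.allclose(a, b)
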