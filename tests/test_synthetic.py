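import numpy as np
import pandas as pd
import pytest

from cogload import precision as prec
from cogload import stats as st
from cogload import synthetic as syn
from tests.conftest import small_effects


class TestStudyConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_participants", 1),
            ("fs", 0.0),
            ("session_length_s", 30.0),
            ("min_repetitions", 0),
        ],
    )
    def test_invalid_fields_rejected_by_name(self, field, value):
        with pytest.raises(ValueError, match=field):
            syn.StudyConfig(**{field: value})


class TestCounterbalancing:
    def test_four_participants_cover_all_subgroups(self):
        study = syn.generate_study(
            syn.StudyConfig(n_participants=4, seed=1), include_signals=False
        )
        subgroups = {p.subgroup for p in study.participants}
        assert subgroups == {"Sub_G1.1", "Sub_G1.2", "Sub_G2.1", "Sub_G2.2"}

    def test_session_order_and_pattern_allocation(self):
        study = syn.generate_study(
            syn.StudyConfig(n_participants=4, seed=1), include_signals=False
        )
        by_subgroup = {p.subgroup: p for p in study.participants}
        g11 = by_subgroup["Sub_G1.1"].sessions
        assert [s.label for s in g11] == ["baseline", "code", "visual"]
        assert g11[1].patterns == (1, 2) and g11[2].patterns == (3, 4)
        g22 = by_subgroup["Sub_G2.2"].sessions
        assert [s.label for s in g22] == ["baseline", "visual", "code"]
        assert g22[1].patterns == (3, 4) and g22[2].patterns == (1, 2)

    def test_every_participant_has_one_subgroup_and_three_sessions(self):
        study = syn.generate_study(
            syn.StudyConfig(n_participants=10, seed=2), include_signals=False
        )
        for p in study.participants:
            assert p.subgroup in {s[0] for s in syn.SUBGROUPS}
            assert len(p.sessions) == 3
            assert {s.label for s in p.sessions} == {"baseline", "visual", "code"}


class TestDeterminism:
    def test_identical_seed_identical_study(self):
        cfg = syn.StudyConfig(
            n_participants=4, fs=50.0, session_length_s=60.0,
            baseline_length_s=60.0, seed=7, effects=small_effects(),
        )
        a, b = syn.generate_study(cfg), syn.generate_study(cfg)
        pa, pb = a.participants[2].sessions[1], b.participants[2].sessions[1]
        assert np.array_equal(pa.ppg.samples, pb.ppg.samples)
        assert np.array_equal(pa.gsr.samples, pb.gsr.samples)
        assert np.array_equal(pa.accel.x, pb.accel.x)
        assert pa.tlx == pb.tlx and pa.dssq == pb.dssq
        pd.testing.assert_frame_equal(syn.trials_frame(a), syn.trials_frame(b))

    def test_different_seed_differs(self):
        base = dict(n_participants=2, fs=50.0, session_length_s=60.0,
                    baseline_length_s=60.0, effects=small_effects())
        a = syn.generate_study(syn.StudyConfig(seed=1, **base))
        b = syn.generate_study(syn.StudyConfig(seed=2, **base))
        assert not np.array_equal(
            a.participants[0].sessions[0].ppg.samples,
            b.participants[0].sessions[0].ppg.samples,
        )


class TestSimulatePPG:
    def test_noiseless_uniform_train_is_periodic(self):
        fs = 250.0
        beats = np.arange(1.0, 9.0, 0.8)
        sig = syn.simulate_ppg(beats, fs, duration_s=10)
        period = int(0.8 * fs)
        core = sig.samples[int(1.5 * fs) : int(8.0 * fs)]
        assert np.allclose(core[:-period], core[period:], atol=1e-6)

    def test_dc_offset_sets_mean(self):
        sig = syn.simulate_ppg(np.arange(0.5, 59, 0.8), 100, dc_offset=5.0,
                               duration_s=60)
        assert abs(sig.samples.mean() - 5.0) < 0.5

    def test_non_increasing_beats_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            syn.simulate_ppg(np.array([1.0, 1.0, 2.0]), 100)


class TestSimulateGSR:
    def test_event_free_flat_tonic_is_constant(self):
        sim = syn.simulate_gsr([], [(0.0, 2.0), (60.0, 2.0)], fs=50, duration_s=60)
        assert np.allclose(sim.signal.samples, 2.0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            syn.simulate_gsr([(5.0, -0.1)], [(0.0, 2.0)], fs=50, duration_s=30)

    def test_ground_truth_components_reconstruct_signal(self):
        sim = syn.simulate_gsr([(10.0, 0.5)], [(0.0, 2.0), (60.0, 2.5)],
                               fs=50, duration_s=60)
        assert np.allclose(sim.tonic + sim.phasic, sim.signal.samples)


class TestSimulateAccel:
    def test_no_motion_std_at_noise_floor(self):
        sig = syn.simulate_accel([], fs=50, duration_s=60, noise_sd_g=0.02,
                                 rng=np.random.default_rng(0))
        assert np.std(sig.x) < 0.03
        assert abs(np.mean(sig.z) - 1.0) < 0.01

    def test_more_repetitions_more_movement(self):
        kw = dict(fs=50, duration_s=120, burst_amp_g=0.5)
        few = syn.simulate_accel(
            list(np.linspace(5, 100, 6)), rng=np.random.default_rng(1), **kw
        )
        many = syn.simulate_accel(
            list(np.linspace(5, 100, 10)), rng=np.random.default_rng(1), **kw
        )
        assert np.mean(np.abs(many.resultant - 1)) > np.mean(np.abs(few.resultant - 1))

    def test_fixed_seed_reproducible(self):
        a = syn.simulate_accel([5.0], fs=50, duration_s=20,
                               rng=np.random.default_rng(3))
        b = syn.simulate_accel([5.0], fs=50, duration_s=20,
                               rng=np.random.default_rng(3))
        assert np.array_equal(a.x, b.x)


class TestProtocolFidelity:
    def test_tct_extension_rule(self):
        study = syn.generate_study(
            syn.StudyConfig(n_participants=8, seed=3), include_signals=False
        )
        for p, s in study.sessions():
            if s.label == "baseline":
                continue
            counts = {pat: 0 for pat in s.patterns}
            for tr in s.trials:
                counts[tr.pattern_id] += 1
            assert all(c >= study.config.min_repetitions for c in counts.values())
            assert s.tct_s >= study.config.session_length_s or all(
                c >= study.config.min_repetitions for c in counts.values()
            )
            assert s.ntr == len(s.trials)

    def test_signal_duration_covers_tct(self):
        cfg = syn.StudyConfig(
            n_participants=2, fs=50.0, session_length_s=60.0,
            baseline_length_s=60.0, seed=4, effects=small_effects(),
        )
        study = syn.generate_study(cfg)
        for p, s in study.sessions():
            if s.label == "baseline":
                continue
            assert s.ppg.duration >= max(cfg.session_length_s, s.tct_s) - 1e-6


class TestConditionEffects:
    def test_questionnaire_scores_within_instrument_bounds(self, behavioural_study):
        from cogload.pipeline import dssq_scores, tlx_scores

        tlx = tlx_scores(behavioural_study)
        assert tlx["cognitive_load"].between(0, 100).all()
        dssq = dssq_scores(behavioural_study)
        for state in ("engagement", "distress", "worry"):
            assert dssq[state].between(0, 32).all()

    def test_null_effects_yield_null_effect_sizes_at_large_n(self):
        flat = {"visual": 45.0, "code": 45.0}
        effects = syn.ConditionEffects(
            tlx_cl_mean=flat,
            tlx_subscale_offset={
                "visual": dict.fromkeys(
                    ("mental", "physical", "temporal", "performance",
                     "effort", "frustration"), 0.0),
                "code": dict.fromkeys(
                    ("mental", "physical", "temporal", "performance",
                     "effort", "frustration"), 0.0),
            },
            rep_duration_mean_s={"visual": 40.0, "code": 40.0},
            placement_sd={"visual": 3.0, "code": 3.0},
        )
        study = syn.generate_study(
            syn.StudyConfig(n_participants=200, seed=21, effects=effects),
            include_signals=False,
        )
        from cogload.pipeline import performance_scores, tlx_scores

        tlx = tlx_scores(study).set_index(["participant_id", "session"])
        wide = tlx["cognitive_load"].unstack("session")
        res = st.paired_compare(wide["visual"].to_numpy(), wide["code"].to_numpy())
        assert abs(res.effect_size) < 0.15
        perf = performance_scores(study).set_index(["participant_id", "session"])
        pw = perf["precision_sd"].unstack("session")
        res2 = st.paired_compare(pw["visual"].to_numpy(), pw["code"].to_numpy())
        assert abs(res2.effect_size) < 0.15


class TestSimulateTrials:
    def test_rigid_motion_only_keeps_precision_zero(self):
        ref = syn.reference_patterns()[3]
        for t in syn.simulate_trials(ref, 4, 0.0, rng=np.random.default_rng(5)):
            assert prec.precision_sd(t, ref).sd < 1e-9

    def test_reference_with_one_piece_rejected(self):
        with pytest.raises(ValueError, match="2 pieces"):
            prec.MarkerPattern(centers={"a": (0.0, 0.0)})

    def test_invalid_arguments_rejected(self):
        ref = syn.reference_patterns()[1]
        with pytest.raises(ValueError, match="n_trials"):
            syn.simulate_trials(ref, 0, 1.0)
        with pytest.raises(ValueError, match="placement_sd"):
            syn.simulate_trials(ref, 1, -1.0)
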