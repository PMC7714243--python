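"""Synthetic split-belt gait generator: waveforms, AR fluctuations, protocols."""

import numpy as np
import pytest

import gaitar as g
from gaitar import synthetic as syn
from gaitar.triangle import StationarityError


class TestSimulateAr2Series:
    def test_zero_noise_zero_memory_is_constant(self):
        x = g.simulate_ar2_series(0.0, 0.0, 10, 0.0, mean=1.1, seed=1)
        assert np.all(x == 1.1)

    def test_zero_noise_with_memory_settles_at_mean(self):
        x = g.simulate_ar2_series(0.5, 0.2, 10, 0.0, mean=2.0, seed=1)
        assert x == pytest.approx(np.full(10, 2.0), abs=1e-12)

    def test_sample_acf_matches_closed_form(self, ar2_sample):
        xc = ar2_sample - ar2_sample.mean()
        rho1 = float(xc[1:] @ xc[:-1]) / float(xc @ xc)
        assert rho1 == pytest.approx(0.5 / (1 - 0.2), abs=0.01)

    def test_nonstationary_coefficients_rejected(self):
        with pytest.raises(StationarityError):
            g.simulate_ar2_series(1.2, -0.1, 100, 1.0, seed=0)

    def test_deterministic_for_fixed_seed(self):
        a = g.simulate_ar2_series(0.5, -0.3, 500, 1.0, seed=7)
        b = g.simulate_ar2_series(0.5, -0.3, 500, 1.0, seed=7)
        assert np.array_equal(a, b)

    def test_mean_parameter_sets_process_mean(self):
        x = g.simulate_ar2_series(0.6, -0.2, 200_000, 1.0, mean=5.0, seed=3)
        assert x.mean() == pytest.approx(5.0, abs=0.05)


class TestStanceWaveform:
    def test_zero_at_stance_boundaries(self):
        assert g.stance_waveform(0.0, 1.1, 1.15, 0.75) == 0.0
        assert g.stance_waveform(1.0, 1.1, 1.15, 0.75) == 0.0

    def test_peaks_anchored_exactly(self):
        assert g.stance_waveform(0.25, 1.1, 1.15, 0.75) == pytest.approx(1.1, abs=1e-12)
        assert g.stance_waveform(0.75, 1.1, 1.15, 0.75) == pytest.approx(1.15, abs=1e-12)
        assert g.stance_waveform(0.5, 1.1, 1.15, 0.75) == pytest.approx(0.75, abs=1e-12)

    def test_dense_scan_has_two_maxima_at_requested_fractions(self):
        t = np.linspace(0, 1, 1001)
        y = g.stance_waveform(t, 1.1, 1.15, 0.75)
        interior = (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])
        maxima = t[1:-1][interior]
        assert maxima.size == 2
        assert maxima[0] == pytest.approx(0.25, abs=2e-3)
        assert maxima[1] == pytest.approx(0.75, abs=2e-3)
        minima = (y[1:-1] < y[:-2]) & (y[1:-1] < y[2:])
        between = (t[1:-1] > 0.25) & (t[1:-1] < 0.75)
        assert np.sum(minima & between) == 1

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            g.stance_waveform(0.5, 1.1, 1.15, 0.75, timing=(0.5, 0.25, 0.75))
        with pytest.raises(ValueError):
            g.stance_waveform(0.5, 0.7, 1.15, 0.75)  # peak below valley


class TestSimulationParams:
    def test_defaults_validate(self):
        p = g.SimulationParams()
        assert p.peak_model(1.5)[0] > p.peak_model(0.75)[0] >= 1.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ar_coeffs": (1.2, -0.1)},
            {"duty_factor": 1.2},
            {"sampling_rate": 60.0},
            {"timing": (0.5, 0.25, 0.75)},
            {"fluctuation_sd": -0.1},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises((ValueError, StationarityError)):
            g.SimulationParams(**kwargs)


class TestSimulateWalkingTrial:
    def test_stance_count_matches_duration_times_cadence(self, noise_free_trial):
        _, truth = noise_free_trial
        # 60 s at cadence 1.8 stances/s
        assert truth["step_index"].nunique() == 108
        assert set(truth["peak_type"]) == {"impact", "propulsive"}

    def test_noise_free_stance_maxima_equal_peak_model(self, noise_free_trial,
                                                       noise_free_params):
        rec, truth = noise_free_trial
        f = rec.force("left") / noise_free_params.body_weight
        base = noise_free_params.peak_model(1.0)[0]
        assert truth["peak_value_bw"].to_numpy() == pytest.approx(
            np.full(len(truth), base), abs=1e-12)
        # the sampled signal attains the true peak value exactly at the event times
        idx = np.round(truth["event_time"].to_numpy() * rec.sampling_rate).astype(int)
        assert f[idx] == pytest.approx(truth["peak_value_bw"].to_numpy(), abs=1e-12)

    def test_same_seed_bit_identical(self, sym_condition):
        p = g.SimulationParams()
        r1, t1 = g.simulate_walking_trial(sym_condition, p, "right", seed=5)
        r2, t2 = g.simulate_walking_trial(sym_condition, p, "right", seed=5)
        assert np.array_equal(r1.force("right"), r2.force("right"))
        assert t1.equals(t2)

    def test_forces_non_negative_with_noise(self, sym_condition):
        p = g.SimulationParams(sensor_noise_sd=5.0)
        rec, _ = g.simulate_walking_trial(sym_condition, p, "left", seed=6)
        assert rec.force("left").min() >= 0.0

    def test_duration_too_short_rejected(self, noise_free_params):
        cond = g.GaitCondition("blip", 1.0, 1.0, 2.0)
        with pytest.raises(ValueError, match="at least 5"):
            g.simulate_walking_trial(cond, noise_free_params, "left", seed=0)


class TestSimulateProtocol:
    def test_symmetric_condition_has_equal_cadence(self):
        proto = g.GaitProtocol((g.GaitCondition("sym", 1.0, 1.0, 30.0),))
        _, truth = g.simulate_protocol(proto, g.SimulationParams(), seed=1)
        counts = truth.groupby("limb")["step_index"].nunique()
        assert counts["left"] == counts["right"]

    def test_asymmetric_condition_cadences_ordered(self):
        proto = g.GaitProtocol((g.GaitCondition("asym", 0.75, 1.0, 30.0),))
        _, truth = g.simulate_protocol(proto, g.SimulationParams(), seed=1)
        counts = truth.groupby("limb")["step_index"].nunique()
        assert counts["left"] < counts["right"]

    def test_default_protocol_segments_tile_time_axis(self):
        proto = g.default_protocol()
        rec, _ = g.simulate_protocol(proto, g.SimulationParams(), seed=2)
        segs = rec.metadata["segments"]
        assert [s["label"] for s in segs] == ["sym_0.75", "sym_1.00", "sym_1.50",
                                              "asym_0.25", "asym_0.50"]
        assert segs[0]["start_s"] == 0.0
        for a, b in zip(segs, segs[1:]):
            assert a["end_s"] == pytest.approx(b["start_s"])
        assert segs[-1]["end_s"] == pytest.approx(rec.time[-1] + 1 / rec.sampling_rate)

    def test_deterministic_and_limbs_independent(self):
        proto = g.default_protocol(duration=20.0)
        p = g.SimulationParams()
        r1, _ = g.simulate_protocol(proto, p, seed=3)
        r2, _ = g.simulate_protocol(proto, p, seed=3)
        assert np.array_equal(r1.force_left, r2.force_left)
        assert np.array_equal(r1.force_right, r2.force_right)
        assert not np.array_equal(r1.force_left, r1.force_right)

    def test_override_for_unknown_condition_rejected(self):
        proto = g.default_protocol(duration=20.0)
        with pytest.raises(ValueError, match="unknown"):
            g.simulate_protocol(proto, g.SimulationParams(), seed=1,
                                condition_overrides={"nope": {}})


class TestStudySimulation:
    def test_peak_table_schema_and_determinism(self):
        design = g.StudyDesign(n_participants=2)
        t1 = g.simulate_study_peak_table(design, seed=9)
        t2 = g.simulate_study_peak_table(design, seed=9)
        assert t1.equals(t2)
        assert list(t1.columns) == ["participant", "limb", "condition", "step_index",
                                    "peak_type", "event_time_s", "value_bw"]
        assert set(t1["condition"]) == {c.label for c in design.protocol}

    def test_fast_path_matches_signal_chain_draws(self):
        """The fast path and the full signal chain share seed substreams, so
        extracted peak values agree up to filter/extraction error."""
        design = g.StudyDesign(n_participants=1)
        pid, rec, truth = next(g.simulate_study_recordings(design, seed=21))
        fast = g.simulate_study_peak_table(design, seed=21, skip_strides=0)
        merged = truth.merge(
            fast, on=["participant", "limb", "condition", "step_index", "peak_type"])
        assert len(merged) == len(truth)
        assert merged["peak_value_bw"].to_numpy() == pytest.approx(
            merged["value_bw"].to_numpy(), abs=1e-12)

    def test_participant_coefficients_stay_inside_triangle(self):
        design = g.StudyDesign(n_participants=6)
        rng = np.random.default_rng(0)
        for _ in range(50):
            for base in design.condition_coeffs.values():
                p1, p2 = syn._jittered_coeffs(base, design.coeff_jitter_sd, rng)
                assert g.is_stationary(p1, p2).inside

    def test_nonstationary_condition_truth_rejected(self):
        with pytest.raises(StationarityError):
            g.StudyDesign(condition_coeffs={**syn.DEFAULT_CONDITION_COEFFS,
                                            "sym_1.00": (1.5, 0.2)})
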