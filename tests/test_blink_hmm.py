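"""Four-state blinking HMM, blink metrics, photon conversion."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretblink import blink_hmm as bh
from fretblink import movie_analysis as ma
from fretblink import synthetic_data as sd


class TestBlinkModelInit:
    def test_transition_matrix_structure(self):
        m = bh.BlinkModel()
        t = m.init_transmat
        assert np.allclose(t.sum(axis=1), 1.0)
        assert np.array_equal(t[bh.BLEACHED], [0, 0, 0, 1])
        # bleaching transitions are 1/10 of the switching probability
        p = m.switch_prob
        assert t[sd.ON1, sd.BLEACHED] == pytest.approx(p / 10)
        assert t[sd.ON1, sd.ON2] == t[sd.ON1, sd.OFF] == p

    def test_initial_means(self):
        m = bh.BlinkModel()
        assert m.init_means.ravel().tolist() == [300.0, 300.0, 0.0, 0.0]


class TestFitAndDecode:
    def alternating_trace(self, on=300.0, n_cycles=20, run=5, noise_sd=5.0, seed=0):
        rng = np.random.default_rng(seed)
        vals = np.tile([on] * run + [0.0] * run, n_cycles)
        return ma.RoiTrace(values=vals + rng.normal(0, noise_sd, vals.size))

    def test_separable_trace_recovers_emission_means(self):
        traces = [self.alternating_trace(seed=s) for s in range(3)]
        model = bh.fit_blink_model(traces, seed=0)
        means = model.state_means
        assert means[:2] == pytest.approx([300.0, 300.0], abs=10.0)
        assert means[2:] == pytest.approx([0.0, 0.0], abs=10.0)

    def test_degenerate_traces_fall_back_to_prior(self):
        traces = [ma.RoiTrace(values=np.zeros(100))]
        with pytest.warns(UserWarning):
            model = bh.fit_blink_model(traces)
        assert model.hmm_ is not None
        assert model.state_means.tolist() == [300.0, 300.0, 0.0, 0.0]

    def test_bleached_remains_absorbing_after_training(self):
        params = sd.PhotophysicsParams(k_on=0.3, k_off=1.0, k_bleach=0.2,
                                       exposure=0.1, n_frames=500)
        noise = sd.CameraNoiseParams(read_noise_sd=40, poisson=False)
        traces = [sd.simulate_blink_trace(params, noise, seed=s)[0]
                  for s in range(20)]
        model = bh.fit_blink_model(traces, seed=0)
        assert np.array_equal(model.hmm_.transmat_[bh.BLEACHED], [0, 0, 0, 1])
        for t in traces:
            path = bh.decode(t, model)
            hit = path == bh.BLEACHED
            if hit.any():
                assert hit[np.argmax(hit):].all()  # never leaves bleached

    def test_fret_pair_means_move_off_the_prior(self):
        """Traces from a FRET pair (on-signal 180 ADU) pull the learned
        on-state means from the 300 ADU prior toward the data."""
        params = sd.PhotophysicsParams(k_on=0.3, k_off=0.5, k_bleach=0.02,
                                       brightness_on=300.0, fret_efficiency=0.4,
                                       exposure=0.1, n_frames=2000)
        noise = sd.CameraNoiseParams(read_noise_sd=30, poisson=False)
        traces = [sd.simulate_blink_trace(params, noise, seed=s)[0]
                  for s in range(30)]
        model = bh.fit_blink_model(traces, seed=0)
        assert 160.0 < model.state_means[:2].mean() < 260.0

    def test_decoding_accuracy_on_ground_truth(self):
        params = sd.PhotophysicsParams(k_on=0.2, k_off=1.0, k_bleach=0.05,
                                       brightness_on=300.0, exposure=0.1,
                                       n_frames=1000)
        noise = sd.CameraNoiseParams(read_noise_sd=50, poisson=False)  # SNR 6
        sims = [sd.simulate_blink_trace(params, noise, seed=s) for s in range(40)]
        model = bh.fit_blink_model([t for t, _ in sims], seed=0)
        agree = []
        for trace, truth in sims:
            path = bh.decode(trace, model)
            agree.append(np.mean(sd.is_on(path) == sd.is_on(truth.states)))
        assert np.mean(agree) >= 0.95


class TestBlinkMetrics:
    def test_run_arithmetic(self):
        # on x4, off x2, on x2 at 0.5 s exposure
        path = [sd.ON1] * 4 + [sd.OFF] * 2 + [sd.ON2] * 2
        rec = bh.blink_metrics(path, exposure=0.5)
        assert rec.total_on_time == pytest.approx(3.0)
        assert rec.blinks == 2
        assert rec.on_state_time == pytest.approx(1.5)
        assert rec.k_off == pytest.approx(2.0 / 3.0)
        assert rec.total_off_time == pytest.approx(1.0)
        assert rec.k_on == pytest.approx(2.0)

    def test_single_run_switching_event(self):
        path = [sd.ON1] * 10 + [sd.BLEACHED] * 10
        rec = bh.blink_metrics(path, exposure=0.5)
        assert rec.blinks == 1
        assert rec.on_state_time == pytest.approx(5.0)

    def test_trailing_off_run_excluded_from_off_time(self):
        path = [sd.ON1] * 4 + [sd.OFF] * 3 + [sd.ON1] * 2 + [sd.OFF] * 5
        rec = bh.blink_metrics(path, exposure=0.5)
        assert rec.total_off_time == pytest.approx(1.5)  # only the bridged gap

    def test_never_on_molecule_flagged(self):
        rec = bh.blink_metrics([sd.OFF] * 20, exposure=0.5)
        assert not rec.valid and rec.blinks == 0

    def test_invalid_exposure(self):
        with pytest.raises(ValueError):
            bh.blink_metrics([sd.ON1] * 3, exposure=0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([sd.ON1, sd.ON2, sd.OFF]), min_size=1,
                    max_size=80), st.integers(0, 40))
    def test_matches_run_length_encoding_oracle(self, prefix, n_bleached):
        """Metrics equal an independent itertools.groupby oracle, and
        on + off + bleached frames account for every frame."""
        path = np.array(prefix + [sd.BLEACHED] * n_bleached)
        rec = bh.blink_metrics(path, exposure=0.5)
        oracle = _rle_oracle(path, 0.5)
        assert rec.blinks == oracle["blinks"]
        assert rec.total_on_time == pytest.approx(oracle["total_on_time"])
        assert rec.total_off_time == pytest.approx(oracle["total_off_time"], nan_ok=True)
        if rec.valid:
            assert rec.on_state_time == pytest.approx(oracle["on_state_time"])
            assert rec.k_off == pytest.approx(rec.blinks / rec.total_on_time)
        n_on = np.sum(sd.is_on(path))
        n_off = np.sum(path == sd.OFF)
        n_bl = np.sum(path == sd.BLEACHED)
        assert n_on + n_off + n_bl == path.size


def _rle_oracle(path, exposure):
    labels = ["on" if s <= sd.ON2 else ("off" if s == sd.OFF else "bl")
              for s in path]
    runs = [(k, len(list(g))) for k, g in itertools.groupby(labels)]
    on_runs = [n for k, n in runs if k == "on"]
    off_frames = sum(n for k, n in runs if k == "off")
    if runs and runs[-1][0] == "off":
        off_frames -= runs[-1][1]
    return {
        "blinks": len(on_runs),
        "total_on_time": sum(on_runs) * exposure,
        "on_state_time": (np.mean(on_runs) * exposure if on_runs else np.nan),
        "total_off_time": off_frames * exposure if on_runs else np.nan,
    }


class TestPhotonConversion:
    def test_unit_signal_is_one_photon(self):
        cam = bh.CameraModel()
        assert bh.photons_from_signal(cam.g_total * cam.te, cam) == pytest.approx(1.0)

    def test_default_gain_matches_calibration(self):
        assert bh.CameraModel().g_total == pytest.approx(33.1, abs=0.05)

    def test_doubling_te_halves_photons(self):
        c1 = bh.CameraModel()
        c2 = bh.CameraModel(eta_coll=0.6)  # doubles TE
        n1 = bh.photons_from_signal(1000.0, c1)
        n2 = bh.photons_from_signal(1000.0, c2)
        assert n2 == pytest.approx(n1 / 2)

    def test_movie_photon_budget_recovery(self):
        """Total photons recovered from an extracted trace agree with the
        generator's emitted-photon ground truth within 5%."""
        cam = bh.CameraModel()
        params = sd.PhotophysicsParams(k_on=0.0, k_off=0.0, k_bleach=0.0,
                                       brightness_on=14700.0, n_frames=20)
        stack, truth = sd.simulate_movie(1, (32, 32), 1.2, params, None,
                                         min_separation=1, seed=3)
        center = tuple(np.round(truth.positions[0]).astype(int))
        trace = ma.extract_trace(stack, center)
        path = np.zeros(20, dtype=int)  # always on
        rec = bh.blink_metrics(path, 0.5, trace=trace, camera=cam)
        true_photons = truth.molecules[0].signal.sum() / (cam.g_total * cam.te)
        assert rec.total_photons == pytest.approx(true_photons, rel=0.05)

    def test_camera_validation(self):
        with pytest.raises(ValueError):
            bh.CameraModel(qe=-0.1)


class TestCohortSummary:
    def make_record(self, path=(sd.ON1, sd.ON1, sd.OFF, sd.ON1, sd.BLEACHED)):
        return bh.blink_metrics(list(path), exposure=0.5)

    def test_identical_records_zero_spread(self):
        records = [self.make_record(), self.make_record()]
        summary = bh.summarize_cohort(records)
        stats = summary["metrics"]["total_on_time"]
        assert stats["mean"] == pytest.approx(1.5)
        assert stats["sem"] == 0.0
        assert summary["n_molecules"] == 2

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            bh.summarize_cohort([])
        with pytest.raises(ValueError):
            bh.summarize_cohort([bh.blink_metrics([sd.OFF] * 5, 0.5)])

    def test_survival_curve(self):
        t, s = bh.survival_curve([1.0, 2.0, 3.0, 4.0])
        assert np.array_equal(t, [1, 2, 3, 4])
        assert np.allclose(s, [0.75, 0.5, 0.25, 0.0])

    def test_k_ratio_present(self):
        summary = bh.summarize_cohort([self.make_record() for _ in range(3)])
        assert "k_on_k_off_ratio" in summary


class TestEstimateRates:
    def test_exact_counts_on_constructed_paths(self):
        # two on->off and one off->on transition; trailing off run excluded
        path = [sd.ON1] * 4 + [sd.OFF] * 2 + [sd.ON1] * 2 + [sd.OFF] * 4
        r = bh.estimate_rates([np.array(path)], exposure=0.5)
        assert r["n_on_off_events"] == 2
        assert r["n_off_on_events"] == 1
        assert r["k_off"] == pytest.approx(2 / 3.0)
        assert r["k_on"] == pytest.approx(1 / 1.0)
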