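"""Synthetic-data generator: agents, timing, neural rendering, containers."""

import numpy as np
import pandas as pd
import pytest

from catglm.design import build_design_matrix
from catglm.session import load_session, save_session
from catglm.signals import neuropil_correct, ratio_dff
from catglm.simulate import (AgentParams, PlantedKernels,
                             simulate_behavior_session, simulate_fluorescence,
                             simulate_neural_session)


class TestAgentBehavior:
    def test_perfect_agent_is_always_correct(self, full_grid_space):
        agent = AgentParams(45.0, lapse_rate=0.0, steepness=np.inf)
        trials = simulate_behavior_session(full_grid_space, agent, 300, seed=1)
        assert trials["correct"].all()

    def test_half_lapse_zero_steepness_is_chance(self, full_grid_space):
        agent = AgentParams(45.0, lapse_rate=0.5, steepness=1e-9)
        trials = simulate_behavior_session(full_grid_space, agent, 20000, seed=2)
        fc = trials[trials["response_made"]]["correct"].mean()
        assert fc == pytest.approx(0.5, abs=0.02)

    def test_event_times_strictly_ordered_within_trials(self, trials):
        resp = trials[trials["response_made"]]
        assert (resp["stimulus_onset"] < resp["stimulus_offset"]).all()
        assert (resp["stimulus_offset"] < resp["response_window_start"]).all()
        assert (resp["response_window_start"] < resp["response_lick_time"]).all()
        rewarded = resp.dropna(subset=["reward_time"])
        assert (rewarded["reward_time"] >= rewarded["response_lick_time"]).all()
        assert (trials["stimulus_onset"].diff().dropna() > 0).all()

    def test_misses_have_no_response_events(self, reduced_space):
        agent = AgentParams(23.0, steepness=3.0, miss_probability=0.4)
        trials = simulate_behavior_session(reduced_space, agent, 300, seed=3)
        misses = trials[~trials["response_made"]]
        assert len(misses) > 0
        assert misses[["choice_lick_time", "response_lick_time",
                       "reward_time", "timeout_time"]].isna().all().all()
        assert (misses["choice"] == "miss").all()

    def test_empty_active_set_errors(self, reduced_space):
        space = reduced_space
        crippled = space.stimulus_grid.copy()
        crippled["active"] = False
        import dataclasses
        empty = dataclasses.replace(space, stimulus_grid=crippled)
        with pytest.raises(ValueError):
            simulate_behavior_session(empty, AgentParams(), 10, seed=0)

    def test_seeded_determinism(self, reduced_space, agent):
        a = simulate_behavior_session(reduced_space, agent, 50, seed=42)
        b = simulate_behavior_session(reduced_space, agent, 50, seed=42)
        pd.testing.assert_frame_equal(a, b)


class TestNeuralSession:
    def test_zero_kernels_zero_noise_give_zero_activity(self, trials):
        kernels = PlantedKernels([{("offset", ""): np.array([0.0])}])
        ses = simulate_neural_session(trials, kernels, 15.0, noise_sd=0.0,
                                      trial_gain_cv=0.0, seed=1)
        assert np.all(ses.activity == 0)

    def test_offset_only_neuron_is_constant(self, trials):
        kernels = PlantedKernels([{("offset", ""): np.array([0.7])}])
        ses = simulate_neural_session(trials, kernels, 15.0, noise_sd=0.0,
                                      trial_gain_cv=0.0, seed=1)
        np.testing.assert_allclose(ses.activity, 0.7)

    def test_category_kernel_gives_identical_within_category_means(
            self, noiseless_session):
        """A category-only neuron responds equally to all stimuli of one
        category (by construction)."""
        ses = noiseless_session
        tr = ses.trials
        fr = ses.frame_rate_hz
        means = {}
        # window covering the full kernel support so sub-frame onset
        # phase cannot shift mass across the window edge
        win = np.arange(int(-2 * fr), int(5.5 * fr))
        for (ori, sf), grp in tr.groupby(["ori_index", "sf_index"]):
            onsets = np.round(grp["stimulus_onset"].to_numpy() * fr).astype(int)
            means[(ori, sf, grp["category"].iloc[0])] = ses.activity[0][
                onsets[:, None] + win[None, :]].mean()
        for side in ("left", "right"):
            vals = [v for (o, s, c), v in means.items() if c == side]
            # +-3 sigma kernel truncation leaves a ~1e-6 phase-dependent
            # residual in the frame-sampled mass
            np.testing.assert_allclose(vals, vals[0], rtol=1e-5)

    def test_noiseless_activity_equals_design_times_weights(self, noiseless_session):
        ses = noiseless_session
        gt = ses.meta["ground_truth"]
        design = build_design_matrix(ses.trials, ses.covariates, ses.n_frames,
                                     ses.frame_rate_hz)
        recon = gt["weights"] @ design.X.T
        assert np.abs(recon - ses.activity).max() < 1e-9

    def test_seeded_determinism_bytewise(self, trials, planted_kernels):
        a = simulate_neural_session(trials, planted_kernels, 15.0, seed=99)
        b = simulate_neural_session(trials, planted_kernels, 15.0, seed=99)
        assert a.activity.tobytes() == b.activity.tobytes()
        for k in a.covariates:
            assert a.covariates[k].tobytes() == b.covariates[k].tobytes()

    def test_negative_kernel_weights_rejected(self, trials):
        kernels = PlantedKernels([{("offset", ""): np.array([-1.0])}])
        with pytest.raises(ValueError):
            simulate_neural_session(trials, kernels, 15.0, seed=0)

    def test_wrong_kernel_length_rejected(self, trials):
        kernels = PlantedKernels([
            {("offset", ""): np.array([0.1]),
             ("category", "left"): np.ones(3)}  # category has 7 offsets
        ])
        with pytest.raises(ValueError, match="offsets"):
            simulate_neural_session(trials, kernels, 15.0, seed=0)


class TestFluorescence:
    def test_zero_contamination_no_drift_is_pure_convolution(self, noiseless_session):
        fluo = simulate_fluorescence(noiseless_session, contamination=0.0,
                                     drift_amplitude=0.0, seed=1)
        # structural channel flat; signal = baseline + convolved spikes
        assert np.ptp(fluo.structural[0]) == 0
        assert fluo.signal.shape == noiseless_session.activity.shape

    def test_ratio_dff_cancels_shared_drift(self, noiseless_session):
        """dR/R of a drifting simulation matches the undrifted one."""
        kw = dict(contamination=0.0, seed=2)
        still = simulate_fluorescence(noiseless_session, drift_amplitude=0.0, **kw)
        drifting = simulate_fluorescence(noiseless_session, drift_amplitude=0.3, **kw)
        fr = noiseless_session.frame_rate_hz
        d0 = ratio_dff(still.signal[0], still.structural[0], fr)
        d1 = ratio_dff(drifting.signal[0], drifting.structural[0], fr)
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_neuropil_correction_recovers_uncontaminated_trace(self, noiseless_session):
        clean = simulate_fluorescence(noiseless_session, contamination=0.0,
                                      drift_amplitude=0.0, seed=3)
        dirty = simulate_fluorescence(noiseless_session, contamination=0.7,
                                      drift_amplitude=0.0, seed=3)
        corrected = neuropil_correct(dirty.signal[0], dirty.neuropil[0], 0.7)
        residual = corrected - clean.signal[0]
        assert np.ptp(residual) < 1e-9  # equal up to the median offset


class TestSessionContainer:
    def test_hdf5_round_trip_preserves_everything(self, session, tmp_path):
        path = tmp_path / "session.h5"
        save_session(session, path)
        back = load_session(path)
        np.testing.assert_array_equal(back.activity, session.activity)
        assert back.frame_rate_hz == session.frame_rate_hz
        for k, v in session.covariates.items():
            np.testing.assert_array_equal(back.covariates[k], v)
        pd.testing.assert_frame_equal(
            back.trials, session.trials, check_dtype=False)
        gt, gt_back = session.meta["ground_truth"], back.meta["ground_truth"]
        np.testing.assert_array_equal(gt_back["weights"], gt["weights"])
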