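"""Ground-truthed generators: determinism, closed-form peaks, ensemble stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tbslice import cfos_counting
from tbslice.synthetic_data import (CalciumSimParams, CfosImageParams,
                                    MepscSimParams, SpineSimParams,
                                    PlacementError, render_traceset_movie,
                                    simulate_calcium_traceset,
                                    simulate_cfos_stack, simulate_mepsc_trace,
                                    simulate_spine_trajectory_set,
                                    spine_innovation_correlation)


class TestCalciumGenerator:
    def test_silent_noiseless_trace_is_flat_baseline(self):
        p = CalciumSimParams(n_units=2, duration=10, spike_rate=0.0,
                             noise_sd=0.0, drift_amplitude=0.0, seed=0)
        ts, truth = simulate_calcium_traceset(p)
        assert np.allclose(ts.traces, p.baseline)
        assert all(len(t) == 0 for t in truth)

    def test_single_forced_spike_peak_matches_kernel(self):
        p = CalciumSimParams(n_units=1, duration=20, noise_sd=0.0,
                             drift_amplitude=0.0, seed=0)
        ts, _ = simulate_calcium_traceset(p, forced_spikes=[[5.0]])
        peak = ts.traces[0].max()
        # frame sampling can miss the exact kernel peak by < one frame
        expected = p.baseline * (1 + p.transient_amplitude)
        assert peak <= expected + 1e-9
        assert peak >= p.baseline * (1 + 0.9 * p.transient_amplitude)

    def test_same_seed_bit_identical(self):
        p = CalciumSimParams(n_units=3, duration=30, seed=7)
        a, ta = simulate_calcium_traceset(p)
        b, tb = simulate_calcium_traceset(p)
        assert np.array_equal(a.traces, b.traces)
        assert all(np.array_equal(x, y) for x, y in zip(ta, tb))

    def test_stimulated_group_scales_rate(self):
        p = CalciumSimParams(n_units=1, duration=10, seed=0)
        ts, _ = simulate_calcium_traceset(p, group="stimulated")
        assert ts.meta["spike_rate"] == pytest.approx(
            p.spike_rate * p.group_rate_multiplier)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), noise=st.floats(0.0, 0.2))
    def test_traces_strictly_positive_at_moderate_noise(self, seed, noise):
        p = CalciumSimParams(n_units=2, duration=20, noise_sd=noise, seed=seed)
        ts, _ = simulate_calcium_traceset(p)
        assert np.all(ts.traces > 0)

    def test_movie_roundtrip_preserves_traces(self):
        from tbslice.calcium_pipeline import extract_label_traces
        p = CalciumSimParams(n_units=5, duration=10, seed=3)
        ts, _ = simulate_calcium_traceset(p)
        frames, mask = render_traceset_movie(ts)
        back = extract_label_traces(frames, mask, ts.frame_rate)
        assert np.allclose(back.traces, ts.traces, rtol=1e-12)


class TestSpineGenerator:
    def test_frozen_dynamics_give_constant_trajectories(self):
        p = SpineSimParams(n_segments=2, spines_per_segment=16,
                           fluctuation_sd=0.0, reversion_rate=0.0,
                           stim_effect_small=0.0, seed=0)
        ts, _ = simulate_spine_trajectory_set(p)
        wide = ts.sizes.pivot_table(index=["segment_id", "spine_id"],
                                    columns="time_label", values="size_au")
        assert np.allclose(wide.to_numpy(), wide.to_numpy()[:, :1])

    def test_correlation_matrix_is_psd_and_anchored(self):
        C = spine_innovation_correlation(20, 0.5, -0.2, 4.0)
        assert np.linalg.eigvalsh(C).min() >= -1e-9
        assert C[0, 1] == pytest.approx(0.5)
        assert C[0, -1] == pytest.approx(-0.2)
        assert np.allclose(np.diag(C), 1.0)

    def test_non_psd_parameters_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            SpineSimParams(spines_per_segment=20, spatial_corr_near=0.5,
                           spatial_corr_far=-0.5, corr_length=2.0)

    def test_adjacent_innovation_correlation_recovered(self):
        """Empirical correlation of adjacent-spine log-size innovations
        matches spatial_corr_near over a large ensemble (Monte-Carlo)."""
        near = 0.6
        p = SpineSimParams(n_segments=200, spines_per_segment=16,
                           spatial_corr_near=near, spatial_corr_far=-0.1,
                           reversion_rate=0.0, stim_effect_small=0.0, seed=9)
        ts, _ = simulate_spine_trajectory_set(p)
        rs = []
        for seg in ts.segment_ids():
            mat = np.log(ts.pivot_segment(seg).to_numpy())
            innov = np.diff(mat, axis=1)
            for i in range(mat.shape[0] - 1):
                rs.append(np.corrcoef(innov[i], innov[i + 1])[0, 1])
        assert np.mean(rs) == pytest.approx(near, abs=0.05)

    def test_stim_enlarges_smallest_tercile_vs_control(self):
        p = SpineSimParams(n_segments=40, seed=21, stim_effect_small=0.3)
        ctrl, t_c = simulate_spine_trajectory_set(p, "control")
        stim, t_s = simulate_spine_trajectory_set(p, "stimulated")

        def small_delta(ts, truth):
            wide = ts.sizes.pivot_table(index=["segment_id", "spine_id"],
                                        columns="time_label", values="size_au")
            delta = (wide["+24h"] - wide["day4"]) / wide["day4"]
            small = truth.set_index(["segment_id", "spine_id"])["tercile"] == 0
            return delta[small.reindex(delta.index)].mean()

        assert small_delta(stim, t_s) > small_delta(ctrl, t_c)

    def test_truth_labels_cover_all_spines(self, spine_set_control):
        ts, truth = spine_set_control
        assert len(truth) == 20 * 20
        assert set(truth["tercile"]) == {0, 1, 2}
        assert (truth["condition"] == "control").all()


class TestMepscGenerator:
    def test_rate_zero_gives_noise_only_trace(self):
        p = MepscSimParams(duration=5, event_rate=0.0, seed=0)
        trace, truth = simulate_mepsc_trace(p)
        assert len(truth) == 0
        assert abs(trace.mean()) < 1.0

    def test_poisson_event_count_mean(self):
        """Mean truth count over replicates within 3 s.e. of rate*duration."""
        lam_t, n_rep = 120.0, 500
        counts = [len(simulate_mepsc_trace(
            MepscSimParams(duration=120, event_rate=1.0, sampling_rate=1000,
                           seed=s))[1]) for s in range(n_rep)]
        se = np.sqrt(lam_t / n_rep)
        assert np.mean(counts) == pytest.approx(lam_t, abs=3 * se)

    def test_noise_free_event_minimum_matches_amplitude(self):
        p = MepscSimParams(duration=2, noise_sd=0.0, seed=0)
        trace, _ = simulate_mepsc_trace(p, forced_events=[(1.0, 30.0)])
        # discrete sampling may miss the continuous kernel peak slightly
        assert trace.min() == pytest.approx(-30.0, rel=0.02)

    def test_same_seed_bit_identical(self):
        p = MepscSimParams(duration=5, seed=11)
        a, ta = simulate_mepsc_trace(p)
        b, tb = simulate_mepsc_trace(p)
        assert np.array_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)


class TestCfosGenerator:
    def test_zero_cells_zero_truth(self):
        p = CfosImageParams(n_cells=0, seed=0)
        cfos, dapi, truth = simulate_cfos_stack(p)
        assert truth["n_qualifying"] == 0
        assert cfos.shape == (p.n_planes, *p.image_shape)

    def test_all_qualifying_discs_counted_in_truth(self):
        p = CfosImageParams(n_cells=50, image_shape=(512, 512),
                            radius_range=(5.0, 8.0),
                            eccentricity_range=(0.0, 0.3), seed=1)
        _, _, truth = simulate_cfos_stack(p)
        assert truth["n_qualifying"] == 50

    def test_undersized_blob_excluded_from_truth(self):
        """One blob below the area minimum among 20 drops the truth count."""
        p = CfosImageParams(n_cells=20, radius_range=(5.0, 8.0),
                            eccentricity_range=(0.0, 0.3), seed=2)
        _, _, base = simulate_cfos_stack(p)
        assert base["n_qualifying"] == 20
        # re-render with one tiny blob appended (area ~ pi*2^2 < 30 px^2)
        specs = [(30.0 + 45 * (i // 5), 30.0 + 45 * (i % 5), 6.0, 6.0, 0.0)
                 for i in range(19)]
        specs.append((225.0, 225.0, 2.0, 2.0, 0.0))
        _, _, truth = simulate_cfos_stack(
            CfosImageParams(n_cells=20, seed=2), blob_specs=specs)
        small = truth["blobs"].iloc[-1]
        assert small["area"] < cfos_counting.DEFAULT_SIZE_RANGE[0]
        assert truth["n_qualifying"] == 19

    def test_impossible_placement_raises(self):
        with pytest.raises(PlacementError):
            simulate_cfos_stack(CfosImageParams(
                n_cells=500, image_shape=(64, 64), radius_range=(8.0, 10.0),
                seed=0), max_tries=300)

    def test_same_seed_bit_identical(self):
        p = CfosImageParams(n_cells=10, seed=3, background_noise_sd=2.0)
        a = simulate_cfos_stack(p)
        b = simulate_cfos_stack(p)
        assert np.array_equal(a[0], b[0])
        assert a[2]["n_qualifying"] == b[2]["n_qualifying"]
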