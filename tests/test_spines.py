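"""Spine-trajectory analyses: normalization, binning, classification,
correlation matrices and the diagonal-averaged unit matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tbslice.protocol import DEFAULT_SCHEDULE
from tbslice.spine_dynamics import (CorrelationMatrix, SpineTrajectorySet,
                                    classify_spines, correlation_matrix,
                                    delta_size_binned, mean_unit_matrix,
                                    near_far_summary, normalize_to_baseline,
                                    transition_table, unit_matrix,
                                    unit_matrix_variance)
from tbslice.synthetic_data import SpineSimParams, simulate_spine_trajectory_set

LABELS = DEFAULT_SCHEDULE.labels


def _set_from_wide(values_by_spine, segment_id="seg0"):
    """Build a SpineTrajectorySet from {spine_id: [11 sizes]}."""
    rows = []
    for sp, vals in values_by_spine.items():
        for lab, v in zip(LABELS, vals):
            rows.append((segment_id, sp, lab, float(v)))
    return SpineTrajectorySet(pd.DataFrame(
        rows, columns=["segment_id", "spine_id", "time_label", "size_au"]))


def brute_force_unit_matrix(c: np.ndarray, k: int) -> np.ndarray:
    """Window-average oracle: explicit loop over all diagonal windows."""
    n = c.shape[0]
    acc = np.zeros((k, k))
    cnt = np.zeros((k, k))
    for s in range(n - k + 1):
        for i in range(k):
            for j in range(k):
                v = c[s + i, s + j]
                if not np.isnan(v):
                    acc[i, j] += v
                    cnt[i, j] += 1
    with np.errstate(invalid="ignore"):
        return acc / cnt


class TestNormalization:
    def test_baseline_becomes_one(self, spine_set_control):
        ts, _ = spine_set_control
        norm = normalize_to_baseline(ts)
        base = norm.sizes[norm.sizes["time_label"] == "day4"]
        assert np.allclose(base["size_au"], 1.0)

    def test_constant_trajectory_all_ones(self):
        ts = _set_from_wide({0: [3.0] * 11})
        norm = normalize_to_baseline(ts)
        assert np.allclose(norm.sizes["size_au"], 1.0)

    def test_simple_arithmetic(self):
        vals = [2.0] * 11
        vals[LABELS.index("+24h")] = 4.0
        norm = normalize_to_baseline(_set_from_wide({0: vals}))
        wide = norm.sizes.set_index("time_label")["size_au"]
        assert wide["day4"] == 1.0
        assert wide["+24h"] == 2.0

    def test_density_normalized_per_segment(self, spine_set_control):
        ts, _ = spine_set_control
        norm = normalize_to_baseline(ts)
        base = norm.density[norm.density["time_label"] == "day4"]
        assert np.allclose(base["spines_per_um"], 1.0)


class TestDeltaBinned:
    def test_no_change_gives_zero_means(self):
        ts = _set_from_wide({i: [1.0 + 0.1 * i] * 11 for i in range(10)})
        out = delta_size_binned(ts, "+24h")
        assert np.allclose(out["mean_delta"].dropna(), 0.0)

    def test_single_spine_occupies_one_bin(self):
        ts = _set_from_wide({0: [2.0] * 11})
        out = delta_size_binned(ts, "+2h", bin_edges=[0, 1, 3, 10])
        assert out["n"].tolist() == [0, 1, 0]

    def test_size_dependent_drift_sign_pattern(self):
        """Mean reversion makes small spines grow and large spines shrink."""
        p = SpineSimParams(n_segments=100, seed=3)
        ts, _ = simulate_spine_trajectory_set(p)
        out = delta_size_binned(ts, "+24h")
        assert out["mean_delta"].iloc[0] > 0 > out["mean_delta"].iloc[-1]

    def test_rejects_baseline_label(self):
        ts = _set_from_wide({0: [1.0] * 11})
        with pytest.raises(ValueError):
            delta_size_binned(ts, "day4")


class TestClassification:
    def test_basic_rules(self):
        vals_up = [1.0] * 11
        vals_up[-1] = 1.2
        vals_tie = [1.0] * 11
        ts = _set_from_wide({0: vals_up, 1: vals_tie})
        lab = classify_spines(ts, "day4", "+24h")
        assert lab[("seg0", 0)] == "enlarged"
        assert lab[("seg0", 1)] == "shrunk"  # ties are conservative

    def test_stimulated_small_spines_mostly_enlarged(self):
        p = SpineSimParams(n_segments=30, seed=14, stim_effect_small=0.3)
        ts, truth = simulate_spine_trajectory_set(p, "stimulated")
        lab = classify_spines(ts, "day4", "+24h")
        small = truth[truth["tercile"] == 0].set_index(
            ["segment_id", "spine_id"]).index
        frac = (lab.loc[small] == "enlarged").mean()
        assert frac > 0.5

    def test_transition_table_hand_fixture(self):
        """Six spines with hand-enumerated early/late paths."""
        early = pd.Series(["enlarged", "enlarged", "shrunk", "shrunk",
                           "shrunk", "enlarged"],
                          index=pd.MultiIndex.from_product([["s"], range(6)]),
                          name="label")
        late = pd.Series(["enlarged", "shrunk", "enlarged", "enlarged",
                          "shrunk", "enlarged"], index=early.index)
        counts, props = transition_table(early, late)
        assert counts.loc["enlarged", "enlarged"] == 2
        assert counts.loc["enlarged", "shrunk"] == 1
        assert counts.loc["shrunk", "enlarged"] == 2
        assert counts.loc["shrunk", "shrunk"] == 1
        assert counts.to_numpy().sum() == 6
        assert props.loc["shrunk", "enlarged"] == pytest.approx(2 / 3)

    def test_single_path_single_cell(self):
        idx = pd.MultiIndex.from_product([["s"], range(4)])
        e = pd.Series(["shrunk"] * 4, index=idx)
        l = pd.Series(["enlarged"] * 4, index=idx)
        counts, _ = transition_table(e, l)
        assert counts.loc["shrunk", "enlarged"] == 4
        assert counts.to_numpy().sum() == 4


class TestCorrelationMatrix:
    def test_identical_trajectories_fully_correlated(self):
        base = np.linspace(1, 2, 11)
        ts = _set_from_wide({i: base * (i + 1) for i in range(3)})
        r = correlation_matrix(ts, "seg0").values
        assert np.allclose(r, 1.0)

    def test_negated_trajectory_anticorrelated(self):
        up = np.linspace(1, 2, 11)
        down = 3.0 - up  # mirrored around the mean
        ts = _set_from_wide({0: up, 1: down})
        r = correlation_matrix(ts, "seg0").values
        assert r[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_three_spine_fixture(self):
        """24 h window restricted to 3 distinct points; frozen Pearson values
        computed by hand from centered vectors (-1,0,1),(−1,0,1)x2,(1,-1,0)."""
        def traj(window_vals):
            vals = [1.0] * 11
            for lab, v in zip(("day4", "+1h", "+2h"), window_vals):
                vals[LABELS.index(lab)] = v
            return vals
        ts = _set_from_wide({0: traj((1, 2, 3)), 1: traj((2, 4, 6)),
                             2: traj((3, 1, 2))})
        r = correlation_matrix(ts, "seg0", labels=("day4", "+1h", "+2h")).values
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-0.5)
        assert r[1, 2] == pytest.approx(-0.5)

    def test_constant_series_flagged_nan(self):
        ts = _set_from_wide({0: [1.0] * 11, 1: list(np.linspace(1, 2, 11))})
        r = correlation_matrix(ts, "seg0").values
        assert np.isnan(r[0, 1])
        assert r[0, 0] == 1.0


class TestUnitMatrix:
    def test_n_equals_k_is_identity_operation(self, rng):
        c = np.corrcoef(rng.normal(size=(15, 8)))
        u = unit_matrix(c, k=15)
        assert np.allclose(u.values, c)
        assert np.all(u.support == 1)

    def test_constant_offdiagonal_analytic_case(self):
        c = np.full((40, 40), 0.3)
        np.fill_diagonal(c, 1.0)
        u = unit_matrix(c, k=15)
        expect = np.full((15, 15), 0.3)
        np.fill_diagonal(expect, 1.0)
        assert np.allclose(u.values, expect, atol=1e-12)
        assert np.all(u.support == 40 - 15 + 1)

    @settings(max_examples=15, deadline=None)
    @given(n=st.integers(20, 60), seed=st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        c = np.corrcoef(rng.normal(size=(n, 9)))
        u = unit_matrix(c, k=15)
        assert np.allclose(u.values, brute_force_unit_matrix(c, 15), atol=1e-12)

    def test_output_side_is_15_by_default(self, rng):
        for n in (15, 23, 58):
            c = np.corrcoef(rng.normal(size=(n, 6)))
            assert unit_matrix(c).values.shape == (15, 15)

    def test_symmetry_preserved(self, rng):
        c = np.corrcoef(rng.normal(size=(30, 7)))
        u = unit_matrix(c, k=15).values
        assert np.allclose(u, u.T, atol=1e-12)

    def test_small_segment_rejected(self, rng):
        c = np.corrcoef(rng.normal(size=(10, 6)))
        with pytest.raises(ValueError, match="side 10"):
            unit_matrix(c, k=15)

    def test_nan_entries_excluded_with_support(self):
        c = np.full((16, 16), 0.5)
        np.fill_diagonal(c, 1.0)
        c[0, 5] = c[5, 0] = np.nan
        u = unit_matrix(c, k=15)
        assert u.support[0, 5] == 1  # only the second window contributes
        assert u.values[0, 5] == pytest.approx(0.5)


class TestVarianceMap:
    def test_identical_matrices_zero_variance(self, rng):
        c = np.corrcoef(rng.normal(size=(20, 6)))
        u = unit_matrix(c, k=15)
        assert np.allclose(unit_matrix_variance([u, u, u]), 0.0)

    def test_two_matrix_hand_variance(self):
        a = unit_matrix(np.eye(15), k=15)
        b = unit_matrix(np.full((15, 15), 1.0), k=15)
        v = unit_matrix_variance([a, b])
        # sample variance of {0, 1} is 0.5; of {1, 1} on the diagonal is 0
        off = ~np.eye(15, dtype=bool)
        assert np.allclose(v[off], 0.5)
        assert np.allclose(np.diag(v), 0.0)

    def test_single_matrix_rejected(self):
        u = unit_matrix(np.eye(15), k=15)
        with pytest.raises(ValueError):
            unit_matrix_variance([u])


class TestEnsembleStructure:
    def test_near_positive_far_negative_control_structure(self):
        p = SpineSimParams(n_segments=60, seed=17)
        ts, _ = simulate_spine_trajectory_set(p, "control")
        mats = [unit_matrix(correlation_matrix(ts, s)) for s in ts.segment_ids()]
        near, far = near_far_summary(mean_unit_matrix(mats))
        assert near > 0 > far
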