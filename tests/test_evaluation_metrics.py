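"""Dice, field MSE, torus lacunae extraction, EMD, rollout evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from pottsnet import (
    LacunaeAreaSet,
    ModelParams,
    TwoChannelFrame,
    dice,
    divergence_diagnostics,
    emd,
    evaluate_rollout,
    field_mse,
    lacunae_areas,
    simulate,
    torus_region_areas,
)
from pottsnet.dataset_builder import frames_from_run
from pottsnet.evaluation_metrics import _emd_or_nan


class TestDice:
    def test_identical_nonempty_masks(self):
        m = np.zeros((8, 8), np.uint8)
        m[2:5, 2:5] = 1
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8), np.uint8)
        b = np.zeros((8, 8), np.uint8)
        a[0, 0] = 1
        b[4, 4] = 1
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((8, 8), np.uint8)
        b = np.zeros((8, 8), np.uint8)
        a[0, 0:4] = 1
        b[0, 2:6] = 1
        assert dice(a, b) == pytest.approx(0.5)  # 2*2 / (4+4)

    def test_both_empty_defined_as_one(self):
        assert dice(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0

    def test_probability_masks_thresholded_at_half(self):
        a = np.full((4, 4), 0.9)
        b = np.ones((4, 4))
        assert dice(a, b) == 1.0

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.random((10, 10)) > 0.5
            b = rng.random((10, 10)) > 0.5
            d = dice(a, b)
            assert d == dice(b, a)
            assert 0.0 <= d <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((4, 4)), np.zeros((5, 5)))


class TestFieldMse:
    def test_identical_fields(self):
        f = np.random.default_rng(0).random((8, 8))
        assert field_mse(f, f) == 0.0

    def test_uniform_offset(self):
        f = np.random.default_rng(1).random((8, 8))
        assert field_mse(f, f + 0.1) == pytest.approx(0.01, abs=1e-12)

    def test_matches_two_loop_reference(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((6, 6)), rng.random((6, 6))
        ref = sum(
            (a[i, j] - b[i, j]) ** 2 for i in range(6) for j in range(6)
        ) / 36
        assert field_mse(a, b) == pytest.approx(ref, abs=1e-12)


def _torus_oracle(mask):
    """Union-find over wraparound 4-adjacency of medium sites (brute force)."""
    H, W = mask.shape
    parent = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i in range(H):
        for j in range(W):
            if mask[i, j] == 0:
                parent[(i, j)] = (i, j)
    for i in range(H):
        for j in range(W):
            if mask[i, j] != 0:
                continue
            for di, dj in ((0, 1), (1, 0)):
                ni, nj = (i + di) % H, (j + dj) % W
                if mask[ni, nj] == 0:
                    union((i, j), (ni, nj))
    from collections import Counter

    counts = Counter(find(site) for site in parent)
    return sorted(counts.values())


class TestLacunaeAreas:
    def test_all_medium_mask_is_one_torus_spanning_region(self):
        mask = np.zeros((12, 12), np.uint8)
        assert lacunae_areas(mask).areas == [144]

    def test_tiny_holes_filtered_as_potts_noise(self):
        mask = np.ones((10, 10), np.uint8)
        mask[3, 3] = 0
        mask[3, 4] = 0  # 2-site hole: below the 3-site floor
        assert lacunae_areas(mask).areas == []

    def test_hole_straddling_periodic_boundary_counted_once(self):
        mask = np.ones((10, 10), np.uint8)
        mask[0, 4:6] = 0
        mask[-1, 4:6] = 0  # 4-site hole wrapping the row seam
        assert lacunae_areas(mask).areas == [4]

    def test_congruent_distinct_lacunae_both_kept(self):
        mask = np.ones((12, 12), np.uint8)
        mask[2, 2:5] = 0
        mask[8, 6:9] = 0  # identical 1x3 shape elsewhere
        assert lacunae_areas(mask).areas == [3, 3]
        # the published signature rule cannot tell congruent twins apart
        assert lacunae_areas(mask, dedup="signature").areas == [3]

    def test_agrees_with_bruteforce_torus_oracle_on_random_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            size = int(rng.integers(8, 20))
            mask = (rng.random((size, size)) < rng.uniform(0.4, 0.8)).astype(np.uint8)
            expected = [a for a in _torus_oracle(mask) if a >= 3]
            assert lacunae_areas(mask).areas == sorted(expected)
            assert torus_region_areas(mask) == _torus_oracle(mask)

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError):
            lacunae_areas(np.full((4, 4), 2))


def _emd_cdf_oracle(a, b):
    """W1 via the area between empirical CDFs (independent closed form)."""
    grid = np.sort(np.unique(np.concatenate([a, b])))
    total = 0.0
    for lo, hi in zip(grid[:-1], grid[1:]):
        fa = np.mean(np.asarray(a) <= lo)
        fb = np.mean(np.asarray(b) <= lo)
        total += abs(fa - fb) * (hi - lo)
    return total


class TestEmd:
    def test_identical_multisets(self):
        s = LacunaeAreaSet([5, 9, 20])
        assert emd(s, s) == 0.0

    def test_singletons_reduce_to_absolute_difference(self):
        assert emd(LacunaeAreaSet([10]), LacunaeAreaSet([25])) == 15.0

    def test_translation_invariance_of_differences(self):
        a = [4, 9, 13]
        b = [6, 6, 30, 44]
        shift = 17
        assert emd(LacunaeAreaSet(a), LacunaeAreaSet(b)) == pytest.approx(
            emd(LacunaeAreaSet([x + shift for x in a]),
                LacunaeAreaSet([x + shift for x in b]))
        )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        a=st.lists(st.integers(3, 60), min_size=1, max_size=5),
        b=st.lists(st.integers(3, 60), min_size=1, max_size=5),
    )
    def test_matches_cdf_transport_oracle(self, a, b):
        assert emd(LacunaeAreaSet(a), LacunaeAreaSet(b)) == pytest.approx(
            _emd_cdf_oracle(a, b), abs=1e-9
        )

    def test_metric_properties_spot_checked(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = LacunaeAreaSet(sorted(rng.integers(3, 50, 4).tolist()))
            b = LacunaeAreaSet(sorted(rng.integers(3, 50, 3).tolist()))
            c = LacunaeAreaSet(sorted(rng.integers(3, 50, 5).tolist()))
            assert emd(a, b) == pytest.approx(emd(b, a))
            assert emd(a, c) <= emd(a, b) + emd(b, c) + 1e-9
        assert emd(LacunaeAreaSet([7, 7]), LacunaeAreaSet([7, 7])) == 0.0

    def test_empty_set_conventions(self):
        assert emd(LacunaeAreaSet([]), LacunaeAreaSet([])) == 0.0
        with pytest.raises(ValueError):
            emd(LacunaeAreaSet([]), LacunaeAreaSet([5]))


def _frame(mask, field, mcs=0):
    return TwoChannelFrame(mask=mask, field=field.astype(np.float32), mcs=mcs)


class TestDivergenceDiagnostics:
    def test_truth_against_itself_gives_identical_curves(self):
        rng = np.random.default_rng(0)
        frames = [
            _frame((rng.random((8, 8)) > 0.5).astype(np.uint8), rng.random((8, 8)))
            for _ in range(4)
        ]
        df = divergence_diagnostics(frames, frames, normalization=2.0)
        assert (df["vessel_area_pred"] == df["vessel_area_truth"]).all()
        assert np.allclose(df["field_sum_pred"], df["field_sum_truth"])

    def test_hand_counted_toy(self):
        mask = np.zeros((8, 8), np.uint8)
        mask[0, :10 % 8] = 1
        mask[1, 0:8] = 1  # 2 + 8 = 10 sites
        f = _frame(mask, np.full((8, 8), 0.5))
        df = divergence_diagnostics([f], [f], normalization=4.0)
        assert df.loc[0, "vessel_area_pred"] == 10
        assert df.loc[0, "field_sum_pred"] == pytest.approx(0.5 * 64 * 4.0)

    def test_empty_frame_has_zero_vessel_area(self):
        f = _frame(np.zeros((8, 8), np.uint8), np.zeros((8, 8)))
        df = divergence_diagnostics([f], [f])
        assert df.loc[0, "vessel_area_pred"] == 0

    def test_misaligned_series_rejected(self):
        f = _frame(np.zeros((8, 8), np.uint8), np.zeros((8, 8)))
        with pytest.raises(ValueError):
            divergence_diagnostics([f, f], [f])


def _eval_run(seed=0, n_snapshots=4):
    params = ModelParams(lattice_size=16, n_cells_initial=3, D=0.5,
                         secretion_rate=0.3, pde_substeps=4)
    return simulate(params, seed, mcs_start_save=100,
                    mcs_end=100 + 100 * (n_snapshots - 1), save_every=100)


class TestEvaluateRollout:
    def test_perfect_oracle_model_scores_perfectly(self):
        run = _eval_run()
        frames = frames_from_run(run)
        by_mcs = {f.mcs: f for f in frames}

        def oracle(frame):
            truth = by_mcs[frame.mcs + 100]
            return TwoChannelFrame(truth.mask.astype(np.float64) * 0.98 + 0.01,
                                   truth.field, truth.mcs, truth.sim_id)

        report = evaluate_rollout(oracle, [run], t0_mcs=100, n_iterations=3)
        assert np.allclose(report.per_step["dice_pred"], 1.0)
        assert report.per_step["mse_pred"].max() < 1e-9

    def test_identity_model_reproduces_reference_baseline(self):
        run = _eval_run(seed=1)

        def identity(frame):
            return TwoChannelFrame(frame.mask, frame.field, frame.mcs + 100,
                                   frame.sim_id)

        report = evaluate_rollout(identity, [run], t0_mcs=100, n_iterations=3)
        df = report.per_step
        assert np.allclose(df["dice_pred"], df["dice_ref"])
        assert np.allclose(df["mse_pred"], df["mse_ref"])
        pred = df["emd_pred"].to_numpy()
        ref = df["emd_ref"].to_numpy()
        both = ~(np.isnan(pred) | np.isnan(ref))
        assert np.allclose(pred[both], ref[both])

    def test_one_row_per_iteration_per_run(self):
        run = _eval_run(seed=2)

        def identity(frame):
            return TwoChannelFrame(frame.mask, frame.field, frame.mcs + 100,
                                   frame.sim_id)

        report = evaluate_rollout(identity, [run], t0_mcs=100, n_iterations=3)
        assert len(report.per_step) == 3
        with_zero = evaluate_rollout(identity, [run], t0_mcs=100, n_iterations=3,
                                     include_step0=True)
        row0 = with_zero.per_step[with_zero.per_step["step"] == 0].iloc[0]
        assert row0["dice_ref"] == 1.0
        assert row0["mse_ref"] == 0.0
        assert row0["emd_ref"] == 0.0 or np.isnan(row0["emd_ref"])

    def test_missing_ground_truth_raises(self):
        run = _eval_run(seed=3, n_snapshots=2)

        def identity(frame):
            return frame

        with pytest.raises(KeyError):
            evaluate_rollout(identity, [run], t0_mcs=100, n_iterations=5)


def test_reference_dice_decays_with_lag_on_simulator_output():
    """The frozen reference decorrelates (weakly but monotonically in
    expectation) as the network evolves: Spearman rho of Dice vs lag < 0."""
    params = ModelParams(lattice_size=64, n_cells_initial=62)
    run = simulate(params, 17, mcs_start_save=200, mcs_end=1800, save_every=40)
    base = run.masks[0]
    lags, dices = [], []
    for i in range(1, len(run)):
        lags.append(int(run.mcs_values[i] - run.mcs_values[0]))
        dices.append(dice(base, run.masks[i]))
    rho = spearmanr(lags, dices).statistic
    assert rho < 0
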