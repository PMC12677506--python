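"""Alignment, error metrics, summaries and the error-vs-ratio regression."""

import itertools

import numpy as np
import pandas as pd
import pytest

import t1relax as tr
from t1relax.evaluation import evaluate_voxel, records_to_frame


def _brute_force_alignment_cost(est, truth):
    """Independent oracle: enumerate assignments with explicit loops."""
    J = len(truth)
    best = np.inf
    for perm in itertools.permutations(range(J)):
        cost = 0.0
        for k in range(J):
            tt1, ta = truth.t1_ms[k], truth.amplitudes[k]
            et1 = est.t1_ms[perm[k]]
            if ta == 0 or np.isnan(tt1):
                continue
            cost += 1.0 if np.isnan(et1) else abs(et1 - tt1) / tt1
        best = min(best, cost)
    return best


class TestAlignComponents:
    def test_swapped_estimate_is_reordered(self):
        truth = tr.ComponentSet([1.0, 1.0], [641.0, 2733.0])
        est = tr.ComponentSet([1.0, 1.0], [650.0, 2700.0])
        perm, cost = tr.align_components(est, truth)
        # canonical sorting puts 650 first; pairing must match 641<->650
        assert truth.t1_ms[perm.index(0)] == 641.0
        assert cost == pytest.approx(abs(650 - 641) / 641 + abs(2700 - 2733) / 2733)

    def test_perfect_estimate_has_zero_cost(self):
        truth = tr.ComponentSet([1.0, 2.0], [641.0, 2733.0])
        perm, cost = tr.align_components(truth, truth)
        assert perm == (0, 1)
        assert cost == 0.0

    def test_degenerate_truth_breaks_ties_lexicographically(self):
        truth = tr.ComponentSet([1.0, 1.0], [1000.0, 1000.0])
        est = tr.ComponentSet([1.0, 1.0], [800.0, 1200.0])
        perm, _ = tr.align_components(est, truth)
        assert perm == (0, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tr.align_components(
                tr.ComponentSet([1.0], [700.0]),
                tr.ComponentSet([1.0, 1.0], [641.0, 2733.0]),
            )

    @pytest.mark.parametrize("J", [2, 3, 4])
    def test_matches_brute_force_on_random_instances(self, J):
        rng = np.random.default_rng(100 + J)
        for _ in range(70):
            truth = tr.ComponentSet(rng.uniform(0.1, 2, J), rng.uniform(100, 4000, J))
            est = tr.ComponentSet(rng.uniform(0.1, 2, J), rng.uniform(100, 4000, J))
            _, cost = tr.align_components(est, truth)
            assert cost == pytest.approx(_brute_force_alignment_cost(est, truth))


class TestErrorMetrics:
    @pytest.mark.parametrize(
        "est, truth, expected",
        [(800.0, 1000.0, 20.0), (1000.0, 1000.0, 0.0), (2733.0, 641.0, 100 * 2092 / 641)],
    )
    def test_relative_error(self, est, truth, expected):
        assert tr.relative_error_pct(est, truth) == pytest.approx(expected)

    def test_zero_truth_redirects_to_max_mean_error(self):
        with pytest.raises(ValueError, match="max_mean_error"):
            tr.relative_error_pct(1.0, 0.0)

    @pytest.mark.parametrize(
        "est, truth, amps, expected",
        [
            (0.3, 0.0, [1.0, 0.0], 30.0),
            (1.0, 1.0, [1.0, 0.0], 0.0),
            (1.0, 0.0, [2.0, 1.0, 0.0], 50.0),
        ],
    )
    def test_max_mean_error(self, est, truth, amps, expected):
        assert tr.max_mean_error_pct(est, truth, amps) == pytest.approx(expected)

    def test_all_zero_truth_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            tr.max_mean_error_pct(1.0, 0.0, [0.0, 0.0])


class TestAugmentZeroComponent:
    def test_appends_zero_amplitude_slot(self):
        truth = tr.ComponentSet([1.0, 1.0], [641.0, 2733.0])
        out = tr.augment_zero_component(truth, 3)
        assert len(out) == 3
        assert out.amplitudes[-1] == 0.0 and np.isnan(out.t1_ms[-1])

    def test_equal_size_is_identity(self):
        truth = tr.ComponentSet([1.0], [641.0])
        assert tr.augment_zero_component(truth, 1) is truth

    def test_shrinking_rejected(self):
        truth = tr.ComponentSet([1.0, 1.0], [641.0, 2733.0])
        with pytest.raises(ValueError):
            tr.augment_zero_component(truth, 1)

    def test_perfect_estimator_with_padding_has_zero_errors(self):
        truth = tr.ComponentSet([1.0, 1.0], [641.0, 2733.0])
        rec = evaluate_voxel(
            truth,
            truth,
            combination_id="Comb-3",
            voxel_index=0,
            method="mul",
            dataset_t1_ratio=4.26,
            expected_J=3,
        )
        assert all(e == 0.0 for e in rec.rel_err_t1_pct)
        assert all(e == 0.0 for e in rec.rel_err_a_pct)

    def test_under_reported_component_scores_full_error(self):
        truth = tr.ComponentSet([1.0, 1.0], [641.0, 2733.0])
        est = tr.ComponentSet([2.0], [650.0])
        rec = evaluate_voxel(
            est,
            truth,
            combination_id="Comb-3",
            voxel_index=0,
            method="ilt",
            dataset_t1_ratio=4.26,
        )
        assert rec.n_est_components == 1
        assert sorted(rec.rel_err_t1_pct)[-1] == pytest.approx(100.0)


class TestSummaries:
    def _records(self):
        truth2 = tr.ComponentSet([1.0, 1.0], [641.0, 2733.0])
        truth3 = tr.ComponentSet([1.0, 1.0, 1.0], [641.0, 1039.0, 2733.0])
        recs = []
        for v, est_t1 in enumerate([(650, 2700), (700, 2500), (600, 2900)]):
            recs.append(
                evaluate_voxel(
                    tr.ComponentSet([1.0, 1.0], est_t1),
                    truth2,
                    combination_id="Comb-3",
                    voxel_index=v,
                    method="mul",
                    dataset_t1_ratio=4.26,
                )
            )
        for v, est_t1 in enumerate([(640, 1000, 2700), (660, 1100, 2600)]):
            recs.append(
                evaluate_voxel(
                    tr.ComponentSet([1.0, 1.0, 1.0], est_t1),
                    truth3,
                    combination_id="Comb-8",
                    voxel_index=v,
                    method="mul",
                    dataset_t1_ratio=2.13,
                )
            )
        return recs

    def test_group_means_match_hand_grouping(self):
        recs = self._records()
        tables = tr.summarize(recs)
        df = tables["errors_by_components"].set_index("n_true_components")
        by_hand = {
            2: np.mean([np.mean(r.rel_err_t1_pct) for r in recs[:3]]),
            3: np.mean([np.mean(r.rel_err_t1_pct) for r in recs[3:]]),
        }
        assert df.loc[2, "mean_rel_err_t1_pct"] == pytest.approx(by_hand[2])
        assert df.loc[3, "mean_rel_err_t1_pct"] == pytest.approx(by_hand[3])
        assert df.loc[2, "n_voxels"] == 3 and df.loc[3, "n_voxels"] == 2

    def test_single_record_mean(self):
        rec = self._records()[0]
        table = tr.summarize([rec])["errors_by_components"]
        assert table["mean_rel_err_t1_pct"][0] == pytest.approx(np.mean(rec.rel_err_t1_pct))

    def test_mean_error_invariant_to_voxel_order(self):
        recs = self._records()
        a = tr.summarize(recs)["errors_by_components"]
        b = tr.summarize(recs[::-1])["errors_by_components"]
        pd.testing.assert_frame_equal(
            a.sort_values("n_true_components").reset_index(drop=True),
            b.sort_values("n_true_components").reset_index(drop=True),
        )

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            tr.summarize([])


class TestRegression:
    def _record(self, method, ratio, err, voxel=0):
        truth = tr.ComponentSet([1.0, 1.0], [1000.0, 1000.0 * ratio])
        est_t1 = (1000.0 * (1 + err / 100.0), 1000.0 * ratio * (1 + err / 100.0))
        return evaluate_voxel(
            tr.ComponentSet([1.0, 1.0], est_t1),
            truth,
            combination_id=f"r{ratio}",
            voxel_index=voxel,
            method=method,
            dataset_t1_ratio=ratio,
        )

    def test_exact_line_recovered(self):
        recs = [self._record("mul", r, 30.0 - 5.0 * r) for r in (1.5, 2.0, 3.0, 4.0)]
        summ = tr.error_vs_ratio_regression(recs)["mul"]
        assert summ.slope_pct_per_ratio == pytest.approx(-5.0, abs=1e-6)
        assert summ.r_squared == pytest.approx(1.0)

    def test_pure_noise_has_flat_slope(self):
        rng = np.random.default_rng(8)
        recs = [
            self._record("mul", r, 20.0 + rng.normal(0, 0.5), voxel=v)
            for r in (1.5, 2.0, 2.5, 3.0, 4.0)
            for v in range(20)
        ]
        summ = tr.error_vs_ratio_regression(recs)["mul"]
        assert abs(summ.slope_pct_per_ratio) < 0.5
        assert summ.r_squared < 0.1

    def test_matches_normal_equations_on_hand_points(self):
        ratios = [1.5, 2.0, 2.5, 3.0, 3.5, 4.0]
        errs = [32.0, 28.0, 27.0, 22.0, 19.0, 15.0]
        recs = [self._record("ilt", r, e) for r, e in zip(ratios, errs)]
        summ = tr.error_vs_ratio_regression(recs)["ilt"]
        x = np.asarray(ratios)
        y = np.asarray(errs)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert summ.slope_pct_per_ratio == pytest.approx(slope)
        assert summ.intercept == pytest.approx(intercept)
        assert summ.n == 6

    def test_single_ratio_design_rejected(self):
        recs = [self._record("mul", 2.0, 10.0, voxel=v) for v in range(5)]
        with pytest.raises(ValueError):
            tr.error_vs_ratio_regression(recs)

    def test_component_order_invariance_of_record_errors(self):
        truth = tr.ComponentSet([1.0, 1.0], [641.0, 2733.0])
        a = evaluate_voxel(
            tr.ComponentSet([1.0, 1.0], [2700.0, 650.0]), truth,
            combination_id="c", voxel_index=0, method="mul", dataset_t1_ratio=4.26,
        )
        b = evaluate_voxel(
            tr.ComponentSet([1.0, 1.0], [650.0, 2700.0]), truth,
            combination_id="c", voxel_index=0, method="mul", dataset_t1_ratio=4.26,
        )
        assert sorted(a.rel_err_t1_pct) == sorted(b.rel_err_t1_pct)
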