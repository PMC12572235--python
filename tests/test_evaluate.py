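"""Performance statistics: correlation, mixed model, hit-ratio ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dbswin.evaluate import (
    cumulative_hit_ratio,
    importance_report,
    lme_performance,
    pearson_performance,
    permutation_null,
    rank_contacts,
)


def _preds(rows):
    return pd.DataFrame(rows, columns=["patient_id", "side", "contact_id", "y_pred"])


class TestPearson:
    def test_identity_and_negation(self, rng):
        y = rng.standard_normal(30)
        assert pearson_performance(y, y)[0] == pytest.approx(1.0)
        assert pearson_performance(y, -y)[0] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        y_true = np.array([0.34, 0.85, -0.34, 0.25])
        y_pred = np.array([1.0, 3.0, -2.0, 0.5])  # rank-preserving transform
        r, _ = pearson_performance(y_true, y_pred)
        a, b = y_true - y_true.mean(), y_pred - y_pred.mean()
        expected = (a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum())
        assert r == pytest.approx(expected)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_performance([1, 2], [1, 2])
        with pytest.raises(ValueError, match="zero variance"):
            pearson_performance([1, 1, 1], [1, 2, 3])


class TestMixedModel:
    def test_perfect_prediction_unit_slope(self, rng):
        y = rng.standard_normal(40)
        elec = np.repeat(np.arange(8), 5)
        perf = lme_performance(y, y, elec)
        assert perf.beta == pytest.approx(1.0, abs=1e-6)
        assert perf.beta_ci[0] <= perf.beta <= perf.beta_ci[1]

    def test_no_electrode_effect_matches_ols(self, rng):
        x = rng.standard_normal(60)
        y = 0.5 * x + 0.3 * rng.standard_normal(60)  # shared intercept only
        elec = np.repeat(np.arange(10), 6)
        perf = lme_performance(y, x, elec)
        ols_slope = np.polyfit(x, y, 1)[0]
        assert perf.beta == pytest.approx(ols_slope, abs=0.02)

    def test_null_coverage(self, rng):
        # independent predictions: the Wald CI should cover 0 at ~95%
        cover = 0
        reps = 60
        for _ in range(reps):
            y = rng.standard_normal(40)
            x = rng.standard_normal(40)
            elec = np.repeat(np.arange(8), 5)
            perf = lme_performance(y, x, elec)
            cover += perf.beta_ci[0] <= 0 <= perf.beta_ci[1]
        assert cover / reps >= 0.85

    def test_needs_repeated_measures(self):
        with pytest.raises(ValueError):
            lme_performance([1, 2, 3], [1, 2, 3], ["a", "b", "c"])


class TestRanking:
    def test_orders_by_predicted_window(self):
        preds = _preds([("P0", "right", 1, 0.2), ("P0", "right", 2, 0.9),
                        ("P0", "right", 3, 0.5)])
        assert rank_contacts(preds)[("P0", "right")] == [2, 3, 1]

    def test_all_equal_tie_rule(self):
        preds = _preds([("P0", "left", c, 0.5) for c in (3, 1, 2)])
        assert rank_contacts(preds)[("P0", "left")] == [1, 2, 3]

    def test_matches_oracle_sort(self, rng):
        vals = rng.standard_normal(10)
        preds = _preds([("P0", "right", c + 1, v) for c, v in enumerate(vals)])
        oracle = [c for _, c in sorted(
            zip(vals, range(1, 11)), key=lambda t: (-t[0], t[1])
        )]
        assert rank_contacts(preds)[("P0", "right")] == oracle


class TestHitRatio:
    def test_all_first_is_flat_one(self):
        rankings = {("P0", "r"): [1, 2, 3, 4], ("P1", "r"): [2, 1, 3, 4]}
        optimal = {("P0", "r"): 1, ("P1", "r"): 2}
        curve = cumulative_hit_ratio(rankings, optimal)
        np.testing.assert_array_equal(curve.observed, np.ones(4))

    def test_two_electrode_count(self):
        rankings = {("P0", "r"): [1, 2, 3, 4], ("P1", "r"): [1, 2, 3, 4]}
        optimal = {("P0", "r"): 2, ("P1", "r"): 4}  # positions 2 and 4
        curve = cumulative_hit_ratio(rankings, optimal)
        np.testing.assert_allclose(curve.observed, [0, 0.5, 0.5, 1.0])

    def test_min_contacts_excludes_short_electrodes(self):
        rankings = {("P0", "r"): [1, 2, 3], ("P1", "r"): [1, 2, 3, 4, 5]}
        optimal = {("P0", "r"): 1, ("P1", "r"): 5}
        curve = cumulative_hit_ratio(rankings, optimal, min_contacts=4)
        assert curve.n_electrodes == 1

    def test_shorter_electrode_counts_as_hit_beyond_depth(self):
        rankings = {("P0", "r"): [1, 2, 3, 4], ("P1", "r"): [1, 2, 3, 4, 5, 6]}
        optimal = {("P0", "r"): 4, ("P1", "r"): 6}
        curve = cumulative_hit_ratio(rankings, optimal)
        # at rank 5: P0 already exhausted (hit), P1's optimal at position 6
        assert curve.observed[4] == pytest.approx(0.5)
        assert curve.observed[-1] == 1.0

    def test_monotone_and_terminates_at_one(self, rng):
        rankings, optimal = {}, {}
        for e in range(10):
            k = int(rng.integers(4, 9))
            order = list(rng.permutation(np.arange(1, k + 1)))
            rankings[("P%d" % e, "r")] = order
            optimal[("P%d" % e, "r")] = int(rng.choice(order))
        curve = cumulative_hit_ratio(rankings, optimal)
        assert np.all(np.diff(curve.observed) >= 0)
        assert curve.observed[-1] == 1.0

    def test_matches_bruteforce_recount(self, rng):
        rankings, optimal = {}, {}
        for e in range(10):
            order = list(rng.permutation(np.arange(1, 7)))
            rankings[("P%d" % e, "r")] = order
            optimal[("P%d" % e, "r")] = int(rng.choice(order))
        curve = cumulative_hit_ratio(rankings, optimal)
        for i in curve.ranks:
            hits = sum(
                1 for e in rankings
                if rankings[e].index(optimal[e]) + 1 <= i
            )
            assert curve.observed[i - 1] == pytest.approx(hits / 10)

    def test_absent_optimal_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            cumulative_hit_ratio({("P0", "r"): [1, 2, 3, 4]}, {("P0", "r"): 9})


class TestPermutationNull:
    def _uniform_case(self, n_elec=12, k=4):
        rankings = {("P%d" % e, "r"): list(range(1, k + 1))
                    for e in range(n_elec)}
        optimal = {e: 1 for e in rankings}
        return rankings, optimal

    def test_rank1_null_mean_is_one_over_k(self):
        rankings, optimal = self._uniform_case()
        curve = permutation_null(rankings, optimal, n_perm=10_000, seed=0)
        se = curve.null_sd[0] / np.sqrt(curve.n_permutations)
        assert abs(curve.null_mean[0] - 0.25) <= 3 * se

    def test_rank_k_null_certainty(self):
        rankings, optimal = self._uniform_case()
        curve = permutation_null(rankings, optimal, n_perm=2_000, seed=0)
        assert curve.null_mean[-1] == 1.0
        assert curve.null_sd[-1] == 0.0

    def test_mixed_contact_counts_vs_enumeration(self):
        # 4 electrodes, K in {4,8}: null mean at rank 1 = mean of 1/K,
        # verified against exhaustive enumeration over optimal positions
        ks = [4, 4, 8, 8]
        rankings = {("P%d" % i, "r"): list(range(1, k + 1))
                    for i, k in enumerate(ks)}
        optimal = {e: 1 for e in rankings}
        exact = np.mean([
            np.mean([pos == 1 for pos in range(1, k + 1)]) for k in ks
        ])
        enum = np.mean([
            np.mean([p <= 1 for p in pos])
            for pos in itertools.product(*[range(1, k + 1) for k in ks])
        ])
        assert exact == pytest.approx(enum)
        curve = permutation_null(rankings, optimal, n_perm=20_000, seed=1)
        se = curve.null_sd[0] / np.sqrt(curve.n_permutations)
        assert abs(curve.null_mean[0] - exact) <= 3 * se

    def test_invariant_to_contact_relabeling(self):
        rankings, optimal = self._uniform_case(n_elec=6)
        relabeled = {e: [c + 10 for c in order] for e, order in rankings.items()}
        opt2 = {e: optimal[e] + 10 for e in optimal}
        a = permutation_null(rankings, optimal, n_perm=3_000, seed=9)
        b = permutation_null(relabeled, opt2, n_perm=3_000, seed=9)
        np.testing.assert_array_equal(a.null_mean, b.null_mean)
        np.testing.assert_array_equal(a.null_p95, b.null_p95)

    def test_oracle_predictor_beats_null_early(self, rng):
        # predictions equal to the true windows: the observed curve should
        # clear the null 95th percentile at the first ranks (47 electrodes)
        rankings, optimal = {}, {}
        for e in range(47):
            k = 8
            true = rng.standard_normal(k)
            order = [c for _, c in sorted(
                zip(true, range(1, k + 1)), key=lambda t: (-t[0], t[1])
            )]
            rankings[("P%d" % e, "r")] = order
            optimal[("P%d" % e, "r")] = order[0]
        curve = permutation_null(rankings, optimal, n_perm=5_000, seed=2)
        assert curve.significant[0] and curve.significant[1]


class TestImportance:
    def test_single_parcel_lobe_passthrough(self):
        freq = pd.Series({"coh_solo_L_alpha": 0.6})
        table = importance_report(freq, parcel_lobes={"solo_L": "islet"})
        assert table.loc["islet", "alpha"] == pytest.approx(0.6)

    def test_lobe_normalization_by_area_count(self):
        lobes = {f"p{i}_L": "big" for i in range(4)}
        freq = pd.Series({f"coh_p{i}_L_beta": v
                          for i, v in enumerate([1.0, 0.0, 0.0, 0.0])})
        table = importance_report(freq, parcel_lobes=lobes)
        assert table.loc["big", "beta"] == pytest.approx(0.25)

    def test_stn_is_own_group(self):
        freq = pd.Series({"stn_hfo": 0.9})
        table = importance_report(freq)
        assert table.loc["stn", "hfo"] == pytest.approx(0.9)

    def test_matches_independent_recomputation(self, rng):
        from dbswin.connectivity import PARCEL_LOBES, PARCELS

        cols = [f"coh_{p}_theta" for p in PARCELS] + ["stn_theta"]
        freq = pd.Series(rng.uniform(0, 1, len(cols)), index=cols)
        table = importance_report(freq)
        # oracle: loop-based recount
        sizes = {}
        for p, lobe in PARCEL_LOBES.items():
            sizes[lobe] = sizes.get(lobe, 0) + 1
        for lobe in set(PARCEL_LOBES.values()):
            expected = sum(
                freq[f"coh_{p}_theta"] for p in PARCELS
                if PARCEL_LOBES[p] == lobe
            ) / sizes[lobe]
            assert table.loc[lobe, "theta"] == pytest.approx(expected)

    def test_unknown_parcel_rejected(self):
        with pytest.raises(ValueError):
            importance_report(
                pd.Series({"coh_mystery_L_alpha": 1.0}),
                parcel_lobes={"other_L": "x"},
            )
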