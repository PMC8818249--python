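"""Kappa statistics, interpretation bands, paired tests, and the simulator."""

import warnings

import numpy as np
import pytest
from statsmodels.stats.inter_rater import cohens_kappa as sm_cohen
from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

from shouldersim import (
    RatingTable,
    cohen_kappa,
    compare_modalities,
    fleiss_kappa,
    interpret_kappa,
    simulate_ratings,
)
from shouldersim.errors import ParameterError, SampleSizeError, ValidationError


def brute_force_kappa(a, b, k):
    """Independent dumb-loop evaluation of Cohen's kappa."""
    n = len(a)
    po = sum(1 for x, y in zip(a, b) if x == y) / n
    pe = 0.0
    for c in range(k):
        pe += (sum(1 for x in a if x == c) / n) * (sum(1 for y in b if y == c) / n)
    if abs(1.0 - pe) < 1e-15:
        return 1.0
    return (po - pe) / (1.0 - pe)


class TestCohenKappa:
    def test_identical_columns_give_one(self):
        t = RatingTable.from_arrays([1, 2, 3, 1, 2], [1, 2, 3, 1, 2])
        assert cohen_kappa(t, n_boot=0).estimate == pytest.approx(1.0)

    def test_closed_form_two_by_two(self):
        perfect = RatingTable.from_arrays([1] * 10 + [0] * 10, [1] * 10 + [0] * 10)
        assert cohen_kappa(perfect, n_boot=0).estimate == pytest.approx(1.0)
        # 5 items in each contingency cell: observed = chance agreement
        a = [1] * 5 + [1] * 5 + [0] * 5 + [0] * 5
        b = [1] * 5 + [0] * 5 + [1] * 5 + [0] * 5
        none = RatingTable.from_arrays(a, b)
        assert cohen_kappa(none, n_boot=0).estimate == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.integers(0, 4, 30)
            b = rng.integers(0, 4, 30)
            t = RatingTable.from_arrays(a, b, scale=[0, 1, 2, 3])
            est = cohen_kappa(t, n_boot=0).estimate
            assert est == pytest.approx(brute_force_kappa(a, b, 4), abs=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(11)
        a = rng.integers(1, 5, 200)
        b = np.where(rng.random(200) < 0.6, a, rng.integers(1, 5, 200))
        t = RatingTable.from_arrays(a, b, scale=[1, 2, 3, 4])
        ct = np.zeros((4, 4))
        for i, j in zip(a, b):
            ct[i - 1, j - 1] += 1
        assert cohen_kappa(t, n_boot=0).estimate == pytest.approx(
            float(sm_cohen(ct, return_results=False)), abs=1e-12
        )

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(13)
        a = rng.integers(0, 4, 100)
        b = rng.integers(0, 4, 100)
        t = RatingTable.from_arrays(a, b, scale=[0, 1, 2, 3])
        perm = np.array([2, 0, 3, 1])
        t2 = RatingTable.from_arrays(perm[a], perm[b], scale=[0, 1, 2, 3])
        assert cohen_kappa(t2, n_boot=0).estimate == pytest.approx(
            cohen_kappa(t, n_boot=0).estimate, abs=1e-12
        )

    def test_degenerate_constant_table(self):
        t = RatingTable(np.ones((5, 2)), list(range(5)), ["a", "b"], [1, 2])
        with pytest.warns(UserWarning, match="degenerate"):
            res = cohen_kappa(t, n_boot=50, seed=0)
        assert res.estimate == 1.0

    def test_missing_ratings_dropped_with_warning(self):
        arr = np.array([[1, 1], [2, 2], [np.nan, 1], [3, 3], [1, 2]])
        t = RatingTable(arr, list(range(5)), ["a", "b"], [1, 2, 3])
        with pytest.warns(UserWarning, match="missing"):
            res = cohen_kappa(t, n_boot=0)
        assert res.n_items == 4

    def test_bootstrap_ci_is_seeded_and_brackets_estimate(self):
        t = simulate_ratings(300, 3, agreement=0.6, seed=5)
        r1 = cohen_kappa(t, n_boot=500, seed=9)
        r2 = cohen_kappa(t, n_boot=500, seed=9)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.estimate <= r1.ci_high
        assert -1.0 <= r1.ci_low and r1.ci_high <= 1.0

    def test_three_raters_rejected(self):
        t = RatingTable(np.ones((4, 3)) * [[1], [2], [1], [2]], list(range(4)), ["a", "b", "c"], [1, 2])
        with pytest.raises(ValidationError, match="2 raters"):
            cohen_kappa(t)


class TestFleissKappa:
    def test_unanimous_raters_give_one(self):
        arr = np.array([[1, 1, 1], [2, 2, 2], [1, 1, 1], [3, 3, 3]], dtype=float)
        t = RatingTable(arr, list(range(4)), ["a", "b", "c"], [1, 2, 3])
        assert fleiss_kappa(t, n_boot=0).estimate == pytest.approx(1.0)

    def test_random_ratings_near_zero(self):
        rng = np.random.default_rng(17)
        arr = rng.integers(1, 4, (1000, 3)).astype(float)
        t = RatingTable(arr, list(range(1000)), ["a", "b", "c"], [1, 2, 3])
        assert abs(fleiss_kappa(t, n_boot=0).estimate) < 0.05

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(19)
        arr = rng.integers(1, 5, (60, 4)).astype(float)
        t = RatingTable(arr, list(range(60)), list("abcd"), [1, 2, 3, 4])
        counts = np.zeros((60, 4))
        for j in range(4):
            counts[:, j] = (arr == j + 1).sum(axis=1)
        assert fleiss_kappa(t, n_boot=0).estimate == pytest.approx(float(sm_fleiss(counts)), abs=1e-12)

    def test_near_cohen_for_balanced_two_rater_tables(self):
        t = simulate_ratings(500, 3, agreement=0.5, seed=23)
        f = fleiss_kappa(t, n_boot=0).estimate
        c = cohen_kappa(t, n_boot=0).estimate
        assert f == pytest.approx(c, abs=0.02)


class TestInterpretation:
    @pytest.mark.parametrize(
        "k,label",
        [
            (-0.3, "poor"), (0.0, "poor"), (0.1, "slight"), (0.2, "slight"),
            (0.3, "fair"), (0.4, "fair"), (0.45, "moderate"), (0.6, "moderate"),
            (0.69, "substantial"), (0.8, "substantial"), (0.81, "perfect"), (1.0, "perfect"),
        ],
    )
    def test_bands(self, k, label):
        assert interpret_kappa(k) == label

    def test_total_monotone_step_function(self):
        order = ["poor", "slight", "fair", "moderate", "substantial", "perfect"]
        labels = [interpret_kappa(k) for k in np.linspace(-1, 1, 401)]
        ranks = [order.index(l) for l in labels]
        assert all(b >= a for a, b in zip(ranks, ranks[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            interpret_kappa(1.5)


class TestCompareModalities:
    def test_identical_numeric_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning, match="zero"):
            res = compare_modalities(x, x.copy(), "numeric")
        assert res.p_value == 1.0

    def test_numeric_detects_shift(self):
        rng = np.random.default_rng(29)
        x = rng.normal(0, 1, 50)
        res = compare_modalities(x, x + 2.0, "numeric")
        assert res.test == "paired-t"
        assert res.p_value < 1e-6

    def test_mcnemar_balanced_discordance(self):
        # 12 discordant pairs each way: statistic (|b-c|)^2/(b+c) = 0
        x = np.array([1] * 12 + [0] * 12 + [1] * 5 + [0] * 5)
        y = np.array([0] * 12 + [1] * 12 + [1] * 5 + [0] * 5)
        res = compare_modalities(x, y, "binary")
        assert res.test == "mcnemar"
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_wilcoxon_symmetric_differences(self):
        base = np.arange(1, 21, dtype=float)
        shift = np.array([d for d in range(1, 11)] + [-d for d in range(1, 11)], dtype=float)
        res = compare_modalities(base, base + shift, "ordinal")
        assert res.test == "wilcoxon"
        assert res.p_value > 0.9

    def test_short_sample_rejected(self):
        with pytest.raises(SampleSizeError):
            compare_modalities([1.0], [2.0], "numeric")


class TestSimulator:
    def test_full_agreement_gives_kappa_one(self):
        t = simulate_ratings(200, 4, agreement=1.0, seed=31)
        assert cohen_kappa(t, n_boot=0).estimate == pytest.approx(1.0)

    def test_independence_gives_kappa_near_zero(self):
        t = simulate_ratings(2000, 3, agreement=0.0, seed=37)
        est = cohen_kappa(t, n_boot=0).estimate
        assert abs(est) < 3 / np.sqrt(2000)  # within ~3 SE of zero

    def test_invalid_marginal_rejected(self):
        with pytest.raises(ParameterError):
            simulate_ratings(100, 3, marginal=[0.5, 0.2], agreement=0.5)


class TestRatingTableIO:
    def test_csv_round_trip(self, tmp_path):
        t = simulate_ratings(20, 3, agreement=0.7, seed=41)
        p = tmp_path / "r.csv"
        t.to_csv(p)
        back = RatingTable.from_csv(p)
        np.testing.assert_array_equal(back.ratings, t.ratings)
        assert back.scale == t.scale
        assert cohen_kappa(back, n_boot=0).estimate == cohen_kappa(t, n_boot=0).estimate

    def test_out_of_scale_rating_rejected(self):
        with pytest.raises(ValidationError, match="scale"):
            RatingTable(np.array([[1, 5], [2, 2]]), [1, 2], ["a", "b"], [1, 2, 3])
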