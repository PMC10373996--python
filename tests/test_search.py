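"""Search machinery: integer-trimmed regression, LOOCV, combination enumeration,
and oracle equivalence of the exhaustive search against a naive reimplementation."""

import itertools

import numpy as np
import pytest

from tofhla_shortform import (
    QualityGoal,
    ScoreVector,
    ShortFormSearch,
    enumerate_combinations,
    fit_integer_mlr,
    loocv_evaluate,
    performance_curve,
)
from tofhla_shortform.grouping import ItemSet, group_items
from tofhla_shortform.items import ResponseMatrix
from tofhla_shortform.search import (
    SearchError,
    press_loocv_predictions,
    round_half_away,
)

from conftest import make_bank, random_responses


# ---------------------------------------------------------------------------
# integer-trimmed least squares


class TestIntegerFit:
    def test_exact_integer_model_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, (30, 2)).astype(float)
        while len(np.unique(X, axis=0)) < 3:  # ensure identifiable design
            X = rng.integers(0, 2, (30, 2)).astype(float)
        y = 23 + 7 * X[:, 0] + 2 * X[:, 1]
        fit = fit_integer_mlr(X, y)
        assert fit.trimmed_intercept == 23
        assert fit.trimmed_coefficients.tolist() == [7, 2]
        trained = fit.trimmed_intercept + X @ fit.trimmed_coefficients
        assert np.sqrt(np.mean((trained - y) ** 2)) == 0

    def test_constant_target_gives_zero_weights(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, (25, 3)).astype(float)
        y = np.full(25, 41.3)
        fit = fit_integer_mlr(X, y)
        assert fit.trimmed_coefficients.tolist() == [0, 0, 0]
        assert fit.trimmed_intercept == 41  # round(mean)

    def test_subhalf_noise_trims_back_to_integers(self):
        """Brute-force check of the rounding rule: per-coefficient perturbations
        below 0.5 are removed by trimming."""
        rng = np.random.default_rng(3)
        true = np.array([5.0, -3.0, 2.0])
        for trial in range(20):
            noisy = true + rng.uniform(-0.49, 0.49, size=3)
            assert round_half_away(noisy).tolist() == true.tolist()

    def test_round_half_away_from_zero(self):
        assert round_half_away(np.array([0.5, -0.5, 2.5, -2.5, 0.49])).tolist() == [
            1, -1, 3, -3, 0]

    def test_too_few_observations_rejected(self):
        with pytest.raises(SearchError, match="n > p"):
            fit_integer_mlr(np.ones((3, 3)), np.ones(3))

    def test_float_fit_never_worse_in_sample(self):
        """Least-squares optimality: the float fit's in-sample RMSE is a lower
        bound for the trimmed-integer model's."""
        rng = np.random.default_rng(4)
        for trial in range(10):
            X = rng.integers(0, 2, (40, 4)).astype(float)
            y = rng.normal(50, 15, 40)
            fit = fit_integer_mlr(X, y)
            float_pred = fit.intercept + X @ fit.coefficients
            int_pred = fit.trimmed_intercept + X @ fit.trimmed_coefficients
            assert np.mean((float_pred - y) ** 2) <= np.mean((int_pred - y) ** 2) + 1e-9


class TestLOOCV:
    def test_noiseless_model_scores_perfectly(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 2, (30, 2)).astype(float)
        y = 10 + 4 * X[:, 0] + 6 * X[:, 1]
        cv = loocv_evaluate(X, y)
        assert cv.rmse == 0
        assert cv.pearson_r == pytest.approx(1.0)
        assert cv.trimmed_intercept == 10
        assert cv.trimmed_coefficients.tolist() == [4, 6]

    def test_independent_target_has_near_zero_r(self):
        # permutation null: float-fit LOO predictions correlate with an
        # independent target well inside the 99.9% band ~ 3.29/sqrt(n)
        rng = np.random.default_rng(6)
        X = rng.integers(0, 2, (200, 2)).astype(float)
        y = rng.normal(70, 15, 200)
        press = press_loocv_predictions(X, y)
        r = np.corrcoef(press, y)[0, 1]
        assert abs(r) < 3.29 / np.sqrt(200) + 0.1
        # the integer-trimmed path may collapse to a constant predictor
        # (undefined r); otherwise its pooled r is also near zero
        cv = loocv_evaluate(X, y)
        assert np.isnan(cv.pearson_r) or abs(cv.pearson_r) < 0.25

    def test_minimal_structural_case(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0], [1.0]])
        y = np.array([1.0, 3.0, 1.2, 2.9, 3.1])
        cv = loocv_evaluate(X, y)
        assert cv.pooled_predictions.shape == (5,)

    def test_trimmed_means_within_half_of_float_means(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 2, (40, 3)).astype(float)
        y = rng.normal(60, 10, 40)
        cv = loocv_evaluate(X, y)
        assert abs(cv.trimmed_intercept - cv.mean_intercept) <= 0.5
        assert (np.abs(cv.trimmed_coefficients - cv.mean_coefficients) <= 0.5).all()

    def test_press_matches_explicit_loo_float_fit(self):
        rng = np.random.default_rng(8)
        X = rng.integers(0, 2, (25, 3)).astype(float)
        y = rng.normal(50, 12, 25)
        press = press_loocv_predictions(X, y)
        A = np.column_stack([np.ones(25), X])
        explicit = np.empty(25)
        mask = np.ones(25, dtype=bool)
        for i in range(25):
            mask[i] = False
            beta, *_ = np.linalg.lstsq(A[mask], y[mask], rcond=None)
            explicit[i] = A[i] @ beta
            mask[i] = True
        assert np.allclose(press, explicit, atol=1e-8)


# ---------------------------------------------------------------------------
# combination enumeration


class TestEnumeration:
    def test_two_ways_to_reach_two_items(self):
        sets = [ItemSet("s1", ("R1",)), ItemSet("s2", ("R2",)), ItemSet("s3", ("R3", "R4"))]
        combos = list(enumerate_combinations(sets, 2))
        assert [tuple(s.set_id for s in c) for c in combos] == [("s1", "s2"), ("s3",)]

    def test_target_zero_is_empty(self):
        sets = [ItemSet("s1", ("R1",))]
        assert list(enumerate_combinations(sets, 0)) == []

    def test_matches_naive_power_set_filter(self):
        """Oracle: brute-force power-set filter on a 12-set instance."""
        rng = np.random.default_rng(9)
        sizes = rng.integers(1, 5, 12)
        sets = []
        pos = 0
        for k, size in enumerate(sizes):
            sets.append(ItemSet(f"s{k:02d}", tuple(f"R{pos + j}" for j in range(size))))
            pos += size
        for target in (1, 5, 9, 14):
            expected = set()
            for mask in itertools.product([0, 1], repeat=12):
                chosen = tuple(s.set_id for s, m in zip(sets, mask) if m)
                if sum(s.size for s, m in zip(sets, mask) if m) == target and chosen:
                    expected.add(chosen)
            got = {tuple(s.set_id for s in c) for c in enumerate_combinations(sets, target)}
            assert got == expected


# ---------------------------------------------------------------------------
# exhaustive search vs an independently coded naive oracle


def _naive_loocv_r_rmse(X, y):
    """Independent LOOCV evaluation: plain per-fold lstsq + trimming."""
    n = X.shape[0]
    A = np.column_stack([np.ones(n), X])
    preds = np.empty(n)
    for i in range(n):
        keep = [k for k in range(n) if k != i]
        beta, *_ = np.linalg.lstsq(A[keep], y[keep], rcond=None)
        trimmed = np.sign(beta) * np.floor(np.abs(beta) + 0.5)
        preds[i] = A[i] @ trimmed
    rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
    if preds.min() == preds.max():
        return float("nan"), rmse
    return float(np.corrcoef(preds, y)[0, 1]), rmse


def _naive_best_per_count(sets, responses, y):
    """Enumerate the full power set, evaluate every subset, pick the best per
    item count by (max r, min rmse, fewest sets, lexicographic ids)."""
    best = {}
    n = len(y)
    for mask in itertools.product([0, 1], repeat=len(sets)):
        chosen = [s for s, m in zip(sets, mask) if m]
        if not chosen:
            continue
        count = sum(s.size for s in chosen)
        if n <= count + 1:
            continue
        ids = [i for s in chosen for i in s.item_ids]
        X = responses.submatrix(ids)
        r, rmse = _naive_loocv_r_rmse(X, y)
        r_key = -r if np.isfinite(r) else np.inf
        key = (r_key, rmse, len(chosen), tuple(s.set_id for s in chosen))
        if count not in best or key < best[count][0]:
            best[count] = (key, tuple(s.set_id for s in chosen), r)
    return best


@pytest.fixture(scope="module")
def small_instance():
    bank = make_bank([1, 2, 2, 3, 1, 2])  # 6 sets, 11 items
    rng = np.random.default_rng(11)
    n = 40
    theta = rng.normal(0, 1, n)
    probs = 1 / (1 + np.exp(-(2.0 * (theta[:, None] - np.linspace(-1.5, 1.0, 11)[None, :]))))
    values = (rng.random((n, 11)) < probs).astype(int)
    responses = ResponseMatrix(
        tuple(f"p{i}" for i in range(n)), tuple(bank.item_ids), values
    )
    y = values.sum(axis=1) * (100 / 11) + rng.normal(0, 3, n)
    scores = ScoreVector(responses.participant_ids, np.round(y))
    return bank, responses, scores


class TestExhaustiveSearch:
    def test_equivalent_to_naive_power_set_oracle(self, small_instance):
        """Per-count winners of the packaged search equal those of a naive
        independent implementation (full power set, separately coded LOOCV)."""
        bank, responses, scores = small_instance
        model = ShortFormSearch(
            responses, bank, scores, QualityGoal(r_min=0.999), exact=True
        )
        results = model.fit()
        naive = _naive_best_per_count(group_items(bank), responses, scores.scores)
        assert set(results.curve) == set(naive)
        for count, winner in results.curve.items():
            assert winner.set_ids == naive[count][1], f"count {count}"
            assert winner.cv.pearson_r == pytest.approx(naive[count][2], abs=1e-12)

    def test_screened_mode_agrees_with_exact(self, small_instance):
        bank, responses, scores = small_instance
        exact = ShortFormSearch(responses, bank, scores, QualityGoal(0.999), exact=True).fit()
        screened = ShortFormSearch(
            responses, bank, scores, QualityGoal(0.999), screen_top=10
        ).fit()
        for count in exact.curve:
            assert screened.curve[count].set_ids == exact.curve[count].set_ids

    def test_deterministic_subset_drives_search_to_r1(self):
        """One 2-item set fully determines the target: the search finds it at
        item count 2 with r = 1 and stops (brute-force-verifiable instance)."""
        bank = make_bank([1, 2, 1, 2])
        rng = np.random.default_rng(12)
        values = rng.integers(0, 2, (30, 6))
        responses = ResponseMatrix(
            tuple(f"p{i}" for i in range(30)), tuple(bank.item_ids), values
        )
        # S2 = {R2, R3}; y depends on them alone
        y = 40 + 9 * values[:, 1] + 5 * values[:, 2]
        scores = ScoreVector(responses.participant_ids, y.astype(float))
        results = ShortFormSearch(responses, bank, scores, QualityGoal(0.9), exact=True).fit()
        assert results.goal_met
        assert results.final_winner.item_count == 2
        assert results.final_winner.set_ids == ("S2",)
        assert results.final_winner.cv.pearson_r == pytest.approx(1.0)
        assert results.final_model.weights == {"R2": 9, "R3": 5}
        assert results.final_model.intercept == 40

    def test_unreachable_goal_returns_full_curve(self, small_instance):
        bank, responses, scores = small_instance
        results = ShortFormSearch(
            responses, bank, scores, QualityGoal(r_min=1.0), exact=True
        ).fit()
        assert not results.goal_met
        assert results.final_model is None
        assert max(results.curve) == 11  # scanned every achievable size

    def test_nested_models_never_increase_insample_rmse(self, small_instance):
        """Least-squares nesting: adding a set cannot worsen the float fit."""
        bank, responses, scores = small_instance
        sets = group_items(bank)
        y = scores.scores

        def insample_rmse(combo):
            ids = [i for s in combo for i in s.item_ids]
            X = responses.submatrix(ids)
            fit = fit_integer_mlr(X, y, warn=False)
            pred = fit.intercept + X @ fit.coefficients
            return np.sqrt(np.mean((pred - y) ** 2))

        rng = np.random.default_rng(13)
        for trial in range(10):
            k = rng.integers(1, 4)
            idx = rng.choice(len(sets), size=k, replace=False)
            combo = tuple(sets[i] for i in sorted(idx))
            extra = sets[rng.choice([i for i in range(len(sets)) if i not in idx])]
            assert insample_rmse(combo + (extra,)) <= insample_rmse(combo) + 1e-9

    def test_search_is_deterministic(self, small_instance):
        bank, responses, scores = small_instance
        a = ShortFormSearch(responses, bank, scores, QualityGoal(0.95), exact=True).fit()
        b = ShortFormSearch(responses, bank, scores, QualityGoal(0.95), exact=True).fit()
        assert a.goal_met == b.goal_met
        assert {c: w.set_ids for c, w in a.curve.items()} == {
            c: w.set_ids for c, w in b.curve.items()}
        for c in a.curve:
            assert a.curve[c].cv.pearson_r == b.curve[c].cv.pearson_r

    def test_performance_curve_accounting(self, small_instance):
        bank, responses, scores = small_instance
        results = ShortFormSearch(responses, bank, scores, QualityGoal(0.999), exact=True).fit()
        curve = performance_curve(results)
        assert list(curve.columns) == ["item_count", "best_r", "best_rmse", "sets"]
        assert curve["item_count"].is_monotonic_increasing
        sizes = {s.set_id: s.size for s in group_items(bank)}
        for _, row in curve.iterrows():
            assert sum(sizes[sid] for sid in row["sets"].split(";")) == row["item_count"]

    def test_numeracy_pass_used_when_reading_insufficient(self):
        """If no reading-only model can meet the goal, the relaxed pass brings
        in numeracy items and records it."""
        bank = make_bank([1, 1], n_numeracy=2)
        rng = np.random.default_rng(14)
        values = rng.integers(0, 2, (30, 4))
        responses = ResponseMatrix(
            tuple(f"p{i}" for i in range(30)), tuple(bank.item_ids), values
        )
        y = 30 + 10 * values[:, 2] + 6 * values[:, 3]  # numeracy-driven target
        scores = ScoreVector(responses.participant_ids, y.astype(float))
        strict = ShortFormSearch(responses, bank, scores, QualityGoal(0.95), exact=True).fit()
        assert not strict.goal_met
        relaxed = ShortFormSearch(
            responses, bank, scores, QualityGoal(0.95, numeracy_allowed=True), exact=True
        ).fit()
        assert relaxed.goal_met
        assert relaxed.pass_used == "with_numeracy"
        assert set(relaxed.final_model.weights) <= {"R1", "R2", "N1", "N2"}
        assert {"N1", "N2"} & set(relaxed.final_model.weights)

    def test_summary_mentions_goal_and_model(self, small_instance):
        bank, responses, scores = small_instance
        results = ShortFormSearch(responses, bank, scores, QualityGoal(0.8), exact=True).fit()
        text = results.summary()
        assert "quality goal" in text
        assert ("goal met" in text) == results.goal_met
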