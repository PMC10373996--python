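"""Exhaustive short-form construction by set-wise best-subset regression.

The short form is an integer-weighted linear rule predicting the full-length
total score from a subset of items. Candidate subsets are unions of whole
sentence-sets (see :mod:`.grouping`). For every model size (total item count),
every combination of sets attaining that size is evaluated by leave-one-out
cross-validation (LOOCV) of an ordinary-least-squares fit whose coefficients
are trimmed to integers, and the combination with the highest pooled LOOCV
Pearson correlation wins. The search stops at the smallest size whose winner
reaches the quality goal (r >= 0.9 by default, reading items only).

Organisation follows the fit/results idiom: build a :class:`ShortFormSearch`
from the data, call :meth:`~ShortFormSearch.fit`, and read the
:class:`ShortFormSearchResults` (per-size performance curve, final integer
model, ``summary()``).

Exact LOOCV refits the model n times per combination. Because the number of
combinations grows quickly, the default is a two-stage evaluation: all
combinations at a size are first screened with the closed-form leave-one-out
residuals of the float fit (PRESS, via hat-matrix leverages), and exact
integer-trimmed LOOCV is run only on the ``screen_top`` best screened
candidates. ``exact=True`` forces exact LOOCV everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .grouping import ItemSet, group_items
from .items import ItemBank, LevelScale, ResponseMatrix, ScoreVector, ShortFormModel
from .scoring import score_full

__all__ = [
    "QualityGoal",
    "CVResult",
    "IntegerFit",
    "SearchError",
    "RankDeficiencyWarning",
    "ShortFormSearch",
    "ShortFormSearchResults",
    "fit_integer_mlr",
    "loocv_evaluate",
    "press_loocv_predictions",
    "enumerate_combinations",
    "exhaustive_search",
    "performance_curve",
    "round_half_away",
]


class SearchError(ValueError):
    pass


class RankDeficiencyWarning(UserWarning):
    """A design matrix was rank-deficient; the pseudo-inverse solution was used."""


def round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round to the nearest integer, halves away from zero (3.5 -> 4, -3.5 -> -4)."""
    x = np.asarray(x, dtype=float)
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


@dataclass(frozen=True)
class QualityGoal:
    """The stopping criterion of the search.

    ``r_min`` is the minimum pooled LOOCV Pearson correlation between
    predicted and full-length scores; ``numeracy_allowed`` permits a second
    search pass over numeracy items if no reading-only model reaches it.
    """

    r_min: float = 0.9
    numeracy_allowed: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.r_min <= 1):
            raise SearchError("r_min must lie in (0, 1]")


@dataclass(frozen=True)
class IntegerFit:
    """Float least-squares solution and its integer trimming."""

    intercept: float
    coefficients: np.ndarray
    trimmed_intercept: int
    trimmed_coefficients: np.ndarray
    rank_deficient: bool = False


@dataclass(frozen=True)
class CVResult:
    """Pooled LOOCV evaluation of one item subset.

    ``pooled_predictions[i]`` is participant i's score predicted by the
    integer-trimmed model fitted on the other n-1 participants. Reported
    coefficients are the per-fold float means (``mean_*``) and their single
    final trimming (``trimmed_*``).
    """

    pooled_predictions: np.ndarray
    rmse: float
    pearson_r: float
    r_ci95: tuple[float, float]
    p_value: float
    mean_intercept: float
    mean_coefficients: np.ndarray
    trimmed_intercept: int
    trimmed_coefficients: np.ndarray
    rank_deficient: bool = False


def _solve_ols(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Least-squares solve; falls back to the pseudo-inverse when rank-deficient."""
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    deficient = rank < A.shape[1]
    if deficient:
        beta = np.linalg.pinv(A) @ y
    return beta, deficient


def fit_integer_mlr(X: np.ndarray, y: np.ndarray, *, warn: bool = True) -> IntegerFit:
    """Fit ``y = b0 + X b`` by least squares and trim all coefficients to integers.

    Trimming rounds half away from zero, applied to the intercept and every
    coefficient. Requires ``n > p + 1``; a rank-deficient design is solved
    with the pseudo-inverse and flagged (with a :class:`RankDeficiencyWarning`
    unless ``warn=False``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise SearchError("X must be 2-D with one response per row")
    n, p = X.shape
    if n <= p + 1:
        raise SearchError(f"need n > p + 1 observations (n={n}, p={p})")
    A = np.column_stack([np.ones(n), X])
    beta, deficient = _solve_ols(A, y)
    if deficient and warn:
        warnings.warn(
            "rank-deficient design matrix; pseudo-inverse solution used",
            RankDeficiencyWarning,
            stacklevel=2,
        )
    trimmed = round_half_away(beta)
    return IntegerFit(
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        trimmed_intercept=int(trimmed[0]),
        trimmed_coefficients=trimmed[1:].astype(int),
        rank_deficient=deficient,
    )


def _pearson_ci_p(pred: np.ndarray, y: np.ndarray) -> tuple[float, tuple[float, float], float]:
    # local import keeps scipy off the hot screening path
    from .psychometrics import pearson_with_ci

    if pred.min() == pred.max() or y.min() == y.max():
        return float("nan"), (float("nan"), float("nan")), float("nan")
    return pearson_with_ci(pred, y)


def _loo_betas(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Per-fold OLS coefficient vectors, one row per left-out observation.

    Uses the rank-one downdate ``beta_(i) = beta - (A'A)^-1 a_i e_i / (1-h_i)``
    when the design has full rank and no leverage is 1; otherwise falls back
    to refitting each fold explicitly (pseudo-inverse for deficient folds).
    The two paths agree exactly on full-rank designs.
    """
    n, q = A.shape
    betas = np.empty((n, q))
    if np.linalg.matrix_rank(A) == q:
        G = np.linalg.inv(A.T @ A)
        B = A @ G
        h = np.einsum("ij,ij->i", B, A)
        if np.all(h < 1 - 1e-8):
            beta = G @ (A.T @ y)
            e = y - A @ beta
            return beta[None, :] - B * (e / (1 - h))[:, None], False

    any_deficient = False
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        betas[i], deficient = _solve_ols(A[mask], y[mask])
        mask[i] = True
        any_deficient |= deficient
    return betas, any_deficient


def loocv_evaluate(X: np.ndarray, y: np.ndarray) -> CVResult:
    """Exact leave-one-out cross-validation of the integer-trimmed fit.

    For each participant i the model is fitted on the other n-1 rows, its
    coefficients trimmed to integers, and row i predicted by the trimmed
    model. The pooled predictions give the RMSE and Pearson r (with Fisher-z
    CI). The reported model parameters are the per-fold float coefficient
    means, trimmed once at the end.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise SearchError("LOOCV needs at least 3 observations")
    if n <= p + 1:
        raise SearchError(f"need n > p + 1 observations (n={n}, p={p})")
    A = np.column_stack([np.ones(n), X])
    fold_betas, any_deficient = _loo_betas(A, y)
    preds = np.einsum("ij,ij->i", A, round_half_away(fold_betas))
    mean_beta = fold_betas.mean(axis=0)
    trimmed = round_half_away(mean_beta)
    rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
    r, ci, pval = _pearson_ci_p(preds, y)
    return CVResult(
        pooled_predictions=preds,
        rmse=rmse,
        pearson_r=r,
        r_ci95=ci,
        p_value=pval,
        mean_intercept=float(mean_beta[0]),
        mean_coefficients=mean_beta[1:].copy(),
        trimmed_intercept=int(trimmed[0]),
        trimmed_coefficients=trimmed[1:].astype(int),
        rank_deficient=any_deficient,
    )


def press_loocv_predictions(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form leave-one-out predictions of the float OLS fit.

    Uses the PRESS identity ``e_(i) = e_i / (1 - h_ii)`` with leverages
    ``h_ii`` from the thin-QR factorisation of the design. Leverages at 1
    (interpolated points) are clamped just below 1, yielding very large
    residuals, which correctly penalises saturated fits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    A = np.column_stack([np.ones(n), X])
    Q, _ = np.linalg.qr(A)
    h = np.minimum((Q**2).sum(axis=1), 1 - 1e-10)
    beta, _ = _solve_ols(A, y)
    resid = y - A @ beta
    return y - resid / (1 - h)


# ---------------------------------------------------------------------------
# combination enumeration


def enumerate_combinations(
    sets: Sequence[ItemSet],
    target_item_count: int,
    extra_sets: Sequence[ItemSet] = (),
) -> Iterator[tuple[ItemSet, ...]]:
    """Yield every combination of sets whose sizes sum to ``target_item_count``.

    Combinations are emitted in lexicographic order of set ids. ``extra_sets``
    (e.g. numeracy singletons for the relaxed pass) are pooled with ``sets``.
    """
    if target_item_count < 1:
        return
    pool = sorted(list(sets) + list(extra_sets), key=lambda s: s.set_id)
    sizes = [s.size for s in pool]
    # suffix sums let the DFS prune branches that cannot reach the target
    suffix = np.concatenate([np.cumsum(sizes[::-1])[::-1], [0]])

    def dfs(start: int, remaining: int, chosen: list[ItemSet]) -> Iterator[tuple[ItemSet, ...]]:
        if remaining == 0:
            yield tuple(chosen)
            return
        for k in range(start, len(pool)):
            if sizes[k] > remaining or suffix[k] < remaining:
                if suffix[k] < remaining:
                    break
                continue
            chosen.append(pool[k])
            yield from dfs(k + 1, remaining - sizes[k], chosen)
            chosen.pop()

    yield from dfs(0, target_item_count, [])


# ---------------------------------------------------------------------------
# the search model


@dataclass(frozen=True)
class _SizeWinner:
    item_count: int
    sets: tuple[ItemSet, ...]
    cv: CVResult

    @property
    def item_ids(self) -> list[str]:
        return [i for s in self.sets for i in s.item_ids]

    @property
    def set_ids(self) -> tuple[str, ...]:
        return tuple(s.set_id for s in self.sets)


def _selection_key(r: float, rmse: float, sets: tuple[ItemSet, ...]):
    # higher r, then lower rmse, then fewer sets, then lexicographic set ids;
    # nan r sorts last
    r_key = -r if np.isfinite(r) else np.inf
    return (r_key, rmse if np.isfinite(rmse) else np.inf, len(sets),
            tuple(s.set_id for s in sets))


class ShortFormSearch:
    """Exhaustive search model for deriving a short form from response data.

    Parameters
    ----------
    responses
        Binary response matrix covering every bank item.
    bank
        The full-length item bank; its reading items must carry a contiguous
        sentence-set partition.
    full_scores
        Optional precomputed full-length total scores; computed with
        :func:`~tofhla_shortform.scoring.score_full` when omitted.
    goal
        Stopping criterion (default r >= 0.9, reading only).
    screen_top
        Number of PRESS-screened candidates per model size given exact
        integer LOOCV (ignored when ``exact=True``).
    exact
        Run exact integer-trimmed LOOCV on every combination.
    max_items
        Largest model size to scan if the goal is never met (defaults to the
        full reading part, or all items on the numeracy pass).
    """

    def __init__(
        self,
        responses: ResponseMatrix,
        bank: ItemBank,
        full_scores: ScoreVector | None = None,
        goal: QualityGoal | None = None,
        *,
        screen_top: int = 50,
        exact: bool = False,
        max_items: int | None = None,
    ) -> None:
        self.responses = responses
        self.bank = bank
        self.goal = goal or QualityGoal()
        self.screen_top = int(screen_top)
        self.exact = bool(exact)
        self.max_items = max_items
        if full_scores is None:
            full_scores = score_full(responses, bank)
        if full_scores.participant_ids != responses.participant_ids:
            raise SearchError("full_scores cover different participants than responses")
        self.full_scores = full_scores
        self.sets = group_items(bank)

    @classmethod
    def from_files(
        cls, bank_path, responses_path, full_scores_path=None, **kwargs
    ) -> "ShortFormSearch":
        from .items import load_item_bank, load_response_matrix
        import pandas as pd

        bank = load_item_bank(bank_path)
        responses = load_response_matrix(responses_path, bank)
        scores = None
        if full_scores_path is not None:
            df = pd.read_csv(full_scores_path, dtype={0: str})
            scores = ScoreVector(tuple(df.iloc[:, 0]), df.iloc[:, 1].to_numpy(float))
        return cls(responses, bank, scores, **kwargs)

    # -- evaluation of one combination ------------------------------------

    def _design(self, sets: tuple[ItemSet, ...]) -> tuple[np.ndarray, list[str]]:
        ids = [i for s in sets for i in s.item_ids]
        return self.responses.submatrix(ids), ids

    def _best_at_count(
        self, count: int, pool: list[ItemSet]
    ) -> _SizeWinner | None:
        y = self.full_scores.scores
        n = len(y)
        combos = [
            c for c in enumerate_combinations(pool, count)
            if n > sum(s.size for s in c) + 1
        ]
        if not combos:
            return None
        if not self.exact and len(combos) > self.screen_top:
            screened = []
            for c in combos:
                X, _ = self._design(c)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RankDeficiencyWarning)
                    pred = press_loocv_predictions(X, y)
                if pred.min() == pred.max() or y.min() == y.max():
                    r, rmse = float("nan"), float("inf")
                else:
                    r = float(np.corrcoef(pred, y)[0, 1])
                    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
                screened.append((_selection_key(r, rmse, c), c))
            screened.sort(key=lambda t: t[0])
            combos = [c for _, c in screened[: self.screen_top]]
        best: tuple | None = None
        for c in combos:
            X, _ = self._design(c)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RankDeficiencyWarning)
                cv = loocv_evaluate(X, y)
            key = _selection_key(cv.pearson_r, cv.rmse, c)
            if best is None or key < best[0]:
                best = (key, c, cv)
        if best is None:
            return None
        return _SizeWinner(item_count=count, sets=best[1], cv=best[2])

    def _run_pass(self, pool: list[ItemSet], max_items: int):
        curve: dict[int, _SizeWinner] = {}
        for count in range(1, max_items + 1):
            winner = self._best_at_count(count, pool)
            if winner is None:
                continue
            curve[count] = winner
            if np.isfinite(winner.cv.pearson_r) and winner.cv.pearson_r >= self.goal.r_min:
                return curve, winner
        return curve, None

    def fit(self) -> "ShortFormSearchResults":
        """Run the search and return its results."""
        reading_pool = list(self.sets)
        n_reading = sum(s.size for s in reading_pool)
        max_items = self.max_items or n_reading
        curve, winner = self._run_pass(reading_pool, min(max_items, n_reading))
        pass_used = "reading_only"
        if winner is None and self.goal.numeracy_allowed:
            numeracy_singletons = [
                ItemSet(set_id=f"N:{it.item_id}", item_ids=(it.item_id,))
                for it in self.bank.numeracy_items
            ]
            pool = reading_pool + numeracy_singletons
            total = sum(s.size for s in pool)
            curve, winner = self._run_pass(pool, min(self.max_items or total, total))
            pass_used = "with_numeracy"
        final_model = None
        if winner is not None:
            weights = {
                item_id: int(w)
                for item_id, w in zip(winner.item_ids, winner.cv.trimmed_coefficients)
            }
            final_model = ShortFormModel(
                intercept=winner.cv.trimmed_intercept,
                weights=weights,
                scale=LevelScale(),
                provenance=(
                    f"exhaustive set search on bank {self.bank.name!r}: "
                    f"{winner.item_count} items from sets {list(winner.set_ids)}, "
                    f"LOOCV r={winner.cv.pearson_r:.3f}, rmse={winner.cv.rmse:.2f}"
                ),
            )
        return ShortFormSearchResults(
            model=self,
            curve=curve,
            final_winner=winner,
            final_model=final_model,
            goal_met=winner is not None,
            pass_used=pass_used,
        )


@dataclass
class ShortFormSearchResults:
    """Results of :meth:`ShortFormSearch.fit`.

    ``curve`` maps each achievable item count (up to the stopping point) to
    the best combination found there; ``final_model`` is the integer scoring
    rule of the smallest size meeting the goal, or ``None`` if the goal was
    never met (``goal_met`` False).
    """

    model: ShortFormSearch
    curve: dict[int, _SizeWinner]
    final_winner: _SizeWinner | None
    final_model: ShortFormModel | None
    goal_met: bool
    pass_used: str = "reading_only"

    def curve_frame(self):
        """The performance curve as a DataFrame (item_count, best_r, best_rmse, sets)."""
        import pandas as pd

        rows = [
            {
                "item_count": c,
                "best_r": w.cv.pearson_r,
                "best_rmse": w.cv.rmse,
                "sets": ";".join(w.set_ids),
            }
            for c, w in sorted(self.curve.items())
        ]
        return pd.DataFrame(rows, columns=["item_count", "best_r", "best_rmse", "sets"])

    def summary(self) -> str:
        lines = ["Short-form exhaustive search", "=" * 60]
        lines.append(f"participants: {self.model.responses.n_participants}")
        lines.append(f"sets searched: {len(self.model.sets)} ({self.pass_used})")
        lines.append(f"quality goal:  LOOCV Pearson r >= {self.model.goal.r_min}")
        lines.append("")
        lines.append(f"{'items':>5} {'best r':>8} {'rmse':>8}  sets")
        for c, w in sorted(self.curve.items()):
            lines.append(
                f"{c:>5} {w.cv.pearson_r:>8.3f} {w.cv.rmse:>8.2f}  {','.join(w.set_ids)}"
            )
        lines.append("")
        if self.goal_met and self.final_model is not None and self.final_winner is not None:
            w = self.final_winner
            lo, hi = w.cv.r_ci95
            lines.append(
                f"goal met at {w.item_count} items: r={w.cv.pearson_r:.3f} "
                f"(CI95 {lo:.2f};{hi:.2f}), rmse={w.cv.rmse:.2f}"
            )
            terms = " + ".join(
                f"{v}*{k}" for k, v in self.final_model.weights.items()
            )
            lines.append(f"model: Y = {self.final_model.intercept} + {terms}")
        else:
            lines.append("goal not met; no final model selected")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers


def exhaustive_search(
    sets: Sequence[ItemSet] | None,
    responses: ResponseMatrix,
    full_scores: ScoreVector | None,
    goal: QualityGoal | None = None,
    *,
    bank: ItemBank,
    **config,
) -> ShortFormSearchResults:
    """Functional wrapper around :class:`ShortFormSearch` (sets read from bank)."""
    model = ShortFormSearch(responses, bank, full_scores, goal, **config)
    return model.fit()


def performance_curve(result: ShortFormSearchResults):
    """The best-model-per-size curve of a finished search, as a DataFrame."""
    return result.curve_frame()
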