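"""Human–machine adversarial scoring of street scenes.

A rater first scores a warm-up batch of images; a random-forest regressor
trained on those scores then predicts the rater's score for each subsequent
image while the rater keeps scoring subjectively. Whenever the model's
prediction misses the subjective score by more than a threshold for a run
of consecutive images (six, by default), an *intervention* occurs: the model
is refit on every subjective score accumulated so far, and keeps refitting
on subsequent images until its error falls back under the threshold. The
final score of every image is the last model's prediction, and a panel's
sessions are combined by a weighted consensus mean.

The forest exposes its per-tree bootstrap in-bag index multisets, so
out-of-bag (OOB) error and the permutation variable importance

    VI_n(X_j) = [ sum_i I(f(X_i) = f_n(X_i)) - sum_i I(f(X_i) = f_n(X_i')) ] / N_OOB

(averaged over trees; X_i' has column j permuted within the tree's OOB set)
can be computed exactly as written. The indicator's equality is realized
for continuous predictions as agreement within a tolerance; a conventional
MSE-increase importance is available as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .composition import CLASS_NAMES

DEFAULT_FOREST_PARAMS = dict(n_trees=500, mtry=6, min_leaf=2, max_depth=None)


@dataclass
class AccuracyReport:
    """Prediction-accuracy metrics on the 0-100 scoring scale.

    ``mean_abs_error_pct`` is the mean absolute error expressed as a percent
    of the 100-point scale (numerically equal to the error in score units).
    """

    mean_abs_error: float
    mean_abs_error_pct: float
    rmse: float
    oob_error_pct: float | None = None
    oob_rmse: float | None = None

    def __post_init__(self):
        for name in ("mean_abs_error", "mean_abs_error_pct", "rmse"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class StressForest:
    """Random-forest regression model for stress scores.

    Parameters
    ----------
    n_trees : int
        Number of regression trees (default 500).
    mtry : int
        Features tried per split (default 6, about a third of the 19
        element classes); capped at the number of columns.
    min_leaf, max_depth : tree regularization (defaults 2, unlimited).
    bootstrap : {'standard', 'two_thirds'}
        'standard' draws n samples with replacement (each tree then sees
        about 63.2% unique samples, with the remaining third out of bag);
        'two_thirds' subsamples exactly round(2n/3) without replacement.
    seed : int, optional
        Drives the bootstrap draws and per-tree randomness.
    """

    def __init__(
        self,
        n_trees: int = 500,
        mtry: int = 6,
        min_leaf: int = 2,
        max_depth: int | None = None,
        bootstrap: str = "standard",
        seed: int | None = None,
    ):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if bootstrap not in ("standard", "two_thirds"):
            raise ValueError("bootstrap must be 'standard' or 'two_thirds'")
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_leaf = min_leaf
        self.max_depth = max_depth
        self.bootstrap = bootstrap
        self.seed = seed

    def fit(self, X, y) -> "StressForestResults":
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D and aligned with y")
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if ((y < 0) | (y > 100)).any():
            raise ValueError("scores must lie in [0, 100]")
        rng = np.random.default_rng(self.seed)
        trees, inbag = [], []
        mtry = min(self.mtry, p)
        for _ in range(self.n_trees):
            if self.bootstrap == "standard":
                idx = rng.integers(0, n, n)
            else:
                idx = rng.choice(n, size=int(round(2 * n / 3)), replace=False)
            tree = DecisionTreeRegressor(
                max_features=mtry,
                min_samples_leaf=self.min_leaf,
                max_depth=self.max_depth,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            trees.append(tree)
            inbag.append(np.sort(idx))
        return StressForestResults(model=self, trees=trees, inbag=inbag, X=X, y=y)


@dataclass
class StressForestResults:
    """Fitted forest: trees, their in-bag multisets, and the training data."""

    model: StressForest | None
    trees: list
    inbag: list[np.ndarray]
    X: np.ndarray
    y: np.ndarray
    _oob_pred: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return len(self.y)

    def oob_masks(self):
        """Per tree, the boolean mask of training samples out of bag."""
        n = self.n_samples
        for idx in self.inbag:
            mask = np.ones(n, dtype=bool)
            mask[idx] = False
            yield mask

    def predict(self, X) -> np.ndarray:
        """Forest prediction: mean of per-tree predictions."""
        X = np.atleast_2d(np.asarray(X, float))
        out = np.zeros(len(X))
        for tree in self.trees:
            out += tree.predict(X)
        return out / len(self.trees)

    def oob_predictions(self) -> np.ndarray:
        """OOB prediction per training sample (NaN if never out of bag)."""
        if self._oob_pred is None:
            n = self.n_samples
            sums = np.zeros(n)
            counts = np.zeros(n)
            for tree, mask in zip(self.trees, self.oob_masks()):
                if mask.any():
                    sums[mask] += tree.predict(self.X[mask])
                    counts[mask] += 1
            with np.errstate(invalid="ignore"):
                self._oob_pred = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return self._oob_pred

    def oob_error(self) -> tuple[float, float]:
        """(OOB mean absolute error as % of the 100-point scale, OOB RMSE).

        Samples never out of bag are excluded and reported in a warning.
        """
        pred = self.oob_predictions()
        covered = ~np.isnan(pred)
        skipped = int((~covered).sum())
        if skipped:
            warnings.warn(f"{skipped} sample(s) never out of bag; excluded", stacklevel=2)
        if not covered.any():
            raise ValueError("no sample has an OOB prediction")
        err = pred[covered] - self.y[covered]
        return float(np.abs(err).mean()), float(np.sqrt((err**2).mean()))

    def variable_importance(
        self,
        agreement_tol: float = 5.0,
        seed: int | None = None,
        feature_names: Sequence[str] | None = None,
    ) -> pd.DataFrame:
        """Permutation variable importance by the agreement-indicator formula.

        For each tree n and feature j, over the tree's OOB samples: the
        count of predictions agreeing with the observed score (within
        ``agreement_tol`` score units) minus the same count after permuting
        column j within the OOB set, divided by N_OOB; averaged over trees.
        Trees with an empty OOB set are skipped with a warning.
        """
        if agreement_tol < 0:
            raise ValueError("agreement_tol must be >= 0")
        rng = np.random.default_rng(seed)
        p = self.X.shape[1]
        vi_sum = np.zeros(p)
        n_used = 0
        skipped = 0
        for tree, mask in zip(self.trees, self.oob_masks()):
            n_oob = int(mask.sum())
            if n_oob == 0:
                skipped += 1
                continue
            X_oob = self.X[mask]
            y_oob = self.y[mask]
            base_agree = (np.abs(y_oob - tree.predict(X_oob)) <= agreement_tol).sum()
            for j in range(p):
                X_perm = X_oob.copy()
                X_perm[:, j] = X_perm[rng.permutation(n_oob), j]
                perm_agree = (np.abs(y_oob - tree.predict(X_perm)) <= agreement_tol).sum()
                vi_sum[j] += (base_agree - perm_agree) / n_oob
            n_used += 1
        if skipped:
            warnings.warn(f"{skipped} tree(s) had an empty OOB set; skipped", stacklevel=2)
        if n_used == 0:
            raise ValueError("no tree has a non-empty OOB set")
        names = list(feature_names) if feature_names is not None else [
            f"x{j}" for j in range(p)
        ]
        return pd.DataFrame({"feature": names, "VI": vi_sum / n_used}).sort_values(
            "VI", ascending=False, ignore_index=True
        )

    def mse_importance(self, seed: int | None = None,
                       feature_names: Sequence[str] | None = None) -> pd.DataFrame:
        """Cross-check importance: mean increase in per-tree OOB MSE on permuting."""
        rng = np.random.default_rng(seed)
        p = self.X.shape[1]
        inc = np.zeros(p)
        n_used = 0
        for tree, mask in zip(self.trees, self.oob_masks()):
            if not mask.any():
                continue
            X_oob, y_oob = self.X[mask], self.y[mask]
            base = ((y_oob - tree.predict(X_oob)) ** 2).mean()
            for j in range(p):
                X_perm = X_oob.copy()
                X_perm[:, j] = X_perm[rng.permutation(len(X_oob)), j]
                inc[j] += ((y_oob - tree.predict(X_perm)) ** 2).mean() - base
            n_used += 1
        names = list(feature_names) if feature_names is not None else [
            f"x{j}" for j in range(p)
        ]
        return pd.DataFrame({"feature": names, "mse_increase": inc / max(n_used, 1)}).sort_values(
            "mse_increase", ascending=False, ignore_index=True
        )


def fit_forest(X, y, n_trees: int = 500, mtry: int = 6, seed: int | None = None,
               **kwargs) -> StressForestResults:
    """Functional alias for ``StressForest(...).fit(X, y)``."""
    return StressForest(n_trees=n_trees, mtry=mtry, seed=seed, **kwargs).fit(X, y)


def oob_error(results: StressForestResults) -> tuple[float, float]:
    """(OOB mean absolute error % of scale, OOB RMSE) of a fitted forest."""
    return results.oob_error()


# ---------------------------------------------------------------------------
# the adversarial loop


@dataclass
class ScoringSession:
    """One rater's pass through the image set.

    ``records`` has one row per presented image: image_id, subjective score,
    model prediction (NaN during warm-up), and phase (warmup / predict /
    intervene). ``final_scores`` are the last model's predictions for every
    image, indexed by image id.
    """

    rater_id: str
    records: pd.DataFrame
    interventions: int
    final_scores: pd.Series
    results: StressForestResults | None = None


def run_scoring_session(
    rater,
    images: pd.DataFrame,
    n_init: int = 50,
    err_thresh: float = 10.0,
    streak: int = 6,
    forest_params: dict | None = None,
    seed: int | None = None,
) -> ScoringSession:
    """Run the warm-up / predict / intervene protocol for one rater.

    ``rater`` is any object with ``rate(composition) -> score`` (and
    optionally ``rater_id``); ``images`` is a composition table with a
    ``point_id`` column. The first ``n_init`` images (in a seeded shuffled
    presentation order) are scored subjectively and train the first model.
    Each later image gets both a model prediction and a subjective score;
    ``streak`` consecutive absolute errors > ``err_thresh`` trigger an
    intervention, after which the model refits on all subjective scores so
    far and keeps refitting on subsequent images until its error drops
    below the threshold.
    """
    if n_init >= len(images):
        raise ValueError("need more images than the warm-up size")
    params = {**DEFAULT_FOREST_PARAMS, **(forest_params or {})}
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(images))
    frac = images[list(CLASS_NAMES)].to_numpy(float)
    ids = images["point_id"].to_numpy()

    def refit(upto: int) -> StressForestResults:
        # seed keyed to the presentation index, so a refit at position k is
        # reproducible independently of how many refits preceded it
        fit_seed = int(np.random.SeedSequence((0 if seed is None else seed, upto))
                       .generate_state(1)[0] % (2**31 - 1))
        rows = order[: upto + 1]
        forest = StressForest(
            n_trees=params["n_trees"],
            mtry=params["mtry"],
            min_leaf=params["min_leaf"],
            max_depth=params["max_depth"],
            seed=fit_seed,
        )
        return forest.fit(frac[rows], np.array(subjective[: upto + 1]))

    subjective: list[float] = []
    records = []
    for k in range(n_init):
        row = order[k]
        s = float(rater.rate(frac[row]))
        subjective.append(s)
        records.append({"image_id": ids[row], "subjective": s,
                        "predicted": np.nan, "phase": "warmup"})
    results = refit(n_init - 1)

    interventions = 0
    run_length = 0
    intervening = False
    for k in range(n_init, len(images)):
        row = order[k]
        pred = float(results.predict(frac[row][None, :])[0])
        s = float(rater.rate(frac[row]))
        subjective.append(s)
        exceeds = abs(pred - s) > err_thresh
        if intervening:
            phase = "intervene"
            if abs(pred - s) < err_thresh:
                intervening = False
                phase = "predict"
                run_length = 0
            else:
                results = refit(k)
        else:
            phase = "predict"
            run_length = run_length + 1 if exceeds else 0
            if run_length >= streak:
                interventions += 1
                intervening = True
                phase = "intervene"
                results = refit(k)
                run_length = 0
        records.append({"image_id": ids[row], "subjective": s,
                        "predicted": pred, "phase": phase})

    final = pd.Series(results.predict(frac), index=pd.Index(ids, name="image_id"))
    return ScoringSession(
        rater_id=getattr(rater, "rater_id", "rater"),
        records=pd.DataFrame(records),
        interventions=interventions,
        final_scores=final,
        results=results,
    )


def consensus_scores(sessions: Sequence[ScoringSession], weights=None) -> pd.Series:
    """Weighted mean of per-rater final scores (weights normalized to sum 1).

    All sessions must cover the same image set; weights default to uniform.
    """
    if not sessions:
        raise ValueError("no sessions")
    index = sessions[0].final_scores.index
    base = set(index)
    for s in sessions[1:]:
        if set(s.final_scores.index) != base:
            raise ValueError("sessions cover different image sets")
    if weights is None:
        weights = np.ones(len(sessions))
    weights = np.asarray(weights, float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    weights = weights / weights.sum()
    out = sum(w * s.final_scores.reindex(index) for w, s in zip(weights, sessions))
    out.name = "consensus_score"
    return out


def evaluate_holdout(
    X,
    y,
    train_frac: float = 0.667,
    forest_params: dict | None = None,
    seed: int | None = None,
) -> AccuracyReport:
    """Train/holdout evaluation of the forest on consensus scores.

    A seeded random split assigns round(train_frac * n) samples to training;
    the report carries the held-out mean absolute error (score units and %
    of the 100-point scale) and RMSE, plus the training fit's OOB metrics.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 samples")
    n_train = int(round(train_frac * n))
    if n_train < 2 or n_train >= n:
        raise ValueError("degenerate train/test split")
    params = {**DEFAULT_FOREST_PARAMS, **(forest_params or {})}
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train, test = perm[:n_train], perm[n_train:]
    forest = StressForest(
        n_trees=params["n_trees"],
        mtry=params["mtry"],
        min_leaf=params["min_leaf"],
        max_depth=params["max_depth"],
        seed=int(rng.integers(2**31 - 1)),
    )
    results = forest.fit(X[train], y[train])
    err = results.predict(X[test]) - y[test]
    mae = float(np.abs(err).mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        oob_pct, oob_rmse = results.oob_error()
    return AccuracyReport(
        mean_abs_error=mae,
        mean_abs_error_pct=mae,
        rmse=float(np.sqrt((err**2).mean())),
        oob_error_pct=oob_pct,
        oob_rmse=oob_rmse,
    )
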