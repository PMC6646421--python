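"""Per-cell-line synergy regressors and tree-variance reliability.

Three algorithm families are supported:

``rf``
    Random forest.  Default preset: 250 trees with a third of the features
    tried per split.  The "baseline" preset (1000 trees, all features)
    mirrors the untuned starting configuration of the exploratory ladder.
``xgb``
    Gradient-boosted trees (XGBoost) with a fixed "recommended" preset and
    a small tuning grid.
``en``
    Elastic net, the linear baseline.

Forests additionally expose a per-prediction reliability score, tree_SD:
the population standard deviation of the individual tree predictions for a
given input.  Low tree_SD flags predictions the forest agrees on, which
empirically are the more accurate ones.

Inference is symmetrized: every prediction is the mean of the model output
on both drug orders, which makes predictions exactly invariant to the order
of the pair.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet
from xgboost import XGBRegressor

from .dataset import PairSample, augment_reverse, random_split

RF_DEFAULT = {"n_trees": 250, "features_per_split": 1 / 3}
RF_BASELINE = {"n_trees": 1000, "features_per_split": 1.0}
XGB_RECOMMENDED = {
    "n_estimators": 200,
    "learning_rate": 0.1,
    "max_depth": 6,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
}
XGB_TUNING_GRID = [
    {"n_estimators": 200, "learning_rate": 0.1, "max_depth": 4},
    {"n_estimators": 200, "learning_rate": 0.1, "max_depth": 6},
    {"n_estimators": 400, "learning_rate": 0.05, "max_depth": 6},
    {"n_estimators": 400, "learning_rate": 0.1, "max_depth": 8},
]
EN_DEFAULT = {"alpha": 1.0, "l1_ratio": 0.5}


@dataclass
class ModelSpec:
    """Algorithm choice, hyperparameters and seed for one model."""

    algorithm: str = "rf"
    hyperparams: dict = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("rf", "xgb", "en"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        defaults = {"rf": RF_DEFAULT, "xgb": XGB_RECOMMENDED, "en": EN_DEFAULT}[
            self.algorithm
        ]
        self.hyperparams = {**defaults, **self.hyperparams}
        if self.algorithm == "rf":
            if self.hyperparams["n_trees"] < 1:
                raise ValueError("n_trees must be >= 1")
            if not 0 < self.hyperparams["features_per_split"] <= 1:
                raise ValueError("features_per_split must be in (0, 1]")


@dataclass
class Prediction:
    """Point estimate for one pair, with tree_SD when from a forest."""

    drug_a: str
    drug_b: str
    cell_line: str
    y_pred: float
    tree_sd: float | None = None


def _feature_space_hash(n_features: int, descriptor: str) -> str:
    h = hashlib.sha256(f"{n_features}|{descriptor}".encode()).hexdigest()[:16]
    return h


@dataclass
class TrainedModel:
    """A fitted per-cell-line regressor bound to its feature space."""

    spec: ModelSpec
    cell_line: str
    n_features: int
    feature_space_hash: str
    learner: object = dc_field(repr=False, default=None)

    def _check(self, x: np.ndarray) -> None:
        if x.shape[1] != self.n_features:
            other = _feature_space_hash(x.shape[1], "")
            raise ValueError(
                f"feature space mismatch: model trained on {self.n_features} "
                f"features (hash {self.feature_space_hash}), got {x.shape[1]} "
                f"(hash {other})"
            )

    @property
    def trees(self) -> list:
        if self.spec.algorithm != "rf":
            raise ValueError("per-tree access requires a random forest model")
        return self.learner.estimators_


def train(
    samples: list[PairSample],
    spec: ModelSpec,
    feature_space: str = "",
    augment: bool = True,
) -> TrainedModel:
    """Fit a regressor on a training table.

    Training rows are reverse-order augmented by default (doubling the
    table) so the learner sees both drug orders.  Deterministic for a given
    spec seed.  Constant targets train but warn, since correlation metrics
    will be degenerate.
    """
    if not samples:
        raise ValueError("empty training set")
    rows = augment_reverse(samples) if augment else list(samples)
    x = np.vstack([s.features for s in rows])
    y = np.array([s.target for s in rows])
    if len(samples) >= 2 and np.ptp(y) == 0:
        warnings.warn("constant training targets; metrics will be degenerate", stacklevel=2)
    hp = spec.hyperparams
    if spec.algorithm == "rf":
        learner = RandomForestRegressor(
            n_estimators=hp["n_trees"],
            max_features=hp["features_per_split"],
            random_state=spec.seed,
            n_jobs=1,
        )
    elif spec.algorithm == "xgb":
        learner = XGBRegressor(
            n_estimators=hp["n_estimators"],
            learning_rate=hp["learning_rate"],
            max_depth=hp["max_depth"],
            subsample=hp.get("subsample", 1.0),
            colsample_bytree=hp.get("colsample_bytree", 1.0),
            random_state=spec.seed,
            n_jobs=1,
            verbosity=0,
        )
    else:
        learner = ElasticNet(
            alpha=hp["alpha"], l1_ratio=hp["l1_ratio"], random_state=spec.seed,
            max_iter=5000,
        )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Objective did not converge.*")
        learner.fit(x, y)
    cell = samples[0].cell_line
    return TrainedModel(
        spec=spec,
        cell_line=cell,
        n_features=x.shape[1],
        feature_space_hash=_feature_space_hash(x.shape[1], feature_space),
        learner=learner,
    )


def _both_orders(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    half = x.shape[1] // 2
    return x, np.hstack([x[:, half:], x[:, :half]])


def predict(model: TrainedModel, samples: list[PairSample]) -> list[Prediction]:
    """Symmetrized predictions (mean over both drug orders), with tree_SD
    attached for forests."""
    if not samples:
        return []
    x = np.vstack([s.features for s in samples])
    model._check(x)
    fwd, rev = _both_orders(x)
    if model.spec.algorithm == "rf":
        # per-tree predictions on both orders: (T, n) each
        tf = np.vstack([t.predict(fwd) for t in model.trees])
        tr = np.vstack([t.predict(rev) for t in model.trees])
        y = (tf.mean(axis=0) + tr.mean(axis=0)) / 2.0
        sd = (tf.std(axis=0) + tr.std(axis=0)) / 2.0
        return [
            Prediction(s.drug_a, s.drug_b, s.cell_line, float(yi), float(si))
            for s, yi, si in zip(samples, y, sd)
        ]
    y = (model.learner.predict(fwd) + model.learner.predict(rev)) / 2.0
    return [
        Prediction(s.drug_a, s.drug_b, s.cell_line, float(yi))
        for s, yi in zip(samples, y)
    ]


def tree_sd(model: TrainedModel, sample: PairSample) -> float:
    """Population SD of the per-tree predictions, averaged over drug orders."""
    if model.spec.algorithm != "rf":
        raise ValueError("tree_sd requires a random forest model")
    return predict(model, [sample])[0].tree_sd


def reliability_strata(
    predictions: list[Prediction], q: float = 0.25
) -> dict[str, np.ndarray]:
    """Index sets of the most/least reliable predictions by tree_SD.

    ``most_reliable`` holds the floor(qN) indices with lowest tree_SD,
    ``least_reliable`` the floor(qN) highest; ties break by input order.
    """
    if any(p.tree_sd is None for p in predictions):
        raise ValueError("all predictions must carry tree_sd")
    n = len(predictions)
    m = int(np.floor(q * n))
    order = np.argsort([p.tree_sd for p in predictions], kind="stable")
    return {
        "most_reliable": np.sort(order[:m]),
        "all": np.arange(n),
        "least_reliable": np.sort(order[n - m :]) if m > 0 else np.array([], dtype=int),
    }


def tune_xgb(
    samples: list[PairSample],
    grid: list[dict] | None = None,
    seed: int = 0,
    inner_fraction: float = 0.1,
) -> ModelSpec:
    """Pick the grid point with the best inner-validation Pearson r.

    Uses a single inner 90/10 split of the training table only; the outer
    test set is never consulted.
    """
    grid = grid if grid is not None else XGB_TUNING_GRID
    if not grid:
        raise ValueError("empty tuning grid")
    inner = random_split(samples, test_fraction=inner_fraction, seed=seed)
    tr = [samples[i] for i in inner.train_idx]
    va = [samples[i] for i in inner.test_idx]
    if not tr or not va:
        raise ValueError("tuning grid exhausts the training data")
    y_va = np.array([s.target for s in va])
    best, best_score = None, -np.inf
    for point in grid:
        spec = ModelSpec("xgb", dict(point), seed=seed)
        model = train(tr, spec)
        y_hat = np.array([p.y_pred for p in predict(model, va)])
        if np.ptp(y_va) == 0 or np.ptp(y_hat) == 0:
            score = -np.inf
        else:
            score = float(np.corrcoef(y_va, y_hat)[0, 1])
        if score > best_score:
            best, best_score = spec, score
    return best
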