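"""Five-regressor volume-prediction benchmark.

The protocol: three independent random 70/30 train/test resamples of the
(n x 23) dataset; on each split every regressor is fitted on the training
portion and scored by mean absolute error (MAE, mm^3) on the test portion.
The contenders mirror the original bench:

* ordinary linear regression,
* 2nd-order polynomial regression (degree-2 feature expansion + OLS —
  ~300 terms on ~31 training rows, expected to overfit badly),
* a 23-12-10-1 feed-forward neural network (ReLU/ReLU/linear, MSE loss,
  Adam optimizer),
* an unlimited-depth decision tree,
* a 10-estimator random forest.

Features are standardized (fit on the training split only) for the linear,
polynomial and neural-net models, whose raw inputs span four orders of
magnitude; tree models receive raw features.  The neural net additionally
standardizes the target internally and de-standardizes its predictions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.tree import DecisionTreeRegressor

from .device import DEFAULT_ML_PER_PULSE
from .features import Dataset

REGRESSOR_KINDS = ("linear", "poly2", "neural_net", "decision_tree", "random_forest")

#: Default split seeds of the three resamples.
DEFAULT_SEEDS: tuple[int, int, int] = (11, 23, 42)

#: Default test fraction of each resample.
DEFAULT_TEST_SIZE = 0.30


class TrainingError(RuntimeError):
    """Neural-network training diverged (non-finite loss)."""


@dataclass(frozen=True)
class RegressorSpec:
    """One bench contender: a model family plus hyperparameter overrides."""

    kind: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in REGRESSOR_KINDS:
            raise ValueError(
                f"unknown regressor kind {self.kind!r}; expected one of "
                f"{REGRESSOR_KINDS}"
            )


def default_specs() -> list[RegressorSpec]:
    return [RegressorSpec(kind) for kind in REGRESSOR_KINDS]


def mae(predicted, truth) -> float:
    """Mean absolute error between two equal-length volume vectors."""
    p = np.asarray(predicted, dtype=float).ravel()
    t = np.asarray(truth, dtype=float).ravel()
    if p.size != t.size:
        raise ValueError(f"length mismatch: {p.size} predictions vs {t.size} truths")
    if p.size < 1:
        raise ValueError("need at least one value")
    return float(np.mean(np.abs(p - t)))


def floor2(x: float) -> float:
    """Truncate toward zero at 2 decimals — the report-table convention
    (printed averages are floored, not rounded)."""
    return math.trunc(x * 100.0) / 100.0


class NeuralNetVolumeRegressor:
    """Committee of 23-12-10-1 networks predicting per-pulse calibration.

    Each member is an MLP (two ReLU hidden layers of 12 and 10 units, linear
    output, MSE loss, Adam optimizer).  Three measures adapt the
    architecture to the tiny training sets of the bench (~31 rows):

    * the regression target is the event's volume per pulse relative to the
      nominal sensor quantum (``y / (q0 * puc)``) rather than raw volume —
      the network models the calibration drift, and the prediction is
      mapped back to mm^3 through the pulse count;
    * inputs are standardized on training statistics, with the 20 time-slot
      columns scaled by their *pooled* standard deviation (they are one
      physical quantity; per-column standardization would amplify the
      late, nearly constant slots into pure-noise inputs);
    * predictions are averaged over ``n_members`` random initializations,
      damping the interpolation variance of individual small-data fits.

    A zero-variance target short-circuits to a constant predictor.
    """

    def __init__(
        self,
        n_members: int = 10,
        alpha: float = 1e-2,
        epochs: int = 1500,
        batch_size: int = 8,
        learning_rate_init: float = 1e-3,
        patience: int = 100,
        random_state: int = 0,
    ) -> None:
        self.n_members = n_members
        self.alpha = alpha
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate_init = learning_rate_init
        self.patience = patience
        self.random_state = random_state

    # feature layout: column 0 = puc, columns 1..20 = time slots
    _TS = slice(1, 21)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self._mu) / self._sd

    def fit(self, X, y) -> "NeuralNetVolumeRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        self._q0 = 1000.0 * DEFAULT_ML_PER_PULSE  # mm^3 per nominal pulse
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        ts_sd = X[:, self._TS].std()
        if ts_sd > 0:
            sd[self._TS] = ts_sd
        self._sd = sd
        self._const = float(y[0]) if np.ptp(y) == 0 else None
        if self._const is not None:
            return self
        ratio = y / (self._q0 * X[:, 0])
        self._ry = StandardScaler().fit(ratio[:, None])
        Z = self._transform(X)
        target = self._ry.transform(ratio[:, None]).ravel()
        self._members = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for r in range(self.n_members):
                member = MLPRegressor(
                    hidden_layer_sizes=(12, 10),
                    activation="relu",
                    solver="adam",
                    alpha=self.alpha,
                    learning_rate_init=self.learning_rate_init,
                    batch_size=min(self.batch_size, len(y)),
                    max_iter=self.epochs,
                    n_iter_no_change=self.patience,
                    tol=1e-9,
                    random_state=int(
                        np.random.SeedSequence(
                            [int(self.random_state), r]
                        ).generate_state(1)[0]
                    ),
                )
                member.fit(Z, target)
                if not np.isfinite(member.loss_):
                    raise TrainingError(
                        f"neural-net training diverged: member {r} final "
                        f"loss {member.loss_!r} (random_state="
                        f"{self.random_state}, n={len(y)})"
                    )
                self._members.append(member)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._const is not None:
            return np.full(X.shape[0], self._const)
        Z = self._transform(X)
        ratio_std = np.mean([m.predict(Z) for m in self._members], axis=0)
        ratio = self._ry.inverse_transform(ratio_std[:, None]).ravel()
        return ratio * self._q0 * X[:, 0]


def build_regressor(spec: RegressorSpec, random_state: int = 0):
    """Instantiate the sklearn estimator behind one bench spec."""
    hp = dict(spec.hyperparams)
    if spec.kind == "linear":
        return Pipeline(
            [("scale", StandardScaler()), ("ols", LinearRegression(**hp))]
        )
    if spec.kind == "poly2":
        degree = hp.pop("degree", 2)
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("poly", PolynomialFeatures(degree=degree, include_bias=False)),
                ("ols", LinearRegression(**hp)),
            ]
        )
    if spec.kind == "neural_net":
        return NeuralNetVolumeRegressor(random_state=random_state, **hp)
    if spec.kind == "decision_tree":
        return DecisionTreeRegressor(random_state=random_state, **hp)
    if spec.kind == "random_forest":
        hp.setdefault("n_estimators", 10)
        return RandomForestRegressor(random_state=random_state, **hp)
    raise ValueError(f"unknown regressor kind {spec.kind!r}")


def fit_neural_net(X_train, y_train, random_state: int = 0, **overrides):
    """Fit the 23-12-10-1 volume network and return the fitted predictor.

    Inputs and target are standardized internally (training statistics
    only); predictions come back in mm^3.  Raises :class:`TrainingError`
    if any committee member's final loss is non-finite.
    """
    model = NeuralNetVolumeRegressor(random_state=random_state, **overrides)
    return model.fit(np.asarray(X_train, float),
                     np.asarray(y_train, float).ravel())


@dataclass(frozen=True)
class BenchResult:
    """Per-fold and average test MAE of every contender (mm^3)."""

    per_fold_mae: np.ndarray          # (n_folds, n_regressors)
    kinds: tuple[str, ...]
    seeds: tuple[int, ...]
    split_ratio: float = DEFAULT_TEST_SIZE

    def __post_init__(self) -> None:
        pf = np.asarray(self.per_fold_mae, dtype=float)
        object.__setattr__(self, "per_fold_mae", pf)
        if pf.ndim != 2 or pf.shape[1] != len(self.kinds):
            raise ValueError("per_fold_mae must be (n_folds, n_regressors)")

    @property
    def average_mae(self) -> np.ndarray:
        """Arithmetic mean of the fold MAEs, per regressor."""
        return self.per_fold_mae.mean(axis=0)

    def to_frame(self, printed: bool = False) -> pd.DataFrame:
        """Bench table: one row per fold plus an Average row.

        With ``printed=True`` every cell is floored at two decimals, the
        report-table convention.
        """
        rows = np.vstack([self.per_fold_mae, self.average_mae])
        if printed:
            rows = np.vectorize(floor2)(rows)
        index = [f"fold{i + 1}" for i in range(self.per_fold_mae.shape[0])]
        return pd.DataFrame(rows, index=index + ["Average"], columns=list(self.kinds))

    def to_csv(self, path, printed: bool = True) -> None:
        self.to_frame(printed=printed).to_csv(path, index_label="Folding")

    def best_kind(self) -> str:
        return self.kinds[int(np.argmin(self.average_mae))]


def run_bench(
    data: Dataset,
    specs: list[RegressorSpec] | None = None,
    seeds: tuple[int, ...] = DEFAULT_SEEDS,
    test_size: float = DEFAULT_TEST_SIZE,
) -> BenchResult:
    """Run the randomized 70/30 resampling benchmark.

    Each seed defines one independent random split (not a k-fold
    partition); all contenders see the same split.  Deterministic given
    ``seeds``.
    """
    if specs is None:
        specs = default_specs()
    if data.n < 10:
        raise ValueError(f"dataset too small for a 70/30 bench: n={data.n}")
    n_test = int(np.ceil(data.n * test_size))
    if n_test < 1 or n_test >= data.n:
        raise ValueError(f"degenerate split: test fraction {test_size} of {data.n}")
    per_fold = np.empty((len(seeds), len(specs)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i, seed in enumerate(seeds):
            X_tr, X_te, y_tr, y_te = train_test_split(
                data.X, data.y, test_size=test_size, random_state=int(seed)
            )
            for j, spec in enumerate(specs):
                if spec.kind == "neural_net":
                    model = fit_neural_net(X_tr, y_tr, random_state=int(seed),
                                           **spec.hyperparams)
                else:
                    model = build_regressor(spec, random_state=int(seed))
                    model.fit(X_tr, y_tr)
                per_fold[i, j] = mae(model.predict(X_te), y_te)
    return BenchResult(
        per_fold_mae=per_fold,
        kinds=tuple(s.kind for s in specs),
        seeds=tuple(int(s) for s in seeds),
        split_ratio=test_size,
    )


__all__ = [
    "NeuralNetVolumeRegressor", "REGRESSOR_KINDS", "DEFAULT_SEEDS", "DEFAULT_TEST_SIZE", "TrainingError",
    "RegressorSpec", "default_specs", "mae", "floor2", "build_regressor",
    "fit_neural_net", "BenchResult", "run_bench",
]
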