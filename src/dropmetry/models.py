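"""Regression harness for print-parameter -> droplet-volume prediction.

Five algorithms are compared on the same footing: decision tree, random
forest, polynomial regression, a multilayer perceptron and an LSTM.  The
harness provides the seeded 70/30 split, 10-fold cross-validation,
exhaustive grid search over hyperparameters (selection by mean validation
RMSE, ties toward the simpler model), the four evaluation metrics
(MAE, MSE, RMSE, R^2), wall-clock train/test timing, and normalized
impurity-based feature importance from the random forest.

Features are the five print parameters; the target is droplet volume in
uL.  Tree models consume raw features (scale-invariant); polynomial
regression, the MLP and the LSTM standardize features, and the two neural
models additionally standardize the target (inverted at predict time).

The LSTM is implemented natively in numpy: tabular records carry no real
temporal ordering, so each record is presented as a length-one sequence of
the five-feature vector to a single recurrent layer (32 units) with a
scalar linear head, trained by Adam on mean-squared error.
"""

from __future__ import annotations

import itertools
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.tree import DecisionTreeRegressor

from .synthetic import PrintRecord

__all__ = [
    "ALGORITHMS",
    "FEATURES",
    "TARGET",
    "ConfigError",
    "ModelSpec",
    "SplitResult",
    "CVResult",
    "MetricsReport",
    "ImportanceReport",
    "TrainedModel",
    "LSTMRegressor",
    "default_spec",
    "records_to_xy",
    "split_dataset",
    "kfold_cv",
    "grid_search",
    "fit",
    "evaluate",
    "feature_importance",
    "compare_algorithms",
]

FEATURES = [
    "viscosity_mPa_s",
    "nozzle_id_mm",
    "printing_time_s",
    "pressure_psi",
    "cell_conc_per_mL",
]
TARGET = "volume_uL"

ALGORITHMS = ("decision_tree", "random_forest", "polynomial_regression", "mlp", "lstm")

#: hyperparameters each algorithm must declare
_REQUIRED = {
    "decision_tree": ("max_depth",),
    "random_forest": (
        "n_estimators",
        "criterion",
        "max_depth",
        "min_samples_split",
        "min_samples_leaf",
    ),
    "polynomial_regression": ("degree",),
    "mlp": ("epochs", "learning_rate", "batch_size", "hidden_layer_sizes"),
    "lstm": ("epochs", "learning_rate", "batch_size", "hidden_units"),
}

#: the complexity knob used for tie-breaking in grid search
_COMPLEXITY_KEY = {
    "decision_tree": "max_depth",
    "random_forest": "n_estimators",
    "polynomial_regression": "degree",
    "mlp": "epochs",
    "lstm": "epochs",
}


class ConfigError(ValueError):
    """Invalid harness configuration (split fraction, fold count, grid)."""


@dataclass(frozen=True)
class ModelSpec:
    """An algorithm plus its hyperparameters and training seed."""

    algorithm: str
    hyperparameters: dict
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        missing = [
            k for k in _REQUIRED[self.algorithm] if k not in self.hyperparameters
        ]
        if missing:
            raise ConfigError(
                f"{self.algorithm} spec is missing hyperparameters: {missing}"
            )

    def with_seed(self, seed: int) -> "ModelSpec":
        return ModelSpec(self.algorithm, dict(self.hyperparameters), seed)


def default_spec(algorithm: str, seed: int = 0) -> ModelSpec:
    """The tuned defaults: DT depth 7, RF with 10 estimators, degree-7
    polynomial, and 100-epoch MLP/LSTM."""
    defaults = {
        "decision_tree": {"max_depth": 7},
        "random_forest": {
            "n_estimators": 10,
            "criterion": "squared_error",
            "max_depth": None,
            "min_samples_split": 2,
            "min_samples_leaf": 1,
        },
        "polynomial_regression": {"degree": 7},
        "mlp": {
            "epochs": 100,
            "learning_rate": 1e-3,
            "batch_size": 32,
            "hidden_layer_sizes": (64, 32),
        },
        "lstm": {
            "epochs": 100,
            "learning_rate": 1e-3,
            "batch_size": 32,
            "hidden_units": 32,
        },
    }
    if algorithm not in defaults:
        raise ConfigError(f"unknown algorithm {algorithm!r}")
    return ModelSpec(algorithm, defaults[algorithm], seed)


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.reset_index(drop=True)
    rows = [
        {f: getattr(r, f) for f in FEATURES} | {TARGET: r.volume_uL} for r in records
    ]
    return pd.DataFrame(rows, columns=FEATURES + [TARGET])


def records_to_xy(records) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (n, 5) and volume target (n,) from records."""
    df = _as_frame(records)
    return df[FEATURES].to_numpy(float), df[TARGET].to_numpy(float)


@dataclass(frozen=True)
class SplitResult:
    train_records: pd.DataFrame
    test_records: pd.DataFrame
    fraction: float
    seed: int


def split_dataset(records, fraction: float = 0.7, seed: int = 0) -> SplitResult:
    """Seeded uniform shuffle, then split at ``floor(fraction * n)``.

    1758 records at the default 70/30 split yield 1230 train / 528 test.
    """
    if not (0.0 < fraction < 1.0):
        raise ConfigError(f"fraction must be in (0, 1), got {fraction}")
    df = _as_frame(records)
    n = len(df)
    if n < 10:
        raise ConfigError(f"need at least 10 records to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(fraction * n))
    return SplitResult(
        train_records=df.iloc[perm[:n_train]].reset_index(drop=True),
        test_records=df.iloc[perm[n_train:]].reset_index(drop=True),
        fraction=fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class LSTMRegressor:
    """Textbook LSTM regressor with a scalar linear head.

    A generic single-layer LSTM: per-gate input weights ``W_*``, recurrent
    weights ``U_*`` and biases, unrolled over the input sequence with full
    backpropagation through time, trained with Adam on mean-squared error.
    Tabular inputs of shape (n, features) are treated as length-one
    sequences; (n, T, features) arrays are consumed as-is.  Features and
    target are standardized internally (target scaling inverted at predict
    time).  Fully deterministic given ``seed``.
    """

    _GATES = ("i", "f", "g", "o")

    def __init__(
        self,
        hidden_units: int = 32,
        epochs: int = 100,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        seed: int = 0,
    ) -> None:
        self.hidden_units = int(hidden_units)
        self.epochs = int(epochs)
        self.learning_rate = float(learning_rate)
        self.batch_size = int(batch_size)
        self.seed = int(seed)

    # -- internals ---------------------------------------------------------

    def _init_params(self, n_features: int, rng: np.random.Generator) -> dict:
        hu = self.hidden_units
        lim_w = np.sqrt(6.0 / (n_features + hu))
        lim_u = np.sqrt(6.0 / (2 * hu))
        p: dict = {}
        for gate in self._GATES:
            p[f"W{gate}"] = rng.uniform(-lim_w, lim_w, (hu, n_features))
            p[f"U{gate}"] = rng.uniform(-lim_u, lim_u, (hu, hu))
            p[f"b{gate}"] = np.zeros(hu)
        p["bf"] = np.ones(self.hidden_units)  # forget-gate bias init
        p["wy"] = rng.uniform(-lim_u, lim_u, hu)
        p["by"] = np.zeros(1)
        return p

    @staticmethod
    def _sigmoid(z: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def _forward(self, x: np.ndarray, p: dict) -> tuple[np.ndarray, list]:
        """Unroll over time; returns predictions and per-step caches."""
        n, n_steps, _ = x.shape
        hu = self.hidden_units
        h = np.zeros((n, hu))
        c = np.zeros((n, hu))
        caches = []
        for t in range(n_steps):
            xt = x[:, t, :]
            i = self._sigmoid(xt @ p["Wi"].T + h @ p["Ui"].T + p["bi"])
            f = self._sigmoid(xt @ p["Wf"].T + h @ p["Uf"].T + p["bf"])
            g = np.tanh(xt @ p["Wg"].T + h @ p["Ug"].T + p["bg"])
            o = self._sigmoid(xt @ p["Wo"].T + h @ p["Uo"].T + p["bo"])
            c_new = f * c + i * g
            hc = np.tanh(c_new)
            h_new = o * hc
            caches.append(
                {"x": xt, "h_prev": h, "c_prev": c, "i": i, "f": f, "g": g,
                 "o": o, "c": c_new, "hc": hc}
            )
            h, c = h_new, c_new
        yhat = h @ p["wy"] + p["by"][0]
        return yhat, caches

    def _backward(self, caches: list, yhat, y, p: dict) -> dict:
        n = len(y)
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dyhat = 2.0 * (yhat - y) / n
        h_last = caches[-1]["o"] * caches[-1]["hc"]
        grads["wy"] = h_last.T @ dyhat
        grads["by"] = np.array([dyhat.sum()])
        dh = np.outer(dyhat, p["wy"])
        dc = np.zeros_like(dh)
        for cache in reversed(caches):
            do = dh * cache["hc"]
            dc = dc + dh * cache["o"] * (1.0 - cache["hc"] ** 2)
            di = dc * cache["g"]
            df = dc * cache["c_prev"]
            dg = dc * cache["i"]
            dzi = di * cache["i"] * (1.0 - cache["i"])
            dzf = df * cache["f"] * (1.0 - cache["f"])
            dzg = dg * (1.0 - cache["g"] ** 2)
            dzo = do * cache["o"] * (1.0 - cache["o"])
            for gate, dz in zip(self._GATES, (dzi, dzf, dzg, dzo)):
                grads[f"W{gate}"] += dz.T @ cache["x"]
                grads[f"U{gate}"] += dz.T @ cache["h_prev"]
                grads[f"b{gate}"] += dz.sum(axis=0)
            dh = (
                dzi @ p["Ui"] + dzf @ p["Uf"] + dzg @ p["Ug"] + dzo @ p["Uo"]
            )
            dc = dc * cache["f"]
        return grads

    @staticmethod
    def _as_sequences(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        return X[:, None, :] if X.ndim == 2 else X

    # -- sklearn-style surface --------------------------------------------

    def fit(self, X, y) -> "LSTMRegressor":
        xseq = self._as_sequences(X)
        y = np.asarray(y, float).ravel()
        flat = xseq.reshape(-1, xseq.shape[-1])
        self._x_mean = flat.mean(axis=0)
        std = flat.std(axis=0)
        self._x_std = np.where(std > 0, std, 1.0)
        self._y_mean = y.mean()
        self._y_std = y.std() if y.std() > 0 else 1.0
        xs = (xseq - self._x_mean) / self._x_std
        ys = (y - self._y_mean) / self._y_std

        rng = np.random.default_rng(self.seed)
        p = self._init_params(xseq.shape[-1], rng)
        m = {k: np.zeros_like(v) for k, v in p.items()}
        v = {k: np.zeros_like(val) for k, val in p.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = len(ys)
        for _ in range(self.epochs):
            perm = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = perm[start : start + self.batch_size]
                yhat, caches = self._forward(xs[idx], p)
                grads = self._backward(caches, yhat, ys[idx], p)
                t += 1
                for k in p:
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                    mh = m[k] / (1 - b1**t)
                    vh = v[k] / (1 - b2**t)
                    p[k] = p[k] - self.learning_rate * mh / (np.sqrt(vh) + eps)
        self._params = p
        return self

    def predict(self, X) -> np.ndarray:
        xs = (self._as_sequences(X) - self._x_mean) / self._x_std
        yhat, _ = self._forward(xs, self._params)
        return yhat * self._y_std + self._y_mean


def build_estimator(spec: ModelSpec):
    """Instantiate the (unfitted) estimator for a spec."""
    hp = spec.hyperparameters
    if spec.algorithm == "decision_tree":
        return DecisionTreeRegressor(max_depth=hp["max_depth"], random_state=spec.seed)
    if spec.algorithm == "random_forest":
        return RandomForestRegressor(
            n_estimators=hp["n_estimators"],
            criterion=hp["criterion"],
            max_depth=hp["max_depth"],
            min_samples_split=hp["min_samples_split"],
            min_samples_leaf=hp["min_samples_leaf"],
            random_state=spec.seed,
        )
    if spec.algorithm == "polynomial_regression":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("poly", PolynomialFeatures(degree=hp["degree"])),
                ("ols", LinearRegression()),
            ]
        )
    if spec.algorithm == "mlp":
        mlp = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPRegressor(
                        hidden_layer_sizes=tuple(hp["hidden_layer_sizes"]),
                        activation="relu",
                        solver="adam",
                        learning_rate_init=hp["learning_rate"],
                        batch_size=hp["batch_size"],
                        max_iter=hp["epochs"],
                        n_iter_no_change=hp["epochs"],  # run every epoch
                        random_state=spec.seed,
                    ),
                ),
            ]
        )
        return TransformedTargetRegressor(regressor=mlp, transformer=StandardScaler())
    if spec.algorithm == "lstm":
        return LSTMRegressor(
            hidden_units=hp["hidden_units"],
            epochs=hp["epochs"],
            learning_rate=hp["learning_rate"],
            batch_size=hp["batch_size"],
            seed=spec.seed,
        )
    raise ConfigError(f"unknown algorithm {spec.algorithm!r}")


@dataclass
class TrainedModel:
    """A fitted estimator plus its spec and training time."""

    spec: ModelSpec
    estimator: object
    train_time_ms: float

    def predict(self, records_or_X) -> np.ndarray:
        if isinstance(records_or_X, np.ndarray):
            X = records_or_X
        else:
            X, _ = records_to_xy(records_or_X)
        return np.asarray(self.estimator.predict(X), float).ravel()


def fit(train_records, spec: ModelSpec) -> TrainedModel:
    """Train one model on the records, recording wall-clock training time."""
    X, y = records_to_xy(train_records)
    if len(y) == 0:
        raise ConfigError("cannot fit on an empty training set")
    est = build_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP max_iter convergence chatter
        t0 = time.perf_counter()
        est.fit(X, y)
        dt = (time.perf_counter() - t0) * 1e3
    return TrainedModel(spec=spec, estimator=est, train_time_ms=dt)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    """MAE/MSE/RMSE/R^2 (volume units; R^2 dimensionless) plus timings."""

    mae: float
    mse: float
    rmse: float
    r2: float
    train_time_ms: float = float("nan")
    test_time_ms: float = float("nan")


def _metrics(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float, float, float]:
    err = y - yhat
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("zero-variance target: R^2 undefined, reporting NaN")
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return mae, mse, rmse, r2


def evaluate(model: TrainedModel, test_records) -> MetricsReport:
    """Score a trained model on held-out records.

    R^2 is ``1 - SS_res / SS_tot`` and may be negative for predictors
    worse than the constant mean.
    """
    X, y = records_to_xy(test_records)
    if len(y) == 0:
        raise ConfigError("cannot evaluate on an empty test set")
    t0 = time.perf_counter()
    yhat = np.asarray(model.estimator.predict(X), float).ravel()
    dt = (time.perf_counter() - t0) * 1e3
    mae, mse, rmse, r2 = _metrics(y, yhat)
    return MetricsReport(
        mae=mae,
        mse=mse,
        rmse=rmse,
        r2=r2,
        train_time_ms=model.train_time_ms,
        test_time_ms=dt,
    )


# ---------------------------------------------------------------------------
# cross-validation and grid search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVResult:
    """Per-fold train/validation metrics and their means / standard
    deviations over the k rounds."""

    fold_indices: tuple
    per_fold: pd.DataFrame
    means: dict
    sds: dict


def kfold_cv(train_records, spec: ModelSpec, k: int = 10, seed: int = 0) -> CVResult:
    """Seeded k-fold cross-validation of one model spec.

    The training set is partitioned into k near-equal folds; each round
    trains on k-1 folds and validates on the held-out fold, recording
    train/validation MAE, RMSE, R^2 and MSE plus wall-clock times.
    """
    df = _as_frame(train_records)
    n = len(df)
    if k < 2:
        raise ConfigError(f"k must be >= 2, got {k}")
    if k > n:
        raise ConfigError(f"k={k} exceeds the {n} training records")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), k)

    X, y = records_to_xy(df)
    rows = []
    for fold_id, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        est = build_estimator(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t0 = time.perf_counter()
            est.fit(X[train_idx], y[train_idx])
            fit_ms = (time.perf_counter() - t0) * 1e3
        t0 = time.perf_counter()
        yhat_val = np.asarray(est.predict(X[val_idx]), float).ravel()
        val_ms = (time.perf_counter() - t0) * 1e3
        yhat_tr = np.asarray(est.predict(X[train_idx]), float).ravel()
        tr = _metrics(y[train_idx], yhat_tr)
        va = _metrics(y[val_idx], yhat_val)
        rows.append(
            {
                "fold": fold_id,
                "train_mae": tr[0],
                "train_mse": tr[1],
                "train_rmse": tr[2],
                "train_r2": tr[3],
                "val_mae": va[0],
                "val_mse": va[1],
                "val_rmse": va[2],
                "val_r2": va[3],
                "train_time_ms": fit_ms,
                "val_time_ms": val_ms,
            }
        )
    per_fold = pd.DataFrame(rows)
    metric_cols = [c for c in per_fold.columns if c != "fold"]
    means = {c: float(per_fold[c].mean()) for c in metric_cols}
    sds = {c: float(per_fold[c].std(ddof=0)) for c in metric_cols}
    return CVResult(
        fold_indices=tuple(np.sort(f) for f in folds),
        per_fold=per_fold,
        means=means,
        sds=sds,
    )


def grid_search(
    train_records,
    algorithm: str,
    grid: dict,
    k: int = 10,
    seed: int = 0,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Exhaustive grid search scored by mean validation RMSE under k-fold CV.

    ``grid`` maps hyperparameter names to candidate lists; unlisted
    required hyperparameters take their defaults.  Candidates are visited
    in the given order (list grids ascending in complexity) and a strictly
    better mean val RMSE is required to displace the incumbent, so ties
    resolve toward the simpler model.  Returns the winning spec and the
    full search trace for optimization-curve plots.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ConfigError("grid must be a non-empty mapping of non-empty lists")
    base = default_spec(algorithm, seed).hyperparameters
    names = list(grid)
    trace_rows = []
    best_spec, best_rmse = None, np.inf
    for combo in itertools.product(*(grid[nm] for nm in names)):
        hp = dict(base)
        hp.update(dict(zip(names, combo)))
        spec = ModelSpec(algorithm, hp, seed)
        cv = kfold_cv(train_records, spec, k=k, seed=seed)
        trace_rows.append(
            dict(zip(names, combo))
            | {key: cv.means[key] for key in (
                "train_mae", "train_rmse", "train_r2", "train_mse",
                "val_mae", "val_rmse", "val_r2", "val_mse",
            )}
        )
        if cv.means["val_rmse"] < best_rmse:
            best_rmse = cv.means["val_rmse"]
            best_spec = spec
    return best_spec, pd.DataFrame(trace_rows)


# ---------------------------------------------------------------------------
# feature importance and model comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImportanceReport:
    """Normalized impurity-based importances of the five print parameters."""

    weights: dict

    def ranking(self) -> list[str]:
        return sorted(self.weights, key=self.weights.get, reverse=True)


def feature_importance(records, rf_spec: ModelSpec | None = None) -> ImportanceReport:
    """Random-forest variance-reduction importance, normalized to sum 1.

    Each feature's importance is the impurity (variance) reduction summed
    over the split nodes using it, averaged across trees and normalized.
    A constant target yields no splits; uniform weights are reported with
    a warning.
    """
    spec = rf_spec or default_spec("random_forest")
    X, y = records_to_xy(records)
    est = build_estimator(spec)
    est.fit(X, y)
    raw = np.asarray(est.feature_importances_, float)
    if raw.sum() <= 0:
        warnings.warn("constant target: importances undefined, reporting uniform")
        raw = np.ones(len(FEATURES))
    weights = raw / raw.sum()
    return ImportanceReport(weights=dict(zip(FEATURES, map(float, weights))))


def compare_algorithms(
    records,
    specs,
    repeats: int = 10,
    fraction: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Benchmark several model specs over repeated seeded runs.

    Each repeat re-splits the data 70/30 and re-seeds training, then
    reports mean +/- sd of MAE / RMSE / R^2 and mean train/test wall-clock
    times per algorithm.  A failure in one algorithm is recorded in its
    row and does not abort the others.
    """
    specs = list(specs)
    if not specs:
        raise ConfigError("need at least one model spec")
    df = _as_frame(records)
    rows = []
    warm = df.head(min(len(df), 64))
    for spec in specs:
        maes, rmses, r2s, fit_ms, pred_ms = [], [], [], [], []
        error = ""
        try:
            # untimed warm-up so first-call lazy initialisation does not
            # leak into the benchmarked training times
            Xw, yw = records_to_xy(warm)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                build_estimator(spec).fit(Xw, yw)
            for rep in range(repeats):
                rep_seed = seed + rep
                split = split_dataset(df, fraction=fraction, seed=rep_seed)
                model = fit(split.train_records, spec.with_seed(rep_seed))
                rep_metrics = evaluate(model, split.test_records)
                maes.append(rep_metrics.mae)
                rmses.append(rep_metrics.rmse)
                r2s.append(rep_metrics.r2)
                fit_ms.append(rep_metrics.train_time_ms)
                pred_ms.append(rep_metrics.test_time_ms)
        except Exception as exc:  # keep the comparison going
            error = f"{type(exc).__name__}: {exc}"
        if maes:
            rows.append(
                {
                    "algorithm": spec.algorithm,
                    "mae_mean": float(np.mean(maes)),
                    "mae_sd": float(np.std(maes)),
                    "rmse_mean": float(np.mean(rmses)),
                    "rmse_sd": float(np.std(rmses)),
                    "r2_mean": float(np.mean(r2s)),
                    "r2_sd": float(np.std(r2s)),
                    "train_time_ms_mean": float(np.mean(fit_ms)),
                    "test_time_ms_mean": float(np.mean(pred_ms)),
                    "status": error or "OK",
                }
            )
        else:
            rows.append(
                {
                    "algorithm": spec.algorithm,
                    "mae_mean": float("nan"),
                    "mae_sd": float("nan"),
                    "rmse_mean": float("nan"),
                    "rmse_sd": float("nan"),
                    "r2_mean": float("nan"),
                    "r2_sd": float("nan"),
                    "train_time_ms_mean": float("nan"),
                    "test_time_ms_mean": float("nan"),
                    "status": error or "no runs",
                }
            )
    return pd.DataFrame(rows)
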