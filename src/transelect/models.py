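"""Per-enzyme conversion classifiers and forward-MVLR selectivity regressors.

Because the commercial enzymes have no published sequences, each enzyme is a
separate single-task model over substrate features only.  Conversion is a
binary random-forest classification at the 25%-conversion gate; selectivity
is a forward stepwise multivariate linear regression (MVLR) on DDG that
starts from the single best-correlated feature and greedily adds the feature
giving the largest leave-one-out cross-validated R^2, stopping as soon as no
candidate improves it.  Model evaluation is leave-one-ketone-out throughout.

For a fixed feature set, the LOOCV residual of ordinary least squares has the
exact closed form e_i / (1 - h_ii) (PRESS identity), which this module uses
to score candidate features; OLS predictions are invariant to affine feature
rescaling, so this is identical to refitting each fold with fold-local
standardization.  The outer :func:`loocv` evaluation instead literally refits
the entire trainer (including feature selection) on every n-1 subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io import RunConfig, ReactionOutcome
from .thermo import DDGValue


class DegenerateTrainingError(ValueError):
    """Training labels contain a single class; caller should fall back to a
    constant prediction (with a warning) instead of fitting."""


def binarize_conversion(conversion: float, threshold: float = 25.0) -> int:
    """1 iff conversion is strictly greater than the success threshold."""
    return int(conversion > threshold)


def drop_unmeasured_ee(reactions: Sequence[ReactionOutcome]) -> list[ReactionOutcome]:
    """Keep only reactions with a measured ee; selectivity models never see
    censored rows.  The number dropped is reported via warning when all rows
    of an enzyme vanish (that enzyme is skipped downstream)."""
    kept = [r for r in reactions if r.ee_measured]
    n_dropped = len(reactions) - len(kept)
    if n_dropped and not kept:
        warnings.warn(
            f"all {n_dropped} reactions lack a measured ee; no selectivity "
            "training data remains"
        )
    return kept


# ---------------------------------------------------------------------------
# Conversion: random-forest gate
# ---------------------------------------------------------------------------

@dataclass
class ConversionModel:
    """Per-enzyme binary RF classifier for the >25%-conversion gate."""

    enzyme_id: str
    featurization_tag: str
    feature_names: list[str]
    estimator: object          # fitted sklearn RandomForestClassifier
    training_substrates: list[str]
    seed: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        proba = self.estimator.predict_proba(X)
        classes = list(self.estimator.classes_)
        if 1 not in classes:
            return np.zeros(X.shape[0])
        return proba[:, classes.index(1)]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Binary gate decision at the 0.5 probability cut-off."""
        return (self.predict_proba(X) >= 0.5).astype(int)


@dataclass
class ConstantConversionModel:
    """Fallback gate when training labels are single-class: predicts that
    class for every substrate (emitted with a warning by callers)."""

    enzyme_id: str
    constant_class: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        n = np.atleast_2d(np.asarray(X, dtype=float)).shape[0]
        return np.full(n, float(self.constant_class))

    def predict(self, X: np.ndarray) -> np.ndarray:
        n = np.atleast_2d(np.asarray(X, dtype=float)).shape[0]
        return np.full(n, self.constant_class, dtype=int)


def train_conversion_classifier(
    features,                      # FeatureTable
    labels: Sequence[int],
    config: RunConfig | None = None,
    enzyme_id: str = "",
) -> ConversionModel:
    """Fit the per-enzyme conversion gate (500 trees, sqrt-features splits,
    unlimited depth, seeded).  Deterministic given (seed, config, data)."""
    from sklearn.ensemble import RandomForestClassifier

    config = config or RunConfig()
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise DegenerateTrainingError(
            f"enzyme {enzyme_id!r}: single-class conversion labels; emit a "
            "constant prediction with a warning instead of fitting"
        )
    X = features.values
    if X.shape[0] != y.shape[0]:
        raise ValueError("feature rows and labels must align")
    rf = RandomForestClassifier(
        n_estimators=config.rf_trees,
        max_features="sqrt",
        random_state=config.seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    return ConversionModel(
        enzyme_id=enzyme_id,
        featurization_tag=features.tag,
        feature_names=features.feature_names,
        estimator=rf,
        training_substrates=features.substrate_ids,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# Selectivity: forward MVLR
# ---------------------------------------------------------------------------

@dataclass
class SelectivityModel:
    """Forward-MVLR result for one enzyme.

    Coefficients are on the z-scored feature scale (standardized with the
    stored per-feature mean/sd); `raw_coefficients` undoes the scaling.
    """

    enzyme_id: str
    selected_feature_names: list[str]      # in order of addition
    coefficients: np.ndarray               # standardized scale
    intercept: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    loocv_r2: float
    n_train: int
    selected_column_indices: list[int] | None = None  # into the training matrix
    n_input_features: int | None = None

    def __post_init__(self) -> None:
        if len(self.selected_feature_names) < 1:
            raise ValueError("at least one feature must be selected")
        if self.loocv_r2 > 1 + 1e-12:
            raise ValueError("LOOCV R^2 cannot exceed 1")

    @property
    def raw_coefficients(self) -> np.ndarray:
        return self.coefficients / self.feature_sds

    @property
    def raw_intercept(self) -> float:
        return float(
            self.intercept - np.sum(self.coefficients * self.feature_means / self.feature_sds)
        )

    def _vector(self, x) -> np.ndarray:
        if isinstance(x, pd.Series):
            missing = [f for f in self.selected_feature_names if f not in x.index]
            if missing:
                raise KeyError(f"feature(s) {missing} missing from input vector")
            return x[self.selected_feature_names].to_numpy(dtype=float)
        if isinstance(x, dict):
            missing = [f for f in self.selected_feature_names if f not in x]
            if missing:
                raise KeyError(f"feature(s) {missing} missing from input vector")
            return np.array([x[f] for f in self.selected_feature_names], dtype=float)
        arr = np.asarray(x, dtype=float)
        if arr.shape[-1] == len(self.selected_feature_names):
            return arr
        if (
            self.selected_column_indices is not None
            and arr.shape[-1] == self.n_input_features
        ):
            return arr[..., self.selected_column_indices]
        raise ValueError(
            f"expected {len(self.selected_feature_names)} selected features "
            f"(or a full {self.n_input_features}-feature row), got {arr.shape[-1]}"
        )

    def predict_raw(self, x) -> float:
        """Unclamped linear prediction (used for LOOCV R^2 evaluation)."""
        v = self._vector(x)
        z = (v - self.feature_means) / self.feature_sds
        return float(self.intercept + z @ self.coefficients)


def predict_ddg(model: SelectivityModel, x, temperature: float = 308.15) -> DDGValue:
    """Predicted DDG for one substrate, clamped at 0 from below (magnitude
    convention); a clamp is logged via warning."""
    pred = model.predict_raw(x)
    if pred < 0:
        warnings.warn(
            f"enzyme {model.enzyme_id!r}: predicted DDG {pred:.3f} < 0 clamped to 0"
        )
        pred = 0.0
    return DDGValue(value=pred, temperature=temperature)


def _press_loocv_r2(X: np.ndarray, y: np.ndarray) -> float:
    """Exact LOOCV R^2 of OLS-with-intercept on columns X via the PRESS
    identity; returns -inf for (near-)singular designs so such candidates are
    never preferred."""
    n = X.shape[0]
    A = np.column_stack([np.ones(n), X])
    Q, Rm = np.linalg.qr(A)
    diag = np.abs(np.diag(Rm))
    if diag.min() < 1e-10 * max(diag.max(), 1.0):
        return -np.inf
    beta = np.linalg.solve(Rm, Q.T @ y)
    resid = y - A @ beta
    h = np.einsum("ij,ij->i", Q, Q)
    denom = 1.0 - h
    if np.any(denom < 1e-10):
        return -np.inf
    press = np.sum((resid / denom) ** 2)
    sst = np.sum((y - y.mean()) ** 2)
    return float(1.0 - press / sst)


def forward_mvlr_select(
    X,                              # (n, p) array or DataFrame
    y: Sequence[float],
    feature_names: Sequence[str] | None = None,
    max_features: int | None = None,
    enzyme_id: str = "",
) -> SelectivityModel:
    """Greedy forward feature selection with LOOCV-R^2 stopping.

    Step 0 commits the feature with the largest |Pearson correlation| with y
    (so exactly one feature is always selected, even for pure noise).  Each
    later step evaluates every remaining feature and adds the one whose
    enlarged OLS model has the highest LOOCV R^2, stopping when the best
    candidate is not strictly better than the current model or when
    `max_features` (default min(9, n-3)) is reached.  Final coefficients are
    refit on all rows with z-scored features.  Ties break by column order.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 5:
        raise ValueError(f"need at least 5 training rows, got {n}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    if np.ptp(y) == 0:
        raise ValueError("constant y: selectivity regression is undefined")
    cap = min(9, n - 3)
    if max_features is None:
        max_features = cap
    elif max_features > n - 2:
        warnings.warn(
            f"max_features {max_features} exceeds rows-2; capped at {n - 2}"
        )
        max_features = n - 2

    sds = X.std(axis=0, ddof=0)
    usable = sds > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        yc = y - y.mean()
        Xc = X - X.mean(axis=0)
        corr = np.zeros(p)
        corr[usable] = (Xc[:, usable].T @ yc) / (
            np.sqrt((Xc[:, usable] ** 2).sum(axis=0)) * np.sqrt((yc**2).sum())
        )
    if not usable.any():
        raise ValueError("all features are constant")
    first = int(np.argmax(np.abs(corr)))  # ties -> lowest column index
    selected = [first]
    current_r2 = _press_loocv_r2(X[:, selected], y)

    while len(selected) < max_features:
        remaining = [j for j in range(p) if j not in selected and usable[j]]
        if not remaining:
            break
        best_j, best_r2 = None, -np.inf
        for j in remaining:
            r2 = _press_loocv_r2(X[:, selected + [j]], y)
            if r2 > best_r2 + 1e-15:
                best_j, best_r2 = j, r2
        if best_j is None or best_r2 <= current_r2:
            break
        selected.append(best_j)
        current_r2 = best_r2

    Xs = X[:, selected]
    means = Xs.mean(axis=0)
    scale = Xs.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    Z = (Xs - means) / scale
    A = np.column_stack([np.ones(n), Z])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return SelectivityModel(
        enzyme_id=enzyme_id,
        selected_feature_names=[feature_names[j] for j in selected],
        coefficients=beta[1:],
        intercept=float(beta[0]),
        feature_means=means,
        feature_sds=scale,
        loocv_r2=current_r2,
        n_train=n,
        selected_column_indices=selected,
        n_input_features=p,
    )


# ---------------------------------------------------------------------------
# Outer leave-one-ketone-out evaluation
# ---------------------------------------------------------------------------

@dataclass
class LoocvResult:
    """Held-out prediction per substrate plus the aggregate metric."""

    substrate_ids: list[str]
    predictions: np.ndarray
    observed: np.ndarray
    metric_name: str
    metric_value: float


def _metric(name: str, y: np.ndarray, pred: np.ndarray) -> float:
    from .evaluation import auroc

    if name == "r2":
        sst = np.sum((y - y.mean()) ** 2)
        if sst == 0:
            raise ValueError("constant observed values: R^2 undefined")
        return float(1.0 - np.sum((y - pred) ** 2) / sst)
    if name == "accuracy":
        return float(np.mean((pred >= 0.5).astype(int) == y.astype(int)))
    if name == "auroc":
        return auroc(pred, y.astype(int))
    raise ValueError(f"unknown metric {name!r}")


def loocv(
    X,
    y: Sequence[float],
    trainer: Callable[[np.ndarray, np.ndarray], object],
    metric: Literal["r2", "accuracy", "auroc"] = "r2",
    substrate_ids: Sequence[str] | None = None,
) -> LoocvResult:
    """Leave-one-ketone-out evaluation with the trainer re-run in every fold.

    The trainer gets only the n-1 retained rows (standardization and feature
    selection happen inside it), so the held-out row cannot leak into its own
    prediction.  Trainers may return any object with ``predict_raw`` (scalar
    regression) or ``predict_proba``/``predict`` (classification); a fold
    whose labels collapse to one class falls back to a constant prediction
    with a warning.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 rows")
    ids = list(substrate_ids) if substrate_ids is not None else [str(i) for i in range(n)]
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            model = trainer(X[keep], y[keep])
        except DegenerateTrainingError:
            constant = float(y[keep][0])
            warnings.warn(
                f"fold {i}: single-class training labels; constant prediction "
                f"{constant}"
            )
            preds[i] = constant
            continue
        if hasattr(model, "predict_raw"):
            preds[i] = model.predict_raw(X[i])
        elif hasattr(model, "predict_proba"):
            preds[i] = float(np.ravel(model.predict_proba(X[i : i + 1]))[-1])
        else:
            preds[i] = float(np.ravel(model.predict(X[i : i + 1]))[0])
    return LoocvResult(
        substrate_ids=ids,
        predictions=preds,
        observed=y,
        metric_name=metric,
        metric_value=_metric(metric, y, preds),
    )
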