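"""Quadratic discriminant colour classification with backward stepwise
variable selection, the six training-set configurations, and validation.

The classifier models each colour class as a multivariate Gaussian over the
retained subset of the eight morphometric features, with class-specific
covariances (QDA).  Variables are selected by backward stepwise elimination
under the partial Wilks' lambda F-test at alpha = 0.05, after a
multicollinearity pre-pass that drops the weaker member of any near-duplicate
variable pair.  Validation reports the resubstitution (self-test) accuracy
and leave-one-out cross-validated accuracy.

Six training-set configurations cover the analysis variants: a base scheme
with a single platelet-iridescence class (1), hummingbird platelets as their
own class (2), non-hummingbird platelets merged into rod iridescence (3),
classification restricted to non-platelet fossil samples (4), a distinct
penguin brown-black class with non-platelet fossils only (5), and the base
scheme with fossil measurements corrected for 20% taphonomic shrinkage (6).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .measurements import FEATURE_NAMES, Sample, compute_feature_table

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# training-set configurations

#: label remaps per dataset id, applied to the base colour labels
_BASE_REMAP = {
    "hummingbird_platelet": "platelet_iridescence",
    "penguin_brown_black": "black",
}

_SCHEMES: dict[int, dict[str, str]] = {
    1: dict(_BASE_REMAP),
    2: {"penguin_brown_black": "black"},
    3: {"platelet_iridescence": "iridescent", "penguin_brown_black": "black"},
    4: dict(_BASE_REMAP),
    5: {"hummingbird_platelet": "platelet_iridescence"},
    6: dict(_BASE_REMAP),
}


@dataclass(frozen=True)
class TrainingConfig:
    """One of the six training-set configurations."""

    dataset_id: int

    def __post_init__(self) -> None:
        if self.dataset_id not in range(1, 7):
            raise ValueError("dataset_id must be in 1..6")

    @property
    def label_remap(self) -> dict[str, str]:
        return dict(_SCHEMES[self.dataset_id])

    @property
    def shrinkage_corrected(self) -> bool:
        return self.dataset_id == 6

    @property
    def non_platelet_only(self) -> bool:
        """Whether only non-platelet fossil samples are classified."""
        return self.dataset_id in (4, 5)


@dataclass
class TrainingSet:
    config: TrainingConfig
    X: pd.DataFrame            # training features, columns = FEATURE_NAMES
    y: np.ndarray              # class labels
    fossil_X: pd.DataFrame     # fossil prediction set (may be empty)
    fossil_meta: pd.DataFrame  # body_region etc. for the fossil rows


def build_training_set(
    library: Sequence[Sample],
    fossil: Sequence[Sample],
    config: TrainingConfig,
    non_platelet_fossil: Optional[Sequence[Sample]] = None,
    min_class_size: int = 3,
    min_measurements: int = 5,
) -> TrainingSet:
    """Assemble labelled training features and the fossil prediction set for
    one configuration.

    For configurations restricted to non-platelet fossils (4, 5) the caller
    supplies ``non_platelet_fossil`` — the platelet-partitioned stream.  For
    configuration 6 the fossil measurements must already carry the shrinkage
    correction (see the taphonomy module); the dimensionless features are
    unaffected by construction.
    """
    if config.non_platelet_only:
        if non_platelet_fossil is None:
            raise ValueError(
                f"dataset {config.dataset_id} classifies non-platelet fossil "
                "samples only; pass non_platelet_fossil"
            )
        fossil = non_platelet_fossil

    remap = config.label_remap
    labelled = [s for s in library if s.colour_label and s.colour_label != "unknown"]
    if not labelled:
        raise ValueError("training library carries no colour labels")
    lib_feats = compute_feature_table(labelled, min_measurements=min_measurements)
    y = lib_feats["colour_label"].map(lambda c: remap.get(c, c)).to_numpy()

    counts = pd.Series(y).value_counts()
    small = counts[counts < min_class_size]
    if not small.empty:
        raise ValueError(
            f"classes with < {min_class_size} training samples: "
            f"{dict(small)}"
        )

    fossil_feats = compute_feature_table(fossil, min_measurements=min_measurements)
    meta_cols = [c for c in ("body_region", "taxon", "source") if c in fossil_feats.columns]
    return TrainingSet(
        config=config,
        X=lib_feats[list(FEATURE_NAMES)],
        y=y,
        fossil_X=fossil_feats[list(FEATURE_NAMES)] if not fossil_feats.empty else pd.DataFrame(columns=list(FEATURE_NAMES)),
        fossil_meta=fossil_feats[meta_cols] if not fossil_feats.empty else pd.DataFrame(),
    )


# ---------------------------------------------------------------------------
# backward stepwise selection (partial Wilks' lambda F)

def wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """Wilks' lambda det(W)/det(T): within-class over total SSCP determinant.
    Small values mean strong multivariate group separation."""
    X = np.asarray(X, dtype=float)
    total = X - X.mean(0)
    T = total.T @ total
    W = np.zeros_like(T)
    for cls in np.unique(y):
        xc = X[y == cls]
        xc = xc - xc.mean(0)
        W += xc.T @ xc
    sign_t, logdet_t = np.linalg.slogdet(T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_t <= 0:
        raise np.linalg.LinAlgError("singular total SSCP")
    if sign_w <= 0:
        return 0.0
    return float(np.exp(logdet_w - logdet_t))


def partial_wilks_f(
    X: pd.DataFrame, y: np.ndarray, variables: Sequence[str], candidate: str
) -> tuple[float, float]:
    """Partial F for removing ``candidate`` from ``variables``.

    F = ((n - g - p + 1)/(g - 1)) * (Lambda_without / Lambda_with - 1) with
    df = (g - 1, n - g - p + 1), p = len(variables).  Large F (small p-value)
    means the variable contributes discrimination beyond the others.
    """
    n = len(X)
    g = len(np.unique(y))
    p = len(variables)
    df2 = n - g - p + 1
    if df2 < 1:
        raise ValueError("too few observations for the partial F test")
    lam_with = wilks_lambda(X[list(variables)].to_numpy(), y)
    reduced = [v for v in variables if v != candidate]
    lam_without = wilks_lambda(X[reduced].to_numpy(), y) if reduced else 1.0
    if lam_with <= 0:
        return np.inf, 0.0
    f_stat = (df2 / (g - 1)) * (lam_without / lam_with - 1.0)
    f_stat = max(f_stat, 0.0)
    p_val = float(stats.f.sf(f_stat, g - 1, df2))
    return float(f_stat), p_val


def _univariate_f(x: np.ndarray, y: np.ndarray) -> float:
    groups = [x[y == cls] for cls in np.unique(y)]
    f, _ = stats.f_oneway(*groups)
    return float(f) if np.isfinite(f) else 0.0


def collinearity_prepass(
    X: pd.DataFrame, y: np.ndarray, r_threshold: float = 0.95
) -> tuple[list[str], list[str]]:
    """Drop the weaker member (smaller univariate between-class F) of any
    variable pair with |Pearson r| > threshold.  Returns (kept, dropped)."""
    kept = list(X.columns)
    dropped: list[str] = []
    strength = {v: _univariate_f(X[v].to_numpy(), y) for v in kept}
    changed = True
    while changed:
        changed = False
        corr = X[kept].corr().abs()
        for i, vi in enumerate(kept):
            for vj in kept[i + 1:]:
                if corr.loc[vi, vj] > r_threshold:
                    loser = vi if strength[vi] <= strength[vj] else vj
                    kept.remove(loser)
                    dropped.append(loser)
                    logger.info("collinearity pre-pass: dropped %s (|r|=%.3f with %s)",
                                loser, corr.loc[vi, vj], vi if loser == vj else vj)
                    changed = True
                    break
            if changed:
                break
    return kept, dropped


@dataclass
class StepwiseResult:
    retained: list[str]
    eliminated: list[tuple[str, float]]      # (variable, p-value at elimination)
    collinear_dropped: list[str]
    final_p_values: dict[str, float]


def stepwise_select(
    X: pd.DataFrame,
    y: np.ndarray,
    alpha: float = 0.05,
    r_threshold: float = 0.95,
) -> StepwiseResult:
    """Backward stepwise elimination of variables that do not significantly
    predict colour, by the partial Wilks' lambda F-test.

    After the multicollinearity pre-pass, repeatedly drop the variable whose
    partial p-value is largest and exceeds alpha, until every retained
    variable is significant.  Raises if all variables would be eliminated.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    retained, collinear_dropped = collinearity_prepass(X, y, r_threshold)
    eliminated: list[tuple[str, float]] = []
    while retained:
        pvals = {
            v: partial_wilks_f(X, y, retained, v)[1] for v in retained
        }
        worst = max(pvals, key=lambda v: pvals[v])
        if pvals[worst] > alpha:
            retained.remove(worst)
            eliminated.append((worst, pvals[worst]))
            logger.info("stepwise: eliminated %s (p=%.4f)", worst, pvals[worst])
        else:
            return StepwiseResult(retained, eliminated, collinear_dropped, pvals)
    raise ValueError(
        "all variables eliminated; elimination trace: "
        + ", ".join(f"{v} (p={p:.3g})" for v, p in eliminated)
    )


# ---------------------------------------------------------------------------
# QDA

@dataclass
class QdaModel:
    """Per-class Gaussian model on the retained variables.

    Discriminant score: delta_k(x) = -1/2 log|Sigma_k|
    - 1/2 (x - mu_k)' Sigma_k^{-1} (x - mu_k) + log pi_k; the posterior is the
    softmax of the scores.
    """

    classes: np.ndarray
    variables: list[str]
    means: np.ndarray          # (k, p)
    covariances: np.ndarray    # (k, p, p), ridge-regularized
    priors: np.ndarray         # (k,), sums to 1
    dataset_id: Optional[int] = None
    _chol: np.ndarray = field(init=False, repr=False)
    _logdet: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if abs(self.priors.sum() - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
        k, p = self.means.shape
        self._chol = np.empty((k, p, p))
        self._logdet = np.empty(k)
        for i, cls in enumerate(self.classes):
            try:
                self._chol[i] = np.linalg.cholesky(self.covariances[i])
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"covariance for class {cls!r} not positive definite "
                    "even after ridge regularization"
                ) from exc
            self._logdet[i] = 2.0 * np.log(np.diag(self._chol[i])).sum()

    def discriminant_scores(self, X: np.ndarray) -> np.ndarray:
        return self._scores(np.atleast_2d(np.asarray(X, dtype=float)))

    def _scores(self, X: np.ndarray) -> np.ndarray:
        from scipy.linalg import solve_triangular
        out = np.empty((len(X), len(self.classes)))
        for i in range(len(self.classes)):
            diff = (X - self.means[i]).T
            z = solve_triangular(self._chol[i], diff, lower=True)
            maha = (z**2).sum(0)
            out[:, i] = -0.5 * self._logdet[i] - 0.5 * maha + np.log(self.priors[i])
        return out

    def predict(self, X) -> tuple[np.ndarray, np.ndarray]:
        """(labels, posteriors): arg-max class and the full posterior matrix."""
        if isinstance(X, pd.DataFrame):
            missing = [v for v in self.variables if v not in X.columns]
            if missing:
                raise ValueError(f"missing retained variables: {missing}")
            X = X[self.variables].to_numpy()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = self._scores(X)
        shifted = scores - scores.max(1, keepdims=True)
        post = np.exp(shifted)
        post /= post.sum(1, keepdims=True)
        return self.classes[np.argmax(scores, 1)], post


def fit_qda(
    X,
    y: np.ndarray,
    priors: str | Mapping[str, float] = "equal",
    ridge: float = 1e-8,
    variables: Optional[Sequence[str]] = None,
    dataset_id: Optional[int] = None,
) -> QdaModel:
    """Fit per-class Gaussian ML estimates (mean and ML covariance) on the
    retained variables.

    Priors: 'equal' (default — fossil class frequencies are unknowable),
    'frequency' (training proportions), or an explicit mapping.  A ridge of
    ``ridge * trace(Sigma)/p`` is added to each covariance diagonal before
    inversion.
    """
    if isinstance(X, pd.DataFrame):
        variables = list(variables) if variables is not None else list(X.columns)
        Xa = X[variables].to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        variables = list(variables) if variables is not None else [f"x{i}" for i in range(Xa.shape[1])]
    y = np.asarray(y)
    classes = np.unique(y)
    k, p = len(classes), Xa.shape[1]
    means = np.empty((k, p))
    covs = np.empty((k, p, p))
    for i, cls in enumerate(classes):
        xc = Xa[y == cls]
        if len(xc) <= p:
            logger.warning("class %s: n=%d <= p=%d; covariance is rank deficient "
                           "and relies on the ridge", cls, len(xc), p)
        means[i] = xc.mean(0)
        centred = xc - means[i]
        cov = centred.T @ centred / len(xc)         # ML (1/n) estimate
        eps = ridge * np.trace(cov) / p if np.trace(cov) > 0 else ridge
        covs[i] = cov + eps * np.eye(p)

    if priors == "equal":
        pri = np.full(k, 1.0 / k)
    elif priors == "frequency":
        pri = np.array([(y == cls).mean() for cls in classes])
    else:
        pri = np.array([priors[cls] for cls in classes], dtype=float)
        pri = pri / pri.sum()
    return QdaModel(classes=classes, variables=variables, means=means,
                    covariances=covs, priors=pri, dataset_id=dataset_id)


# ---------------------------------------------------------------------------
# validation

@dataclass
class ClassificationReport:
    self_test_accuracy: float
    loo_accuracy: float
    confusion: pd.DataFrame     # rows true, columns predicted (LOO)
    n_loo_skipped: int
    retained_variables: list[str]


def evaluate(
    X: pd.DataFrame,
    y: np.ndarray,
    variables: Sequence[str],
    priors: str = "equal",
    model_builder: Callable[..., QdaModel] = fit_qda,
) -> ClassificationReport:
    """Self-test (resubstitution) and leave-one-out accuracy of the QDA.

    The variable set is fixed from the full-data stepwise selection and not
    re-run per fold; each LOO fold refits only the Gaussian parameters.
    Folds that would empty a training class are skipped with a warning and
    counted.
    """
    y = np.asarray(y)
    full = model_builder(X, y, priors=priors, variables=variables)
    pred_self, _ = full.predict(X)
    self_acc = float((pred_self == y).mean())

    classes = np.unique(y)
    counts = {cls: int((y == cls).sum()) for cls in classes}
    loo_pred = np.full(len(y), None, dtype=object)
    skipped = 0
    for i in range(len(y)):
        if counts[y[i]] <= 1:
            warnings.warn(f"LOO fold {i} skipped: class {y[i]!r} would be empty",
                          stacklevel=2)
            skipped += 1
            continue
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        model = model_builder(X.iloc[mask], y[mask], priors=priors, variables=variables)
        pred_i, _ = model.predict(X.iloc[[i]])
        loo_pred[i] = pred_i[0]
    evaluated = loo_pred != None  # noqa: E711 — object array
    loo_acc = float((loo_pred[evaluated] == y[evaluated]).mean()) if evaluated.any() else float("nan")

    confusion = pd.crosstab(
        pd.Series(y[evaluated], name="true"),
        pd.Series(loo_pred[evaluated].astype(str), name="predicted"),
        dropna=False,
    )
    return ClassificationReport(
        self_test_accuracy=self_acc,
        loo_accuracy=loo_acc,
        confusion=confusion,
        n_loo_skipped=skipped,
        retained_variables=list(variables),
    )


def predict_fossil(model: QdaModel, fossil_X: pd.DataFrame,
                   fossil_meta: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Classify fossil samples: arg-max posterior class per sample, with the
    full posterior vector, assembled into a per-sample (and per body region,
    when available) colour table."""
    labels, post = model.predict(fossil_X)
    out = pd.DataFrame(
        post, index=fossil_X.index,
        columns=[f"p_{c}" for c in model.classes],
    )
    out.insert(0, "predicted_colour", labels)
    if fossil_meta is not None and "body_region" in getattr(fossil_meta, "columns", ()):
        out.insert(1, "body_region", fossil_meta["body_region"])
    return out


def run_classification(
    training: TrainingSet,
    alpha: float = 0.05,
    priors: str = "equal",
) -> tuple[StepwiseResult, QdaModel, ClassificationReport, pd.DataFrame]:
    """Full classification stage for one training configuration: stepwise
    selection, QDA fit, validation, and fossil prediction."""
    selection = stepwise_select(training.X, training.y, alpha=alpha)
    model = fit_qda(training.X, training.y, priors=priors,
                    variables=selection.retained,
                    dataset_id=training.config.dataset_id)
    report = evaluate(training.X, training.y, selection.retained, priors=priors)
    predictions = (
        predict_fossil(model, training.fossil_X, training.fossil_meta)
        if not training.fossil_X.empty else pd.DataFrame()
    )
    return selection, model, report, predictions
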