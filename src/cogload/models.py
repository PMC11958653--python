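"""Condition classification from the segment-level feature table.

Binary and multinomial logistic regression (maximum likelihood, via
statsmodels) with backward-elimination feature selection: starting from
the full candidate set, each step removes the single least-contributing
feature — by default the one with the largest Wald p-value while it
exceeds ``removal_alpha`` (0.10); an AIC-improvement criterion is
available.  Model fit is assessed against the intercept-only null with
the likelihood-ratio chi-square, whose degrees of freedom obey

    df = (n_classes - 1) * n_selected_features.

Classification quality is reported as accuracy and macro-averaged
precision/recall, either in-sample or by stratified k-fold
cross-validation (selection re-run inside each fold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import accuracy_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold


@dataclass
class ModelFit:
    """A fitted (multinomial) logistic regression and its fit statistics."""

    kind: str  # "binary" or "multinomial"
    reference_class: str
    classes: list[str]
    selected_features: list[str]
    params: pd.DataFrame  # feature x non-reference class coefficients
    pvalues: pd.DataFrame  # Wald p-values, same shape
    chi_square: float
    df: int
    model_p: float
    llf: float
    llnull: float
    standardized: bool
    scaler_mean: pd.Series | None
    scaler_std: pd.Series | None
    regularized: bool = False
    _result: object = field(default=None, repr=False)


@dataclass(frozen=True)
class ClassMetrics:
    """Percent accuracy / macro precision / macro recall."""

    accuracy: float
    precision: float
    recall: float
    per_class: pd.DataFrame
    scheme: str


def lr_df(n_selected: int, n_classes: int) -> int:
    """Likelihood-ratio degrees of freedom: (classes - 1) * predictors."""
    if n_selected < 1 or n_classes < 2:
        raise ValueError("need n_selected >= 1 and n_classes >= 2")
    return (n_classes - 1) * n_selected


class _RidgeFit:
    """Ridge-penalized multinomial logistic fit (separation fallback).

    Minimizes the negative log-likelihood plus ``alpha/2 * ||B||^2``
    (intercepts unpenalized), which stays finite under perfect
    separation.  Exposes the same surface ``fit_logistic`` reads from a
    statsmodels result: ``params``, ``pvalues`` (NaN — Wald standard
    errors are not meaningful here), ``llf`` and ``predict``.
    """

    def __init__(self, design: np.ndarray, codes: np.ndarray, n_classes: int,
                 alpha: float = 1e-4):
        from scipy.optimize import minimize

        n, p = design.shape
        k = n_classes - 1

        def unpack(w):
            return w.reshape(k, p)

        def nll_grad(w):
            b = unpack(w)
            eta = np.hstack([np.zeros((n, 1)), design @ b.T])
            eta -= eta.max(axis=1, keepdims=True)
            expeta = np.exp(eta)
            z = expeta.sum(axis=1)
            ll = float((eta[np.arange(n), codes] - np.log(z)).sum())
            proba = expeta / z[:, None]
            onehot = np.zeros((n, n_classes))
            onehot[np.arange(n), codes] = 1.0
            grad = (proba - onehot)[:, 1:].T @ design
            pen_mask = np.ones(p)
            pen_mask[0] = 0.0  # first design column is the intercept
            value = -ll + 0.5 * alpha * float((b**2 * pen_mask).sum())
            grad = grad + alpha * b * pen_mask
            return value, grad.ravel()

        res = minimize(nll_grad, np.zeros(k * p), jac=True, method="L-BFGS-B",
                       options={"maxiter": 1000})
        b = unpack(res.x)
        self.params = b.T  # (k_vars, n_classes-1), statsmodels orientation
        self.pvalues = np.full_like(self.params, np.nan)
        eta = np.hstack([np.zeros((n, 1)), design @ b.T])
        eta -= eta.max(axis=1, keepdims=True)
        z = np.exp(eta).sum(axis=1)
        self.llf = float((eta[np.arange(n), codes] - np.log(z)).sum())
        self._b = b

    def predict(self, design: np.ndarray) -> np.ndarray:
        eta = np.hstack([np.zeros((design.shape[0], 1)), design @ self._b.T])
        eta -= eta.max(axis=1, keepdims=True)
        expeta = np.exp(eta)
        return expeta / expeta.sum(axis=1, keepdims=True)


def _encode(y: pd.Series, reference_class: str) -> tuple[np.ndarray, list[str]]:
    classes = sorted(set(y))
    if reference_class not in classes:
        raise ValueError(f"reference class {reference_class!r} not in labels")
    ordered = [reference_class] + [c for c in classes if c != reference_class]
    codes = pd.Categorical(y, categories=ordered).codes
    return np.asarray(codes), ordered


def fit_logistic(
    features: pd.DataFrame,
    target: pd.Series,
    reference_class: str,
    feature_names: list[str] | None = None,
    standardize: bool = True,
) -> ModelFit:
    """Maximum-likelihood multinomial/binary logistic regression.

    The reference class maps to outcome 0, so a negative coefficient
    means the predictor decreases the odds of the condition relative to
    the reference.  Perfect separation or non-convergence triggers a
    flagged L1-penalized fallback (alpha = 1e-4).
    """
    feature_names = (
        list(features.columns) if feature_names is None else list(feature_names)
    )
    x = features[feature_names].astype(float)
    if x.isna().any().any():
        raise ValueError("missing values in features")
    codes, ordered = _encode(target, reference_class)
    n_classes = len(ordered)
    if n_classes < 2:
        raise ValueError("need at least 2 classes present")

    if standardize:
        mean, std = x.mean(), x.std(ddof=0).replace(0.0, 1.0)
        xs = (x - mean) / std
    else:
        mean = std = None
        xs = x
    if feature_names:
        design = sm.add_constant(xs.to_numpy(), has_constant="add")
    else:
        design = np.ones((len(codes), 1))

    regularized = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(codes, design)
        try:
            result = model.fit(disp=0, maxiter=500, gtol=1e-8)
            if not result.mle_retvals.get("converged", True):
                raise RuntimeError("no convergence")
            if not np.isfinite(np.asarray(result.params)).all():
                raise RuntimeError("diverged coefficients")
        except Exception:
            result = _RidgeFit(design, codes, n_classes, alpha=1e-4)
            regularized = True
        null_res = sm.MNLogit(codes, np.ones((len(codes), 1))).fit(disp=0)

    non_ref = ordered[1:]
    params = pd.DataFrame(
        np.asarray(result.params)[1:, :], index=feature_names, columns=non_ref
    )
    pvalues = pd.DataFrame(
        np.asarray(result.pvalues)[1:, :], index=feature_names, columns=non_ref
    )
    llf, llnull = float(result.llf), float(null_res.llf)
    chi_square = max(0.0, 2.0 * (llf - llnull))
    # an empty selection is the null model compared with itself
    df = lr_df(len(feature_names), n_classes) if feature_names else 0
    model_p = float(sps.chi2.sf(chi_square, df)) if df else 1.0
    return ModelFit(
        kind="binary" if n_classes == 2 else "multinomial",
        reference_class=reference_class,
        classes=ordered,
        selected_features=feature_names,
        params=params,
        pvalues=pvalues,
        chi_square=chi_square,
        df=df,
        model_p=model_p,
        llf=llf,
        llnull=llnull,
        standardized=standardize,
        scaler_mean=mean,
        scaler_std=std,
        regularized=regularized,
        _result=result,
    )


def backward_eliminate(
    features: pd.DataFrame,
    target: pd.Series,
    reference_class: str,
    criterion: str = "wald",
    removal_alpha: float = 0.10,
    standardize: bool = True,
) -> tuple[list[str], list[dict], ModelFit]:
    """Backward-elimination feature selection.

    Starting from all candidate features, each iteration drops the one
    contributing least: with ``criterion="wald"``, the feature whose
    best (smallest across classes) Wald p-value is largest, as long as
    it exceeds ``removal_alpha``; with ``criterion="aic"``, the removal
    that lowers AIC most, as long as AIC improves.  Constant features
    are dropped before fitting.  Returns the retained names, the step
    trace, and the final fit.
    """
    candidates = [
        c for c in features.columns if features[c].nunique() > 1
    ]
    dropped_const = [c for c in features.columns if c not in candidates]
    if dropped_const:
        warnings.warn(f"constant features dropped before fitting: {dropped_const}")
    if not candidates:
        raise ValueError("no non-constant candidate features")

    trace: list[dict] = []
    fit = fit_logistic(features, target, reference_class, candidates, standardize)
    while len(candidates) > 1:
        if criterion == "wald":
            # a regularized fallback fit has no Wald p-values; treat its
            # features as non-significant so elimination still terminates
            per_feature = fit.pvalues.min(axis=1).fillna(1.0)
            worst = per_feature.idxmax()
            if per_feature[worst] <= removal_alpha:
                break
            new = [c for c in candidates if c != worst]
            new_fit = fit_logistic(features, target, reference_class, new, standardize)
            trace.append(
                {"removed": worst, "criterion": float(per_feature[worst]),
                 "remaining": len(new), "chi_square": new_fit.chi_square}
            )
        elif criterion == "aic":
            # parameter count includes one intercept per non-reference class
            current_aic = -2 * fit.llf + 2 * (fit.df + (len(fit.classes) - 1))
            best_aic, best_fit, worst = np.inf, None, None
            for c in candidates:
                reduced = [f for f in candidates if f != c]
                cand_fit = fit_logistic(
                    features, target, reference_class, reduced, standardize
                )
                aic = -2 * cand_fit.llf + 2 * (cand_fit.df + (len(cand_fit.classes) - 1))
                if aic < best_aic:
                    best_aic, best_fit, worst = aic, cand_fit, c
            if best_aic >= current_aic:
                break
            new = best_fit.selected_features
            new_fit = best_fit
            trace.append(
                {"removed": worst, "criterion": float(best_aic),
                 "remaining": len(new), "chi_square": new_fit.chi_square}
            )
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        candidates, fit = new, new_fit
    return candidates, trace, fit


def _predict_labels(fit: ModelFit, features: pd.DataFrame) -> np.ndarray:
    x = features[fit.selected_features].astype(float)
    if fit.standardized:
        x = (x - fit.scaler_mean) / fit.scaler_std
    design = sm.add_constant(x.to_numpy(), has_constant="add")
    proba = np.asarray(fit._result.predict(design))
    return np.array(fit.classes)[proba.argmax(axis=1)]


def evaluate(
    fit: ModelFit,
    features: pd.DataFrame,
    labels: pd.Series,
    scheme: str = "in-sample",
    n_folds: int = 5,
    random_state: int = 0,
    selection_kwargs: dict | None = None,
) -> ClassMetrics:
    """Accuracy and macro precision/recall as percentages.

    ``in-sample`` scores the provided fit on its own training data;
    ``k-fold`` re-runs backward elimination and fitting inside each
    stratified fold and averages the held-out metrics.
    """
    labels = pd.Series(labels).reset_index(drop=True)
    missing = set(fit.classes) - set(labels)
    if missing:
        raise ValueError(f"labels missing classes: {sorted(missing)}")
    features = features.reset_index(drop=True)

    if scheme == "in-sample":
        pred = _predict_labels(fit, features)
        return _metrics(labels.to_numpy(), pred, fit.classes, scheme)
    if scheme != "k-fold":
        raise ValueError(f"unknown scheme {scheme!r}")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=random_state)
    y_true, y_pred = [], []
    kwargs = selection_kwargs or {}
    for train_idx, test_idx in skf.split(features, labels):
        _, _, fold_fit = backward_eliminate(
            features.iloc[train_idx], labels.iloc[train_idx],
            fit.reference_class, **kwargs,
        )
        y_true.append(labels.iloc[test_idx].to_numpy())
        y_pred.append(_predict_labels(fold_fit, features.iloc[test_idx]))
    return _metrics(
        np.concatenate(y_true), np.concatenate(y_pred), fit.classes, scheme
    )


def _metrics(
    y_true: np.ndarray, y_pred: np.ndarray, classes: list[str], scheme: str
) -> ClassMetrics:
    acc = accuracy_score(y_true, y_pred) * 100.0
    prec = precision_score(
        y_true, y_pred, labels=classes, average="macro", zero_division=0
    ) * 100.0
    rec = recall_score(
        y_true, y_pred, labels=classes, average="macro", zero_division=0
    ) * 100.0
    per_class = pd.DataFrame(
        {
            "precision": precision_score(
                y_true, y_pred, labels=classes, average=None, zero_division=0
            ) * 100.0,
            "recall": recall_score(
                y_true, y_pred, labels=classes, average=None, zero_division=0
            ) * 100.0,
        },
        index=classes,
    )
    return ClassMetrics(
        accuracy=float(acc), precision=float(prec), recall=float(rec),
        per_class=per_class, scheme=scheme,
    )
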