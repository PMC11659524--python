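"""ICI response prediction from pairwise signature-interaction features.

From a 30-signature profile, 1740 = C(30,2) x 4 interaction features are
engineered — for each unordered signature pair (A, B) with A before B in
canonical registry order: ``A+B``, ``A-B``, ``exp(A)*exp(B)`` and
``exp(A)/exp(B)`` (signatures can be negative, so the exponent is taken
before products/quotients to keep those features monotone and positive).
A random forest ranks the features by impurity importance; the number of
kept features is tuned by stratified 5-fold cross-validation of a gradient-
boosted tree classifier (XGBoost, logistic objective, early stopping); the
final model is refit on the whole training set with the tuned feature set,
and a probability cutpoint is chosen by maximizing the Youden index.
"""

from __future__ import annotations

import logging
import pickle
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

OPS = ("+", "-", "*", "/")

_NAME_RE = re.compile(
    r"^(?:(?P<a1>[^+\-*/]+)\+(?P<b1>[^+\-*/]+)"
    r"|(?P<a2>[^+\-*/]+)-(?P<b2>[^+\-*/]+)"
    r"|exp\((?P<a3>[^()]+)\)\*exp\((?P<b3>[^()]+)\)"
    r"|exp\((?P<a4>[^()]+)\)/exp\((?P<b4>[^()]+)\))$"
)


def feature_name(a: str, b: str, op: str) -> str:
    if op == "+":
        return f"{a}+{b}"
    if op == "-":
        return f"{a}-{b}"
    if op == "*":
        return f"exp({a})*exp({b})"
    if op == "/":
        return f"exp({a})/exp({b})"
    raise ValueError(f"unknown op {op!r}")


def parse_feature_name(name: str) -> tuple[str, str, str]:
    """Invert :func:`feature_name`: "A+B" -> (A, B, '+') etc."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"unparseable feature name {name!r}")
    for i, op in enumerate(OPS, start=1):
        a = m.group(f"a{i}")
        if a is not None:
            return a, m.group(f"b{i}"), op
    raise AssertionError("unreachable")


def engineer_interactions(profiles: pd.DataFrame, max_abs: float = 50.0) -> pd.DataFrame:
    """Expand signature profiles into the pairwise interaction feature matrix.

    Accepts a samples x m profile DataFrame; returns samples x (C(m,2)*4)
    features, pairs ordered lexicographically by signature index and the four
    operations in the order +, -, *, /. Values with |x| > ``max_abs`` are
    rejected (exp overflow guard).
    """
    X = profiles.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("profiles contain non-finite values")
    if np.abs(X).max() > max_abs:
        raise ValueError(f"profile magnitude exceeds {max_abs}; scale inputs before exponentiating")
    names = list(profiles.columns)
    e = np.exp(X)
    cols: dict[str, np.ndarray] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            cols[feature_name(a, b, "+")] = X[:, i] + X[:, j]
            cols[feature_name(a, b, "-")] = X[:, i] - X[:, j]
            cols[feature_name(a, b, "*")] = e[:, i] * e[:, j]
            cols[feature_name(a, b, "/")] = e[:, i] / e[:, j]
    return pd.DataFrame(cols, index=profiles.index)


def stratified_split(
    labels: pd.Series,
    train_frac: float = 0.7,
    seed: int = 0,
) -> tuple[list, list]:
    """Stratified train/test split with deterministic per-class allocation.

    The train total is ``round(n * train_frac)``. Each class contributes the
    floor of its proportional quota; leftover train seats are assigned to the
    larger strata first (ties broken by label order). Within a class, which
    patients land in train is a seeded shuffle.
    """
    labels = labels.dropna()
    classes = list(pd.unique(labels))
    counts = {c: int((labels == c).sum()) for c in classes}
    if train_frac < 1.0:
        for c, cnt in counts.items():
            if cnt < 2:
                raise ValueError(f"class {c!r} has fewer than 2 members")
    n = len(labels)
    n_train = int(round(n * train_frac))
    quota = {c: counts[c] * train_frac for c in classes}
    alloc = {c: int(np.floor(quota[c])) for c in classes}
    leftover = n_train - sum(alloc.values())
    for c in sorted(classes, key=lambda c: (-counts[c], classes.index(c))):
        if leftover <= 0:
            break
        if alloc[c] < counts[c]:
            alloc[c] += 1
            leftover -= 1
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for c in classes:
        ids = list(labels.index[labels == c])
        perm = rng.permutation(len(ids))
        chosen = set(perm[: alloc[c]].tolist())
        train_ids += [ids[i] for i in range(len(ids)) if i in chosen]
        test_ids += [ids[i] for i in range(len(ids)) if i not in chosen]
    return train_ids, test_ids


def rf_select_features(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    k: int,
    n_trees: int = 1000,
    seed: int = 0,
) -> list[str]:
    """Top-k features by random-forest impurity importance.

    Rows are canonicalized by sample-id order before fitting, so the
    selection is invariant to the incoming sample order under a fixed seed.
    Ties in importance break by canonical (column) feature order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds number of features {X.shape[1]}")
    y = pd.Series(np.asarray(y), index=X.index)
    order = np.argsort(X.index.to_numpy(), kind="stable")
    Xs, ys = X.iloc[order], y.iloc[order]
    if len(np.unique(ys)) < 2:
        raise ValueError("need both classes for feature selection")
    rf = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt", random_state=seed)
    rf.fit(Xs.to_numpy(), ys.to_numpy())
    imp = rf.feature_importances_
    ranked = np.lexsort((np.arange(len(imp)), -imp))  # importance desc, column order on ties
    return [X.columns[i] for i in ranked[:k]]


def _fit_xgb(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    lr: float = 0.1,
    gamma: float = 0.1,
    rounds: int = 35,
    early_stopping_rounds: int | None = None,
    seed: int = 0,
) -> xgb.XGBClassifier:
    clf = xgb.XGBClassifier(
        n_estimators=rounds,
        learning_rate=lr,
        gamma=gamma,
        objective="binary:logistic",
        eval_metric="logloss",
        early_stopping_rounds=early_stopping_rounds,
        random_state=seed,
        n_jobs=1,
        tree_method="exact",
    )
    if early_stopping_rounds is not None:
        clf.fit(X_tr, y_tr, eval_set=[(X_val, y_val)], verbose=False)
    else:
        clf.fit(X_tr, y_tr, verbose=False)
    return clf


def cv_tune(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    k_grid: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50),
    seed: int = 0,
    n_folds: int = 5,
    rf_trees: int = 1000,
    lr: float = 0.1,
    gamma: float = 0.1,
    max_rounds: int = 500,
    early_stopping_rounds: int = 100,
) -> tuple[int, int, pd.DataFrame]:
    """Tune the number of selected features by stratified 5-fold CV AUROC.

    Feature selection runs *inside* each fold on that fold's training part
    only (leakage-safe). Boosting rounds use early stopping (patience 100 on
    logistic loss) with the validation AUROC recorded. Returns
    ``(best_k, best_rounds, per-k record)``; ties in mean AUROC go to the
    smaller k, and best_rounds is the rounded mean best iteration of the
    winning k's folds.
    """
    y = pd.Series(np.asarray(y), index=X.index).astype(int)
    if len(X) < 25:
        raise ValueError("need >= 25 samples for 5-fold tuning")
    folds = None
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        cand = list(skf.split(X, y))
        if all(len(np.unique(y.iloc[tr])) == 2 and len(np.unique(y.iloc[va])) == 2 for tr, va in cand):
            folds = cand
            break
    if folds is None:
        raise ValueError("could not form folds with both classes after 10 attempts")
    records = []
    per_k_rounds: dict[int, list[int]] = {}
    per_k_auc: dict[int, float] = {}
    for k in k_grid:
        aucs, rounds_used = [], []
        for fi, (tr, va) in enumerate(folds):
            X_tr, X_va = X.iloc[tr], X.iloc[va]
            y_tr, y_va = y.iloc[tr], y.iloc[va]
            feats = rf_select_features(X_tr, y_tr, k=k, n_trees=rf_trees, seed=seed + fi)
            clf = _fit_xgb(
                X_tr[feats].to_numpy(), y_tr.to_numpy(),
                X_va[feats].to_numpy(), y_va.to_numpy(),
                lr=lr, gamma=gamma, rounds=max_rounds,
                early_stopping_rounds=early_stopping_rounds, seed=seed,
            )
            best_it = getattr(clf, "best_iteration", None)
            rounds_used.append((best_it if best_it is not None else max_rounds - 1) + 1)
            proba = clf.predict_proba(X_va[feats].to_numpy())[:, 1]
            aucs.append(roc_auc_score(y_va.to_numpy(), proba))
        per_k_auc[k] = float(np.mean(aucs))
        per_k_rounds[k] = rounds_used
        records.append({"k": k, "cv_auroc": per_k_auc[k], "cv_auroc_sd": float(np.std(aucs)),
                        "mean_rounds": float(np.mean(rounds_used))})
    best_k = min(per_k_auc, key=lambda k: (-per_k_auc[k], k))
    best_rounds = int(round(np.mean(per_k_rounds[best_k])))
    return best_k, max(best_rounds, 1), pd.DataFrame(records).set_index("k")


def train_gbt(
    X_selected: pd.DataFrame,
    y: pd.Series | np.ndarray,
    lr: float = 0.1,
    gamma: float = 0.1,
    rounds: int = 35,
    seed: int = 0,
) -> xgb.XGBClassifier:
    """Final gradient-boosted tree fit with a fixed number of rounds."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to train")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    return _fit_xgb(X_selected.to_numpy(), y, lr=lr, gamma=gamma, rounds=rounds, seed=seed)


def shap_attributions(model: xgb.XGBClassifier, X: pd.DataFrame):
    """TreeSHAP attributions on the margin (log-odds) scale.

    Returns ``(phi, base)`` where ``phi`` is a samples x features DataFrame
    and ``base`` the expected margin; for every sample
    ``base + phi.sum(1)`` equals the model's margin prediction.
    """
    booster = model.get_booster()
    if booster.num_features() != X.shape[1]:
        raise ValueError("feature count mismatch between model and matrix")
    dm = xgb.DMatrix(X.to_numpy(), feature_names=[str(c) for c in X.columns])
    contribs = booster.predict(dm, pred_contribs=True)
    phi = pd.DataFrame(contribs[:, :-1], index=X.index, columns=X.columns)
    base = float(contribs[0, -1])
    return phi, base


def shap_importance(phi: pd.DataFrame) -> pd.Series:
    """Mean |attribution| per feature, descending (summary-plot ordering)."""
    return phi.abs().mean(axis=0).sort_values(ascending=False)


def youden_threshold(probs: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Probability cutpoint maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the observed probabilities; the decision rule is
    ``prob >= threshold``; ties in J resolve to the lowest threshold.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes")
    if np.ptp(probs) < 1e-15:
        logger.warning("constant probabilities: Youden J = 0")
        thr = float(probs[0])
        sens = float((probs >= thr)[labels == 1].mean())
        spec = float((probs < thr)[labels == 0].mean())
        return thr, sens, spec
    best = None
    for thr in np.unique(probs):  # ascending, so first max is the lowest threshold
        pred = probs >= thr
        sens = pred[labels == 1].mean()
        spec = (~pred)[labels == 0].mean()
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(thr), float(sens), float(spec))
    return best[1], best[2], best[3]


@dataclass
class ResponseModel:
    """Fitted response predictor: feature set + boosted ensemble + cutpoint."""

    selected_features: list[str]
    ensemble: xgb.XGBClassifier
    cutpoint: float
    cv_record: pd.DataFrame
    best_k: int
    best_rounds: int
    train_sensitivity: float = float("nan")
    train_specificity: float = float("nan")

    def predict_proba(self, profiles: pd.DataFrame) -> pd.Series:
        feats = engineer_interactions(profiles)[self.selected_features]
        p = self.ensemble.predict_proba(feats.to_numpy())[:, 1]
        return pd.Series(p, index=profiles.index, name="p_responder")

    def predict_label(self, profiles: pd.DataFrame) -> pd.Series:
        p = self.predict_proba(profiles)
        return (p >= self.cutpoint).astype(int).rename("predicted_responder")

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as f:
            pickle.dump(self, f)

    @classmethod
    def load(cls, path: str | Path) -> "ResponseModel":
        with open(path, "rb") as f:
            return pickle.load(f)


def fit_response_model(
    profiles: pd.DataFrame,
    responder: pd.Series,
    k_grid: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50),
    seed: int = 0,
    rf_trees: int = 1000,
    lr: float = 0.1,
    gamma: float = 0.1,
    n_folds: int = 5,
    rounds: int | None = None,
) -> ResponseModel:
    """End-to-end fit on a training cohort.

    CV tunes k (selection re-run inside every fold); the final feature set is
    selected on the full training set, the ensemble refit with the tuned
    round count (or an explicit ``rounds``), and the Youden cutpoint computed
    on training predictions.
    """
    responder = responder.loc[profiles.index].astype(int)
    X = engineer_interactions(profiles)
    best_k, best_rounds, record = cv_tune(
        X, responder, k_grid=k_grid, seed=seed, n_folds=n_folds,
        rf_trees=rf_trees, lr=lr, gamma=gamma,
    )
    final_rounds = rounds if rounds is not None else best_rounds
    feats = rf_select_features(X, responder, k=best_k, n_trees=rf_trees, seed=seed)
    ens = train_gbt(X[feats], responder, lr=lr, gamma=gamma, rounds=final_rounds, seed=seed)
    p_train = ens.predict_proba(X[feats].to_numpy())[:, 1]
    thr, sens, spec = youden_threshold(p_train, responder.to_numpy())
    return ResponseModel(
        selected_features=feats,
        ensemble=ens,
        cutpoint=thr,
        cv_record=record,
        best_k=best_k,
        best_rounds=final_rounds,
        train_sensitivity=sens,
        train_specificity=spec,
    )
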