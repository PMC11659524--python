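"""TME subtyping: cluster signature profiles into Immune-Inflamed vs Immune-Desert.

Cohorts of (predicted) signature profiles are scaled by cohort-specific
means/standard deviations, clustered (k-means by default, PAM optionally),
the number of clusters chosen by a bootstrap of the average silhouette
score, and a random-forest classifier trained on the cluster labels so new
patients can be assigned a subtype. The cluster with the higher mean over
the antitumor-immune signatures is always labeled "Immune-Inflamed",
resolving k-means label switching deterministically.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import silhouette_score

from .signatures import SignatureSet, default_registry

logger = logging.getLogger(__name__)

INFLAMED = "Immune-Inflamed"
DESERT = "Immune-Desert"


@dataclass
class CohortScaler:
    """Per-signature mean/sd of one named cohort."""

    cohort: str
    mean: pd.Series
    sd: pd.Series

    @classmethod
    def fit(cls, profiles: pd.DataFrame, cohort: str = "train") -> "CohortScaler":
        if profiles.shape[0] < 2:
            raise ValueError("scaler requires >= 2 samples")
        mean = profiles.mean(axis=0)
        sd = profiles.std(axis=0, ddof=1)
        bad = sd.index[sd <= 0].tolist()
        if bad:
            raise ValueError(f"zero standard deviation for signature(s): {bad}")
        return cls(cohort=cohort, mean=mean, sd=sd)

    def transform(self, profiles: pd.DataFrame) -> pd.DataFrame:
        return (profiles - self.mean) / self.sd


def cohort_scale(profiles: pd.DataFrame, scaler: CohortScaler | None = None) -> pd.DataFrame:
    """Scale each signature by cohort mean/sd (self-fitted when no scaler given)."""
    if scaler is None:
        scaler = CohortScaler.fit(profiles)
    return scaler.transform(profiles)


def _pam(X: np.ndarray, k: int, seed: int, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Classic partitioning-around-medoids (BUILD + SWAP) on Euclidean distances.

    Returns (labels, medoid_indices). O(k n^2) per sweep; fine at cohort scale.
    """
    n = X.shape[0]
    if k > n:
        raise ValueError("k exceeds number of samples")
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    # BUILD: greedy cost-minimizing medoid additions (seeded tie-break order)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)  # tie-break preference, deterministic under seed
    medoids: list[int] = []
    first = order[np.argmin(d[order].sum(axis=1))]
    medoids.append(int(first))
    while len(medoids) < k:
        cur = d[:, medoids].min(axis=1)
        best_gain, best_j = -np.inf, -1
        for j in order:
            if j in medoids:
                continue
            gain = np.maximum(cur - d[:, j], 0.0).sum()
            if gain > best_gain:
                best_gain, best_j = gain, int(j)
        medoids.append(best_j)
    # SWAP until no improving swap
    for _ in range(max_iter):
        cost = d[:, medoids].min(axis=1).sum()
        best_cost, best_swap = cost, None
        for mi, m in enumerate(medoids):
            others = [x for x in medoids if x != m]
            for j in range(n):
                if j in medoids:
                    continue
                trial = others + [j]
                c = d[:, trial].min(axis=1).sum()
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (mi, j)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    med = np.array(sorted(medoids))
    labels = np.argmin(d[:, med], axis=1)
    return labels, med


def cluster_profiles(
    profiles: pd.DataFrame,
    k: int,
    method: str = "kmeans",
    n_init: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Cluster scaled profiles into ``k`` groups (k-means default, PAM optional)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X = profiles.to_numpy(dtype=float)
    if X.shape[0] < k:
        raise ValueError("fewer samples than clusters")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        return km.fit_predict(X)
    if method == "pam":
        labels, _ = _pam(X, k, seed)
        return labels
    raise ValueError(f"unknown clustering method {method!r}")


def select_k(
    profiles: pd.DataFrame,
    k_min: int = 2,
    k_max: int = 6,
    n_boot: int = 100,
    frac: float = 0.8,
    seed: int = 0,
    method: str = "kmeans",
    n_init: int = 10,
    aggregate: str = "median",
) -> tuple[int, dict[int, np.ndarray]]:
    """Choose the number of clusters by bootstrapped average silhouette.

    For each bootstrap replicate an ``frac`` subsample is clustered at every
    k in [k_min, k_max] and the mean silhouette (Euclidean) recorded; the
    selected K maximizes the median (configurable to mean) silhouette across
    replicates.
    """
    X = profiles.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 20:
        raise ValueError("need >= 20 samples for silhouette bootstrap")
    if k_max >= n:
        raise ValueError("k_max must be < number of samples")
    rng = np.random.default_rng(seed)
    sub_n = max(k_max + 1, int(round(frac * n)))
    dist: dict[int, np.ndarray] = {k: np.empty(n_boot) for k in range(k_min, k_max + 1)}
    for b in range(n_boot):
        idx = rng.choice(n, size=sub_n, replace=False)
        sub = X[idx]
        for k in range(k_min, k_max + 1):
            if method == "kmeans":
                labels = KMeans(n_clusters=k, n_init=n_init, random_state=seed * 100003 + b).fit_predict(sub)
            else:
                labels, _ = _pam(sub, k, seed * 100003 + b)
            if len(np.unique(labels)) < 2:
                dist[k][b] = -1.0  # degenerate clustering never wins
            else:
                dist[k][b] = silhouette_score(sub, labels)
    agg = np.median if aggregate == "median" else np.mean
    best_k = max(dist, key=lambda k: agg(dist[k]))
    return best_k, dist


@dataclass
class SubtypeModel:
    """Fitted subtype classifier: scaling stats + clusters + random forest."""

    scaler: CohortScaler
    k: int
    method: str
    cluster_labels: np.ndarray
    cluster_to_subtype: dict[int, str]
    classifier: RandomForestClassifier
    feature_importances: pd.Series
    oob_accuracy: float
    signature_names: tuple[str, ...] = field(default_factory=tuple)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as f:
            pickle.dump(self, f)

    @classmethod
    def load(cls, path: str | Path) -> "SubtypeModel":
        with open(path, "rb") as f:
            return pickle.load(f)


def _label_clusters(
    scaled: pd.DataFrame, labels: np.ndarray, registry: SignatureSet
) -> dict[int, str]:
    """Name the cluster with higher mean antitumor-immune score "Immune-Inflamed"."""
    anti = [n for n in scaled.columns if registry.groups.get(n) == "antitumor_immune"]
    if not anti:
        anti = list(scaled.columns)
    means = {c: scaled.loc[labels == c, anti].to_numpy().mean() for c in np.unique(labels)}
    ranked = sorted(means, key=means.get, reverse=True)
    out = {int(ranked[0]): INFLAMED}
    for c in ranked[1:]:
        out[int(c)] = DESERT
    return out


def fit_subtype_classifier(
    profiles: pd.DataFrame,
    labels: np.ndarray | None = None,
    n_trees: int = 500,
    seed: int = 0,
    method: str = "kmeans",
    registry: SignatureSet | None = None,
    cohort: str = "train",
) -> SubtypeModel:
    """Scale, (optionally) cluster, and fit the random-forest subtype classifier.

    When ``labels`` is omitted the cohort is clustered with K = 2 first.
    Out-of-bag accuracy is logged; impurity feature importances (summing to 1)
    are stored for inspection of which signatures drive the subtypes.
    """
    registry = registry or default_registry()
    scaler = CohortScaler.fit(profiles, cohort=cohort)
    scaled = scaler.transform(profiles)
    if labels is None:
        labels = cluster_profiles(scaled, 2, method=method, seed=seed)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("cluster labels contain a single class")
    mapping = _label_clusters(scaled, labels, registry)
    y = np.array([mapping[int(c)] for c in labels])
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", oob_score=True, random_state=seed
    )
    rf.fit(scaled.to_numpy(), y)
    logger.info("subtype RF out-of-bag accuracy: %.3f", rf.oob_score_)
    importances = pd.Series(rf.feature_importances_, index=scaled.columns)
    return SubtypeModel(
        scaler=scaler,
        k=len(np.unique(labels)),
        method=method,
        cluster_labels=labels,
        cluster_to_subtype=mapping,
        classifier=rf,
        feature_importances=importances,
        oob_accuracy=float(rf.oob_score_),
        signature_names=tuple(profiles.columns),
    )


def assign_subtype(
    model: SubtypeModel,
    profiles: pd.DataFrame,
    scaler: CohortScaler | None = None,
) -> pd.DataFrame:
    """Assign subtypes to (already profile-level) samples.

    ``scaler`` defaults to fitting on the incoming cohort itself (the
    deployment convention: each cohort is scaled by its own statistics);
    pass the model's stored scaler to reuse training statistics instead.
    Returns a DataFrame with ``subtype`` and the classifier's vote fraction
    for that subtype.
    """
    if scaler is None:
        scaler = CohortScaler.fit(profiles, cohort="deploy") if profiles.shape[0] >= 2 else model.scaler
    scaled = scaler.transform(profiles[list(model.signature_names)])
    arr = scaled.to_numpy(dtype=float)
    if np.abs(arr).max() > 10:
        logger.warning("scaled profiles have |z| > 10; input may be unscaled or mismatched")
    proba = model.classifier.predict_proba(arr)
    classes = model.classifier.classes_
    idx = np.argmax(proba, axis=1)
    return pd.DataFrame(
        {"subtype": classes[idx], "probability": proba[np.arange(len(idx)), idx]},
        index=profiles.index,
    )
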