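"""Statistics and classification on single-cell OMI feature tables.

Covers the reporting layer of the analysis: Glass's-Delta effect sizes
(chosen over p-values because thousand-cell samples make any nonzero
population effect "significant"), coefficient-of-variation heterogeneity
summaries, z-score Ward clustering, UMAP embedding of the nine OMI
variables, and the activation classifiers — random forests on the fit
variables (70/30 split) and logistic-regression / random-forest models on
the eight cell-level phasor coordinates (50/50 split). Misclassification
cost is equal across classes throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split

from .features import OMI_FEATURES

__all__ = [
    "EffectSize",
    "ClassifierReport",
    "PHASOR_FEATURES",
    "glass_delta",
    "coefficient_of_variation",
    "zscore_cluster",
    "umap_embed",
    "train_activation_classifier",
    "train_phasor_classifier",
    "group_comparison",
]

#: Cell-level phasor features: (G, S) for both channels at 80 and 160 MHz.
PHASOR_FEATURES = [
    "nadh_g1", "nadh_s1", "nadh_g2", "nadh_s2",
    "fad_g1", "fad_s1", "fad_g2", "fad_s2",
]

_POSITIVE_CLASS = "activated"


@dataclass(frozen=True)
class EffectSize:
    """Glass's Delta = (mu_control - mu_test) / sigma_control."""

    delta: float
    mu_control: float
    mu_test: float
    sigma_control: float
    n_control: int
    n_test: int

    @property
    def magnitude(self) -> str:
        """Interpretation band: none / small / moderate / large."""
        d = abs(self.delta)
        if d <= 0.2:
            return "none"
        if d <= 0.5:
            return "small"
        if d <= 0.8:
            return "moderate"
        return "large"


def glass_delta(control: np.ndarray, test: np.ndarray, ddof: int = 1) -> EffectSize:
    """Effect size standardized by the control group's SD (sample SD by default)."""
    control = np.asarray(control, dtype=float)
    test = np.asarray(test, dtype=float)
    if control.size < 2:
        raise ValueError("need at least 2 control values")
    sigma = control.std(ddof=ddof)
    if sigma == 0:
        raise ValueError("control group has zero spread")
    mu_c, mu_t = control.mean(), test.mean()
    return EffectSize(
        delta=(mu_c - mu_t) / sigma,
        mu_control=float(mu_c), mu_test=float(mu_t), sigma_control=float(sigma),
        n_control=control.size, n_test=test.size,
    )


def coefficient_of_variation(values: np.ndarray, ddof: int = 1) -> float:
    """SD / mean (sample SD by default); summarizes cell-to-cell heterogeneity."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(values.std(ddof=ddof) / mean)


@dataclass
class ClusterResult:
    zscores: pd.DataFrame
    linkage_matrix: np.ndarray
    cluster_labels: np.ndarray


def zscore_cluster(
    table: pd.DataFrame,
    features: list[str] | None = None,
    n_clusters: int = 2,
) -> ClusterResult:
    """Ward-linkage hierarchical clustering of per-cell z-scores.

    Each feature is standardized by the population mean and population SD
    over all included cells; clustering uses Euclidean distance with
    Ward's method. Group labels are never used in the clustering itself.
    """
    features = list(features or OMI_FEATURES)
    X = table[features].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 cells to cluster")
    sd = X.std(axis=0, ddof=0)
    for name, s in zip(features, sd):
        if s == 0:
            raise ValueError(f"feature {name!r} is constant; z-score undefined")
    Z = (X - X.mean(axis=0)) / sd
    lk = linkage(Z, method="ward", metric="euclidean")
    labels = fcluster(lk, t=n_clusters, criterion="maxclust")
    return ClusterResult(
        zscores=pd.DataFrame(Z, columns=features, index=table.index),
        linkage_matrix=lk,
        cluster_labels=labels,
    )


def umap_embed(
    table: pd.DataFrame,
    features: list[str] | None = None,
    n_neighbors: int = 15,
    min_dist: float = 0.4,
    metric: str = "euclidean",
    seed: int = 0,
) -> np.ndarray:
    """2-D UMAP of the feature table (neighbors 15, min dist 0.4, Euclidean)."""
    import umap  # deferred: numba compilation is slow to import

    features = list(features or OMI_FEATURES)
    X = table[features].to_numpy(dtype=float)
    if X.shape[0] < n_neighbors:
        raise ValueError(f"need at least n_neighbors={n_neighbors} cells")
    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
        metric=metric, random_state=seed,
    )
    return reducer.fit_transform(X)


@dataclass
class ClassifierReport:
    """Held-out evaluation of an activation classifier."""

    accuracy: float
    auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    operating_point: tuple[float, float]  # (FPR, TPR) at probability 0.5
    confusion: np.ndarray  # rows true, cols predicted, order (quiescent, activated)
    importances: pd.Series  # percentages summing to 100
    train_size: int
    test_size: int
    seed: int
    feature_set: str
    model: str = "random_forest"
    classes: tuple[str, str] = ("quiescent", "activated")

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "auc": self.auc,
            "operating_point": list(self.operating_point),
            "confusion": self.confusion.tolist(),
            "importances_pct": self.importances.round(4).to_dict(),
            "train_size": self.train_size, "test_size": self.test_size,
            "seed": self.seed, "feature_set": self.feature_set, "model": self.model,
        }


def _labeled_subset(table: pd.DataFrame) -> pd.DataFrame:
    sub = table[table["activation"].isin(["activated", "quiescent"])]
    if sub["activation"].nunique() < 2:
        raise ValueError("need both activated and quiescent cells")
    return sub


def _fit_and_report(
    X: np.ndarray, y: np.ndarray, features: list[str], test_size: float,
    seed: int, model: str, feature_set: str, n_trees: int = 100,
) -> ClassifierReport:
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, random_state=seed, stratify=y
    )
    if model == "random_forest":
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        clf.fit(X_tr, y_tr)
        raw_imp = clf.feature_importances_
    elif model == "logistic":
        clf = LogisticRegression(max_iter=2000, random_state=seed)
        clf.fit(X_tr, y_tr)
        raw_imp = np.abs(clf.coef_[0]) * X_tr.std(axis=0, ddof=0)
    else:
        raise ValueError(f"unknown model {model!r}")

    pos_idx = list(clf.classes_).index(_POSITIVE_CLASS)
    prob = clf.predict_proba(X_te)[:, pos_idx]
    pred = clf.predict(X_te)
    acc = float((pred == y_te).mean())
    y_bin = (y_te == _POSITIVE_CLASS).astype(int)
    fpr, tpr, _ = roc_curve(y_bin, prob)
    auc = float(roc_auc_score(y_bin, prob))
    cm = confusion_matrix(y_te, pred, labels=["quiescent", "activated"])
    pred_bin = (prob >= 0.5).astype(int)
    op_fpr = float(((pred_bin == 1) & (y_bin == 0)).sum() / max((y_bin == 0).sum(), 1))
    op_tpr = float(((pred_bin == 1) & (y_bin == 1)).sum() / max((y_bin == 1).sum(), 1))
    total = raw_imp.sum()
    imp = raw_imp / total * 100.0 if total > 0 else np.full(len(features), 100.0 / len(features))
    return ClassifierReport(
        accuracy=acc, auc=auc, roc_fpr=fpr, roc_tpr=tpr,
        operating_point=(op_fpr, op_tpr), confusion=cm,
        importances=pd.Series(imp, index=features),
        train_size=len(y_tr), test_size=len(y_te), seed=seed,
        feature_set=feature_set, model=model,
    )


def train_activation_classifier(
    table: pd.DataFrame,
    features: list[str] | None = None,
    feature_set: str = "all",
    test_size: float = 0.3,
    seed: int = 0,
    n_trees: int = 100,
) -> ClassifierReport:
    """Random forest on OMI fit variables, 70/30 stratified split.

    ``features`` defaults to the nine OMI variables; named subsets (e.g.
    NAD(P)H-only, top-k by importance, single variable) are passed
    explicitly as column lists.
    """
    features = list(features or OMI_FEATURES)
    sub = _labeled_subset(table)
    return _fit_and_report(
        sub[features].to_numpy(dtype=float), sub["activation"].to_numpy(),
        features, test_size, seed, "random_forest", feature_set, n_trees,
    )


def train_phasor_classifier(
    table: pd.DataFrame,
    features: list[str] | None = None,
    model: str = "random_forest",
    test_size: float = 0.5,
    seed: int = 0,
    n_trees: int = 100,
) -> ClassifierReport:
    """Classifier on cell-level phasor coordinates, 50/50 split.

    Features default to NAD(P)H and FAD (G, S) at 80 and 160 MHz; the
    model is either a 100-tree random forest or a logistic regression
    with the logit link.
    """
    features = list(features or PHASOR_FEATURES)
    sub = _labeled_subset(table)
    return _fit_and_report(
        sub[features].to_numpy(dtype=float), sub["activation"].to_numpy(),
        features, test_size, seed, model, "phasor", n_trees,
    )


@dataclass
class GroupComparison:
    method: str
    statistic: float
    pvalue: float
    posthoc: pd.DataFrame | None = None


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-sum pairwise test with Holm adjustment."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g in names:
        n = groups[g].size
        mean_ranks[g] = ranks[start:start + n].mean()
        sizes[g] = n
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "pvalue": p})
    out = pd.DataFrame(rows)
    order = np.argsort(out["pvalue"].to_numpy())
    m = len(out)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * out["pvalue"].iloc[idx])
        adj[idx] = min(running, 1.0)
    out["pvalue_holm"] = adj
    return out


def group_comparison(groups: dict[str, np.ndarray]) -> GroupComparison:
    """Two groups: two-tailed unpaired t-test; more: Kruskal-Wallis + Dunn/Holm."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    if len(arrays) == 2:
        a, b = arrays.values()
        t, p = stats.ttest_ind(a, b)
        return GroupComparison(method="t-test", statistic=float(t), pvalue=float(p))
    h, p = stats.kruskal(*arrays.values())
    return GroupComparison(
        method="kruskal-wallis", statistic=float(h), pvalue=float(p),
        posthoc=_dunn_posthoc(arrays),
    )
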