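"""Multivariate indices and phenotypes over the seven morphometry features.

All models are fitted on a training cohort and frozen: test cohorts are
standardized with the *training* means and standard deviations, projected
through the *training* principal-component loadings, and assigned to the
*training* K-means centroids. The first two oriented components are the
Chronicity Index (fibrillary collagen loads positively) and the Inverted
Acute Index (tubular cell fraction loads positively; low values indicate
acute tubular injury).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .morphometry import FEATURES_7

INDEX_LABELS = ("ChronicityIndex", "InvertedAcuteIndex")


@dataclass
class ZScaler:
    """Frozen per-feature training mean and standard deviation (ddof=1)."""

    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZScaler":
        return cls(list(d["feature_names"]), np.asarray(d["mean"]), np.asarray(d["sd"]))


def _check_features(df: pd.DataFrame, names: list[str]) -> np.ndarray:
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise KeyError(f"feature columns missing: {missing}")
    x = df[names].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("features contain NaN")
    return x


def fit_scaler(training: pd.DataFrame, feature_names: list[str] | None = None) -> ZScaler:
    """Fit the z-score reference on the training cohort."""
    names = list(feature_names or FEATURES_7)
    x = _check_features(training, names)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training cases to fit a scaler")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    bad = [n for n, s in zip(names, sd) if s == 0]
    if bad:
        raise ValueError(f"constant features cannot be z-scored: {bad}")
    return ZScaler(names, mean, sd)


def apply_scaler(scaler: ZScaler, features: pd.DataFrame) -> pd.DataFrame:
    """Standardize features against the frozen training reference."""
    x = _check_features(features, scaler.feature_names)
    z = (x - scaler.mean) / scaler.sd
    return pd.DataFrame(z, columns=scaler.feature_names, index=features.index)


@dataclass
class IndexModel:
    """Frozen scaler + oriented PCA loadings defining the two indices.

    Loadings columns are orthonormal eigenvectors of the training
    correlation matrix, retained by the Kaiser rule (eigenvalue > 1) by
    default and sign-oriented so that iColl% loads positively on the
    first component and tCell% positively on the second.
    """

    scaler: ZScaler
    loadings: np.ndarray  # (n_features, n_components)
    explained_variance: np.ndarray  # eigenvalues of retained components
    component_labels: list[str]
    warning: str | None = None

    def to_dict(self) -> dict:
        return {
            "scaler": self.scaler.to_dict(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "component_labels": list(self.component_labels),
            "warning": self.warning,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IndexModel":
        return cls(
            scaler=ZScaler.from_dict(d["scaler"]),
            loadings=np.asarray(d["loadings"]),
            explained_variance=np.asarray(d["explained_variance"]),
            component_labels=list(d["component_labels"]),
            warning=d.get("warning"),
        )


def fit_pca(
    training: pd.DataFrame,
    retention: str | int = "kaiser",
    feature_names: list[str] | None = None,
    scaler: ZScaler | None = None,
) -> IndexModel:
    """Fit the index-defining PCA on the training cohort.

    ``retention`` is either the Kaiser rule ("kaiser": keep eigenvalues of
    the correlation matrix above 1) or a fixed component count. At least
    two components are always kept so both indices exist; if the rule
    alone would keep fewer, the model carries an explicit warning.
    """
    names = list(feature_names or FEATURES_7)
    if len(training) < 8:
        raise ValueError("need at least 8 training cases for a stable PCA")
    scaler = scaler or fit_scaler(training, names)
    z = apply_scaler(scaler, training).to_numpy()
    corr = np.cov(z, rowvar=False, ddof=1)  # correlation matrix of raw features
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    warning = None
    if retention == "kaiser":
        k = int((evals > 1.0).sum())
        if k < 2:
            warning = f"Kaiser rule retained {k} component(s); forcing 2 for the indices"
            warnings.warn(warning, stacklevel=2)
            k = 2
    else:
        k = int(retention)
        if k < 2:
            raise ValueError("at least 2 components are required for the indices")
    load = evecs[:, :k].copy()

    # orientation convention: Chronicity Index has positive fibrillary
    # collagen loading; Inverted Acute Index has positive tubular cell loading
    i_coll = names.index("iColl%") if "iColl%" in names else 0
    i_cell = names.index("tCell%") if "tCell%" in names else min(1, len(names) - 1)
    anchors = [i_coll, i_cell]
    for j in range(k):
        anchor = anchors[j] if j < 2 else int(np.argmax(np.abs(load[:, j])))
        if load[anchor, j] < 0:
            load[:, j] = -load[:, j]

    labels = list(INDEX_LABELS[:k]) + [f"PC{j + 1}" for j in range(2, k)]
    return IndexModel(
        scaler=scaler,
        loadings=load,
        explained_variance=evals[:k],
        component_labels=labels,
        warning=warning,
    )


def project(model: IndexModel, features: pd.DataFrame) -> pd.DataFrame:
    """Project cases into the frozen index space.

    Features are standardized with the TRAINING scaler, then multiplied by
    the training loadings; projecting the training cohort reproduces its
    fit scores exactly.
    """
    z = apply_scaler(model.scaler, features).to_numpy()
    scores = z @ model.loadings
    return pd.DataFrame(scores, columns=model.component_labels, index=features.index)


def fit_index_model(training: pd.DataFrame, retention: str | int = "kaiser") -> IndexModel:
    """Fit scaler + PCA in one step on the training feature table."""
    return fit_pca(training, retention=retention)


# --------------------------------------------------------------------------
# K-means phenotyping


SEMANTIC_LABELS = ("intact", "intermediate", "chronic_severe", "acute")


@dataclass
class ClusterModel:
    """Frozen K-means centroids in z-space with semantic phenotype labels."""

    feature_names: list[str]
    centroids: np.ndarray  # (k, n_features) in z-space
    semantic_labels: list[str]
    training_assignment: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    selected_k: int = 0
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "centroids": self.centroids.tolist(),
            "semantic_labels": list(self.semantic_labels),
            "training_assignment": self.training_assignment.tolist(),
            "selected_k": self.selected_k,
            "silhouette_by_k": {str(k): v for k, v in self.silhouette_by_k.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterModel":
        return cls(
            feature_names=list(d["feature_names"]),
            centroids=np.asarray(d["centroids"]),
            semantic_labels=list(d["semantic_labels"]),
            training_assignment=np.asarray(d["training_assignment"], dtype=int),
            selected_k=int(d["selected_k"]),
            silhouette_by_k={int(k): v for k, v in d.get("silhouette_by_k", {}).items()},
        )


def _semantic_labels(centroids: np.ndarray, names: list[str]) -> list[str]:
    """Deterministic phenotype names from centroid profiles.

    chronic_severe = highest fibrillary collagen centroid; acute = highest
    tubular lumen among the rest; intact = highest tCell%+tSize among the
    rest; remaining centroids are intermediate (numbered if several).
    """
    k = centroids.shape[0]
    idx = {n: names.index(n) for n in names}
    labels = [""] * k
    remaining = set(range(k))

    def take(score_fn, label):
        if not remaining:
            return
        best = max(remaining, key=score_fn)
        labels[best] = label
        remaining.discard(best)

    take(lambda i: centroids[i, idx["iColl%"]], "chronic_severe")
    take(lambda i: centroids[i, idx["tLumen%"]], "acute")
    take(lambda i: centroids[i, idx["tCell%"]] + centroids[i, idx["tSize"]], "intact")
    rest = sorted(remaining)
    for j, i in enumerate(rest):
        labels[i] = "intermediate" if len(rest) == 1 else f"intermediate_{j + 1}"
    return labels


def fit_clusters(
    z_features: pd.DataFrame,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 8),
    seed: int = 0,
    n_init: int = 10,
) -> ClusterModel:
    """Fit K-means phenotypes in z-space.

    If ``k`` is None the cluster count is selected by mean silhouette over
    ``k_range`` (inclusive). Fitting is deterministic for a fixed seed.
    """
    x = z_features.to_numpy(dtype=float)
    n = x.shape[0]
    sil: dict[int, float] = {}
    if k is None:
        lo, hi = k_range
        candidates = [kk for kk in range(lo, hi + 1) if kk < n]
        if not candidates:
            raise ValueError("not enough cases to select k")
        for kk in candidates:
            km = KMeans(n_clusters=kk, n_init=n_init, random_state=seed).fit(x)
            sil[kk] = float(silhouette_score(x, km.labels_))
        k = max(sil, key=sil.get)
    if k > n:
        raise ValueError(f"k={k} exceeds number of cases n={n}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    names = list(z_features.columns)
    return ClusterModel(
        feature_names=names,
        centroids=km.cluster_centers_.copy(),
        semantic_labels=_semantic_labels(km.cluster_centers_, names),
        training_assignment=km.labels_.copy(),
        selected_k=int(k),
        silhouette_by_k=sil,
    )


def predict_clusters(model: ClusterModel, z_features: pd.DataFrame) -> np.ndarray:
    """Nearest-centroid assignment in z-space (the frozen training metric)."""
    x = z_features[model.feature_names].to_numpy(dtype=float)
    return np.argmin(cdist(x, model.centroids), axis=1)


def cluster_profiles(z_features: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster mean z-profile (radar-plot data, axes not rescaled)."""
    df = z_features.copy()
    df["_cluster"] = np.asarray(labels)
    return df.groupby("_cluster").mean()


def within_cluster_correlations(
    features: pd.DataFrame,
    labels: np.ndarray,
    method: str = "pearson",
    min_cases: int = 3,
) -> dict[int, pd.DataFrame | None]:
    """Pairwise feature correlations within each cluster.

    Clusters with fewer than ``min_cases`` members yield None rather than
    a fabricated matrix.
    """
    out: dict[int, pd.DataFrame | None] = {}
    labels = np.asarray(labels)
    for lab in np.unique(labels):
        sub = features.loc[labels == lab]
        out[int(lab)] = sub.corr(method=method) if len(sub) >= min_cases else None
    return out
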