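"""Firing-type clustering: sparse PCA reduction + Gaussian-mixture BIC.

Each of the per-cell feature datasets is z-scored column-wise and
reduced with sparse principal component analysis, keeping components
until the cumulative (adjusted) explained variance reaches ``var_target``
(default 0.95), with a per-dataset cap so the concatenated score matrix
stays low-dimensional.  Cells are then clustered with Gaussian mixture
models fitted by EM over a grid of component counts and covariance
structures; the model minimizing the Bayesian information criterion
BIC = -2 logL + k log n is selected, with ties broken toward fewer
clusters and the simpler (diagonal) structure.

A rule-based classification in the Petilla spirit is also provided:
cells are split into irregular and regular firing by the ISI CV above
rheobase; irregular cells with sag ratio > 1.6 form the high-sag
(rosehip-like) group, and regular cells whose first spike at rheobase
arrives later than half the step are labeled late-spiking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA, SparsePCA
from sklearn.mixture import GaussianMixture

from .ap_features import CellFeatures

__all__ = [
    "SparsePCAResult",
    "ClusterModel",
    "PetillaThresholds",
    "sparse_pca",
    "fit_gmm_bic",
    "cluster_cohort",
    "classify_firing_petilla",
    "embed_tsne",
]


@dataclass
class SparsePCAResult:
    scores: np.ndarray        # (n_cells, n_retained)
    loadings: np.ndarray      # (n_retained, n_features)
    explained_ratio: np.ndarray
    n_retained: int


@dataclass
class ClusterModel:
    """Fitted sPCA + GMM model for a cohort."""

    K_selected: int
    structure: str
    labels: np.ndarray
    bic_table: dict                      # (K, structure) -> BIC
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    scores: np.ndarray                   # concatenated sPCA scores
    dataset_components: list = field(default_factory=list)  # per-dataset n_retained
    dataset_loadings: list = field(default_factory=list)
    seed: Optional[int] = None

    def to_summary(self) -> dict:
        return {
            "K_selected": int(self.K_selected),
            "structure": self.structure,
            "bic_table": {f"{k}|{s}": float(v) for (k, s), v in self.bic_table.items()},
            "dataset_components": [int(c) for c in self.dataset_components],
            "n_cells": int(len(self.labels)),
            "seed": self.seed,
        }


def _zscore_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (X - mu) / sd


def sparse_pca(
    dataset_matrix: np.ndarray,
    var_target: float = 0.95,
    penalty: float = 0.0,
    max_components: int = 5,
    standardize: bool = True,
    seed: int = 0,
) -> SparsePCAResult:
    """Reduce one feature dataset with (sparse) PCA.

    With ``penalty == 0`` this is ordinary PCA.  With ``penalty > 0`` an
    l1 penalty is applied to the loadings and explained variance is the
    adjusted variance computed by QR-decomposing the score matrix (the
    standard correction for non-orthogonal sparse components).
    Components are retained until the cumulative explained-variance
    ratio reaches ``var_target``, up to ``max_components``.
    """
    if not 0.0 < var_target <= 1.0:
        raise ValueError("var_target must be in (0, 1]")
    X = np.asarray(dataset_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("dataset_matrix must be 2-D (cells x features)")
    n, p = X.shape
    if standardize:
        X = _zscore_columns(X)
    else:
        X = X - X.mean(axis=0)
    total_var = float(np.sum(X.var(axis=0, ddof=1))) if n > 1 else 0.0
    if total_var < 1e-12:
        warnings.warn("zero-variance dataset: no components retained")
        return SparsePCAResult(
            scores=np.zeros((n, 0)), loadings=np.zeros((0, p)),
            explained_ratio=np.zeros(0), n_retained=0,
        )
    n_max = min(max_components, n - 1 if n > 1 else 1, p)

    if penalty <= 0.0:
        model = PCA(n_components=n_max, svd_solver="full")
        scores_full = model.fit_transform(X)
        loadings = model.components_
        evr = model.explained_variance_ratio_
    else:
        model = SparsePCA(
            n_components=n_max, alpha=penalty, ridge_alpha=1e-8,
            random_state=seed, max_iter=500, tol=1e-7,
        )
        model.fit(X)
        loadings = model.components_
        scores_full = X @ loadings.T
        # adjusted explained variance via QR of the score matrix
        _, R = np.linalg.qr(scores_full)
        adj_var = np.diag(R) ** 2 / max(n - 1, 1)
        evr = adj_var / total_var

    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, var_target - 1e-12) + 1)
    k = min(k, n_max)
    return SparsePCAResult(
        scores=scores_full[:, :k],
        loadings=loadings[:k],
        explained_ratio=np.asarray(evr[:k]),
        n_retained=k,
    )


def fit_gmm_bic(
    scores: np.ndarray,
    K_range: Sequence[int] = range(1, 11),
    structures: Sequence[str] = ("diag", "full"),
    n_init: int = 5,
    seed: int = 0,
    reg_covar: float = 1e-2,
) -> ClusterModel:
    """Fit Gaussian mixtures over (K, covariance structure) and pick the
    BIC minimum.

    EM uses k-means++ initialization with ``n_init`` restarts; ties in
    BIC are broken toward smaller K, then the diagonal structure.
    ``reg_covar`` floors every covariance eigenvalue: with unconstrained
    full covariances and more dimensions than the sample size supports,
    a floor far below the data scale lets EM profit from degenerate
    volume shrinkage and over-split heavy-tailed clusters, so the
    default is scaled to O(1) score variances.
    """
    X = np.asarray(scores, dtype=float)
    if np.any(~np.isfinite(X)):
        raise ValueError("scores contain missing values")
    bic_table: dict[tuple[int, str], float] = {}
    fits: dict[tuple[int, str], GaussianMixture] = {}
    for K in K_range:
        if K > len(X):
            continue
        for struct in structures:
            gm = GaussianMixture(
                n_components=K, covariance_type=struct, n_init=n_init,
                init_params="k-means++", random_state=seed, reg_covar=reg_covar,
                max_iter=300,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(X)
            bic_table[(K, struct)] = float(gm.bic(X))
            fits[(K, struct)] = gm
    # tie-break: smaller K first, then 'diag' before 'full'
    order = {"diag": 0, "full": 1}
    best = min(bic_table, key=lambda ks: (round(bic_table[ks], 9), ks[0], order.get(ks[1], 9)))
    gm = fits[best]
    return ClusterModel(
        K_selected=best[0],
        structure=best[1],
        labels=gm.predict(X) + 1,
        bic_table=bic_table,
        weights=gm.weights_,
        means=gm.means_,
        covariances=gm.covariances_,
        scores=X,
        seed=seed,
    )


def cluster_cohort(
    matrices: Sequence[np.ndarray],
    var_target: float = 0.95,
    penalty: float = 0.0,
    max_components: int = 5,
    K_range: Sequence[int] = range(1, 11),
    structures: Sequence[str] = ("diag", "full"),
    n_init: int = 5,
    seed: int = 0,
    reg_covar: float = 1e-2,
) -> ClusterModel:
    """Reduce each feature dataset with sPCA and cluster the concatenated
    scores with GMM + BIC."""
    results = [
        sparse_pca(M, var_target=var_target, penalty=penalty,
                   max_components=max_components, seed=seed)
        for M in matrices
    ]
    kept = [r for r in results if r.n_retained > 0]
    if not kept:
        raise ValueError("no dataset yielded any component")
    scores = np.hstack([r.scores for r in kept])
    model = fit_gmm_bic(scores, K_range=K_range, structures=structures,
                        n_init=n_init, seed=seed, reg_covar=reg_covar)
    model.dataset_components = [r.n_retained for r in results]
    model.dataset_loadings = [r.loadings for r in results]
    return model


@dataclass
class PetillaThresholds:
    cv_threshold: float = 0.35       # ISI CV separating irregular from regular
    sag_threshold: float = 1.6       # rosehip-like high-sag criterion
    latency_fraction: float = 0.5    # of the step duration, for late-spiking
    step_duration_ms: float = 800.0
    cv_at_rel_current: float = 40.0  # pA above rheobase where CV is read


def classify_firing_petilla(
    features: CellFeatures,
    thresholds: Optional[PetillaThresholds] = None,
) -> str:
    """Rule-based firing classification.

    Returns one of ``late-spiking``, ``no-sag/irregular``,
    ``non-late/regular``, ``high-sag/irregular`` or ``unclassifiable``
    (cell without a defined rheobase).
    """
    th = thresholds or PetillaThresholds()
    if features.rheobase is None:
        return "unclassifiable"
    cv = features.isi_cv_profile.get(th.cv_at_rel_current)
    if cv is None and features.isi_cv_profile:
        # nearest available current step above rheobase
        key = min(features.isi_cv_profile,
                  key=lambda k: abs(k - th.cv_at_rel_current))
        cv = features.isi_cv_profile[key]
    irregular = cv is not None and cv > th.cv_threshold
    if irregular:
        if np.isfinite(features.sag_ratio) and features.sag_ratio > th.sag_threshold:
            return "high-sag/irregular"
        return "no-sag/irregular"
    lat = features.first_spike_latency
    if lat is not None and lat > th.latency_fraction * th.step_duration_ms:
        return "late-spiking"
    return "non-late/regular"


def embed_tsne(scores: np.ndarray, perplexity: float = 15.0, seed: int = 0) -> np.ndarray:
    """2-D t-SNE embedding of the score matrix (visualization only)."""
    from sklearn.manifold import TSNE

    X = np.asarray(scores, dtype=float)
    if len(X) < 3 * perplexity:
        raise ValueError(
            f"need at least 3*perplexity={3 * perplexity:.0f} cells, got {len(X)}"
        )
    ts = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return ts.fit_transform(X)
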