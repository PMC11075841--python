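"""Evolutionary signatures: normalization, projection, clustering, nulls.

A region's evolutionary signature is its vector of per-feature OU-vs-BM
log likelihood ratios.  Parameter matrices are z-scored per feature before
PCA (features have wildly different intrinsic scales); signatures are
clustered with average linkage (UPGMA) on the correlation distance
1 - Pearson r.  Significance-count analyses compare the observed joint
distribution of significant features against a null that shuffles each
feature's LLRs across regions independently, preserving every marginal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "Signature",
    "ClusterResult",
    "zscore_normalize",
    "pca_project",
    "rate_pc1_vs_divergence",
    "filter_by_rates",
    "cluster_signatures",
    "shuffled_llr_null",
    "significance_counts",
]


@dataclass
class Signature:
    region_id: str
    llr_vector: np.ndarray  # NaN marks missing tests


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy merge table
    labels: np.ndarray  # flat cluster label per input signature
    members: dict  # label -> list of region ids


def zscore_normalize(matrix: np.ndarray) -> np.ndarray:
    """Per-feature (column) z-scores over non-missing entries.

    Population standard deviation; NaN entries are preserved; a
    zero-variance column becomes all-NaN with a warning.
    """
    X = np.asarray(matrix, dtype=float).copy()
    if X.ndim != 2:
        raise ValueError("expected a 2-D regions x features matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0)
    out = np.full_like(X, np.nan)
    for j in range(X.shape[1]):
        col = X[:, j]
        finite = np.isfinite(col)
        if finite.sum() < 2 or sd[j] == 0 or not np.isfinite(sd[j]):
            if finite.any():
                warnings.warn(f"feature column {j} has zero variance; z-scores set missing")
            continue
        out[finite, j] = (col[finite] - mean[j]) / sd[j]
    return out


def pca_project(matrix: np.ndarray, n_components: int):
    """Centered SVD principal components.

    Missing entries must be imputed beforehand (the pipeline imputes 0
    after z-scoring).  Sign convention: the largest-magnitude loading of
    each component is positive.  Returns (scores, loadings, explained
    variance ratios); loadings are (n_features, n_components).
    """
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains NaN; impute before PCA")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    V = Vt[:n_components].T
    for c in range(n_components):
        if V[np.argmax(np.abs(V[:, c])), c] < 0:
            V[:, c] *= -1.0
            U[:, c] *= -1.0
    scores = U[:, :n_components] * s[:n_components]
    var = s**2 / max(X.shape[0] - 1, 1)
    ratios = var[:n_components] / var.sum()
    return scores, V, ratios


def rate_pc1_vs_divergence(pc1_scores: np.ndarray, region_rates: np.ndarray, ids_a=None, ids_b=None) -> float:
    """Pearson r between PC1 of the rate matrix and aa_rate + indel_rate."""
    if ids_a is not None and ids_b is not None and list(ids_a) != list(ids_b):
        raise ValueError("region id mismatch between PC scores and rates")
    x = np.asarray(pc1_scores, dtype=float)
    y = np.asarray(region_rates, dtype=float)
    if x.shape != y.shape:
        raise ValueError("mismatched lengths")
    return float(np.corrcoef(x, y)[0, 1])


def filter_by_rates(regions, aa_rates, indel_rates, aa_cutoff: float = 1.0, indel_cutoff: float = 0.1):
    """Keep regions whose aa rate OR indel rate strictly exceeds its cutoff."""
    aa = np.asarray(aa_rates, dtype=float)
    ind = np.asarray(indel_rates, dtype=float)
    keep = (aa > aa_cutoff) | (ind > indel_cutoff)
    return [r for r, k in zip(regions, keep) if k], keep


def _correlation_distance_matrix(X: np.ndarray) -> np.ndarray:
    """1 - Pearson r between rows; rows with zero variance get distance 1."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    constant = sd == 0
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.where(sd > 0, np.sqrt((Xc**2).sum(axis=1)), 1.0)
    Z = Xc / norm[:, None]
    corr = Z @ Z.T
    D = 1.0 - np.clip(corr, -1.0, 1.0)
    D[constant, :] = 1.0
    D[:, constant] = 1.0
    np.fill_diagonal(D, 0.0)
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant signature(s): correlation undefined, distance set to 1")
    return D


def cluster_signatures(
    signatures: list[Signature],
    distance: str = "correlation",
    linkage_method: str = "average",
    cut_height: float | None = None,
    n_clusters: int | None = None,
    standardize: bool = False,
) -> ClusterResult:
    """UPGMA clustering of signatures on correlation distance.

    Missing LLRs are imputed as 0 (no evidence either way) for the
    distance computation only.  Flat clusters come from a distance
    threshold (``cut_height``) or a requested cluster count; by default
    the tree is cut at 70% of the maximum merge height.

    ``standardize`` z-scores each feature's LLRs across signatures before
    computing correlations.  Raw LLR vectors are non-negative, so their
    pairwise correlations share a common positive offset that lets
    average-linkage chain unrelated regions through a tight cluster;
    per-feature standardization removes the offset and makes block
    recovery robust.  Off by default to match the plain correlation
    definition of the distance.
    """
    if len(signatures) < 2:
        raise ValueError("need at least 2 signatures")
    if distance != "correlation" or linkage_method != "average":
        raise ValueError("only correlation distance with UPGMA is supported")
    X = np.vstack([np.nan_to_num(s.llr_vector, nan=0.0) for s in signatures])
    if standardize:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            X = np.nan_to_num(zscore_normalize(X), nan=0.0)
    D = _correlation_distance_matrix(X)
    Z = linkage(squareform(D, checks=False), method="average")
    if n_clusters is not None:
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        height = cut_height if cut_height is not None else 0.7 * Z[:, 2].max()
        labels = fcluster(Z, t=height, criterion="distance")
    members: dict[int, list[str]] = {}
    for sig, lab in zip(signatures, labels):
        members.setdefault(int(lab), []).append(sig.region_id)
    return ClusterResult(Z, np.asarray(labels), members)


def shuffled_llr_null(llr_matrix: np.ndarray, seed: int) -> np.ndarray:
    """Permute each feature's LLRs across regions independently.

    Marginal per-feature distributions are preserved exactly; the joint
    dependence between features is destroyed.
    """
    X = np.asarray(llr_matrix, dtype=float).copy()
    rng = np.random.default_rng(seed)
    for j in range(X.shape[1]):
        X[:, j] = X[rng.permutation(X.shape[0]), j]
    return X


def significance_counts(llr_matrix: np.ndarray, critical_values: dict):
    """Per-region significant-feature counts and per-feature fractions.

    ``critical_values`` maps level -> critical; significance is strict
    (llr > critical); NaN entries (missing tests) are excluded from both
    counts and denominators.
    """
    X = np.asarray(llr_matrix, dtype=float)
    finite = np.isfinite(X)
    per_region = {}
    per_feature = {}
    for level, crit in critical_values.items():
        sig = finite & (X > crit)
        per_region[level] = sig.sum(axis=1)
        denom = finite.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_feature[level] = np.where(denom > 0, sig.sum(axis=0) / np.maximum(denom, 1), np.nan)
    return per_region, per_feature
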