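"""PCA class-separation statistics for gene signatures.

Projects the signature-gene submatrix of a labeled expression dataset onto
its first principal components, measures the Euclidean distance between the
two class centroids in the 2-D embedding, and assesses it against two nulls:
class-label permutation (fixed embedding) and size-matched random gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionDataset
from .signatures import normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "SeparationResult",
    "signature_pca",
    "centroid_distance",
    "permutation_test",
    "random_geneset_baseline",
]


@dataclass
class SeparationResult:
    """Observed centroid separation plus its permutation / random-set nulls."""

    embedding: pd.DataFrame  # samples x components
    centroid_a: np.ndarray
    centroid_b: np.ndarray
    distance: float
    permutation_null: np.ndarray
    permutation_p: float
    baseline_distances: np.ndarray | None = None
    baseline_p: float | None = None
    classes: tuple[str, str] | None = None
    genes_used: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        out = {
            "distance": self.distance,
            "permutation_p": self.permutation_p,
            "permutation_null": [float(x) for x in self.permutation_null],
            "classes": list(self.classes) if self.classes else None,
            "genes_used": list(self.genes_used),
            "centroid_a": [float(x) for x in self.centroid_a],
            "centroid_b": [float(x) for x in self.centroid_b],
            "embedding": {
                str(s): [float(v) for v in row]
                for s, row in self.embedding.iterrows()
            },
        }
        if self.baseline_distances is not None:
            out["baseline_distances"] = [float(x) for x in self.baseline_distances]
            out["baseline_p"] = self.baseline_p
        return out


def _standardize_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row (gene) across samples, dropping zero-variance rows."""
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    nonconst = sd[:, 0] > 0
    if not nonconst.all():
        dropped = values.index[~nonconst].tolist()
        logger.warning("dropping %d zero-variance genes: %s",
                       len(dropped), dropped[:10])
    z = (arr[nonconst] - mean[nonconst]) / sd[nonconst]
    return pd.DataFrame(z, index=values.index[nonconst], columns=values.columns)


def signature_pca(
    ds: ExpressionDataset,
    genes: Iterable[str],
    n_components: int = 2,
    scale: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PCA of the signature-gene submatrix.

    Genes are standardized across samples (``scale=False`` gives plain
    covariance PCA on centered rows), then the samples are decomposed with an
    SVD.  Returns ``(embedding, loadings)``: per-sample component scores and
    per-gene component weights.  PC1 is sign-oriented so that its scores
    correlate non-negatively with the per-sample mean of the (standardized)
    signature genes; further components get a deterministic largest-loading-
    positive orientation.
    """
    wanted = {normalize_symbol(g) for g in genes}
    present = [f for f in ds.feature_ids if normalize_symbol(str(f)) in wanted]
    sub = ds.values.loc[present]
    if scale:
        z = _standardize_rows(sub)
    else:
        arr = sub.to_numpy(dtype=float)
        z = pd.DataFrame(arr - arr.mean(axis=1, keepdims=True),
                         index=sub.index, columns=sub.columns)
    if z.shape[0] < 2:
        raise ValueError("signature too small in dataset")
    if z.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA")

    x = z.to_numpy().T  # samples x genes, already column-centered
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, s.size)
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T  # genes x components

    # orient PC1 against the per-sample mean of the standardized genes
    mean_profile = z.to_numpy().mean(axis=0)
    align = float(np.dot(scores[:, 0], mean_profile - mean_profile.mean()))
    if align < 0:
        scores[:, 0] *= -1
        loadings[:, 0] *= -1
    for j in range(1, k):
        lead = loadings[np.argmax(np.abs(loadings[:, j])), j]
        if lead < 0:
            scores[:, j] *= -1
            loadings[:, j] *= -1

    comps = [f"PC{i + 1}" for i in range(k)]
    embedding = pd.DataFrame(scores, index=z.columns, columns=comps)
    loadings_df = pd.DataFrame(loadings, index=z.index, columns=comps)
    return embedding, loadings_df


def _class_split(labels: pd.Series) -> tuple[str, str]:
    classes = sorted(set(labels.dropna()))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    return classes[0], classes[1]


def centroid_distance(embedding: pd.DataFrame, labels: pd.Series) -> float:
    """Euclidean distance between the two class mean points in the embedding."""
    labels = labels.reindex(embedding.index).dropna()
    a, b = _class_split(labels)
    pts_a = embedding.loc[labels.index[labels == a]].to_numpy()
    pts_b = embedding.loc[labels.index[labels == b]].to_numpy()
    if len(pts_a) == 0 or len(pts_b) == 0:
        raise ValueError("a class has no samples in the embedding")
    return float(np.linalg.norm(pts_a.mean(axis=0) - pts_b.mean(axis=0)))


def permutation_test(
    ds: ExpressionDataset,
    genes: Iterable[str],
    labels: pd.Series | None = None,
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
    n_components: int = 2,
    scale: bool = True,
    refit: bool = False,
) -> SeparationResult:
    """Class-label permutation test of the centroid separation.

    Labels are shuffled with class sizes preserved; by default the embedding
    stays fixed (PCA is unsupervised, so labels cannot influence it) and only
    the centroids are recomputed.  ``refit=True`` re-runs the PCA per
    permutation instead.  ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if labels is None:
        labels = ds.labels
    if labels is None:
        raise ValueError("labels required")
    rng = np.random.default_rng(seed)
    embedding, loadings = signature_pca(ds, genes, n_components=n_components,
                                        scale=scale)
    labels = labels.reindex(embedding.index).dropna()
    a, b = _class_split(labels)
    observed = centroid_distance(embedding, labels)

    lab_values = labels.to_numpy()
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = pd.Series(rng.permutation(lab_values), index=labels.index)
        if refit:
            emb_i, _ = signature_pca(ds, genes, n_components=n_components,
                                     scale=scale)
        else:
            emb_i = embedding
        null[i] = centroid_distance(emb_i, shuffled)
    # tolerance guard so numerically tied permutations count as >= observed
    gamma = max(1e-12, 1e-12 * abs(observed))
    p = (1.0 + float(np.sum(null >= observed - gamma))) / (1.0 + n_perm)

    pts_a = embedding.loc[labels.index[labels == a]].to_numpy().mean(axis=0)
    pts_b = embedding.loc[labels.index[labels == b]].to_numpy().mean(axis=0)
    return SeparationResult(
        embedding=embedding,
        centroid_a=pts_a,
        centroid_b=pts_b,
        distance=observed,
        permutation_null=null,
        permutation_p=p,
        classes=(a, b),
        genes_used=tuple(str(g) for g in loadings.index),
    )


def random_geneset_baseline(
    ds: ExpressionDataset,
    signature_size: int,
    universe: Iterable[str],
    labels: pd.Series | None = None,
    observed_distance: float | None = None,
    n_sets: int = 100,
    seed: int | np.random.Generator = 0,
    n_components: int = 2,
    scale: bool = True,
) -> tuple[np.ndarray, float | None]:
    """Centroid distances for size-matched random gene sets from the universe.

    Random sets are drawn uniformly without replacement from the universe
    restricted to genes measured in ``ds``; each gets its own PCA.  When
    ``observed_distance`` is given, returns the plus-one-rule p-value of the
    observed separation against the baseline distances.
    """
    if labels is None:
        labels = ds.labels
    if labels is None:
        raise ValueError("labels required")
    rng = np.random.default_rng(seed)
    measured = {normalize_symbol(str(f)) for f in ds.feature_ids}
    pool = np.array(sorted({normalize_symbol(g) for g in universe} & measured))
    if pool.size < signature_size:
        raise ValueError(
            f"universe too small: {pool.size} measured genes < {signature_size}"
        )
    distances = np.empty(n_sets)
    for i in range(n_sets):
        picked = pool[rng.choice(pool.size, size=signature_size, replace=False)]
        emb, _ = signature_pca(ds, picked, n_components=n_components, scale=scale)
        distances[i] = centroid_distance(emb, labels)
    p = None
    if observed_distance is not None:
        gamma = max(1e-12, 1e-12 * abs(observed_distance))
        p = (1.0 + float(np.sum(distances >= observed_distance - gamma))) \
            / (1.0 + n_sets)
    return distances, p
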