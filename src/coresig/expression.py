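"""Expression-matrix ingestion, probe collapsing and feature filters.

Datasets are log2-scale feature x sample matrices with optional phenotype
labels and an optional probe-to-gene map.  Two filters are provided: a
fluorescence-intensity filter (value above a log2 threshold in at least a
fraction of samples) and a cross-dataset consistency filter (median pairwise
rank correlation over shared samples at or above a threshold).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "ConsistencyReport",
    "intensity_filter",
    "collapse_probes",
    "align_common",
    "consistency_filter",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_labels_tsv",
    "read_feature_map_tsv",
]

DEFAULT_INTENSITY_THRESHOLD = math.log2(100.0)


@dataclass
class ExpressionDataset:
    """A log2 expression matrix (features x samples) with optional metadata."""

    values: pd.DataFrame
    labels: pd.Series | None = None
    feature_map: pd.Series | None = None  # probe id -> gene symbol
    name: str = "dataset"

    def __post_init__(self) -> None:
        cols = self.values.columns
        if cols.duplicated().any():
            dupes = cols[cols.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        vals = self.values.to_numpy(dtype=float, copy=False)
        if not np.isfinite(vals).all():
            raise ValueError("matrix contains non-finite values")
        if self.labels is not None:
            extra = set(self.labels.index) - set(cols)
            if extra:
                raise ValueError(f"labels for unknown samples: {sorted(extra)}")
            self.labels = self.labels.reindex(
                [c for c in cols if c in set(self.labels.index)]
            )

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, features: Sequence[str]) -> "ExpressionDataset":
        keep = [f for f in features if f in set(self.values.index)]
        return replace(self, values=self.values.loc[keep])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionDataset":
        sub = self.values.loc[:, list(samples)]
        labels = None
        if self.labels is not None:
            labels = self.labels.reindex(
                [s for s in samples if s in set(self.labels.index)]
            )
        return replace(self, values=sub, labels=labels)


@dataclass(frozen=True)
class ConsistencyReport:
    """Per-feature pairwise rank correlations across dataset pairs."""

    correlations: pd.DataFrame  # features x dataset-pair columns
    medians: pd.Series
    kept: pd.Series  # boolean per feature
    threshold: float
    degenerate: pd.Series  # features with at least one undefined correlation

    def to_frame(self) -> pd.DataFrame:
        out = self.correlations.copy()
        out["median"] = self.medians
        out["kept"] = self.kept
        out["degenerate"] = self.degenerate
        return out


# ---------------------------------------------------------------------------
# filters


def intensity_filter(
    ds: ExpressionDataset,
    threshold_log2: float = DEFAULT_INTENSITY_THRESHOLD,
    min_fraction: float = 0.10,
) -> ExpressionDataset:
    """Keep features above ``threshold_log2`` in at least ``min_fraction`` of samples.

    The sample count requirement is ``ceil(min_fraction * n_samples)``.
    An empty result is a warning, not an error.
    """
    need = math.ceil(min_fraction * ds.n_samples)
    above = (ds.values.to_numpy() > threshold_log2).sum(axis=1)
    mask = above >= need
    if not mask.any():
        logger.warning("intensity_filter removed every feature of %s", ds.name)
    logger.info(
        "intensity_filter(%s): %d of %d features kept",
        ds.name, int(mask.sum()), ds.n_features,
    )
    return replace(ds, values=ds.values.loc[mask])


def collapse_probes(
    ds: ExpressionDataset, method: str = "max_mean"
) -> ExpressionDataset:
    """Collapse probe rows to one row per mapped gene symbol.

    ``max_mean`` (default) lets the probe with the highest mean intensity
    represent the gene; ``median`` takes the per-sample median across the
    gene's probes.  Probes without a mapping are dropped (count logged).
    """
    if ds.feature_map is None:
        raise ValueError("collapse_probes requires a feature_map")
    fmap = ds.feature_map
    mapped = ds.values.index.intersection(fmap.index)
    n_dropped = ds.n_features - len(mapped)
    if n_dropped:
        logger.info("collapse_probes(%s): dropped %d unmapped probes",
                    ds.name, n_dropped)
    sub = ds.values.loc[mapped]
    genes = fmap.reindex(mapped).astype(str).str.strip().str.upper()
    if method == "max_mean":
        means = sub.mean(axis=1)
        order = pd.DataFrame({"gene": genes.values, "mean": means.values,
                              "probe": mapped})
        best = (order.sort_values(["gene", "mean", "probe"])
                     .groupby("gene", sort=True).last()["probe"])
        collapsed = sub.loc[best.values]
        collapsed.index = best.index
    elif method == "median":
        collapsed = sub.groupby(genes.values, sort=True).median()
        collapsed.index.name = None
    else:
        raise ValueError(f"unknown collapse method {method!r}")
    return replace(ds, values=collapsed, feature_map=None)


def align_common(
    dsets: Sequence[ExpressionDataset], samples: bool = True
) -> list[ExpressionDataset]:
    """Restrict datasets to shared features (and optionally shared samples).

    Sample matching is by exact id string after case-folding; outputs share
    identical row ordering (sorted feature ids) and column ordering (the
    first dataset's sample order restricted to the shared set).
    """
    if len(dsets) < 2:
        raise ValueError("align_common needs at least 2 datasets")
    shared_features = set(dsets[0].feature_ids)
    for ds in dsets[1:]:
        shared_features &= set(ds.feature_ids)
    if not shared_features:
        raise ValueError("empty feature intersection")
    feature_order = sorted(shared_features)

    out = []
    if samples:
        folded = [
            {str(s).casefold(): s for s in ds.sample_ids} for ds in dsets
        ]
        shared = set(folded[0])
        for f in folded[1:]:
            shared &= set(f)
        if not shared:
            raise ValueError("empty sample intersection")
        order = [str(s).casefold() for s in dsets[0].sample_ids
                 if str(s).casefold() in shared]
        for ds, f in zip(dsets, folded):
            cols = [f[key] for key in order]
            out.append(ds.subset_features(feature_order).subset_samples(cols))
    else:
        out = [ds.subset_features(feature_order) for ds in dsets]
    return out


def _rowwise_spearman(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-by-row Spearman correlation (midranks) between two equal-shape arrays.

    Returns (rho, degenerate) where degenerate marks rows whose correlation
    is undefined (a constant vector on either side); those rows score 0.
    """
    ra = np.apply_along_axis(stats.rankdata, 1, a)
    rb = np.apply_along_axis(stats.rankdata, 1, b)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    na = np.sqrt((ra ** 2).sum(axis=1))
    nb = np.sqrt((rb ** 2).sum(axis=1))
    degenerate = (na == 0) | (nb == 0)
    denom = np.where(degenerate, 1.0, na * nb)
    rho = (ra * rb).sum(axis=1) / denom
    rho[degenerate] = 0.0
    return rho, degenerate


def consistency_filter(
    dsets: Sequence[ExpressionDataset], threshold: float = 0.50
) -> tuple[set[str], ConsistencyReport]:
    """Keep features whose median cross-dataset rank correlation meets ``threshold``.

    For every dataset pair, each feature's expression profile over the shared
    samples is rank-correlated (Spearman with midranks); a feature is kept iff
    the median over all D*(D-1)/2 pair coefficients is at least ``threshold``.
    Undefined correlations (constant vectors) count as 0 and are flagged.
    """
    if len(dsets) < 2:
        raise ValueError("consistency_filter needs at least 2 datasets")
    first = dsets[0]
    for ds in dsets[1:]:
        if not ds.feature_ids.equals(first.feature_ids) or \
                ds.n_samples != first.n_samples:
            raise ValueError("datasets must be aligned first (see align_common)")
    if first.n_samples < 3:
        raise ValueError("need at least 3 shared samples")

    arrays = [ds.values.to_numpy(dtype=float) for ds in dsets]
    cols: dict[str, np.ndarray] = {}
    degenerate = np.zeros(first.n_features, dtype=bool)
    for i in range(len(dsets)):
        for j in range(i + 1, len(dsets)):
            rho, degen = _rowwise_spearman(arrays[i], arrays[j])
            cols[f"{dsets[i].name}|{dsets[j].name}"] = rho
            degenerate |= degen
    corr = pd.DataFrame(cols, index=first.feature_ids)
    medians = corr.median(axis=1)
    kept_mask = medians >= threshold
    report = ConsistencyReport(
        correlations=corr,
        medians=medians,
        kept=kept_mask,
        threshold=threshold,
        degenerate=pd.Series(degenerate, index=first.feature_ids),
    )
    kept = set(first.feature_ids[kept_mask])
    logger.info("consistency_filter: %d of %d features kept",
                len(kept), first.n_features)
    return kept, report


# ---------------------------------------------------------------------------
# I/O


def read_expression_tsv(
    path: str | Path,
    labels_path: str | Path | None = None,
    feature_map_path: str | Path | None = None,
    name: str | None = None,
) -> ExpressionDataset:
    """Read an expression TSV (first column feature id, header sample ids)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    labels = read_labels_tsv(labels_path) if labels_path else None
    fmap = read_feature_map_tsv(feature_map_path) if feature_map_path else None
    return ExpressionDataset(
        values=values, labels=labels, feature_map=fmap,
        name=name or Path(path).stem,
    )


def write_expression_tsv(ds: ExpressionDataset, path: str | Path) -> None:
    ds.values.to_csv(path, sep="\t", index_label="feature_id")


def read_labels_tsv(path: str | Path) -> pd.Series:
    """Read a phenotype TSV with columns sample_id, label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"labels file {path} needs sample_id and label columns")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="label")


def read_feature_map_tsv(path: str | Path) -> pd.Series:
    """Read a probe-to-gene TSV with columns probe_id, gene_symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"feature map {path} needs probe_id and gene_symbol columns")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="gene")
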