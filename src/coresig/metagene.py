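"""Cross-dataset metagene model: PC1 loadings, robustness, scoring, tests.

The model stores, per gene, the PC1 loading observed in each training
dataset, the median over available datasets, and a robustness flag (loadings
sign-consistent across datasets).  Scoring a dataset is a weighted sum of
within-dataset standardized gene expression using the median loadings of the
robust genes.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionDataset
from .separation import signature_pca
from .signatures import normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "GeneLoading",
    "MetageneModel",
    "ScoreVector",
    "fit_loadings",
    "build_model",
    "score_samples",
    "trend_test",
    "group_test",
]


@dataclass(frozen=True)
class GeneLoading:
    """Per-gene training record: one PC1 loading per dataset it was seen in."""

    loadings: Mapping[str, float]  # dataset name -> loading
    median: float
    robust: bool
    single_source: bool


@dataclass(frozen=True)
class MetageneModel:
    genes: Mapping[str, GeneLoading]
    orientation: str = "pc1-vs-mean-positive"
    training_datasets: tuple[str, ...] = ()

    def robust_genes(self) -> list[str]:
        return sorted(g for g, rec in self.genes.items() if rec.robust)

    def weights(self, robust_only: bool = True) -> pd.Series:
        items = {
            g: rec.median for g, rec in self.genes.items()
            if rec.robust or not robust_only
        }
        return pd.Series(items).sort_index()

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "orientation": self.orientation,
            "training_datasets": list(self.training_datasets),
            "genes": {
                g: {
                    "loadings": dict(rec.loadings),
                    "median": rec.median,
                    "robust": rec.robust,
                    "single_source": rec.single_source,
                }
                for g, rec in sorted(self.genes.items())
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MetageneModel":
        genes = {
            g: GeneLoading(
                loadings=dict(rec["loadings"]),
                median=float(rec["median"]),
                robust=bool(rec["robust"]),
                single_source=bool(rec["single_source"]),
            )
            for g, rec in d["genes"].items()
        }
        return cls(
            genes=genes,
            orientation=d.get("orientation", "pc1-vs-mean-positive"),
            training_datasets=tuple(d.get("training_datasets", ())),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "MetageneModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ScoreVector:
    """Per-sample metagene scores plus bookkeeping of the genes involved."""

    scores: pd.Series
    genes_used: tuple[str, ...]
    genes_missing: tuple[str, ...]


# ---------------------------------------------------------------------------
# model fitting


def fit_loadings(
    dsets: Sequence[ExpressionDataset],
    genes: Iterable[str],
    scale: bool = True,
) -> dict[str, pd.Series]:
    """Per-dataset PC1 loadings of the signature genes.

    Each dataset gets its own PCA under the shared orientation convention so
    loading signs are comparable across datasets.  Genes absent from a
    dataset are simply absent from that dataset's series (never zero-filled).
    """
    genes = [normalize_symbol(g) for g in genes]
    out: dict[str, pd.Series] = {}
    for ds in dsets:
        _, loadings = signature_pca(ds, genes, n_components=1, scale=scale)
        series = loadings["PC1"]
        series.index = [normalize_symbol(str(g)) for g in series.index]
        out[ds.name] = series
    return out


def build_model(loadings: Mapping[str, pd.Series]) -> MetageneModel:
    """Aggregate per-dataset PC1 loadings into a metagene model.

    Median is taken over the datasets where the gene was observed; a gene is
    robust when its loadings share a strict sign (a range crossing or touching
    zero marks it non-robust).  Genes observed nowhere are excluded.
    """
    if not loadings:
        raise ValueError("need at least 1 dataset of loadings")
    all_genes = sorted(set(itertools.chain.from_iterable(
        s.index for s in loadings.values()
    )))
    genes: dict[str, GeneLoading] = {}
    for g in all_genes:
        per_ds = {name: float(s[g]) for name, s in loadings.items() if g in s.index}
        vals = np.array(list(per_ds.values()))
        robust = bool(np.all(vals > 0) or np.all(vals < 0))
        genes[g] = GeneLoading(
            loadings=per_ds,
            median=float(np.median(vals)),
            robust=robust,
            single_source=len(per_ds) == 1,
        )
    return MetageneModel(
        genes=genes, training_datasets=tuple(sorted(loadings.keys()))
    )


def score_samples(
    model: MetageneModel,
    ds: ExpressionDataset,
    robust_only: bool = True,
) -> ScoreVector:
    """Score samples as a weighted sum of standardized gene expression.

    ``score(s) = sum_g w_g * z_g(s)`` over the model's (robust) genes present
    in the dataset, with ``w_g`` the median loading and ``z`` the
    within-dataset per-gene z-score.  Missing genes are dropped without
    renormalization and reported.
    """
    weights = model.weights(robust_only=robust_only)
    by_symbol = {normalize_symbol(str(f)): f for f in ds.feature_ids}
    used = [g for g in weights.index if g in by_symbol]
    missing = tuple(g for g in weights.index if g not in by_symbol)
    if missing:
        logger.info("score_samples: %d model genes missing from %s",
                    len(missing), ds.name)
    rows = ds.values.loc[[by_symbol[g] for g in used]].to_numpy(dtype=float)
    sd = rows.std(axis=1, ddof=1, keepdims=True)
    ok = sd[:, 0] > 0
    if ok.sum() < 2:
        raise ValueError("fewer than 2 usable model genes in dataset")
    z = (rows[ok] - rows[ok].mean(axis=1, keepdims=True)) / sd[ok]
    w = weights.loc[[g for g, flag in zip(used, ok) if flag]].to_numpy()
    scores = pd.Series(w @ z, index=ds.sample_ids, name="score")
    return ScoreVector(
        scores=scores,
        genes_used=tuple(g for g, flag in zip(used, ok) if flag),
        genes_missing=missing + tuple(g for g, flag in zip(used, ok) if not flag),
    )


# ---------------------------------------------------------------------------
# downstream tests


def trend_test(scores: ScoreVector | pd.Series,
               covariate: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation (midranks) of scores against a covariate.

    The two-sided p-value is exact (full enumeration of rank orderings) for
    ties-free inputs with n <= 8, and the usual t-approximation otherwise.
    """
    s = scores.scores if isinstance(scores, ScoreVector) else scores
    cov = covariate.reindex(s.index).astype(float)
    mask = cov.notna()
    s, cov = s[mask], cov[mask]
    if len(s) < 4:
        raise ValueError("need at least 4 paired observations")
    if s.nunique() <= 1 or cov.nunique() <= 1:
        raise ValueError("constant scores or covariate: rho undefined")
    x, y = s.to_numpy(), cov.to_numpy()
    rho, p = stats.spearmanr(x, y)
    n = len(x)
    if n <= 8 and len(set(x)) == n and len(set(y)) == n:
        ry = stats.rankdata(y)
        hits = sum(
            abs(np.corrcoef(perm, ry)[0, 1]) >= abs(rho) - 1e-12
            for perm in itertools.permutations(stats.rankdata(x))
        )
        p = hits / math.factorial(n)
    return float(rho), float(p)


def group_test(
    scores: ScoreVector | pd.Series,
    labels: pd.Series,
    posthoc: str = "rank_holm",
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis H across >= 2 groups plus pairwise post-hoc tests.

    Post-hoc ``rank_holm`` (default) runs pairwise Mann-Whitney U tests with
    Holm family-wise adjustment; ``tukey`` runs Tukey HSD on the raw scores
    for parity with ANOVA-style workflows.
    """
    s = scores.scores if isinstance(scores, ScoreVector) else scores
    labels = labels.reindex(s.index).dropna()
    s = s.reindex(labels.index)
    groups = {g: s[labels == g].to_numpy() for g in sorted(set(labels))}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    arrays = list(groups.values())
    if len(set(np.concatenate(arrays).tolist())) == 1:
        h, p = 0.0, 1.0  # all observations identical: no separation at all
    else:
        h, p = stats.kruskal(*arrays)
        h, p = float(h), float(p)

    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    if posthoc == "rank_holm":
        raw = []
        for a, b in pairs:
            if np.array_equal(np.sort(groups[a]), np.sort(groups[b])):
                raw.append(1.0)
            else:
                raw.append(float(stats.mannwhitneyu(
                    groups[a], groups[b], alternative="two-sided"
                ).pvalue))
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(raw, method="holm")[1]
        table = pd.DataFrame({
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "p_raw": raw,
            "p_adjusted": adj,
        })
    elif posthoc == "tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        res = pairwise_tukeyhsd(s.to_numpy(), labels.to_numpy())
        table = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    else:
        raise ValueError(f"unknown posthoc method {posthoc!r}")
    return h, p, table
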