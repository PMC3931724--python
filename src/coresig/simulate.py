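"""Synthetic fixtures: signature collections with planted cores, labeled
expression matrices, shared-sample dataset families and time series.

Every generator is deterministic given its config seed and returns the
planted ground truth alongside the data, so recovery, calibration and power
suites never need external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionDataset
from .signatures import GeneSignature, SignatureCollection

__all__ = [
    "SimulationConfig",
    "SignatureCollectionTruth",
    "DatasetFamilyTruth",
    "TimeSeriesData",
    "default_signature_sizes",
    "simulate_signature_collection",
    "simulate_expression",
    "simulate_dataset_family",
    "simulate_timeseries",
]

# the 21 published collection sizes used as the default size sampler
DEFAULT_SIGNATURE_SIZES: tuple[int, ...] = (
    105, 21, 32, 648, 263, 26, 50, 44, 55, 756,
    135, 147, 136, 33, 113, 128, 186, 105, 89, 45, 92,
)


def default_signature_sizes() -> tuple[int, ...]:
    return DEFAULT_SIGNATURE_SIZES


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs shared by all generators; unused fields are simply ignored."""

    seed: int = 0
    # signature collections
    universe_size: int = 2000
    n_signatures: int = 20
    signature_sizes: tuple[int, ...] | None = None  # None -> resample defaults
    n_core: int = 10
    core_multiplicity_fraction: float = 0.8
    # expression datasets
    n_genes: int = 500
    n_samples_per_class: int = 15
    baseline: float = 8.0
    effect_size: float = 2.0  # SD units of planted between-class shift
    noise_sd: float = 1.0
    class_labels: tuple[str, str] = ("non-invasive", "invasive")
    n_low_genes: int = 0  # decoys planted below the intensity threshold
    low_baseline: float = 5.0
    # dataset families
    n_datasets: int = 3
    dataset_noise_sd: float = 0.3
    scrambled_fraction: float = 0.0
    # time series
    timepoints: tuple[float, ...] = (0.0, 8.0, 16.0, 24.0, 48.0, 72.0)
    n_per_timepoint: int = 3
    slope: float = 0.05  # log2 units per unit time on signature genes

    def __post_init__(self) -> None:
        if self.universe_size < 1 or self.n_signatures < 1 or self.n_genes < 1:
            raise ValueError("sizes must be positive")
        if not (0.0 <= self.core_multiplicity_fraction <= 1.0):
            raise ValueError("core_multiplicity_fraction must be in [0, 1]")
        if self.n_core < 0 or self.n_core > self.universe_size:
            raise ValueError("n_core must be in [0, universe_size]")
        for x in (self.effect_size, self.noise_sd, self.dataset_noise_sd,
                  self.slope):
            if not np.isfinite(x):
                raise ValueError("effect sizes must be finite")


@dataclass(frozen=True)
class SignatureCollectionTruth:
    collection: SignatureCollection
    core_genes: frozenset[str]


@dataclass(frozen=True)
class DatasetFamilyTruth:
    datasets: tuple[ExpressionDataset, ...]
    consistent_features: frozenset[str]
    scrambled_features: frozenset[str]
    signature_genes: frozenset[str]


@dataclass(frozen=True)
class TimeSeriesData:
    dataset: ExpressionDataset
    time: pd.Series  # per-sample exposure time


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# signature collections


def simulate_signature_collection(
    cfg: SimulationConfig,
) -> SignatureCollectionTruth:
    """A collection with ``n_core`` planted high-multiplicity genes.

    Each core gene joins each signature independently with probability
    ``core_multiplicity_fraction``; the remaining slots of every signature
    are filled uniformly without replacement from the rest of the universe.
    """
    rng = np.random.default_rng(cfg.seed)
    universe = np.array(_gene_names(cfg.universe_size))
    core = universe[: cfg.n_core]

    if cfg.signature_sizes is not None:
        sizes = tuple(cfg.signature_sizes)
        if len(sizes) != cfg.n_signatures:
            raise ValueError("signature_sizes length must equal n_signatures")
    else:
        sizes = tuple(
            int(x) for x in rng.choice(DEFAULT_SIGNATURE_SIZES, cfg.n_signatures)
        )
    for sz in sizes:
        if sz < 1 or sz > cfg.universe_size:
            raise ValueError(f"infeasible signature size {sz}")

    sigs = []
    for i, size in enumerate(sizes):
        members: list[str] = []
        if cfg.n_core:
            picked = rng.random(cfg.n_core) < cfg.core_multiplicity_fraction
            members.extend(core[picked][: size])
        remaining = size - len(members)
        if remaining > 0:
            pool = np.array(sorted(set(universe) - set(members)))
            idx = rng.choice(pool.size, size=remaining, replace=False)
            members.extend(pool[idx])
        sigs.append(GeneSignature.from_symbols(
            f"sim_sig_{i:02d}", members, source="simulated"))
    return SignatureCollectionTruth(
        collection=SignatureCollection(tuple(sigs)),
        core_genes=frozenset(str(g) for g in core),
    )


# ---------------------------------------------------------------------------
# expression matrices


def _base_matrix(rng: np.random.Generator, cfg: SimulationConfig,
                 signature: Sequence[str]) -> tuple[pd.DataFrame, pd.Series]:
    """Shared scaffolding: gene space, two balanced classes, planted shift."""
    sig = sorted({g.strip().upper() for g in signature})
    n_extra = max(cfg.n_genes - len(sig), 0)
    genes = sig + _gene_names(n_extra, prefix="BG")
    n = 2 * cfg.n_samples_per_class
    samples = [f"S{i:03d}" for i in range(n)]
    lab_a, lab_b = cfg.class_labels
    labels = pd.Series(
        [lab_a] * cfg.n_samples_per_class + [lab_b] * cfg.n_samples_per_class,
        index=samples, name="label",
    )
    mat = np.full((len(genes), n), cfg.baseline)
    if cfg.n_low_genes:
        mat[len(sig): len(sig) + cfg.n_low_genes] = cfg.low_baseline
    shift = cfg.effect_size * cfg.noise_sd
    mat[: len(sig), cfg.n_samples_per_class:] += shift
    mat += rng.normal(0.0, cfg.noise_sd, size=mat.shape)
    return pd.DataFrame(mat, index=genes, columns=samples), labels


def simulate_expression(
    cfg: SimulationConfig, signature: Sequence[str],
    name: str = "sim_expr",
) -> ExpressionDataset:
    """One labeled log2 matrix with the signature genes shifted in class B."""
    rng = np.random.default_rng(cfg.seed)
    values, labels = _base_matrix(rng, cfg, signature)
    return ExpressionDataset(values=values, labels=labels, name=name)


def simulate_dataset_family(
    cfg: SimulationConfig, signature: Sequence[str],
) -> DatasetFamilyTruth:
    """Datasets sharing one latent truth matrix plus per-dataset noise.

    A ``scrambled_fraction`` of background features is replaced by
    independent per-dataset noise; these are the targets the consistency
    filter must remove.
    """
    if cfg.n_datasets < 2:
        raise ValueError("n_datasets must be >= 2")
    rng = np.random.default_rng(cfg.seed)
    truth, labels = _base_matrix(rng, cfg, signature)
    genes = truth.index.to_numpy()
    sig = frozenset(g.strip().upper() for g in signature)
    background = np.array([g for g in genes if g not in sig])
    n_scrambled = int(round(cfg.scrambled_fraction * background.size))
    scrambled = frozenset(
        background[rng.choice(background.size, n_scrambled, replace=False)]
    ) if n_scrambled else frozenset()
    scram_mask = truth.index.isin(scrambled)

    dsets = []
    for d in range(cfg.n_datasets):
        vals = truth.to_numpy().copy()
        if cfg.dataset_noise_sd > 0:
            vals += rng.normal(0.0, cfg.dataset_noise_sd, size=vals.shape)
        if scram_mask.any():
            vals[scram_mask] = rng.normal(
                cfg.baseline, cfg.noise_sd, size=(scram_mask.sum(), vals.shape[1])
            )
        dsets.append(ExpressionDataset(
            values=pd.DataFrame(vals, index=truth.index, columns=truth.columns),
            labels=labels.copy(),
            name=f"sim_family_{d}",
        ))
    return DatasetFamilyTruth(
        datasets=tuple(dsets),
        consistent_features=frozenset(genes) - scrambled,
        scrambled_features=scrambled,
        signature_genes=sig,
    )


def simulate_timeseries(
    cfg: SimulationConfig, signature: Sequence[str],
    name: str = "sim_timeseries",
) -> TimeSeriesData:
    """Signature-gene means rise linearly with exposure time."""
    if len(cfg.timepoints) < 4:
        raise ValueError("need at least 4 timepoints")
    rng = np.random.default_rng(cfg.seed)
    sig = sorted({g.strip().upper() for g in signature})
    n_extra = max(cfg.n_genes - len(sig), 0)
    genes = sig + _gene_names(n_extra, prefix="BG")
    times = np.repeat(np.asarray(cfg.timepoints, dtype=float),
                      cfg.n_per_timepoint)
    samples = [f"T{i:03d}" for i in range(times.size)]
    mat = np.full((len(genes), times.size), cfg.baseline)
    mat[: len(sig)] += cfg.slope * times[None, :]
    mat += rng.normal(0.0, cfg.noise_sd, size=mat.shape)
    ds = ExpressionDataset(
        values=pd.DataFrame(mat, index=genes, columns=samples), name=name,
    )
    return TimeSeriesData(
        dataset=ds, time=pd.Series(times, index=samples, name="time"),
    )
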