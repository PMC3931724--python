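import numpy as np
import pandas as pd
import pytest

from coresig.expression import ExpressionDataset
from coresig.signatures import FrequencyTable, GeneSignature, SignatureCollection
from coresig.simulate import SimulationConfig, simulate_expression


@pytest.fixture
def toy_collection() -> SignatureCollection:
    return SignatureCollection((
        GeneSignature.from_symbols("s1", ["A", "B", "C"]),
        GeneSignature.from_symbols("s2", ["B", "C"]),
        GeneSignature.from_symbols("s3", ["C"]),
    ))


@pytest.fixture
def reference_frequency_tables() -> tuple[FrequencyTable, FrequencyTable]:
    """Published at-least-k repetition counts for multiplicities 2..7."""
    observed = FrequencyTable.from_cumulative(
        {2: 646, 3: 202, 4: 62, 5: 16, 6: 6, 7: 3}, kind="observed")
    expected = FrequencyTable.from_cumulative(
        {2: 1065, 3: 376, 4: 87, 5: 14, 6: 1, 7: 1}, kind="expected")
    return observed, expected


@pytest.fixture
def signature_genes() -> list[str]:
    return [f"SIG{i:02d}" for i in range(16)]


@pytest.fixture
def shifted_dataset(signature_genes) -> ExpressionDataset:
    """30 samples, strong planted two-class shift in the signature genes."""
    cfg = SimulationConfig(seed=11, n_genes=120, n_samples_per_class=15,
                           effect_size=3.0, noise_sd=1.0)
    return simulate_expression(cfg, signature_genes)


@pytest.fixture
def noise_dataset(signature_genes) -> ExpressionDataset:
    cfg = SimulationConfig(seed=12, n_genes=120, n_samples_per_class=15,
                           effect_size=0.0, noise_sd=1.0)
    return simulate_expression(cfg, signature_genes)


def make_dataset(values: np.ndarray, genes=None, samples=None,
                 labels=None, name="ds") -> ExpressionDataset:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    lab = pd.Series(labels, index=samples) if labels is not None else None
    return ExpressionDataset(
        values=pd.DataFrame(values, index=genes, columns=samples),
        labels=lab, name=name,
    )
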