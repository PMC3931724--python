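"""coresig: consensus gene-signature discovery, validation and scoring.

Workflow: discover core genes overrepresented across a collection of gene
signatures against a size-matched randomization null; validate a candidate
signature by PCA centroid-separation permutation testing on labeled
expression data; build a median-PC1-loading metagene model and score new
datasets, with trend and group tests downstream.
"""

from importlib import resources

import pandas as pd

from .signatures import (
    GeneSignature,
    SignatureCollection,
    FrequencyTable,
    CoreSelectionResult,
    observed_frequencies,
    sample_random_collection,
    expected_frequencies,
    chi_square_gof,
    select_core_signature,
    read_gmt,
    write_gmt,
)
from .expression import (
    ExpressionDataset,
    ConsistencyReport,
    intensity_filter,
    collapse_probes,
    align_common,
    consistency_filter,
    read_expression_tsv,
    write_expression_tsv,
)
from .separation import (
    SeparationResult,
    signature_pca,
    centroid_distance,
    permutation_test,
    random_geneset_baseline,
)
from .metagene import (
    MetageneModel,
    ScoreVector,
    fit_loadings,
    build_model,
    score_samples,
    trend_test,
    group_test,
)
from .simulate import (
    SimulationConfig,
    simulate_signature_collection,
    simulate_expression,
    simulate_dataset_family,
    simulate_timeseries,
)

__version__ = "0.1.0"


def load_core_signature() -> GeneSignature:
    """The packaged 16-gene core invasiveness signature fixture."""
    ref = resources.files("coresig.data").joinpath("cig16.gmt")
    with resources.as_file(ref) as path:
        return read_gmt(path).signatures[0]


def load_signature_table() -> "pd.DataFrame":
    """Metadata (names and sizes) of the 21 published source signatures."""
    ref = resources.files("coresig.data").joinpath("signature_table.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
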