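"""Gene-signature collections, repetition-frequency tables and core-gene selection.

A *signature* is a named set of gene symbols; a *collection* of signatures
induces a gene universe (the union of all member sets) and, for every gene,
a *multiplicity*: the number of distinct signatures it appears in.  Genes
whose multiplicity exceeds what a size-matched random collection would
produce form the *core signature*.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSignature",
    "SignatureCollection",
    "FrequencyTable",
    "CoreSelectionResult",
    "normalize_symbol",
    "observed_frequencies",
    "sample_random_collection",
    "expected_frequencies",
    "chi_square_gof",
    "select_core_signature",
    "read_gmt",
    "write_gmt",
    "frequency_frame",
    "write_frequency_tsv",
    "read_frequency_tsv",
]


def normalize_symbol(symbol: str, alias: Mapping[str, str] | None = None) -> str:
    """Strip whitespace, apply an optional alias map, and uppercase a symbol."""
    s = symbol.strip()
    if alias:
        s = alias.get(s, alias.get(s.upper(), s))
    return s.upper()


@dataclass(frozen=True)
class GeneSignature:
    """A named, deduplicated set of uppercased gene symbols."""

    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")

    @classmethod
    def from_symbols(
        cls,
        name: str,
        symbols: Iterable[str],
        source: str = "",
        alias: Mapping[str, str] | None = None,
    ) -> "GeneSignature":
        genes = frozenset(
            normalize_symbol(s, alias) for s in symbols if s and s.strip()
        )
        return cls(name=name, genes=genes, source=source)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SignatureCollection:
    """An ordered sequence of signatures plus the induced gene universe."""

    signatures: tuple[GeneSignature, ...]

    def __post_init__(self) -> None:
        if not self.signatures:
            raise ValueError("empty collection")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for sig in self.signatures:
            out |= sig.genes
        return frozenset(out)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.signatures)

    @property
    def total_slots(self) -> int:
        """Total signature memberships (sum of member sizes)."""
        return sum(self.sizes)

    def multiplicities(self) -> dict[str, int]:
        """Per-gene count of member signatures containing the gene."""
        counts: Counter[str] = Counter()
        for sig in self.signatures:
            counts.update(sig.genes)
        return dict(counts)

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self) -> Iterator[GeneSignature]:
        return iter(self.signatures)


@dataclass(frozen=True)
class FrequencyTable:
    """Exact and cumulative repetition counts by multiplicity.

    ``exact[k]`` is the number of genes appearing in exactly ``k`` signatures;
    ``cumulative[k]`` the number appearing in at least ``k``.  Expected tables
    (Monte-Carlo averages) may hold fractional counts.
    """

    exact: Mapping[int, float]
    cumulative: Mapping[int, float]
    kind: str = "observed"
    replicates: int = 1

    @classmethod
    def from_exact(
        cls, exact: Mapping[int, float], kind: str = "observed", replicates: int = 1
    ) -> "FrequencyTable":
        ks = sorted(exact)
        if not ks:
            raise ValueError("empty frequency table")
        full = {k: float(exact.get(k, 0.0)) for k in range(1, max(ks) + 1)}
        cum: dict[int, float] = {}
        running = 0.0
        for k in sorted(full, reverse=True):
            running += full[k]
            cum[k] = running
        return cls(exact=full, cumulative=dict(sorted(cum.items())), kind=kind,
                   replicates=replicates)

    @classmethod
    def from_cumulative(
        cls, cumulative: Mapping[int, float], kind: str = "observed",
        replicates: int = 1,
    ) -> "FrequencyTable":
        ks = sorted(cumulative)
        if not ks:
            raise ValueError("empty frequency table")
        exact: dict[int, float] = {}
        for i, k in enumerate(ks):
            nxt = cumulative[ks[i + 1]] if i + 1 < len(ks) else 0.0
            exact[k] = float(cumulative[k]) - float(nxt)
        return cls(exact=exact, cumulative={k: float(v) for k, v in cumulative.items()},
                   kind=kind, replicates=replicates)

    def exact_at(self, k: int) -> float:
        return float(self.exact.get(k, 0.0))

    def cumulative_at(self, k: int) -> float:
        if k in self.cumulative:
            return float(self.cumulative[k])
        if self.cumulative and k < min(self.cumulative):
            return float(self.cumulative[min(self.cumulative)])
        return 0.0

    @property
    def max_multiplicity(self) -> int:
        return max(self.exact)


@dataclass(frozen=True)
class CoreSelectionResult:
    """Outcome of the core-selection rule."""

    threshold_multiplicity: int | None
    core_genes: frozenset[str]
    core_size: int
    chi_square_stat: float
    p_value: float
    qualifying_multiplicities: frozenset[int]
    flag: str = "ok"  # ok | not significant | no overrepresentation


# ---------------------------------------------------------------------------
# frequency computation


def observed_frequencies(collection: SignatureCollection) -> FrequencyTable:
    """Count how many genes appear in exactly / at least k signatures.

    Membership is counted once per signature (sets carry no duplicates), and
    the support runs over multiplicities 1..len(collection).
    """
    if len(collection) == 0:  # pragma: no cover - dataclass forbids this
        raise ValueError("empty collection")
    mult = collection.multiplicities()
    exact = Counter(mult.values())
    full = {k: float(exact.get(k, 0)) for k in range(1, len(collection) + 1)}
    return FrequencyTable.from_exact(full, kind="observed", replicates=1)


def sample_random_collection(
    collection: SignatureCollection, seed: int | np.random.Generator
) -> SignatureCollection:
    """Draw a size-matched random collection from the collection's universe.

    Each random list is sampled uniformly without replacement within a list;
    lists are independent of each other.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    universe = np.array(sorted(collection.universe))
    sigs = []
    for i, sig in enumerate(collection):
        if len(sig) > universe.size:
            raise ValueError(
                f"signature {sig.name!r} larger than universe "
                f"({len(sig)} > {universe.size})"
            )
        picked = rng.choice(universe.size, size=len(sig), replace=False)
        sigs.append(
            GeneSignature(
                name=f"random_{i}_{sig.name}",
                genes=frozenset(universe[picked]),
                source="random",
            )
        )
    return SignatureCollection(tuple(sigs))


def expected_frequencies(
    collection: SignatureCollection,
    replicates: int = 1000,
    seed: int | np.random.Generator = 0,
) -> FrequencyTable:
    """Monte-Carlo expected frequency table under size-matched random draws.

    Averages the observed table of ``replicates`` independent random
    collections.  Uses an integer-coded fast path that is distributionally
    identical to running :func:`sample_random_collection` repeatedly.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    n_universe = len(collection.universe)
    sizes = collection.sizes
    for sz in sizes:
        if sz > n_universe:
            raise ValueError("signature larger than universe")
    n_sigs = len(collection)
    acc = np.zeros(n_sigs + 1, dtype=float)
    for _ in range(replicates):
        counts = np.zeros(n_universe, dtype=np.int64)
        for sz in sizes:
            idx = rng.choice(n_universe, size=sz, replace=False)
            counts[idx] += 1
        binned = np.bincount(counts, minlength=n_sigs + 1)
        acc += binned[: n_sigs + 1]
    acc /= replicates
    exact = {k: float(acc[k]) for k in range(1, n_sigs + 1)}
    return FrequencyTable.from_exact(exact, kind="expected", replicates=replicates)


# ---------------------------------------------------------------------------
# testing and selection


def chi_square_gof(
    observed: FrequencyTable,
    expected: FrequencyTable,
    min_multiplicity: int = 2,
    pool_tail: bool = True,
) -> tuple[float, int, float]:
    """Pearson chi-square of observed vs expected exact counts.

    Bins are multiplicities ``k >= min_multiplicity``; when ``pool_tail``,
    trailing bins with expected count < 5 are pooled into the last retained
    bin (standard practice).  Returns ``(stat, df, p)`` with ``df = bins - 1``.
    """
    kmax = max(observed.max_multiplicity, expected.max_multiplicity)
    ks = [k for k in range(min_multiplicity, kmax + 1)]
    if not ks:
        raise ValueError("no bins at or above min_multiplicity")
    obs = np.array([observed.exact_at(k) for k in ks], dtype=float)
    exp = np.array([expected.exact_at(k) for k in ks], dtype=float)
    if pool_tail:
        while obs.size > 1 and exp[-1] < 5.0:
            obs[-2] += obs[-1]
            exp[-2] += exp[-1]
            obs, exp = obs[:-1], exp[:-1]
    if np.any(exp <= 0):
        raise ValueError("degenerate expected bin")
    if obs.size < 2:
        raise ValueError("need at least 2 bins for a chi-square test")
    stat = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def select_core_signature(
    collection: SignatureCollection | None,
    observed: FrequencyTable,
    expected: FrequencyTable,
    alpha: float = 0.05,
) -> CoreSelectionResult:
    """Apply the core-selection rule.

    Qualifying multiplicities are ``k >= 2`` where the observed cumulative
    count exceeds the expected one; the threshold ``k*`` is the qualifying
    multiplicity with the largest observed cumulative count (ties broken
    toward smaller ``k``).  The whole selection is gated on a significant
    chi-square test at ``alpha``.

    ``collection`` may be ``None`` when only the tables are available (e.g.
    counts transcribed from a publication); ``core_size`` is then taken from
    the observed cumulative count and ``core_genes`` is empty.
    """
    stat, _, p = chi_square_gof(observed, expected)
    kmax = max(observed.max_multiplicity, expected.max_multiplicity)
    qualifying = frozenset(
        k for k in range(2, kmax + 1)
        if observed.cumulative_at(k) > expected.cumulative_at(k)
    )
    if p >= alpha:
        return CoreSelectionResult(None, frozenset(), 0, stat, p,
                                   qualifying, flag="not significant")
    if not qualifying:
        return CoreSelectionResult(None, frozenset(), 0, stat, p,
                                   qualifying, flag="no overrepresentation")
    k_star = max(qualifying, key=lambda k: (observed.cumulative_at(k), -k))
    if collection is not None:
        mult = collection.multiplicities()
        core = frozenset(g for g, m in mult.items() if m >= k_star)
        size = len(core)
    else:
        core = frozenset()
        size = int(round(observed.cumulative_at(k_star)))
    return CoreSelectionResult(k_star, core, size, stat, p, qualifying, flag="ok")


# ---------------------------------------------------------------------------
# I/O


def read_gmt(
    path: str | Path, alias: Mapping[str, str] | None = None
) -> SignatureCollection:
    """Read a GMT file (name <tab> description <tab> genes...) as a collection."""
    sigs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        name, desc, genes = fields[0], fields[1], fields[2:]
        sigs.append(GeneSignature.from_symbols(name, genes, source=desc, alias=alias))
    if not sigs:
        raise ValueError(f"no signatures in {path}")
    return SignatureCollection(tuple(sigs))


def write_gmt(collection: SignatureCollection | Iterable[GeneSignature],
              path: str | Path) -> None:
    sigs = collection.signatures if isinstance(collection, SignatureCollection) \
        else tuple(collection)
    lines = [
        "\t".join([s.name, s.source or "na", *sorted(s.genes)]) for s in sigs
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def frequency_frame(
    observed: FrequencyTable, expected: FrequencyTable | None = None
) -> pd.DataFrame:
    """Tabulate observed (and optionally expected) counts by multiplicity."""
    kmax = observed.max_multiplicity
    if expected is not None:
        kmax = max(kmax, expected.max_multiplicity)
    rows = []
    for k in range(1, kmax + 1):
        row = {
            "multiplicity": k,
            "observed_exact": observed.exact_at(k),
            "observed_cumulative": observed.cumulative_at(k),
        }
        if expected is not None:
            row["expected_exact"] = expected.exact_at(k)
            row["expected_cumulative"] = expected.cumulative_at(k)
        rows.append(row)
    return pd.DataFrame(rows)


def write_frequency_tsv(
    path: str | Path, observed: FrequencyTable,
    expected: FrequencyTable | None = None,
) -> None:
    frequency_frame(observed, expected).to_csv(path, sep="\t", index=False)


def read_frequency_tsv(path: str | Path) -> tuple[FrequencyTable, FrequencyTable | None]:
    """Read a frequency TSV back into (observed, expected-or-None) tables.

    Cumulative columns take precedence when present, so that tables
    transcribed as at-least-k counts (the common published form) round-trip
    faithfully; exact columns are accepted as a fallback.
    """
    df = pd.read_csv(path, sep="\t")
    ks = df["multiplicity"].astype(int)

    def build(col_cum: str, col_exact: str, kind: str) -> FrequencyTable | None:
        if col_cum in df.columns:
            return FrequencyTable.from_cumulative(dict(zip(ks, df[col_cum])), kind=kind)
        if col_exact in df.columns:
            return FrequencyTable.from_exact(dict(zip(ks, df[col_exact])), kind=kind)
        return None

    obs = build("observed_cumulative", "observed_exact", "observed")
    if obs is None:
        raise ValueError(f"no observed counts in {path}")
    exp = build("expected_cumulative", "expected_exact", "expected")
    return obs, exp
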