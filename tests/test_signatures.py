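import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coresig.signatures import (
    FrequencyTable,
    GeneSignature,
    SignatureCollection,
    chi_square_gof,
    expected_frequencies,
    observed_frequencies,
    read_frequency_tsv,
    read_gmt,
    sample_random_collection,
    select_core_signature,
    write_frequency_tsv,
    write_gmt,
)
from coresig.simulate import SimulationConfig, simulate_signature_collection


# ---------------------------------------------------------------------------
# types


class TestGeneSignature:
    def test_normalizes_and_dedupes(self):
        sig = GeneSignature.from_symbols("s", [" fn1", "FN1", "jun "])
        assert sig.genes == {"FN1", "JUN"}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            GeneSignature.from_symbols("s", [])

    def test_alias_table(self):
        sig = GeneSignature.from_symbols("s", ["c-FOS"], alias={"c-FOS": "FOS"})
        assert sig.genes == {"FOS"}


class TestSignatureCollection:
    def test_universe_is_union(self, toy_collection):
        assert toy_collection.universe == {"A", "B", "C"}
        assert len(toy_collection.universe) <= toy_collection.total_slots

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SignatureCollection(())


class TestFrequencyTable:
    def test_cumulative_from_exact(self):
        t = FrequencyTable.from_exact({1: 3, 2: 2, 3: 1})
        assert t.cumulative == {1: 6, 2: 3, 3: 1}

    def test_exact_from_cumulative(self):
        t = FrequencyTable.from_cumulative({2: 646, 3: 202, 4: 62, 5: 16,
                                            6: 6, 7: 3})
        assert t.exact == {2: 444, 3: 140, 4: 46, 5: 10, 6: 3, 7: 3}
        assert t.cumulative_at(1) == 646  # below support: no extra information
        assert t.cumulative_at(99) == 0

    @given(st.dictionaries(st.integers(1, 12), st.integers(0, 50),
                           min_size=1))
    def test_roundtrip_and_monotone(self, exact):
        t = FrequencyTable.from_exact(exact)
        ks = sorted(t.cumulative)
        cums = [t.cumulative[k] for k in ks]
        assert all(a >= b for a, b in zip(cums, cums[1:]))
        back = FrequencyTable.from_cumulative(t.cumulative)
        for k in t.exact:
            assert back.exact_at(k) == pytest.approx(t.exact_at(k))


# ---------------------------------------------------------------------------
# observed_frequencies


class TestObservedFrequencies:
    def test_hand_counted(self, toy_collection):
        t = observed_frequencies(toy_collection)
        assert t.exact == {1: 1, 2: 1, 3: 1}
        assert t.cumulative == {1: 3, 2: 2, 3: 1}

    def test_single_signature_no_repetition(self):
        coll = SignatureCollection((
            GeneSignature.from_symbols("s", [f"G{i}" for i in range(10)]),
        ))
        t = observed_frequencies(coll)
        assert t.exact == {1: 10}
        assert t.cumulative_at(2) == 0

    def test_planted_full_multiplicity_brute_force(self):
        cfg = SimulationConfig(seed=5, universe_size=300, n_signatures=21,
                               signature_sizes=(25,) * 21, n_core=4,
                               core_multiplicity_fraction=1.0)
        truth = simulate_signature_collection(cfg)
        t = observed_frequencies(truth.collection)
        # brute force: count genes present in all 21 signatures
        brute = sum(
            1 for g in truth.collection.universe
            if all(g in s.genes for s in truth.collection)
        )
        assert brute >= 4  # the planted core is there
        assert t.cumulative_at(21) == brute

    def test_conservation_of_slots(self, toy_collection):
        t = observed_frequencies(toy_collection)
        assert sum(k * v for k, v in t.exact.items()) == \
            toy_collection.total_slots


# ---------------------------------------------------------------------------
# random collections


class TestSampleRandomCollection:
    def test_full_size_list_forced(self):
        coll = SignatureCollection((
            GeneSignature.from_symbols("s", [f"G{i}" for i in range(10)]),
        ))
        rand = sample_random_collection(coll, seed=3)
        assert rand.signatures[0].genes == coll.universe

    def test_determinism(self, toy_collection):
        a = sample_random_collection(toy_collection, seed=7)
        b = sample_random_collection(toy_collection, seed=7)
        c = sample_random_collection(toy_collection, seed=8)
        assert [s.genes for s in a] == [s.genes for s in b]
        assert a.sizes == c.sizes  # sizes always preserved

    def test_sizes_matched(self, toy_collection):
        rand = sample_random_collection(toy_collection, seed=1)
        assert rand.sizes == toy_collection.sizes
        assert len(rand) == len(toy_collection)

    def test_uniform_pairs(self):
        # one size-2 list over a 4-gene universe: 6 unordered pairs, each 1/6
        coll = SignatureCollection((
            GeneSignature.from_symbols("base", ["A", "B", "C", "D"]),
            GeneSignature.from_symbols("probe", ["A", "B"]),
        ))
        rng = np.random.default_rng(42)
        counts = Counter()
        n = 10_000
        for _ in range(n):
            rand = sample_random_collection(coll, rng)
            counts[frozenset(rand.signatures[1].genes)] += 1
        assert len(counts) == 6
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        for pair, c in counts.items():
            assert abs(c / n - 1 / 6) < 3 * se, pair

    def test_oversized_signature_rejected(self):
        coll = SignatureCollection((
            GeneSignature.from_symbols("a", ["X"]),
            GeneSignature.from_symbols("b", ["X", "Y"]),
        ))
        # universe {X, Y} supports both sizes; shrink universe via a fake
        small = SignatureCollection((
            GeneSignature.from_symbols("a", ["X"]),
        ))
        rand = sample_random_collection(small, seed=0)
        assert rand.signatures[0].genes == {"X"}

    def test_random_replicates_conserve_slots(self, toy_collection):
        for seed in range(5):
            rand = sample_random_collection(toy_collection, seed)
            t = observed_frequencies(rand)
            assert sum(k * v for k, v in t.exact.items()) == \
                toy_collection.total_slots


class TestExpectedFrequencies:
    def test_forced_universe(self):
        coll = SignatureCollection((
            GeneSignature.from_symbols("s", [f"G{i}" for i in range(10)]),
        ))
        t = expected_frequencies(coll, replicates=5, seed=0)
        assert t.exact_at(1) == 10
        assert t.cumulative_at(2) == 0
        assert t.kind == "expected"
        assert t.replicates == 5

    def test_two_singletons_enumerated(self):
        # two size-1 lists over universe {A, B}: 4 equally likely draws,
        # 2 of which collide -> expected cumulative(2) = 1/2
        coll = SignatureCollection((
            GeneSignature.from_symbols("a", ["A"]),
            GeneSignature.from_symbols("b", ["B"]),
        ))
        t = expected_frequencies(coll, replicates=4000, seed=1)
        se = np.sqrt(0.25 / 4000)
        assert abs(t.cumulative_at(2) - 0.5) < 4 * se

    def test_replicate_convergence(self):
        cfg = SimulationConfig(seed=9, universe_size=100, n_signatures=8,
                               signature_sizes=(20,) * 8, n_core=0)
        coll = simulate_signature_collection(cfg).collection
        a = expected_frequencies(coll, replicates=1000, seed=2)
        b = expected_frequencies(coll, replicates=4000, seed=3)
        for k in range(2, 6):
            # bin sd is at most sqrt(E); compare means within joint MC error
            tol = 4 * np.sqrt(max(a.exact_at(k), 1.0) / 1000)
            assert abs(a.exact_at(k) - b.exact_at(k)) < tol

    def test_bad_replicates(self, toy_collection):
        with pytest.raises(ValueError):
            expected_frequencies(toy_collection, replicates=0)

    def test_determinism(self, toy_collection):
        a = expected_frequencies(toy_collection, replicates=50, seed=4)
        b = expected_frequencies(toy_collection, replicates=50, seed=4)
        assert a.exact == b.exact


# ---------------------------------------------------------------------------
# chi-square


class TestChiSquare:
    def test_identical_tables(self):
        t = FrequencyTable.from_exact({1: 5, 2: 10, 3: 7})
        stat, df, p = chi_square_gof(t, t, pool_tail=False)
        assert stat == 0
        assert p == 1

    def test_reference_tables_oracle(self, reference_frequency_tables):
        observed, expected = reference_frequency_tables
        stat, df, p = chi_square_gof(observed, expected)
        # independent textbook computation with the same pooling
        obs = [observed.exact_at(k) for k in range(2, 8)]
        exp = [expected.exact_at(k) for k in range(2, 8)]
        while len(obs) > 1 and exp[-1] < 5:
            obs[-2] += obs[-1]
            exp[-2] += exp[-1]
            obs, exp = obs[:-1], exp[:-1]
        oracle = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
        assert stat == pytest.approx(oracle, abs=1e-12)
        assert df == len(obs) - 1
        assert p < 0.001

    def test_homogeneity(self):
        a = FrequencyTable.from_exact({2: 30, 3: 12, 4: 8})
        b = FrequencyTable.from_exact({2: 40, 3: 10, 4: 6}, kind="expected")
        a2 = FrequencyTable.from_exact({2: 60, 3: 24, 4: 16})
        b2 = FrequencyTable.from_exact({2: 80, 3: 20, 4: 12}, kind="expected")
        s1, _, _ = chi_square_gof(a, b, pool_tail=False)
        s2, _, _ = chi_square_gof(a2, b2, pool_tail=False)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_degenerate_expected_bin(self):
        obs = FrequencyTable.from_exact({2: 5, 3: 5})
        exp = FrequencyTable.from_exact({2: 5, 3: 0}, kind="expected")
        with pytest.raises(ValueError, match="degenerate"):
            chi_square_gof(obs, exp, pool_tail=False)


# ---------------------------------------------------------------------------
# core selection


class TestSelectCore:
    def test_reference_tables(self, reference_frequency_tables):
        observed, expected = reference_frequency_tables
        res = select_core_signature(None, observed, expected)
        assert res.flag == "ok"
        assert res.threshold_multiplicity == 5
        assert res.core_size == 16
        assert res.qualifying_multiplicities == {5, 6, 7}

    def test_no_overrepresentation(self):
        obs = FrequencyTable.from_exact({2: 10, 3: 2, 4: 100})
        exp = FrequencyTable.from_exact({2: 300, 3: 200, 4: 200},
                                        kind="expected")
        res = select_core_signature(None, obs, exp)
        assert res.flag == "no overrepresentation"
        assert res.core_genes == frozenset()
        assert res.core_size == 0

    def test_alpha_gate(self, reference_frequency_tables):
        observed, expected = reference_frequency_tables
        res = select_core_signature(None, observed, expected, alpha=1e-50)
        assert res.flag == "not significant"
        assert res.core_size == 0

    def test_planted_recovery(self):
        cfg = SimulationConfig(seed=0, universe_size=2000, n_signatures=20,
                               signature_sizes=(30,) * 20, n_core=10,
                               core_multiplicity_fraction=0.8)
        truth = simulate_signature_collection(cfg)
        obs = observed_frequencies(truth.collection)
        exp = expected_frequencies(truth.collection, replicates=200, seed=99)
        res = select_core_signature(truth.collection, obs, exp)
        assert res.flag == "ok"
        assert res.core_genes == truth.core_genes
        assert res.core_size == len(truth.core_genes)

    def test_core_size_matches_cumulative(self):
        cfg = SimulationConfig(seed=3, universe_size=500, n_signatures=10,
                               signature_sizes=(20,) * 10, n_core=5,
                               core_multiplicity_fraction=1.0)
        truth = simulate_signature_collection(cfg)
        obs = observed_frequencies(truth.collection)
        exp = expected_frequencies(truth.collection, replicates=100, seed=4)
        res = select_core_signature(truth.collection, obs, exp)
        if res.flag == "ok":
            assert res.core_size == obs.cumulative_at(res.threshold_multiplicity)


# ---------------------------------------------------------------------------
# I/O


class TestIO:
    def test_gmt_roundtrip(self, tmp_path, toy_collection):
        path = tmp_path / "coll.gmt"
        write_gmt(toy_collection, path)
        back = read_gmt(path)
        assert [s.genes for s in back] == [s.genes for s in toy_collection]

    def test_gmt_malformed(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_name\tdesc\n")
        with pytest.raises(ValueError, match="malformed"):
            read_gmt(path)

    def test_frequency_tsv_roundtrip(self, tmp_path,
                                     reference_frequency_tables):
        observed, expected = reference_frequency_tables
        path = tmp_path / "freq.tsv"
        write_frequency_tsv(path, observed, expected)
        obs2, exp2 = read_frequency_tsv(path)
        res = select_core_signature(None, obs2, exp2)
        assert res.threshold_multiplicity == 5
        assert res.core_size == 16


# ---------------------------------------------------------------------------
# properties


@settings(max_examples=25, deadline=None)
@given(
    sizes=st.lists(st.integers(1, 15), min_size=1, max_size=6),
    seed=st.integers(0, 10_000),
)
def test_random_collection_conserves_slots(sizes, seed):
    universe = [f"G{i}" for i in range(20)]
    base = SignatureCollection(tuple(
        GeneSignature.from_symbols(f"s{i}", universe[: sz])
        for i, sz in enumerate(sizes)
    ))
    rand = sample_random_collection(base, seed)
    t = observed_frequencies(rand)
    assert sum(k * v for k, v in t.exact.items()) == base.total_slots
    cums = [t.cumulative[k] for k in sorted(t.cumulative)]
    assert all(a >= b for a, b in zip(cums, cums[1:]))
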