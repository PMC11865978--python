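"""Null models, nullomer enumeration, neighborhoods, truncates, rarity."""

import itertools
import math

import numpy as np
import pytest

from pepnull import (
    ALPHABET,
    ProteinRecord,
    SyntheticSpec,
    aa_frequency_model,
    brute_force_count,
    build_census,
    codon_frequency_model,
    count_of,
    enumerate_nullomers,
    expected_count,
    generate_proteome,
    is_high_order_nullomer,
    mutation_neighborhood,
    rank_rare,
    residue_frequencies,
    truncate_counts,
    underrepresentation_pvalue,
)
from pepnull.core import FrequencyModel, _expected_vector


def uniform_model():
    return FrequencyModel(kind="aa_occurrence", probs=np.full(20, 0.05))


class TestNullomerEnumeration:
    def test_empty_corpus_yields_full_space(self):
        nullomers = enumerate_nullomers(build_census([], 2))
        assert len(nullomers) == 400
        assert nullomers == sorted(nullomers)

    def test_dimer_covering_sequence_leaves_none(self):
        # A sequence containing every dimer as a window has no k=2
        # nullomers: concatenating all 400 dimers places each at an even
        # offset.
        covering = "".join(a + b for a, b in itertools.product(ALPHABET, repeat=2))
        census = build_census([ProteinRecord("COVER", "", covering)], 2)
        assert (census.counts > 0).all()
        assert enumerate_nullomers(census) == []

    def test_avoided_motif_is_a_nullomer(self):
        spec = SyntheticSpec(
            n_records=50, length_low=100, length_high=200,
            avoided_motifs=["CQWW"], seed=3,
        )
        records = generate_proteome(spec)
        assert brute_force_count(records, "CQWW") == 0
        census = build_census(records, 4)
        assert count_of(census, "CQWW") == 0
        assert "CQWW" in set(enumerate_nullomers(census))

    def test_partition_of_space(self, small_corpus):
        census = build_census(small_corpus, 3)
        n_observed = int((census.counts > 0).sum())
        assert len(enumerate_nullomers(census)) + n_observed == 8000

    def test_monotone_shrinkage(self, small_corpus):
        # Adding records can only remove nullomers, never create them.
        half = set(enumerate_nullomers(build_census(small_corpus[:15], 3)))
        full = set(enumerate_nullomers(build_census(small_corpus, 3)))
        assert full <= half


class TestFrequencyModels:
    def test_aa_model_delegates_to_residue_frequencies(self, small_corpus):
        census = build_census(small_corpus, 2)
        model = aa_frequency_model(census)
        assert model.kind == "aa_occurrence"
        assert np.array_equal(model.probs, residue_frequencies(census))

    def test_aa_model_degenerate_corpus(self):
        census = build_census([ProteinRecord("P1", "", "AAAA")], 2)
        model = aa_frequency_model(census)
        assert model.prob("A") == 1.0

    def test_default_codon_model_is_genetic_code(self):
        model = codon_frequency_model()
        assert model.kind == "codon_frequency"
        assert model.prob("M") == model.prob("W") == pytest.approx(1 / 61)
        assert model.prob("L") == model.prob("R") == pytest.approx(6 / 61)
        assert model.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_custom_table_is_uniform(self):
        model = codon_frequency_model([7] * 20)
        assert np.allclose(model.probs, 0.05)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            codon_frequency_model([1] * 19 + [0])


class TestExpectedCount:
    def test_uniform_arithmetic(self):
        assert expected_count("ACDE", uniform_model(), 10**6) == pytest.approx(6.25)

    def test_zero_probability_letter(self):
        probs = np.full(20, 1 / 19)
        probs[1] = 0.0  # C
        model = FrequencyModel(kind="aa_occurrence", probs=probs)
        assert expected_count("ACDE", model, 10**6) == 0.0

    @pytest.mark.parametrize("k", [2, 3])
    def test_expected_sums_to_total_windows(self, small_corpus, k):
        census = build_census(small_corpus, k)
        for model in (aa_frequency_model(census), codon_frequency_model()):
            total = _expected_vector(model, k, census.total_windows).sum()
            assert total == pytest.approx(census.total_windows, rel=1e-6)

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            expected_count("A", uniform_model(), 10)


class TestUnderrepresentationPvalue:
    def test_degenerate_zero_expected(self):
        assert underrepresentation_pvalue(0, 0.0) == 1.0

    def test_zero_observed_closed_form(self):
        assert underrepresentation_pvalue(0, 5.0) == pytest.approx(math.exp(-5))

    def test_matches_summation_oracle(self):
        # P(X <= n) by direct term-by-term summation of the Poisson mass
        # (each term evaluated in log space to survive large means).
        for expected in (0.5, 2.0, 17.3, 400.0):
            for observed in (0, 1, 5, int(expected)):
                oracle = sum(
                    math.exp(-expected + j * math.log(expected) - math.lgamma(j + 1))
                    for j in range(observed + 1)
                )
                got = underrepresentation_pvalue(observed, expected)
                assert got == pytest.approx(oracle, rel=1e-9)

    def test_monotone_in_expected(self):
        grid = [0.1, 1.0, 5.0, 50.0, 1e3, 1e6]
        pvals = [underrepresentation_pvalue(3, e) for e in grid]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))
        assert all(0.0 <= p <= 1.0 for p in pvals)

    def test_large_mean_is_stable(self):
        p = underrepresentation_pvalue(10**6, 10**6)
        assert 0.45 < p < 0.55

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            underrepresentation_pvalue(-1, 2.0)
        with pytest.raises(ValueError):
            underrepresentation_pvalue(1, -2.0)


@pytest.fixture(scope="module")
def planted():
    spec = SyntheticSpec(
        n_records=60, length_low=80, length_high=160,
        planted_motifs=[("CQWW", 5), ("YQWW", 9)], seed=42,
    )
    records = generate_proteome(spec)
    census = build_census(records, 4)
    return records, census


class TestMutationNeighborhood:
    def test_exactly_19k_rows_ordered(self, planted):
        _, census = planted
        rows = mutation_neighborhood(
            census, "CQWW", aa_frequency_model(census), codon_frequency_model()
        )
        assert len(rows) == 76
        assert [(r.position, r.substituted_residue) for r in rows] == sorted(
            (r.position, r.substituted_residue) for r in rows
        )
        for row in rows:
            assert row.variant != "CQWW"
            diffs = [i for i, (a, b) in enumerate(zip(row.variant, "CQWW")) if a != b]
            assert diffs == [row.position]
            assert row.original_residue == "CQWW"[row.position]
            assert 0.0 <= row.p_under_aa <= 1.0

    def test_observed_matches_brute_force(self, planted):
        records, census = planted
        rows = mutation_neighborhood(
            census, "CQWW", aa_frequency_model(census), codon_frequency_model()
        )
        by_variant = {r.variant: r.observed for r in rows}
        assert by_variant["YQWW"] == brute_force_count(records, "YQWW") >= 9
        for variant, observed in by_variant.items():
            assert observed == brute_force_count(records, variant)

    def test_nonstandard_query_rejected(self, planted):
        _, census = planted
        with pytest.raises(ValueError, match="'X'"):
            mutation_neighborhood(
                census, "CXWW", aa_frequency_model(census), codon_frequency_model()
            )

    def test_length_mismatch_rejected(self, planted):
        _, census = planted
        with pytest.raises(ValueError):
            mutation_neighborhood(
                census, "CQW", aa_frequency_model(census), codon_frequency_model()
            )


class TestTruncates:
    def test_record_equal_to_kmer(self):
        census3 = build_census([ProteinRecord("P1", "", "CQWW")], 3)
        left, right = truncate_counts(census3, "CQWW")
        assert left >= 1 and right >= 1

    def test_matches_brute_force(self, small_corpus):
        census3 = build_census(small_corpus, 3)
        for kmer in ("ACDE", "CQWW", "LLLL"):
            left, right = truncate_counts(census3, kmer)
            assert left == brute_force_count(small_corpus, kmer[:-1])
            assert right == brute_force_count(small_corpus, kmer[1:])

    def test_k_mismatch_rejected(self, small_corpus):
        census2 = build_census(small_corpus, 2)
        with pytest.raises(ValueError, match="truncate length 3"):
            truncate_counts(census2, "CQWW")


class TestHighOrderNullomer:
    def test_empty_corpus_everything_high_order(self):
        census = build_census([], 4)
        assert is_high_order_nullomer(census, "CQWW")

    def test_observed_variant_defeats_high_order(self):
        census = build_census([ProteinRecord("P1", "", "AYQWWA")], 4)
        assert count_of(census, "CQWW") == 0
        assert not is_high_order_nullomer(census, "CQWW")

    def test_observed_query_rejected(self):
        census = build_census([ProteinRecord("P1", "", "CQWW")], 4)
        with pytest.raises(ValueError, match="not a nullomer"):
            is_high_order_nullomer(census, "CQWW")

    def test_agrees_with_brute_force_on_sparse_corpora(self):
        for seed in range(3):
            spec = SyntheticSpec(
                n_records=5, length_low=30, length_high=60, seed=seed
            )
            records = generate_proteome(spec)
            census = build_census(records, 4)
            for kmer in ("CQWW", "WWWW", "MMHH"):
                if count_of(census, kmer) != 0:
                    continue
                oracle = all(
                    brute_force_count(
                        records, kmer[:pos] + sub + kmer[pos + 1:]
                    ) == 0
                    for pos in range(4)
                    for sub in ALPHABET
                    if sub != kmer[pos]
                )
                assert is_high_order_nullomer(census, kmer) == oracle


class TestRankRare:
    def test_max_pvalue_one_returns_every_observed_kmer(self, small_corpus):
        census = build_census(small_corpus, 2)
        hits = rank_rare(census, aa_frequency_model(census), 1.0)
        assert len(hits) == int((census.counts > 0).sum())
        assert all(h.observed >= 1 for h in hits)
        keys = [(h.p_under, h.observed, h.kmer) for h in hits]
        assert keys == sorted(keys)

    def test_planted_depletion_is_recovered(self):
        # A dimer generated at ~1/100 of its model-expected rate must be
        # flagged at p <= 0.001.
        spec = SyntheticSpec(
            n_records=10, length_low=4000, length_high=4000,
            avoided_motifs=["CW"], seed=5,
        )
        records = generate_proteome(spec) + [ProteinRecord("PLANT", "", "ACWA")]
        census = build_census(records, 2)
        hits = rank_rare(census, aa_frequency_model(census), 0.001)
        assert "CW" in {h.kmer for h in hits}
        (cw,) = [h for h in hits if h.kmer == "CW"]
        assert cw.observed == 1
        assert cw.expected > 50

    def test_bad_threshold_rejected(self, small_corpus):
        census = build_census(small_corpus, 2)
        with pytest.raises(ValueError):
            rank_rare(census, aa_frequency_model(census), 0.0)
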