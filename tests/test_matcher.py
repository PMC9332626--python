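import itertools
import random

import pytest

from genealias.errors import SuggestionStateError
from genealias.fixture_gen import random_fixture
from genealias.gene_db import SynonymEntry, build_index
from genealias.matcher import (
    MatchType,
    accept_suggestion,
    classify_term,
    match_list,
    rank_suggestions,
    tokenize_input,
)
from genealias.normalizer import variants

from conftest import EXPECTED_SYMBOLS, INFLAMMATION_TERMS
from oracle_utils import brute_classify, random_queries


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("CRP, IL-8\nTNF-α", ["CRP", "IL-8", "TNF-α"]),
        ("", []),
        ("CRP,,CRP", ["CRP", "CRP"]),
        ("  a\t b ,c  ", ["a", "b", "c"]),
    ],
)
def test_tokenize_input(raw, expected):
    assert tokenize_input(raw) == expected


class TestClassifyTiers:
    def test_exact_official_symbol(self, canonical_index):
        r = classify_term("CRP", canonical_index, [])
        assert r.match_type is MatchType.EXACT
        assert r.gene_id == 1401

    @pytest.mark.parametrize(
        "identifier, gene_id",
        [
            ("1401", 1401),          # numeric Entrez
            ("HGNC:11766", 7040),    # nested HGNC value
            ("11766", 7040),         # bare HGNC number
            ("ENSG00000169429", 3576),
            ("190180", 7040),        # OMIM number
        ],
    )
    def test_exact_cross_reference_without_declaring_type(
        self, canonical_index, identifier, gene_id
    ):
        r = classify_term(identifier, canonical_index, [])
        assert r.match_type is MatchType.EXACT
        assert r.gene_id == gene_id

    def test_greek_variant_auto_accepted_against_unique_symbol(self, canonical_index):
        r = classify_term("TGF-β1", canonical_index, [])
        assert r.match_type is MatchType.AUTO_ACCEPTED
        assert r.gene_id == 7040

    def test_pure_case_change_is_auto_accepted_not_exact(self, canonical_index):
        r = classify_term("crp", canonical_index, [])
        assert r.match_type is MatchType.AUTO_ACCEPTED
        assert r.gene_id == 1401

    def test_ambiguous_alias_yields_ranked_suggestions(self, canonical_index):
        r = classify_term("IL-8", canonical_index, [])
        assert r.match_type is MatchType.SUGGESTION_PENDING
        symbols = [
            canonical_index.by_gene_id[s.gene_id].symbol for s in r.suggestions
        ]
        assert symbols == ["CXCL8", "CXCR1", "CXCR2", "CXCR2P1"]
        assert r.suggestions[0].exact_synonym
        assert [s.rank for s in r.suggestions] == [1, 2, 3, 4]

    def test_variant_hitting_multiple_symbols_stays_pending(self, canonical_index):
        # TGFB keys to no symbol, but substring-matches TGFB1/2/3; the exact
        # TGFB synonym puts TGFB1 first.
        r = classify_term("TGF-β", canonical_index, [])
        assert r.match_type is MatchType.SUGGESTION_PENDING
        symbols = [
            canonical_index.by_gene_id[s.gene_id].symbol for s in r.suggestions
        ]
        assert symbols == ["TGFB1", "TGFB2", "TGFB3"]

    def test_no_match(self, canonical_index):
        r = classify_term("QQXYZ123", canonical_index, [])
        assert r.match_type is MatchType.NO_MATCH
        assert r.gene_id is None and r.suggestions == ()

    def test_duplicate_points_at_first_occurrence(self, canonical_index):
        r = classify_term("CRP", canonical_index, ["TNF", "CRP", "IL8"])
        assert r.match_type is MatchType.DUPLICATE
        assert r.duplicate_of == 1

    def test_duplicate_uses_raw_terms_not_variants(self, canonical_index):
        # "IL-8" and "IL8" normalize alike but are distinct searches
        r = classify_term("IL8", canonical_index, ["IL-8"])
        assert r.match_type is not MatchType.DUPLICATE

    def test_symbol_beats_synonym_of_other_gene(self):
        # a term equal to an official symbol is EXACT even when it is also
        # another gene's synonym
        from genealias.fixture_gen import FixtureGene, FixtureSpec

        spec = FixtureSpec(
            tax_id=9606,
            genes=(
                FixtureGene(10, "AAA"),
                FixtureGene(11, "BBB", synonyms=("AAA",)),
            ),
        )
        idx = build_index(spec.to_records())
        r = classify_term("AAA", idx, [])
        assert r.match_type is MatchType.EXACT
        assert r.gene_id == 10


class TestRankSuggestions:
    IL8_CANDIDATES = [
        SynonymEntry("IL8", False, 3576),
        SynonymEntry("IL8RA", False, 3577),
        SynonymEntry("IL8RB", False, 3579),
        SynonymEntry("IL8RBP", False, 3580),
    ]

    def test_exact_synonym_first_then_shorter_targets(self):
        ranked = rank_suggestions(variants("IL-8"), self.IL8_CANDIDATES)
        assert [s.gene_id for s in ranked] == [3576, 3577, 3579, 3580]

    def test_single_candidate_gets_rank_one(self):
        (s,) = rank_suggestions(variants("MYPT1"), [SynonymEntry("MYPT1", False, 4659)])
        assert s.rank == 1 and s.exact_synonym

    def test_order_invariant_under_input_permutation(self):
        expected = rank_suggestions(variants("IL-8"), self.IL8_CANDIDATES)
        for perm in itertools.permutations(self.IL8_CANDIDATES):
            assert rank_suggestions(variants("IL-8"), list(perm)) == expected


class TestMatchList:
    def test_inflammation_terms_counts(self, canonical_index):
        fl = match_list(INFLAMMATION_TERMS, canonical_index, auto_top=False)
        c = fl.counts()
        assert c[MatchType.EXACT] == 4
        assert c[MatchType.AUTO_ACCEPTED] == 1
        assert c[MatchType.SUGGESTION_PENDING] == 5

    def test_auto_top_resolves_to_published_symbols(self, canonical_index):
        fl = match_list(INFLAMMATION_TERMS, canonical_index, auto_top=True)
        symbols = [
            canonical_index.by_gene_id[r.gene_id].symbol for r in fl.results
        ]
        assert symbols == EXPECTED_SYMBOLS

    def test_empty_input(self, canonical_index):
        fl = match_list([], canonical_index)
        assert len(fl) == 0

    def test_positions_are_identity(self, canonical_index):
        fl = match_list(INFLAMMATION_TERMS, canonical_index)
        assert [r.position for r in fl.results] == list(range(len(INFLAMMATION_TERMS)))


class TestAcceptSuggestion:
    def test_accept_named_gene(self, canonical_index):
        fl = match_list(["IL-8"], canonical_index)
        fl = accept_suggestion(fl, 0, 3576)
        r = fl.results[0]
        assert r.match_type is MatchType.SUGGESTION_ACCEPTED
        assert canonical_index.by_gene_id[r.gene_id].symbol == "CXCL8"

    def test_accept_on_exact_result_is_an_error(self, canonical_index):
        fl = match_list(["CRP"], canonical_index)
        with pytest.raises(SuggestionStateError, match="not awaiting"):
            accept_suggestion(fl, 0, 1401)

    def test_accept_unoffered_gene_is_an_error(self, canonical_index):
        fl = match_list(["IL-8"], canonical_index)
        with pytest.raises(SuggestionStateError, match="not among"):
            accept_suggestion(fl, 0, 1401)

    def test_position_out_of_range(self, canonical_index):
        fl = match_list(["IL-8"], canonical_index)
        with pytest.raises(SuggestionStateError, match="out of range"):
            accept_suggestion(fl, 5, 3576)

    def test_other_positions_untouched(self, canonical_index):
        fl = match_list(["CRP", "IL-8", "MCP-1"], canonical_index)
        fl2 = accept_suggestion(fl, 1, 3576)
        assert fl2.results[0] == fl.results[0]
        assert fl2.results[2] == fl.results[2]


class TestProperties:
    def test_order_and_length_conserved_on_random_inputs(self):
        rng = random.Random(11)
        spec = random_fixture(seed=11, n_genes=30)
        idx = build_index(spec.to_records())
        for trial in range(20):
            terms = random_queries(rng, spec.to_records(), rng.randint(0, 25))
            fl = match_list(terms, idx, auto_top=bool(trial % 2))
            assert len(fl) == len(terms)
            assert [r.term for r in fl.results] == terms
            assert [r.position for r in fl.results] == list(range(len(terms)))

    def test_classify_agrees_with_brute_force_oracle(self):
        spec = random_fixture(seed=7, n_genes=50)
        records = spec.to_records()
        idx = build_index(records)
        rng = random.Random(7)
        queries = random_queries(rng, records, 200)
        for i, q in enumerate(queries):
            prior = queries[:i]
            got = classify_term(q, idx, prior)
            want = brute_classify(q, records, prior)
            assert got.match_type.name == want[0], q
            assert got.gene_id == want[1], q
            assert got.duplicate_of == want[2], q
            assert tuple(s.gene_id for s in got.suggestions) == want[3], q

    def test_oracle_agreement_on_canonical_terms(self, canonical_index, canonical_records):
        for i, term in enumerate(INFLAMMATION_TERMS):
            prior = INFLAMMATION_TERMS[:i]
            got = classify_term(term, canonical_index, prior)
            want = brute_classify(term, canonical_records, prior)
            assert (got.match_type.name, got.gene_id) == (want[0], want[1])
            assert tuple(s.gene_id for s in got.suggestions) == want[3]

    def test_exact_synonym_suggestions_precede_substring_ones(self):
        spec = random_fixture(seed=19, n_genes=40)
        idx = build_index(spec.to_records())
        rng = random.Random(19)
        for q in random_queries(rng, spec.to_records(), 100):
            r = classify_term(q, idx, [])
            flags = [s.exact_synonym for s in r.suggestions]
            assert flags == sorted(flags, reverse=True), q

    def test_determinism_identical_reruns(self, canonical_index):
        a = match_list(INFLAMMATION_TERMS, canonical_index, auto_top=True)
        b = match_list(INFLAMMATION_TERMS, canonical_index, auto_top=True)
        assert a == b
        assert repr(a) == repr(b)
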