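import logging

import pytest
from hypothesis import given
from hypothesis import strategies as st

from griefwatch.lexicon import (
    DuplicateIdentifierError,
    LexiconMatcher,
    TerritoryLexicon,
    compile_lexicons,
    is_primarily_numeric,
    normalize_phrase,
    read_lexicon_csv,
    validate_keywords,
    write_lexicon_csv,
)

GRIEF_ROWS = [
    ("RIP", "rip"),
    ("RIP", "r.i.p"),
    ("RIP", "rest in peace"),
    ("Rest Up", "rest up"),
    ("Rest Up", "restup"),
    ("Long Live", "long live"),
    ("Long Live", "longlive"),
]
TERR_ROWS = [
    ("cbe", "cbe"),
    ("benzie", "benzie"),
    ("benzie", "benzie block"),
    ("gang6", "gang 6"),
]


@pytest.fixture(scope="module")
def lexicons():
    return compile_lexicons(GRIEF_ROWS, TERR_ROWS)


@pytest.fixture(scope="module")
def matcher(lexicons):
    return LexiconMatcher(*lexicons)


class TestCompile:
    def test_numeric_identifiers_dropped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            _, registry = compile_lexicons(
                GRIEF_ROWS, TERR_ROWS + [("cbe", "#700"), ("cbe", "059")]
            )
        idents = {i for t in registry for i in t.identifiers}
        assert "#700" not in idents and "059" not in idents
        assert sum("numeric" in r.message for r in caplog.records) == 2

    @pytest.mark.parametrize(
        "ident,numeric",
        [("#700", True), ("059", True), ("cbe", False), ("g45kw", False),
         ("g45", True), ("benzie block", False)],
    )
    def test_primarily_numeric_rule(self, ident, numeric):
        assert is_primarily_numeric(ident) is numeric

    def test_killer_forms_derived_from_identifiers(self, lexicons):
        _, registry = lexicons
        cbe = next(t for t in registry if t.territory_id == "cbe")
        assert cbe.killer_forms == frozenset({"cbek"})

    def test_duplicate_identifier_across_territories_raises(self):
        with pytest.raises(DuplicateIdentifierError) as err:
            compile_lexicons(GRIEF_ROWS, TERR_ROWS + [("rival", "benzie")])
        assert "benzie" in str(err.value)
        assert "rival" in str(err.value)

    def test_empty_grief_lexicon_raises(self):
        with pytest.raises(ValueError):
            compile_lexicons([], TERR_ROWS)

    def test_territory_lexicon_rejects_numeric_identifier(self):
        with pytest.raises(ValueError):
            TerritoryLexicon("t", frozenset({"123a"}))


class TestMatchText:
    @pytest.mark.parametrize(
        "text,grief,terr",
        [
            ("R.I.P J-Boy #CBE", {"RIP"}, {"cbe"}),
            ("Happy bday Big Benzie #RIP", {"RIP"}, {"benzie"}),
            ("", set(), set()),
            ("REST IN PEACE [GANG 6] LIL JOSH", {"RIP"}, {"gang6"}),
            ("I lost another one Rest Up Javon CBE keep ya head up",
             {"Rest Up"}, {"cbe"}),
            # grief string only inside a mentioned handle: no grief hit
            ("@rip_legend come thru CBE", set(), {"cbe"}),
            # "rip" must not match inside words
            ("took a trip downtown", set(), set()),
            ("#rip benzie", {"RIP"}, {"benzie"}),
        ],
    )
    def test_worked_examples(self, matcher, text, grief, terr):
        g, t, _ = matcher.match(text)
        assert g == grief
        assert t == terr

    def test_killer_form_hits_named_territory(self, matcher):
        g, t, via_killer = matcher.match("rip the opps CBEk")
        assert g == {"RIP"}
        assert t == {"cbe"}
        assert via_killer

    def test_case_and_whitespace_invariance(self, matcher):
        base = matcher.match("rip benzie")
        assert matcher.match("  RIP   BENZIE  ") == base
        assert matcher.match("Rip Benzie\n") == base

    @given(
        st.lists(
            st.sampled_from(
                ["rip", "R.I.P", "rest", "up", "in", "peace", "benzie", "cbe",
                 "@rip_fan", "@cbe_boy", "trip", "gripping", "the", "block",
                 "LONG", "live", "#RIP", "#cbe", "yo!!", "111"]
            ),
            max_size=12,
        )
    )
    def test_grief_hits_equal_brute_force_oracle(self, matcher, words):
        """Grief hits equal a naive substring scan of the squashed text
        outside @-tokens."""
        text = " ".join(words)
        got, _, _ = matcher.match(text)
        body = " " + " ".join(
            normalize_phrase(w) for w in text.split() if not w.startswith("@")
        ) + " "
        expected = {
            canon
            for canon, variants in matcher.grief.entries.items()
            if any(f" {normalize_phrase(v)} " in body for v in variants)
        }
        assert got == expected

    def test_variant_matches_its_own_canonical_rendering(self, lexicons, matcher):
        grief, _ = lexicons
        for canon, variants in grief.entries.items():
            for v in variants:
                hits, _, _ = matcher.match(f"{v} cbe")
                assert canon in hits


def test_registry_roundtrips_through_csv_bit_identically(tmp_path, lexicons):
    grief, registry = lexicons
    p1 = tmp_path / "lex1.csv"
    p2 = tmp_path / "lex2.csv"
    write_lexicon_csv(p1, grief, registry)
    grief2, registry2 = read_lexicon_csv(p1)
    write_lexicon_csv(p2, grief2, registry2)
    assert p1.read_bytes() == p2.read_bytes()
    assert grief2.entries == dict(grief.entries)


class TestValidateKeywords:
    def test_grief_token_ranks_first_in_grief_corpus(self):
        """Oracle: raw token frequency on a corpus built only from templates
        containing "rip"."""
        corpus = [
            ["rip", "homie", "gone"],
            ["rip", "miss", "you"],
            ["rip", "forever", "homie"],
            ["rip", "gone", "soon"],
        ] * 5
        ranking = validate_keywords(corpus, n_topics=2, seed=0)
        assert ranking.tokens()[0] == "rip"

    def test_single_document_matches_frequency_order(self):
        doc = ["rip"] * 5 + ["gone"] * 3 + ["homie"] * 1
        ranking = validate_keywords([doc], n_topics=1, seed=0)
        top3 = ranking.tokens()[:3]
        assert top3 == ["rip", "gone", "homie"]

    def test_fewer_documents_than_topics_raises(self):
        with pytest.raises(ValueError):
            validate_keywords([["rip"]], n_topics=2, seed=0)

    def test_deterministic_for_fixed_seed(self):
        corpus = [["rip", "gone"], ["homie", "rip"], ["block", "love"]] * 4
        r1 = validate_keywords(corpus, n_topics=2, seed=11)
        r2 = validate_keywords(corpus, n_topics=2, seed=11)
        assert r1.ranked == r2.ranked

    def test_weights_non_increasing(self):
        corpus = [["rip", "gone", "homie"], ["rip", "love"]] * 3
        weights = [w for _, w in validate_keywords(corpus, 1, 0).ranked]
        assert all(a >= b for a, b in zip(weights, weights[1:]))
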