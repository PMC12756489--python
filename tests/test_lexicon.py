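"""Lexicon loading, compilation, and matcher semantics."""

import io
import re

import pytest
from hypothesis import given, strategies as st

import srflex
from srflex.lexicon import LexiconError, MatchSettings, _compile_phrase


def _tsv(rows):
    return io.StringIO(
        "category_id\tlabel\tphrase\n"
        + "".join(f"{c}\t{c}\t{p}\n" for c, p in rows)
    )


def brute_force_counts(lexicon, text):
    """Independent oracle: enumerate every candidate match at every start
    position, then greedily select leftmost-longest non-overlapping spans
    per category."""
    from srflex.lexicon import _normalize

    norm = _normalize(text, lexicon.settings)
    counts = {}
    for cat in lexicon.categories:
        candidates = []
        for pos in range(len(norm) + 1):
            for phrase in cat.phrases:
                m = phrase.compiled.match(norm, pos)
                if m and m.start() == pos:
                    candidates.append((m.start(), m.end()))
        chosen = []
        cursor = -1
        for start, end in sorted(set(candidates), key=lambda c: (c[0], -c[1])):
            if start >= cursor:
                chosen.append((start, end))
                cursor = end
        counts[cat.id] = len(chosen)
    return counts


class TestLoading:
    def test_file_order_and_phrase_counts(self):
        lex = srflex.load_lexicon(_tsv([
            ("hopelessness", "no hope"),
            ("hopelessness", "nothing will ever change"),
            ("loneliness", "all alone"),
        ]))
        assert lex.category_ids == ["hopelessness", "loneliness"]
        assert lex.phrase_counts() == {"hopelessness": 2, "loneliness": 1}

    def test_packaged_lexicon_has_twenty_categories(self, toy_lexicon):
        assert len(toy_lexicon.categories) == 20
        assert all(len(c.phrases) >= 1 for c in toy_lexicon.categories)

    @pytest.mark.parametrize("rows,message", [
        ([("a", "x"), ("b", "y"), ("a", "z")], "duplicate"),
        ([], "no phrase rows"),
        ([("a", "   ")], "empty"),
    ])
    def test_malformed_sources_error(self, rows, message):
        with pytest.raises(LexiconError, match=message):
            srflex.load_lexicon(_tsv(rows))

    def test_empty_file_errors(self):
        with pytest.raises(LexiconError, match="empty"):
            srflex.load_lexicon(io.StringIO(""))

    def test_tsv_round_trip(self, toy_lexicon):
        buf = io.StringIO()
        srflex.write_lexicon(toy_lexicon, buf)
        again = srflex.load_lexicon(io.StringIO(buf.getvalue()))
        assert again.category_ids == toy_lexicon.category_ids
        assert again.phrase_counts() == toy_lexicon.phrase_counts()

    def test_yaml_source(self, tmp_path):
        path = tmp_path / "lex.yaml"
        path.write_text(
            "categories:\n"
            "  - id: hopelessness\n    label: Hopelessness\n"
            "    phrases: ['no hope']\n"
            "  - id: loneliness\n    label: Loneliness\n"
            "    phrases: ['all alone', 'alone']\n"
        )
        lex = srflex.load_lexicon(path)
        assert lex.category_ids == ["hopelessness", "loneliness"]
        assert lex.phrase_counts()["loneliness"] == 2


class TestCompilation:
    @pytest.mark.parametrize("phrase,text,matches", [
        ("no hope", "No  hope", True),
        ("no hope", "no, hope", True),
        ("no hope", "nohope", False),
        ("no hope", "no hopes", False),
        ("end my life", "end   my life!", True),
        ("hopeless", "hopelessness", False),
        ("hopeless", "i am hopeless.", True),
    ])
    def test_boundary_and_separator_rules(self, phrase, text, matches):
        pat = _compile_phrase(phrase, MatchSettings())
        found = pat.search(text.casefold()) is not None
        assert found is matches

    def test_punctuation_only_phrase_errors(self):
        with pytest.raises(LexiconError, match="empty token sequence"):
            srflex.compile_lexicon(srflex.load_lexicon(_tsv([("a", "!!!")])))

    def test_compilation_is_deterministic(self, toy_lexicon):
        again = srflex.packaged_lexicon()
        for c1, c2 in zip(toy_lexicon.categories, again.categories):
            for p1, p2 in zip(c1.phrases, c2.phrases):
                assert p1.compiled.pattern == p2.compiled.pattern


class TestCounting:
    def test_two_phrases_one_category(self, mini_lexicon):
        counts = srflex.count_matches(
            mini_lexicon, "i feel hopeless. there is no hope.")
        assert counts["hopelessness"] == 2

    def test_empty_text_all_zero(self, toy_lexicon):
        assert set(srflex.count_matches(toy_lexicon, "").values()) == {0}

    def test_cross_category_independence(self, mini_lexicon):
        counts = srflex.count_matches(mini_lexicon, "all alone")
        assert counts == {"hopelessness": 0, "loneliness": 1}

    def test_leftmost_longest_within_category(self, mini_lexicon):
        # "all alone" wins over "alone" at the same region; a later "alone"
        # still counts separately
        counts = srflex.count_matches(mini_lexicon, "all alone and alone")
        assert counts["loneliness"] == 2

    def test_spans_consistent_with_counts(self, mini_lexicon):
        text = "no hope at all"
        spans = srflex.explain_matches(mini_lexicon, text)
        assert [(s.start_char, s.end_char) for s in spans] == [(0, 7)]
        assert srflex.explain_matches(mini_lexicon, "") == []

    def test_spans_sorted_and_non_overlapping_per_category(self, toy_lexicon):
        text = ("i feel hopeless and so lonely, no hope left, "
                "i cut myself and i am a burden on everyone")
        spans = srflex.explain_matches(toy_lexicon, text)
        starts = [s.start_char for s in spans]
        assert starts == sorted(starts)
        per_cat = {}
        for s in spans:
            per_cat.setdefault(s.category_id, []).append(s)
        for cat_spans in per_cat.values():
            for a, b in zip(cat_spans, cat_spans[1:]):
                assert a.end_char <= b.start_char
        counts = srflex.count_matches(toy_lexicon, text)
        for cat, n in counts.items():
            assert len(per_cat.get(cat, [])) == n

    def test_uncompiled_lexicon_rejected(self):
        lex = srflex.load_lexicon(_tsv([("a", "x")]))
        with pytest.raises(LexiconError, match="compiled"):
            srflex.count_matches(lex, "x")


WORDS = ["hope", "no", "alone", "all", "end", "life", "dark", "cold", "rain",
         "stone", "hopeless", "lost"]


@st.composite
def lexicon_and_text(draw):
    n_cats = draw(st.integers(1, 4))
    rows = []
    for c in range(n_cats):
        for _ in range(draw(st.integers(1, 4))):
            phrase = " ".join(draw(
                st.lists(st.sampled_from(WORDS), min_size=1, max_size=3)))
            rows.append((f"cat{c}", phrase))
    text = " ".join(draw(
        st.lists(st.sampled_from(WORDS + [",", "."]), min_size=0, max_size=60)))
    return rows, text


class TestMatcherOracle:
    @given(lexicon_and_text())
    def test_counts_equal_brute_force_oracle(self, case):
        rows, text = case
        lex = srflex.compile_lexicon(srflex.load_lexicon(_tsv(rows)))
        assert srflex.count_matches(lex, text) == brute_force_counts(lex, text)

    @given(lexicon_and_text())
    def test_concatenation_monotonicity(self, case):
        rows, text = case
        lex = srflex.compile_lexicon(srflex.load_lexicon(_tsv(rows)))
        base = srflex.count_matches(lex, text)
        extended = srflex.count_matches(lex, text + ". " + "stone rain cold")
        assert all(extended[c] >= base[c] for c in base)

    @given(lexicon_and_text())
    def test_determinism(self, case):
        rows, text = case
        lex = srflex.compile_lexicon(srflex.load_lexicon(_tsv(rows)))
        assert srflex.count_matches(lex, text) == srflex.count_matches(lex, text)
        assert srflex.explain_matches(lex, text) == srflex.explain_matches(lex, text)
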