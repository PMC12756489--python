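"""Suicide-risk-factor (SRF) lexicon: loading, compilation, and matching.

An SRF lexicon is an ordered set of psychological-construct categories
(hopelessness, loneliness, previous suicide attempt, ...), each a list of
phrases.  Matching is deliberately literal: phrases are compiled to regular
expressions that fold case, apply Unicode canonical normalization, anchor at
word boundaries, and tolerate arbitrary whitespace/punctuation runs between
phrase tokens — but perform no stemming, lemmatization, or fuzzy matching.
Category order in the source file is preserved and defines the feature-column
order used by every downstream model, so lexicon files are reproducible
instruments, not bags of words.

Word boundaries are defined at transitions between letter/digit characters
and everything else after normalization, which keeps the matcher
language-neutral (it behaves identically for Hebrew and Latin scripts;
case folding is a no-op for caseless scripts).
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import yaml

__all__ = [
    "LexiconError",
    "MatchSettings",
    "PhrasePattern",
    "Category",
    "SRFLexicon",
    "MatchSpan",
    "load_lexicon",
    "write_lexicon",
    "packaged_lexicon",
    "compile_lexicon",
    "count_matches",
    "explain_matches",
    "write_explanations",
]


class LexiconError(ValueError):
    """Malformed lexicon source or phrase that cannot be compiled."""


# A "word" character is a letter or digit; underscore is treated as a
# separator so boundaries sit exactly at letter/digit transitions.
_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)
_SEPARATOR = r"[\W_]+"
_LEFT_BOUNDARY = r"(?<![^\W_])"
_RIGHT_BOUNDARY = r"(?![^\W_])"


@dataclass(frozen=True)
class MatchSettings:
    """Matching configuration shared by every phrase of a lexicon."""

    case_fold: bool = True
    word_boundaries: bool = True
    #: Unicode normalization form applied to phrases and to matched text.
    unicode_form: str = "NFKC"
    #: collapse any run of whitespace/punctuation between tokens to one
    #: separator when matching multi-token phrases.
    separator_tolerance: bool = True


@dataclass
class PhrasePattern:
    """One lexicon phrase plus its compiled matcher (``None`` until compile)."""

    raw_phrase: str
    compiled: re.Pattern | None = None

    def __post_init__(self) -> None:
        if not self.raw_phrase.strip():
            raise LexiconError("phrase is empty after trimming")


@dataclass
class Category:
    id: str
    label: str
    phrases: list[PhrasePattern]

    def __post_init__(self) -> None:
        if not self.id or not self.id.strip():
            raise LexiconError("category id must be non-empty")
        if not self.phrases:
            raise LexiconError(f"category {self.id!r} has no phrases")


@dataclass
class SRFLexicon:
    """Ordered categories plus matching settings.

    The category order is fixed at load time and defines downstream feature
    columns; two lexicons with the same categories in a different order are
    different instruments.
    """

    categories: list[Category]
    settings: MatchSettings = field(default_factory=MatchSettings)
    compiled: bool = False

    def __post_init__(self) -> None:
        ids = [c.id for c in self.categories]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise LexiconError(f"duplicate category id(s): {sorted(dupes)}")
        if not self.categories:
            raise LexiconError("lexicon has no categories")

    @property
    def category_ids(self) -> list[str]:
        return [c.id for c in self.categories]

    def phrase_counts(self) -> dict[str, int]:
        return {c.id: len(c.phrases) for c in self.categories}

    def __getitem__(self, category_id: str) -> Category:
        for c in self.categories:
            if c.id == category_id:
                return c
        raise KeyError(category_id)


@dataclass(frozen=True)
class MatchSpan:
    """Half-open character span of one selected match in normalized text."""

    category_id: str
    phrase_index: int
    start_char: int
    end_char: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_char < self.end_char):
            raise ValueError("invalid span offsets")


# ---------------------------------------------------------------------------
# Loading / writing
# ---------------------------------------------------------------------------

def _rows_from_tsv(lines: Iterable[str]) -> list[tuple[str, str, str]]:
    rows = []
    it = iter(lines)
    try:
        header = next(it)
    except StopIteration:
        raise LexiconError("empty lexicon file") from None
    cols = [c.strip() for c in header.rstrip("\n").split("\t")]
    if cols[:3] != ["category_id", "label", "phrase"]:
        raise LexiconError(
            "lexicon TSV must start with header 'category_id\\tlabel\\tphrase'"
        )
    for lineno, line in enumerate(it, start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise LexiconError(f"line {lineno}: expected 3 tab-separated fields")
        rows.append((parts[0].strip(), parts[1].strip(), parts[2]))
    return rows


def _lexicon_from_rows(rows: Sequence[tuple[str, str, str]],
                       settings: MatchSettings) -> SRFLexicon:
    if not rows:
        raise LexiconError("lexicon file contains no phrase rows")
    order: list[str] = []
    labels: dict[str, str] = {}
    phrases: dict[str, list[PhrasePattern]] = {}
    closed: set[str] = set()
    prev_id: str | None = None
    for cid, label, phrase in rows:
        if cid != prev_id:
            if cid in phrases:
                # the id appeared earlier in a non-adjacent block
                raise LexiconError(f"duplicate category id {cid!r} in two blocks")
            if prev_id is not None:
                closed.add(prev_id)
            order.append(cid)
            labels[cid] = label
            phrases[cid] = []
            prev_id = cid
        elif label != labels[cid]:
            raise LexiconError(
                f"category {cid!r} has conflicting labels "
                f"{labels[cid]!r} and {label!r}"
            )
        phrases[cid].append(PhrasePattern(phrase))
    cats = [Category(cid, labels[cid], phrases[cid]) for cid in order]
    return SRFLexicon(categories=cats, settings=settings)


def _lexicon_from_mapping(doc: Mapping, settings: MatchSettings) -> SRFLexicon:
    try:
        entries = doc["categories"]
    except (KeyError, TypeError):
        raise LexiconError("structured lexicon must have a 'categories' list")
    rows: list[tuple[str, str, str]] = []
    for entry in entries:
        cid = entry["id"]
        label = entry.get("label", cid)
        for phrase in entry["phrases"]:
            rows.append((cid, label, phrase))
    if "settings" in doc:
        settings = MatchSettings(**doc["settings"])
    return _lexicon_from_rows(rows, settings)


def load_lexicon(source: Union[str, Path, TextIO],
                 settings: MatchSettings | None = None) -> SRFLexicon:
    """Load a lexicon from a TSV file or a YAML/JSON structured document.

    File order defines category order.  Duplicate category ids, categories
    without phrases, and empty files are hard errors.
    """
    settings = settings or MatchSettings()
    if hasattr(source, "read"):
        text = source.read()
        suffix = ".tsv"
    else:
        path = Path(source)
        text = path.read_text(encoding="utf-8")
        suffix = path.suffix.lower()
    if suffix in (".yaml", ".yml"):
        return _lexicon_from_mapping(yaml.safe_load(text), settings)
    if suffix == ".json":
        return _lexicon_from_mapping(json.loads(text), settings)
    return _lexicon_from_rows(_rows_from_tsv(text.splitlines(keepends=False)),
                              settings)


def write_lexicon(lexicon: SRFLexicon, sink: Union[str, Path, TextIO]) -> None:
    """Write a lexicon back to TSV (lossless round trip of ids/labels/phrases)."""
    lines = ["category_id\tlabel\tphrase"]
    for cat in lexicon.categories:
        for p in cat.phrases:
            lines.append(f"{cat.id}\t{cat.label}\t{p.raw_phrase}")
    text = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text, encoding="utf-8")


def packaged_lexicon(compiled: bool = True) -> SRFLexicon:
    """The packaged 20-category toy lexicon (English stand-in instrument)."""
    from importlib.resources import files

    path = files("srflex.data").joinpath("toy_lexicon.tsv")
    lex = _lexicon_from_rows(
        _rows_from_tsv(path.read_text(encoding="utf-8").splitlines()),
        MatchSettings(),
    )
    return compile_lexicon(lex) if compiled else lex


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------

def _normalize(text: str, settings: MatchSettings) -> str:
    out = unicodedata.normalize(settings.unicode_form, text)
    if settings.case_fold:
        out = out.casefold()
    return out


def _compile_phrase(raw: str, settings: MatchSettings) -> re.Pattern:
    tokens = _TOKEN_RE.findall(_normalize(raw, settings))
    if not tokens:
        raise LexiconError(
            f"phrase {raw!r} reduces to an empty token sequence after "
            "normalization"
        )
    sep = _SEPARATOR if settings.separator_tolerance else r"\s"
    body = sep.join(re.escape(t) for t in tokens)
    if settings.word_boundaries:
        body = _LEFT_BOUNDARY + body + _RIGHT_BOUNDARY
    return re.compile(body, re.UNICODE)


def compile_lexicon(lexicon: SRFLexicon) -> SRFLexicon:
    """Return a compiled copy; compilation is deterministic per settings."""
    cats = []
    for cat in lexicon.categories:
        compiled = [
            PhrasePattern(p.raw_phrase, _compile_phrase(p.raw_phrase, lexicon.settings))
            for p in cat.phrases
        ]
        cats.append(Category(cat.id, cat.label, compiled))
    return SRFLexicon(categories=cats, settings=lexicon.settings, compiled=True)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _all_occurrences(pattern: re.Pattern, text: str) -> list[tuple[int, int]]:
    """Every match span, including overlapping ones (search-and-advance)."""
    spans = []
    pos = 0
    while True:
        m = pattern.search(text, pos)
        if m is None:
            break
        spans.append((m.start(), m.end()))
        pos = m.start() + 1
    return spans


def _select_spans(candidates: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Greedy leftmost-longest non-overlapping selection within one category.

    Candidates are (start, end, phrase_index); at equal (start, end) the
    lowest phrase index wins, making the result deterministic.
    """
    chosen = []
    cursor = -1
    for start, end, idx in sorted(candidates, key=lambda c: (c[0], -c[1], c[2])):
        if start >= cursor:
            chosen.append((start, end, idx))
            cursor = end
    return chosen


def _require_compiled(lexicon: SRFLexicon) -> None:
    if not lexicon.compiled:
        raise LexiconError("lexicon must be compiled first (compile_lexicon)")


def explain_matches(lexicon: SRFLexicon, text: str) -> list[MatchSpan]:
    """Span-level explanation of every counted match, sorted by start offset.

    Offsets index the normalized form of *text*; text already produced by
    ``corpus.clean_text`` is a fixed point of normalization, so offsets then
    index the cleaned text directly.  Categories are matched independently:
    one text span may be claimed by several categories, while spans within a
    category never overlap (leftmost-longest greedy selection).
    """
    _require_compiled(lexicon)
    norm = _normalize(text, lexicon.settings)
    spans: list[MatchSpan] = []
    for cat in lexicon.categories:
        candidates = [
            (s, e, i)
            for i, phrase in enumerate(cat.phrases)
            for (s, e) in _all_occurrences(phrase.compiled, norm)
        ]
        spans.extend(
            MatchSpan(cat.id, idx, s, e)
            for s, e, idx in _select_spans(candidates)
        )
    spans.sort(key=lambda m: (m.start_char, m.end_char, m.category_id))
    return spans


def count_matches(lexicon: SRFLexicon, text: str) -> dict[str, int]:
    """Non-overlapping match count per category (empty text -> all zeros)."""
    _require_compiled(lexicon)
    counts = dict.fromkeys(lexicon.category_ids, 0)
    for span in explain_matches(lexicon, text):
        counts[span.category_id] += 1
    return counts


def write_explanations(rows: Iterable[tuple[str, SRFLexicon, str]],
                       sink: Union[str, Path, TextIO]) -> None:
    """Per-session explanation report: session_id, category, phrase, start, end."""
    lines = ["session_id\tcategory_id\tphrase\tstart\tend"]
    for session_id, lexicon, text in rows:
        for span in explain_matches(lexicon, text):
            phrase = lexicon[span.category_id].phrases[span.phrase_index].raw_phrase
            lines.append(
                f"{session_id}\t{span.category_id}\t{phrase}"
                f"\t{span.start_char}\t{span.end_char}"
            )
    text_out = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(text_out)
    else:
        Path(sink).write_text(text_out, encoding="utf-8")
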