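"""Design-matrix construction: sessions x lexicon categories -> model input.

Each session becomes one row of per-category match counts over the cleaned
help-seeker text of its prefix slice.  Raw counts are the default feature
scale (odds ratios are then per-mention effects); a per-1,000-characters
normalization and a binary-presence reduction are available as switches.
The intercept column of ones is appended last, and the category order of the
lexicon fixes the column order across strata and fractions so trajectory
joins are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, TextIO, Union

import numpy as np

from .corpus import (
    AGE_GROUPS,
    GENDERS,
    ChatSession,
    CorpusError,
    help_seeker_text,
    slice_prefix,
)
from .lexicon import SRFLexicon, count_matches

__all__ = [
    "FeatureVector",
    "DesignMatrix",
    "FeatureOptions",
    "vectorize",
    "build_design",
    "export_feature_matrix",
]

INTERCEPT = "intercept"


@dataclass(frozen=True)
class FeatureOptions:
    """Feature-scale switches.

    normalize_per_1000
        divide each count by the help-seeker character length of the slice
        and multiply by 1,000 (mentions per thousand characters).
    binary_presence
        reduce each count to 0/1 before any normalization.
    slice_unit
        unit of prefix slicing ("chars" or "messages").
    """

    normalize_per_1000: bool = False
    binary_presence: bool = False
    slice_unit: str = "chars"


@dataclass
class FeatureVector:
    session_id: str
    counts: np.ndarray
    fraction: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("feature counts must be non-negative")


@dataclass
class DesignMatrix:
    """Rows x (categories + intercept) with the binary SR outcome.

    ``X`` carries the intercept as its last column; ``column_names`` matches
    ``X``'s columns.
    """

    X: np.ndarray
    y: np.ndarray
    column_names: list[str]
    session_ids: list[str]
    stratum: str = "All"
    fraction: float = 1.0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("row count must equal outcome length")
        if self.X.shape[1] != len(self.column_names):
            raise ValueError("column_names must match X columns")

    @classmethod
    def from_arrays(cls, features: np.ndarray, y: Sequence[int],
                    category_ids: Sequence[str], *, stratum: str = "All",
                    fraction: float = 1.0,
                    session_ids: Sequence[str] | None = None) -> "DesignMatrix":
        """Assemble a design from a raw feature array, appending the intercept."""
        features = np.asarray(features, dtype=float)
        X = np.column_stack([features, np.ones(features.shape[0])])
        ids = list(session_ids) if session_ids is not None else [
            str(i) for i in range(features.shape[0])
        ]
        return cls(X, np.asarray(y), list(category_ids) + [INTERCEPT], ids,
                   stratum=stratum, fraction=fraction)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def prevalence(self) -> float:
        return float(np.mean(self.y))


def vectorize(session: ChatSession, lexicon: SRFLexicon, fraction: float = 1.0,
              options: FeatureOptions | None = None) -> FeatureVector:
    """Per-category counts over the help-seeker text of the prefix slice."""
    options = options or FeatureOptions()
    sliced = slice_prefix(session, fraction, unit=options.slice_unit)
    text = help_seeker_text(sliced)
    counts = count_matches(lexicon, text)
    vec = np.array([counts[c] for c in lexicon.category_ids], dtype=float)
    if options.binary_presence:
        vec = (vec > 0).astype(float)
    if options.normalize_per_1000:
        n_chars = sum(m.char_len for m in sliced.help_seeker_messages())
        vec = vec * 1000.0 / n_chars  # slice_prefix guarantees n_chars > 0
    return FeatureVector(session.session_id, vec, fraction)


def _passes(session: ChatSession, stratum_filter) -> bool:
    if stratum_filter is None:
        return True
    dim, value = stratum_filter
    if dim == "gender":
        if value not in GENDERS or value == "unknown":
            raise ValueError(f"bad gender stratum {value!r}")
        return session.gender == value
    if dim == "age_group":
        if value not in AGE_GROUPS or value == "unknown":
            raise ValueError(f"bad age stratum {value!r}")
        return session.age_group == value
    raise ValueError(f"unknown stratification dimension {dim!r}")


def counts_matrix(sessions: Sequence[ChatSession], lexicon: SRFLexicon,
                  fraction: float = 1.0,
                  options: FeatureOptions | None = None) -> np.ndarray:
    """(sessions x categories) feature matrix; one matcher pass per session.

    Computing this once and slicing rows per stratum avoids re-matching the
    same text for every stratified model.
    """
    return np.vstack([vectorize(s, lexicon, fraction, options).counts
                      for s in sessions])


def build_design(sessions: Sequence[ChatSession], lexicon: SRFLexicon,
                 fraction: float = 1.0,
                 stratum_filter: tuple[str, str] | None = None,
                 options: FeatureOptions | None = None,
                 stratum_name: str | None = None,
                 precomputed_counts: np.ndarray | None = None) -> DesignMatrix:
    """Design matrix for one stratum at one chat fraction.

    ``stratum_filter`` is ``None`` (the "All" model, which keeps
    unknown-demographic sessions) or ``("gender", value)`` /
    ``("age_group", value)``; stratified designs exclude sessions whose
    stratification variable is unknown by construction.  Both outcome classes
    must survive the filter.  ``precomputed_counts`` (from
    :func:`counts_matrix` over the same sessions/fraction/options) skips the
    matcher pass.
    """
    name = stratum_name or (stratum_filter[1] if stratum_filter else "All")
    kept_idx = [i for i, s in enumerate(sessions) if _passes(s, stratum_filter)]
    if not kept_idx:
        raise CorpusError(f"stratum {name!r} is empty")
    kept = [sessions[i] for i in kept_idx]
    y = np.array([s.sr_label for s in kept])
    if len(np.unique(y)) < 2:
        raise CorpusError(
            f"stratum {name!r} has a single outcome class "
            f"(prevalence {float(np.mean(y)):.3f})"
        )
    if precomputed_counts is not None:
        counts = np.asarray(precomputed_counts)[kept_idx]
    else:
        counts = counts_matrix(kept, lexicon, fraction, options)
    return DesignMatrix.from_arrays(
        counts, y, lexicon.category_ids,
        stratum=name, fraction=fraction,
        session_ids=[s.session_id for s in kept],
    )


def export_feature_matrix(design: DesignMatrix,
                          sink: Union[str, Path, TextIO],
                          provenance: str | None = None) -> None:
    """TSV export: session_id, category columns, sr_label, fraction."""
    cats = [c for c in design.column_names if c != INTERCEPT]
    lines = []
    if provenance:
        lines.append(f"# {provenance}")
    lines.append("\t".join(["session_id", *cats, "sr_label", "fraction"]))
    counts = design.X[:, : len(cats)]
    for sid, row, label in zip(design.session_ids, counts, design.y):
        vals = "\t".join(f"{v:g}" for v in row)
        lines.append(f"{sid}\t{vals}\t{label}\t{design.fraction:g}")
    text = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text, encoding="utf-8")
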