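"""Chat-session container, text cleaning, serialization, and prefix slicing.

A session is an ordered list of speaker-tagged messages (help-seeker vs.
counselor) plus self-reported gender, an age group drawn from four
developmental bins (10-17 school age, 18-20 mandatory-service age, 21-40,
41+), and a binary suicide-risk (SR) label.  Sessions travel as JSON Lines,
one session per line.

Prefix slicing implements the five within-chat progress stages (20%, 40%,
60%, 80%, 100%) used by the temporal analysis: the slice at fraction f is the
shortest whole-message prefix whose cumulative help-seeker character count
(after cleaning) reaches f times the session total.  Only help-seeker text
carries risk language downstream; counselor messages ride along for context
but are never matched.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, TextIO, Union

__all__ = [
    "CorpusError",
    "HELP_SEEKER",
    "COUNSELOR",
    "GENDERS",
    "AGE_GROUPS",
    "FRACTIONS",
    "Message",
    "ChatSession",
    "clean_text",
    "help_seeker_text",
    "slice_prefix",
    "read_sessions",
    "write_sessions",
]


class CorpusError(ValueError):
    """Malformed session record or degenerate slicing input."""


HELP_SEEKER = "help_seeker"
COUNSELOR = "counselor"
GENDERS = ("female", "male", "unknown")
AGE_GROUPS = ("10-17", "18-20", "21-40", "41+", "unknown")
#: the five chat-progress stages of the temporal analysis
FRACTIONS = (0.2, 0.4, 0.6, 0.8, 1.0)

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_TAG_RE = re.compile(r"<[^<>]*>")
_CTRL_RE = re.compile("[\u0000-\u0008\u000b-\u001f\u007f-\u009f]")
_WS_RE = re.compile(r"\s+")


def clean_text(raw: str) -> str:
    """Normalize raw chat text for matching.

    Unicode NFKC normalization; URLs, markup tags and control characters
    removed; whitespace runs collapsed to single spaces; trimmed; case-folded.
    Idempotent, and empty input maps to empty output.
    """
    text = unicodedata.normalize("NFKC", raw)
    text = _URL_RE.sub(" ", text)
    text = _TAG_RE.sub(" ", text)
    text = _CTRL_RE.sub(" ", text)
    text = _WS_RE.sub(" ", text).strip()
    return text.casefold()


@dataclass
class Message:
    speaker: str
    text: str
    index: int = 0

    def __post_init__(self) -> None:
        if self.speaker not in (HELP_SEEKER, COUNSELOR):
            raise CorpusError(f"unknown speaker {self.speaker!r}")

    @property
    def char_len(self) -> int:
        """Length of the cleaned text."""
        return len(clean_text(self.text))


@dataclass
class ChatSession:
    session_id: str
    messages: list[Message]
    gender: str = "unknown"
    age_group: str = "unknown"
    sr_label: int = 0

    def __post_init__(self) -> None:
        if not self.messages:
            raise CorpusError(f"session {self.session_id!r} has no messages")
        if self.gender not in GENDERS:
            raise CorpusError(f"session {self.session_id!r}: bad gender {self.gender!r}")
        if self.age_group not in AGE_GROUPS:
            raise CorpusError(
                f"session {self.session_id!r}: bad age_group {self.age_group!r}"
            )
        if self.sr_label not in (0, 1):
            raise CorpusError(f"session {self.session_id!r}: sr_label must be 0 or 1")
        for i, m in enumerate(self.messages):
            m.index = i

    def help_seeker_messages(self) -> list[Message]:
        return [m for m in self.messages if m.speaker == HELP_SEEKER]


def help_seeker_text(session: ChatSession, joiner: str = " . ") -> str:
    """Cleaned help-seeker text, message-joined with a sentence break.

    Matching runs over this concatenation.  Because phrase matching treats
    any punctuation/whitespace run as a token separator, a multi-token
    phrase split across two consecutive help-seeker messages still matches —
    consistent with matching the chat as one utterance stream.
    """
    return joiner.join(clean_text(m.text) for m in session.help_seeker_messages())


def slice_prefix(session: ChatSession, fraction: float,
                 unit: str = "chars") -> ChatSession:
    """Whole-message prefix covering the first *fraction* of help-seeker text.

    ``unit="chars"`` (default) accumulates cleaned help-seeker characters;
    ``unit="messages"`` counts help-seeker messages instead.  The returned
    prefix is the shortest one whose cumulative quantity reaches
    ``fraction * total``; prefixes are nested in ``fraction`` and metadata and
    label are copied unchanged.  ``fraction == 1.0`` returns the session
    intact (including trailing counselor messages).
    """
    if not (0.0 < fraction <= 1.0):
        raise CorpusError(f"fraction must be in (0, 1], got {fraction}")
    if unit not in ("chars", "messages"):
        raise CorpusError(f"unknown slicing unit {unit!r}")
    if fraction == 1.0:
        return replace(session, messages=list(session.messages))

    weights = [
        (m.char_len if unit == "chars" else 1) if m.speaker == HELP_SEEKER else 0
        for m in session.messages
    ]
    total = sum(weights)
    if total == 0:
        raise CorpusError(
            f"session {session.session_id!r} has no help-seeker "
            f"{'characters' if unit == 'chars' else 'messages'}"
        )
    target = fraction * total
    cum = 0.0
    cut = None
    for i, w in enumerate(weights):
        cum += w
        if w > 0 and cum >= target - 1e-9:
            cut = i
            break
    assert cut is not None  # fraction <= 1 guarantees the loop cuts
    prefix = [Message(m.speaker, m.text) for m in session.messages[: cut + 1]]
    return replace(session, messages=prefix)


# ---------------------------------------------------------------------------
# JSON Lines serialization
# ---------------------------------------------------------------------------

def _session_to_record(session: ChatSession) -> dict:
    return {
        "session_id": session.session_id,
        "gender": session.gender,
        "age_group": session.age_group,
        "sr_label": session.sr_label,
        "messages": [{"speaker": m.speaker, "text": m.text} for m in session.messages],
    }


def _session_from_record(rec: dict, lineno: int) -> ChatSession:
    try:
        if "sr_label" not in rec:
            raise CorpusError("missing sr_label")
        msgs = [Message(m["speaker"], m["text"]) for m in rec["messages"]]
        return ChatSession(
            session_id=str(rec["session_id"]),
            messages=msgs,
            gender=rec.get("gender", "unknown"),
            age_group=rec.get("age_group", "unknown"),
            sr_label=int(rec["sr_label"]),
        )
    except (KeyError, TypeError, CorpusError) as exc:
        raise CorpusError(f"line {lineno}: malformed session record ({exc})") from exc


def read_sessions(source: Union[str, Path, TextIO]) -> list[ChatSession]:
    """Read JSON Lines session records; errors carry the offending line number."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text(encoding="utf-8").splitlines()
    sessions = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise CorpusError(f"line {lineno}: invalid JSON ({exc})") from exc
        sessions.append(_session_from_record(rec, lineno))
    return sessions


def write_sessions(sessions: Iterable[ChatSession],
                   sink: Union[str, Path, TextIO]) -> None:
    text = "".join(
        json.dumps(_session_to_record(s), ensure_ascii=False) + "\n"
        for s in sessions
    )
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text, encoding="utf-8")
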