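"""Partial-credit scoring of transcribed responses.

Words are scored at the phoneme level: the number of tokens correct is the
target length minus the Levenshtein edit distance between response and
target, clamped at zero.  Sentences are scored by the number of keywords
present in the response, each response token consumable at most once.
Tokens are opaque strings, so any transcription alphabet works.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TranscriptionPair",
    "TrialRecord",
    "edit_distance",
    "read_transcriptions",
    "score_pair",
    "score_sentence_keywords",
    "score_transcription_file",
    "score_word",
]

MODES = ("phoneme", "keyword")


@dataclass(frozen=True)
class TranscriptionPair:
    """One target/response pair awaiting scoring.

    ``mode`` selects the scoring rule: ``phoneme`` (edit distance on word
    tokens) or ``keyword`` (sentence keyword matching).  The response may be
    empty (no response given).
    """

    trial_id: str
    target_tokens: tuple[str, ...]
    response_tokens: tuple[str, ...]
    mode: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_tokens", tuple(self.target_tokens))
        object.__setattr__(self, "response_tokens", tuple(self.response_tokens))
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}; got {self.mode!r}")
        if len(self.target_tokens) == 0:
            raise ValueError(f"trial {self.trial_id!r}: target_tokens must be non-empty")


@dataclass(frozen=True)
class TrialRecord:
    """One scored stimulus presentation: n_correct tokens out of n_tokens."""

    participant_id: str
    trial_id: str
    n_tokens: int
    n_correct: int

    def __post_init__(self) -> None:
        if self.n_tokens < 1:
            raise ValueError(f"trial {self.trial_id!r}: n_tokens must be >= 1")
        if not 0 <= self.n_correct <= self.n_tokens:
            raise ValueError(
                f"trial {self.trial_id!r}: n_correct={self.n_correct} outside "
                f"0..n_tokens={self.n_tokens}"
            )


def edit_distance(a: Sequence[str], b: Sequence[str]) -> int:
    """Levenshtein distance with unit-cost insertion, deletion, substitution.

    Standard two-row dynamic program; tokens compared by exact equality.
    """
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, tok_a in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, tok_b in enumerate(b, start=1):
            cost = 0 if tok_a == tok_b else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[len(b)]


def score_word(pair: TranscriptionPair, participant_id: str = "") -> TrialRecord:
    """Score a word trial: tokens correct = target length minus the edit
    distance from response to target, to a minimum of zero."""
    if pair.mode != "phoneme":
        raise ValueError(f"trial {pair.trial_id!r}: score_word requires mode='phoneme'")
    n_tokens = len(pair.target_tokens)
    dist = edit_distance(pair.response_tokens, pair.target_tokens)
    return TrialRecord(
        participant_id=participant_id,
        trial_id=pair.trial_id,
        n_tokens=n_tokens,
        n_correct=max(0, n_tokens - dist),
    )


def score_sentence_keywords(pair: TranscriptionPair, participant_id: str = "") -> TrialRecord:
    """Score a sentence trial by keywords present in the response.

    Matching is case-insensitive exact string equality and each response
    token can satisfy at most one keyword (so repeated keywords need repeated
    response tokens).
    """
    if pair.mode != "keyword":
        raise ValueError(
            f"trial {pair.trial_id!r}: score_sentence_keywords requires mode='keyword'"
        )
    target = Counter(t.lower() for t in pair.target_tokens)
    response = Counter(t.lower() for t in pair.response_tokens)
    n_correct = sum(min(count, response[tok]) for tok, count in target.items())
    return TrialRecord(
        participant_id=participant_id,
        trial_id=pair.trial_id,
        n_tokens=len(pair.target_tokens),
        n_correct=n_correct,
    )


def score_pair(pair: TranscriptionPair, participant_id: str = "") -> TrialRecord:
    if pair.mode == "phoneme":
        return score_word(pair, participant_id)
    return score_sentence_keywords(pair, participant_id)


def read_transcriptions(path: str | Path) -> list[tuple[str, TranscriptionPair]]:
    """Read a tab-delimited transcription file.

    Columns: participant_id, trial_id, mode, target_tokens (space-separated),
    response_tokens (space-separated; may be blank).  Returns
    (participant_id, pair) tuples in file order.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["participant_id", "trial_id", "mode", "target_tokens", "response_tokens"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for row in frame.itertuples(index=False):
        pair = TranscriptionPair(
            trial_id=row.trial_id,
            target_tokens=tuple(row.target_tokens.split()),
            response_tokens=tuple(row.response_tokens.split()),
            mode=row.mode,
        )
        out.append((row.participant_id, pair))
    return out


def score_transcription_file(path: str | Path) -> pd.DataFrame:
    """Score a transcription file into a trial table (one row per trial)."""
    records = [score_pair(pair, pid) for pid, pair in read_transcriptions(path)]
    return records_to_frame(records)


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "trial_id": r.trial_id,
                "n_tokens": r.n_tokens,
                "n_correct": r.n_correct,
            }
            for r in records
        ]
    )
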