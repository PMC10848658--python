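"""Synthetic cohorts with the statistical structure the analysis assumes.

Defaults emulate the study design this package targets: 20 participants,
250 three-phoneme word trials each, 36 sentence trials each with variable
keyword counts, per-participant accuracy spanning roughly 0.3-0.9, and a
shared (or per-participant) intraclass correlation.  Ground-truth parameters
travel with every generated table so recovery tests can close the loop.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from bbscore import betabinom
from bbscore.io import write_json

__all__ = [
    "CohortSpec",
    "ParticipantParams",
    "generate_cohort",
    "generate_transcriptions",
    "generate_trials",
    "write_cohort_truth",
]

DEFAULT_ALPHABET = tuple("abdefghijklmnopqrstuvwxzCDEGIJMNORSTUWYZ^@cT")


@dataclass(frozen=True)
class ParticipantParams:
    """True (or estimated) per-participant accuracy and intraclass correlation."""

    participant_id: str
    mu_p: float
    rho_p: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mu_p < 1.0:
            raise ValueError(f"{self.participant_id}: mu_p must lie in (0, 1); got {self.mu_p}")
        if not 0.0 <= self.rho_p < 1.0:
            raise ValueError(f"{self.participant_id}: rho_p must lie in [0, 1); got {self.rho_p}")


@dataclass(frozen=True)
class CohortSpec:
    """Configuration for one synthetic cohort.

    ``mu_values`` (explicit list) overrides ``mu_range`` (uniform draw).
    ``rho_values`` (per-participant list) overrides ``rho`` (shared value).
    """

    n_participants: int = 20
    mu_range: tuple[float, float] = (0.29, 0.92)
    mu_values: tuple[float, ...] | None = None
    rho: float = 0.35
    rho_values: tuple[float, ...] | None = None
    word_trials: int = 250
    phonemes_per_word: int = 3
    sentence_trials: int = 36
    keywords_per_sentence: tuple[int, ...] = (3, 4, 5, 6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError(f"n_participants must be >= 1; got {self.n_participants}")
        if self.mu_values is not None:
            object.__setattr__(self, "mu_values", tuple(float(m) for m in self.mu_values))
            if len(self.mu_values) != self.n_participants:
                raise ValueError("mu_values length must equal n_participants")
        else:
            lo, hi = self.mu_range
            if not (0.0 < lo <= hi < 1.0):
                raise ValueError(f"mu_range must satisfy 0 < lo <= hi < 1; got {self.mu_range}")
        if self.rho_values is not None:
            object.__setattr__(self, "rho_values", tuple(float(r) for r in self.rho_values))
            if len(self.rho_values) != self.n_participants:
                raise ValueError("rho_values length must equal n_participants")
        elif not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1); got {self.rho}")
        if self.word_trials < 0 or self.sentence_trials < 0:
            raise ValueError("trial counts must be nonnegative")
        if self.word_trials + self.sentence_trials == 0:
            raise ValueError("at least one of word_trials / sentence_trials must be positive")
        if self.phonemes_per_word < 1:
            raise ValueError("phonemes_per_word must be >= 1")
        if self.sentence_trials > 0 and len(self.keywords_per_sentence) == 0:
            raise ValueError("keywords_per_sentence must be non-empty")


def generate_cohort(spec: CohortSpec) -> list[ParticipantParams]:
    """Assign (mu_p, rho_p) to each participant, deterministically in the seed."""
    rng = np.random.default_rng([spec.seed, 101])
    if spec.mu_values is not None:
        mus = np.asarray(spec.mu_values, dtype=float)
    else:
        lo, hi = spec.mu_range
        mus = rng.uniform(lo, hi, size=spec.n_participants)
    if spec.rho_values is not None:
        rhos = np.asarray(spec.rho_values, dtype=float)
    else:
        rhos = np.full(spec.n_participants, spec.rho, dtype=float)
    width = len(str(spec.n_participants))
    return [
        ParticipantParams(f"P{i + 1:0{width}d}", float(mus[i]), float(rhos[i]))
        for i in range(spec.n_participants)
    ]


def generate_trials(params: list[ParticipantParams], spec: CohortSpec) -> pd.DataFrame:
    """Draw the trial table (word + sentence trials) for a cohort.

    Word trials score counts out of ``phonemes_per_word``; sentence trials
    out of a keyword count drawn uniformly from ``keywords_per_sentence``
    (shared across participants, as with a fixed stimulus list).
    Columns: participant_id, trial_id, n_tokens, n_correct, stimulus.
    """
    rng = np.random.default_rng([spec.seed, 202])
    sentence_ns = rng.choice(spec.keywords_per_sentence, size=spec.sentence_trials)
    rows: list[dict] = []
    for p in params:
        if spec.word_trials > 0:
            dist = betabinom.BetaBinomialParams(spec.phonemes_per_word, p.mu_p, p.rho_p)
            counts = betabinom.sample(dist, spec.word_trials, rng)
            for t, k in enumerate(counts, start=1):
                rows.append(
                    {
                        "participant_id": p.participant_id,
                        "trial_id": f"word-{t:04d}",
                        "n_tokens": spec.phonemes_per_word,
                        "n_correct": int(k),
                        "stimulus": "word",
                    }
                )
        for t, n_kw in enumerate(sentence_ns, start=1):
            dist = betabinom.BetaBinomialParams(int(n_kw), p.mu_p, p.rho_p)
            k = int(betabinom.sample(dist, 1, rng)[0])
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "trial_id": f"sent-{t:04d}",
                    "n_tokens": int(n_kw),
                    "n_correct": k,
                    "stimulus": "sentence",
                }
            )
    return pd.DataFrame(rows)


def generate_transcriptions(
    trials: pd.DataFrame,
    token_alphabet: tuple[str, ...] = DEFAULT_ALPHABET,
    seed: int = 0,
) -> pd.DataFrame:
    """Fabricate transcription pairs that score back to the given counts.

    Word trials get a random target and a response differing from it by
    exactly ``n_tokens - n_correct`` substitutions whose replacement tokens
    never occur in the target, which pins the edit distance to that
    substitution count.  Sentence trials get unique keywords with
    ``n_correct`` of them echoed in the response amid filler tokens.
    """
    alphabet = tuple(dict.fromkeys(token_alphabet))
    rng = np.random.default_rng(seed)
    rows = []
    for row in trials.itertuples(index=False):
        n, k = int(row.n_tokens), int(row.n_correct)
        stimulus = getattr(row, "stimulus", "word")
        if stimulus == "word":
            if len(alphabet) < n + 1:
                raise ValueError(
                    f"token alphabet too small: need at least n_tokens+1="
                    f"{n + 1} symbols, have {len(alphabet)}"
                )
            target = list(rng.choice(alphabet, size=n, replace=False))
            response = list(target)
            wrong_positions = rng.choice(n, size=n - k, replace=False)
            spare = [tok for tok in alphabet if tok not in target]
            replacements = rng.choice(spare, size=n - k, replace=False)
            for pos, tok in zip(wrong_positions, replacements):
                response[pos] = tok
            mode = "phoneme"
        else:
            if len(alphabet) < 2 * n:
                raise ValueError(
                    f"token alphabet too small for {n} unique keywords plus fillers"
                )
            picks = rng.choice(alphabet, size=2 * n, replace=False)
            target = [f"kw{tok}" for tok in picks[:n]]
            fillers = [f"fx{tok}" for tok in picks[n:]]
            heard = list(rng.choice(n, size=k, replace=False))
            response = [target[i] for i in heard] + fillers[: n - k]
            rng.shuffle(response)
            mode = "keyword"
        rows.append(
            {
                "participant_id": row.participant_id,
                "trial_id": row.trial_id,
                "mode": mode,
                "target_tokens": " ".join(target),
                "response_tokens": " ".join(response),
            }
        )
    return pd.DataFrame(rows)


def write_cohort_truth(
    params: list[ParticipantParams], spec: CohortSpec, path: str | Path
) -> None:
    """Write ground-truth parameters and the generating spec as JSON."""
    write_json(
        {
            "spec": asdict(spec),
            "participants": [asdict(p) for p in params],
        },
        path,
    )
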