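"""Question-effectiveness scoring with harmonic position weights.

Two related metrics quantify how efficiently a sequence of yes/no questions
narrows a pool of N suspects down to the hidden spy:

* **QEM** scores each question by the fraction of the *full* room the player
  actually crossed out after it, ``eliminated_i / N``, and sums these with
  weights ``1/i`` so that early questions dominate:
  ``QEM = sum_i (1/i) * eliminated_i / N``.

* **Effective QEM** ignores the player's crossing-out behaviour and replays
  the question/answer sequence against ground truth: each classified question
  scores ``potential_eliminations_i / remaining_i`` where ``remaining_i`` is
  the number of answer-consistent suspects before the question and
  ``potential_eliminations_i`` is how many of them the answer rules out.
  Questions the classifier cannot label are excluded from the sequence.

Because the replay's consistent set always retains the spy, the effective-QEM
denominator is at least 1 at every step; a question asked after the pool is
already resolved simply scores 0 rather than dividing by zero ("overshooting").
Replays of external logs that claim impossible elimination counts, or whose
answers contradict the spy, are flagged ``clamped`` instead of failing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classifier import ClassifiedQuestion, Lexicon, classify_question
from .errors import (
    NegativeElimination,
    NoClassifiableQuestion,
    RoomMismatch,
)
from .oracle import AnswerLabel
from .room import DEFAULT_ROOM_SIZE, Room, consistent_suspects


@dataclass
class TurnRecord:
    """One question turn: the question, the answer, and elimination counts."""

    index: int
    question: ClassifiedQuestion
    answer: AnswerLabel
    player_eliminations: int = 0
    remaining_before: int = 0
    potential_eliminations: int = 0
    elapsed_s: float | None = None

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "question": self.question.to_dict(),
            "answer": self.answer.name,
            "player_eliminations": self.player_eliminations,
            "remaining_before": self.remaining_before,
            "potential_eliminations": self.potential_eliminations,
            "elapsed_s": self.elapsed_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TurnRecord":
        return cls(
            index=int(d["index"]),
            question=ClassifiedQuestion.from_dict(d["question"]),
            answer=AnswerLabel[d["answer"]],
            player_eliminations=int(d.get("player_eliminations", 0)),
            remaining_before=int(d.get("remaining_before", 0)),
            potential_eliminations=int(d.get("potential_eliminations", 0)),
            elapsed_s=d.get("elapsed_s"),
        )


@dataclass
class Guess:
    suspect_id: int
    correct: bool
    elapsed_s: float | None = None

    def to_dict(self) -> dict:
        return {
            "suspect_id": self.suspect_id,
            "correct": self.correct,
            "elapsed_s": self.elapsed_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Guess":
        return cls(int(d["suspect_id"]), bool(d["correct"]), d.get("elapsed_s"))


@dataclass
class GameTranscript:
    """One full game: ordered turns, guesses, and the outcome."""

    session_id: str
    room_ref: dict
    turns: list[TurnRecord]
    guesses: list[Guess]
    outcome: str  # "WIN" | "LOSS"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.outcome not in ("WIN", "LOSS"):
            raise ValueError(f"outcome must be WIN or LOSS, got {self.outcome!r}")
        if sum(g.correct for g in self.guesses) > 1:
            raise ValueError("at most one correct guess per game")
        if self.guesses:
            won = self.guesses[-1].correct
            if won != (self.outcome == "WIN"):
                raise ValueError("WIN iff the last guess is correct")

    @property
    def won(self) -> bool:
        return self.outcome == "WIN"

    def to_dict(self) -> dict:
        d = {
            "session_id": self.session_id,
            "room_ref": dict(self.room_ref),
            "turns": [t.to_dict() for t in self.turns],
            "guesses": [g.to_dict() for g in self.guesses],
            "outcome": self.outcome,
        }
        d.update(self.extra)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GameTranscript":
        known = {"session_id", "room_ref", "turns", "guesses", "outcome"}
        return cls(
            session_id=str(d["session_id"]),
            room_ref=dict(d["room_ref"]),
            turns=[TurnRecord.from_dict(t) for t in d["turns"]],
            guesses=[Guess.from_dict(g) for g in d["guesses"]],
            outcome=d["outcome"],
            extra={k: v for k, v in d.items() if k not in known},
        )


@dataclass
class ScoreBreakdown:
    """Per-question weighted scores and their harmonic-weighted total."""

    per_question: list[tuple[int, float, float]]  # (i, weight 1/i, score)
    total: float
    excluded_indices: list[int] = field(default_factory=list)
    clamped: bool = False

    @property
    def scores(self) -> list[float]:
        return [s for _, _, s in self.per_question]


def harmonic_weighted_total(scores: list[float]) -> float:
    """``sum_i score_i / i`` with i = 1-based position in the sequence."""
    return sum(s / i for i, s in enumerate(scores, start=1))


def qem(
    transcript: GameTranscript, total_suspects: int = DEFAULT_ROOM_SIZE
) -> ScoreBreakdown:
    """Player-elimination QEM with a fixed denominator of ``total_suspects``.

    Every turn is included — no classification is needed, because the score
    only reflects what the player visually crossed out.
    """
    if total_suspects < 1:
        raise ValueError("total_suspects must be >= 1")
    per_question = []
    total = 0.0
    for i, turn in enumerate(transcript.turns, start=1):
        if turn.player_eliminations < 0:
            raise NegativeElimination(
                f"turn {i} records {turn.player_eliminations} eliminations"
            )
        score = turn.player_eliminations / total_suspects
        weight = 1.0 / i
        per_question.append((i, weight, score))
        total += weight * score
    return ScoreBreakdown(per_question=per_question, total=total)


def effective_qem(
    transcript: GameTranscript,
    room: Room,
    lexicon: Lexicon | None = None,
    keep_original_index: bool = False,
) -> ScoreBreakdown:
    """Ground-truth replay QEM: potential eliminations over suspects left.

    Each question is (re-)classified; unclassified, deflected, and unanswerable
    turns are excluded from the sequence.  For an included question the score
    is ``(|consistent before| - |consistent after|) / |consistent before|``,
    where the consistent set always retains the spy, so the denominator is
    never zero.  By default the harmonic index ``i`` runs over included
    questions only; ``keep_original_index`` keeps each question's original
    transcript position instead.

    With ``lexicon=None`` the labels stored on the transcript are trusted
    as-is (useful for pre-classified or hand-built logs).
    """
    ref_checksum = transcript.room_ref.get("checksum")
    if ref_checksum is not None and ref_checksum != room.checksum():
        raise RoomMismatch(
            f"transcript expects room {ref_checksum}, got {room.checksum()}"
        )

    remaining = {s.suspect_id for s in room.suspects}
    per_question: list[tuple[int, float, float]] = []
    excluded: list[int] = []
    clamped = False
    included_pos = 0

    for original_i, turn in enumerate(transcript.turns, start=1):
        cq = (
            classify_question(turn.question.raw_text, lexicon)
            if lexicon is not None
            else turn.question
        )
        answerable = turn.answer in (AnswerLabel.AFFIRMATIVE, AnswerLabel.NEGATIVE)
        if cq.label is None or not answerable:
            excluded.append(original_i)
            continue
        prop, value = cq.label
        before = len(remaining)
        after_set = consistent_suspects(
            room, [(prop, value, turn.answer)], within=remaining
        )
        if room.spy_id not in after_set:
            # the answer contradicts the spy (noisy/external log): keep the
            # spy so the pool can never empty, and flag the divergence
            after_set.add(room.spy_id)
            clamped = True
        if turn.player_eliminations > before - 1:
            clamped = True
        potential = before - len(after_set)
        score = potential / before
        included_pos += 1
        i_eff = original_i if keep_original_index else included_pos
        per_question.append((i_eff, 1.0 / i_eff, score))
        remaining = after_set

    total = sum(w * s for _, w, s in per_question)
    return ScoreBreakdown(
        per_question=per_question,
        total=total,
        excluded_indices=excluded,
        clamped=clamped,
    )


def first_question_effective_qem(
    transcript: GameTranscript,
    room: Room,
    lexicon: Lexicon | None = None,
) -> float:
    """Unweighted effective-QEM score of the first classifiable question."""
    breakdown = effective_qem(transcript, room, lexicon)
    if not breakdown.per_question:
        raise NoClassifiableQuestion(
            f"transcript {transcript.session_id} has no classifiable question"
        )
    return breakdown.per_question[0][2]
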