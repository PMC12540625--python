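"""Deterministic yes/no answer oracle.

Answers classified questions strictly from the ground-truth attributes of the
spy, using a fixed three-way response contract plus a deflection for questions
addressed to the agent itself ("Are you wearing glasses?").  Unlike a live
chatbot the oracle is never wrong by default; an optional error rate flips
affirmative/negative answers to study the effect of inaccurate feedback.
"""

from __future__ import annotations

import enum
import random
import re
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .classifier import ClassifiedQuestion
    from .room import Room


class AnswerLabel(enum.Enum):
    """The oracle's four possible responses, with canonical surface strings."""

    AFFIRMATIVE = "Affirmative agent"
    NEGATIVE = "Negative agent"
    CANNOT_ANSWER = "I cannot give the answer to that question"
    SELF_DEFLECTION = (
        "I am not the spy, so that's not relevant. "
        "What do you want to know about the spy?"
    )

    @property
    def surface(self) -> str:
        """Canonical string the agent utters for this label."""
        return self.value


_TOKEN_RE = re.compile(r"[a-z]+(?:-[a-z]+)*")

# Nouns that, when immediately following a possessive second-person pronoun,
# indicate the question is still about the target ("Is your spy a woman?").
_TARGET_NOUNS = frozenset(
    {"spy", "target", "suspect", "suspects", "character", "characters",
     "person", "guess", "answer"}
)

_SECOND_PERSON = frozenset({"you", "yourself", "u"})
_POSSESSIVE = frozenset({"your", "yours"})


def tokenize(text: str) -> list[str]:
    """Lowercase, punctuation-stripped whole-word tokens (hyphens kept)."""
    return _TOKEN_RE.findall(text.lower())


def detect_self_reference(text: str) -> bool:
    """True when second-person cues address the agent rather than the spy.

    "Are you wearing glasses?" is self-referential; "Is your spy a woman?"
    is not, because the possessive modifies a target noun.
    """
    tokens = tokenize(text)
    for i, tok in enumerate(tokens):
        if tok in _SECOND_PERSON:
            return True
        if tok in _POSSESSIVE:
            nxt = tokens[i + 1] if i + 1 < len(tokens) else None
            if nxt not in _TARGET_NOUNS:
                return True
    return False


def answer_question(
    cq: "ClassifiedQuestion",
    room: "Room",
    error_rate: float = 0.0,
    rng: random.Random | None = None,
) -> AnswerLabel:
    """Answer a classified question about the room's spy.

    Pure function of ``(cq, room)`` at ``error_rate == 0``: self-referential
    questions are deflected, unclassified ones receive the cannot-answer
    response, and classified ones are answered truthfully against the spy's
    attributes.  With ``error_rate > 0`` a seeded ``rng`` must be supplied;
    affirmative/negative answers are then flipped with that probability.
    """
    if cq.self_referential:
        return AnswerLabel.SELF_DEFLECTION
    if cq.label is None:
        return AnswerLabel.CANNOT_ANSWER
    prop, value = cq.label
    spy = room.spy()
    truthful = (
        AnswerLabel.AFFIRMATIVE
        if spy.attributes.get(prop) == value
        else AnswerLabel.NEGATIVE
    )
    if error_rate > 0.0:
        if rng is None:
            raise ValueError("error_rate > 0 requires a seeded rng")
        if rng.random() < error_rate:
            return (
                AnswerLabel.NEGATIVE
                if truthful is AnswerLabel.AFFIRMATIVE
                else AnswerLabel.AFFIRMATIVE
            )
    return truthful
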