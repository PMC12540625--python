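"""Harmonic-weighted question-effectiveness scoring."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import make_custom_room, make_transcript, make_turn, worked_example
from spyquest import (
    AnswerLabel,
    GameTranscript,
    Guess,
    effective_qem,
    first_question_effective_qem,
    harmonic_weighted_total,
    qem,
)
from spyquest.errors import (
    NegativeElimination,
    NoClassifiableQuestion,
    RoomMismatch,
)


class TestQem:
    def test_zero_eliminations_score_zero(self):
        turns = [
            make_turn(i, ("p1", "a"), AnswerLabel.NEGATIVE, player_elims=0)
            for i in range(1, 4)
        ]
        assert qem(make_transcript(turns), total_suspects=50).total == 0.0

    def test_worked_three_question_sequence(self):
        _, transcript, expected, _ = worked_example()
        breakdown = qem(transcript, total_suspects=50)
        assert breakdown.total == pytest.approx(expected, abs=1e-12)
        assert breakdown.total == pytest.approx(0.66, abs=1e-12)

    def test_single_near_total_elimination(self):
        turns = [make_turn(1, ("p1", "a"), AnswerLabel.AFFIRMATIVE, player_elims=49)]
        breakdown = qem(make_transcript(turns), total_suspects=50)
        assert breakdown.per_question[0][2] == pytest.approx(0.98, abs=1e-12)

    def test_denominator_is_fixed_not_shrinking(self):
        turns = [
            make_turn(1, ("p1", "a"), AnswerLabel.AFFIRMATIVE, player_elims=10),
            make_turn(2, ("p2", "x"), AnswerLabel.NEGATIVE, player_elims=10),
        ]
        breakdown = qem(make_transcript(turns), total_suspects=50)
        assert breakdown.scores == [0.2, 0.2]

    def test_negative_elimination_raises(self):
        turns = [make_turn(1, ("p1", "a"), AnswerLabel.NEGATIVE, player_elims=-1)]
        with pytest.raises(NegativeElimination):
            qem(make_transcript(turns))


class TestEffectiveQem:
    def test_worked_three_question_sequence(self):
        room, transcript, _, expected = worked_example()
        breakdown = effective_qem(transcript, room)
        assert breakdown.total == pytest.approx(expected, abs=1e-12)
        assert breakdown.total == pytest.approx(0.8938, abs=5e-5)
        assert [p for _, _, p in breakdown.per_question] == pytest.approx(
            [25 / 50, 12 / 25, 6 / 13]
        )
        assert breakdown.excluded_indices == []
        assert not breakdown.clamped

    def test_all_unclassified_questions_are_excluded(self):
        room, _, _, _ = worked_example()
        turns = [
            make_turn(i, None, AnswerLabel.CANNOT_ANSWER) for i in range(1, 4)
        ]
        breakdown = effective_qem(make_transcript(turns, room=room), room)
        assert breakdown.total == 0.0
        assert breakdown.excluded_indices == [1, 2, 3]
        assert breakdown.per_question == []

    def test_excluded_questions_do_not_consume_weight_slots(self):
        room, _, _, _ = worked_example()
        turns = [
            make_turn(1, None, AnswerLabel.CANNOT_ANSWER),
            make_turn(2, ("p1", "a"), AnswerLabel.AFFIRMATIVE),
        ]
        t = make_transcript(turns, room=room)
        shifted = effective_qem(t, room)
        assert shifted.per_question == [(1, 1.0, 0.5)]
        original = effective_qem(t, room, keep_original_index=True)
        assert original.per_question == [(2, 0.5, 0.5)]

    def test_cannot_answer_and_deflection_turns_are_excluded(self):
        room, transcript, _, _ = worked_example()
        turns = [
            transcript.turns[0],
            make_turn(2, ("p2", "x"), AnswerLabel.SELF_DEFLECTION),
            make_turn(3, ("p2", "x"), AnswerLabel.NEGATIVE),
        ]
        breakdown = effective_qem(make_transcript(turns, room=room), room)
        assert breakdown.excluded_indices == [2]
        assert len(breakdown.per_question) == 2

    def test_room_checksum_mismatch_raises(self):
        room, transcript, _, _ = worked_example()
        other = make_custom_room({"p1": ["a", "b"] * 25}, spy_id=1)
        with pytest.raises(RoomMismatch):
            effective_qem(transcript, other)

    def test_contradictory_answer_is_clamped_not_crashed(self):
        """An answer that would eliminate the spy keeps the spy and flags it."""
        room, _, _, _ = worked_example()
        # the spy holds p1=a, so a NEGATIVE answer about (p1, a) contradicts it
        turns = [
            make_turn(1, ("p1", "a"), AnswerLabel.NEGATIVE),
            make_turn(2, ("p2", "x"), AnswerLabel.NEGATIVE),
        ]
        breakdown = effective_qem(make_transcript(turns, room=room), room)
        assert breakdown.clamped
        assert all(0.0 <= s <= 1.0 for s in breakdown.scores)

    def test_overclaimed_player_eliminations_set_clamped(self):
        room, transcript, _, _ = worked_example()
        transcript.turns[1].player_eliminations = 49
        assert effective_qem(transcript, room).clamped

    def test_qem_equals_effective_qem_when_tracking_is_exact(self):
        """With faithful crossing-out and no further ground-truth movement the
        player metric and the replay metric coincide."""
        room, _, _, _ = worked_example()
        turns = [
            make_turn(1, ("p1", "a"), AnswerLabel.AFFIRMATIVE, player_elims=25),
            # the remaining 25 all share p1=a; re-asking related splits that
            # eliminate nobody keeps both metrics aligned
            make_turn(2, ("p1", "b"), AnswerLabel.NEGATIVE, player_elims=0),
        ]
        t = make_transcript(turns, room=room)
        assert qem(t, total_suspects=50).total == effective_qem(t, room).total


class TestFirstQuestion:
    def test_even_split_scores_half(self):
        room, transcript, _, _ = worked_example()
        assert first_question_effective_qem(transcript, room) == 0.5

    def test_exclusion_shifts_to_next_classifiable_question(self):
        p = ["w"] * 10 + ["z"] * 40
        room = make_custom_room({"g": p}, spy_id=20)
        turns = [
            make_turn(1, None, AnswerLabel.CANNOT_ANSWER),
            make_turn(2, ("g", "w"), AnswerLabel.NEGATIVE),
        ]
        t = make_transcript(turns, room=room)
        assert first_question_effective_qem(t, room) == pytest.approx(0.2)

    def test_value_held_only_by_spy_affirmative_scores_098(self):
        u = ["s"] + ["o"] * 49
        room = make_custom_room({"u": u}, spy_id=0)
        turns = [make_turn(1, ("u", "s"), AnswerLabel.AFFIRMATIVE)]
        t = make_transcript(turns, room=room)
        assert first_question_effective_qem(t, room) == pytest.approx(49 / 50)

    def test_no_classifiable_question_raises(self):
        room, _, _, _ = worked_example()
        t = make_transcript([make_turn(1, None, AnswerLabel.CANNOT_ANSWER)],
                            room=room)
        with pytest.raises(NoClassifiableQuestion):
            first_question_effective_qem(t, room)


class TestHarmonicWeighting:
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12)
    )
    @settings(max_examples=200, derandomize=True)
    def test_total_bounded_by_harmonic_number(self, scores):
        n = len(scores)
        h_n = sum(1.0 / i for i in range(1, n + 1))
        assert 0.0 <= harmonic_weighted_total(scores) <= h_n + 1e-9

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=10),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=300, derandomize=True)
    def test_descending_order_maximizes_weighted_total(self, scores, perm_seed):
        best = harmonic_weighted_total(sorted(scores, reverse=True))
        shuffled = list(scores)
        random.Random(perm_seed).shuffle(shuffled)
        assert harmonic_weighted_total(shuffled) <= best + 1e-12


def test_transcript_outcome_must_match_last_guess():
    with pytest.raises(ValueError):
        GameTranscript(
            session_id="bad",
            room_ref={},
            turns=[],
            guesses=[Guess(0, correct=True)],
            outcome="LOSS",
        )


def test_at_most_one_correct_guess():
    with pytest.raises(ValueError):
        GameTranscript(
            session_id="bad",
            room_ref={},
            turns=[],
            guesses=[Guess(0, True), Guess(1, True)],
            outcome="WIN",
        )
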