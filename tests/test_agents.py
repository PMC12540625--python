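"""Simulated player policies and the game loop."""

import math
import random

import pytest

from helpers import make_custom_room
from spyquest import (
    GameConfig,
    PolicyConfig,
    default_schema,
    effective_qem,
    generate_room,
    propose_question,
    run_batch,
    run_game,
)
from spyquest.errors import NoInformativeQuestion


def suspects_of(room, ids=None):
    if ids is None:
        return list(room.suspects)
    return [s for s in room.suspects if s.suspect_id in ids]


class TestProposeQuestion:
    def test_constraint_seeker_prefers_the_even_split(self):
        # gender splits 2/2; the other property splits 3/1
        room = make_custom_room(
            {"gender": ["male", "male", "female", "female"],
             "hair": ["short", "short", "short", "long"]}
        )
        pair = propose_question(
            PolicyConfig(name="constraint_seeking"),
            suspects_of(room),
            room.schema,
            random.Random(0),
        )
        assert pair == ("gender", "male")

    def test_hypothesis_scanner_prefers_the_rarest_value(self):
        room = make_custom_room(
            {"gender": ["male", "male", "female", "female"],
             "face": ["plain", "plain", "plain", "scar"]}
        )
        pair = propose_question(
            PolicyConfig(name="hypothesis_scanning"),
            suspects_of(room),
            room.schema,
            random.Random(0),
        )
        assert pair == ("face", "scar")

    def test_two_suspects_get_an_isolating_question(self):
        room = make_custom_room({"gender": ["male", "female"]})
        for name in ("constraint_seeking", "hypothesis_scanning"):
            pair = propose_question(
                PolicyConfig(name=name),
                suspects_of(room),
                room.schema,
                random.Random(0),
            )
            prop, value = pair
            holders = [
                s for s in room.suspects if s.attributes[prop] == value
            ]
            assert len(holders) == 1

    def test_no_informative_question_raises(self):
        room = make_custom_room({"gender": ["male", "female"]})
        asked = set(room.schema.all_pairs())
        with pytest.raises(NoInformativeQuestion):
            propose_question(
                PolicyConfig(name="constraint_seeking"),
                suspects_of(room),
                room.schema,
                random.Random(0),
                asked=asked,
            )

    def test_random_policy_never_repeats_a_question(self, schema, room50):
        rng = random.Random(5)
        asked = set()
        for _ in range(len(schema.all_pairs())):
            pair = propose_question(
                PolicyConfig(name="random"), list(room50.suspects), schema,
                rng, asked=asked,
            )
            assert pair not in asked
            asked.add(pair)


class TestRunGame:
    def test_noiseless_constraint_seeking_always_wins_in_one_guess(self, schema):
        for seed in range(25):
            room = generate_room(schema, 50, seed=seed)
            t = run_game(room, PolicyConfig(name="constraint_seeking"), seed=seed)
            assert t.outcome == "WIN"
            assert len(t.guesses) == 1 and t.guesses[0].correct
            trace = [turn.remaining_before for turn in t.turns]
            assert trace == sorted(trace, reverse=True)
            assert len(set(trace)) == len(trace)  # strictly decreasing

    def test_same_seed_reproduces_the_transcript(self, room50):
        pol = PolicyConfig(name="random", lapse_rate=0.1)
        t1 = run_game(room50, pol, seed=9)
        t2 = run_game(room50, pol, seed=9)
        assert t1.to_dict() == t2.to_dict()

    def test_noncompliant_player_has_zero_recorded_but_positive_effective(
        self, room50
    ):
        pol = PolicyConfig(name="constraint_seeking", elimination_compliance=0.0,
                           guess_threshold=3)
        t = run_game(room50, pol, seed=3)
        assert all(turn.player_eliminations == 0 for turn in t.turns)
        assert effective_qem(t, room50).total > 0

    def test_emitted_questions_classify_back_to_their_pair(self, room50, lexicon):
        t = run_game(room50, PolicyConfig(name="random"), seed=11, lexicon=lexicon)
        assert t.turns
        for turn in t.turns:
            assert turn.question.label is not None

    def test_spy_is_never_ground_truth_eliminated(self, schema):
        for seed in range(25):
            room = generate_room(schema, 50, seed=seed)
            pol = PolicyConfig(name="noisy_human", lapse_rate=0.3,
                               elimination_compliance=0.5, guess_threshold=2,
                               premature_guess_rate=0.1)
            t = run_game(room, pol, seed=seed)
            for turn in t.turns:
                assert turn.remaining_before >= 1
                assert turn.potential_eliminations <= turn.remaining_before - 1

    def test_overshoot_questions_after_isolation_score_zero(self, schema):
        room = generate_room(schema, 50, seed=4)
        pol = PolicyConfig(name="constraint_seeking", overshoot_questions=3)
        t = run_game(room, pol, seed=4)
        tail = [turn for turn in t.turns if turn.remaining_before == 1]
        assert len(tail) == 3
        assert all(turn.potential_eliminations == 0 for turn in tail)
        breakdown = effective_qem(t, room)
        assert all(0.0 <= s <= 1.0 for s in breakdown.scores)

    def test_constraint_seeking_tracks_the_binary_split_bound(self, schema):
        """Noiseless mean questions-to-win sits between log2(N) and the
        exhaustive worst case of the same greedy splitter over all spies."""
        policy = PolicyConfig(name="constraint_seeking")
        means = []
        worsts = []
        for seed in range(30):
            room = generate_room(schema, 50, seed=seed)
            t = run_game(room, policy, seed=seed)
            means.append(len(t.turns))
            worst = 0
            for alt_spy in range(0, 50, 7):  # exhaustive-in-kind spy sweep
                alt = generate_room(schema, 50, seed=seed)
                alt.spy_id = alt_spy
                worst = max(worst, len(run_game(alt, policy, seed=seed).turns))
            worsts.append(worst)
        mean_q = sum(means) / len(means)
        assert math.log2(50) <= mean_q <= sum(worsts) / len(worsts)


class TestRunBatch:
    def test_batch_seeds_are_distinct_and_sized(self, schema):
        batch = run_batch(20, schema=schema, master_seed=7)
        assert len(batch.transcripts) == 20
        assert len(set(batch.seeds)) == 20

    def test_single_game_batch_matches_run_game_with_derived_seed(self, schema):
        batch = run_batch(1, schema=schema, master_seed=13)
        s = batch.seeds[0]
        room = generate_room(schema, 50, seed=s)
        direct = run_game(
            room,
            PolicyConfig(),
            GameConfig(),
            seed=(s ^ 0x5BD1E995) & 0x7FFFFFFF,
            session_id="batch13-0",
        )
        assert batch.transcripts[0].to_dict() == direct.to_dict()

    def test_packaged_noisy_preset_lands_in_the_engagement_band(self):
        from spyquest import noisy_human_preset

        batch = run_batch(200, policy=noisy_human_preset(), master_seed=23)
        win_rate = sum(t.won for t in batch.transcripts) / 200
        assert 0.60 <= win_rate <= 0.80
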