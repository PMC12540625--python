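"""Shared test helpers: hand-constructed rooms, transcripts, and oracles."""

from spyquest import (
    AnswerLabel,
    AttributeSchema,
    ClassifiedQuestion,
    GameTranscript,
    Guess,
    PropertySpec,
    Room,
    Suspect,
    TurnRecord,
)


def make_custom_room(columns: dict[str, list[str]], spy_id: int = 0) -> Room:
    """Build a room directly from per-suspect value columns.

    A synthetic ``tag`` property is appended to guarantee pairwise
    distinctness, so the stated columns can repeat freely.
    """
    n = len(next(iter(columns.values())))
    assert all(len(v) == n for v in columns.values())
    columns = dict(columns)
    columns["tag"] = [f"t{i}" for i in range(n)]
    props = []
    for name, values in columns.items():
        domain = tuple(dict.fromkeys(values))
        if len(domain) < 2:
            domain = domain + ("_pad",)
        props.append(PropertySpec(name=name, domain=domain))
    schema = AttributeSchema(properties=tuple(props))
    suspects = [
        Suspect(suspect_id=i, attributes={name: columns[name][i] for name in columns})
        for i in range(n)
    ]
    return Room(schema=schema, suspects=suspects, spy_id=spy_id, seed=0)


def make_turn(i, label, answer, player_elims=0, raw_text=None):
    return TurnRecord(
        index=i,
        question=ClassifiedQuestion(
            raw_text=raw_text or (f"Is the spy's {label[0]} {label[1]}?" if label
                                  else "Is the spy happy?"),
            label=label,
        ),
        answer=answer,
        player_eliminations=player_elims,
    )


def make_transcript(turns, room=None, outcome="WIN", session_id="fixture"):
    room_ref = {"checksum": room.checksum()} if room is not None else {}
    guesses = [Guess(suspect_id=room.spy_id if room else 0,
                     correct=(outcome == "WIN"))]
    return GameTranscript(
        session_id=session_id,
        room_ref=room_ref,
        turns=turns,
        guesses=guesses,
        outcome=outcome,
    )


def worked_example():
    """A 50-suspect room and 3-question transcript with elimination pattern
    25-of-50, 12-of-25, 6-of-13 — the engine's reference scoring fixture.

    Returns (room, transcript, expected_qem, expected_effective_qem).
    """
    p1 = ["a"] * 25 + ["b"] * 25
    p2 = ["y"] * 13 + ["x"] * 12 + ["x"] * 25
    p3 = ["v"] * 7 + ["u"] * 6 + ["u"] * 37
    room = make_custom_room({"p1": p1, "p2": p2, "p3": p3}, spy_id=0)
    turns = [
        make_turn(1, ("p1", "a"), AnswerLabel.AFFIRMATIVE, player_elims=25),
        make_turn(2, ("p2", "x"), AnswerLabel.NEGATIVE, player_elims=12),
        make_turn(3, ("p3", "u"), AnswerLabel.NEGATIVE, player_elims=6),
    ]
    transcript = make_transcript(turns, room=room)
    expected_qem = 25 / 50 + (1 / 2) * (12 / 50) + (1 / 3) * (6 / 50)
    expected_eqem = 25 / 50 + (1 / 2) * (12 / 25) + (1 / 3) * (6 / 13)
    return room, transcript, expected_qem, expected_eqem


def brute_force_consistent(room, constraints):
    """Independent per-suspect predicate check over the whole room."""
    result = set()
    for s in room.suspects:
        ok = True
        for prop, value, answer in constraints:
            has = s.attributes[prop] == value
            if answer is AnswerLabel.AFFIRMATIVE and not has:
                ok = False
                break
            if answer is AnswerLabel.NEGATIVE and has:
                ok = False
                break
        if ok:
            result.add(s.suspect_id)
    return result
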