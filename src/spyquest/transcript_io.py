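"""Reading, writing, and summarising game transcripts.

Transcripts are stored as JSON Lines with a schema-versioned header line, so
they can be streamed and appended safely; session summaries are flat CSV
tables, one row per game, ready for any downstream statistics tool.  External
logs that fail validation raise with their line number rather than being
silently dropped, and sessions that would be excluded from analysis (no
questions asked, nothing classifiable) are flagged in an ``excluded_reason``
column rather than removed.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classifier import Lexicon
from .errors import (
    MalformedRecord,
    NoClassifiableQuestion,
    SchemaVersionMismatch,
    SpyquestError,
)
from .room import Room
from .scoring import (
    GameTranscript,
    effective_qem,
    first_question_effective_qem,
    qem,
)

FORMAT_NAME = "spyquest-transcripts"
FORMAT_VERSION = 1

SESSION_COLUMNS = [
    "session_id",
    "won",
    "n_questions",
    "n_guesses",
    "n_player_eliminated",
    "qem",
    "effective_qem",
    "first_q_eqem",
    "mean_question_time_s",
    "n_excluded_questions",
    "excluded_reason",
]

_REQUIRED_KEYS = ("session_id", "room_ref", "turns", "guesses", "outcome")


def write_transcripts(
    transcripts: Iterable[GameTranscript], path: str | Path
) -> None:
    """Write transcripts as JSONL under a versioned header line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(json.dumps({"format": FORMAT_NAME, "version": FORMAT_VERSION}))
        fh.write("\n")
        for t in transcripts:
            fh.write(json.dumps(t.to_dict()))
            fh.write("\n")


def read_transcripts(path: str | Path) -> list[GameTranscript]:
    """Read a JSONL transcript file written by :func:`write_transcripts`."""
    path = Path(path)
    transcripts = []
    with path.open() as fh:
        header_line = fh.readline()
        try:
            header = json.loads(header_line)
        except json.JSONDecodeError as exc:
            raise MalformedRecord(f"unreadable header: {exc}", line=1)
        if header.get("format") != FORMAT_NAME:
            raise SchemaVersionMismatch(f"not a {FORMAT_NAME} file")
        if header.get("version") != FORMAT_VERSION:
            raise SchemaVersionMismatch(
                f"unsupported version {header.get('version')!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise MalformedRecord(str(exc), line=lineno)
            missing = [k for k in _REQUIRED_KEYS if k not in record]
            if missing:
                raise MalformedRecord(
                    f"missing required fields {missing}", line=lineno
                )
            try:
                transcripts.append(GameTranscript.from_dict(record))
            except (KeyError, TypeError, ValueError) as exc:
                raise MalformedRecord(f"invalid record: {exc}", line=lineno)
    return transcripts


def write_rooms(rooms: Iterable[Room], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([r.to_dict() for r in rooms], indent=None) + "\n"
    )


def read_rooms(path: str | Path) -> list[Room]:
    return [Room.from_dict(d) for d in json.loads(Path(path).read_text())]


def build_room_index(rooms: Iterable[Room]) -> dict[str, Room]:
    """Index rooms by checksum for transcript resolution."""
    return {r.checksum(): r for r in rooms}


def summarize_sessions(
    transcripts: Sequence[GameTranscript],
    rooms: dict[str, Room] | Sequence[Room],
    lexicon: Lexicon | None = None,
) -> tuple[pd.DataFrame, dict]:
    """One summary row per game plus an aggregate block.

    Rows with scoring errors are flagged in ``excluded_reason``, never
    dropped.  Aggregates are recomputed from the table's own columns, so
    re-reading the written CSV reproduces them bit-for-bit.
    """
    index = rooms if isinstance(rooms, dict) else build_room_index(rooms)
    records = []
    for t in transcripts:
        row: dict = {c: None for c in SESSION_COLUMNS}
        row["session_id"] = t.session_id
        row["won"] = t.won
        row["n_questions"] = len(t.turns)
        row["n_guesses"] = len(t.guesses)
        row["n_player_eliminated"] = sum(x.player_eliminations for x in t.turns)
        times = [x.elapsed_s for x in t.turns if x.elapsed_s is not None]
        row["mean_question_time_s"] = (
            float(np.mean(times)) if times else math.nan
        )
        row["excluded_reason"] = ""
        if not t.turns:
            row["excluded_reason"] = "no_questions"
        room = index.get(t.room_ref.get("checksum"))
        try:
            if room is None:
                raise SpyquestError("room not resolvable")
            row["qem"] = qem(t, total_suspects=room.size).total
            eq = effective_qem(t, room, lexicon)
            row["effective_qem"] = eq.total
            row["n_excluded_questions"] = len(eq.excluded_indices)
            try:
                row["first_q_eqem"] = first_question_effective_qem(t, room, lexicon)
            except NoClassifiableQuestion:
                row["first_q_eqem"] = math.nan
                if not row["excluded_reason"]:
                    row["excluded_reason"] = "no_classifiable_questions"
        except SpyquestError as exc:
            row["excluded_reason"] = f"scoring_error: {exc}"
        records.append(row)
    table = pd.DataFrame(records, columns=SESSION_COLUMNS)
    return table, aggregate_sessions(table)


def aggregate_sessions(table: pd.DataFrame) -> dict:
    """Aggregate block over a session table (win rate, question/guess stats).

    The elimination histogram uses fixed bins 0–9, 10–19, 20–29, 30–39, 40+.
    Undefined aggregates (empty table, no winners) are reported as None.
    """
    if len(table) == 0:
        return {
            "n_sessions": 0,
            "win_rate": None,
            "mean_questions": None,
            "sd_questions": None,
            "mean_guesses_winners": None,
            "sd_guesses_winners": None,
            "elimination_histogram": None,
        }
    winners = table[table["won"].astype(bool)]
    counts, _ = np.histogram(
        table["n_player_eliminated"].astype(float),
        bins=[0, 10, 20, 30, 40, np.inf],
    )
    return {
        "n_sessions": int(len(table)),
        "win_rate": float(table["won"].astype(bool).mean()),
        "mean_questions": float(table["n_questions"].mean()),
        "sd_questions": float(table["n_questions"].std(ddof=1))
        if len(table) > 1
        else None,
        "mean_guesses_winners": float(winners["n_guesses"].mean())
        if len(winners)
        else None,
        "sd_guesses_winners": float(winners["n_guesses"].std(ddof=1))
        if len(winners) > 1
        else None,
        "elimination_histogram": {
            "bins": ["0-9", "10-19", "20-29", "30-39", "40+"],
            "counts": [int(c) for c in counts],
        },
    }


def write_session_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, columns=SESSION_COLUMNS)


def read_session_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    df["excluded_reason"] = df["excluded_reason"].fillna("")
    return df
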