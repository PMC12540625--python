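# spyquest

A deterministic, seedable engine for studying **question-asking strategies**
in a hidden-object search game. A room holds 50 visually distinct suspects;
one is secretly a spy. A player asks yes/no questions about the spy's visible
attributes ("Does the spy have grey hair?"), visually crosses out suspects
ruled out by each answer, and may make up to 5 guesses. The engine replaces
every human-facing component with a controlled counterpart — a ground-truth
answer oracle instead of a chatbot, simulated player policies instead of
participants — so that questioning strategies can be generated, scored, and
analysed entirely in code, with no human subjects and no language model.

It is aimed at researchers in cognitive and behavioural science who study
information search (20-questions-style games, constraint-seeking vs.
hypothesis-scanning strategies) and want a reproducible test bed, plus a
validated scoring pipeline for real game transcripts in the same format.

## The measures

For a game of `N` suspects and questions `q_1 … q_n`, the
**question-effectiveness measure (QEM)** scores each question by the fraction
of the full room the player crossed out after it, and aggregates with
harmonic position weights so early questions dominate:

```
QEM(q_i) = (suspects eliminated after q_i) / N
QEM      = Σ_{i=1..n} (1/i) · QEM(q_i)
```

The **effective QEM** ignores the player's crossing-out behaviour and replays
the question/answer sequence against ground truth. Each free-text question is
mapped to a `(property, value)` label by keyword pattern matching (with
property–colour pairs, so "grey" + "hair" → hair colour); unclassifiable
questions are excluded from the sequence. For each included question,

```
effective_QEM(q_i) = (potential suspects eliminated) / (suspects left before q_i)
effective_QEM      = Σ_{i=1..n} (1/i) · effective_QEM(q_i)
```

The replay's consistent set always retains the spy, so the denominator is at
least 1 at every step: questions asked after the pool is already resolved
("overshooting") score 0 instead of dividing by zero.

The simulator provides four policies — `random`, `hypothesis_scanning`
(probe the rarest value), `constraint_seeking` (probe the value splitting the
remaining pool closest to 50/50), and `noisy_human` (constraint seeking with
lapses, imperfect crossing-out, and early guesses) — and the analysis module
reproduces the outcome-prediction pipeline: SMOTE class rebalancing followed
by logistic regression of win/loss on the number of suspects eliminated.

## Worked example

```python
import spyquest as sq

schema = sq.default_schema()                       # 6 properties, 1,800 combos
room = sq.generate_room(schema, size=50, seed=1)   # 50 distinct suspects + spy
lexicon = sq.build_default_lexicon(schema)

transcript = sq.run_game(room, sq.PolicyConfig(name="constraint_seeking"), seed=1)
for turn in transcript.turns:
    print(f"  Q{turn.index}: {turn.question.raw_text!r} -> {turn.answer.surface}"
          f" ({turn.potential_eliminations} of {turn.remaining_before} eliminated)")

print("QEM:          ", round(sq.qem(transcript, total_suspects=50).total, 4))
print("effective QEM:", round(sq.effective_qem(transcript, room, lexicon).total, 4))
```

prints

```
  Q1: 'Is the spy a man?' -> Affirmative agent (25 of 50 eliminated)
  Q2: 'Is the spy bald?' -> Negative agent (12 of 25 eliminated)
  Q3: 'Does the spy have short hair?' -> Affirmative agent (7 of 13 eliminated)
  Q4: 'Is the spy wearing a shirt?' -> Affirmative agent (3 of 6 eliminated)
  Q5: 'Does the spy have grey hair?' -> Affirmative agent (1 of 3 eliminated)
  Q6: "Is the spy's face unadorned?" -> Negative agent (1 of 2 eliminated)
QEM:           0.689
effective QEM: 1.1945
```

The constraint-seeking player halves the pool with its first question
(effective score 25/50 = 0.5), isolates the spy in six questions — close to
the log2(50) ≈ 5.6 binary-split bound — and wins on its single guess. The
effective QEM of 1.19 is the harmonic-weighted sum of the six per-question
elimination fractions; the plain QEM is lower (0.689) because its
denominator stays fixed at 50 while the pool shrinks.

The same operations are available from the shell:

```bash
spyquest simulate --policy noisy_human --games 500 --seed 7 \
    --out games.jsonl --rooms-out rooms.json
spyquest summarize --transcripts games.jsonl --rooms rooms.json --out sessions.csv
spyquest analyze --sessions sessions.csv --features n_player_eliminated \
    --seed 3 --out report.json
```

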