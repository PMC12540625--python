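# Methods

## The game model

A game world ("room") is a set of `N` suspects, each a total assignment over
an ordered attribute schema, pairwise distinct, with one suspect uniformly
chosen as the spy. The packaged schema has six properties — gender (2),
hair length (3), hair colour (5), face accessory (3), clothing type (4),
clothing colour (5) — for 1,800 possible characters. The full 50-character
attribute table of the original game is not public, so this schema is a
reconstruction chosen to span every property and value the game's question
taxonomy names while leaving the product space comfortably larger than the
default room size of 50. Suspects are sampled without replacement from the
enumerated product space with a single seeded stream (suspects first, spy
last), so a `(schema, size, seed)` triple is a complete, bit-reproducible
description of a world. Screen coordinates are carried as optional metadata
and never influence scoring.

The answer oracle is a pure function of the classified question and the
room: questions addressed to the agent itself ("Are you wearing glasses?")
are deflected; unclassifiable questions receive the cannot-answer response;
everything else is answered truthfully against the spy's attributes, using
the fixed surface strings "Affirmative agent" / "Negative agent". An
optional error rate ε (default 0, seeded) flips affirmative/negative answers
to study the effect of an unreliable answerer. This is the one deliberate
departure from a live-chatbot setup: determinism here is what makes the
replay metrics exact.

## Question classification

Classification is whole-word, case-insensitive keyword matching on
punctuation-stripped tokens, with no stemming — "scarf" does not match
"scar". Colour words are ambiguous on their own (black hair vs. a black
jacket), so they resolve only through property–colour pairs: a colour
keyword co-occurring with a property cue ("hair", "wearing", "clothes", …)
maps to the corresponding colour-bearing property, and a firing pair takes
precedence over any single-keyword match. Remaining cases: exactly one
distinct non-colour target → that label; two or more distinct targets
(conjunctive questions), a bare colour with no cue, or no keyword at all →
UNCLASSIFIED, which is a value, not an error. Negated phrasings ("not
wearing glasses") classify by their keywords as if positive by default,
since a single-label scheme cannot represent negation; a `strict_negation`
flag routes them to UNCLASSIFIED instead.

The lexicon also stores one canonical question text per `(property, value)`
pair. The simulator renders questions from these templates, which guarantees
the classifier round-trips every emitted question back to its generating
pair — the property the whole replay pipeline rests on.

## Scoring

Both metrics weight question positions by `1/i`, giving the opening
questions the most influence; the total over `n` questions is bounded by the
harmonic number `H_n`, and for a fixed multiset of per-question scores the
descending arrangement maximises the total (verified as a property test).

QEM divides each question's *recorded* eliminations by the fixed room size.
Effective QEM replays the transcript against ground truth: classify, filter
the answer-consistent set, score the shrinkage fraction. Two design points
deserve note:

* **Overshooting.** If the denominator counted only non-spy candidates it
  would reach zero once the pool is resolved, making scores undefined for
  players who keep asking. Here the consistent set always retains the spy,
  so the denominator is ≥ 1 by construction and post-isolation questions
  score exactly 0. Replayed external logs whose answers contradict the spy
  (possible with a noisy answerer), or that claim more eliminations than
  arithmetically possible, set a `clamped` audit flag rather than raising.
* **Index shifting.** Excluded (unclassifiable) questions do not consume a
  `1/i` slot by default; `keep_original_index=True` preserves the original
  transcript positions instead. Both readings are defensible; the default
  matches treating exclusion as removal from the sequence.

Turns answered with the cannot-answer or deflection response carry no
`(property, value)` and are excluded from effective QEM; in plain QEM they
are included (their recorded eliminations are whatever the player did, which
for a compliant player is 0). Guesses never consume question indices. In
QEM the eliminations occurring between question *i* and the next question
(or game end) are attributed to question *i*.

The reference fixture used in tests is a 50-suspect room engineered so three
questions eliminate 25 of 50, 12 of 25, and 6 of 13, giving
`QEM = 0.5 + 0.12 + 0.04 = 0.66` and
`effective QEM = 1/2 + (1/2)(12/25) + (1/3)(6/13) ≈ 0.8938` by direct
arithmetic.

## Simulated players

Policies choose a `(property, value)` probe from the answer-consistent pool:
`constraint_seeking` takes the pair whose holder fraction is closest to 1/2
(ties broken by schema order, then domain order), `hypothesis_scanning` the
rarest held pair, `random` any unasked pair including uninformative ones.
Because suspects are pairwise distinct, an informative pair always exists
while two or more candidates remain, so noiseless play always isolates the
spy; the noiseless constraint seeker needs about 5.8 questions on the
packaged schema, just above the `log2(50) ≈ 5.64` binary-split bound.

Noise enters through four seeded knobs: `lapse_rate` (a turn asks a
uniformly random question), `elimination_compliance` δ (a question's
justified eliminations are recorded with probability δ, else not at all),
`premature_guess_rate`, and `guess_threshold` (guess when the pool is at
most this large). Guesses draw uniformly from the player's *believed* pool —
the room minus what was actually crossed out and already-guessed suspects —
modelling imperfect bookkeeping: a non-compliant player faces a much larger
guessing pool than the ground truth would allow. An `overshoot_questions`
budget forces extra questions after isolation, exercising the overshoot
path.

The packaged `noisy_human` preset is `lapse_rate=0.2`, `δ=0.85`,
`premature_guess_rate=0.05`, `guess_threshold=3`. δ was calibrated by a
seeded sweep (300 games per configuration) so that 400–500-game batches land
near the middle of the 60–80 % win-rate band that the serious-games
literature identifies as the engagement sweet spot; lower compliance values
(δ ≈ 0.6) drop the win rate near 35 % because the believed guessing pool
stays large. Setting δ=0 reproduces the "winner who crossed out nothing"
phenotype; δ near 1 reproduces near-total elimination.

What the simulator does *not* emulate: free-form human phrasing (questions
are template-rendered unless paraphrases are injected deliberately),
question complexity dynamics, fatigue or learning across a session, and
answer latencies beyond uniform placeholder timings. Passing tests therefore
establish the correctness of the scoring and analysis machinery on
transcripts of the documented shape, not behavioural claims about human
players.

## Outcome analysis

Session tables (one row per game: outcome, question/guess counts, recorded
eliminations, both scores) feed a win/loss classifier. Because outcomes are
imbalanced, the minority class is grown to exact parity with SMOTE —
synthetic points `x_i + u·(x_nn − x_i)`, `u ~ U(0,1)`, `x_nn` among the
k = 5 nearest minority neighbours (Euclidean distance on standardised
features); majority rows are never modified, and the interpolation is
implemented in-package with scikit-learn's nearest-neighbour search.
SMOTE is applied to the 80 % stratified training fold only, avoiding
leakage into the held-out 20 %. The logistic regression is fitted by Newton
iterations (tolerance 1e-8, at most 100 iterations) via statsmodels;
perfectly separated data is flagged and refitted with a tiny ridge penalty
(λ = 1e-6) so coefficients stay finite. Evaluation reports accuracy and
per-class precision/recall/F1 at a 0.5 threshold. The default model uses the
single eliminations feature; arbitrary feature subsets are accepted.

## Numerical and I/O choices

Transcripts are JSON Lines under a versioned header (streamable,
append-safe; unknown fields round-trip untouched); rooms and lexicons are
JSON; session tables are CSV with a fixed, documented column order, and the
aggregate block is computed from the table's own columns so re-reading the
CSV reproduces it exactly. Malformed external records raise with their line
number; sessions that would be excluded from analysis are flagged in an
`excluded_reason` column, never silently dropped. All randomness flows
through explicit integer seeds; batch child seeds are drawn distinct from a
master seed, and every derived seed stays below 2³¹.

Problem sizes in the test suite and the acceptance script (300–500-game
batches, 1,000 replay cross-checks, 10,000 fuzzed games on mixed room sizes)
were chosen as the smallest runs at which the stochastic assertions are
stable across seeds.

## Known limitations

* The keyword classifier is English-only and deliberately shallow; it cannot
  represent conjunctive or negated questions and has no semantic fallback.
* The policies are idealised: no memory errors inside a turn, no
  question-complexity dimension, no adaptation.
* The believed-pool guessing model is one of several defensible readings of
  how players with incomplete crossing-out choose a guess; the δ and
  threshold knobs can produce lucky-guesser and thorough-eliminator
  phenotypes but cannot adjudicate between them.
* With a noisy oracle (ε > 0) the replay's spy-retention guard makes
  effective QEM a lower bound on the nominal shrinkage rather than an exact
  replay of what a player experienced; such games are flagged `clamped`.
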