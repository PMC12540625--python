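"""Keyword pattern-matching question classifier.

Free-text yes/no questions are mapped to a single (property, value) label by
whole-word, case-insensitive keyword matching.  Colour words are deliberately
ambiguous on their own (black hair vs. a black shirt), so they only classify
through property–colour pairs: a colour keyword co-occurring with a property
cue such as "hair" or "wearing" resolves to the corresponding colour-bearing
property.  Questions that match no keyword, or more than one distinct target,
are UNCLASSIFIED — a value, not an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .oracle import detect_self_reference, tokenize
from .room import AttributeSchema

PropertyValue = tuple[str, str]

# Cue words that bind a bare colour word to a colour-bearing property.
DEFAULT_PROPERTY_CUES: dict[str, tuple[str, ...]] = {
    "hair_color": ("hair", "haired"),
    "clothing_color": (
        "wearing", "wear", "wears", "clothes", "clothing", "dressed",
        "outfit", "shirt", "t-shirt", "dress", "jacket", "top",
    ),
}

_NEGATION_TOKENS = frozenset(
    {"not", "no", "never", "without", "isn", "doesn", "don", "aren", "hasn"}
)


@dataclass
class Lexicon:
    """Bound vocabulary of a schema: keywords, colour words, and cue pairs.

    ``keyword_to_property_value`` holds unambiguous non-colour keywords;
    ``property_color_pairs`` maps (cue keyword, colour keyword) to the
    colour-property target; ``canonical_questions`` gives, for every
    (property, value), a rendered question text guaranteed to classify back
    to that pair — the simulator's question templates.
    """

    keyword_to_property_value: dict[str, PropertyValue]
    color_keywords: set[str]
    property_color_pairs: dict[tuple[str, str], PropertyValue]
    canonical_questions: dict[PropertyValue, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "keyword_to_property_value": {
                kw: list(pv) for kw, pv in self.keyword_to_property_value.items()
            },
            "color_keywords": sorted(self.color_keywords),
            "property_color_pairs": [
                {"cue": cue, "color": ck, "target": list(pv)}
                for (cue, ck), pv in self.property_color_pairs.items()
            ],
            "canonical_questions": [
                {"property": p, "value": v, "text": t}
                for (p, v), t in self.canonical_questions.items()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Lexicon":
        return cls(
            keyword_to_property_value={
                kw: tuple(pv) for kw, pv in d["keyword_to_property_value"].items()
            },
            color_keywords=set(d["color_keywords"]),
            property_color_pairs={
                (e["cue"], e["color"]): tuple(e["target"])
                for e in d["property_color_pairs"]
            },
            canonical_questions={
                (e["property"], e["value"]): e["text"]
                for e in d.get("canonical_questions", [])
            },
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Lexicon":
        return cls.from_dict(json.loads(text))


@dataclass
class ClassifiedQuestion:
    """A question text with its resolved label (or None for UNCLASSIFIED)."""

    raw_text: str
    label: PropertyValue | None
    matched_keywords: list[str] = field(default_factory=list)
    self_referential: bool = False

    @property
    def is_classified(self) -> bool:
        return self.label is not None

    def to_dict(self) -> dict:
        return {
            "raw_text": self.raw_text,
            "label": list(self.label) if self.label is not None else None,
            "matched_keywords": list(self.matched_keywords),
            "self_referential": self.self_referential,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifiedQuestion":
        label = d.get("label")
        return cls(
            raw_text=d["raw_text"],
            label=tuple(label) if label is not None else None,
            matched_keywords=list(d.get("matched_keywords", [])),
            self_referential=bool(d.get("self_referential", False)),
        )


# Per-property rendering templates for the packaged schema; {v} is the value's
# canonical keyword.  Custom schemas fall back to a generic template.
_CANONICAL_TEMPLATES: dict[str, dict[str, str]] = {
    "gender": {"male": "Is the spy a man?", "female": "Is the spy a woman?"},
    "hair_length": {
        "bald": "Is the spy bald?",
        "short": "Does the spy have short hair?",
        "long": "Does the spy have long hair?",
    },
    "hair_color": {},  # filled generically: "Does the spy have {v} hair?"
    "face_accessory": {
        "none": "Is the spy's face unadorned?",
        "glasses": "Is the spy wearing glasses?",
        "scar": "Does the spy have a scar?",
    },
    "clothing_type": {},  # "Is the spy wearing a {v}?"
    "clothing_color": {},  # "Is the spy wearing {v} clothes?"
}


def _canonical_question(prop_name: str, value: str, is_color: bool) -> str:
    special = _CANONICAL_TEMPLATES.get(prop_name, {})
    if value in special:
        return special[value]
    if prop_name == "hair_color":
        return f"Does the spy have {value} hair?"
    if prop_name == "clothing_type":
        return f"Is the spy wearing a {value}?"
    if prop_name == "clothing_color":
        return f"Is the spy wearing {value} clothes?"
    if is_color:
        # generic colour property: the property-name tokens act as cues
        cue = prop_name.replace("_", " ")
        return f"Is the spy's {cue} {value}?"
    return f"Is the spy's {prop_name.replace('_', ' ')} {value}?"


def build_default_lexicon(
    schema: AttributeSchema,
    property_cues: dict[str, tuple[str, ...]] | None = None,
) -> Lexicon:
    """Build the packaged lexicon for a schema.

    Non-colour values contribute their schema keywords directly; colour-bearing
    properties contribute their colour words to ``color_keywords`` and are
    reachable only through (cue, colour) pairs.  Raises ``ValueError`` if two
    different targets claim the same keyword.
    """
    if property_cues is None:
        property_cues = dict(DEFAULT_PROPERTY_CUES)
    kw_map: dict[str, PropertyValue] = {}
    color_keywords: set[str] = set()
    pairs: dict[tuple[str, str], PropertyValue] = {}
    canonical: dict[PropertyValue, str] = {}

    for spec in schema.properties:
        cues = property_cues.get(spec.name)
        if spec.is_color and cues is None:
            # derive cues from the property name ("eye_color" -> "eye")
            cues = tuple(
                t for t in spec.name.lower().split("_") if t not in ("color", "colour")
            )
        for value in spec.domain:
            keywords = spec.keywords.get(value, (value.lower(),))
            if spec.is_color:
                for ck in keywords:
                    color_keywords.add(ck)
                    for cue in cues:
                        key = (cue, ck)
                        if key in pairs and pairs[key] != (spec.name, value):
                            raise ValueError(f"pair {key} bound to two targets")
                        pairs[key] = (spec.name, value)
            else:
                for kw in keywords:
                    if kw in kw_map and kw_map[kw] != (spec.name, value):
                        raise ValueError(f"keyword {kw!r} bound to two targets")
                    kw_map[kw] = (spec.name, value)
            canonical[(spec.name, value)] = _canonical_question(
                spec.name, value, spec.is_color
            )
    return Lexicon(
        keyword_to_property_value=kw_map,
        color_keywords=color_keywords,
        property_color_pairs=pairs,
        canonical_questions=canonical,
    )


def classify_question(
    text: str,
    lexicon: Lexicon,
    strict_negation: bool = False,
) -> ClassifiedQuestion:
    """Classify one question by keyword pattern matching.

    Resolution order: if a colour keyword co-occurs with a property cue
    forming a known pair, the pair label wins; otherwise, if the non-colour
    keywords present resolve to exactly one (property, value), that label is
    returned; otherwise UNCLASSIFIED.  With ``strict_negation`` set, questions
    containing a negation token are routed to UNCLASSIFIED instead of being
    classified by their keywords as if phrased positively.
    """
    tokens = tokenize(text)
    token_set = set(tokens)
    self_ref = detect_self_reference(text)

    if strict_negation and token_set & _NEGATION_TOKENS:
        return ClassifiedQuestion(text, None, [], self_ref)

    colors_present = token_set & lexicon.color_keywords

    # property-colour pairs take precedence
    if colors_present:
        pair_hits: dict[PropertyValue, list[str]] = {}
        for (cue, ck), target in lexicon.property_color_pairs.items():
            if cue in token_set and ck in token_set:
                pair_hits.setdefault(target, []).extend([cue, ck])
        if len(pair_hits) == 1:
            (target, kws), = pair_hits.items()
            matched = sorted(set(kws), key=kws.index)
            return ClassifiedQuestion(text, target, matched, self_ref)
        if len(pair_hits) > 1:
            matched = sorted({kw for kws in pair_hits.values() for kw in kws})
            return ClassifiedQuestion(text, None, matched, self_ref)

    # single unambiguous non-colour keyword target
    kw_hits = [t for t in tokens if t in lexicon.keyword_to_property_value]
    targets = {lexicon.keyword_to_property_value[t] for t in kw_hits}
    if len(targets) == 1:
        target = next(iter(targets))
        matched = sorted(set(kw_hits), key=kw_hits.index)
        return ClassifiedQuestion(text, target, matched, self_ref)

    matched = sorted(set(kw_hits) | colors_present)
    return ClassifiedQuestion(text, None, matched, self_ref)
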