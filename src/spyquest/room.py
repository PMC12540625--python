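"""Ground-truth world model: attribute schema, rooms of distinct suspects, spy.

A room is a set of pairwise-distinct attribute vectors ("suspects"), one of
which is marked as the hidden spy.  The default schema reconstructs the kind
of visual feature space used in hidden-object question games: gender, hair
length and colour, face accessories, and clothing type and colour, giving
1,800 possible distinct characters — comfortably more than the 50 suspects a
default room holds.

``consistent_suspects`` is the engine's single source of truth for answer
bookkeeping: given a chain of (property, value, answer) constraints it returns
the suspects still compatible with every answer.  When answers are truthful
about the spy, the spy is always in that set, which is what guarantees the
scoring denominators downstream never reach zero.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import random
from dataclasses import dataclass, field
from math import prod
from typing import Iterable, Sequence

from .errors import SchemaTooSmall, UnknownProperty, UnknownValue
from .oracle import AnswerLabel

DEFAULT_ROOM_SIZE = 50
DEFAULT_GUESS_BUDGET = 5


@dataclass(frozen=True)
class PropertySpec:
    """One visual property: its finite value domain and per-value keywords."""

    name: str
    domain: tuple[str, ...]
    is_color: bool = False
    keywords: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.domain) < 2:
            raise ValueError(f"property {self.name!r} needs >= 2 values")
        if len(set(self.domain)) != len(self.domain):
            raise ValueError(f"property {self.name!r} has duplicate values")


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered collection of properties spanning the suspect feature space."""

    properties: tuple[PropertySpec, ...]

    def __post_init__(self):
        names = [p.name for p in self.properties]
        if len(set(names)) != len(names):
            raise ValueError("property names must be unique")

    @property
    def property_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.properties)

    def property(self, name: str) -> PropertySpec:
        for p in self.properties:
            if p.name == name:
                return p
        raise UnknownProperty(name)

    def validate_pair(self, prop: str, value: str) -> None:
        spec = self.property(prop)
        if value not in spec.domain:
            raise UnknownValue(f"{value!r} not in domain of {prop!r}")

    def product_size(self) -> int:
        return prod(len(p.domain) for p in self.properties)

    def all_pairs(self) -> list[tuple[str, str]]:
        """Every (property, value) pair, in schema order then domain order."""
        return [(p.name, v) for p in self.properties for v in p.domain]

    def to_dict(self) -> dict:
        return {
            "properties": [
                {
                    "name": p.name,
                    "domain": list(p.domain),
                    "is_color": p.is_color,
                    "keywords": {v: list(kws) for v, kws in p.keywords.items()},
                }
                for p in self.properties
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AttributeSchema":
        return cls(
            properties=tuple(
                PropertySpec(
                    name=p["name"],
                    domain=tuple(p["domain"]),
                    is_color=bool(p.get("is_color", False)),
                    keywords={
                        v: tuple(kws) for v, kws in p.get("keywords", {}).items()
                    },
                )
                for p in d["properties"]
            )
        )


@dataclass
class Suspect:
    """A character in the room: a total assignment of schema properties."""

    suspect_id: int
    attributes: dict[str, str]
    screen_pos: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = {"suspect_id": self.suspect_id, "attributes": dict(self.attributes)}
        if self.screen_pos is not None:
            d["screen_pos"] = list(self.screen_pos)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Suspect":
        pos = d.get("screen_pos")
        return cls(
            suspect_id=int(d["suspect_id"]),
            attributes=dict(d["attributes"]),
            screen_pos=tuple(pos) if pos is not None else None,
        )


@dataclass
class Room:
    """A generated game world: schema, suspects, and the hidden spy."""

    schema: AttributeSchema
    suspects: list[Suspect]
    spy_id: int
    seed: int

    def __post_init__(self):
        vectors = [
            tuple(s.attributes[p] for p in self.schema.property_names)
            for s in self.suspects
        ]
        if len(set(vectors)) != len(vectors):
            raise ValueError("suspect attribute vectors must be pairwise distinct")
        if self.spy_id not in {s.suspect_id for s in self.suspects}:
            raise ValueError("spy_id must be a valid suspect_id")

    @property
    def size(self) -> int:
        return len(self.suspects)

    def spy(self) -> Suspect:
        return next(s for s in self.suspects if s.suspect_id == self.spy_id)

    def suspect(self, suspect_id: int) -> Suspect:
        return next(s for s in self.suspects if s.suspect_id == suspect_id)

    def checksum(self) -> str:
        """Stable digest of the room contents, used to match transcripts."""
        payload = json.dumps(
            {
                "suspects": [s.to_dict() for s in self.suspects],
                "spy_id": self.spy_id,
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "schema": self.schema.to_dict(),
            "suspects": [s.to_dict() for s in self.suspects],
            "spy_id": self.spy_id,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Room":
        return cls(
            schema=AttributeSchema.from_dict(d["schema"]),
            suspects=[Suspect.from_dict(s) for s in d["suspects"]],
            spy_id=int(d["spy_id"]),
            seed=int(d["seed"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Room":
        return cls.from_dict(json.loads(text))


@dataclass
class GameConfig:
    """Parameters of one game: room size, guess budget, scoring options."""

    room_size: int = DEFAULT_ROOM_SIZE
    guess_budget: int = DEFAULT_GUESS_BUDGET
    seed: int = 0
    oracle_error_rate: float = 0.0
    keep_original_index: bool = False

    def __post_init__(self):
        if self.room_size < 2:
            raise ValueError("room_size must be >= 2")
        if self.guess_budget < 1:
            raise ValueError("guess_budget must be >= 1")


def default_schema() -> AttributeSchema:
    """The packaged six-property schema of visually distinct characters.

    Spans gender, hair length/colour, face accessories, and clothing
    type/colour; the product space holds 1,800 distinct characters.
    """
    return AttributeSchema(
        properties=(
            PropertySpec(
                name="gender",
                domain=("male", "female"),
                keywords={
                    "male": ("man", "boy", "male", "guy", "gentleman"),
                    "female": ("woman", "girl", "female", "lady"),
                },
            ),
            PropertySpec(
                name="hair_length",
                domain=("bald", "short", "long"),
                keywords={
                    "bald": ("bald",),
                    "short": ("short",),
                    "long": ("long",),
                },
            ),
            PropertySpec(
                name="hair_color",
                domain=("black", "brown", "grey", "red", "blond"),
                is_color=True,
                keywords={
                    "black": ("black",),
                    "brown": ("brown",),
                    "grey": ("grey", "gray"),
                    "red": ("red", "ginger"),
                    "blond": ("blond", "blonde"),
                },
            ),
            PropertySpec(
                name="face_accessory",
                domain=("none", "glasses", "scar"),
                keywords={
                    "none": ("unadorned",),
                    "glasses": ("glasses", "spectacles"),
                    "scar": ("scar",),
                },
            ),
            PropertySpec(
                name="clothing_type",
                domain=("t-shirt", "shirt", "dress", "jacket"),
                keywords={
                    "t-shirt": ("t-shirt", "tshirt", "tee"),
                    "shirt": ("shirt",),
                    "dress": ("dress",),
                    "jacket": ("jacket", "coat"),
                },
            ),
            PropertySpec(
                name="clothing_color",
                domain=("black", "red", "blue", "green", "white"),
                is_color=True,
                keywords={
                    "black": ("black",),
                    "red": ("red",),
                    "blue": ("blue",),
                    "green": ("green",),
                    "white": ("white",),
                },
            ),
        )
    )


# Above this many combinations we sample by rejection rather than enumerating.
_ENUMERATION_LIMIT = 500_000


def generate_room(
    schema: AttributeSchema, size: int = DEFAULT_ROOM_SIZE, seed: int = 0
) -> Room:
    """Sample ``size`` pairwise-distinct suspects and pick a spy uniformly.

    Sampling is without replacement from the attribute product space; the
    same (schema, size, seed) always yields a bit-identical room.  The seeded
    stream is consumed in a documented order: suspects first, spy last.
    """
    space = schema.product_size()
    if space < size:
        raise SchemaTooSmall(
            f"product space has {space} combinations < requested size {size}"
        )
    rng = random.Random(seed)
    names = schema.property_names
    if space <= _ENUMERATION_LIMIT:
        combos = list(itertools.product(*(p.domain for p in schema.properties)))
        chosen = rng.sample(combos, size)
    else:  # rejection sampling; duplicates are vanishingly rare here
        seen: set[tuple[str, ...]] = set()
        chosen = []
        while len(chosen) < size:
            vec = tuple(rng.choice(p.domain) for p in schema.properties)
            if vec not in seen:
                seen.add(vec)
                chosen.append(vec)
    suspects = [
        Suspect(
            suspect_id=i,
            attributes=dict(zip(names, vec)),
            screen_pos=(float(i % 10), float(i // 10)),
        )
        for i, vec in enumerate(chosen)
    ]
    spy_id = rng.randrange(size)
    return Room(schema=schema, suspects=suspects, spy_id=spy_id, seed=seed)


Constraint = tuple[str, str, AnswerLabel]


def _satisfies(suspect: Suspect, prop: str, value: str, answer: AnswerLabel) -> bool:
    if answer is AnswerLabel.AFFIRMATIVE:
        return suspect.attributes[prop] == value
    return suspect.attributes[prop] != value


def consistent_suspects(
    room: Room,
    constraints: Sequence[Constraint],
    within: Iterable[int] | None = None,
) -> set[int]:
    """Ids of suspects satisfying every (property, value, answer) constraint.

    AFFIRMATIVE requires the attribute to equal the value, NEGATIVE to differ.
    ``within`` optionally restricts the search to a subset of ids (used by the
    replay loop to filter incrementally).  For constraints answered truthfully
    about the spy, the spy is always in the result.
    """
    for prop, value, answer in constraints:
        room.schema.validate_pair(prop, value)
        if answer not in (AnswerLabel.AFFIRMATIVE, AnswerLabel.NEGATIVE):
            raise ValueError(f"constraints must be affirmative/negative, got {answer}")
    pool = (
        room.suspects
        if within is None
        else [s for s in room.suspects if s.suspect_id in set(within)]
    )
    return {
        s.suspect_id
        for s in pool
        if all(_satisfies(s, p, v, a) for p, v, a in constraints)
    }
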