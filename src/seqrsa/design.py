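"""Wedding ritual transition structure, schedules, and answer keys.

The experimental design uses two schemas (North, South) that share the same
six rituals but impose opposite transition structures over them.  Each
wedding follows one of four paths through three analyzed stages (2, 3, 4);
the stage-2 ritual is unpredictable, after which the remaining transitions
are deterministic given the schema.  This module is the single source of
truth for that graph: every labeling, contrast and generator downstream
derives its design facts from here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Ritual",
    "Schema",
    "Path",
    "WeddingDesign",
    "Schedule",
    "START",
    "UNPREDICTABLE",
    "END",
    "PATHS",
    "STAGES",
    "next_ritual",
    "deduce_path",
    "enumerate_paths",
    "make_schedule",
    "schema_test_key",
    "DesignError",
]

STAGES = (2, 3, 4)


class DesignError(ValueError):
    """Raised when inputs violate the ritual graph's constraints."""


class Ritual(enum.Enum):
    campfire = "campfire"
    flower = "flower"
    coin = "coin"
    torch = "torch"
    egg = "egg"
    painting = "painting"

    @property
    def stage(self) -> int:
        return _RITUAL_STAGE[self]


_RITUAL_STAGE = {
    Ritual.campfire: 2,
    Ritual.flower: 2,
    Ritual.coin: 3,
    Ritual.torch: 3,
    Ritual.egg: 4,
    Ritual.painting: 4,
}


class Schema(enum.Enum):
    North = "North"
    South = "South"

    @property
    def other(self) -> "Schema":
        return Schema.South if self is Schema.North else Schema.North


# Sentinels for the transition function.
class _Sentinel:
    def __init__(self, name: str):
        self._name = name

    def __repr__(self) -> str:
        return self._name


START = _Sentinel("START")
UNPREDICTABLE = _Sentinel("UNPREDICTABLE")
END = _Sentinel("END")


@dataclass(frozen=True)
class Path:
    """One of the four ritual sequences (stages 2, 3, 4) within a schema."""

    id: str
    schema: Schema
    rituals: tuple[Ritual, Ritual, Ritual]

    def ritual_at(self, stage: int) -> Ritual:
        if stage not in STAGES:
            raise DesignError(f"stage must be one of {STAGES}, got {stage}")
        return self.rituals[stage - 2]

    def __contains__(self, ritual: Ritual) -> bool:
        return ritual in self.rituals


PATHS: dict[str, Path] = {
    "A": Path("A", Schema.North, (Ritual.campfire, Ritual.coin, Ritual.egg)),
    "B": Path("B", Schema.North, (Ritual.flower, Ritual.torch, Ritual.painting)),
    "C": Path("C", Schema.South, (Ritual.campfire, Ritual.torch, Ritual.egg)),
    "D": Path("D", Schema.South, (Ritual.flower, Ritual.coin, Ritual.painting)),
}


def enumerate_paths() -> list[Path]:
    """Return the four paths in canonical order A, B, C, D."""
    return [PATHS[k] for k in "ABCD"]


def paths_of(schema: Schema) -> list[Path]:
    return [p for p in enumerate_paths() if p.schema is schema]


def next_ritual(schema: Schema, current):
    """Successor of ``current`` under ``schema``.

    ``START`` maps to ``UNPREDICTABLE`` (the stage-2 ritual is equiprobable),
    stage-2/3 rituals map to their unique successor, stage-4 rituals to
    ``END``.
    """
    if current is START:
        return UNPREDICTABLE
    if not isinstance(current, Ritual):
        raise DesignError(f"unknown ritual: {current!r}")
    if not isinstance(schema, Schema):
        raise DesignError(f"unknown schema: {schema!r}")
    if current.stage == 4:
        return END
    for path in paths_of(schema):
        rituals = path.rituals
        if current in rituals:
            idx = rituals.index(current)
            return rituals[idx + 1]
    raise DesignError(f"ritual {current} not reachable under schema {schema}")


def deduce_path(schema: Schema, stage2: Ritual) -> Path:
    """The unique path determined by a schema plus its stage-2 ritual."""
    if not isinstance(stage2, Ritual) or stage2.stage != 2:
        raise DesignError(f"{stage2!r} is not a stage-2 ritual")
    for path in paths_of(schema):
        if path.ritual_at(2) is stage2:
            return path
    raise DesignError(f"no path for ({schema}, {stage2})")  # pragma: no cover


def predecessor_ritual(schema: Schema, ritual: Ritual) -> Optional[Ritual]:
    """Ritual immediately preceding ``ritual`` on its path under ``schema``.

    Returns None for stage-2 rituals (no analyzed predecessor).
    """
    if ritual.stage == 2:
        return None
    for path in paths_of(schema):
        if ritual in path:
            return path.ritual_at(ritual.stage - 1)
    raise DesignError(f"ritual {ritual} not on any {schema} path")


def successor_ritual(schema: Schema, ritual: Ritual) -> Optional[Ritual]:
    """Ritual immediately following ``ritual`` on its path; None at stage 4."""
    nxt = next_ritual(schema, ritual)
    return nxt if isinstance(nxt, Ritual) else None


@dataclass(frozen=True)
class WeddingDesign:
    wedding_id: int
    schema: Schema
    path: Path
    position_in_schedule: int

    def __post_init__(self):
        if self.path.schema is not self.schema:
            raise DesignError(
                f"wedding {self.wedding_id}: path {self.path.id} belongs to "
                f"{self.path.schema}, not {self.schema}"
            )

    def ritual_at(self, stage: int) -> Ritual:
        return self.path.ritual_at(stage)


# Day-2 presentation order of schemas, fixed by the design.
DAY2_SCHEMA_ORDER = "SNNSSNNSSNNS"


@dataclass(frozen=True)
class Schedule:
    day: int
    weddings: tuple[WeddingDesign, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.weddings)

    def __iter__(self):
        return iter(self.weddings)

    def __getitem__(self, i: int) -> WeddingDesign:
        return self.weddings[i]

    @property
    def wedding_ids(self) -> list[int]:
        return [w.wedding_id for w in self.weddings]

    def wedding(self, wedding_id: int) -> WeddingDesign:
        for w in self.weddings:
            if w.wedding_id == wedding_id:
                return w
        raise KeyError(wedding_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "wedding_id": w.wedding_id,
                "day": self.day,
                "position": w.position_in_schedule,
                "schema": w.schema.value,
                "path": w.path.id,
                "ritual_stage2": w.ritual_at(2).value,
                "ritual_stage3": w.ritual_at(3).value,
                "ritual_stage4": w.ritual_at(4).value,
            }
            for w in self.weddings
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Schedule":
        days = frame["day"].unique()
        if len(days) != 1:
            raise DesignError(f"schedule frame mixes days: {days}")
        weddings = []
        for _, row in frame.sort_values("position").iterrows():
            schema = Schema(row["schema"])
            path = PATHS[row["path"]]
            for stage in STAGES:
                expect = path.ritual_at(stage).value
                if row[f"ritual_stage{stage}"] != expect:
                    raise DesignError(
                        f"wedding {row['wedding_id']}: stage-{stage} ritual "
                        f"{row[f'ritual_stage{stage}']!r} inconsistent with path "
                        f"{path.id} (expected {expect!r})"
                    )
            weddings.append(
                WeddingDesign(int(row["wedding_id"]), schema, path, int(row["position"]))
            )
        return cls(day=int(days[0]), weddings=tuple(weddings))


def _balanced_path_order(schema: Schema, n: int, rng: np.random.Generator) -> list[Path]:
    """n path draws from ``schema`` with counts as equal as possible."""
    options = paths_of(schema)
    reps = [options[i % 2] for i in range(n)]
    order = rng.permutation(n)
    return [reps[i] for i in order]


def make_schedule(day: int, first_context: Schema, seed: int) -> Schedule:
    """Build a learning (day-1) or scanning (day-2) wedding schedule.

    Day 1 is blocked: two blocks of six weddings of ``first_context``, then
    two blocks of six of the other schema, with both paths of the block's
    schema occurring equally often within every block.  Day 2 interleaves
    six of each schema in the fixed order S,N,N,S,S,N,N,S,S,N,N,S with each
    schema's two paths balanced 3/3.  Path order is randomized by ``seed``.
    """
    rng = np.random.default_rng(seed)
    if day == 1:
        weddings = []
        block_schemas = [first_context] * 2 + [first_context.other] * 2
        for schema in block_schemas:
            block_paths = _balanced_path_order(schema, 6, rng)
            for path in block_paths:
                i = len(weddings)
                weddings.append(WeddingDesign(i, schema, path, i))
        return Schedule(day=1, weddings=tuple(weddings))
    if day == 2:
        schemas = [Schema.North if c == "N" else Schema.South for c in DAY2_SCHEMA_ORDER]
        per_schema_paths = {
            s: iter(_balanced_path_order(s, schemas.count(s), rng))
            for s in (Schema.North, Schema.South)
        }
        weddings = tuple(
            WeddingDesign(i, s, next(per_schema_paths[s]), i)
            for i, s in enumerate(schemas)
        )
        return Schedule(day=2, weddings=weddings)
    raise DesignError(f"day must be 1 or 2, got {day}")


def schema_test_key() -> list[dict]:
    """Answer key for the eight end-of-study transition questions.

    One question per schema x {campfire, flower, coin, torch}: the correct
    option is the successor under the cued schema, the 'opposite' option is
    the successor under the other schema.
    """
    cues = [Ritual.campfire, Ritual.flower, Ritual.coin, Ritual.torch]
    key = []
    for schema in (Schema.North, Schema.South):
        for cue in cues:
            key.append(
                {
                    "schema": schema,
                    "cue_ritual": cue,
                    "correct_next": next_ritual(schema, cue),
                    "opposite_next": next_ritual(schema.other, cue),
                }
            )
    return key
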