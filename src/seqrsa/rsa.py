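"""Leave-one-wedding-out template RSA and the comparison taxonomy.

For each held-out wedding we build 12 template patterns (one per
ritual x schema cell, averaged over all other weddings) and correlate each
template with the held-out wedding's three stage patterns, yielding 36
labeled comparisons per held-out wedding.  The labels encode the full
sorting taxonomy used by the downstream contrasts: stage relation, path
relation, schema/ritual identity, shared preceding ritual, and whether the
template ritual is the immediate predecessor/successor of the held-out
ritual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    PATHS,
    STAGES,
    DesignError,
    Ritual,
    Schedule,
    Schema,
    paths_of,
    predecessor_ritual,
    successor_ritual,
)

__all__ = [
    "TEMPLATE_CELLS",
    "TemplateSet",
    "RSAError",
    "build_templates",
    "similarity",
    "compare_all",
    "label_comparison",
    "label_same_preceding",
    "label_table",
]


class RSAError(ValueError):
    pass


# Canonical template-cell order: rituals in stage order, schema-major within.
TEMPLATE_CELLS: tuple[tuple[Ritual, Schema], ...] = tuple(
    (ritual, schema)
    for ritual in Ritual
    for schema in (Schema.North, Schema.South)
)


def cell_path(ritual: Ritual, schema: Schema):
    """The unique path of ``schema`` containing ``ritual``."""
    for path in paths_of(schema):
        if ritual in path:
            return path
    raise DesignError(f"no {schema} path contains {ritual}")  # pragma: no cover


@dataclass(frozen=True)
class TemplateSet:
    """The 12 (ritual, schema) mean patterns with one wedding held out."""

    held_out_wedding: int
    templates: dict  # (Ritual, Schema) -> 1-D voxel vector

    def __post_init__(self):
        if len(self.templates) != 12:
            raise RSAError(
                f"expected 12 templates, got {len(self.templates)}"
            )

    def __getitem__(self, cell):
        return self.templates[cell]


def build_templates(data, held_out: int, voxels=None, participant: int = 0) -> TemplateSet:
    """Average each (ritual, schema) cell over all weddings except ``held_out``.

    ``data`` is a PatternDataset; ``voxels`` an optional integer index array
    selecting a voxel subset (e.g. one searchlight's members).
    """
    schedule = data.schedule
    templates = {}
    for ritual, schema in TEMPLATE_CELLS:
        vecs = []
        for w in schedule:
            if w.wedding_id == held_out or w.schema is not schema:
                continue
            if w.ritual_at(ritual.stage) is ritual:
                vecs.append(
                    data.pattern(
                        w.wedding_id, ritual.stage, participant=participant, voxels=voxels
                    )
                )
        if not vecs:
            raise RSAError(
                f"unestimable template: cell ({ritual.value}, {schema.value}) "
                f"has no contributing wedding once wedding {held_out} is held out"
            )
        templates[(ritual, schema)] = np.mean(vecs, axis=0)
    return TemplateSet(held_out_wedding=held_out, templates=templates)


def similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two voxel vectors.

    Constant vectors are rejected: a flat pattern signals an upstream
    masking bug, not a zero-similarity observation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise RSAError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise RSAError(f"need >= 3 voxels, got {a.size}")
    sa = a.std()
    sb = b.std()
    if sa == 0 or sb == 0:
        raise RSAError("undefined similarity: constant voxel vector")
    return float(np.dot(a - a.mean(), b - b.mean()) / (a.size * sa * sb))


def label_same_preceding(template_cell, heldout_cell) -> bool:
    """Whether two cells' paths share the same stage-(s-1) ritual.

    Each cell is a (ritual, schema) pair.  Stage-2 cells have no analyzed
    predecessor, so any comparison involving one is False.
    """
    t_ritual, t_schema = template_cell
    h_ritual, h_schema = heldout_cell
    if t_ritual.stage == 2 or h_ritual.stage == 2:
        return False
    t_pred = predecessor_ritual(t_schema, t_ritual)
    h_pred = predecessor_ritual(h_schema, h_ritual)
    return t_pred is h_pred


def label_comparison(
    template_ritual: Ritual,
    template_schema: Schema,
    heldout_path,
    heldout_stage: int,
) -> dict:
    """Full sorting taxonomy for one template-vs-held-out comparison."""
    heldout_ritual = heldout_path.ritual_at(heldout_stage)
    heldout_schema = heldout_path.schema
    template_path = cell_path(template_ritual, template_schema)
    template_stage = template_ritual.stage

    same_schema = template_schema is heldout_schema
    same_ritual = template_ritual is heldout_ritual
    within = template_stage == heldout_stage

    if same_schema:
        path_relation = 1 if template_path is heldout_path else 2
    else:
        path_relation = 4 if template_ritual in heldout_path else 3

    # Predecessor/successor matching is by ritual identity only; schema of
    # the template is ignored because the putative carried-over trace is a
    # sensory trace of the ritual itself.
    is_pred = (
        template_stage == heldout_stage - 1
        and template_ritual is heldout_path.ritual_at(heldout_stage - 1)
    )
    is_succ = (
        template_stage == heldout_stage + 1
        and template_ritual is heldout_path.ritual_at(heldout_stage + 1)
    )

    t_succ = successor_ritual(template_schema, template_ritual)
    h_succ = (
        heldout_path.ritual_at(heldout_stage + 1) if heldout_stage < 4 else None
    )
    same_upcoming = t_succ is not None and h_succ is not None and t_succ is h_succ

    return {
        "template_ritual": template_ritual.value,
        "template_schema": template_schema.value,
        "template_stage": template_stage,
        "heldout_stage": heldout_stage,
        "heldout_ritual": heldout_ritual.value,
        "heldout_schema": heldout_schema.value,
        "stage_relation": "within" if within else "across",
        "path_relation": path_relation,
        "same_schema": same_schema,
        "same_ritual": same_ritual,
        "same_preceding_ritual": label_same_preceding(
            (template_ritual, template_schema), (heldout_ritual, heldout_schema)
        ),
        "same_upcoming_ritual": same_upcoming,
        "template_is_predecessor": is_pred,
        "template_is_successor": is_succ,
    }


def label_table(schedule: Schedule) -> pd.DataFrame:
    """All 36 x n_weddings comparison labels for a schedule, in engine order.

    Row order: held-out wedding (schedule order) -> template cell
    (TEMPLATE_CELLS order) -> held-out stage (2, 3, 4).  The searchlight
    engine relies on this ordering to map vectorized similarities onto
    labels.
    """
    rows = []
    for w in schedule:
        for ritual, schema in TEMPLATE_CELLS:
            for stage in STAGES:
                row = {"held_out_wedding": w.wedding_id}
                row.update(label_comparison(ritual, schema, w.path, stage))
                rows.append(row)
    return pd.DataFrame(rows)


def compare_all(data, voxels=None, participants=None) -> pd.DataFrame:
    """Loop every held-out wedding; emit the 36 labeled similarities each.

    Returns a tidy DataFrame (the ComparisonTable): one row per
    (participant, held-out wedding, template cell, held-out stage).
    """
    schedule = data.schedule
    if participants is None:
        participants = range(data.n_participants)
    labels = label_table(schedule)
    frames = []
    for p in participants:
        sims = []
        for w in schedule:
            tset = build_templates(data, w.wedding_id, voxels=voxels, participant=p)
            for cell in TEMPLATE_CELLS:
                for stage in STAGES:
                    held = data.pattern(
                        w.wedding_id, stage, participant=p, voxels=voxels
                    )
                    sims.append(similarity(tset[cell], held))
        frame = labels.copy()
        frame.insert(0, "participant", p)
        frame["similarity"] = sims
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    n_expected = len(participants) * len(schedule) * 36
    assert len(table) == n_expected
    return table
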