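"""The five scalar code-strength contrasts over labeled comparison tables.

Every code is a linear functional of the 36-per-wedding similarity records:
a difference of means between a positive and a negative set of label
categories (the rotated code averages two such differences).  Scores can be
taken per participant (over all held-out weddings) or per wedding (over
that wedding's own 36 records).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import PATHS, STAGES
from .rsa import TEMPLATE_CELLS, label_comparison

__all__ = [
    "CODE_NAMES",
    "ContrastError",
    "weight_vector",
    "score_table",
    "schema_score",
    "path_score",
    "current_ritual_score",
    "rotated_preceding_score",
    "nonrotated_score",
    "predicted_matrix",
]

CODE_NAMES = (
    "schema",
    "path",
    "current_ritual",
    "rotated_preceding",
    "nonrotated_preceding_upcoming",
)


class ContrastError(ValueError):
    pass


def _mean_weights(mask: np.ndarray, sign: float, name: str) -> np.ndarray:
    n = int(mask.sum())
    if n == 0:
        raise ContrastError(f"empty condition cell: {name}")
    w = np.zeros(mask.shape[0])
    w[mask] = sign / n
    return w


def weight_vector(code: str, labels: pd.DataFrame) -> np.ndarray:
    """Per-record weights w such that the code score equals w . similarities.

    ``labels`` is any subset of a comparison/label table (already scoped);
    weights are computed from its label columns alone.
    """
    if code == "schema":
        same = labels["same_schema"].to_numpy()
        return _mean_weights(same, 1.0, "same-schema") + _mean_weights(
            ~same, -1.0, "different-schema"
        )
    if code == "path":
        rel = labels["path_relation"].to_numpy()
        return _mean_weights(rel == 1, 1.0, "same-path, same-schema") + _mean_weights(
            rel == 2, -1.0, "different-path, same-schema"
        )
    if code == "current_ritual":
        within = (labels["stage_relation"] == "within").to_numpy()
        same = labels["same_ritual"].to_numpy()
        return _mean_weights(within & same, 1.0, "within-stage same-ritual") + _mean_weights(
            within & ~same, -1.0, "within-stage different-ritual"
        )
    if code == "rotated_preceding":
        ts = labels["template_stage"].to_numpy()
        hs = labels["heldout_stage"].to_numpy()
        pred = labels["template_is_predecessor"].to_numpy()
        succ = labels["template_is_successor"].to_numpy()
        half1 = (ts == 2) & (hs == 3)
        half2 = (ts == 3) & (hs == 2)
        w = _mean_weights(half1 & ~pred, 0.5, "stage2-template mismatch")
        w += _mean_weights(half1 & pred, -0.5, "stage2-template predecessor match")
        w += _mean_weights(half2 & ~succ, 0.5, "stage3-template mismatch")
        w += _mean_weights(half2 & succ, -0.5, "stage3-template successor match")
        return w
    if code == "nonrotated_preceding_upcoming":
        return -weight_vector("rotated_preceding", labels)
    raise ContrastError(f"unknown code: {code!r}")


def score_table(table: pd.DataFrame, code: str, scope: str = "participant") -> pd.DataFrame:
    """Contrast scores grouped per participant or per (participant, wedding)."""
    if scope == "participant":
        keys = ["participant"]
    elif scope == "wedding":
        keys = ["participant", "held_out_wedding"]
    else:
        raise ContrastError(f"scope must be 'participant' or 'wedding', got {scope!r}")
    if len(table) == 0:
        raise ContrastError("empty comparison table")
    rows = []
    for group_key, group in table.groupby(keys, sort=True):
        w = weight_vector(code, group)
        value = float(group["similarity"].to_numpy() @ w)
        if not np.isfinite(value):
            raise ContrastError(f"non-finite {code} score for {keys}={group_key}")
        row = dict(zip(keys, group_key if isinstance(group_key, tuple) else (group_key,)))
        row["code"] = code
        row["value"] = value
        rows.append(row)
    out = pd.DataFrame(rows)
    if scope == "wedding":
        out = out.rename(columns={"held_out_wedding": "wedding_id"})
    return out


def schema_score(table: pd.DataFrame, scope: str = "participant") -> pd.DataFrame:
    """Mean same-schema minus mean different-schema similarity."""
    return score_table(table, "schema", scope)


def path_score(table: pd.DataFrame, scope: str = "participant") -> pd.DataFrame:
    """Same-path/same-schema minus different-path/same-schema; cross-schema omitted."""
    return score_table(table, "path", scope)


def current_ritual_score(table: pd.DataFrame, scope: str = "participant") -> pd.DataFrame:
    """Within-stage same-ritual minus other-ritual similarity."""
    return score_table(table, "current_ritual", scope)


def rotated_preceding_score(table: pd.DataFrame, scope: str = "participant") -> pd.DataFrame:
    """Average of the two stage-2<->3 mismatch-minus-match differences.

    Positive values indicate the anticorrelated (rotated) carry-over of the
    preceding ritual; stage-4 comparisons are excluded.
    """
    return score_table(table, "rotated_preceding", scope)


def nonrotated_score(table: pd.DataFrame, scope: str = "participant") -> pd.DataFrame:
    """Sign-flipped rotated contrast: detects a non-rotated carry-over."""
    return score_table(table, "nonrotated_preceding_upcoming", scope)


def _classify(code: str, label: dict) -> int:
    """+1 high-similarity cell, -1 low-similarity cell, 0 omitted."""
    if code == "schema":
        return 1 if label["same_schema"] else -1
    if code == "path":
        if label["path_relation"] == 1:
            return 1
        if label["path_relation"] == 2:
            return -1
        return 0
    if code == "current_ritual":
        if label["stage_relation"] != "within":
            return 0
        return 1 if label["same_ritual"] else -1
    if code == "rotated_preceding":
        ts, hs = label["template_stage"], label["heldout_stage"]
        if (ts, hs) == (2, 3):
            return -1 if label["template_is_predecessor"] else 1
        if (ts, hs) == (3, 2):
            return -1 if label["template_is_successor"] else 1
        return 0
    if code == "nonrotated_preceding_upcoming":
        return -_classify("rotated_preceding", label)
    raise ContrastError(f"unknown code: {code!r}")


def predicted_matrix(code: str, heldout_path_id: str = "A") -> pd.DataFrame:
    """12-template x 3-stage predicted-similarity matrix for one held-out path.

    Entries: +1 where high similarity is predicted, -1 where low, 0 where
    the cell is omitted from the contrast.
    """
    heldout_path = PATHS[heldout_path_id]
    index = [f"{r.value}-{s.value}" for r, s in TEMPLATE_CELLS]
    mat = pd.DataFrame(
        0, index=index, columns=[f"stage{st}" for st in STAGES], dtype=int
    )
    for i, (ritual, schema) in enumerate(TEMPLATE_CELLS):
        for stage in STAGES:
            label = label_comparison(ritual, schema, heldout_path, stage)
            mat.iloc[i, STAGES.index(stage)] = _classify(code, label)
    return mat
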