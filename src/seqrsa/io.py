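"""Readers/writers for the pipeline's standard formats and the YAML config."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path as FilePath
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .design import PATHS, STAGES, Ritual, Schedule, Schema, WeddingDesign
from .simulate import GeneratorConfig, PatternDataset, default_layout

__all__ = [
    "IOError_",
    "RunConfig",
    "read_dataset",
    "read_events",
    "schedule_from_events",
    "load_config",
]

EVENT_COLUMNS = ["volume_index", "wedding_id", "stage", "schema", "path", "ritual"]


class IOError_(ValueError):
    """Validation failure while reading pipeline inputs."""


def read_events(path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise IOError_(f"{path}: events file missing columns {missing}")
    return events


def schedule_from_events(events: pd.DataFrame, day: int = 2) -> Schedule:
    """Reconstruct and validate the wedding schedule from an events sidecar."""
    weddings = []
    seen_positions = {}
    for wid, group in events.groupby("wedding_id", sort=False):
        schemas = group["schema"].unique()
        if len(schemas) != 1:
            raise IOError_(f"wedding {wid}: inconsistent schema labels {schemas}")
        try:
            schema = Schema(schemas[0])
        except ValueError:
            raise IOError_(f"wedding {wid}: unknown schema {schemas[0]!r}") from None
        path_ids = group["path"].unique()
        if len(path_ids) != 1 or path_ids[0] not in PATHS:
            raise IOError_(f"wedding {wid}: bad path labels {path_ids}")
        path = PATHS[path_ids[0]]
        if path.schema is not schema:
            raise IOError_(
                f"wedding {wid}: path {path.id} belongs to {path.schema.value}, "
                f"but schema column says {schema.value}"
            )
        stages = sorted(group["stage"].tolist())
        if stages != list(STAGES):
            raise IOError_(
                f"incomplete design: wedding {wid} has stages {stages}, "
                f"expected {list(STAGES)}"
            )
        for _, row in group.iterrows():
            try:
                ritual = Ritual(row["ritual"])
            except ValueError:
                raise IOError_(f"wedding {wid}: unknown ritual {row['ritual']!r}") from None
            if ritual.stage != row["stage"]:
                raise IOError_(
                    f"wedding {wid}: ritual {ritual.value} is a stage-{ritual.stage} "
                    f"ritual but is labeled stage {row['stage']}"
                )
            if path.ritual_at(int(row["stage"])) is not ritual:
                raise IOError_(
                    f"wedding {wid}: ritual {ritual.value} at stage {row['stage']} "
                    f"inconsistent with path {path.id}"
                )
        position = len(weddings)
        seen_positions[wid] = position
        weddings.append(WeddingDesign(int(wid), schema, path, position))
    if not weddings:
        raise IOError_("events file contains no weddings")
    return Schedule(day=day, weddings=tuple(weddings))


def read_dataset(data_dir) -> PatternDataset:
    """Load a dataset written by :func:`seqrsa.simulate.write_dataset`.

    Expects ``sub-*_patterns.nii.gz`` + ``sub-*_events.tsv`` pairs plus
    ``mask.nii.gz`` and optionally ``regions.nii.gz``.
    """
    data_dir = FilePath(data_dir)
    mask_path = data_dir / "mask.nii.gz"
    if not mask_path.exists():
        raise IOError_(f"missing mask file: {mask_path}")
    mask = np.asarray(nib.load(mask_path).dataobj).astype(bool)
    flat = np.flatnonzero(mask.ravel())

    regions = None
    regions_path = data_dir / "regions.nii.gz"
    if regions_path.exists():
        regions = np.asarray(nib.load(regions_path).dataobj).astype(np.int16)

    pattern_files = sorted(data_dir.glob("sub-*_patterns.nii.gz"))
    if not pattern_files:
        raise IOError_(f"no sub-*_patterns.nii.gz files in {data_dir}")

    schedule = None
    all_patterns = []
    for img_path in pattern_files:
        ev_path = data_dir / img_path.name.replace("_patterns.nii.gz", "_events.tsv")
        if not ev_path.exists():
            raise IOError_(f"missing events sidecar for {img_path.name}")
        events = read_events(ev_path)
        sched = schedule_from_events(events)
        if schedule is None:
            schedule = sched
        elif sched.to_frame().to_dict() != schedule.to_frame().to_dict():
            raise IOError_(f"{ev_path}: design differs across participants")

        vols = np.asarray(nib.load(img_path).dataobj, dtype=float)
        n_vols = vols.shape[-1]
        if n_vols != len(events):
            raise IOError_(
                f"{img_path.name}: {n_vols} volumes but {len(events)} event rows"
            )
        expected = len(schedule) * len(STAGES)
        if n_vols != expected:
            raise IOError_(
                f"{img_path.name}: expected {expected} volumes for "
                f"{len(schedule)} weddings x {len(STAGES)} stages, got {n_vols}"
            )
        vol_flat = vols.reshape(-1, n_vols)[flat]  # (V, n_vols)
        P = np.empty((len(schedule), len(STAGES), flat.size))
        for _, row in events.iterrows():
            wi = schedule.wedding_ids.index(int(row["wedding_id"]))
            si = STAGES.index(int(row["stage"]))
            P[wi, si] = vol_flat[:, int(row["volume_index"])]
        all_patterns.append(P)

    return PatternDataset(
        patterns=np.stack(all_patterns),
        schedule=schedule,
        mask=mask,
        region_labels=regions,
    )


@dataclass
class RunConfig:
    """Pipeline configuration loaded from YAML."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    q_thresh: float = 0.05
    p_liberal: float = 0.1
    min_members: int = 63
    n_perm: int = 1000
    seed: int = 0


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gen_raw = raw.pop("generator", {})
    layout = None
    if "grid_shape" in gen_raw:
        layout = default_layout(tuple(gen_raw.pop("grid_shape")))
    gen = GeneratorConfig(layout=layout, **gen_raw)
    known = {"q_thresh", "p_liberal", "min_members", "n_perm", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise IOError_(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(generator=gen, **raw)
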