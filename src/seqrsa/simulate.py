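"""Synthetic multivoxel patterns with planted codes and coupled behavior.

Patterns are generated directly at the stage level (one voxel vector per
ritual viewing), as an additive mixture of region-specific code components
plus i.i.d. Gaussian noise:

* region 1 carries a schema component (amplitude jittered per wedding),
* region 2 a path component,
* regions 3 and 4 a current-ritual component,
* regions 3 and 5 an *anticorrelated* copy of the immediately preceding
  ritual's vector at stages 3 and 4 (the rotated carry-over).

Basis vectors are drawn orthonormal within each region so the planted codes
do not leak into one another and expected contrast values are analytically
computable.  Behavior scores are coupled to the per-wedding schema
amplitude only, so brain-behavior nulls for the other codes hold by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path as FilePath
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .design import STAGES, Ritual, Schedule, Schema, make_schedule

__all__ = [
    "RegionLayout",
    "GeneratorConfig",
    "PatternDataset",
    "default_layout",
    "generate_patterns",
    "generate_behavior",
    "write_dataset",
    "GeneratorError",
]

REGION_NAMES = {
    0: "background",
    1: "schema",
    2: "path",
    3: "rotated+current",
    4: "current-only",
    5: "rotated-only",
}

SEARCHLIGHT_EDGE = 5  # 5x5x5 cube = radius 2 around the center


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class RegionLayout:
    """Integer region-label field over the voxel grid.

    Labels: 0 background, 1 schema, 2 path, 3 rotated+current,
    4 current-only, 5 rotated-only.  Every non-background region must
    contain at least one full searchlight cube.
    """

    region_labels: np.ndarray  # 3-D int array

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return self.region_labels.shape

    @property
    def labels_present(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.region_labels) if v != 0)

    def region_voxels(self, label: int, flat_index: np.ndarray) -> np.ndarray:
        """Column indices (into the in-mask voxel axis) of one region."""
        region_flat = np.flatnonzero(self.region_labels.ravel() == label)
        cols = np.searchsorted(flat_index, region_flat)
        if not np.array_equal(flat_index[cols], region_flat):
            raise GeneratorError(f"region {label} extends outside the mask")
        return cols

    def validate(self) -> None:
        labels = self.region_labels
        if labels.ndim != 3:
            raise GeneratorError("region labels must be a 3-D array")
        for label in self.labels_present:
            inside = (labels == label).astype(np.int8)
            # a full searchlight fits iff the binary erosion by a 5-cube
            # leaves at least one voxel
            fits = ndimage.minimum_filter(
                inside, size=SEARCHLIGHT_EDGE, mode="constant", cval=0
            )
            if not fits.any():
                raise GeneratorError(
                    f"region {label} ({REGION_NAMES.get(label, '?')}) too small: "
                    f"no full {SEARCHLIGHT_EDGE}^3 searchlight fits inside"
                )


def default_layout(shape: tuple[int, int, int] = (20, 20, 20)) -> RegionLayout:
    """Five disjoint 6x6x6 region blocks inside a background grid."""
    if min(shape) < 19:
        raise GeneratorError(f"grid {shape} too small for the default layout")
    labels = np.zeros(shape, dtype=np.int16)
    edge = 6
    blocks = {
        1: (1, 1, 1),
        2: (1, shape[1] - edge - 1, 1),
        3: (shape[0] - edge - 1, 1, 1),
        4: (shape[0] - edge - 1, shape[1] - edge - 1, 1),
        5: (shape[0] // 2 - edge // 2, shape[1] // 2 - edge // 2, shape[2] - edge - 1),
    }
    for label, (x, y, z) in blocks.items():
        labels[x : x + edge, y : y + edge, z : z + edge] = label
    layout = RegionLayout(labels)
    layout.validate()
    return layout


@dataclass(frozen=True)
class GeneratorConfig:
    n_participants: int = 10
    schedule: Optional[Schedule] = None
    layout: Optional[RegionLayout] = None
    # basis vectors are unit-norm over a whole region, so a beta of b gives
    # a per-voxel signal SD of b / sqrt(region size); the defaults put the
    # planted per-voxel signal on the order of the noise SD
    beta_schema: float = 5.0
    beta_path: float = 5.0
    beta_ritual: float = 5.0
    beta_rotated: float = 5.0
    # weak current-ritual component in the rotated-only region: the rotated
    # contrast measures anticorrelation between a carried trace and the
    # *current* representation of the same ritual, so a region with no
    # current-ritual signal at all would be blind to its own rotated code
    beta_current_leak: float = 1.0
    noise_sd: float = 0.5
    amplitude_jitter_sd: float = 0.5
    gamma_details: float = 2.0
    gamma_rituals: float = 2.0
    behavior_noise_sd: float = 1.0
    behavior_base: float = 5.0
    rotated_sign: int = -1  # -1 plants the anticorrelated carry-over; +1 the non-rotated variant
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 2:
            raise GeneratorError("need at least 2 participants")
        for name in ("beta_schema", "beta_path", "beta_ritual", "beta_rotated",
                     "beta_current_leak", "noise_sd", "amplitude_jitter_sd",
                     "behavior_noise_sd"):
            if getattr(self, name) < 0:
                raise GeneratorError(f"{name} must be nonnegative")
        if self.rotated_sign not in (-1, 1):
            raise GeneratorError("rotated_sign must be -1 or +1")

    def resolved(self) -> "GeneratorConfig":
        """Fill in default schedule/layout where unset."""
        out = self
        if out.schedule is None:
            out = replace(out, schedule=make_schedule(2, Schema.North, self.seed))
        if out.layout is None:
            out = replace(out, layout=default_layout())
        return out


@dataclass
class PatternDataset:
    """participant x wedding x stage voxel patterns plus design labels.

    ``patterns`` has shape (n_participants, n_weddings, 3, n_voxels) with
    voxels ordered by C-order flat index of the in-mask grid positions.
    """

    patterns: np.ndarray
    schedule: Schedule
    mask: np.ndarray  # 3-D bool
    region_labels: Optional[np.ndarray] = None
    amplitudes: Optional[np.ndarray] = None  # (P, W) schema-component amplitudes
    _wedding_pos: dict = field(init=False, repr=False)

    def __post_init__(self):
        P, W, S, V = self.patterns.shape
        if S != len(STAGES):
            raise GeneratorError(f"expected {len(STAGES)} stages, got {S}")
        if W != len(self.schedule):
            raise GeneratorError("pattern axis 1 does not match schedule length")
        if V != int(self.mask.sum()):
            raise GeneratorError("voxel axis does not match mask size")
        self._wedding_pos = {w.wedding_id: i for i, w in enumerate(self.schedule)}

    @property
    def n_participants(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_weddings(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[3]

    @property
    def flat_index(self) -> np.ndarray:
        """Flat grid indices of the in-mask voxels, in pattern-column order."""
        return np.flatnonzero(self.mask.ravel())

    @property
    def voxel_coords(self) -> np.ndarray:
        """(V, 3) integer grid coordinates of the in-mask voxels."""
        return np.argwhere(self.mask)

    def wedding_axis(self, wedding_id: int) -> int:
        return self._wedding_pos[wedding_id]

    def pattern(self, wedding_id: int, stage: int, participant: int = 0, voxels=None):
        vec = self.patterns[
            participant, self._wedding_pos[wedding_id], STAGES.index(stage)
        ]
        return vec if voxels is None else vec[voxels]

    def region_columns(self, label: int) -> np.ndarray:
        if self.region_labels is None:
            raise GeneratorError("dataset has no region labels")
        return RegionLayout(self.region_labels).region_voxels(label, self.flat_index)


def _orthonormal_vectors(n_voxels: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """(k, n_voxels) row-orthonormal basis from Gaussian draws."""
    if k > n_voxels:
        raise GeneratorError(f"cannot draw {k} orthonormal vectors in {n_voxels} voxels")
    q, r = np.linalg.qr(rng.standard_normal((n_voxels, k)))
    # fix signs for determinism across LAPACK builds
    q = q * np.sign(np.diag(r))
    return q.T


def generate_patterns(config: GeneratorConfig) -> PatternDataset:
    """Generate the additive-code pattern dataset; deterministic under seed."""
    config = config.resolved()
    layout = config.layout
    layout.validate()
    schedule = config.schedule
    mask = np.ones(layout.volume_shape, dtype=bool)
    flat_index = np.flatnonzero(mask.ravel())

    P = config.n_participants
    W = len(schedule)
    V = flat_index.size
    rng = np.random.default_rng(config.seed)

    region_cols = {
        label: layout.region_voxels(label, flat_index) for label in layout.labels_present
    }

    jitter = rng.normal(0.0, config.amplitude_jitter_sd, size=(P, W))
    amplitudes = np.maximum(0.0, 1.0 + jitter)

    patterns = rng.normal(0.0, config.noise_sd, size=(P, W, len(STAGES), V))

    schemas = list(Schema)
    rituals = list(Ritual)
    for p in range(P):
        basis = {}
        if 1 in region_cols:
            u = _orthonormal_vectors(len(region_cols[1]), 2, rng)
            basis["schema"] = {s: u[i] for i, s in enumerate(schemas)}
        if 2 in region_cols:
            u = _orthonormal_vectors(len(region_cols[2]), 4, rng)
            basis["path"] = {pid: u[i] for i, pid in enumerate("ABCD")}
        for label in (3, 4, 5):
            if label in region_cols:
                u = _orthonormal_vectors(len(region_cols[label]), len(rituals), rng)
                basis[f"ritual{label}"] = {r: u[i] for i, r in enumerate(rituals)}

        for wi, wedding in enumerate(schedule):
            for si, stage in enumerate(STAGES):
                vec = patterns[p, wi, si]
                ritual = wedding.ritual_at(stage)
                if "schema" in basis:
                    vec[region_cols[1]] += (
                        amplitudes[p, wi] * config.beta_schema
                        * basis["schema"][wedding.schema]
                    )
                if "path" in basis:
                    vec[region_cols[2]] += config.beta_path * basis["path"][wedding.path.id]
                for label in (3, 4):
                    if label in region_cols:
                        vec[region_cols[label]] += (
                            config.beta_ritual * basis[f"ritual{label}"][ritual]
                        )
                if 5 in region_cols:
                    vec[region_cols[5]] += (
                        config.beta_current_leak * basis["ritual5"][ritual]
                    )
                if stage >= 3:
                    preceding = wedding.ritual_at(stage - 1)
                    for label in (3, 5):
                        if label in region_cols:
                            vec[region_cols[label]] += (
                                config.rotated_sign * config.beta_rotated
                                * basis[f"ritual{label}"][preceding]
                            )

    return PatternDataset(
        patterns=patterns,
        schedule=schedule,
        mask=mask,
        region_labels=layout.region_labels,
        amplitudes=amplitudes,
    )


def generate_behavior(config: GeneratorConfig, data: PatternDataset) -> pd.DataFrame:
    """Per-wedding memory scores coupled to the schema-component amplitude.

    ``details_score`` and ``rituals_score`` are rounded to integers (they
    model correct-minus-incorrect annotation counts and may be negative).
    """
    if data.amplitudes is None:
        raise GeneratorError("dataset lacks schema amplitudes; regenerate patterns first")
    config = config.resolved()
    rng = np.random.default_rng([config.seed, 7919])
    P, W = data.amplitudes.shape
    noise_d = rng.normal(0.0, config.behavior_noise_sd, size=(P, W))
    noise_r = rng.normal(0.0, config.behavior_noise_sd, size=(P, W))
    details = np.round(
        config.behavior_base + config.gamma_details * data.amplitudes + noise_d
    ).astype(int)
    rituals = np.round(
        config.behavior_base + config.gamma_rituals * data.amplitudes + noise_r
    ).astype(int)
    rows = []
    ids = data.schedule.wedding_ids
    for p in range(P):
        for wi, wid in enumerate(ids):
            rows.append(
                {
                    "participant": p,
                    "wedding_id": wid,
                    "details_score": details[p, wi],
                    "rituals_score": rituals[p, wi],
                }
            )
    return pd.DataFrame(rows)


def _events_frame(schedule: Schedule) -> pd.DataFrame:
    rows = []
    vol = 0
    for w in schedule:
        for stage in STAGES:
            rows.append(
                {
                    "volume_index": vol,
                    "wedding_id": w.wedding_id,
                    "stage": stage,
                    "schema": w.schema.value,
                    "path": w.path.id,
                    "ritual": w.ritual_at(stage).value,
                }
            )
            vol += 1
    return pd.DataFrame(rows)


def write_dataset(data: PatternDataset, behavior: Optional[pd.DataFrame], out_dir) -> dict:
    """Write NIfTI/TSV artifacts for the dataset; returns the path map.

    Volumes are ordered wedding-major then stage ('sub-XX_patterns.nii.gz'
    has 3 x n_weddings volumes); the events sidecar documents the mapping.
    """
    import nibabel as nib

    out_dir = FilePath(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    shape = data.mask.shape
    paths: dict[str, object] = {"participants": []}

    mask_path = out_dir / "mask.nii.gz"
    nib.save(nib.Nifti1Image(data.mask.astype(np.uint8), affine), mask_path)
    paths["mask"] = mask_path

    if data.region_labels is not None:
        regions_path = out_dir / "regions.nii.gz"
        nib.save(nib.Nifti1Image(data.region_labels.astype(np.int16), affine), regions_path)
        paths["regions"] = regions_path

    events = _events_frame(data.schedule)
    flat = data.flat_index
    for p in range(data.n_participants):
        stem = f"sub-{p:02d}"
        vols = np.zeros(shape + (data.n_weddings * len(STAGES),), dtype=np.float64)
        vol_flat = vols.reshape(-1, vols.shape[-1])
        for wi in range(data.n_weddings):
            for si in range(len(STAGES)):
                vol_flat[flat, wi * len(STAGES) + si] = data.patterns[p, wi, si]
        img_path = out_dir / f"{stem}_patterns.nii.gz"
        nib.save(nib.Nifti1Image(vols, affine), img_path)
        ev_path = out_dir / f"{stem}_events.tsv"
        events.to_csv(ev_path, sep="\t", index=False)
        paths["participants"].append({"patterns": img_path, "events": ev_path})

    if behavior is not None:
        behavior_path = out_dir / "behavior.tsv"
        behavior.to_csv(behavior_path, sep="\t", index=False)
        paths["behavior"] = behavior_path
    return paths
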