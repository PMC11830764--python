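"""Cubic-searchlight contrast maps, group statistics, and the test battery.

The searchlight engine recomputes, inside every 5x5x5 voxel neighborhood,
the leave-one-wedding-out template correlations and turns them into code
scores via precomputed linear weights.  Group-level maps use one-sample
one-tailed t-tests with Benjamini-Hochberg FDR across retained centers;
conjunction/disjunction masks combine two maps.  Also here: the
Shapiro-Wilk-gated paired test with effect sizes, and JZS Bayes factors for
one-sample designs (Cauchy prior, default scale 0.707).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats
from statsmodels.stats.multitest import multipletests

from .contrasts import CODE_NAMES, weight_vector
from .design import STAGES, Schedule
from .rsa import TEMPLATE_CELLS, label_table

__all__ = [
    "Searchlight",
    "SearchlightResult",
    "StatMap",
    "RegionMask",
    "StatsError",
    "iter_searchlights",
    "run_searchlights",
    "group_map",
    "fdr_q",
    "significant_mask",
    "conjunction",
    "disjunction",
    "paired_contrast_test",
    "jzs_bf01",
    "jzs_bf01_from_t",
]

SEARCHLIGHT_RADIUS = 2  # Chebyshev radius: 5x5x5 cube
DEFAULT_MIN_MEMBERS = 63  # > half of a full 125-voxel cube


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class Searchlight:
    center: tuple[int, int, int]
    members: np.ndarray  # column indices into the in-mask voxel axis


def _column_grid(mask: np.ndarray) -> np.ndarray:
    """Grid of in-mask voxel column indices; -1 outside the mask."""
    cols = np.full(mask.shape, -1, dtype=np.int64)
    cols[mask] = np.arange(int(mask.sum()))
    return cols


def iter_searchlights(
    mask: np.ndarray, min_members: int = DEFAULT_MIN_MEMBERS
) -> list[Searchlight]:
    """All retained searchlights: cube-within-mask member sets per center.

    Centers are in-mask voxels whose 5x5x5 cube intersected with the mask
    has at least ``min_members`` voxels.
    """
    cols = _column_grid(mask)
    out = []
    r = SEARCHLIGHT_RADIUS
    for x, y, z in np.argwhere(mask):
        cube = cols[
            max(x - r, 0) : x + r + 1,
            max(y - r, 0) : y + r + 1,
            max(z - r, 0) : z + r + 1,
        ]
        members = cube[cube >= 0]
        if members.size >= min_members:
            out.append(Searchlight((int(x), int(y), int(z)), np.sort(members)))
    if not out:
        raise StatsError(
            f"no searchlight centers retained at min_members={min_members}"
        )
    return out


def _engine_tables(schedule: Schedule):
    """Static design arrays for the vectorized engine.

    Every leave-one-out template is a mean of stage patterns, so each
    template is a linear combination of the W*3 patterns with coefficient
    matrix ``A``; all Pearson correlations then follow from the pattern
    Gram matrix alone.  Returns (labels, A, K, M) where A is
    (W*12, W*3) and K/M map each of the W*36 label rows onto its
    (held-out-wedding x template-cell, held-out-pattern) index pair.
    """
    labels = label_table(schedule)
    W = len(schedule)
    S = len(STAGES)
    cell_index = {cell: i for i, cell in enumerate(TEMPLATE_CELLS)}
    pattern_cell = np.empty((W, S), dtype=int)
    for wi, wedding in enumerate(schedule):
        for si, stage in enumerate(STAGES):
            pattern_cell[wi, si] = cell_index[(wedding.ritual_at(stage), wedding.schema)]

    A = np.zeros((W, 12, W * S))
    for held in range(W):
        for c in range(12):
            members = [
                wi * S + si
                for wi in range(W)
                for si in range(S)
                if wi != held and pattern_cell[wi, si] == c
            ]
            if not members:
                ritual, schema = TEMPLATE_CELLS[c]
                raise StatsError(
                    f"unestimable template: cell ({ritual.value}, {schema.value}) "
                    f"is empty when wedding {schedule[held].wedding_id} is held out"
                )
            A[held, c, members] = 1.0 / len(members)
    A2 = A.reshape(W * 12, W * S)

    K = np.empty(W * 12 * S, dtype=int)
    M = np.empty(W * 12 * S, dtype=int)
    r = 0
    for held in range(W):
        for c in range(12):
            for si in range(S):
                K[r] = held * 12 + c
                M[r] = held * S + si
                r += 1
    return labels, A2, K, M


def _center_similarities(X: np.ndarray, A2: np.ndarray, K: np.ndarray, M: np.ndarray):
    """All W*36 template correlations for a batch of voxel subsets.

    X: (..., W*3, V) patterns restricted to one member set (leading axes are
    batch axes).  Returns sims with shape (..., W*36) in label-table order.
    """
    Xc = X - X.mean(axis=-1, keepdims=True)
    gram = Xc @ np.swapaxes(Xc, -1, -2)  # (..., W*3, W*3)
    AG = A2 @ gram  # centered template . centered pattern, (..., W*12, W*3)
    tnorm2 = np.einsum("...kn,kn->...k", AG, A2)  # template centered sq norms
    pnorm2 = np.diagonal(gram, axis1=-2, axis2=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = AG[..., K, M] / np.sqrt(tnorm2[..., K] * pnorm2[..., M])
    return sims


@dataclass
class SearchlightResult:
    """Per-center code scores: participant scope (P, N) and optionally
    wedding scope (P, W, N) arrays keyed by code name."""

    centers: np.ndarray  # (N, 3)
    codes: tuple[str, ...]
    participant_values: dict
    wedding_values: Optional[dict] = None
    wedding_ids: Optional[list] = None

    @property
    def n_centers(self) -> int:
        return self.centers.shape[0]


def run_searchlights(
    data,
    codes: Sequence[str] = CODE_NAMES,
    mask: Optional[np.ndarray] = None,
    min_members: int = DEFAULT_MIN_MEMBERS,
    wedding_scope: bool = False,
    searchlights: Optional[list[Searchlight]] = None,
) -> SearchlightResult:
    """Run every code contrast in every retained searchlight.

    ``mask`` restricts the *centers* (default: the dataset mask); member
    voxels always come from the dataset mask.  A precomputed searchlight
    list can be passed to skip geometry setup.
    """
    for code in codes:
        if code not in CODE_NAMES:
            raise StatsError(f"unknown code: {code!r}")
    if searchlights is None:
        center_mask = data.mask if mask is None else (mask & data.mask)
        searchlights = iter_searchlights(center_mask, min_members=min_members)
    labels, A2, K, M = _engine_tables(data.schedule)
    W = len(data.schedule)

    w_part = {code: weight_vector(code, labels) for code in codes}
    w_wed = {
        code: np.stack(
            [
                weight_vector(code, labels.iloc[b * 36 : (b + 1) * 36])
                for b in range(W)
            ]
        )
        for code in codes
    }  # (W, 36) each

    P = data.n_participants
    N = len(searchlights)
    part_vals = {code: np.empty((P, N)) for code in codes}
    wed_vals = {code: np.empty((P, W, N)) for code in codes} if wedding_scope else None

    # batch centers with equal member counts so the engine runs as a few
    # large matmuls instead of one small one per center
    by_size: dict[int, list[int]] = {}
    for j, sl in enumerate(searchlights):
        by_size.setdefault(sl.members.size, []).append(j)

    flat_patterns = data.patterns.reshape(P, W * 3, -1)
    chunk = max(1, int(2**23 // max(1, P * W * 3 * 125)))
    for size, idxs in by_size.items():
        for start in range(0, len(idxs), chunk):
            batch = idxs[start : start + chunk]
            members = np.stack([searchlights[j].members for j in batch])  # (B, size)
            X = flat_patterns[:, :, members]  # (P, W*3, B, size)
            X = np.moveaxis(X, 2, 0)  # (B, P, W*3, size)
            sims = _center_similarities(X, A2, K, M)  # (B, P, W*36)
            for code in codes:
                part_vals[code][:, batch] = (sims @ w_part[code]).T
                if wedding_scope:
                    blocks = sims.reshape(len(batch), P, W, 36)
                    wed_vals[code][:, :, batch] = np.moveaxis(
                        np.einsum("bpwk,wk->bpw", blocks, w_wed[code]), 0, 2
                    )

    return SearchlightResult(
        centers=np.array([sl.center for sl in searchlights]),
        codes=tuple(codes),
        participant_values=part_vals,
        wedding_values=wed_vals,
        wedding_ids=data.schedule.wedding_ids if wedding_scope else None,
    )


def fdr_q(p_values: np.ndarray, method: str = "fdr_bh") -> np.ndarray:
    """FDR q-values (Benjamini-Hochberg by default; 'fdr_by' available)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return p_values.copy()
    return multipletests(p_values, method=method)[1]


@dataclass
class StatMap:
    """Group statistics per retained searchlight center."""

    centers: np.ndarray  # (N, 3)
    mean: np.ndarray
    t: np.ndarray
    p: np.ndarray  # one-tailed
    q: np.ndarray  # BH-FDR over valid centers; NaN where invalid
    valid: np.ndarray  # zero-variance centers flagged False
    log_bf01: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "x": self.centers[:, 0],
                "y": self.centers[:, 1],
                "z": self.centers[:, 2],
                "mean": self.mean,
                "t": self.t,
                "p": self.p,
                "q": self.q,
                "valid": self.valid,
            }
        )
        if self.log_bf01 is not None:
            frame["log_bf01"] = self.log_bf01
        return frame


def group_map(
    values: np.ndarray,
    centers: np.ndarray,
    tail: str = "greater",
    fdr_method: str = "fdr_bh",
    with_bf: bool = False,
    cauchy_scale: float = 0.707,
) -> StatMap:
    """One-sample group t-map with one-tailed p and FDR q per center.

    ``values`` is (n_participants, n_centers).  Centers with zero variance
    across participants are flagged invalid and excluded from the FDR
    family rather than assigned p = 1.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 3:
        raise StatsError("need a (participants >= 3, centers) value matrix")
    if tail != "greater":
        raise StatsError("only tail='greater' is supported for group maps")
    P, N = values.shape
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    valid = sd > 0
    t = np.full(N, np.nan)
    p = np.full(N, np.nan)
    t[valid] = mean[valid] / (sd[valid] / np.sqrt(P))
    p[valid] = stats.t.sf(t[valid], df=P - 1)
    q = np.full(N, np.nan)
    if valid.any():
        q[valid] = fdr_q(p[valid], method=fdr_method)
    log_bf = None
    if with_bf:
        log_bf = np.full(N, np.nan)
        for j in np.flatnonzero(valid):
            log_bf[j] = np.log(
                jzs_bf01_from_t(t[j], P, tail="greater", cauchy_scale=cauchy_scale)
            )
    return StatMap(centers=np.asarray(centers), mean=mean, t=t, p=p, q=q,
                   valid=valid, log_bf01=log_bf)


@dataclass
class RegionMask:
    """A named subset of retained searchlight centers."""

    name: str
    centers: np.ndarray  # (N, 3) all retained centers
    keep: np.ndarray  # (N,) bool

    @property
    def selected_centers(self) -> np.ndarray:
        return self.centers[self.keep]

    @property
    def size(self) -> int:
        return int(self.keep.sum())


def _check_geometry(map_a: StatMap, map_b: StatMap) -> None:
    if map_a.centers.shape != map_b.centers.shape or not np.array_equal(
        map_a.centers, map_b.centers
    ):
        raise StatsError("stat maps have mismatched searchlight geometry")


def significant_mask(stat_map: StatMap, q_thresh: float = 0.05, name: str = "sig") -> RegionMask:
    keep = stat_map.valid & (stat_map.q < q_thresh)
    return RegionMask(name=name, centers=stat_map.centers, keep=keep)


def conjunction(
    map_a: StatMap, map_b: StatMap, q_thresh: float = 0.05, name: str = "conjunction"
) -> RegionMask:
    """Centers FDR-significant on both maps."""
    _check_geometry(map_a, map_b)
    keep = (
        map_a.valid & map_b.valid & (map_a.q < q_thresh) & (map_b.q < q_thresh)
    )
    return RegionMask(name=name, centers=map_a.centers, keep=keep)


def disjunction(
    map_primary: StatMap,
    map_excluded: StatMap,
    q_thresh: float = 0.05,
    p_liberal: float = 0.1,
    name: str = "disjunction",
) -> RegionMask:
    """Centers FDR-significant on the primary map but failing even a liberal
    uncorrected (one-tailed) threshold on the excluded map."""
    _check_geometry(map_primary, map_excluded)
    keep = (
        map_primary.valid
        & (map_primary.q < q_thresh)
        & map_excluded.valid
        & (map_excluded.p > p_liberal)
    )
    return RegionMask(name=name, centers=map_primary.centers, keep=keep)


def _rank_biserial_ci(rb: float, n: int, level: float = 0.95) -> tuple[float, float]:
    # normal-theory CI on the Fisher-z scale, as in standard practice for
    # the matched-pairs rank-biserial correlation
    se = np.sqrt(2.0 * (2.0 * n + 1.0) / (3.0 * n * (n + 1.0)))
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    z = np.arctanh(np.clip(rb, -1 + 1e-12, 1 - 1e-12))
    return float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))


def _cohens_d_ci(t_stat: float, n: int, level: float = 0.95) -> tuple[float, float]:
    # CI for d = t/sqrt(n) by inverting the noncentral t distribution
    lo_p, hi_p = 0.5 + level / 2.0, 0.5 - level / 2.0
    df = n - 1

    def bound(target):
        def f(ncp):
            val = stats.nct.cdf(t_stat, df, ncp)
            if np.isnan(val):  # far tails underflow inside scipy
                val = 0.0 if ncp > t_stat else 1.0
            return val - target

        lo, hi = t_stat - 30.0, t_stat + 30.0
        if f(lo) * f(hi) > 0:
            return np.sign(t_stat) * np.inf
        return optimize.brentq(f, lo, hi, xtol=1e-8)

    return bound(lo_p) / np.sqrt(n), bound(hi_p) / np.sqrt(n)


def paired_contrast_test(
    cond_a: np.ndarray, cond_b: np.ndarray, normality_alpha: float = 0.05
) -> dict:
    """Two-tailed paired test, Shapiro-Wilk-gated between t and Wilcoxon.

    Returns a dict with the chosen test, statistic, two-tailed p, effect
    size (Cohen's d for t, matched-pairs rank-biserial for Wilcoxon) and
    its 95% CI.  The Wilcoxon statistic reported is the sum of positive
    ranks.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 5:
        raise StatsError("need paired 1-D samples with n >= 5")
    d = a - b
    if np.allclose(d, d[0]):
        raise StatsError("degenerate input: all paired differences identical")
    n = d.size
    sw_p = stats.shapiro(d).pvalue
    if sw_p >= normality_alpha:
        t_stat, p = stats.ttest_rel(a, b)
        eff = float(d.mean() / d.std(ddof=1))
        ci = _cohens_d_ci(float(t_stat), n)
        return {
            "test": "t",
            "statistic": float(t_stat),
            "p_two_tailed": float(p),
            "shapiro_p": float(sw_p),
            "effect": "cohens_d",
            "effect_size": eff,
            "ci95": ci,
            "n": n,
        }
    nz = d[d != 0]
    ranks = stats.rankdata(np.abs(nz))
    w_pos = float(ranks[nz > 0].sum())
    w_neg = float(ranks[nz < 0].sum())
    total = w_pos + w_neg
    rb = (w_pos - w_neg) / total
    p = float(stats.wilcoxon(nz).pvalue)
    return {
        "test": "wilcoxon",
        "statistic": w_pos,
        "p_two_tailed": p,
        "shapiro_p": float(sw_p),
        "effect": "rank_biserial",
        "effect_size": float(rb),
        "ci95": _rank_biserial_ci(rb, nz.size),
        "n": n,
    }


def jzs_bf01_from_t(
    t_stat: float, n: int, tail: str = "greater", cauchy_scale: float = 0.707
) -> float:
    """JZS Bayes factor BF-01 for a one-sample t statistic.

    The marginal likelihood under H1 integrates the noncentral-t likelihood
    over a Cauchy(0, scale) prior on the standardized effect (half-Cauchy on
    the positive axis when ``tail='greater'``).
    """
    if n < 3:
        raise StatsError("need n >= 3 for a Bayes factor")
    nu = n - 1
    sqrt_n = np.sqrt(n)
    m0 = stats.t.pdf(t_stat, nu)

    def integrand(delta):
        return stats.nct.pdf(t_stat, nu, delta * sqrt_n) * stats.cauchy.pdf(
            delta, scale=cauchy_scale
        )

    if tail == "greater":
        m1, err = integrate.quad(
            lambda dlt: 2.0 * integrand(dlt), 0, np.inf, limit=200
        )
    elif tail == "two_sided":
        m1_neg, e1 = integrate.quad(integrand, -np.inf, 0, limit=200)
        m1_pos, e2 = integrate.quad(integrand, 0, np.inf, limit=200)
        m1, err = m1_neg + m1_pos, e1 + e2
    else:
        raise StatsError(f"tail must be 'greater' or 'two_sided', got {tail!r}")
    if not np.isfinite(m1) or m1 <= 0 or err > max(1e-8, 1e-4 * m1):
        raise StatsError(f"JZS integral did not converge (m1={m1}, err={err})")
    return float(m0 / m1)


def jzs_bf01(
    values: np.ndarray, tail: str = "greater", cauchy_scale: float = 0.707
) -> float:
    """BF-01 for a one-sample design on per-participant scores."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 3:
        raise StatsError("need >= 3 per-participant values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise StatsError("degenerate input: zero variance")
    t_stat = values.mean() / (sd / np.sqrt(values.size))
    return jzs_bf01_from_t(t_stat, values.size, tail=tail, cauchy_scale=cauchy_scale)
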