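"""Per-wedding code strengths, behavioral scoring, and the permutation
brain-behavior test.

Neural strength of a code in a region = the wedding-scope contrast averaged
over the region's searchlight centers.  The test correlates strengths with
memory scores across weddings within each participant (Spearman), averages
the correlations, and compares the mean against a null built by shuffling
the behavior scores within participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .searchlight import RegionMask, iter_searchlights, jzs_bf01, run_searchlights

__all__ = [
    "BehaviorError",
    "BrainBehaviorResult",
    "per_wedding_strengths",
    "correlate",
    "permutation_test",
    "fisherz_bf",
    "memory_scores",
    "schema_test_score",
]


class BehaviorError(ValueError):
    pass


@dataclass
class BrainBehaviorResult:
    code: str
    measure: str
    r_mean: float
    sem: float
    rhos: np.ndarray  # per participant
    p_perm: float
    n_perm: int
    seed: int
    bf01: float | None = None


def per_wedding_strengths(
    data, region: RegionMask, code: str, min_members: int = 63
) -> pd.DataFrame:
    """participant x wedding strength matrix for a code within a region.

    Strength = unweighted mean over the region's searchlight centers of the
    wedding-scope contrast at that center.
    """
    if region.size == 0:
        raise BehaviorError(f"region {region.name!r} is empty")
    all_sls = iter_searchlights(data.mask, min_members=min_members)
    by_center = {sl.center: sl for sl in all_sls}
    selected = []
    for c in map(tuple, region.selected_centers):
        if c not in by_center:
            raise BehaviorError(f"region center {c} is not a retained searchlight")
        selected.append(by_center[c])
    result = run_searchlights(
        data, codes=[code], wedding_scope=True, searchlights=selected
    )
    values = result.wedding_values[code].mean(axis=2)  # (P, W)
    return pd.DataFrame(
        values,
        index=pd.RangeIndex(data.n_participants, name="participant"),
        columns=pd.Index(result.wedding_ids, name="wedding_id"),
    )


def _aligned_matrices(
    strengths: pd.DataFrame, behavior: pd.DataFrame, measure: str
) -> tuple[np.ndarray, np.ndarray]:
    if measure not in behavior.columns:
        raise BehaviorError(f"unknown behavior measure {measure!r}")
    pivot = behavior.pivot(index="participant", columns="wedding_id", values=measure)
    pivot = pivot.reindex(index=strengths.index, columns=strengths.columns)
    if pivot.isna().any().any():
        raise BehaviorError("behavior table does not cover all participants x weddings")
    return strengths.to_numpy(dtype=float), pivot.to_numpy(dtype=float)


def _per_participant_rhos(s: np.ndarray, b: np.ndarray) -> np.ndarray:
    P, W = s.shape
    if W < 3:
        raise BehaviorError("need at least 3 weddings per participant")
    rhos = np.empty(P)
    for p in range(P):
        if np.all(s[p] == s[p, 0]):
            raise BehaviorError(f"constant neural strengths for participant {p}")
        if np.all(b[p] == b[p, 0]):
            raise BehaviorError(f"constant behavior scores for participant {p}")
        rhos[p] = stats.spearmanr(s[p], b[p]).statistic
    return rhos


def _sem(values: np.ndarray) -> float:
    return float(stats.sem(values)) if values.size > 1 else float("nan")


def correlate(
    strengths: pd.DataFrame, behavior: pd.DataFrame, measure: str = "details_score"
) -> tuple[np.ndarray, float, float]:
    """Within-participant Spearman rho per participant, plus mean and SEM."""
    s, b = _aligned_matrices(strengths, behavior, measure)
    rhos = _per_participant_rhos(s, b)
    return rhos, float(rhos.mean()), _sem(rhos)


def permutation_test(
    strengths: pd.DataFrame,
    behavior: pd.DataFrame,
    measure: str = "details_score",
    n_perm: int = 1000,
    seed: int = 0,
    add_one: bool = False,
    code: str = "",
) -> BrainBehaviorResult:
    """One-tailed permutation test of the mean within-participant correlation.

    Each permutation shuffles behavior scores across weddings independently
    within every participant; p = proportion of null mean correlations at or
    above the observed mean (``add_one`` switches to (k+1)/(n+1)).
    """
    s, b = _aligned_matrices(strengths, behavior, measure)
    rhos = _per_participant_rhos(s, b)
    observed = rhos.mean()
    rng = np.random.default_rng(seed)
    P, W = s.shape

    # Spearman = Pearson on ranks; pre-rank both sides once so each
    # permutation is a cheap vectorized correlation of rank rows.
    sr = stats.rankdata(s, axis=1)
    br = stats.rankdata(b, axis=1)

    def rank_corr(x, y):
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(xc, axis=1) * np.linalg.norm(yc, axis=1)
        return (xc * yc).sum(axis=1) / denom

    null_means = np.empty(n_perm)
    for i in range(n_perm):
        perm = np.argsort(rng.random((P, W)), axis=1)
        null_means[i] = rank_corr(sr, np.take_along_axis(br, perm, axis=1)).mean()

    k = int((null_means >= observed).sum())
    p_perm = (k + 1) / (n_perm + 1) if add_one else k / n_perm
    return BrainBehaviorResult(
        code=code,
        measure=measure,
        r_mean=float(observed),
        sem=_sem(rhos),
        rhos=rhos,
        p_perm=float(p_perm),
        n_perm=n_perm,
        seed=seed,
    )


def fisherz_bf(
    rhos: np.ndarray, cauchy_scale: float = 0.707, clip: float | None = None
) -> float:
    """BF-01 from a one-tailed one-sample Bayesian t-test on Fisher-Z rhos."""
    rhos = np.asarray(rhos, dtype=float)
    if np.any(np.abs(rhos) >= 1):
        if clip is None:
            raise BehaviorError(
                "|rho| = 1 transforms to infinity; pass clip=<1 to truncate"
            )
        rhos = np.clip(rhos, -clip, clip)
    return jzs_bf01(np.arctanh(rhos), tail="greater", cauchy_scale=cauchy_scale)


def memory_scores(annotations: pd.DataFrame) -> pd.DataFrame:
    """Correct-minus-incorrect details and rituals scores per wedding.

    Expects columns participant, wedding_id, correct_details,
    incorrect_details, correct_rituals, incorrect_rituals.
    """
    required = [
        "participant",
        "wedding_id",
        "correct_details",
        "incorrect_details",
        "correct_rituals",
        "incorrect_rituals",
    ]
    missing = [c for c in required if c not in annotations.columns]
    if missing:
        raise BehaviorError(f"annotation table missing columns: {missing}")
    counts = annotations[required[2:]]
    if (counts.to_numpy() < 0).any():
        raise BehaviorError("annotation counts must be nonnegative")
    out = annotations[["participant", "wedding_id"]].copy()
    out["details_score"] = annotations["correct_details"] - annotations["incorrect_details"]
    out["rituals_score"] = annotations["correct_rituals"] - annotations["incorrect_rituals"]
    return out


def schema_test_score(allocations: pd.DataFrame) -> tuple[float, float, float]:
    """Mean percentage allocated to correct / opposite / other options.

    ``allocations`` has one row per question with columns ``correct``,
    ``opposite``, and ``other`` columns for the remaining four options (any
    column names besides correct/opposite are treated as 'other').  Each
    row must sum to 100.  The 'other' average is divided by 4 (it pools
    four of the six answer options).
    """
    if "correct" not in allocations.columns or "opposite" not in allocations.columns:
        raise BehaviorError("allocations need 'correct' and 'opposite' columns")
    numeric = allocations.select_dtypes("number")
    sums = numeric.sum(axis=1)
    if not np.allclose(sums, 100.0, atol=0.01):
        bad = sums[~np.isclose(sums, 100.0, atol=0.01)]
        raise BehaviorError(f"allocations must sum to 100 per question; got {bad.to_dict()}")
    other_cols = [c for c in numeric.columns if c not in ("correct", "opposite")]
    pct_correct = float(numeric["correct"].mean())
    pct_opposite = float(numeric["opposite"].mean())
    pct_other = float(numeric[other_cols].sum(axis=1).mean() / 4.0) if other_cols else 0.0
    return pct_correct, pct_opposite, pct_other
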