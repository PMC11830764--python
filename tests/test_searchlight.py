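import numpy as np
import pytest
from scipy import stats

from seqrsa.contrasts import CODE_NAMES, score_table
from seqrsa.rsa import compare_all
from seqrsa.searchlight import (
    StatMap,
    StatsError,
    conjunction,
    disjunction,
    fdr_q,
    group_map,
    iter_searchlights,
    jzs_bf01,
    jzs_bf01_from_t,
    paired_contrast_test,
    run_searchlights,
    significant_mask,
)
from tests.conftest import center_region_labels


# ---------------------------------------------------------------- geometry
class TestSearchlightGeometry:
    def test_full_cube_interior_counts(self):
        mask = np.ones((7, 7, 7), dtype=bool)
        sls = iter_searchlights(mask, min_members=125)
        assert len(sls) == 27  # the 3x3x3 interior
        assert all(sl.members.size == 125 for sl in sls)

    def test_corner_membership(self):
        mask = np.ones((7, 7, 7), dtype=bool)
        sls = {sl.center: sl for sl in iter_searchlights(mask, min_members=1)}
        assert sls[(0, 0, 0)].members.size == 27  # 3x3x3 clipped cube

    def test_min_members_filter(self):
        mask = np.ones((7, 7, 7), dtype=bool)
        sls = iter_searchlights(mask, min_members=63)
        assert all(sl.members.size >= 63 for sl in sls)
        assert (0, 0, 0) not in {sl.center for sl in sls}

    def test_no_centers_raises(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        with pytest.raises(StatsError, match="no searchlight"):
            iter_searchlights(mask, min_members=63)

    def test_members_match_brute_force_on_random_masks(self, rng):
        for _ in range(5):
            mask = rng.random((8, 8, 8)) < 0.7
            if not mask.any():
                continue
            coords = np.argwhere(mask)
            col_of = {tuple(c): i for i, c in enumerate(coords)}
            try:
                sls = iter_searchlights(mask, min_members=10)
            except StatsError:
                continue
            for sl in sls[:20]:
                cx, cy, cz = sl.center
                expected = sorted(
                    col_of[(x, y, z)]
                    for (x, y, z) in map(tuple, coords)
                    if abs(x - cx) <= 2 and abs(y - cy) <= 2 and abs(z - cz) <= 2
                )
                assert list(sl.members) == expected


# ---------------------------------------------------------------- engine
class TestEngineEquivalence:
    def test_engine_matches_reference_scores(self, toy_dataset):
        sls = iter_searchlights(toy_dataset.mask, min_members=3)
        res = run_searchlights(
            toy_dataset, searchlights=sls[:2], wedding_scope=True
        )
        for j, sl in enumerate(sls[:2]):
            table = compare_all(toy_dataset, voxels=sl.members)
            for code in CODE_NAMES:
                ref = score_table(table, code, scope="participant")["value"].to_numpy()
                np.testing.assert_allclose(
                    res.participant_values[code][:, j], ref, atol=1e-12
                )
                refw = (
                    score_table(table, code, scope="wedding")
                    .sort_values(["participant", "wedding_id"])["value"]
                    .to_numpy()
                    .reshape(toy_dataset.n_participants, -1)
                )
                np.testing.assert_allclose(
                    res.wedding_values[code][:, :, j], refw, atol=1e-12
                )

    def test_unknown_code_rejected(self, toy_dataset):
        with pytest.raises(StatsError):
            run_searchlights(toy_dataset, codes=["nope"])

    def test_planted_schema_peak_in_own_region(self, planted_dataset):
        _, data = planted_dataset
        res = run_searchlights(data, codes=["schema"])
        gm = group_map(res.participant_values["schema"], res.centers)
        labels = center_region_labels(data, res.centers)
        assert labels[np.argmax(gm.mean)] == 1


# ---------------------------------------------------------------- group stats
class TestGroupMap:
    def test_all_zero_values_flagged_invalid(self):
        values = np.zeros((5, 10))
        centers = np.zeros((10, 3), dtype=int)
        gm = group_map(values, centers)
        assert not gm.valid.any()
        assert not (gm.q < 0.05).any()

    def test_zero_variance_center_excluded_from_family(self, rng):
        values = rng.standard_normal((6, 8))
        values[:, 3] = 1.0  # constant across participants
        gm = group_map(values, np.zeros((8, 3), dtype=int))
        assert not gm.valid[3]
        assert np.isnan(gm.q[3])
        assert np.isfinite(gm.q[gm.valid]).all()

    def test_one_tailed_p(self, rng):
        values = rng.standard_normal((10, 50)) + 3.0
        gm = group_map(values, np.zeros((50, 3), dtype=int))
        assert (gm.p[gm.valid] < 0.5).all()

    def test_needs_three_participants(self):
        with pytest.raises(StatsError):
            group_map(np.zeros((2, 4)), np.zeros((4, 3)))

    def test_type_one_error_calibration(self, rng):
        # one-tailed group test at null centers rejects at ~alpha
        values = rng.standard_normal((10, 4000))
        gm = group_map(values, np.zeros((4000, 3), dtype=int))
        rate = (gm.p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 4000)
        assert abs(rate - 0.05) < 3 * se + 0.005

    def test_t_matches_scipy(self, rng):
        values = rng.standard_normal((8, 20))
        gm = group_map(values, np.zeros((20, 3), dtype=int))
        ref = stats.ttest_1samp(values, 0.0, alternative="greater")
        np.testing.assert_allclose(gm.t, ref.statistic, atol=1e-12)
        np.testing.assert_allclose(gm.p, ref.pvalue, atol=1e-12)


def _bh_oracle(p):
    """Textbook Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestFdr:
    def test_hand_pvalues(self):
        p = np.array([0.001, 0.01, 0.02, 0.2, 0.9])
        expected = np.array([0.005, 0.025, 1 / 30, 0.25, 0.9])
        np.testing.assert_allclose(fdr_q(p), expected, atol=1e-12)
        np.testing.assert_allclose(_bh_oracle(p), expected, atol=1e-12)

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(1, 60))
            np.testing.assert_allclose(fdr_q(p), _bh_oracle(p), atol=1e-12)

    def test_q_monotone_in_p(self, rng):
        p = rng.random(100)
        q = fdr_q(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_null_false_discovery_control(self, rng):
        # under the global null BH rejects anything at all in <= ~alpha of runs
        hits = 0
        reps = 400
        for _ in range(reps):
            q = fdr_q(rng.random(200))
            hits += (q < 0.05).any()
        rate = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rate < 0.05 + 3 * se


# ---------------------------------------------------------------- masks
def _fake_map(p_values, q_values=None):
    p = np.asarray(p_values, dtype=float)
    q = fdr_q(p) if q_values is None else np.asarray(q_values, dtype=float)
    n = p.size
    centers = np.stack([np.arange(n)] * 3, axis=1)
    return StatMap(
        centers=centers, mean=np.zeros(n), t=np.zeros(n), p=p, q=q,
        valid=np.ones(n, dtype=bool),
    )


class TestConjunctionDisjunction:
    def test_disjoint_significant_sets_empty_conjunction(self):
        a = _fake_map([0.0001] * 3 + [0.5] * 3)
        b = _fake_map([0.5] * 3 + [0.0001] * 3)
        assert conjunction(a, b).size == 0

    def test_all_nonsignificant_b_empty(self):
        a = _fake_map([1e-6] * 6)
        b = _fake_map([0.9] * 6)
        assert conjunction(a, b).size == 0

    def test_conjunction_intersection(self):
        a = _fake_map([1e-6, 1e-6, 0.9, 0.9])
        b = _fake_map([1e-6, 0.9, 1e-6, 0.9])
        mask = conjunction(a, b)
        assert mask.size == 1
        assert tuple(mask.selected_centers[0]) == (0, 0, 0)

    def test_disjunction_liberal_threshold(self):
        primary = _fake_map([1e-6, 1e-6, 0.9])
        excluded = _fake_map([0.05, 0.5, 0.5])  # p=0.05 fails "above 0.1"
        mask = disjunction(primary, excluded)
        assert mask.size == 1
        assert tuple(mask.selected_centers[0]) == (1, 1, 1)

    def test_excluded_everywhere_significant_empty(self):
        primary = _fake_map([1e-6] * 4)
        excluded = _fake_map([1e-6] * 4)
        assert disjunction(primary, excluded).size == 0

    def test_primary_empty_gives_empty(self):
        primary = _fake_map([0.9] * 4)
        excluded = _fake_map([0.9] * 4)
        assert disjunction(primary, excluded).size == 0

    def test_geometry_mismatch_raises(self):
        a = _fake_map([0.5] * 4)
        b = _fake_map([0.5] * 5)
        with pytest.raises(StatsError, match="geometry"):
            conjunction(a, b)

    def test_significant_mask_subset(self):
        a = _fake_map([1e-6, 0.2, 1e-6])
        mask = significant_mask(a)
        assert mask.size == 2
        assert mask.keep.tolist() == [True, False, True]


# ---------------------------------------------------------------- paired tests
class TestPairedContrastTest:
    def test_forced_wilcoxon_all_positive(self):
        # heavy-tailed differences force the normality gate to Wilcoxon
        b = np.zeros(5)
        a = np.array([1.0, 1.0, 1.0, 2.0, 100.0])
        res = paired_contrast_test(a, b)
        assert res["test"] == "wilcoxon"
        assert res["statistic"] == 15.0  # all 5 ranks positive
        assert res["effect"] == "rank_biserial"
        assert res["effect_size"] == pytest.approx(1.0)

    def test_constant_shift_degenerate(self):
        b = np.arange(8.0)
        with pytest.raises(StatsError, match="degenerate"):
            paired_contrast_test(b + 1.0, b)

    def test_gaussian_differences_choose_t(self, rng):
        chose_t = 0
        covered = 0
        for _ in range(20):
            d = rng.standard_normal(40) + 1.0  # true effect size d = 1
            res = paired_contrast_test(d, np.zeros(40))
            if res["test"] == "t":
                chose_t += 1
                lo, hi = res["ci95"]
                assert lo < res["effect_size"] < hi
                covered += lo <= 1.0 <= hi
        assert chose_t >= 15
        assert covered >= chose_t - 3  # ~95% CI coverage

    def test_t_branch_matches_scipy(self, rng):
        a = rng.standard_normal(30)
        b = rng.standard_normal(30)
        res = paired_contrast_test(a, b)
        if res["test"] == "t":
            t_ref, p_ref = stats.ttest_rel(a, b)
            assert res["statistic"] == pytest.approx(t_ref)
            assert res["p_two_tailed"] == pytest.approx(p_ref)

    def test_small_sample_rejected(self):
        with pytest.raises(StatsError):
            paired_contrast_test(np.ones(3), np.zeros(3))


# ---------------------------------------------------------------- Bayes factors
def _chi_pdf_w(w, nu):
    # density of W = sqrt(chi2_nu / nu)
    return 2.0 * nu * w * stats.chi2.pdf(nu * w * w, nu)


def _nct_pdf_oracle(t, nu, mu, w_grid):
    # noncentral t density via its scale-mixture definition T = (Z+mu)/W
    fw = _chi_pdf_w(w_grid, nu)
    vals = w_grid * stats.norm.pdf(t * w_grid - mu) * fw
    return np.trapezoid(vals, w_grid)


def _jzs_bf01_oracle(t, n, tail, r=0.707):
    """Independent brute-force quadrature on fixed grids."""
    nu = n - 1
    w_grid = np.linspace(1e-6, 4.0, 4001)
    if tail == "greater":
        delta = np.linspace(1e-6, 40.0, 8001)
        prior = 2.0 * stats.cauchy.pdf(delta, scale=r)
    else:
        delta = np.linspace(-40.0, 40.0, 16001)
        prior = stats.cauchy.pdf(delta, scale=r)
    lik = np.array([_nct_pdf_oracle(t, nu, d * np.sqrt(n), w_grid) for d in delta])
    m1 = np.trapezoid(lik * prior, delta)
    m0 = stats.t.pdf(t, nu)
    return m0 / m1


class TestJzsBayesFactor:
    def test_null_t_favors_null(self):
        assert jzs_bf01_from_t(0.0, 20, tail="greater") > 1.0
        assert jzs_bf01_from_t(0.0, 20, tail="two_sided") > 1.0

    def test_huge_t_favors_alternative(self):
        assert jzs_bf01_from_t(6.0, 40, tail="greater") < 1e-3

    def test_matches_quadrature_oracle(self):
        for t, n in [(0.5, 10), (2.0, 25), (-1.0, 15), (3.5, 40)]:
            for tail in ("greater", "two_sided"):
                ours = jzs_bf01_from_t(t, n, tail=tail)
                oracle = _jzs_bf01_oracle(t, n, tail)
                assert ours == pytest.approx(oracle, rel=1e-4), (t, n, tail)

    def test_values_interface(self, rng):
        x = rng.standard_normal(20) * 0.1
        bf = jzs_bf01(x, tail="greater")
        t_stat = x.mean() / (x.std(ddof=1) / np.sqrt(20))
        assert bf == pytest.approx(jzs_bf01_from_t(t_stat, 20, tail="greater"))

    def test_degenerate_rejected(self):
        with pytest.raises(StatsError):
            jzs_bf01(np.ones(10))
        with pytest.raises(StatsError):
            jzs_bf01(np.array([1.0, 2.0]))

    def test_bad_tail_rejected(self):
        with pytest.raises(StatsError):
            jzs_bf01_from_t(1.0, 10, tail="less")
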