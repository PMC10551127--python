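import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connectoperm import ValidationError, bh_fdr, glm_tstat, make_design, maxstat_pvalues
from connectoperm.perm_glm import DesignMatrix, family_test, freedman_lane_permute


def _group_design(groups):
    groups = np.asarray(groups, dtype=float)
    return DesignMatrix(
        X=np.column_stack([np.ones(len(groups)), groups]),
        columns=("intercept", "group"),
        contrast=1,
        subject_ids=tuple(f"s{i}" for i in range(len(groups))),
    )


class TestGlmTstat:
    def test_matches_pooled_two_sample_t(self):
        # groups {1,2,3} vs {4,5,6}: mean diff 3, pooled SD 1, SE = sqrt(2/3)
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        design = _group_design([1, 1, 1, 0, 0, 0])
        t = glm_tstat(y, design)
        assert abs(t) == pytest.approx(3.0 / np.sqrt(2 / 3), abs=1e-10)
        assert t < 0  # group-coded subjects have the smaller mean

    def test_constant_outcome_gives_zero(self):
        design = _group_design([1, 1, 0, 0])
        assert glm_tstat(np.full(4, 7.0), design) == 0.0

    def test_orthogonal_covariate_changes_t_only_through_df(self, rng):
        n = 24
        g = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        y = rng.standard_normal(n) + 0.8 * g
        base = _group_design(g)
        t1 = glm_tstat(y, base)
        # build a covariate orthogonal to intercept, group and y
        q, _ = np.linalg.qr(np.column_stack([np.ones(n), g, y, rng.standard_normal(n)]))
        z = q[:, 3]
        with_cov = DesignMatrix(
            X=np.column_stack([np.ones(n), g, z]),
            columns=("intercept", "group", "z"),
            contrast=1,
            subject_ids=base.subject_ids,
        )
        t2 = glm_tstat(y, with_cov)
        assert t2 == pytest.approx(t1 * np.sqrt(with_cov.df_resid / base.df_resid), rel=1e-10)

    def test_rank_deficiency_names_columns(self):
        n = 8
        g = np.r_[np.ones(4), np.zeros(4)]
        with pytest.raises(ValidationError, match="collinear"):
            DesignMatrix(
                X=np.column_stack([np.ones(n), g, 2 * g]),
                columns=("intercept", "group", "group_copy"),
                contrast=1,
                subject_ids=tuple(str(i) for i in range(n)),
            )


class TestMakeDesign:
    def test_design_columns_and_contrast(self, small_cohort):
        _, pheno, _ = small_cohort
        design = make_design(pheno)
        assert design.columns == (
            "intercept", "group", "age", "sex", "mean_fd", "cortex_volume",
        )
        assert design.X[:, design.contrast].sum() == pheno.n_patients


class TestFreedmanLane:
    def test_null_mean_near_zero(self, rng):
        n, n_perm = 30, 500
        g = rng.permutation(np.r_[np.ones(15), np.zeros(15)])
        design = _group_design(g)
        y = rng.standard_normal((n, 1))
        _, null = freedman_lane_permute(y, design, n_perm, seed=3)
        assert abs(null.mean()) < 3 * null.std() / np.sqrt(n_perm)

    def test_identical_seed_identical_null(self, rng):
        design = _group_design(np.r_[np.ones(5), np.zeros(5)])
        y = rng.standard_normal((10, 3))
        _, null1 = freedman_lane_permute(y, design, 50, seed=11)
        _, null2 = freedman_lane_permute(y, design, 50, seed=11)
        np.testing.assert_array_equal(null1, null2)

    def test_nuisance_free_reduces_to_label_permutation(self, rng):
        """With intercept-only nuisance, Freedman-Lane equals permuting y."""
        n = 10
        g = np.r_[np.ones(5), np.zeros(5)]
        design = _group_design(g)
        y = rng.standard_normal(n)
        n_perm = 20
        _, null = freedman_lane_permute(y[:, None], design, n_perm, seed=5)
        perm_rng = np.random.default_rng(5)
        expected = [
            glm_tstat(y[perm_rng.permutation(n)], design) for _ in range(n_perm)
        ]
        np.testing.assert_allclose(null[:, 0], expected, atol=1e-10)

    def test_covariate_effect_does_not_inflate_null(self, rng):
        """Strong covariate signal, no group effect: null t stays centred."""
        n = 40
        g = rng.permutation(np.r_[np.ones(20), np.zeros(20)])
        z = rng.standard_normal(n)
        y = 3.0 * z + rng.standard_normal(n)
        design = DesignMatrix(
            X=np.column_stack([np.ones(n), g, z]),
            columns=("intercept", "group", "z"),
            contrast=1,
            subject_ids=tuple(str(i) for i in range(n)),
        )
        obs, null = freedman_lane_permute(y[:, None], design, 1000, seed=8)
        p = (1 + (np.abs(null) >= abs(obs[0])).sum()) / 1001
        assert p > 0.01  # no spurious group effect


class TestMaxstat:
    def test_boundary_p_with_add_one(self):
        observed = np.array([10.0])
        null = np.abs(np.random.default_rng(0).standard_normal((10_000, 1)))
        res = maxstat_pvalues(observed, null, ["m"])
        assert res.table["p_corr"].iloc[0] == pytest.approx(1 / 10_001)

    def test_null_median_gives_half(self, rng):
        null = rng.standard_normal((2000, 1))
        observed = np.array([np.median(np.abs(null))])
        res = maxstat_pvalues(observed, null, ["m"])
        assert res.table["p_corr"].iloc[0] == pytest.approx(0.5, abs=0.05)

    def test_single_outcome_corrected_equals_uncorrected(self, rng):
        null = rng.standard_normal((500, 1))
        res = maxstat_pvalues(np.array([1.3]), null, ["m"])
        assert res.table["p_corr"].iloc[0] == res.table["p_unc"].iloc[0]

    def test_corrected_never_below_uncorrected(self, rng):
        null = rng.standard_normal((500, 6))
        observed = rng.standard_normal(6) * 2
        res = maxstat_pvalues(observed, null, list("abcdef"))
        assert (res.table["p_corr"] >= res.table["p_unc"] - 1e-12).all()
        assert (res.table["q"] >= res.table["p_unc"] - 1e-12).all()

    def test_nan_outcome_dropped_and_counted(self, rng):
        null = rng.standard_normal((200, 3))
        observed = np.array([1.0, np.nan, 0.5])
        res = maxstat_pvalues(observed, null, ["a", "b", "c"])
        assert res.n_dropped == 1
        assert np.isnan(res.table.loc[1, "p_corr"])
        assert np.isfinite(res.table.loc[0, "p_corr"])


class TestBhFdr:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr(np.ones(3)), 1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=20))
    def test_monotone_in_p(self, ps):
        p = np.array(ps)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr(np.array([0.0, 0.5]))


class TestFamilyTestPower:
    def test_detects_strong_single_outcome_shift(self, rng):
        """Cohen's d ~ 1.2 on one of 8 outcomes at n = 35+40 is found by the
        max-stat test in most replicates."""
        hits = 0
        n_rep = 20
        for k in range(n_rep):
            r = np.random.default_rng(1000 + k)
            g = np.r_[np.ones(35), np.zeros(40)]
            Y = r.standard_normal((75, 8))
            Y[:, 0] += 1.2 * g
            design = _group_design(g)
            res = family_test(Y, design, [f"m{i}" for i in range(8)], n_perm=500, seed=k)
            if res.table["p_corr"].iloc[0] <= 0.05:
                hits += 1
        assert hits >= 0.8 * n_rep
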