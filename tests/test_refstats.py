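"""Reference-database statistics: summaries, correlations, PCA, MANOVA, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from retvol import phantom as ph
from retvol import refstats as rs
from retvol.volumetry import RegionVolumes, SLICE_NAMES


def _cohort_df(slices_matrix, sex=None, origin=None, eye=None):
    """Build a cohort DataFrame from a per-eye slice matrix."""
    n = len(slices_matrix)
    rows = []
    for i, s in enumerate(slices_matrix):
        v = RegionVolumes.from_slices(s)
        rows.append(
            {
                "animal_id": f"A{i}",
                "eye": eye[i] if eye is not None else ("OD" if i % 2 == 0 else "OS"),
                "sex": sex[i] if sex is not None else "male",
                "origin": origin[i] if origin is not None else "Asia",
                **v.as_dict(),
            }
        )
    return pd.DataFrame(rows)


class TestSummarize:
    def test_hand_computed_three_values(self):
        df = _cohort_df(np.tile([[0.1] * 9, [0.2] * 9, [0.3] * 9], 1).reshape(3, 9))
        ss = rs.summarize(df, region="S1")
        assert ss.mean == pytest.approx(0.2)
        assert ss.median == pytest.approx(0.2)
        assert ss.std == pytest.approx(0.1)  # n-1 denominator
        assert ss.cv == pytest.approx(0.5)

    def test_constant_cohort_degenerates_cleanly(self):
        df = _cohort_df(np.full((5, 9), 0.2))
        ss = rs.summarize(df, region="Z2")
        assert ss.std == 0.0 and ss.cv == 0.0
        assert ss.min == ss.median == ss.max == ss.mean

    def test_grouped_summaries_skip_empty_groups(self):
        df = _cohort_df(np.full((4, 9), 0.2), sex=["male"] * 4)
        out = rs.summarize(df, group_keys=("sex",), region="Z1")
        assert list(out) == [("male",)]
        assert out[("male",)].count == 4

    def test_cv_invariant_under_rescaling(self, default_cohort):
        df = default_cohort.to_dataframe()
        scaled = df.copy()
        cols = [c for c in df.columns if c not in ("animal_id", "eye", "sex", "origin", "age_months", "weight_kg")]
        scaled[cols] = scaled[cols] * 3.7
        for region in ("Z1", "Q2", "S7"):
            assert rs.summarize(df, region=region).cv == pytest.approx(
                rs.summarize(scaled, region=region).cv
            )

    def test_unknown_region_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="region"):
            rs.summarize(default_cohort, region="Z9")


class TestCorrelationBlocks:
    def test_shared_factor_gives_unit_correlations(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(0.5, 1.5, size=50)
        slices = np.outer(f, np.linspace(0.1, 0.3, 9))
        cb = rs.correlation_block_summary(_cohort_df(slices))
        for block in cb.blocks.values():
            assert block["mean"] == pytest.approx(1.0)
            assert block["n_excluded"] == 0

    def test_block_pair_counts(self, default_cohort):
        cb = rs.correlation_block_summary(default_cohort)
        expected = {
            "among_zones": 3,
            "among_quadrants": 6,
            "among_slices": 36,
            "zones_and_quadrants": 12,
            "zones_and_slices": 27,
            "quadrants_and_slices": 36,
        }
        assert {k: v["n_pairs"] for k, v in cb.blocks.items()} == expected

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(1)
        slices = np.full((10_000, 9), 0.2) + rng.normal(0, 0.01, (10_000, 9))
        cb = rs.correlation_block_summary(_cohort_df(slices))
        assert abs(cb.blocks["among_slices"]["mean"]) < 0.03

    def test_zero_variance_variable_excluded_with_count(self):
        rng = np.random.default_rng(2)
        slices = np.full((30, 9), 0.2) + rng.normal(0, 0.01, (30, 9))
        slices[:, 0] = 0.2  # S1 (and hence Z1) constant
        cb = rs.correlation_block_summary(_cohort_df(slices))
        assert cb.blocks["among_slices"]["n_excluded"] == 8
        assert np.isfinite(cb.blocks["among_slices"]["mean"])

    def test_default_calibration_targets_mean_slice_correlation(self, default_cohort):
        cb = rs.correlation_block_summary(default_cohort)
        assert cb.blocks["among_slices"]["mean"] == pytest.approx(0.49, abs=0.10)


class TestPca:
    def test_two_variable_closed_form(self):
        # cov [[2,1],[1,2]] has eigenvalues 3 and 1
        rng = np.random.default_rng(3)
        L = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 2.0]]))
        X = rng.standard_normal((200_00, 2)) @ L.T
        cov = np.cov(X, rowvar=False)
        w = np.linalg.eigvalsh(cov)[::-1]
        assert w == pytest.approx([3.0, 1.0], rel=0.05)

    def test_isotropic_data_spreads_evenly(self):
        rng = np.random.default_rng(4)
        slices = np.full((5000, 9), 0.2) + rng.normal(0, 0.01, (5000, 9))
        res = rs.pca_slices(_cohort_df(slices), eye_side=None)
        assert res.explained_fraction == pytest.approx(np.full(9, 1 / 9), abs=0.02)

    def test_completeness_and_unit_norm(self, default_cohort):
        res = rs.pca_slices(default_cohort, "OD")
        assert res.cumulative_fraction[-1] == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(res.coefficients, axis=0) == pytest.approx(np.ones(9))
        # deterministic sign convention: dominant loading positive
        dom = np.abs(res.coefficients).argmax(axis=0)
        assert (res.coefficients[dom, np.arange(9)] > 0).all()

    def test_eigenvalues_descending(self, default_cohort):
        res = rs.pca_slices(default_cohort, "OS")
        assert (np.diff(res.eigenvalues) <= 1e-15).all()

    def test_too_few_records_rejected(self):
        df = _cohort_df(np.full((8, 9), 0.2))
        with pytest.raises(ValueError, match="at least 10"):
            rs.pca_slices(df, eye_side=None)


class TestManova:
    def test_detects_injected_sex_effect(self, default_cohort):
        res = rs.manova_slices(default_cohort, "OD")
        assert 0.0 < res.factors["sex"].wilks_lambda < 1.0
        assert res.factors["sex"].p < 1e-6
        assert res.interaction_dropped  # no interaction was injected

    def test_null_factor_lambda_near_one(self):
        rng = np.random.default_rng(5)
        n = 400
        slices = np.full((n, 9), 0.2) + rng.normal(0, 0.01, (n, 9))
        df = _cohort_df(
            slices,
            sex=rng.choice(["male", "female"], n),
            origin=rng.choice(["Mauritius", "Asia"], n),
        )
        res = rs.manova_slices(df, eye_side=None)
        assert res.factors["sex"].wilks_lambda > 0.95
        assert res.factors["sex"].p > 0.001

    def test_single_level_factor_raises(self):
        df = _cohort_df(np.full((30, 9), 0.2), sex=["male"] * 30)
        with pytest.raises(ValueError, match="sex"):
            rs.manova_slices(df, eye_side=None)

    def test_unknown_origin_excluded_before_fit(self, default_cohort):
        df = default_cohort.to_dataframe()
        df.loc[df.index[:20], "origin"] = "unknown"
        res = rs.manova_slices(df, eye_side=None)
        assert res.n_records == len(df) - 20


class TestAnova:
    def test_matches_statsmodels_type2_workflow(self, default_cohort):
        """The batched engine reproduces statsmodels anova_lm(typ=2) exactly."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        table = rs.anova_per_slice(default_cohort, "OD")
        df = default_cohort.to_dataframe()
        df = df[(df.eye == "OD") & df.origin.isin(["Mauritius", "Asia"])]
        for s in SLICE_NAMES:
            full = ols(f"{s} ~ C(sex) * C(origin)", df).fit()
            at = sm.stats.anova_lm(full, typ=2)
            p_int = at.loc["C(sex):C(origin)", "PR(>F)"]
            assert table.interaction_p[s] == pytest.approx(p_int, rel=1e-8)
            if p_int >= rs.ANOVA_INTERACTION_DROP:
                at = sm.stats.anova_lm(ols(f"{s} ~ C(sex) + C(origin)", df).fit(), typ=2)
            for f in ("sex", "origin"):
                assert table.cells[(s, f)]["F"] == pytest.approx(
                    at.loc[f"C({f})", "F"], rel=1e-8
                )
                assert table.cells[(s, f)]["p"] == pytest.approx(
                    at.loc[f"C({f})", "PR(>F)"], rel=1e-8
                )

    def test_balanced_design_type2_equals_type1(self):
        rng = np.random.default_rng(6)
        sex = ["male", "male", "female", "female"] * 25
        origin = ["Asia", "Mauritius"] * 50
        slices = np.full((100, 9), 0.2) + rng.normal(0, 0.01, (100, 9))
        df = _cohort_df(slices, sex=sex, origin=origin)
        table = rs.anova_per_slice(df, eye_side=None)
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        for s in ("S1", "S5"):
            t1 = sm.stats.anova_lm(ols(f"{s} ~ C(sex) + C(origin)", df).fit(), typ=1)
            assert table.cells[(s, "sex")]["F"] == pytest.approx(
                t1.loc["C(sex)", "F"], rel=1e-8
            )

    def test_single_dependent_variable_wilks_equivalence(self):
        """With one response, the Wilks-lambda F reduces to the ANOVA F.

        Λ = RSS(full)/RSS(without factor) and F = (1−Λ)/Λ · df_den equal
        the univariate Type II F for the same factor.
        """
        rng = np.random.default_rng(7)
        n = 120
        sex = rng.choice(["male", "female"], n)
        origin = rng.choice(["Mauritius", "Asia"], n)
        y = (0.2 + 0.01 * (sex == "female") + rng.normal(0, 0.01, n)).reshape(-1, 1)
        a = (sex == "female").astype(float).reshape(-1, 1)
        b = (origin == "Mauritius").astype(float).reshape(-1, 1)
        one = np.ones((n, 1))
        rss_full = rs._rss(np.hstack([one, a, b]), y)[0]
        rss_no_a = rs._rss(np.hstack([one, b]), y)[0]
        wilks = rss_full / rss_no_a
        f_wilks = (1 - wilks) / wilks * (n - 3)
        (F_a, _), _, _ = rs._type2_two_factor(y, a.ravel() > 0, b.ravel() > 0, 0.0)
        assert 0.0 < wilks < 1.0
        assert F_a[0] == pytest.approx(f_wilks, rel=1e-9)

    def test_detects_default_injected_effects(self, default_cohort):
        table = rs.anova_per_slice(default_cohort, "OD")
        assert "S4" in table.significant_slices("sex")  # largest sex offset
        assert "S1" in table.significant_slices("origin")  # largest origin offset


class TestBonferroniStars:
    @pytest.mark.parametrize(
        "p,m,expected",
        [
            (9.8e-6, 9, "***"),
            (3.0e-3, 9, "*"),
            (1.6e-4, 9, "**"),
            (0.05 / 9, 9, ""),  # strict inequality at the boundary
            (0.5, 9, ""),
            (0.04, 1, "*"),
        ],
    )
    def test_thresholds(self, p, m, expected):
        assert rs.bonferroni_stars(p, m) == expected

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.integers(1, 20))
    def test_monotone_in_p(self, p1, p2, m):
        lo, hi = sorted((p1, p2))
        order = {"***": 3, "**": 2, "*": 1, "": 0}
        assert order[rs.bonferroni_stars(lo, m)] >= order[rs.bonferroni_stars(hi, m)]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            rs.bonferroni_stars(1.5)


class TestReproduceReport:
    def test_full_report_on_simulated_cohort(self, default_cohort, tmp_path):
        bundle = rs.reproduce_report(default_cohort, outdir=tmp_path)
        assert set(bundle.summary_tables) == {"zones", "quadrants", "slices"}
        assert bundle.unavailable == {}
        assert bundle.overall_central.mean == pytest.approx(0.205, abs=0.005)
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "anova_stars_OD.csv").exists()

    def test_cohort_without_origin_degrades_gracefully(self, default_cohort):
        df = default_cohort.to_dataframe()
        df["origin"] = "unknown"
        bundle = rs.reproduce_report(df)
        assert "manova_OD" in bundle.unavailable
        assert "anova_OS" in bundle.unavailable
        assert "zones" in bundle.summary_tables  # summaries still emitted

    def test_tiny_cohort_marks_multivariate_sections_unavailable(self):
        df = _cohort_df(np.full((2, 9), 0.2))
        bundle = rs.reproduce_report(df)
        assert any(k.startswith("pca_") for k in bundle.unavailable)
        assert "zones" in bundle.summary_tables
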