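import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osmo.io import OrganismMeta, ValidationError
from osmo.screens import (
    fourway_anova,
    select_anova_hits,
    tolerance_screen,
    upper_quartile,
)


def make_metas(n=16, seed=0):
    rng = np.random.default_rng(seed)
    groups = ["alpha", "gamma", "firmicutes", "actino", "fungi", "human"]
    habitats = ["free-living", "plant-associated", "animal-associated"]
    metas = []
    for i in range(n):
        metas.append(
            OrganismMeta(
                organism_id=f"o{i:02d}",
                taxonomy_group=groups[i % 6],
                habitat=habitats[int(rng.integers(3))],
                cell_wall="thin" if rng.random() < 0.5 else "thick",
                ic50=float(np.exp(rng.uniform(np.log(150), np.log(1500)))),
            )
        )
    return metas


class TestFourwayAnova:
    def test_single_factor_f_equals_squared_t(self):
        """Two groups [1,2,3] vs [4,5,6]: F = 13.5 = t^2, p matching the
        pooled t-test."""
        metas = [
            OrganismMeta(organism_id=f"o{i}", taxonomy_group="g1" if i < 3 else "g2",
                         habitat="h", cell_wall="w", ic50=500.0)
            for i in range(6)
        ]
        fc = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
            index=["m1"],
            columns=[m.organism_id for m in metas],
        )
        (res,) = fourway_anova(fc, metas, factors=("taxonomy_group",))
        p = res.p_values["taxonomy_group"]
        assert p == pytest.approx(0.0213, abs=1e-4)
        # cross-check against statsmodels OLS ANOVA
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = pd.DataFrame(
            {"y": [1, 2, 3, 4, 5, 6], "g": ["a"] * 3 + ["b"] * 3}
        )
        tab = sm.stats.anova_lm(smf.ols("y ~ C(g)", data=df).fit(), typ=2)
        assert p == pytest.approx(float(tab.loc["C(g)", "PR(>F)"]), rel=1e-9)

    def test_constant_response_gives_f_zero(self):
        metas = make_metas(12)
        fc = pd.DataFrame(
            [np.full(12, 1.5)], index=["m1"], columns=[m.organism_id for m in metas]
        )
        (res,) = fourway_anova(fc, metas)
        for p in res.p_values.values():
            assert np.isnan(p) or p > 0.99

    def test_empty_factor_level_marks_untestable(self):
        metas = [
            OrganismMeta(organism_id=f"o{i}", taxonomy_group="g1",
                         habitat="h1" if i < 3 else "h2", cell_wall="w", ic50=500.0)
            for i in range(6)
        ]
        fc = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
            index=["m1"],
            columns=[m.organism_id for m in metas],
        )
        (res,) = fourway_anova(fc, metas, factors=("taxonomy_group", "habitat"))
        assert np.isnan(res.p_values["taxonomy_group"])  # single level
        assert np.isfinite(res.p_values["habitat"])

    def test_group_means_computed_from_members(self):
        metas = make_metas(12)
        rng = np.random.default_rng(1)
        fc = pd.DataFrame(
            rng.normal(size=(3, 12)), index=["m1", "m2", "m3"],
            columns=[m.organism_id for m in metas],
        )
        results = fourway_anova(fc, metas)
        meta_by_id = {m.organism_id: m for m in metas}
        for res in results:
            stats_tax = res.group_stats["taxonomy_group"]
            for level in stats_tax.index:
                members = [
                    m.organism_id for m in metas if m.taxonomy_group == level
                ]
                expected = fc.loc[res.metabolite_id, members].mean()
                assert stats_tax.loc[level, "mean"] == pytest.approx(expected)
        del meta_by_id

    def test_null_p_values_approximately_uniform(self):
        """Pooled ANOVA p-values under the null pass a KS uniformity check."""
        from scipy import stats as sps

        metas = make_metas(16, seed=3)
        rng = np.random.default_rng(4)
        fc = pd.DataFrame(
            rng.normal(size=(300, 16)),
            index=[f"m{i}" for i in range(300)],
            columns=[m.organism_id for m in metas],
        )
        results = fourway_anova(fc, metas)
        pooled = [
            p for r in results for p in r.p_values.values() if np.isfinite(p)
        ]
        assert sps.kstest(pooled, "uniform").pvalue > 0.01


class TestSelectAnovaHits:
    def test_no_passing_metabolite(self):
        metas = make_metas(12)
        fc = pd.DataFrame(
            np.random.default_rng(5).normal(scale=0.1, size=(5, 12)),
            index=[f"m{i}" for i in range(5)],
            columns=[m.organism_id for m in metas],
        )
        hits, union = select_anova_hits(fourway_anova(fc, metas))
        assert union == 0
        assert all(df.empty for df in hits.values())

    def test_union_counts_each_metabolite_once(self):
        metas = make_metas(16, seed=6)
        # strong taxonomy+habitat-confounded signal on one metabolite
        vals = np.array(
            [3.0 if m.taxonomy_group in ("alpha", "gamma") else -3.0 for m in metas]
        )
        fc = pd.DataFrame(
            [vals + np.random.default_rng(7).normal(0, 0.1, 16)],
            index=["m1"], columns=[m.organism_id for m in metas],
        )
        hits, union = select_anova_hits(fourway_anova(fc, metas))
        n_lists = sum(not df.empty for df in hits.values())
        assert union == 1
        assert n_lists >= 1

    def test_planted_factor_specific_hits_recovered(self):
        """20 planted single-factor effects are selected for their factor."""
        rng = np.random.default_rng(8)
        metas = make_metas(16, seed=8)
        rows = {}
        planted = {}
        factor_of = {
            "taxonomy_group": lambda m: m.taxonomy_group,
            "habitat": lambda m: m.habitat,
            "cell_wall": lambda m: m.cell_wall,
        }
        for i in range(20):
            factor = list(factor_of)[i % 3]
            levels = sorted({factor_of[factor](m) for m in metas})
            level = levels[int(rng.integers(len(levels)))]
            shift = rng.choice([-2.5, 2.5])
            rows[f"hit{i}"] = np.array(
                [shift if factor_of[factor](m) == level else 0.0 for m in metas]
            ) + rng.normal(0, 0.25, 16)
            planted[f"hit{i}"] = factor
        for i in range(50):
            rows[f"null{i}"] = rng.normal(0, 0.25, 16)
        fc = pd.DataFrame(rows, index=[m.organism_id for m in metas]).T
        results = fourway_anova(fc, metas)
        hits, union = select_anova_hits(results)
        selected = {
            r.metabolite_id: r.selected_factors
            for r in results if r.selected_factors
        }
        correct = sum(
            1 for met, factor in planted.items()
            if factor in selected.get(met, set())
        )
        assert correct >= 19
        assert union >= 19

    def test_top_k_truncation_reports_only_k(self):
        metas = make_metas(16, seed=9)
        rng = np.random.default_rng(9)
        rows = {
            f"m{i}": np.array(
                [4.0 if m.taxonomy_group == "alpha" else 0.0 for m in metas]
            ) + rng.normal(0, 0.2, 16)
            for i in range(12)
        }
        fc = pd.DataFrame(rows, index=[m.organism_id for m in metas]).T
        hits, union = select_anova_hits(fourway_anova(fc, metas), top_k=5)
        assert len(hits["taxonomy_group"]) == 5
        assert union >= 10  # union counted before truncation


class TestUpperQuartile:
    def test_interpolated_position(self):
        assert upper_quartile([0.5, 1.5, 2.5, 3.5]) == pytest.approx(2.75)

    def test_single_value(self):
        assert upper_quartile([2.0]) == 2.0


class TestToleranceScreen:
    def test_perfect_correlation(self):
        fc = pd.DataFrame(
            [[1.0, 2.0, 3.0]], index=["m1"], columns=["a", "b", "c"]
        )
        (res,) = tolerance_screen(fc, {"a": 100.0, "b": 200.0, "c": 300.0})
        assert res.r == pytest.approx(1.0)
        assert res.hit_direction == "none"  # only 3 species

    def test_detected_in_exactly_ten_species_excluded(self):
        rng = np.random.default_rng(10)
        ic50 = {f"o{i}": 100.0 * (i + 1) for i in range(12)}
        row = {f"o{i}": 0.002 * ic50[f"o{i}"] + rng.normal(0, 0.05) for i in range(12)}
        fc10 = pd.DataFrame([{**row, "o10": np.nan, "o11": np.nan}], index=["m"])
        (res10,) = tolerance_screen(fc10, ic50)
        assert res10.n_detected == 10 and res10.hit_direction == "none"
        fc11 = pd.DataFrame([{**row, "o11": np.nan}], index=["m"])
        (res11,) = tolerance_screen(fc11, ic50)
        assert res11.n_detected == 11 and res11.hit_direction == "correlating"

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 100.0))
    def test_invariant_to_order_and_ic50_rescaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        orgs = [f"o{i}" for i in range(12)]
        fc = pd.DataFrame(
            rng.normal(size=(3, 12)), index=["m1", "m2", "m3"], columns=orgs
        )
        ic50 = pd.Series(rng.uniform(100, 1500, 12), index=orgs)
        base = tolerance_screen(fc, ic50)
        perm = rng.permutation(12)
        shuffled = tolerance_screen(fc.iloc[:, perm], ic50 * scale)
        for r1, r2 in zip(base, shuffled):
            assert r1.r == pytest.approx(r2.r, rel=1e-9)
            assert r1.x075 == pytest.approx(r2.x075, rel=1e-9)
            assert r1.hit_direction == r2.hit_direction

    def test_missing_ic50_rejected(self):
        fc = pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"], columns=["a", "b", "c"])
        with pytest.raises(ValidationError):
            tolerance_screen(fc, {"a": 100.0, "b": 200.0, "c": float("nan")})

    def test_planted_hits_recovered_with_low_false_positive_rate(self):
        """Planted linear IC50 relationships recovered; nulls stay quiet."""
        rng = np.random.default_rng(11)
        orgs = [f"o{i}" for i in range(16)]
        ic50 = pd.Series(
            np.exp(rng.uniform(np.log(150), np.log(1500), 16)), index=orgs
        )
        z = (ic50 - ic50.min()) / (ic50.max() - ic50.min())
        rows = {}
        for i in range(10):
            sign = 1 if i % 2 == 0 else -1
            rows[f"hit{i}"] = sign * (0.3 + 2.4 * z) + rng.normal(0, 0.45, 16)
        for i in range(200):
            rows[f"null{i}"] = rng.normal(0, 0.3, 16)
        fc = pd.DataFrame(rows, index=orgs).T
        results = {s.metabolite_id: s for s in tolerance_screen(fc, ic50)}
        sens = np.mean([results[f"hit{i}"].is_hit for i in range(10)])
        fpr = np.mean([results[f"null{i}"].is_hit for i in range(200)])
        assert sens >= 0.9
        assert fpr <= 0.05
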