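"""MWAS regression scan, BH-FDR, and subclass aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dioxome.mwas import (
    MWASResults,
    aggregate_subclass,
    bh_adjust,
    categorize_features,
    run_mwas,
)
from dioxome.related import RelatedCompoundSet
from dioxome.synthetic import SimConfig, generate_cohort
from dioxome.tables import ALL_CONGENERS, ConfigurationError, FeatureTable

from oracles import bh_stepup, ols_normal_equations


def _ln_table(values: pd.DataFrame) -> FeatureTable:
    features = pd.DataFrame(
        {"mz": np.linspace(100, 900, values.shape[1]),
         "rt": np.linspace(30, 500, values.shape[1])},
        index=values.columns,
    )
    return FeatureTable(features=features, intensities=values, mode="C18neg",
                        is_log=True)


@pytest.fixture(scope="module")
def covariates():
    return generate_cohort(SimConfig(seed=21))


class TestRunMwas:
    def test_self_regression(self, covariates):
        rng = np.random.default_rng(0)
        x = pd.Series(rng.normal(1.0, 0.5, len(covariates)), index=covariates.index)
        table = _ln_table(pd.DataFrame({"f": x}, index=covariates.index))
        out = run_mwas(table, x, covariates)
        assert out.loc["f", "beta"] == pytest.approx(1.0, abs=1e-10)
        assert out.loc["f", "p"] < 1e-10

    def test_matches_normal_equations_oracle(self, covariates):
        rng = np.random.default_rng(1)
        n = len(covariates)
        x = pd.Series(rng.normal(0, 1, n), index=covariates.index)
        y = pd.DataFrame(rng.normal(0, 1, (n, 5)),
                         index=covariates.index,
                         columns=[f"f{i}" for i in range(5)])
        out = run_mwas(_ln_table(y), x, covariates, model=2)
        design = np.column_stack(
            [
                x.to_numpy(),
                np.ones(n),
                covariates["age"].to_numpy(),
                (covariates["factory"] == "A").to_numpy(float),
                covariates["bmi"].to_numpy(),
                (covariates["smoking"] == "former").to_numpy(float),
                (covariates["smoking"] == "current").to_numpy(float),
                covariates["alcohol"].to_numpy(),
            ]
        )
        for j, f in enumerate(y.columns):
            beta, se = ols_normal_equations(design, y[f].to_numpy())
            assert out.loc[f, "beta"] == pytest.approx(beta[0], abs=1e-8)
            assert out.loc[f, "se"] == pytest.approx(se[0], abs=1e-8)

    def test_null_p_values_uniform(self, covariates):
        rng = np.random.default_rng(2)
        n = len(covariates)
        x = pd.Series(rng.lognormal(1, 1, n), index=covariates.index)
        y = pd.DataFrame(rng.normal(9, 1, (n, 10_000)), index=covariates.index,
                         columns=[f"f{i}" for i in range(10_000)])
        out = run_mwas(_ln_table(y), np.log(x), covariates)
        ks = stats.kstest(out["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_beta_recovered_without_bias(self, covariates):
        rng = np.random.default_rng(3)
        n = len(covariates)
        x = rng.normal(0.0, 1.0, n)
        betas = 0.5
        y = pd.DataFrame(
            betas * x[:, None] + rng.normal(0, 0.5, (n, 500)),
            index=covariates.index, columns=[f"f{i}" for i in range(500)],
        )
        out = run_mwas(_ln_table(y), pd.Series(x, index=covariates.index), covariates)
        assert abs(out["beta"].mean() - 0.5) < 0.05

    def test_single_factory_drops_collinear_term(self, covariates):
        sub = covariates[covariates["factory"] == "A"]
        rng = np.random.default_rng(4)
        y = pd.DataFrame({"f": rng.normal(0, 1, len(sub))}, index=sub.index)
        x = pd.Series(rng.normal(0, 1, len(sub)), index=sub.index)
        with pytest.warns(UserWarning, match="factory"):
            out = run_mwas(_ln_table(y), x, sub)
        assert np.isfinite(out.loc["f", "p"])


class TestBHAdjust:
    def test_worked_example(self):
        q, flags = bh_adjust([0.01, 0.02, 0.03, 0.5], fdr=0.2)
        np.testing.assert_array_equal(flags, [True, True, True, False])

    def test_all_ones(self):
        q, flags = bh_adjust([1.0, 1.0, 1.0])
        assert (q == 1.0).all() and not flags.any()

    def test_single_p(self):
        _, flags = bh_adjust([0.05], fdr=0.2)
        assert flags[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            bh_adjust([0.5, 1.5])

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            m = int(rng.integers(1, 21))
            p = rng.uniform(0, 1, m)
            if rng.random() < 0.3:
                p[: m // 2] = rng.uniform(0, 0.05, m // 2)
            q, _ = bh_adjust(p, fdr=0.2)
            q_oracle, _ = bh_stepup(p, alpha=0.2)
            np.testing.assert_allclose(q, q_oracle, atol=1e-12)

    def test_q_dominates_p_and_flags_consistent(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, 200)
        q, flags = bh_adjust(p, fdr=0.2)
        assert (q >= p - 1e-12).all()
        np.testing.assert_array_equal(flags, q < 0.2)


def _results_from_sets(sig: dict) -> MWASResults:
    """Build an MWASResults whose significant sets are exactly ``sig``."""
    res = MWASResults()
    features = sorted({f for s in sig.values() for f in s} | {"pad1", "pad2"})
    for (exp, mode), flagged in sig.items():
        tab = pd.DataFrame(
            {
                "beta": 0.0, "se": 1.0, "t": 0.0,
                "p": [0.001 if f in flagged else 0.9 for f in features],
                "q": [0.01 if f in flagged else 0.95 for f in features],
                "significant": [f in flagged for f in features],
            },
            index=features,
        )
        res.tables[(exp, mode)] = tab
    return res


class TestAggregation:
    def test_exhaustive_set_arithmetic(self):
        related = RelatedCompoundSet(
            per_congener={"TCDD": [("SC9", 0.8, 1e-5)]},
            subclass_sets={"PCDD": {"SC9"}, "PCDF": set(), "PCB": set()},
        )
        res = _results_from_sets(
            {
                ("TCDD", "C18neg"): {"f1", "f2"},
                ("SC9", "C18neg"): {"f2", "f3"},
            }
        )
        sets = aggregate_subclass(res, related, modes=("C18neg",))
        row = sets.per_congener.loc["TCDD"]
        assert row["C18neg_targeted"] == 2
        assert row["C18neg_related"] == 2
        assert row["C18neg_total"] == 3
        assert sets.union_sets[("PCDD", "C18neg")] == {"f1", "f2", "f3"}

    def test_congener_without_related_reports_na(self):
        related = RelatedCompoundSet(
            per_congener={}, subclass_sets={"PCDD": set(), "PCDF": set(), "PCB": set()}
        )
        res = _results_from_sets({("2378F", "C18neg"): {"f1"}})
        sets = aggregate_subclass(res, related, modes=("C18neg",))
        row = sets.per_congener.loc["2378F"]
        assert pd.isna(row["C18neg_related"])
        assert row["C18neg_total"] == row["C18neg_targeted"] == 1

    def test_empty_results_all_zero(self):
        related = RelatedCompoundSet(
            per_congener={}, subclass_sets={"PCDD": set(), "PCDF": set(), "PCB": set()}
        )
        sets = aggregate_subclass(MWASResults(), related, modes=("C18neg",))
        totals = sets.per_congener.filter(like="_total")
        assert (totals.fillna(0) == 0).all().all()

    def test_totals_equal_union_cardinality(self, pipeline_result):
        sets = pipeline_result.subclass_sets
        for sub in ("PCDD", "PCDF", "PCB"):
            for mode in ("C18neg", "HILICpos"):
                row = sets.per_congener.loc[f"total_{sub}"]
                assert row[f"{mode}_total"] == len(sets.union_sets[(sub, mode)])
                assert sets.union_sets[(sub, mode)] == (
                    sets.targeted_sets[(sub, mode)] | sets.related_sets[(sub, mode)]
                )

    def test_categorize_allows_overlap(self):
        related = RelatedCompoundSet(
            per_congener={"TCDD": [("SC1", 0.9, 1e-6)], "PCB77": [("SC2", 0.9, 1e-6)]},
            subclass_sets={"PCDD": {"SC1"}, "PCDF": set(), "PCB": {"SC2"}},
        )
        res = _results_from_sets(
            {("SC1", "C18neg"): {"shared"}, ("SC2", "C18neg"): {"shared"}}
        )
        sets = aggregate_subclass(res, related, modes=("C18neg",))
        lists = categorize_features(sets, modes=("C18neg",))
        assert "shared" in lists["PCDD"]["C18neg"]
        assert "shared" in lists["PCB"]["C18neg"]

    def test_planted_effects_land_in_their_subclass(self, pipeline_result):
        gt = pipeline_result.study.ground_truth
        lists = pipeline_result.subclass_features
        for mode in ("C18neg", "HILICpos"):
            for sub in ("PCDD", "PCDF", "PCB"):
                planted = [
                    f for f, info in gt.affected[mode].items()
                    if info["subclass"] == sub
                ]
                hit = sum(f in set(lists[sub][mode]) for f in planted)
                assert hit / len(planted) >= 0.8
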