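"""Generator: cohort structure, planted correlations, ground-truth closure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dioxome.synthetic import (
    SimConfig,
    generate_chem_features,
    generate_cohort,
    generate_immune_markers,
    generate_metabolome,
    generate_pathway_db,
    generate_study,
    generate_targeted_exposures,
)
from dioxome.tables import ALL_CONGENERS, CONGENERS, ConfigurationError, PROTON


class TestCohort:
    def test_default_sizes_and_factories(self):
        subjects = generate_cohort(SimConfig(seed=0))
        assert len(subjects) == 137
        assert (subjects["factory"] == "A").sum() == 76
        assert (subjects["factory"] == "B").sum() == 61
        assert (subjects.loc[subjects.factory == "B", "lag_years"] == 0).all()
        assert (subjects.loc[subjects.factory == "A", "lag_years"] > 0).all()

    def test_factory_age_distributions_at_large_n(self):
        cfg = SimConfig(n_A=4000, n_B=4000, seed=3)
        subjects = generate_cohort(cfg)
        mean_a = subjects.loc[subjects.factory == "A", "age"].mean()
        mean_b = subjects.loc[subjects.factory == "B", "age"].mean()
        assert mean_a == pytest.approx(69.0, abs=0.5)
        assert mean_b == pytest.approx(58.8, abs=0.5)

    def test_empty_cohort_allowed(self):
        subjects = generate_cohort(SimConfig(n_A=0, n_B=0))
        assert len(subjects) == 0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_A=-1)


class TestTargetedPanel:
    def test_column_layout(self, study):
        panel = study.panel
        assert list(panel.concentrations.columns) == list(ALL_CONGENERS)
        assert len(CONGENERS["PCDD"]) == 7
        assert len(CONGENERS["PCDF"]) == 10
        assert len(CONGENERS["PCB"]) == 12

    def test_high_pcb_correlation_when_configured(self):
        cfg = SimConfig(seed=7, subclass_rho={"PCDD": 0.5, "PCDF": 0.2, "PCB": 0.95})
        subjects = generate_cohort(cfg)
        panel = generate_targeted_exposures(subjects, cfg)
        pcb = panel.concentrations[list(CONGENERS["PCB"])]
        rho = stats.spearmanr(pcb).statistic
        off_diag = rho[np.triu_indices_from(rho, k=1)]
        # population rank correlation is ~0.945; allow sampling noise at n=137
        assert np.median(off_diag) > 0.9
        assert off_diag.min() > 0.85

    def test_tcdd_stochastically_larger_in_factory_a(self, study):
        tcdd = study.panel.concentrations["TCDD"]
        fac = study.subjects["factory"]
        assert tcdd[fac == "A"].median() > 5 * tcdd[fac == "B"].median()

    def test_zero_lod_flags_nothing(self):
        cfg = SimConfig(seed=1, lod_quantile=0.0)
        subjects = generate_cohort(cfg)
        panel = generate_targeted_exposures(subjects, cfg)
        assert not panel.below_lod.to_numpy().any()
        # flagged values retain their (positive) machine reading
        assert (panel.concentrations.to_numpy() > 0).all()


class TestChemFeatures:
    def test_envelope_ratio_four_chlorines(self, study):
        # M+2/M for 4 Cl is 4 * p37/p35 = 1.2792... before noise
        gt = study.ground_truth
        cid = next(c for c, n in gt.chlorinated.items() if n == 4)
        fids = gt.compound_features[cid]
        mono, m2 = fids[0], fids[1]
        ratio = (study.chem.intensities[m2] / study.chem.intensities[mono]).median()
        assert ratio == pytest.approx(4 * 0.2423 / 0.7577, rel=0.05)
        dm = study.chem.features.loc[m2, "mz"] - study.chem.features.loc[mono, "mz"]
        assert dm == pytest.approx(1.99705, abs=1e-9)

    def test_decoys_have_no_chlorine_spacing(self, study):
        gt = study.ground_truth
        feats = study.chem.features
        for cid, fids in gt.compound_features.items():
            if cid.startswith("DEC"):
                mz = feats.loc[fids, "mz"].to_numpy()
                if len(mz) > 1:
                    assert abs(np.diff(np.sort(mz))[0] - 1.99705) > 0.05

    def test_planted_congener_correlation(self, study):
        gt = study.ground_truth
        panel = study.panel.concentrations
        rhos = []
        # compound abundance proxy: its monoisotopic feature
        for congener, pairs in gt.related.items():
            for cid, r in pairs:
                mono = gt.compound_features[cid][0]
                rho = stats.spearmanr(
                    study.chem.intensities[mono], panel[congener]
                ).statistic
                rhos.append(rho)
        rhos = np.array(rhos)
        assert 0.65 <= np.median(rhos) <= 0.9
        assert (rhos > 0.5).mean() > 0.9

    def test_scan_range_respected(self, study):
        mz = study.chem.features["mz"]
        assert mz.min() >= 85.0 and mz.max() <= 850.0


class TestMetabolome:
    def test_mz_bounds_and_replicates(self, study):
        for table in (study.c18neg, study.hilicpos):
            assert table.features["mz"].between(85.0, 1275.0).all()
            assert table.has_replicates
            assert (
                table.intensities.index.get_level_values("replicate").nunique() == 3
            )

    def test_affected_feature_placed_at_adduct_mz(self, study):
        gt = study.ground_truth
        masses = dict(
            zip(study.pathway_db["metabolite_id"], study.pathway_db["neutral_mass"])
        )
        for mode, table, sign in (
            ("C18neg", study.c18neg, -1), ("HILICpos", study.hilicpos, +1),
        ):
            for fid, info in gt.affected[mode].items():
                expected = masses[info["metabolite"]] + sign * PROTON
                observed = table.features.loc[fid, "mz"]
                assert abs(observed - expected) / expected < 5e-6

    def test_null_config_gives_near_nominal_mwas_rate(self):
        # with beta = 0 nothing is planted, so per-family discoveries are rare
        import warnings

        from dioxome.mwas import bh_adjust, run_mwas
        from dioxome.preprocess import correct_batches, filter_features, impute_left_censored

        cfg = SimConfig(seed=11, beta=0.0, n_metab_features=400)
        subjects = generate_cohort(cfg)
        panel = generate_targeted_exposures(subjects, cfg)
        c18, _, _ = generate_metabolome(subjects, panel, cfg)
        filtered, _ = filter_features(c18)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corrected, _ = correct_batches(filtered)
        table = impute_left_censored(corrected, seed=5)
        scan = run_mwas(table, np.log(panel.concentrations["TCDD"]), subjects)
        _, flags = bh_adjust(scan["p"].to_numpy(), fdr=0.2)
        assert flags.mean() < 0.02

    def test_ground_truth_closure(self, study):
        gt = study.ground_truth
        chem_ids = set(study.chem.features.index)
        for cid, fids in gt.compound_features.items():
            assert set(fids) <= chem_ids
        assert set(gt.chlorinated) <= set(gt.compound_features)
        for congener, pairs in gt.related.items():
            assert congener in ALL_CONGENERS
            for cid, _ in pairs:
                assert cid in gt.chlorinated
        for mode, table in (("C18neg", study.c18neg), ("HILICpos", study.hilicpos)):
            assert set(gt.affected[mode]) <= set(table.features.index)
        db_pathways = set(study.pathway_db["pathway_id"])
        assert set(gt.enriched_pathways) <= db_pathways
        assert set(gt.marker_loadings) == set(gt.enriched_pathways)
        for loadings in gt.marker_loadings.values():
            assert set(loadings) <= set(study.markers.columns)
        assert all(1 <= n <= 10 for n in gt.chlorinated.values())


class TestImmuneMarkers:
    def test_category_layout(self, study):
        counts = study.marker_categories.value_counts()
        assert study.markers.shape[1] == 54
        assert counts["cytokine_growth_factor"] == 21
        assert counts["hematologic"] == 23
        assert counts["humoral"] == 7
        assert counts["lymphoma"] == 3

    def test_zero_loading_means_independence(self):
        cfg = SimConfig(seed=5, marker_loading=0.0)
        subjects = generate_cohort(cfg)
        panel = generate_targeted_exposures(subjects, cfg)
        markers, _, gt = generate_immune_markers(subjects, cfg, panel)
        x = np.log(panel.concentrations["TCDD"])
        cors = markers.apply(lambda col: stats.pearsonr(col, x).statistic)
        assert abs(cors.mean()) < 0.05
        assert gt.marker_loadings == {}

    def test_loaded_markers_track_the_factor(self, study):
        gt = study.ground_truth
        for pid, loadings in gt.marker_loadings.items():
            driver = gt.enriched_pathways[pid]["exposure"]
            x = np.log(study.panel.concentrations[driver])
            for marker in loadings:
                r = stats.pearsonr(study.markers[marker], x).statistic
                assert r > 0.5


def test_byte_identical_regeneration():
    a = generate_study(SimConfig(seed=42, n_metab_features=100, n_chlorinated=10,
                                 n_decoys=20, n_related=5, n_chem_features=80))
    b = generate_study(SimConfig(seed=42, n_metab_features=100, n_chlorinated=10,
                                 n_decoys=20, n_related=5, n_chem_features=80))
    pd.testing.assert_frame_equal(a.subjects, b.subjects)
    pd.testing.assert_frame_equal(a.panel.concentrations, b.panel.concentrations)
    pd.testing.assert_frame_equal(a.chem.intensities, b.chem.intensities)
    pd.testing.assert_frame_equal(a.c18neg.intensities, b.c18neg.intensities)
    pd.testing.assert_frame_equal(a.markers, b.markers)
    assert a.ground_truth.chlorinated == b.ground_truth.chlorinated
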