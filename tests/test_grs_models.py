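import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import pathgrs as pg
from pathgrs.grs import GrsDefinition, GrsMember, GrsVector
from pathgrs.grs_models import GrsModelError


def _vector(scores, phenotype="TG", groups=True):
    s = pd.Series(np.asarray(scores, dtype=float),
                  index=[f"i{j:04d}" for j in range(len(scores))])
    d = GrsDefinition(phenotype, "TOTAL", (GrsMember("rs5882", "G"),), "additive")
    v = GrsVector(scores=s, definition=d, n_missing_members=pd.Series(0, index=s.index))
    return pg.assign_risk_groups(v) if groups else v


@pytest.fixture(scope="module")
def total_tg(cohort, panel, base_covariates):
    assoc = pg.associate_panel(
        cohort["genotypes"], cohort["phenotypes"]["tg"], panel, "TG",
        covariates=base_covariates,
        snp_ids=[r.snp_id for r in panel.score_candidates("TG")], ls_means=False)
    definition = pg.build_pathway_definition(panel, "TG", "TOTAL", associations=assoc)
    return pg.compute_grs(cohort["genotypes"], definition)


class TestGrsModel:
    def test_partial_r2_equals_nested_delta_r2(self, cohort, base_covariates, total_tg):
        result = pg.fit_grs_model(cohort["phenotypes"]["tg"], total_tg,
                                  covariates=base_covariates, transform="log")
        frame = pd.DataFrame({"y": np.log(cohort["phenotypes"]["tg"]),
                              "score": total_tg.scores}).join(base_covariates).dropna()
        full = sm.OLS(frame["y"], sm.add_constant(frame[["score", "age", "sex"]])).fit()
        reduced = sm.OLS(frame["y"], sm.add_constant(frame[["age", "sex"]])).fit()
        assert result.grs_partial_r2 == pytest.approx(
            full.rsquared - reduced.rsquared, abs=1e-10)
        assert result.model_r2 == pytest.approx(full.rsquared, abs=1e-12)
        assert result.grs_partial_r2 <= result.model_r2
        assert result.ci_low <= result.beta <= result.ci_high

    def test_percent_suppressed_when_not_significant(self):
        rng = np.random.default_rng(8)
        v = _vector(rng.integers(0, 29, 500), groups=False)
        y = pd.Series(rng.normal(50, 10, 500), index=v.scores.index)
        result = pg.fit_grs_model(y, v, transform="identity")
        if result.grs_p >= 0.05:
            assert result.pct_grs is None
        table = pg.grs_results_table([result])
        assert table.loc[0, "pct_grs"] == "NC" or isinstance(table.loc[0, "pct_grs"], float)

    def test_constant_score_rejected(self):
        v = _vector([5] * 100, groups=False)
        y = pd.Series(np.random.default_rng(0).normal(size=100), index=v.scores.index)
        with pytest.raises(GrsModelError):
            pg.fit_grs_model(y, v, transform="identity")

    def test_bmi_model_r2_not_smaller(self, cohort, total_tg):
        pheno = cohort["phenotypes"]
        base = pg.fit_grs_model(pheno["tg"], total_tg,
                                covariates=pheno[["age", "sex"]], transform="log")
        with_bmi = pg.fit_grs_model(pheno["tg"], total_tg,
                                    covariates=pheno[["age", "sex", "bmi"]], transform="log")
        assert with_bmi.model_r2 >= base.model_r2 - 1e-12

    def test_pathway_with_simulated_effects_dominates(self, panel):
        """TG effects confined to the RCT pathway: its score explains more
        than the other pathways' in most replicates."""
        rct = {r.snp_id for r in panel.pathway_members("RCT")}
        wins = 0
        reps = 25
        for seed in range(reps):
            cfg = pg.SimulationConfig(
                n_individuals=580,
                allele_freqs={r.snp_id: r.maf_cohort for r in panel.score_candidates("TG")},
                panel=panel,
                tg_model=pg.PhenotypeModel(
                    intercept=4.6,
                    snp_effects={s: 0.06 for s in rct if s != "rs9282541"},
                    noise_sd=0.42, log_scale=True),
                seed=1000 + seed)
            geno, _, pheno = pg.simulate_cohort(cfg)
            assoc = pg.associate_panel(geno, pheno["tg"], panel, "TG",
                                       snp_ids=list(cfg.allele_freqs),
                                       transform="log", ls_means=False)
            results = {}
            for scope in ("RCT", "CLU", "LPF"):
                d = pg.build_pathway_definition(panel, "TG", scope, associations=assoc)
                results[scope] = pg.fit_grs_model(
                    pheno["tg"], pg.compute_grs(geno, d), transform="log").grs_partial_r2
            wins += results["RCT"] > max(results["CLU"], results["LPF"])
        assert wins / reps >= 0.9


class TestRiskGroupComparison:
    def test_equals_indicator_regression(self, cohort, total_tg):
        """With no covariates the two-group t-test must match the p-value of
        regressing the phenotype on the group indicator."""
        tg = cohort["phenotypes"]["tg"]
        comparison = pg.compare_risk_groups(tg, total_tg, "TG", transform="log")
        frame = pd.DataFrame({"y": np.log(tg),
                              "g": (total_tg.risk_group == "high").astype(float)}).dropna()
        fit = sm.OLS(frame["y"], sm.add_constant(frame["g"])).fit()
        assert comparison.t_p == pytest.approx(float(fit.pvalues["g"]), abs=1e-10)

    def test_groups_partition_analysed_sample(self, total_tg):
        assert set(total_tg.risk_group.unique()) == {"high", "low"}
        assert total_tg.risk_group.index.equals(total_tg.scores.index)

    def test_shift_detected_with_power(self):
        rng = np.random.default_rng(5)
        detections = 0
        reps = 30
        for _ in range(reps):
            v = _vector(np.concatenate([np.zeros(290), np.ones(290)]))
            shift = np.where(v.scores > 0, 0.1, 0.0)
            tg = pd.Series(np.exp(rng.normal(4.6 + shift, 0.42)), index=v.scores.index)
            comparison = pg.compare_risk_groups(tg, v, "TG", transform="log")
            detections += comparison.t_p < 0.05
        assert detections / reps >= 0.8

    def test_back_transformed_means_are_geometric(self, cohort, total_tg):
        tg = cohort["phenotypes"]["tg"]
        comparison = pg.compare_risk_groups(tg, total_tg, "TG", transform="log")
        high_ids = total_tg.risk_group[total_tg.risk_group == "high"].index
        geometric = np.exp(np.log(tg.loc[high_ids].dropna()).mean())
        assert comparison.mean_high == pytest.approx(geometric, rel=1e-12)

    def test_tiny_group_rejected(self):
        v = _vector([1, 2, 2, 3])
        v.risk_group = pd.Series(["high", "low", "low", "low"], index=v.scores.index)
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=v.scores.index)
        with pytest.raises(GrsModelError):
            pg.compare_risk_groups(y, v, "TG", transform="identity")


class TestSexStratification:
    def test_strata_sum_to_pooled(self, cohort, base_covariates, total_tg):
        out = pg.stratify_by_sex(cohort["phenotypes"]["tg"], total_tg,
                                 base_covariates, transform="log")
        pooled = pg.fit_grs_model(cohort["phenotypes"]["tg"], total_tg,
                                  covariates=base_covariates, transform="log")
        assert out["male"].n_used + out["female"].n_used == pooled.n_used
        assert "sex" not in out["male"].covariates

    def test_homogeneous_effect_recovered_in_both(self, cohort, study_config,
                                                  base_covariates, total_tg):
        out = pg.stratify_by_sex(cohort["phenotypes"]["tg"], total_tg,
                                 base_covariates, transform="log")
        # effects are sex-homogeneous by construction: strata agree within 2 SEs
        diff = out["male"].beta - out["female"].beta
        se = np.hypot(out["male"].se, out["female"].se)
        assert abs(diff) < 2.5 * se

    def test_small_stratum_skipped(self, cohort, total_tg):
        covs = cohort["phenotypes"][["age", "sex"]].copy()
        covs["sex"] = 0.0
        covs.iloc[:5, covs.columns.get_loc("sex")] = 1.0
        with pytest.warns(UserWarning, match="skipped"):
            out = pg.stratify_by_sex(cohort["phenotypes"]["tg"], total_tg, covs,
                                     transform="log")
        assert "male" not in out


class TestTgCategories:
    @pytest.mark.parametrize(
        "tg,expected",
        [
            (89.9, "Optimal"),
            (90.0, "Early metabolic risk"),
            (129.9, "Early metabolic risk"),
            (130.0, "Borderline metabolic risk"),
            (149.9, "Borderline metabolic risk"),
            (150.0, "Clinical hypertriglyceridemia"),
            (300.0, "Clinical hypertriglyceridemia"),
        ],
    )
    def test_guideline_boundaries(self, tg, expected):
        assert pg.classify_tg_category(tg) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(GrsModelError):
            pg.classify_tg_category(0.0)
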