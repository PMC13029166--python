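import numpy as np
import pandas as pd
import pytest

import pathgrs as pg
from pathgrs.grs import GrsDefinition, GrsError, GrsMember

from conftest import make_matrix


# SNPs removed by the emulated study's LD pruning (tags rs2278236, rs10499859)
STUDY_PRUNED = {"rs1044250", "rs7255436", "rs1527483"}


def _definition(panel, phenotype="TG", scope="TOTAL", weighting="additive", weights=None):
    members = []
    for record in panel.score_candidates(phenotype):
        if record.snp_id in STUDY_PRUNED:
            continue
        w = 1.0 if weights is None else weights.get(record.snp_id, 1.0)
        members.append(GrsMember(record.snp_id, record.counted_allele, w))
    return GrsDefinition(phenotype=phenotype, scope=scope,
                         members=tuple(members), weighting=weighting)


@pytest.fixture()
def tg_definition(panel):
    return _definition(panel)


class TestOrientation:
    def test_counted_equals_risk_identity(self, panel):
        m = make_matrix({"rs5882": [2, 1, 0]}, panel=panel)
        d = GrsDefinition("TG", "RCT", (GrsMember("rs5882", "G"),), "additive")
        counts = pg.orient_dosages(m, d)
        assert counts["rs5882"].tolist() == [2, 1, 0]

    def test_counted_not_risk_complemented(self, panel):
        m = make_matrix({"rs5882": [2, 1, 0]}, panel=panel)
        d = GrsDefinition("TG", "RCT", (GrsMember("rs5882", "A"),), "additive")
        counts = pg.orient_dosages(m, d)
        assert counts["rs5882"].tolist() == [0, 1, 2]

    def test_missing_propagates(self, panel):
        m = make_matrix({"rs5882": [np.nan, 1]}, panel=panel)
        d = GrsDefinition("TG", "RCT", (GrsMember("rs5882", "A"),), "additive")
        counts = pg.orient_dosages(m, d)
        assert np.isnan(counts["rs5882"].iloc[0])

    def test_absent_member_named_in_error(self, panel):
        m = make_matrix({"rs5882": [1]}, panel=panel)
        d = GrsDefinition("TG", "RCT", (GrsMember("rs805743", "C"),), "additive")
        with pytest.raises(GrsError, match="rs805743"):
            pg.orient_dosages(m, d)


class TestAdditive:
    def test_homozygous_risk_individual_attains_maximum(self, panel, tg_definition):
        assert len(tg_definition.members) == 14
        m = make_matrix({s: [2] for s in tg_definition.snp_ids}, panel=panel)
        counts = pg.orient_dosages(m, tg_definition)
        vector = pg.build_additive_grs(counts, tg_definition)
        assert vector.scores.iloc[0] == 28.0

    def test_sum_arithmetic(self, panel):
        snps = ["rs5882", "rs289714", "rs1532624", "rs805743", "rs1260326"]
        m = make_matrix({s: [v] for s, v in zip(snps, (0, 1, 2, 2, 1))}, panel=panel)
        d = GrsDefinition("TG", "TOTAL",
                          tuple(GrsMember(s, panel.get(s).counted_allele) for s in snps),
                          "additive")
        vector = pg.build_additive_grs(pg.orient_dosages(m, d), d)
        assert vector.scores.iloc[0] == 6.0

    def test_scores_bounded_and_missing_excluded(self, cohort, tg_definition):
        counts = pg.orient_dosages(cohort["genotypes"], tg_definition)
        vector = pg.build_additive_grs(counts, tg_definition)
        m = len(tg_definition.members)
        assert vector.scores.between(0, 2 * m).all()
        incomplete = vector.n_missing_members[vector.n_missing_members > 0].index
        assert not vector.scores.index.isin(incomplete).any()

    def test_empty_member_list_rejected(self):
        with pytest.raises(GrsError):
            pg.build_additive_grs(pd.DataFrame(),
                                  GrsDefinition("TG", "TOTAL", (), "additive"))

    def test_member_order_irrelevant(self, cohort, panel, tg_definition):
        shuffled = GrsDefinition("TG", "TOTAL", tuple(reversed(tg_definition.members)),
                                 "additive")
        a = pg.build_additive_grs(pg.orient_dosages(cohort["genotypes"], tg_definition),
                                  tg_definition)
        b = pg.build_additive_grs(pg.orient_dosages(cohort["genotypes"], shuffled), shuffled)
        pd.testing.assert_series_equal(a.scores, b.scores[a.scores.index])


class TestWeighted:
    def test_unit_weights_reduce_to_additive(self, cohort, panel, tg_definition):
        weighted_def = GrsDefinition(
            "TG", "TOTAL",
            tuple(GrsMember(m.snp_id, m.risk_allele, 1.0) for m in tg_definition.members),
            "weighted")
        counts = pg.orient_dosages(cohort["genotypes"], tg_definition)
        additive = pg.build_additive_grs(counts, tg_definition)
        weighted = pg.build_weighted_grs(counts, weighted_def)
        pd.testing.assert_series_equal(additive.scores, weighted.scores)

    def test_weighted_arithmetic(self, panel):
        snps = ["rs5882", "rs289714"]
        m = make_matrix({"rs5882": [2], "rs289714": [1]}, panel=panel)
        d = GrsDefinition("TG", "RCT",
                          (GrsMember("rs5882", "G", 0.5), GrsMember("rs289714", "C", -0.2)),
                          "weighted")
        vector = pg.build_weighted_grs(pg.orient_dosages(m, d), d)
        assert vector.scores.iloc[0] == pytest.approx(0.8)

    def test_missing_weight_rejected(self, panel):
        d = GrsDefinition("TG", "RCT", (GrsMember("rs5882", "G", np.nan),), "weighted")
        m = make_matrix({"rs5882": [1]}, panel=panel)
        with pytest.raises(GrsError):
            pg.build_weighted_grs(pg.orient_dosages(m, d), d)

    def test_weighted_hdl_scores_negative(self, cohort, panel, base_covariates):
        """HDL weights are signed toward the adverse (lowering) direction,
        so raw weighted HDL scores sum negative."""
        assoc = pg.associate_panel(
            cohort["genotypes"], cohort["phenotypes"]["hdl"], panel, "HDL",
            covariates=base_covariates,
            snp_ids=[r.snp_id for r in panel.score_candidates("HDL")], ls_means=False)
        definition = pg.build_pathway_definition(panel, "HDL", "TOTAL",
                                                 associations=assoc, weighting="weighted")
        vector = pg.compute_grs(cohort["genotypes"], definition)
        assert vector.scores.mean() < 0


class TestTopHits:
    def test_strict_subset_of_loose(self, cohort, panel, base_covariates):
        assoc = pg.associate_panel(
            cohort["genotypes"], cohort["phenotypes"]["tg"], panel, "TG",
            covariates=base_covariates,
            snp_ids=[r.snp_id for r in panel.score_candidates("TG")], ls_means=False)
        strict = pg.build_top_hits_definition(panel, assoc, "TG", alpha=0.05)
        loose = pg.build_top_hits_definition(panel, assoc, "TG", alpha=0.10)
        assert set(strict.snp_ids) <= set(loose.snp_ids)
        expected = {s for s, a in assoc.items() if a.p_value < 0.10}
        assert set(loose.snp_ids) == expected

    def test_no_qualifying_snp_warns_empty(self, panel):
        assoc = {"rs5882": pg.SnpAssociation(
            snp_id="rs5882", phenotype="TG", transform="log", beta=0.01, se=0.01,
            p_value=0.9, ci_low=0, ci_high=0, partial_r2=0.0, n_used=100,
            risk_allele="G")}
        with pytest.warns(UserWarning, match="top-hits"):
            d = pg.build_top_hits_definition(panel, assoc, "TG", alpha=0.05)
        assert d.members == ()


class TestRiskGroups:
    def _vector(self, scores):
        s = pd.Series(scores, index=[f"i{j}" for j in range(len(scores))], dtype=float)
        d = GrsDefinition("TG", "TOTAL", (GrsMember("rs5882", "G"),), "additive")
        return pg.grs.GrsVector(scores=s, definition=d,
                                n_missing_members=pd.Series(0, index=s.index))

    def test_strict_greater_than_median(self):
        v = pg.assign_risk_groups(self._vector([1, 2, 3, 4, 5]))
        assert (v.risk_group == "high").sum() == 2
        assert set(v.scores[v.risk_group == "high"]) == {4, 5}
        assert v.median == 3

    def test_even_split_ties_to_low(self):
        v = pg.assign_risk_groups(self._vector([1, 1, 2, 2]))
        assert list(v.scores[v.risk_group == "high"]) == [2, 2]

    def test_degenerate_distribution_errors(self):
        with pytest.raises(GrsError, match="degenerate"):
            pg.assign_risk_groups(self._vector([3, 3, 3]))

    def test_partition_invariant_under_constant_shift(self):
        base = self._vector([1, 4, 2, 7, 5, 5, 3, 9])
        shifted = self._vector(np.array([1, 4, 2, 7, 5, 5, 3, 9]) + 17.5)
        a = pg.assign_risk_groups(base).risk_group
        b = pg.assign_risk_groups(shifted).risk_group
        pd.testing.assert_series_equal(a, b)


class TestKeySnpRemoval:
    def test_cardinality_and_inverse(self, tg_definition):
        removed = pg.remove_key_snp(tg_definition, "rs4149310")
        assert len(removed.members) == 13
        assert "rs4149310" not in removed.snp_ids
        restored = GrsDefinition(
            removed.phenotype, removed.scope,
            removed.members + (next(m for m in tg_definition.members
                                    if m.snp_id == "rs4149310"),),
            removed.weighting)
        assert set(restored.members) == set(tg_definition.members)

    def test_nonmember_rejected(self, tg_definition):
        with pytest.raises(GrsError):
            pg.remove_key_snp(tg_definition, "rs3173798")

    def test_dominant_snp_removal_abolishes_association(self, panel):
        """One SNP carries essentially all the pathway-score signal:
        dropping it moves the score association from significant to null.
        Additive weighting keeps the check free of the in-sample-weight
        overfitting that a weighted score would add."""
        rct_hdl = [r.snp_id for r in panel.score_candidates("HDL") if r.pathway == "RCT"]
        cfg = pg.SimulationConfig(
            n_individuals=580,
            allele_freqs={s: panel.get(s).maf_cohort for s in rct_hdl},
            panel=panel,
            hdl_model=pg.PhenotypeModel(intercept=50.0,
                                        snp_effects={"rs9282541": -10.0},
                                        noise_sd=11.0),
            seed=99,
        )
        geno, _, pheno = pg.simulate_cohort(cfg)
        assoc = pg.associate_panel(geno, pheno["hdl"], panel, "HDL",
                                   snp_ids=rct_hdl, ls_means=False,
                                   transform="identity")
        definition = pg.build_pathway_definition(panel, "HDL", "RCT",
                                                 associations=assoc)
        full = pg.fit_grs_model(pheno["hdl"], pg.compute_grs(geno, definition),
                                transform="identity")
        reduced_def = pg.remove_key_snp(definition, "rs9282541")
        reduced = pg.fit_grs_model(pheno["hdl"], pg.compute_grs(geno, reduced_def),
                                   transform="identity")
        assert full.grs_p < 0.05
        assert reduced.grs_p > 0.05


def test_definition_json_roundtrip(tmp_path, tg_definition):
    path = tmp_path / "def.json"
    tg_definition.to_json(path)
    again = GrsDefinition.from_json(path)
    assert again == tg_definition
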