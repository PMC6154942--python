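"""Synthetic cohort, planted-effect OTU table and tree generation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gutmets.io import FormatError
from gutmets.simulate import (
    CohortConfig,
    GroundTruthEffect,
    MissingDataError,
    OtuConfig,
    assign_taxonomy,
    diagnose_mets,
    generate_cohort,
    generate_otu_table,
    generate_tree,
    mets_components,
    plant_effects,
)


class TestDiagnosis:
    def test_three_components_is_mets(self):
        flags = diagnose_mets("female", waist=86, sbp=131, dbp=70, tg=1.8, hdl=1.2, fbg=5.0)
        assert flags["waist_flag"] and flags["bp_flag"] and flags["tg_flag"]
        assert not flags["hdl_flag"] and not flags["fbg_flag"]
        assert flags["mets"]

    def test_all_healthy_is_not_mets(self):
        flags = diagnose_mets("male", waist=80, sbp=110, dbp=70, tg=1.0, hdl=1.5, fbg=5.0)
        assert not any(flags.values())

    def test_thresholds_inclusive_except_hdl(self):
        f = diagnose_mets("female", waist=85.0, sbp=130.0, dbp=85.0, tg=1.7, hdl=1.04, fbg=6.1)
        assert f["waist_flag"] and f["bp_flag"] and f["tg_flag"] and f["fbg_flag"]
        assert not f["hdl_flag"]  # HDL < 1.04 is strict
        assert diagnose_mets("male", waist=90.0, sbp=100, dbp=70, tg=1, hdl=1.2, fbg=5)["waist_flag"]

    def test_missing_measurement_named(self):
        with pytest.raises(MissingDataError, match="tg"):
            diagnose_mets("male", waist=80, sbp=110, dbp=70, tg=float("nan"), hdl=1.5, fbg=5.0)

    def test_two_components_not_mets(self):
        flags = diagnose_mets("male", waist=95, sbp=140, dbp=70, tg=1.0, hdl=1.5, fbg=5.0)
        assert not flags["mets"]


class TestCohort:
    def test_prevalence_near_survey_level(self):
        cohort = generate_cohort(6896, seed=1)
        assert 0.154 <= cohort["mets"].mean() <= 0.254

    def test_flags_consistent_with_diagnosis(self):
        cohort = generate_cohort(200, seed=2)
        recomputed = mets_components(cohort[[c for c in cohort.columns if "flag" not in c and c != "mets"]])
        assert recomputed["mets"].equals(cohort["mets"])
        row = cohort.iloc[7]
        single = diagnose_mets(
            row["gender"], row["waist"], row["sbp"], row["dbp"], row["tg"], row["hdl"], row["fbg"]
        )
        assert single["mets"] == bool(row["mets"])

    def test_sedentary_spending_coupling_recovered(self):
        cfg = CohortConfig(sedentary_spending_rho=0.3)
        cohort = generate_cohort(5000, cfg, seed=7)
        rho = sps.spearmanr(cohort["spending"], cohort["sedentary"]).statistic
        assert 0.2 <= rho <= 0.4

    def test_zero_variance_healthy_config(self):
        cfg = CohortConfig(
            diagnostic_sd={k: 0.0 for k in ("waist", "sbp", "dbp", "tg", "hdl", "fbg")},
            diagnostic_mean={"waist": 75, "sbp": 110, "dbp": 70, "tg": 1.0, "hdl": 1.5, "fbg": 5.0},
        )
        cohort = generate_cohort(2, cfg, seed=0)
        assert not cohort["mets"].any()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(1)
        bad = CohortConfig(diagnostic_sd={"waist": -1, "sbp": 20, "dbp": 11, "tg": 0.8, "hdl": 0.33, "fbg": 1.1})
        with pytest.raises(ValueError, match="invalid config"):
            generate_cohort(10, bad)

    def test_reproducible(self):
        a = generate_cohort(50, seed=11)
        b = generate_cohort(50, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_basic_invariants(self):
        cohort = generate_cohort(500, seed=3)
        assert (cohort["age"] >= 18).all()
        assert cohort["bristol"].between(1, 7).all()
        for col in ("waist", "sbp", "dbp", "tg", "hdl", "fbg"):
            assert (cohort[col] > 0).all()
        assert set(cohort["spending_group"]) == {"low", "moderate", "high"}

    def test_spending_group_proportions(self):
        cohort = generate_cohort(4000, seed=4)
        props = cohort["spending_group"].value_counts(normalize=True)
        assert props["low"] == pytest.approx(0.251, abs=0.02)
        assert props["moderate"] == pytest.approx(0.513, abs=0.02)


class TestOtuTable:
    def test_rows_sum_to_depth_and_reproducible(self):
        cohort = generate_cohort(30, seed=5)
        t1 = generate_otu_table(cohort, [], n_otus=50, depth=800, seed=6)
        t2 = generate_otu_table(cohort, [], n_otus=50, depth=800, seed=6)
        assert (t1.counts.sum(axis=1) == 800).all()
        assert t1 == t2

    def test_unknown_factor_rejected(self):
        cohort = generate_cohort(20, seed=5)
        with pytest.raises(ValueError, match="unknown factor"):
            generate_otu_table(cohort, [GroundTruthEffect("OTU00000", "bmi", 0.5)], n_otus=20, depth=500)

    def test_unknown_otu_rejected(self):
        cohort = generate_cohort(20, seed=5)
        with pytest.raises(ValueError, match="unknown OTU"):
            generate_otu_table(cohort, [GroundTruthEffect("nope", "mets", 0.5)], n_otus=20, depth=500)

    def test_planted_positive_effect_raises_abundance_in_mets(self):
        cohort = generate_cohort(2000, seed=8)
        tax = assign_taxonomy(60, seed=8)
        effects = [GroundTruthEffect("OTU00010", "mets", 0.5)]
        table = generate_otu_table(cohort, effects, n_otus=60, depth=2000, seed=9, taxonomy=tax)
        rel = table.relative_abundance()["OTU00010"]
        mean_mets = rel[cohort["mets"]].mean()
        mean_non = rel[~cohort["mets"]].mean()
        assert mean_mets > mean_non

    def test_non_planted_otus_stay_null(self):
        # with a direction-mixed planted set the redistribution must not
        # leak into non-planted OTUs
        cohort = generate_cohort(3000, seed=18)
        tax = assign_taxonomy(80, seed=18)
        effects = [
            GroundTruthEffect("OTU00005", "mets", 0.8),
            GroundTruthEffect("OTU00006", "mets", -0.8),
        ]
        table = generate_otu_table(cohort, effects, n_otus=80, depth=5000, seed=19, taxonomy=tax)
        rel = table.relative_abundance()
        pvals = []
        for otu in rel.columns:
            if otu in ("OTU00005", "OTU00006"):
                continue
            a = rel.loc[cohort["mets"], otu]
            b = rel.loc[~cohort["mets"], otu]
            pvals.append(sps.mannwhitneyu(a, b).pvalue)
        frac_sig = np.mean(np.asarray(pvals) < 0.05)
        assert frac_sig < 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(pvals))

    def test_depth_and_size_validation(self):
        cohort = generate_cohort(10, seed=5)
        with pytest.raises(ValueError):
            generate_otu_table(cohort, [], n_otus=50, depth=50)
        with pytest.raises(ValueError):
            generate_otu_table(cohort, [], n_otus=5, depth=500)


class TestPlantedEffects:
    def test_directions_cluster_within_families(self):
        tax = assign_taxonomy(500, seed=20)
        effects = plant_effects(tax, 150, seed=21)
        by_family = {}
        for e in effects:
            if e.factor != "mets":
                continue
            fam = [p[3:] for p in tax[e.otu_id].split(";") if p.startswith("f__")][0]
            by_family.setdefault(fam, []).append(e.direction)
        consistent = [
            max(dirs.count(1), dirs.count(-1)) / len(dirs)
            for dirs in by_family.values()
            if len(dirs) >= 5
        ]
        assert np.mean(consistent) > 0.75

    def test_hdl_effect_opposes_disorder_direction(self):
        tax = assign_taxonomy(300, seed=22)
        effects = plant_effects(tax, 100, seed=23)
        by_otu = {}
        for e in effects:
            by_otu.setdefault(e.otu_id, {})[e.factor] = e.effect
        checked = 0
        for d in by_otu.values():
            if "hdl" in d:
                assert np.sign(d["hdl"]) == -np.sign(d["mets"])
                checked += 1
        assert checked > 5

    def test_one_record_per_otu_factor(self):
        tax = assign_taxonomy(100, seed=24)
        effects = plant_effects(tax, 40, seed=25)
        keys = [(e.otu_id, e.factor) for e in effects]
        assert len(keys) == len(set(keys))


class TestTree:
    def test_two_tips_cherry(self):
        tree = generate_tree(["A", "B"], seed=0)
        assert sorted(t.name for t in tree.tips()) == ["A", "B"]

    @pytest.mark.parametrize("k", [5, 23])
    def test_bifurcating_with_k_minus_1_internal_nodes(self, k):
        ids = [f"T{i}" for i in range(k)]
        tree = generate_tree(ids, seed=1)
        tips = list(tree.tips())
        internal = [n for n in tree.traverse() if n.children]
        assert len(tips) == k
        assert len(internal) == k - 1
        assert all(len(n.children) == 2 for n in internal)
        assert all(n.length > 0 for n in tree.traverse(include_self=False))

    def test_newick_deterministic(self):
        ids = [f"T{i}" for i in range(50)]
        s1 = str(generate_tree(ids, seed=42))
        s2 = str(generate_tree(ids, seed=42))
        assert s1 == s2

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            generate_tree(["A", "A"], seed=0)
        with pytest.raises(ValueError):
            generate_tree(["A"], seed=0)
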