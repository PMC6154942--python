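"""Association engine: transform, filtering, model oracles, de-confounding
and the directional network summary."""

import numpy as np
import pandas as pd
import pytest

from gutmets.association import (
    ArcsineSqrtTransform,
    AssociationModel,
    PrevalenceFilter,
    fit_associations,
    prevalence_filter,
    summarize_network,
    transform_abundance,
)
from gutmets.io import AssociationRecord, OtuTable
from gutmets.simulate import (
    CohortConfig,
    GroundTruthEffect,
    assign_taxonomy,
    generate_cohort,
    generate_otu_table,
)


class TestPrevalenceFilter:
    def make(self, present_fraction, n=100):
        counts = np.zeros((n, 2), dtype=int)
        counts[:, 0] = 5  # always-present reference OTU
        k = int(round(present_fraction * n))
        counts[:k, 1] = 3
        df = pd.DataFrame(counts, index=[f"s{i}" for i in range(n)], columns=["ref", "target"])
        return OtuTable(df)

    def test_boundary_inclusive(self):
        table = self.make(0.10)
        kept = prevalence_filter(table, 0.10)
        assert "target" in kept.otu_ids

    def test_below_threshold_removed(self):
        table = self.make(0.01)
        kept = prevalence_filter(table, 0.10)
        assert kept.otu_ids == ["ref"]

    def test_all_removed_raises(self):
        table = self.make(0.0)
        empty = OtuTable(table.counts[["target"]])
        with pytest.raises(ValueError, match="removed every OTU"):
            prevalence_filter(empty, 0.5)

    def test_sklearn_interface(self):
        f = PrevalenceFilter(min_prevalence=0.2)
        assert f.get_params() == {"min_prevalence": 0.2}
        f.set_params(min_prevalence=0.3)
        table = self.make(0.5)
        out = f.fit_transform(table)
        assert out.otu_ids == table.otu_ids


class TestAbundanceTransform:
    def test_closed_form_values(self):
        counts = pd.DataFrame([[0, 25, 75]], index=["s0"], columns=["a", "b", "c"])
        table = OtuTable(counts)
        y = transform_abundance(table)
        assert y.loc["s0", "a"] == 0.0
        assert y.loc["s0", "b"] == pytest.approx(np.arcsin(np.sqrt(0.25)), abs=1e-12)

    def test_full_abundance_maps_to_half_pi(self):
        table = OtuTable(pd.DataFrame([[10, 0]], index=["s0"], columns=["a", "b"]))
        y = transform_abundance(table)
        assert y.loc["s0", "a"] == pytest.approx(np.pi / 2, abs=1e-12)

    def test_log10_mode(self):
        table = OtuTable(pd.DataFrame([[10, 90]], index=["s0"], columns=["a", "b"]))
        y = ArcsineSqrtTransform(mode="log10", pseudo=0.5).fit(table).transform(table)
        assert y.loc["s0", "a"] == pytest.approx(np.log10(10.5 / 100), abs=1e-12)


class TestModelAgainstOLSOracle:
    def test_beta_matches_statsmodels_partial_coefficient(self):
        import statsmodels.api as sm

        from gutmets.simulate import factor_matrix

        cohort = generate_cohort(300, seed=31)
        tax = assign_taxonomy(20, seed=32)
        effects = [GroundTruthEffect("OTU00003", "mets", 0.4)]
        table = generate_otu_table(cohort, effects, n_otus=20, depth=2000, seed=33, taxonomy=tax)
        model = AssociationModel(factors=("mets",), confounders=("age",)).fit(table, cohort)
        recs = {r.otu_id: r for r in model.records_}

        y_all = transform_abundance(table)
        z = factor_matrix(cohort)["mets"].to_numpy()
        age = cohort["age"].to_numpy()
        age = (age - age.mean()) / age.std()
        X = sm.add_constant(np.column_stack([z, age]))
        for otu in table.otu_ids[:8]:
            fit = sm.OLS(y_all[otu].to_numpy(), X).fit()
            assert recs[otu].beta == pytest.approx(fit.params[1], abs=1e-8)
            assert recs[otu].p == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_aliased_covariate_dropped_with_warning(self):
        cohort = generate_cohort(120, seed=35)
        cohort["bristol"] = cohort["age"]  # perfectly aliased after scaling
        tax = assign_taxonomy(12, seed=36)
        table = generate_otu_table(cohort, [], n_otus=12, depth=800, seed=37, taxonomy=tax)
        with pytest.warns(UserWarning, match="aliased"):
            AssociationModel(factors=("mets",), confounders=("age", "bristol")).fit(table, cohort)

    def test_too_few_samples_skips_factor(self):
        cohort = generate_cohort(12, seed=38)
        tax = assign_taxonomy(10, seed=39)
        table = generate_otu_table(cohort, [], n_otus=10, depth=600, seed=40, taxonomy=tax)
        with pytest.warns(UserWarning, match="skipping factor"):
            model = AssociationModel(
                factors=("mets",), confounders=("age", "gender", "region", "bristol")
            ).fit(table, cohort)
        assert model.records_ == []


class TestRecovery:
    def test_single_planted_effect_recovered(self):
        cohort = generate_cohort(2000, seed=41)
        tax = assign_taxonomy(40, seed=42)
        effects = [GroundTruthEffect("OTU00007", "mets", 0.5)]
        table = generate_otu_table(cohort, effects, n_otus=40, depth=2000, seed=43, taxonomy=tax)
        records = fit_associations(table, cohort, factors=("mets",), confounders=())
        rec = {r.otu_id: r for r in records}["OTU00007"]
        assert rec.beta > 0
        assert rec.q <= 0.05

    def test_null_scenario_calibrated(self):
        cohort = generate_cohort(800, seed=44)
        tax = assign_taxonomy(150, seed=45)
        table = generate_otu_table(cohort, [], n_otus=150, depth=3000, seed=46, taxonomy=tax)
        filtered = prevalence_filter(table, 0.10)
        model = AssociationModel().fit(filtered, cohort)
        frac = len(model.significant_) / len(model.records_)
        se = np.sqrt(0.05 * 0.95 / len(model.records_))
        assert frac <= 0.05 + 3 * se

    def test_deconfounding_contrast(self):
        # OTU driven only by age; age correlated with MetS through the risk
        # latent. Adjusting for age must remove the spurious MetS hit.
        cfg = CohortConfig(age_risk_weight=0.6)
        cohort = generate_cohort(2500, seed=47)
        cohort_strong = generate_cohort(2500, cfg, seed=47)
        tax = assign_taxonomy(30, seed=48)
        table = generate_otu_table(cohort_strong, [], n_otus=30, depth=2000, seed=49, taxonomy=tax)
        # overwrite one OTU with an age-driven signal
        age = cohort_strong["age"].to_numpy()
        age_z = (age - age.mean()) / age.std()
        rng = np.random.default_rng(50)
        driven = np.clip(
            np.round(40 + 25 * age_z + 10 * rng.standard_normal(len(age_z))), 0, None
        ).astype(int)
        counts = table.counts.copy()
        counts["OTU00000"] = driven
        table2 = OtuTable(counts, table.taxonomy)

        with_conf = {
            r.otu_id: r
            for r in fit_associations(table2, cohort_strong, factors=("mets",), confounders=("age",))
        }
        without_conf = {
            r.otu_id: r
            for r in fit_associations(table2, cohort_strong, factors=("mets",), confounders=())
        }
        assert without_conf["OTU00000"].q <= 0.05
        assert with_conf["OTU00000"].q > 0.05

    def test_boosted_selection_keeps_planted_signal(self):
        cohort = generate_cohort(600, seed=51)
        tax = assign_taxonomy(25, seed=52)
        effects = [GroundTruthEffect("OTU00004", "mets", 0.6)]
        table = generate_otu_table(cohort, effects, n_otus=25, depth=2000, seed=53, taxonomy=tax)
        records = fit_associations(
            table, cohort, factors=("mets",), selection="boosted"
        )
        rec = {r.otu_id: r for r in records}["OTU00004"]
        assert rec.beta > 0 and rec.q <= 0.05


def make_record(otu, factor, sign, taxonomy="", q=0.01):
    return AssociationRecord(
        otu_id=otu, factor=factor, beta=sign * 0.2, p=q / 2, q=q,
        n_used=100, taxonomy=taxonomy, significant=True,
    )


class TestNetworkSummary:
    def test_hdl_valence_flip_in_totals(self):
        # 3 negative non-HDL, 2 positive non-HDL, 2 positive HDL, 1 negative HDL
        recs = (
            [make_record(f"O{i}", "waist", -1) for i in range(3)]
            + [make_record(f"P{i}", "tg", +1) for i in range(2)]
            + [make_record(f"H{i}", "hdl", +1) for i in range(2)]
            + [make_record("H9", "hdl", -1)]
        )
        s = summarize_network(recs)
        # raw per-factor counts keep the modelled sign
        assert s.per_factor.loc["hdl", "n_positive"] == 2
        assert s.per_factor.loc["hdl", "n_negative"] == 1
        # totals flip HDL: negatives 3 + 2, positives 2 + 1
        assert s.n_negative == 5
        assert s.n_positive == 3
        assert s.n_total == 8

    def test_per_taxon_counts_sum_to_taxon_records(self):
        tax_b = "k__Bacteria;p__Bacteroidetes;c__;o__;f__;g__;s__"
        tax_p = "k__Bacteria;p__Proteobacteria;c__;o__;f__;g__;s__"
        recs = [make_record(f"B{i}", "mets", -1, tax_b) for i in range(4)] + [
            make_record(f"P{i}", "mets", +1, tax_p) for i in range(3)
        ]
        s = summarize_network(recs, rank="phylum")
        assert s.per_taxon.loc["Bacteroidetes", "total"] == 4
        assert s.per_taxon.loc["Proteobacteria", "total"] == 3
        assert s.per_taxon["total"].sum() == s.n_total

    def test_missing_taxonomy_counted_unassigned(self):
        recs = [make_record("X1", "mets", +1, "")]
        s = summarize_network(recs)
        assert s.per_taxon.loc["Unassigned", "total"] == 1

    def test_empty_records_all_zero(self):
        s = summarize_network([])
        assert s.n_total == 0 and s.n_positive == 0 and s.n_negative == 0
        assert len(s.per_taxon) == 0

    def test_order_invariant(self):
        recs = (
            [make_record(f"O{i}", "waist", -1) for i in range(3)]
            + [make_record(f"H{i}", "hdl", +1) for i in range(2)]
        )
        s1 = summarize_network(recs)
        s2 = summarize_network(list(reversed(recs)))
        assert s1.n_negative == s2.n_negative
        pd.testing.assert_frame_equal(s1.per_factor, s2.per_factor)

    def test_insignificant_records_excluded(self):
        recs = [make_record("O1", "mets", +1)]
        weak = AssociationRecord("O2", "mets", 0.1, 0.5, 0.9, 100)
        s = summarize_network(recs + [weak])
        assert s.n_total == 1
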