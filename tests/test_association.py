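import numpy as np
import pytest
from scipy import stats

from genediv.association import (
    allele_class_test,
    glm_association,
    glm_single,
    maf_filter,
    trait_correlations,
    trait_summaries,
)
from genediv.io_core import PhenotypeTable, QMatrix
from genediv.variant_scan import MISSING, Variant, VariantTable

import pandas as pd


def make_variant(genotypes, vid="v1", kind="snp"):
    g = np.array(genotypes, dtype=object)
    alleles = sorted({a for a in g if a != MISSING},
                     key=lambda a: (-(g == a).sum(), a))
    return Variant(vid, kind, 1, 1, alleles, g)


class TestMafFilter:
    def test_rare_allele_dropped_and_carriers_masked(self):
        g = ["A"] * 50 + ["D"] * 27 + ["E"] * 3
        vt = VariantTable([f"s{i}" for i in range(80)], [make_variant(g)])
        out = maf_filter(vt, 0.05)
        v = out.variants[0]
        assert v.alleles == ["A", "D"]  # E at 3/80 = 0.0375 < 0.05
        assert v.n_missing == 3

    def test_allele_at_exact_threshold_retained(self):
        g = ["A"] * 76 + ["G"] * 4  # 4/80 = 0.05 exactly
        vt = VariantTable([f"s{i}" for i in range(80)], [make_variant(g)])
        assert maf_filter(vt, 0.05).variants[0].alleles == ["A", "G"]

    def test_balanced_biallelic_unchanged(self):
        g = ["A"] * 40 + ["G"] * 40
        vt = VariantTable([f"s{i}" for i in range(80)], [make_variant(g)])
        out = maf_filter(vt, 0.05)
        assert out.variants[0].counts == {"A": 40, "G": 40}

    def test_variant_left_monomorphic_is_removed(self):
        g = ["A"] * 78 + ["G"] * 2
        vt = VariantTable([f"s{i}" for i in range(80)], [make_variant(g)])
        assert len(maf_filter(vt, 0.05).variants) == 0


class TestGlmSingle:
    def test_without_structure_partial_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        x = np.array([0.0] * 30 + [1.0] * 20)
        y = rng.normal(0, 1, 50) + 0.4 * x
        res = glm_single(y, x, np.empty((50, 0)))
        t, p = stats.ttest_ind(y[x == 1], y[x == 0], equal_var=True)
        assert res["F"] == pytest.approx(t**2, rel=1e-10)
        assert res["p"] == pytest.approx(p, rel=1e-10)

    def test_collinear_marker_is_flagged(self):
        rng = np.random.default_rng(1)
        q = np.array([0.0] * 25 + [1.0] * 25).reshape(-1, 1)
        y = rng.normal(0, 1, 50)
        res = glm_single(y, q[:, 0], q)
        assert res["flagged"] and np.isnan(res["p"])

    def test_adding_covariates_never_increases_fit_error(self):
        rng = np.random.default_rng(2)
        n = 60
        y = rng.normal(0, 1, n)
        x = rng.integers(0, 2, n).astype(float)
        import statsmodels.api as sm

        q = rng.dirichlet([1, 1, 1], size=n)[:, :2]
        base = sm.OLS(y, sm.add_constant(x)).fit().ssr
        with_q = sm.OLS(y, sm.add_constant(np.column_stack([q, x]))).fit().ssr
        assert with_q <= base + 1e-12

    def test_marker_r2_invariant_to_affine_trait_rescale(self):
        rng = np.random.default_rng(3)
        n = 60
        x = rng.integers(0, 2, n).astype(float)
        q = rng.dirichlet([1, 1, 1], size=n)[:, :2]
        y = rng.normal(0, 1, n) + 0.5 * x
        a = glm_single(y, x, q)
        b = glm_single(5.0 - 2.5 * y, x, q)
        assert a["marker_r2"] == pytest.approx(b["marker_r2"], rel=1e-10)
        assert a["p"] == pytest.approx(b["p"], rel=1e-10)

    def test_type_one_error_controlled_under_null(self):
        """beta = 0, n = 80, Q covariates present: rejection rate at
        alpha = 0.05 stays within 0.05 +/- 0.02 over 1000 replicates."""
        rng = np.random.default_rng(20140801)
        n, reps = 80, 1000
        x = rng.integers(0, 2, n).astype(float)
        q = rng.dirichlet([2, 2, 2], size=n)[:, :2]
        rejections = 0
        for _ in range(reps):
            y = rng.normal(0, 1, n)
            rejections += glm_single(y, x, q)["p"] < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestAlleleClassTest:
    def test_class_means_match_direct_averages(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 20)
        res = allele_class_test(a, b)
        assert res["mean0"] == pytest.approx(a.mean(), abs=1e-12)
        assert res["sd1"] == pytest.approx(b.std(ddof=1), abs=1e-12)

    def test_power_for_half_sd_shift(self):
        """Planted shift of -0.5 sd with 27 vs 50 samples is detected at
        alpha = 0.05 in more than half of 200 replicates."""
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(200):
            a = rng.normal(0, 1, 50)
            b = rng.normal(-0.5, 1, 27)
            hits += allele_class_test(a, b)["t_p"] < 0.05
        assert hits / 200 > 0.5

    def test_null_p_is_roughly_uniform(self):
        rng = np.random.default_rng(6)
        ps = [allele_class_test(rng.normal(0, 1, 30), rng.normal(0, 1, 30))["t_p"]
              for _ in range(400)]
        assert 0.02 < np.mean(np.array(ps) < 0.05) < 0.10
        assert abs(np.mean(ps) - 0.5) < 0.06


class TestTraitSummaries:
    def test_descriptives_and_anova_on_generator_traits(self, phenotypes):
        df = trait_summaries(phenotypes).set_index("trait")
        assert (df["min"] <= df["mean"]).all() and (df["mean"] <= df["max"]).all()
        assert (df["F"] > 0).all()
        assert (df["p"] < 0.05).all()  # replicate noise was calibrated to real F scales

    def test_duplicated_trait_correlates_perfectly(self, phenotypes):
        pt = PhenotypeTable(phenotypes.data.assign(PV2=phenotypes.data["PV"]))
        r, p = trait_correlations(pt)
        assert r.loc["PV", "PV2"] == pytest.approx(1.0)
        assert p.loc["PV", "PV2"] < 1e-10

    def test_constant_trait_has_undefined_correlations(self, phenotypes):
        data = phenotypes.data.copy()
        data["flat"] = 1.0
        r, _ = trait_correlations(PhenotypeTable(data))
        assert r.loc["flat", "PV"] != r.loc["flat", "PV"]  # NaN

    def test_independent_traits_show_nominal_false_positive_rate(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame({"line": [f"L{i}" for i in range(100)]})
        for t in range(12):
            data[f"T{t}"] = rng.normal(0, 1, 100)
        r, p = trait_correlations(PhenotypeTable(data))
        mask = np.triu(np.ones_like(p, dtype=bool), k=1)
        pvals = p.to_numpy()[mask]
        assert np.mean(pvals < 0.05) < 0.15
        off = np.abs(r.to_numpy()[mask])
        assert off.mean() < 0.2


class TestAssociationScan:
    def test_causal_indel_tops_the_scan_on_its_trait(self, variants, phenotypes, qmatrix):
        scan = glm_association(variants, phenotypes, qmatrix, traits=["dH"])
        res = scan.results.dropna(subset=["p"])
        assert res.nsmallest(1, "p").iloc[0]["variant"] == "indel7"
        row = res[res["variant"] == "indel7"].iloc[0]
        assert row["n"] == 77  # the rare two-residue deletion class is excluded
        assert 0 <= row["marker_r2"] <= 1
        assert row["mean1"] < row["mean0"]  # deletion carriers have lower values

    def test_bonferroni_column_scales_raw_p(self, variants, phenotypes, qmatrix):
        scan = glm_association(variants, phenotypes, qmatrix, traits=["dH", "PV"])
        res = scan.results.dropna(subset=["p"])
        m = res["p"].notna().sum()
        expected = np.minimum(res["p"] * m, 1.0)
        np.testing.assert_allclose(res["p_bonferroni"], expected)

    def test_omitting_q_inflates_structured_null_trait(self, cfg):
        """PV carries subpopulation shifts but no causal variant: a
        structure-correlated variant shows inflated significance without
        Q and nominal significance with it."""
        from genediv.simulate import simulate_panel, simulate_phenotypes, simulate_q
        from genediv.variant_scan import call_variants

        with_q = without_q = 0
        reps = 60
        for seed in range(reps):
            panel, truth = simulate_panel(cfg, seed)
            vt = call_variants(panel, cfg.model)
            q = simulate_q(cfg, truth, seed)
            phen = simulate_phenotypes(cfg, truth, q, seed)
            ones = QMatrix(q.sample_ids, np.ones((len(q.sample_ids), 1)))
            snp = next(v for v in vt.snps() if v.position == 40)  # one-subpop clade marker
            sub = VariantTable(vt.sample_ids, [snp])
            res_q = glm_association(sub, phen, q, traits=["PV"]).results
            res_0 = glm_association(sub, phen, ones, traits=["PV"]).results
            with_q += res_q["p"].iloc[0] < 0.05
            without_q += res_0["p"].iloc[0] < 0.05
        assert without_q / reps > with_q / reps + 0.15
        assert with_q / reps < 0.2
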