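import numpy as np
import pytest

from genediv.diversity import (
    fu_li_star,
    neutrality_constants,
    pairwise_pi,
    summarize_regions,
    tajima_d_pvalue,
    tajimas_d,
    watterson_theta,
)
from genediv.simulate import simulate_neutral_panel
from genediv.variant_scan import call_snps

from conftest import toy_panel


def brute_force_pi(rows: list[str]) -> float:
    """Independent double-loop oracle: mean over pairs of per-site
    mismatch fraction over both-called sites."""
    n = len(rows)
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            diffs = shared = 0
            for a, b in zip(rows[i], rows[j]):
                if a == "N" or b == "N":
                    continue
                shared += 1
                diffs += a != b
            if shared:
                vals.append(diffs / shared)
    return sum(vals) / len(vals)


class TestPairwisePi:
    def test_identical_sequences_give_zero(self):
        panel = toy_panel(["ACGT" * 5] * 3)
        assert pairwise_pi(panel, range(1, 21)) == 0.0

    def test_two_sequences_one_diff_in_hundred(self):
        a = "A" * 100
        b = "A" * 99 + "G"
        assert pairwise_pi(toy_panel([a, b]), range(1, 101)) == pytest.approx(0.01)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_random_panels(self, seed):
        rng = np.random.default_rng(seed)
        rows = ["".join(rng.choice(list("ACGTN"), 50, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
                for _ in range(8)]
        panel = toy_panel(rows)
        assert pairwise_pi(panel, range(1, 51)) == pytest.approx(brute_force_pi(rows), abs=1e-12)

    def test_invariant_under_sample_and_column_permutation(self):
        rng = np.random.default_rng(5)
        rows = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(6)]
        panel = toy_panel(rows)
        base = pairwise_pi(panel, range(1, 31))
        cols = rng.permutation(np.arange(1, 31))
        assert pairwise_pi(panel, cols) == pytest.approx(base, abs=1e-15)
        shuffled = toy_panel([rows[i] for i in rng.permutation(6)])
        assert pairwise_pi(shuffled, range(1, 31)) == pytest.approx(base, abs=1e-15)

    def test_empty_column_set_is_nan(self):
        assert np.isnan(pairwise_pi(toy_panel(["AC", "AC"]), []))


class TestWattersonTheta:
    def test_zero_segregating_sites(self):
        assert watterson_theta(0, 80, 1000) == 0.0

    def test_closed_form_small_case(self):
        # n=4: a1 = 1 + 1/2 + 1/3 = 11/6
        assert watterson_theta(11, 4, 100) == pytest.approx(11 / ((11 / 6) * 100))


class TestTajimasD:
    def test_numerator_identity_gives_zero(self):
        c = neutrality_constants(80)
        S, L = 10, 1000
        pi = S / c.a1 / L  # pi*L == S/a1
        assert tajimas_d(pi, S, 80, L) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_without_segregating_sites(self):
        assert np.isnan(tajimas_d(0.0, 0, 80, 1000))

    def test_pvalue_properties(self):
        assert 0 <= tajima_d_pvalue(0.0, 80) <= 1
        assert tajima_d_pvalue(3.0, 80) < tajima_d_pvalue(1.0, 80)


class TestFuLiStar:
    def test_dstar_numerator_identity(self):
        n, S = 80, 22
        c = neutrality_constants(n)
        eta_s = (n / (n - 1)) * S / c.a1
        dstar, _ = fu_li_star(S, eta_s, 0.001, n, 2000)
        assert dstar == pytest.approx(0.0, abs=1e-12)

    def test_nan_pair_without_segregating_sites(self):
        d, f = fu_li_star(0, 0, 0.0, 80, 1000)
        assert np.isnan(d) and np.isnan(f)

    @pytest.mark.parametrize("n,S,eta_s,kbar", [(4, 3, 1, 1.5), (6, 8, 2, 3.2), (10, 5, 0, 2.4)])
    def test_matches_independent_transcription_of_published_forms(self, n, S, eta_s, kbar):
        """Re-derive D*/F* from an independent, direct transcription of the
        coefficient formulas and compare to 1e-9."""
        i = np.arange(1, n)
        an = np.sum(1.0 / i)
        bn = np.sum(1.0 / i**2)
        an1 = an + 1.0 / n
        cn = 2.0 * (n * an - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
        dn = cn + (n - 2.0) / (n - 1) ** 2 + (2.0 / (n - 1)) * (
            1.5 - (2 * an1 - 3) / (n - 2.0) - 1.0 / n)
        vD = ((n / (n - 1.0)) ** 2 * bn + an**2 * dn
              - 2 * (n * an * (an + 1)) / (n - 1.0) ** 2) / (an**2 + bn)
        uD = (n / (n - 1.0)) * (an - n / (n - 1.0)) - vD
        expected_d = ((n / (n - 1.0)) * S - an * eta_s) / np.sqrt(uD * S + vD * S**2)
        vF = ((2 * n**3 + 110 * n**2 - 255 * n + 153) / (9.0 * n**2 * (n - 1))
              + (2 * (n - 1) * an) / n**2 - 8.0 * bn / n) / (an**2 + bn)
        uF = ((4 * n**2 + 19 * n + 3 - 12 * (n + 1) * an1) / (3.0 * n * (n - 1))) / an - vF
        expected_f = (kbar - ((n - 1.0) / n) * eta_s) / np.sqrt(uF * S + vF * S**2)
        L = 100
        d, f = fu_li_star(S, eta_s, kbar / L, n, L)
        assert d == pytest.approx(expected_d, abs=1e-9)
        assert f == pytest.approx(expected_f, abs=1e-9)


class TestRegionSummaries:
    def test_monomorphic_regions_report_zero_and_nan(self, panel, cfg, variants):
        df = summarize_regions(panel, cfg.model, variants).set_index("region")
        for region in ("intron1", "exon2", "intron2"):
            row = df.loc[region]
            assert row["S"] == 0 and row["pi"] == 0.0 and row["theta_w"] == 0.0
            assert np.isnan(row["tajima_D"]) and np.isnan(row["fu_li_Dstar"])

    def test_net_lengths_exclude_indel_columns(self, panel, cfg, variants):
        df = summarize_regions(panel, cfg.model, variants).set_index("region")
        assert df.loc["promoter", "L_net"] == 519
        assert df.loc["exon1", "L_net"] == 621
        assert df.loc["entire", "L_net"] == 2436 - 37

    def test_union_segregating_sites_are_additive(self, panel, cfg, variants):
        df = summarize_regions(panel, cfg.model, variants,
                               {"exons": ["exon1", "exon2", "exon3"]}).set_index("region")
        assert df.loc["exons", "S"] == df.loc["exon1", "S"] + df.loc["exon2", "S"] + df.loc["exon3", "S"]
        assert df.loc["exons", "L_net"] == df.loc["exon1", "L_net"] + df.loc["exon2", "L_net"] + df.loc["exon3", "L_net"]

    def test_pi_from_variant_counts_equals_sequence_pi(self, panel, cfg, variants):
        """Oracle equivalence: with no missing bases, per-site pi from the
        variant table's allele counts must equal the sequence computation."""
        df = summarize_regions(panel, cfg.model, variants).set_index("region")
        n = panel.n_samples
        from genediv.variant_scan import gap_columns

        is_gap = gap_columns(panel)
        for region in cfg.model.regions:
            snps = [v for v in variants.snps() if region.start <= v.position <= region.end]
            L_net = int(np.sum(~is_gap[region.start - 1:region.end]))
            k = 0.0
            for v in snps:
                counts = np.array(list(v.counts.values()))
                k += (counts.sum() ** 2 - np.sum(counts**2)) / (n * (n - 1))
            expected = k / L_net if L_net else np.nan
            assert df.loc[region.name, "pi"] == pytest.approx(expected, abs=1e-12)


class TestNeutralSanityBand:
    def test_mean_statistics_near_zero_on_neutral_panels(self):
        """On neutral-equilibrium panels (n=80, S=20), the mean of Tajima's
        D and Fu & Li's D* over replicates sits in a band around 0 — a
        sanity check, not an exact test."""
        n, S, L, reps = 80, 20, 500, 500
        c = neutrality_constants(n)
        ds, dstars = [], []
        for seed in range(reps):
            panel = simulate_neutral_panel(n, S, L, seed=seed)
            vt = call_snps(panel)
            counts = [list(v.counts.values()) for v in vt.variants]
            k = sum((sum(cc) ** 2 - sum(c_ * c_ for c_ in cc)) / (n * (n - 1)) for cc in counts)
            s_obs = len(counts)
            eta_s = sum(1 for cc in counts if min(cc) == 1)
            ds.append(tajimas_d(k / L, s_obs, n, L))
            dstars.append(fu_li_star(s_obs, eta_s, k / L, n, L)[0])
        assert -0.3 < np.mean(ds) < 0.3
        assert abs(np.mean(dstars)) < 0.3
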