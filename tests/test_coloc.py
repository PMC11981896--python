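"""Colocalization: ABF formula, enumeration oracle, loci, proxies, exclusion."""

import numpy as np
import pandas as pd
import pytest

from gsemkit.coloc import (
    ColocPriors, GenomicRegion, LocusData, coloc_posteriors, define_loci,
    exclude_region, ld_proxy, log_abf, wakefield_abf,
)
from gsemkit.sumstats import InputError, MungedTrait, ReferencePanel
from gsemkit.synthgen import simulate_coloc_locus


def locus_from_frames(df1, df2, **kw):
    return LocusData("L", 1, (1, 10 ** 6), df1["SNP"].iloc[0], df1, df2, **kw)


def random_locus(n, seed):
    rng = np.random.default_rng(seed)
    mk = lambda: pd.DataFrame({
        "SNP": [f"s{i}" for i in range(n)],
        "BETA": rng.normal(0, 0.15, n),
        "VARBETA": rng.uniform(0.001, 0.01, n),
        "MAF": rng.uniform(0.1, 0.5, n),
        "N": 50_000.0,
    })
    return locus_from_frames(mk(), mk())


def brute_force_pph(l1, l2, priors):
    """Enumeration over all causal-configuration pairs (the oracle)."""
    b1, b2 = np.exp(l1), np.exp(l2)
    n = len(b1)
    h0 = 1.0
    h1 = priors.p1 * b1.sum()
    h2 = priors.p2 * b2.sum()
    h3 = priors.p1 * priors.p2 * sum(
        b1[i] * b2[j] for i in range(n) for j in range(n) if i != j)
    h4 = priors.p12 * float(b1 @ b2)
    raw = np.array([h0, h1, h2, h3, h4])
    return raw / raw.sum()


class TestWakefieldAbf:
    def test_null_z_shrinks_below_one(self):
        W, varbeta = 0.04, 0.01
        r = W / (W + varbeta)
        assert wakefield_abf(0.0, varbeta, W) == pytest.approx(np.sqrt(1 - r))
        assert wakefield_abf(0.0, varbeta, W) < 1

    def test_direct_evaluation(self):
        # z = 5, r = 0.8 -> sqrt(0.2) e^10
        assert wakefield_abf(0.5, 0.01, 0.04) == pytest.approx(
            np.sqrt(0.2) * np.exp(10.0), rel=1e-12)

    def test_vanishing_prior_gives_unit_bayes_factor(self):
        assert wakefield_abf(0.5, 0.01, 0.0) == 1.0

    def test_nonpositive_varbeta_rejected(self):
        with pytest.raises(InputError):
            wakefield_abf(0.1, 0.0, 0.04)


class TestPosteriors:
    def test_single_snp_unit_abf_hand_enumeration(self):
        df = pd.DataFrame({"SNP": ["s0"], "BETA": [0.1], "VARBETA": [0.01],
                           "MAF": [0.3], "N": [50_000.0]})
        res = coloc_posteriors(locus_from_frames(df, df.copy()), W1=0.0, W2=0.0)
        expected0 = 1.0 / (1 + 1e-4 + 1e-4 + 1e-5)
        assert res.pph0 == pytest.approx(expected0, abs=1e-12)
        assert res.pph0 == pytest.approx(0.99979, abs=1e-5)
        assert res.pph3 == 0.0  # no two-distinct-variant configuration exists

    @pytest.mark.parametrize("n,seed", [(2, 0), (3, 1), (4, 2), (4, 3)])
    def test_matches_brute_force_enumeration(self, n, seed):
        locus = random_locus(n, seed)
        priors = ColocPriors()
        res = coloc_posteriors(locus, priors)
        l1 = log_abf(locus.trait1["BETA"].to_numpy(),
                     locus.trait1["VARBETA"].to_numpy(), 0.04)
        l2 = log_abf(locus.trait2["BETA"].to_numpy(),
                     locus.trait2["VARBETA"].to_numpy(), 0.04)
        assert np.allclose(res.pph, brute_force_pph(l1, l2, priors), atol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_posteriors_normalize(self, seed):
        res = coloc_posteriors(random_locus(10, seed))
        assert res.pph.sum() == pytest.approx(1.0, abs=1e-10)

    def test_snp_order_permutation_invariant(self):
        locus = random_locus(8, 5)
        res = coloc_posteriors(locus)
        perm = np.random.default_rng(0).permutation(8)
        locus_p = locus_from_frames(
            locus.trait1.iloc[perm].reset_index(drop=True),
            locus.trait2.iloc[perm].reset_index(drop=True))
        res_p = coloc_posteriors(locus_p)
        assert np.allclose(res.pph, res_p.pph, atol=1e-12)

    def test_prior_monotonicity_in_p12(self):
        locus = simulate_coloc_locus("H4", seed=0)
        last = -1.0
        for p12 in (1e-6, 1e-5, 1e-4):
            res = coloc_posteriors(locus, ColocPriors(p12=p12))
            assert res.pph4 >= last
            last = res.pph4

    def test_log_space_matches_naive_space(self):
        locus = random_locus(6, 7)
        priors = ColocPriors()
        res = coloc_posteriors(locus, priors)
        l1 = log_abf(locus.trait1["BETA"].to_numpy(),
                     locus.trait1["VARBETA"].to_numpy(), 0.04)
        l2 = log_abf(locus.trait2["BETA"].to_numpy(),
                     locus.trait2["VARBETA"].to_numpy(), 0.04)
        assert np.allclose(res.pph, brute_force_pph(l1, l2, priors), atol=1e-12)

    def test_large_z_no_overflow(self):
        n = 5
        df = pd.DataFrame({"SNP": [f"s{i}" for i in range(n)],
                           "BETA": [3.0] * n, "VARBETA": [1e-4] * n,
                           "MAF": [0.3] * n, "N": [5e5] * n})
        res = coloc_posteriors(locus_from_frames(df, df.copy()))
        assert np.isfinite(res.pph).all()
        assert res.pph.sum() == pytest.approx(1.0, abs=1e-10)

    def test_call_rule(self):
        h4 = coloc_posteriors(simulate_coloc_locus("H4", seed=1))
        assert (h4.call == "colocalized") == (h4.pph4 >= 0.75)
        h3 = coloc_posteriors(simulate_coloc_locus("H3", seed=1))
        assert (h3.call == "distinct_variants") == (h3.pph3 >= 0.75)

    def test_invalid_priors_rejected(self):
        with pytest.raises(InputError):
            ColocPriors(p1=1e-4, p2=1e-4, p12=1e-3)  # p12 > min(p1, p2)


class TestDefineLoci:
    @staticmethod
    def toy_table(rows):
        return pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "P"])

    def test_two_significant_snps_100kb_apart_merge(self):
        tab = self.toy_table([
            ("a", 1, 1_000_000, 1e-10),
            ("b", 1, 1_100_000, 1e-9),
        ])
        loci = define_loci(tab)
        assert len(loci) == 1
        assert loci[0][0] == "a"  # smaller p leads

    def test_no_significant_snps_empty(self):
        tab = self.toy_table([("a", 1, 1000, 1e-6)])
        assert define_loci(tab) == []

    def test_brute_force_clump_on_toy_table(self):
        # 10 SNPs: cluster A (3 sig within 250 kb), cluster B (2 sig, far),
        # chromosome 2 singleton, rest non-significant
        tab = self.toy_table([
            ("a1", 1, 1_000_000, 1e-12), ("a2", 1, 1_150_000, 1e-9),
            ("a3", 1, 1_350_000, 1e-8 / 2), ("ns1", 1, 1_200_000, 1e-4),
            ("b1", 1, 5_000_000, 1e-10), ("b2", 1, 5_200_000, 1e-9),
            ("ns2", 1, 5_100_000, 0.5), ("c1", 2, 1_000_000, 1e-9),
            ("ns3", 2, 1_001_000, 0.9), ("ns4", 2, 9_000_000, 1e-7),
        ])
        loci = define_loci(tab)
        leads = sorted(l for l, _ in loci)
        assert leads == ["a1", "b1", "c1"]
        regions = {l: r for l, r in loci}
        assert regions["a1"].start == 500_000
        assert regions["a1"].end == 1_500_000

    def test_sixteen_loci_toy(self):
        rows = [(f"s{i}", (i % 8) + 1, 10_000_000 * (i // 8 + 1), 1e-9)
                for i in range(16)]
        assert len(define_loci(self.toy_table(rows))) == 16

    def test_window_is_one_megabase(self):
        tab = self.toy_table([("a", 1, 2_000_000, 1e-9)])
        _, region = define_loci(tab)[0]
        assert region.end - region.start == 1_000_000


class TestLdProxy:
    def test_lead_present_in_both(self):
        assert ld_proxy("rs1", [("rs2", 0.99)], {"rs1", "rs2"}) == "rs1"

    def test_below_threshold_gives_none(self):
        assert ld_proxy("rs1", [("rs2", 0.6)], {"rs2"}) is None

    def test_argmax_r2_selected(self):
        got = ld_proxy("rs1", [("rs2", 0.85), ("rs3", 0.95)], {"rs2", "rs3"})
        assert got == "rs3"

    def test_unavailable_candidates_skipped(self):
        got = ld_proxy("rs1", [("rs2", 0.99), ("rs3", 0.9)], {"rs3"})
        assert got == "rs3"


class TestExcludeRegion:
    @staticmethod
    def panel_and_traits():
        panel = ReferencePanel(pd.DataFrame({
            "SNP": ["rs1", "rs2", "rs3", "rs4"],
            "CHR": [1, 1, 2, 2],
            "BP": [100, 200, 100, 200],
            "A1": list("AAAA"), "A2": list("GGGG"),
        }))
        t = MungedTrait("t", pd.DataFrame({
            "SNP": ["rs1", "rs2", "rs3", "rs4"],
            "Z": [1.0, 2.0, 3.0, 4.0], "N": [100.0] * 4,
        }))
        return panel, [t]

    def test_empty_region_is_noop(self):
        panel, traits = self.panel_and_traits()
        out = exclude_region(traits, GenomicRegion(1, 500, 600), panel)
        pd.testing.assert_frame_equal(out[0].table, traits[0].table)

    def test_whole_chromosome_removed(self):
        panel, traits = self.panel_and_traits()
        out = exclude_region(traits, GenomicRegion(2, 1, 10_000), panel)
        assert list(out[0].table["SNP"]) == ["rs1", "rs2"]

    def test_closed_interval_boundaries(self):
        panel, traits = self.panel_and_traits()
        out = exclude_region(traits, GenomicRegion(1, 100, 200), panel)
        assert list(out[0].table["SNP"]) == ["rs3", "rs4"]
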