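import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thermomethyl import dmr as dmr_mod
from thermomethyl import simulate as sim
from thermomethyl.config import SimulationConfig
from thermomethyl.dmr import DMRParams
from tests.conftest import make_sites


def two_groups(rows1, rows2):
    return [make_sites(rows1)], [make_sites(rows2)]


class TestSmoothing:
    def test_isolated_site_is_its_own_level(self):
        g = [make_sites([("chr1", 100, "+", 3, 10, "CG")])]
        out = dmr_mod.smooth_levels(g, "CG", "chr1", window_bp=500)
        assert np.isclose(out.iloc[0]["smoothed"], 0.3)

    def test_constant_region_identity(self):
        rows = [("chr1", 100 + 10 * i, "+", 4, 10, "CG") for i in range(20)]
        out = dmr_mod.smooth_levels([make_sites(rows)], "CG", "chr1", window_bp=500)
        np.testing.assert_allclose(out["smoothed"], 0.4, rtol=1e-12)

    def test_three_site_window_arithmetic(self):
        rows = [("chr1", 100, "+", 0, 10, "CG"), ("chr1", 150, "+", 10, 10, "CG"),
                ("chr1", 200, "+", 0, 10, "CG")]
        out = dmr_mod.smooth_levels([make_sites(rows)], "CG", "chr1", window_bp=500)
        assert np.isclose(out.iloc[1]["smoothed"], 1 / 3)

    def test_replicates_pooled_by_counts(self):
        g = [make_sites([("chr1", 100, "+", 2, 10, "CG")]),
             make_sites([("chr1", 100, "+", 8, 30, "CG")])]
        out = dmr_mod.smooth_levels(g, "CG", "chr1", window_bp=500)
        assert np.isclose(out.iloc[0]["smoothed"], 10 / 40)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dmr_mod.smooth_levels([], "CG", "chr1")


class TestDispersionShrinkage:
    def test_identical_sites_equal_common_estimate(self):
        # every site carries the same data -> site estimate == global estimate
        mc = np.tile(np.array([[2.0], [8.0], [3.0], [7.0]]), (1, 50))
        n = np.full((4, 50), 10.0)
        grp = np.array([1, 1, 2, 2])
        phi = dmr_mod.shrink_dispersion(mc, n, grp)
        np.testing.assert_allclose(phi, phi[0], rtol=1e-12)

    def test_huge_depth_converges_to_site_estimate(self):
        rng = np.random.default_rng(1)
        # 200 background sites at modest depth + one enormous-depth site
        n_bg = np.full((4, 200), 20.0)
        mc_bg = rng.binomial(20, 0.5, size=(4, 200)).astype(float)
        big_n, big_p = 5e7, 0.5
        mc_big = np.array([[0.4 * big_n], [0.6 * big_n], [0.45 * big_n], [0.55 * big_n]])
        mc = np.hstack([mc_bg, mc_big])
        n = np.hstack([n_bg, np.full((4, 1), big_n)])
        grp = np.array([1, 1, 2, 2])
        phi = dmr_mod.shrink_dispersion(mc, n, grp)
        # independent moment oracle for the big site alone
        phi_site = _moment_phi(mc[:, -1], n[:, -1], grp)
        assert abs(phi[-1] - min(max(phi_site, 1e-4), 0.5)) < 1e-3

    def test_two_site_toy_matches_moment_oracle(self):
        mc = np.array([[1.0, 9.0], [5.0, 5.0], [2.0, 8.0], [4.0, 6.0]])
        n = np.full((4, 2), 10.0)
        grp = np.array([1, 1, 2, 2])
        phi = dmr_mod.shrink_dispersion(mc, n, grp, prior_sites=0.0)
        # prior weight 0 -> pure site estimates
        for j in range(2):
            expect = min(max(_moment_phi(mc[:, j], n[:, j], grp), 0.0), 0.5)
            assert abs(phi[j] - max(expect, 1e-4)) < 1e-12


def _moment_phi(mc, n, grp):
    """Independent method-of-moments oracle for one site."""
    num, n_obs, info = 0.0, 0, 0.0
    for g in np.unique(grp):
        rows = grp == g
        mu = (mc[rows].sum() + 0.5) / (n[rows].sum() + 1.0)
        r = int(rows.sum())
        for m, d in zip(mc[rows], n[rows]):
            if d > 0:
                phat = m / d
                num += (phat - mu) ** 2 * d / (mu * (1 - mu)) * r / (r - 1)
                n_obs += 1
                info += d - 1
    return (num - n_obs) / info


class TestWaldTest:
    def test_identical_groups_null(self):
        rows = [("chr1", 100, "+", 5, 10, "CG"), ("chr1", 600, "+", 3, 12, "CG")]
        g1, g2 = two_groups(rows, rows)
        out = dmr_mod.site_tests(g1, g2, "CG", smooth_window_bp=0)
        np.testing.assert_allclose(out["wald"], 0.0)
        np.testing.assert_allclose(out["p"], 1.0)

    def test_extreme_separation(self):
        g1, g2 = two_groups([("chr1", 100, "+", 30, 30, "CG")],
                            [("chr1", 100, "+", 0, 30, "CG")])
        out = dmr_mod.site_tests(g1, g2, "CG", smooth_window_bp=0, phi_override=0.0)
        assert abs(out.iloc[0]["wald"]) > 10
        assert out.iloc[0]["p"] < 1e-10

    def test_phi_zero_reduces_to_two_proportion_ztest(self, rng):
        rows1 = [("chr1", 50 * i, "+", int(rng.integers(1, 9)), 10, "CG")
                 for i in range(30)]
        rows2 = [("chr1", 50 * i, "+", int(rng.integers(1, 9)), 12, "CG")
                 for i in range(30)]
        g1, g2 = two_groups(rows1, rows2)
        out = dmr_mod.site_tests(g1, g2, "CG", smooth_window_bp=0, phi_override=0.0)
        for i, (r1, r2) in enumerate(zip(rows1, rows2)):
            p1, n1 = r1[3] / r1[4], r1[4]
            p2, n2 = r2[3] / r2[4], r2[4]
            z = (p1 - p2) / np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
            assert np.isclose(out.iloc[i]["wald"], z, rtol=1e-12)

    def test_zero_coverage_group_skipped(self):
        g1, g2 = two_groups([("chr1", 100, "+", 5, 10, "CG")],
                            [("chr1", 100, "+", 0, 0, "CG")])
        out = dmr_mod.site_tests(g1, g2, "CG", smooth_window_bp=0)
        assert not out.iloc[0]["coverage_ok"]
        assert np.isnan(out.iloc[0]["p"])


class TestCallDmrs:
    def _tests_frame(self, specs):
        """Site-test rows from (pos, p, delta) tuples."""
        return pd.DataFrame({
            "chrom": "chr1", "pos": [s[0] for s in specs], "strand": "+",
            "context": "CG", "mu1": [0.5 + s[2] / 2 for s in specs],
            "mu2": [0.5 - s[2] / 2 for s in specs], "phi": 0.01,
            "wald": [5.0 * np.sign(s[2]) if s[1] < 1e-5 else 0.1 for s in specs],
            "p": [s[1] for s in specs], "coverage_ok": True,
            "raw_mc1": [int(100 * (0.5 + s[2] / 2)) for s in specs], "raw_n1": 100,
            "raw_mc2": [int(100 * (0.5 - s[2] / 2)) for s in specs], "raw_n2": 100,
        })

    def test_no_significant_sites_empty(self):
        t = self._tests_frame([(100, 0.5, 0.0), (200, 0.9, 0.0)])
        assert dmr_mod.call_dmrs(t).empty

    def test_five_site_run_single_hyper_dmr(self):
        t = self._tests_frame([(100 + 30 * i, 1e-6, 0.4) for i in range(5)])
        out = dmr_mod.call_dmrs(t)
        assert len(out) == 1
        d = out.iloc[0]
        assert d["direction"] == "hyper"
        assert d["start"] == 100 and d["end"] == 221
        assert d["n_sites"] == 5

    def test_distant_runs_not_merged(self):
        runs = [(100 + 20 * i, 1e-6, 0.4) for i in range(4)] + \
               [(310 + 20 * i, 1e-6, 0.4) for i in range(4)]  # 150 bp gap
        out = dmr_mod.call_dmrs(self._tests_frame(runs))
        assert len(out) == 2

    def test_close_runs_merged(self):
        runs = [(100 + 20 * i, 1e-6, 0.4) for i in range(4)] + \
               [(240 + 20 * i, 1e-6, 0.4) for i in range(4)]  # 80 bp gap
        out = dmr_mod.call_dmrs(self._tests_frame(runs))
        assert len(out) == 1

    def test_min_len_filter(self):
        t = self._tests_frame([(100, 1e-7, 0.3), (110, 1e-7, 0.3), (120, 1e-7, 0.3)])
        assert dmr_mod.call_dmrs(t).empty  # 21 bp < min_len 50
        assert len(dmr_mod.call_dmrs(t, DMRParams(min_len=10))) == 1

    def test_direction_follows_pooled_delta(self):
        t = self._tests_frame([(100 + 30 * i, 1e-6, -0.4) for i in range(5)])
        out = dmr_mod.call_dmrs(t)
        assert out.iloc[0]["direction"] == "hypo"
        assert out.iloc[0]["delta"] < 0


class TestDmgAnnotation:
    def test_body_containment(self, tiny_world):
        from thermomethyl.io import GeneModel
        genes = [GeneModel("g", "chr1", "+", 900, 2000)]
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 1000, "end": 1100,
                              "context": "CG", "direction": "hyper", "delta": 0.2}])
        out = dmr_mod.annotate_dmgs(dmrs, genes)
        assert list(out["region"]) == ["body"]

    def test_touching_is_not_overlap(self):
        from thermomethyl.io import GeneModel
        genes = [GeneModel("g", "chr1", "+", 1000, 2000)]
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 800, "end": 1000,
                              "context": "CG", "direction": "hyper", "delta": 0.2}])
        out = dmr_mod.annotate_dmgs(dmrs, genes)
        # touches the body at 1000 but overlaps only the promoter [0,1000)
        assert list(out["region"]) == ["promoter"]

    def test_random_fixture_matches_bruteforce(self, rng):
        from thermomethyl.io import GeneModel
        genes = [
            GeneModel(f"g{i}", "chr1", "+-"[i % 2],
                      int(s := rng.integers(2000, 180_000)), int(s + rng.integers(500, 4000)),
                      chrom_length=200_000)
            for i in range(50)
        ]
        starts = rng.integers(0, 199_000, 200)
        dmrs = pd.DataFrame({
            "chrom": "chr1", "start": starts,
            "end": starts + rng.integers(50, 1500, 200),
            "context": "CG", "direction": "hyper", "delta": 0.2,
        })
        got = dmr_mod.annotate_dmgs(dmrs, genes)
        got_keys = set(zip(got["gene_id"], got["region"], got["dmr_start"]))
        expect = set()
        for g in genes:
            for _, d in dmrs.iterrows():
                for region, (lo, hi) in (("promoter", g.promoter), ("body", g.body)):
                    if lo < hi and d["start"] < hi and lo < d["end"]:
                        expect.add((g.gene_id, region, int(d["start"])))
        assert got_keys == expect


class TestGroupSwapSymmetry:
    def test_swapping_groups_flips_direction(self, default_sim):
        cfg, genome, genes, reports, truth, _ = default_sim
        g28 = [reports["28C_IM_meth1"], reports["28C_IM_meth2"]]
        g16 = [reports["16C_IM_meth1"], reports["16C_IM_meth2"]]
        fwd = dmr_mod.run_dmr_analysis(g28, g16, contexts=("CG",))
        rev = dmr_mod.run_dmr_analysis(g16, g28, contexts=("CG",))
        assert len(fwd) == len(rev)
        f = fwd.sort_values("start").reset_index(drop=True)
        r = rev.sort_values("start").reset_index(drop=True)
        pd.testing.assert_frame_equal(
            f[["chrom", "start", "end", "n_sites"]], r[["chrom", "start", "end", "n_sites"]])
        assert (f["direction"].map({"hyper": "hypo", "hypo": "hyper"}) == r["direction"]).all()
        np.testing.assert_allclose(f["delta"], -r["delta"], rtol=1e-12)
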