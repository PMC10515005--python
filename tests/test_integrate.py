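import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from thermomethyl import integrate as im
from thermomethyl.config import ConfigurationError


class TestVenn:
    def test_basic_partition(self):
        v = im.venn_partition({"g1", "g2"}, {"g2", "g3"})
        assert v.a_only == {"g1"} and v.shared == {"g2"} and v.b_only == {"g3"}

    def test_equal_sets(self):
        v = im.venn_partition({"a", "b"}, {"a", "b"})
        assert v.a_only == frozenset() and v.b_only == frozenset()

    def test_random_sets_match_membership_scan(self, rng):
        pool = [f"g{i}" for i in range(60)]
        for _ in range(20):
            a = set(rng.choice(pool, rng.integers(0, 40), replace=False))
            b = set(rng.choice(pool, rng.integers(0, 40), replace=False))
            v = im.venn_partition(a, b)
            for g in pool:
                if g in a and g in b:
                    assert g in v.shared
                elif g in a:
                    assert g in v.a_only
                elif g in b:
                    assert g in v.b_only
                else:
                    assert g not in v.a_only | v.shared | v.b_only
            assert v.a_only | v.shared | v.b_only == a | b
            assert not (v.a_only & v.shared or v.a_only & v.b_only or v.shared & v.b_only)


class TestFcgCandidates:
    def test_set_difference_per_direction(self):
        deg_sets = {
            ("28Cvs16C", "IM"): {"up": {"a", "b", "c"}, "down": {"x"}},
            ("22Cvs16C", "IM"): {"up": {"b"}, "down": set()},
        }
        rules = [im.CandidateRule("IM", ("28Cvs16C", "IM"), ("22Cvs16C", "IM"), "IM")]
        out = im.select_fcg_candidates(deg_sets, rules)
        up = set(out.loc[out["direction"] == "up", "gene_id"])
        down = set(out.loc[out["direction"] == "down", "gene_id"])
        assert up == {"a", "c"} and down == {"x"}

    def test_empty_sets_no_candidates(self):
        deg_sets = {("A", "IM"): {"up": set(), "down": set()},
                    ("B", "IM"): {"up": set(), "down": set()}}
        rules = [im.CandidateRule("IM", ("A", "IM"), ("B", "IM"), "IM")]
        assert im.select_fcg_candidates(deg_sets, rules).empty

    def test_missing_contrast_is_config_error(self):
        rules = [im.CandidateRule("IM", ("A", "IM"), ("B", "IM"), "IM")]
        with pytest.raises(ConfigurationError, match="missing DEG table"):
            im.select_fcg_candidates({("A", "IM"): {"up": set()}}, rules)

    def test_default_rules_cover_both_cessations(self):
        available = {("28Cvs16C", "VR"), ("22Cvs16C", "VR"),
                     ("28Cvs16C", "IM"), ("22Cvs16C", "IM"),
                     ("22Cvs16C", "FP"), ("16C-FBvs16C-FP", "FP")}
        rules = im.default_cessation_rules(available)
        assert len(rules) == 4
        by_stage = {r.cessation_stage for r in rules}
        assert by_stage == {"IM", "FP"}
        # the FP-stage rule excludes the same-temperature developmental contrast
        fp_rules = [r for r in rules if r.cessation_stage == "FP"]
        assert any(r.exclude_key == ("16C-FBvs16C-FP", "FP") for r in fp_rules)
        # evidence from the cessation stage and the preceding stage stays separate
        im_rules = [r for r in rules if r.cessation_stage == "IM"]
        assert {r.evidence_stage for r in im_rules} == {"VR", "IM"}

    def test_rules_restricted_to_available(self):
        rules = im.default_cessation_rules({("28Cvs16C", "IM"), ("22Cvs16C", "IM")})
        assert len(rules) == 2  # IM rule + the FP rule using IM-stage tables


class TestMethDegs:
    def _dmgs(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "region", "chrom", "dmr_start",
                                           "dmr_end", "context", "direction", "delta"])

    def _degs(self, status):
        return pd.DataFrame({
            "baseMean": 10.0, "log2FC": 1.0, "p": 0.01, "padj": 0.01,
            "deg_status": pd.Series(status),
        })

    def test_label_mapping(self):
        dmgs = self._dmgs([("g1", "promoter", "chr1", 0, 100, "CG", "hyper", 0.3)])
        degs = self._degs({"g1": "down"})
        methdegs, counts = im.classify_methdegs(dmgs, degs)
        assert list(methdegs["class"]) == ["hyper-down"]
        assert counts == {"hyper-up": 0, "hyper-down": 1, "hypo-up": 0, "hypo-down": 0}

    def test_disjoint_sets_empty(self):
        dmgs = self._dmgs([("g1", "body", "chr1", 0, 100, "CG", "hyper", 0.3)])
        degs = self._degs({"g2": "up"})
        methdegs, counts = im.classify_methdegs(dmgs, degs)
        assert methdegs.empty and sum(counts.values()) == 0

    def test_counts_match_bruteforce_crosstab(self, rng):
        genes = [f"g{i}" for i in range(40)]
        dmg_rows = []
        for g in rng.choice(genes, 25, replace=False):
            dmg_rows.append((g, rng.choice(["promoter", "body"]), "chr1", 0, 100,
                             "CG", rng.choice(["hyper", "hypo"]), 0.2))
        dmgs = self._dmgs(dmg_rows)
        status = {g: rng.choice(["up", "down", "not"]) for g in genes}
        degs = self._degs(status)
        _, counts = im.classify_methdegs(dmgs, degs)
        for mdir, edir in itertools.product(("hyper", "hypo"), ("up", "down")):
            expect = len({
                g for (g, _, _, _, _, _, d, _) in dmg_rows
                if d == mdir and status[g] == edir
            })
            assert counts[f"{mdir}-{edir}"] == expect

    def test_order_invariance(self, rng):
        dmg_rows = [(f"g{i}", "promoter", "chr1", 0, 100, "CG", "hyper", 0.2)
                    for i in range(10)]
        dmgs = self._dmgs(dmg_rows)
        degs = self._degs({f"g{i}": "down" for i in range(10)})
        _, c1 = im.classify_methdegs(dmgs, degs)
        _, c2 = im.classify_methdegs(dmgs.sample(frac=1, random_state=3), degs)
        assert c1 == c2


class TestTripartite:
    def test_monotone_consistent(self):
        meth = pd.DataFrame({"16C": [0.3], "22C": [0.4], "28C": [0.5]}, index=["g"])
        expr = pd.DataFrame({"16C": [100.0], "22C": [50.0], "28C": [25.0]}, index=["g"])
        out = im.tripartite_relation(meth, expr, ["16C", "22C", "28C"])
        assert out.loc["g", "status"] == "consistent"
        assert out.loc["g", "rho_meth_temp"] == 1.0
        assert out.loc["g", "rho_meth_expr"] == -1.0

    def test_constant_methylation_uninformative(self):
        meth = pd.DataFrame({"16C": [0.3], "22C": [0.3], "28C": [0.3]}, index=["g"])
        expr = pd.DataFrame({"16C": [9.0], "22C": [5.0], "28C": [1.0]}, index=["g"])
        out = im.tripartite_relation(meth, expr, ["16C", "22C", "28C"])
        assert out.loc["g", "status"] == "uninformative"

    def test_wrong_direction_inconsistent(self):
        meth = pd.DataFrame({"16C": [0.5], "22C": [0.4], "28C": [0.3]}, index=["g"])
        expr = pd.DataFrame({"16C": [9.0], "22C": [5.0], "28C": [1.0]}, index=["g"])
        out = im.tripartite_relation(meth, expr, ["16C", "22C", "28C"])
        assert out.loc["g", "status"] == "inconsistent"

    def test_planted_fcgs_consistent(self, default_sim):
        cfg, _, _, _, truth, _ = default_sim
        fcg = sorted(truth.fcg_ids)
        out = im.tripartite_relation(
            truth.promoter_methylation.loc[fcg],
            truth.expression_mean.loc[fcg],
            list(cfg.conditions),
        )
        assert (out["status"] == "consistent").mean() >= 0.9

    def test_needs_two_temperatures(self):
        with pytest.raises(ValueError, match="two"):
            im.tripartite_relation(pd.DataFrame(), pd.DataFrame(), ["16C"])


class TestEnrichment:
    def test_exact_hypergeometric_example(self):
        universe = {f"g{i}" for i in range(20)}
        term_genes = {f"g{i}" for i in range(5)}
        tm = pd.DataFrame({"term": "T", "gene_id": sorted(term_genes)})
        out = im.enrich_terms(term_genes, universe, tm)
        # all 5 selected genes in a 5-gene term: p = 1/C(20,5)
        assert np.isclose(out.iloc[0]["p"], 1 / comb(20, 5), rtol=1e-12)
        assert out.iloc[0]["significant"]

    def test_zero_overlap_not_significant(self):
        universe = {f"g{i}" for i in range(20)}
        tm = pd.DataFrame({"term": "T", "gene_id": ["g0", "g1"]})
        out = im.enrich_terms({"g10", "g11"}, universe, tm)
        assert out.iloc[0]["p"] == 1.0 and not out.iloc[0]["significant"]

    def test_selection_equals_universe_saturates(self):
        universe = {f"g{i}" for i in range(10)}
        tm = pd.DataFrame({"term": "T", "gene_id": ["g0", "g1", "g2"]})
        out = im.enrich_terms(universe, universe, tm)
        assert out.iloc[0]["p"] == 1.0

    def test_gene_set_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            im.enrich_terms({"x"}, {"a"}, pd.DataFrame({"term": [], "gene_id": []}))

    def test_matches_exact_combinatorial_oracle(self, rng):
        """p equals the enumeration P(overlap >= k) for small universes."""
        for trial in range(25):
            m = int(rng.integers(5, 31))
            universe = {f"g{i}" for i in range(m)}
            k_term = int(rng.integers(1, m + 1))
            n_sel = int(rng.integers(1, m + 1))
            term = set(rng.choice(sorted(universe), k_term, replace=False))
            sel = set(rng.choice(sorted(universe), n_sel, replace=False))
            tm = pd.DataFrame({"term": "T", "gene_id": sorted(term)})
            out = im.enrich_terms(sel, universe, tm)
            k_obs = len(term & sel)
            oracle = sum(
                comb(k_term, j) * comb(m - k_term, n_sel - j)
                for j in range(k_obs, min(k_term, n_sel) + 1)
                if n_sel - j <= m - k_term
            ) / comb(m, n_sel)
            assert np.isclose(out.iloc[0]["p"], oracle, rtol=1e-9)


class TestQpcr:
    def test_zero_ddct_is_one(self):
        assert im.qpcr_relative_expression([20], [20], [20], [20]) == 1.0

    def test_ddct_two_is_quarter(self):
        # trt: target 24, ref 20; ctl: target 22, ref 20 -> ddCT = 2
        assert np.isclose(im.qpcr_relative_expression([24], [20], [22], [20]), 0.25)

    def test_replicates_averaged(self):
        out = im.qpcr_relative_expression([23, 25], [20, 20], [22, 22], [20, 20])
        assert np.isclose(out, 0.25)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="replicate"):
            im.qpcr_relative_expression([], [20], [20], [20])
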