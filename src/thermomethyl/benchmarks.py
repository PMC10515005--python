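"""Self-contained benchmark runs: calibration, null control, recovery.

Each function builds its own synthetic inputs from a seed, runs the relevant
pipeline stages from scratch and measures the result, so the same code backs
both the validation test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dmr as dmr_mod
from . import expression as expr_mod
from . import integrate as int_mod
from . import methcall as mc_mod
from . import simulate as sim_mod
from .config import SimulationConfig
from .pipeline import RunConfig, run_pipeline


def caller_null_rate(
    seed: int, n_seeds: int = 20, n_sites: int = 50_000,
    depth: float = 30.0, r: float = 0.005,
) -> dict:
    """Fraction of truly-unmethylated sites called methylated, per replicate.

    All sites have pi = 0; every methylated read is non-conversion noise, so
    any positive call is a false discovery of the binomial caller.
    """
    fractions = []
    for i in range(n_seeds):
        rng = np.random.default_rng([seed, 40, i])
        total = rng.poisson(depth, n_sites)
        mc = rng.binomial(total, r)
        sites = pd.DataFrame({
            "chrom": "chr1", "pos": np.arange(n_sites), "strand": "+",
            "mc": mc, "total": total, "context": "CG", "trinucleotide": "CGA",
        })
        called = mc_mod.call_methylated_sites(sites, r)
        fractions.append(called["is_methylated"].mean())
    arr = np.asarray(fractions)
    se = arr.std(ddof=1) / np.sqrt(n_seeds) if n_seeds > 1 else 0.0
    return {"mean_fraction": float(arr.mean()), "se": float(se),
            "fractions": arr.tolist(), "bound": 0.05 + 2 * float(se)}


def dmr_null_rates(seed: int, n_seeds: int = 20) -> dict:
    """Spurious DMRs per 200 kb per context on identical-pi two-group data."""
    per_context = {ctx: [] for ctx in ("CG", "CHG", "CHH")}
    for i in range(n_seeds):
        cfg = SimulationConfig(seed=seed + i, conditions=("16C", "28C"),
                               hyper_condition="28C", promoter_hyper_delta=0.0)
        genome, genes = sim_mod.generate_genome(cfg)
        reports, _ = sim_mod.simulate_methylome(genome, genes, cfg)
        dmrs = dmr_mod.run_dmr_analysis(
            [reports["28C_IM_meth1"], reports["28C_IM_meth2"]],
            [reports["16C_IM_meth1"], reports["16C_IM_meth2"]])
        units = cfg.n_chroms * cfg.chrom_length_bp / 200_000
        for ctx in per_context:
            n = int((dmrs["context"] == ctx).sum()) if not dmrs.empty else 0
            per_context[ctx].append(n / units)
    return {ctx: float(np.mean(v)) for ctx, v in per_context.items()}


def dmr_recovery(seed: int) -> dict:
    """Planted-effect recovery of the DMR caller at the default design.

    Promoter hypermethylation delta = 0.2 planted in the FCG set, 2
    replicates per group at 30x depth; measures the fraction of FCG
    promoters overlapped by a hyper-DMR, the fraction of unperturbed
    promoters hit, and the directional DMR counts.
    """
    cfg = SimulationConfig(seed=seed)
    genome, genes = sim_mod.generate_genome(cfg)
    reports, truth = sim_mod.simulate_methylome(genome, genes, cfg)
    warm = [reports[f"{cfg.hyper_condition}_IM_meth{r}"]
            for r in range(1, cfg.n_replicates_meth + 1)]
    cool = [reports[f"{cfg.conditions[0]}_IM_meth{r}"]
            for r in range(1, cfg.n_replicates_meth + 1)]
    dmrs = dmr_mod.run_dmr_analysis(warm, cool)
    dmgs = dmr_mod.annotate_dmgs(dmrs, genes)
    prom_hyper = set(dmgs.loc[(dmgs["region"] == "promoter")
                              & (dmgs["direction"] == "hyper"), "gene_id"])
    fcg = truth.fcg_ids
    non_fcg = {g.gene_id for g in genes} - fcg
    n_hyper = int((dmrs["direction"] == "hyper").sum()) if not dmrs.empty else 0
    n_hypo = int((dmrs["direction"] == "hypo").sum()) if not dmrs.empty else 0
    return {
        "promoter_recall": len(prom_hyper & fcg) / len(fcg),
        "nonfcg_hit_rate": len(prom_hyper & non_fcg) / len(non_fcg),
        "n_hyper": n_hyper, "n_hypo": n_hypo,
        "n_fcg": len(fcg),
    }


def de_calibration(seed: int, n_null: int = 5000, n_effect: int = 100) -> dict:
    """Type-I error on a null NB simulation and power on a planted 4-fold.

    Null: ``n_null`` genes, no effect, n = 3 per group; power: ``n_effect``
    genes at mean 200, dispersion 0.05 and 4-fold up, embedded among 900
    null genes so the BH family is realistic.
    """
    rng = np.random.default_rng([seed, 41])
    alpha = 0.05

    def nb(mu, size):
        lam = rng.gamma(1 / alpha, alpha * np.broadcast_to(mu, size))
        return rng.poisson(lam)

    cols = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=cols)

    mu0 = rng.lognormal(np.log(200), 1.0, n_null)
    null = pd.DataFrame(nb(mu0[:, None], (n_null, 6)), columns=cols,
                        index=[f"n{i}" for i in range(n_null)])
    res = expr_mod.nb_wald_test(null, groups, "A", "B")
    p = res["p"].dropna()
    type1 = float((p < 0.05).mean())

    n_bg = 900
    mu_bg = rng.lognormal(np.log(200), 1.0, n_bg)
    mu_eff = np.full(n_effect, 200.0)
    data = np.vstack([
        np.hstack([nb(4.0 * mu_eff[:, None], (n_effect, 3)),
                   nb(mu_eff[:, None], (n_effect, 3))]),
        nb(mu_bg[:, None], (n_bg, 6)),
    ])
    idx = [f"e{i}" for i in range(n_effect)] + [f"bg{i}" for i in range(n_bg)]
    power_res = expr_mod.nb_wald_test(
        pd.DataFrame(data, columns=cols, index=idx), groups, "A", "B")
    detected = (power_res.iloc[:n_effect]["deg_status"] == "up").sum()
    return {"type1_error": type1, "n_null_tested": int(len(p)),
            "power_4fold": float(detected / n_effect), "n_effect": n_effect}


def end_to_end_recovery(seed: int, outdir) -> dict:
    """Full default pipeline; recall/FDR of recovered FCGs vs ground truth."""
    cfg = RunConfig(simulation=SimulationConfig(seed=seed))
    report = run_pipeline(cfg, outdir)
    return report["recovery"] | {
        "methdeg_counts": report["methdeg_counts"],
        "dmr_counts": report["dmr_counts"],
    }


def tripartite_consistency(seed: int) -> dict:
    """Fraction of planted FCGs showing the expected tripartite trend."""
    cfg = SimulationConfig(seed=seed)
    genome, genes = sim_mod.generate_genome(cfg)
    _, truth = sim_mod.simulate_methylome(genome, genes, cfg)
    _, truth = sim_mod.simulate_expression(genes, truth, cfg)
    fcg = sorted(truth.fcg_ids)
    out = int_mod.tripartite_relation(
        truth.promoter_methylation.loc[fcg],
        truth.expression_mean.loc[fcg], list(cfg.conditions))
    return {"fraction_consistent": float((out["status"] == "consistent").mean()),
            "n_fcg": len(fcg)}
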