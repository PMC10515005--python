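"""End-to-end orchestration: simulate -> call -> DMR -> DE -> integrate -> scan.

A run is fully determined by a :class:`SimulationConfig` (or pre-existing
input files) plus analysis parameters; the report JSON carries DMR counts
per direction and context, DEG counts per contrast, methDEG class counts,
FCG-candidate counts and, when ground truth is available, recovery
precision/recall.  Input checksums are logged for auditability.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import dmr as dmr_mod
from . import expression as expr_mod
from . import integrate as int_mod
from . import io as io_mod
from . import methcall as mc_mod
from . import motifs as motif_mod
from . import simulate as sim_mod
from .config import SimulationConfig


@dataclass
class RunConfig:
    """All parameters of one pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    dmr_params: dmr_mod.DMRParams = field(default_factory=dmr_mod.DMRParams)
    fdr: float = 0.05
    fc_min: float = 1.5
    padj_max: float = 0.05
    motif_file: str | None = None
    motif_threshold: float = 0.85


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage on synthetic data and write outputs + report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    sim.validate()

    # ---- stage 1: synthetic data -----------------------------------------
    genome, genes = sim_mod.generate_genome(sim)
    reports, truth = sim_mod.simulate_methylome(genome, genes, sim)
    counts, truth = sim_mod.simulate_expression(genes, truth, sim)

    io_mod.write_fasta(genome, outdir / "genome.fa")
    io_mod.write_gtf(genes, outdir / "annotation.gtf")
    for name, rep in reports.items():
        io_mod.write_cytosine_report(rep, outdir / f"{name}.CX.tsv")
    io_mod.write_counts(counts, outdir / "expression_counts.tsv")
    truth.to_tsv(outdir / "ground_truth.tsv")

    checksums = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv")) + [outdir / "genome.fa"]
    }

    # ---- stage 2: methylation calling ------------------------------------
    meth_call_counts = {}
    for name, rep in reports.items():
        called = mc_mod.call_methylated_sites(rep, sim.nonconversion_rate_r, fdr=config.fdr)
        meth_call_counts[name] = int(called["is_methylated"].sum())

    # ---- stage 3: DMR calling (warm vs cool contrast) --------------------
    cool = sim.conditions[0]
    warm = sim.hyper_condition
    stage = sim.stages[0]
    group_names = {
        c: [f"{c}_{stage}_meth{r}" for r in range(1, sim.n_replicates_meth + 1)]
        for c in sim.conditions
    }
    dmrs = dmr_mod.run_dmr_analysis(
        [reports[n] for n in group_names[warm]],
        [reports[n] for n in group_names[cool]],
        params=config.dmr_params,
    )
    io_mod.write_bed(dmr_mod.dmrs_to_bed(dmrs), outdir / f"dmrs_{warm}vs{cool}.bed")
    dmgs = dmr_mod.annotate_dmgs(dmrs, genes)

    dmr_counts = {
        f"{ctx}:{direction}": int(
            ((dmrs["context"] == ctx) & (dmrs["direction"] == direction)).sum()
        )
        for ctx in io_mod.CONTEXTS for direction in ("hyper", "hypo")
    }

    # ---- stage 4: differential expression --------------------------------
    sample_cond = pd.Series(
        {c: c.split("_")[0] for c in counts.columns}, name="condition"
    )
    contrasts = [(c, cool) for c in sim.conditions if c != cool]
    de_results: dict[str, pd.DataFrame] = {}
    deg_counts = {}
    for warm_c, cool_c in contrasts:
        cols = sample_cond.index[sample_cond.isin([warm_c, cool_c])]
        res = expr_mod.nb_wald_test(
            counts[list(cols)], sample_cond[list(cols)], warm_c, cool_c,
            fc_min=config.fc_min, padj_max=config.padj_max,
        )
        label = f"{warm_c}vs{cool_c}"
        de_results[label] = res
        res.to_csv(outdir / f"de_{label}.tsv", sep="\t", index_label="gene_id")
        deg_counts[label] = {
            "up": int((res["deg_status"] == "up").sum()),
            "down": int((res["deg_status"] == "down").sum()),
        }

    # ---- stage 5: integration --------------------------------------------
    warm_label = f"{warm}vs{cool}"
    deg_sets = {
        (label, stage): expr_mod.deg_sets(res) for label, res in de_results.items()
    }
    other = [lab for lab, _ in deg_sets if lab != warm_label]
    rules = [
        int_mod.CandidateRule(stage, (warm_label, stage), (lab, stage), stage)
        for lab in other
    ]
    candidates = int_mod.select_fcg_candidates(deg_sets, rules)
    methdegs, methdeg_counts = int_mod.classify_methdegs(dmgs, de_results[warm_label])
    methdegs.to_csv(outdir / "methdegs.tsv", sep="\t", index=False)
    candidates.to_csv(outdir / "fcg_candidates.tsv", sep="\t", index=False)

    recovery = int_mod.recover_fcgs(methdegs, candidates, truth.fcg_ids)

    report = {
        "seed": sim.seed,
        "contrast": warm_label,
        "methylated_site_calls": meth_call_counts,
        "dmr_counts": dmr_counts,
        "n_dmgs": int(dmgs["gene_id"].nunique()) if not dmgs.empty else 0,
        "deg_counts": deg_counts,
        "methdeg_counts": methdeg_counts,
        "n_fcg_candidates": int(candidates["gene_id"].nunique()),
        "recovery": recovery.as_dict(),
        "null_run": sim.promoter_hyper_delta == 0.0,
        "input_checksums": checksums,
    }

    # ---- stage 6: optional motif scan ------------------------------------
    if config.motif_file:
        pfms = io_mod.read_jaspar(config.motif_file)
        fcg_prom = dmgs[
            (dmgs["region"] == "promoter")
            & dmgs["gene_id"].isin(set(methdegs["gene_id"]))
        ]
        hits = motif_mod.scan_promoter_dmrs(
            fcg_prom, genome, pfms, threshold=config.motif_threshold
        )
        motif_mod.summarize_hits(hits).to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
        report["n_motif_hits"] = int(len(hits))

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
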