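"""Methylome-transcriptome integration.

Implements the study's integrative logic: Venn partitions of DEG sets,
stage-specific FCG (floral-development cessation-associated gene) candidate
selection from non-overlapping DEGs, methDEG classification (DMG x DEG with
hyper/hypo x up/down labels), the tripartite temperature-methylation-
expression relation, plain hypergeometric term enrichment, and the
2^-ddCT qPCR helper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import ConfigurationError


@dataclass(frozen=True)
class VennPartition:
    """Disjoint partition of two same-direction DEG sets."""

    a_only: frozenset
    shared: frozenset
    b_only: frozenset


def venn_partition(set_a: set, set_b: set) -> VennPartition:
    a, b = set(set_a), set(set_b)
    return VennPartition(frozenset(a - b), frozenset(a & b), frozenset(b - a))


# ---------------------------------------------------------------------------
# FCG candidate selection


@dataclass(frozen=True)
class CandidateRule:
    """Take source-key DEGs not present in exclude-key DEGs, per direction.

    ``source_key``/``exclude_key`` address DEG tables as (contrast, stage)
    pairs; ``evidence_stage`` records whether the evidence comes from the
    cessation stage itself or the preceding stage (kept separate, never
    merged).
    """

    cessation_stage: str
    source_key: tuple[str, str]
    exclude_key: tuple[str, str]
    evidence_stage: str


def default_cessation_rules(
    available: set[tuple[str, str]],
    warm_contrast: str = "28Cvs16C",
    mild_contrast: str = "22Cvs16C",
    fb_contrast: str = "16C-FBvs16C-FP",
) -> list[CandidateRule]:
    """Rules for the IM- and FP-stage cessations, restricted to available keys.

    IM cessation (warmest regime): non-overlap of the warm contrast against
    the mild contrast at the VR and IM stages.  FP cessation (mild regime):
    non-overlap of the mild contrast against the same-temperature
    across-stage contrast at FP, plus the IM-stage non-overlap of the mild
    contrast against the warm one.
    """
    wanted = [
        CandidateRule("IM", (warm_contrast, "VR"), (mild_contrast, "VR"), "VR"),
        CandidateRule("IM", (warm_contrast, "IM"), (mild_contrast, "IM"), "IM"),
        CandidateRule("FP", (mild_contrast, "IM"), (warm_contrast, "IM"), "IM"),
        CandidateRule("FP", (mild_contrast, "FP"), (fb_contrast, "FP"), "FP"),
    ]
    return [r for r in wanted if r.source_key in available and r.exclude_key in available]


def select_fcg_candidates(
    deg_sets: dict[tuple[str, str], dict[str, set[str]]],
    rules: list[CandidateRule],
) -> pd.DataFrame:
    """Stage-specific candidates: source DEGs minus the excluded contrast's.

    ``deg_sets`` maps (contrast, stage) -> {"up": set, "down": set}.  One
    output row per (gene, rule, direction), with provenance columns.
    """
    rows = []
    for rule in rules:
        for key in (rule.source_key, rule.exclude_key):
            if key not in deg_sets:
                raise ConfigurationError(f"missing DEG table for contrast/stage {key}")
        for direction in ("up", "down"):
            src = deg_sets[rule.source_key].get(direction, set())
            excl = deg_sets[rule.exclude_key].get(direction, set())
            for gene in sorted(src - excl):
                rows.append({
                    "gene_id": gene, "cessation_stage": rule.cessation_stage,
                    "source_contrast": rule.source_key[0],
                    "source_stage": rule.source_key[1],
                    "direction": direction, "evidence_stage": rule.evidence_stage,
                })
    return pd.DataFrame(rows, columns=["gene_id", "cessation_stage", "source_contrast",
                                       "source_stage", "direction", "evidence_stage"])


# ---------------------------------------------------------------------------
# methDEG classification


def classify_methdegs(
    dmgs: pd.DataFrame, de_results: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Genes that are both DMG and DEG, classed (hyper/hypo) x (up/down).

    One row per (gene, region, methylation direction); the counts dict
    tallies unique genes per class label over all regions.
    """
    degs = de_results[de_results["deg_status"].isin(["up", "down"])]
    if dmgs.empty or degs.empty:
        empty = pd.DataFrame(columns=["gene_id", "region", "meth_direction",
                                      "expr_direction", "class"])
        return empty, {"hyper-up": 0, "hyper-down": 0, "hypo-up": 0, "hypo-down": 0}
    assoc = (
        dmgs.groupby(["gene_id", "region", "direction"], observed=True)
        .size().reset_index(name="n_dmrs")
    )
    assoc = assoc[assoc["gene_id"].isin(degs.index)]
    rows = []
    for _, a in assoc.iterrows():
        expr_dir = degs.loc[a["gene_id"], "deg_status"]
        rows.append({
            "gene_id": a["gene_id"], "region": a["region"],
            "meth_direction": a["direction"], "expr_direction": expr_dir,
            "class": f"{a['direction']}-{expr_dir}",
        })
    methdegs = pd.DataFrame(rows, columns=["gene_id", "region", "meth_direction",
                                           "expr_direction", "class"])
    methdegs = methdegs.sort_values(["gene_id", "region"]).reset_index(drop=True)
    counts = {}
    for mdir in ("hyper", "hypo"):
        for edir in ("up", "down"):
            label = f"{mdir}-{edir}"
            counts[label] = int(methdegs.loc[methdegs["class"] == label, "gene_id"].nunique())
    return methdegs, counts


# ---------------------------------------------------------------------------
# tripartite temperature-methylation-expression relation


def tripartite_relation(
    promoter_methylation: pd.DataFrame,
    expression: pd.DataFrame,
    temperature_order: list[str],
) -> pd.DataFrame:
    """Per-gene Spearman trends of methylation vs temperature and expression.

    A gene is 'consistent' iff its promoter methylation rises with
    temperature (rho > 0) and its expression falls as methylation rises
    (rho < 0); genes with constant inputs are 'uninformative'.
    """
    if len(temperature_order) < 2:
        raise ValueError("need at least two ordered temperatures")
    temps = np.arange(len(temperature_order), dtype=float)
    rows = []
    common = promoter_methylation.index.intersection(expression.index)
    for gene in common:
        meth = promoter_methylation.loc[gene, temperature_order].to_numpy(dtype=float)
        expr = expression.loc[gene, temperature_order].to_numpy(dtype=float)
        rho_mt = _spearman(meth, temps)
        rho_me = _spearman(meth, expr)
        if np.isnan(rho_mt) or np.isnan(rho_me):
            status = "uninformative"
        elif rho_mt > 0 and rho_me < 0:
            status = "consistent"
        else:
            status = "inconsistent"
        rows.append({"gene_id": gene, "rho_meth_temp": rho_mt,
                     "rho_meth_expr": rho_me, "status": status})
    return pd.DataFrame(rows).set_index("gene_id")


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# term enrichment


def enrich_terms(
    gene_set: set[str],
    universe: set[str],
    term_map: pd.DataFrame,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term, BH-corrected.

    ``term_map`` has columns ``term`` and ``gene_id``.  With selection size
    n out of a universe of M genes and K term members, p = P(overlap >= k)
    under sampling without replacement.
    """
    if not gene_set <= universe:
        raise ValueError("gene set must be a subset of the universe")
    m_universe = len(universe)
    n_sel = len(gene_set)
    rows = []
    tm = term_map[term_map["gene_id"].isin(universe)]
    for term, sub in tm.groupby("term"):
        members = set(sub["gene_id"])
        k = len(members & gene_set)
        p = float(stats.hypergeom.sf(k - 1, m_universe, len(members), n_sel))
        rows.append({"term": term, "overlap": k, "term_size": len(members),
                     "selection_size": n_sel, "universe_size": m_universe, "p": p})
    out = pd.DataFrame(rows, columns=["term", "overlap", "term_size",
                                      "selection_size", "universe_size", "p"])
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < q_max
    return out.sort_values("p").reset_index(drop=True)


# ---------------------------------------------------------------------------
# qPCR helper


def qpcr_relative_expression(
    target_treatment, reference_treatment, target_control, reference_control
) -> float:
    """Relative expression by 2^-ddCT, CT means taken over replicates.

    ddCT = (CT_target,trt - CT_ref,trt) - (CT_target,ctl - CT_ref,ctl).
    """
    arrs = [np.asarray(a, dtype=float).ravel()
            for a in (target_treatment, reference_treatment,
                      target_control, reference_control)]
    if any(a.size == 0 for a in arrs):
        raise ValueError("need at least one CT replicate per cell")
    tt, rt, tc, rc = (float(a.mean()) for a in arrs)
    ddct = (tt - rt) - (tc - rc)
    return float(2.0 ** (-ddct))


# ---------------------------------------------------------------------------
# recovery metrics against simulated ground truth


@dataclass
class RecoveryReport:
    predicted: set[str] = field(default_factory=set)
    truth: set[str] = field(default_factory=set)

    @property
    def recall(self) -> float:
        return len(self.predicted & self.truth) / len(self.truth) if self.truth else float("nan")

    @property
    def fdr(self) -> float:
        if not self.predicted:
            return 0.0
        return len(self.predicted - self.truth) / len(self.predicted)

    def as_dict(self) -> dict:
        return {"n_predicted": len(self.predicted), "n_truth": len(self.truth),
                "recall": self.recall, "fdr": self.fdr}


def recover_fcgs(
    methdegs: pd.DataFrame, candidates: pd.DataFrame, truth_fcg_ids: set[str]
) -> RecoveryReport:
    """Promoter hyper-down methDEGs intersected with down candidates, vs truth."""
    hyper_down = set(
        methdegs.loc[
            (methdegs["region"] == "promoter")
            & (methdegs["class"] == "hyper-down"), "gene_id"
        ]
    )
    cand_down = set(candidates.loc[candidates["direction"] == "down", "gene_id"])
    return RecoveryReport(predicted=hyper_down & cand_down, truth=set(truth_fcg_ids))
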