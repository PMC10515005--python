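"""Ground-truthed synthetic data: genome, annotation, methylomes, expression.

The generator emulates the statistical structure of a warming-temperature
methylome/transcriptome co-profiling experiment: per-cytosine counts with
context-specific baselines (CG >> CHG >> CHH), beta-binomial overdispersion,
bisulfite non-conversion noise, promoter hypermethylation planted in a chosen
FCG set under the warm condition, and negative-binomial expression whose mean
decays exponentially with promoter methylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.special import ndtri as _norm_ppf

from .config import ConfigurationError, SimulationConfig
from .io import GeneModel

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class GroundTruth:
    """Everything planted by the simulator, for downstream benchmarking."""

    fcg_ids: set[str] = field(default_factory=set)
    #: gene x condition mean planted promoter methylation probability
    promoter_methylation: pd.DataFrame | None = None
    #: gene x condition true expression mean (before size factors)
    expression_mean: pd.DataFrame | None = None
    #: site table (chrom,pos,strand,context) + one pi_<condition> column each
    site_pi: pd.DataFrame | None = None

    def to_tsv(self, path) -> None:
        df = self.promoter_methylation.add_prefix("prommeth_")
        if self.expression_mean is not None:
            df = df.join(self.expression_mean.add_prefix("exprmean_"))
        df.insert(0, "is_fcg", df.index.isin(sorted(self.fcg_ids)))
        df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# genome + annotation


def generate_genome(config: SimulationConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Uniform-random chromosomes with non-overlapping, strand-alternating genes.

    Genes are laid out in equal slots with a >= 2 kb margin on both sides, so
    every gene keeps a full-length promoter and no promoter touches a
    neighboring gene body.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    genome = {
        f"chr{i + 1}": b"".join(
            rng.choice(bases, size=config.chrom_length_bp)
        ).decode()
        for i in range(config.n_chroms)
    }

    genes: list[GeneModel] = []
    if config.n_genes == 0:
        return genome, genes
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    gi = 0
    for ci, k in enumerate(per_chrom):
        if k == 0:
            continue
        chrom = f"chr{ci + 1}"
        slot = config.chrom_length_bp // k
        if slot < config.gene_length_bp + 4000:
            raise ConfigurationError(
                f"infeasible packing on {chrom}: slot {slot} bp < "
                f"gene_length_bp + 4000 = {config.gene_length_bp + 4000}"
            )
        for j in range(k):
            start = j * slot + 2000
            genes.append(
                GeneModel(
                    gene_id=f"g{gi:04d}", chrom=chrom,
                    strand="+" if gi % 2 == 0 else "-",
                    start=start, end=start + config.gene_length_bp,
                    chrom_length=config.chrom_length_bp,
                )
            )
            gi += 1
    return genome, genes


# ---------------------------------------------------------------------------
# cytosine site enumeration


def enumerate_cytosines(genome: dict[str, str]) -> pd.DataFrame:
    """All C sites on both strands with trinucleotide contexts.

    A site's context comes from the actual trinucleotide read 5'->3' on the
    site's own strand (CG, CHG or CHH with H = A, T or C).  Sites whose
    trinucleotide would run past the chromosome end are skipped.  CG sites on
    opposite strands are kept as independent records, mirroring per-strand
    cytosine reports.
    """
    frames = []
    for chrom in sorted(genome):
        seq = np.frombuffer(genome[chrom].encode(), dtype="S1")
        n = len(seq)
        if n < 3:
            continue
        is_c = seq == b"C"
        is_g = seq == b"G"
        # plus strand: need two downstream bases
        plus = np.flatnonzero(is_c[: n - 2])
        plus_ctx = _context(is_g[plus + 1], is_g[plus + 2])
        plus_tri = _trinucs(genome[chrom], plus, "+")
        # minus strand: cytosine appears as G on the reference; context read
        # on the reverse complement, i.e. two upstream reference bases
        minus = np.flatnonzero(is_g[2:]) + 2
        minus_ctx = _context(is_c[minus - 1], is_c[minus - 2])
        minus_tri = _trinucs(genome[chrom], minus, "-")
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": np.concatenate([plus, minus]),
            "strand": ["+"] * len(plus) + ["-"] * len(minus),
            "context": np.concatenate([plus_ctx, minus_ctx]),
            "trinucleotide": plus_tri + minus_tri,
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context", "trinucleotide"])
    sites = pd.concat(frames, ignore_index=True)
    sites.sort_values(["chrom", "pos", "strand"], inplace=True, kind="mergesort")
    return sites.reset_index(drop=True)


def _context(next_is_pair: np.ndarray, next2_is_pair: np.ndarray) -> np.ndarray:
    ctx = np.where(next_is_pair, "CG", np.where(next2_is_pair, "CHG", "CHH"))
    return ctx


def _trinucs(seq: str, positions: np.ndarray, strand: str) -> list[str]:
    if strand == "+":
        return [seq[p:p + 3] for p in positions]
    return ["".join(_COMPLEMENT[b] for b in reversed(seq[p - 2:p + 1])) for p in positions]


# ---------------------------------------------------------------------------
# methylome simulation


def simulate_methylome(
    genome: dict[str, str],
    genes: list[GeneModel],
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Per-sample cytosine reports plus the planted ground truth.

    Site methylation probabilities are drawn once per site from a Beta
    distribution centered on the context baseline; FCG promoter sites in the
    warm condition are shifted up by ``promoter_hyper_delta`` (capped at 1).
    Per sample, depth is Poisson, the methylated count is beta-binomial, and
    each truly-unmethylated read falsely reports methylated with probability
    ``nonconversion_rate_r`` (methylated reads never de-convert).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    sites = enumerate_cytosines(genome)
    n_sites = len(sites)

    # base per-site probability, shared across conditions (null surface)
    pi0 = np.empty(n_sites)
    conc = config.site_pi_concentration
    for ctx, base in config.baseline_methylation.items():
        mask = (sites["context"] == ctx).to_numpy()
        if base <= 0.0 or base >= 1.0:
            pi0[mask] = base
        else:
            pi0[mask] = rng.beta(base * conc, (1.0 - base) * conc, size=int(mask.sum()))

    # choose FCGs and locate their promoter cytosines
    fcg_ids = _choose_fcgs(genes, config, rng)
    fcg_prom_mask = _promoter_mask(sites, genes, fcg_ids)

    pi_by_condition: dict[str, np.ndarray] = {}
    for cond in config.conditions:
        pi = pi0.copy()
        if cond == config.hyper_condition and config.promoter_hyper_delta > 0:
            pi[fcg_prom_mask] = np.minimum(pi[fcg_prom_mask] + config.promoter_hyper_delta, 1.0)
        pi_by_condition[cond] = pi

    phi = np.empty(n_sites)
    for ctx, val in config.overdispersion.items():
        phi[(sites["context"] == ctx).to_numpy()] = val

    reports: dict[str, pd.DataFrame] = {}
    r = config.nonconversion_rate_r
    for cond in config.conditions:
        pi = pi_by_condition[cond]
        for stage in config.stages:
            for rep in range(1, config.n_replicates_meth + 1):
                depth = rng.poisson(config.mean_depth, size=n_sites)
                p = _betabin_p(pi, phi, rng)
                m_true = rng.binomial(depth, p)
                m_obs = m_true + (rng.binomial(depth - m_true, r) if r > 0 else 0)
                df = sites.copy()
                df["mc"] = m_obs
                df["total"] = depth
                reports[f"{cond}_{stage}_meth{rep}"] = df[
                    ["chrom", "pos", "strand", "mc", "total", "context", "trinucleotide"]
                ]

    truth = GroundTruth(fcg_ids=fcg_ids)
    truth.promoter_methylation = _promoter_truth(sites, genes, pi_by_condition, config)
    site_pi = sites[["chrom", "pos", "strand", "context"]].copy()
    for cond in config.conditions:
        site_pi[f"pi_{cond}"] = pi_by_condition[cond]
    truth.site_pi = site_pi
    return reports, truth


def _betabin_p(pi: np.ndarray, phi: np.ndarray, rng) -> np.ndarray:
    """Per-read success probability: Beta(pi(1-phi)/phi, (1-pi)(1-phi)/phi)."""
    p = pi.copy()
    stochastic = (phi > 1e-8) & (pi > 0.0) & (pi < 1.0)
    if stochastic.any():
        scale = (1.0 - phi[stochastic]) / phi[stochastic]
        p[stochastic] = rng.beta(pi[stochastic] * scale, (1.0 - pi[stochastic]) * scale)
    return p


def _choose_fcgs(genes: list[GeneModel], config: SimulationConfig, rng) -> set[str]:
    ids = [g.gene_id for g in genes]
    if config.n_fcg == 0 or not ids:
        return set()
    return {str(g) for g in rng.choice(ids, size=config.n_fcg, replace=False)}


def _promoter_mask(sites: pd.DataFrame, genes: list[GeneModel], gene_ids: set[str]) -> np.ndarray:
    mask = np.zeros(len(sites), dtype=bool)
    pos = sites["pos"].to_numpy()
    chrom_arr = sites["chrom"].to_numpy()
    for g in genes:
        if g.gene_id not in gene_ids:
            continue
        lo, hi = g.promoter
        mask |= (chrom_arr == g.chrom) & (pos >= lo) & (pos < hi)
    return mask


def _promoter_truth(sites, genes, pi_by_condition, config) -> pd.DataFrame:
    rows = {}
    pos = sites["pos"].to_numpy()
    chrom_arr = sites["chrom"].to_numpy()
    for g in genes:
        lo, hi = g.promoter
        m = (chrom_arr == g.chrom) & (pos >= lo) & (pos < hi)
        rows[g.gene_id] = {
            cond: float(pi_by_condition[cond][m].mean()) if m.any() else 0.0
            for cond in config.conditions
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(config.conditions))


# ---------------------------------------------------------------------------
# expression simulation


def simulate_expression(
    genes: list[GeneModel],
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Gene x sample NB counts linked to promoter methylation.

    Mean model: ``mu_gc = mu_g0 * exp(-beta * promoter_methylation_gc)``;
    counts are negative binomial (Gamma-Poisson) with dispersion
    ``nb_dispersion`` around ``mu_gc * sizefactor_s``, size factors drawn
    log-uniform in [0.7, 1.4].  FCG base means are drawn from the upper
    tail of the log-normal (above ``fcg_basemean_quantile``): the genes
    whose suppression the design probes are apex-highly-expressed.
    """
    config.validate()
    if truth.promoter_methylation is None:
        raise ValueError("truth must carry per-gene promoter methylation per condition")
    rng = np.random.default_rng([config.seed, 3])
    gene_ids = [g.gene_id for g in genes]
    prom = truth.promoter_methylation.loc[gene_ids]
    mu0 = rng.lognormal(config.expr_basemean_log_mean, config.expr_basemean_log_sd,
                        size=len(gene_ids))
    is_fcg = np.array([g in truth.fcg_ids for g in gene_ids])
    if is_fcg.any() and config.fcg_basemean_quantile > 0:
        # truncated log-normal above the chosen quantile
        q0 = config.fcg_basemean_quantile
        u = rng.uniform(q0, 1.0, size=int(is_fcg.sum()))
        z = _norm_ppf(u)
        mu0[is_fcg] = np.exp(config.expr_basemean_log_mean
                             + config.expr_basemean_log_sd * z)
    beta = config.expression_link_beta
    mu = pd.DataFrame(
        {cond: mu0 * np.exp(-beta * prom[cond].to_numpy()) for cond in config.conditions},
        index=gene_ids,
    )

    alpha = config.nb_dispersion
    cols = {}
    for cond in config.conditions:
        for stage in config.stages:
            for rep in range(1, config.n_replicates_expr + 1):
                sf = np.exp(rng.uniform(np.log(0.7), np.log(1.4)))
                lam = rng.gamma(1.0 / alpha, alpha * mu[cond].to_numpy() * sf)
                cols[f"{cond}_{stage}_expr{rep}"] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    truth.expression_mean = mu
    return counts, truth
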