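"""Simulation and run configuration objects, with YAML (de)serialization."""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import yaml


class ConfigurationError(ValueError):
    """A configuration that violates a stated precondition."""


def _default_baseline() -> dict[str, float]:
    # CG >> CHG >> CHH, the ordering typical of plant methylomes
    return {"CG": 0.50, "CHG": 0.17, "CHH": 0.05}


def _default_overdispersion() -> dict[str, float]:
    return {"CG": 0.05, "CHG": 0.05, "CHH": 0.02}


@dataclass
class SimulationConfig:
    """Parameters of the miniature three-temperature co-profiling simulation.

    Defaults describe a desk-scale design: a 2 x 200 kb genome carrying 60
    non-overlapping genes, of which 12 are floral-development
    cessation-associated genes (FCGs) whose promoters gain
    ``promoter_hyper_delta`` methylation in the warmest condition, which in
    turn suppresses their expression through
    ``mu = mu0 * exp(-beta * promoter_methylation)``.
    """

    n_chroms: int = 2
    chrom_length_bp: int = 200_000
    n_genes: int = 60
    gene_length_bp: int = 2000
    conditions: tuple[str, ...] = ("16C", "22C", "28C")
    stages: tuple[str, ...] = ("IM",)
    n_replicates_meth: int = 2
    n_replicates_expr: int = 3
    mean_depth: float = 30.0
    baseline_methylation: dict[str, float] = field(default_factory=_default_baseline)
    overdispersion: dict[str, float] = field(default_factory=_default_overdispersion)
    nonconversion_rate_r: float = 0.005
    n_fcg: int = 12
    promoter_hyper_delta: float = 0.2
    hyper_condition: str = "28C"  # the condition carrying the planted effect
    expression_link_beta: float = 5.0
    nb_dispersion: float = 0.05
    expr_basemean_log_mean: float = math.log(200.0)
    expr_basemean_log_sd: float = 1.0
    #: FCGs are apex-highly-expressed: their base means are drawn from the
    #: upper tail of the expression distribution (above this quantile)
    fcg_basemean_quantile: float = 0.5
    site_pi_concentration: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_chroms < 1 or self.chrom_length_bp < 1:
            raise ConfigurationError("need at least one chromosome of positive length")
        if self.n_genes < 0 or self.n_fcg < 0:
            raise ConfigurationError("gene counts must be nonnegative")
        if self.n_fcg > self.n_genes:
            raise ConfigurationError(f"n_fcg={self.n_fcg} exceeds n_genes={self.n_genes}")
        for ctx, v in self.baseline_methylation.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"baseline_methylation[{ctx}]={v} outside [0,1]")
        for ctx, v in self.overdispersion.items():
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"overdispersion[{ctx}]={v} outside [0,1)")
        if not 0.0 <= self.nonconversion_rate_r <= 0.05:
            raise ConfigurationError(
                f"nonconversion_rate_r={self.nonconversion_rate_r} outside [0, 0.05]"
            )
        if not 0.0 <= self.promoter_hyper_delta <= 1.0:
            raise ConfigurationError("promoter_hyper_delta must lie in [0,1]")
        if self.expression_link_beta < 0:
            raise ConfigurationError(
                "expression_link_beta < 0: the suppression direction is a modeling "
                "commitment; invert the planted effect via configuration instead"
            )
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if not 0.0 <= self.fcg_basemean_quantile < 1.0:
            raise ConfigurationError("fcg_basemean_quantile must lie in [0, 1)")
        if self.hyper_condition not in self.conditions:
            raise ConfigurationError(
                f"hyper_condition {self.hyper_condition!r} not among conditions"
            )
        if self.n_genes > 0:
            per_chrom = math.ceil(self.n_genes / self.n_chroms)
            need = per_chrom * (self.gene_length_bp + 4000)
            if self.chrom_length_bp < need:
                raise ConfigurationError(
                    "infeasible gene packing: require chrom_length_bp >= "
                    f"ceil(n_genes/n_chroms) * (gene_length_bp + 4000) = {need}, "
                    f"got {self.chrom_length_bp}"
                )

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        d["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        cfg = cls(**d)
        cfg.validate()
        return cfg
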