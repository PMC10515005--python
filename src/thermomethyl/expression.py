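"""FPKM quantification and negative-binomial differential expression.

The test is a deliberately compact DESeq2-style NB Wald test: median-of-ratios
size factors, per-gene method-of-moments dispersion shrunk toward a fitted
mean-dispersion trend, and a Wald test on the log mean difference with a
delta-method standard error.  No Cox-Reid adjustment, LFC shrinkage,
independent filtering or outlier refitting.  DEG gates follow the study
convention: linear fold change >= 1.5 (or <= 1/1.5) and BH-adjusted
p <= 0.05, both boundaries inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DE_COLUMNS = ["baseMean", "log2FC", "p", "padj", "deg_status"]


def fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    mapped_totals: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM = counts * 1e9 / (gene length in bp * mapped fragments in sample)."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    if mapped_totals is None:
        mapped_totals = counts.sum(axis=0)
    totals = mapped_totals.reindex(counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("every sample needs a positive mapped total")
    return counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios normalization factors.

    The reference is the per-gene geometric mean over samples, restricted to
    genes with nonzero counts in every sample.  With ``pseudo_reference``
    the geometric mean ignores zeros instead (fallback for sparse matrices).
    """
    x = counts.to_numpy(dtype=float)
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logx = np.where(x > 0, np.log(x), np.nan)
        with np.errstate(invalid="ignore"):
            ref = np.exp(np.nanmean(logx, axis=1))
        usable = np.isfinite(ref) & (ref > 0)
        if not usable.any():
            raise ValueError("count matrix has no usable reference genes")
    else:
        usable = (x > 0).all(axis=1)
        if not usable.any():
            raise ValueError(
                "no gene has nonzero counts in all samples; "
                "re-run with pseudo_reference=True"
            )
        ref = np.full(x.shape[0], np.nan)
        ref[usable] = np.exp(np.log(x[usable]).mean(axis=1))
    ratios = x[usable] / ref[usable][:, None]
    factors = np.nanmedian(np.where(ratios > 0, ratios, np.nan), axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def nb_wald_test(
    counts: pd.DataFrame,
    groups: pd.Series,
    group1: str,
    group2: str,
    factors: pd.Series | None = None,
    prior_weight: float = 6.0,
    fc_min: float = 1.5,
    padj_max: float = 0.05,
) -> pd.DataFrame:
    """Per-gene NB Wald test of group1 vs group2 (log2FC = group1/group2).

    Genes with all-zero counts are excluded from testing and from the BH
    family.  Dispersion: method-of-moments on normalized counts per gene,
    shrunk toward a 1/mu trend with a prior weight of ``prior_weight``
    pseudo-samples.
    """
    groups = groups.reindex(counts.columns)
    cols1 = groups.index[groups == group1]
    cols2 = groups.index[groups == group2]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("need >= 2 samples per group for a dispersion estimate")
    if factors is None:
        factors = size_factors(counts[list(cols1) + list(cols2)])
    q = counts.div(factors, axis=1)

    tested = counts[list(cols1) + list(cols2)].sum(axis=1) > 0
    q1 = q.loc[tested, cols1].to_numpy(dtype=float)
    q2 = q.loc[tested, cols2].to_numpy(dtype=float)
    r1, r2 = q1.shape[1], q2.shape[1]
    c1 = float((1.0 / factors[cols1]).mean())
    c2 = float((1.0 / factors[cols2]).mean())

    mu1, mu2 = q1.mean(axis=1), q2.mean(axis=1)
    s1 = q1.var(axis=1, ddof=1)
    s2 = q2.var(axis=1, ddof=1)
    base_mean = q.loc[tested].mean(axis=1).to_numpy()

    # method-of-moments dispersion: Var(q) ~ mu * mean(1/sf) + alpha * mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = np.where(mu1 > 0, (s1 - mu1 * c1) / mu1**2, np.nan)
        a2 = np.where(mu2 > 0, (s2 - mu2 * c2) / mu2**2, np.nan)
    w1, w2 = r1 - 1.0, r2 - 1.0
    alpha_raw = np.nansum(np.vstack([a1 * w1, a2 * w2]), axis=0) / (
        w1 * np.isfinite(a1) + w2 * np.isfinite(a2)
    )
    alpha_raw = np.clip(np.nan_to_num(alpha_raw, nan=0.0), 0.0, 10.0)

    alpha_trend = _fit_dispersion_trend(base_mean, alpha_raw)
    df_total = r1 + r2 - 2.0
    alpha = (df_total * alpha_raw + prior_weight * alpha_trend) / (df_total + prior_weight)
    alpha = np.clip(alpha, 1e-8, 10.0)

    # moderated means only where a group mean is zero (half a normalized count)
    m1 = np.where(mu1 > 0, mu1, 0.5 * c1 / r1)
    m2 = np.where(mu2 > 0, mu2, 0.5 * c2 / r2)
    var_log = (c1 / m1 + alpha) / r1 + (c2 / m2 + alpha) / r2
    z = (np.log(m1) - np.log(m2)) / np.sqrt(var_log)
    p = 2.0 * stats.norm.sf(np.abs(z))
    padj = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame(index=counts.index, columns=DE_COLUMNS, dtype=object)
    out.loc[tested, "baseMean"] = base_mean
    out.loc[tested, "log2FC"] = (np.log(m1) - np.log(m2)) / np.log(2.0)
    out.loc[tested, "p"] = p
    out.loc[tested, "padj"] = padj
    for col in ("baseMean", "log2FC", "p", "padj"):
        out[col] = pd.to_numeric(out[col])
    out["deg_status"] = "not"
    out.loc[tested, "deg_status"] = classify_degs(
        out.loc[tested], fc_min=fc_min, padj_max=padj_max
    )
    out.loc[~tested, "deg_status"] = "not"
    return out


def _fit_dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha ~ a0 + a1/mu on informative genes."""
    ok = (mu > 0) & (alpha > 1e-6) & (alpha < 10.0)
    if ok.sum() < 10:
        fallback = float(np.median(alpha[alpha > 0])) if (alpha > 0).any() else 0.01
        return np.full_like(mu, max(fallback, 1e-8))
    x = 1.0 / mu[ok]
    design = np.column_stack([np.ones(ok.sum()), x])
    coef, *_ = np.linalg.lstsq(design, alpha[ok], rcond=None)
    a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    if a0 == 0.0 and a1 == 0.0:
        a0 = float(np.median(alpha[ok]))
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(mu > 0, mu, np.inf)
    return np.clip(trend, 1e-8, 10.0)


def classify_degs(
    results: pd.DataFrame, fc_min: float = 1.5, padj_max: float = 0.05
) -> pd.Series:
    """'up' iff FC >= fc_min and padj <= padj_max; 'down' symmetric; else 'not'."""
    fc = np.power(2.0, results["log2FC"].to_numpy(dtype=float))
    padj = results["padj"].to_numpy(dtype=float)
    ok = np.isfinite(fc) & np.isfinite(padj) & (padj <= padj_max)
    status = np.where(ok & (fc >= fc_min), "up",
                      np.where(ok & (fc <= 1.0 / fc_min), "down", "not"))
    return pd.Series(status, index=results.index, name="deg_status")


def deg_sets(results: pd.DataFrame) -> dict[str, set[str]]:
    """Gene-id sets for each direction, keyed 'up'/'down'."""
    return {
        "up": set(results.index[results["deg_status"] == "up"]),
        "down": set(results.index[results["deg_status"] == "down"]),
    }
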