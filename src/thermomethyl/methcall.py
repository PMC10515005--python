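"""Methylated-cytosine calling and methylation-level summaries.

A site is a true methylated cytosine when its methylated read count is
inconclusively large under the bisulfite non-conversion null: an exact
upper-tail binomial test of mC out of (mC + umC) reads at the non-conversion
rate r, corrected by Benjamini-Hochberg across all sites of a sample.  All
region-level summaries are read-pooled: level = sum(mC) / sum(mC + umC).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CONTEXTS, GeneModel


def call_methylated_sites(sites: pd.DataFrame, r: float, fdr: float = 0.05) -> pd.DataFrame:
    """Exact binomial test of each site against the non-conversion rate.

    Returns the site table with ``p``, ``q`` (BH within the sample, all
    contexts jointly), ``level`` and ``is_methylated`` columns.  Sites with
    zero coverage get undefined p/level and are never called methylated.
    """
    if not 0.0 <= r < 1.0:
        raise ValueError(f"non-conversion rate r={r} must lie in [0, 1)")
    out = sites.copy()
    total = out["total"].to_numpy()
    mc = out["mc"].to_numpy()
    covered = total > 0
    p = np.full(len(out), np.nan)
    # upper tail P(X >= mC) for X ~ Binomial(total, r)
    p[covered] = stats.binom.sf(mc[covered] - 1, total[covered], r)
    q = np.full(len(out), np.nan)
    if covered.any():
        q[covered] = multipletests(p[covered], method="fdr_bh")[1]
    out["p"] = p
    out["q"] = q
    out["level"] = np.where(covered, mc / np.where(covered, total, 1), np.nan)
    out["is_methylated"] = covered & (q < fdr)
    return out


def site_levels(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-site level mC/(mC+umC); NaN where the site has no coverage."""
    out = sites.copy()
    total = out["total"].to_numpy()
    out["level"] = np.where(total > 0, out["mc"] / np.where(total > 0, total, 1), np.nan)
    return out


def bin_levels(
    sites: pd.DataFrame,
    bin_bp: int = 10_000,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Read-pooled methylation level per 10-kb bin per context.

    With ``chrom_sizes`` the full bin grid is emitted and bins without
    covered sites are reported with an undefined (NaN) level, not 0.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    df = sites.copy()
    df["bin"] = df["pos"] // bin_bp
    pooled = (
        df.groupby(["chrom", "bin", "context"], observed=True)[["mc", "total"]]
        .sum()
        .reset_index()
    )
    if chrom_sizes is not None:
        grid = [
            (chrom, b, ctx)
            for chrom, size in sorted(chrom_sizes.items())
            for b in range(int(np.ceil(size / bin_bp)))
            for ctx in CONTEXTS
        ]
        full = pd.DataFrame(grid, columns=["chrom", "bin", "context"])
        pooled = full.merge(pooled, on=["chrom", "bin", "context"], how="left")
        pooled[["mc", "total"]] = pooled[["mc", "total"]].fillna(0).astype(np.int64)
    pooled["start"] = pooled["bin"] * bin_bp
    pooled["end"] = pooled["start"] + bin_bp
    tot = pooled["total"].to_numpy()
    pooled["level"] = np.where(tot > 0, pooled["mc"] / np.where(tot > 0, tot, 1), np.nan)
    return pooled[["chrom", "start", "end", "context", "mc", "total", "level"]]


def genic_region_levels(sites: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    """Read-pooled levels for promoter / gene body / 2-kb downstream, per context.

    One row per (gene, region, context) with pooled counts; empty regions
    (e.g. a fully clipped promoter) yield an undefined level.
    """
    by_chrom = _index_sites(sites)
    rows = []
    for g in genes:
        for region, (lo, hi) in (
            ("promoter", g.promoter), ("body", g.body), ("downstream", g.downstream),
        ):
            sub = _slice(by_chrom, g.chrom, lo, hi)
            if sub is None:
                pooled = pd.DataFrame(index=pd.Index([], name="context"),
                                      columns=["mc", "total"])
            else:
                pooled = sub.groupby("context", observed=True)[["mc", "total"]].sum()
            for ctx in CONTEXTS:
                if ctx in pooled.index:
                    mc, tot = int(pooled.loc[ctx, "mc"]), int(pooled.loc[ctx, "total"])
                else:
                    mc, tot = 0, 0
                rows.append({
                    "gene_id": g.gene_id, "region": region, "context": ctx,
                    "mc": mc, "total": tot,
                    "level": mc / tot if tot > 0 else np.nan,
                })
    return pd.DataFrame(rows)


def region_level_summary(region_levels: pd.DataFrame) -> pd.DataFrame:
    """Genome-wide read-weighted average level per (region, context)."""
    pooled = (
        region_levels.groupby(["region", "context"], observed=True)[["mc", "total"]]
        .sum()
        .reset_index()
    )
    tot = pooled["total"].to_numpy()
    pooled["level"] = np.where(tot > 0, pooled["mc"] / np.where(tot > 0, tot, 1), np.nan)
    return pooled


def metagene_profile(
    sites: pd.DataFrame,
    genes: list[GeneModel],
    flank_bp: int = 2000,
    flank_bin_bp: int = 50,
    n_body_bins: int = 40,
) -> pd.DataFrame:
    """Pooled methylation profile over upstream flank, scaled body, downstream flank.

    Flanks use fixed ``flank_bin_bp`` bins; the gene body is rescaled to
    ``n_body_bins`` relative bins (site -> bin floor(n_body_bins * offset /
    length)).  Minus-strand genes are flipped into transcription orientation
    before pooling, so bin 0 is the far upstream edge and the last bin the
    far downstream edge for every gene.  Levels are read-pooled across genes.
    """
    if flank_bp % flank_bin_bp != 0:
        raise ValueError("flank_bp must be divisible by flank_bin_bp")
    n_flank = flank_bp // flank_bin_bp
    n_bins = 2 * n_flank + n_body_bins
    mc_acc = {ctx: np.zeros(n_bins) for ctx in CONTEXTS}
    tot_acc = {ctx: np.zeros(n_bins) for ctx in CONTEXTS}
    by_chrom = _index_sites(sites)

    for g in genes:
        length = g.length
        if g.strand == "+":
            spans = [(g.start - flank_bp, g.start), (g.start, g.end), (g.end, g.end + flank_bp)]
        else:
            spans = [(g.end, g.end + flank_bp), (g.start, g.end), (g.start - flank_bp, g.start)]
        for which, (lo, hi) in zip(("up", "body", "down"), spans):
            sub = _slice(by_chrom, g.chrom, max(lo, 0), hi)
            if sub is None or sub.empty:
                continue
            pos = sub["pos"].to_numpy()
            if which == "body":
                off = pos - g.start if g.strand == "+" else g.end - 1 - pos
                bins = n_flank + np.minimum(
                    (n_body_bins * off) // length, n_body_bins - 1
                ).astype(int)
            elif which == "up":
                d = g.start - 1 - pos if g.strand == "+" else pos - g.end
                bins = n_flank - 1 - d // flank_bin_bp  # bin n_flank-1 abuts the TSS
            else:
                d = pos - g.end if g.strand == "+" else g.start - 1 - pos
                bins = n_flank + n_body_bins + d // flank_bin_bp
            bins = np.asarray(bins, dtype=int)
            for ctx in CONTEXTS:
                m = (sub["context"] == ctx).to_numpy()
                if m.any():
                    np.add.at(mc_acc[ctx], bins[m], sub["mc"].to_numpy()[m])
                    np.add.at(tot_acc[ctx], bins[m], sub["total"].to_numpy()[m])

    data = {}
    for ctx in CONTEXTS:
        with np.errstate(invalid="ignore"):
            data[ctx] = np.where(tot_acc[ctx] > 0,
                                 mc_acc[ctx] / np.where(tot_acc[ctx] > 0, tot_acc[ctx], 1),
                                 np.nan)
    out = pd.DataFrame(data)
    out.index.name = "bin"
    return out


# ---------------------------------------------------------------------------
# site-table indexing helpers (sorted positions + searchsorted slicing)


def _index_sites(sites: pd.DataFrame) -> dict[str, pd.DataFrame]:
    out = {}
    for chrom, sub in sites.groupby("chrom", observed=True):
        out[chrom] = sub.sort_values("pos", kind="mergesort").reset_index(drop=True)
    return out


def _slice(by_chrom: dict[str, pd.DataFrame], chrom: str, lo: int, hi: int):
    sub = by_chrom.get(chrom)
    if sub is None or lo >= hi:
        return None
    pos = sub["pos"].to_numpy()
    i, j = np.searchsorted(pos, lo, "left"), np.searchsorted(pos, hi, "left")
    return sub.iloc[i:j]
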