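"""Two-group differentially-methylated-region calling.

The model family is beta-binomial: each replicate's methylated count at a
site is BetaBin(n, pi_group, phi).  Group means are smoothed by pooling read
counts over a local window (500 bp for CG by default; CHG/CHH sites are
tested individually), the per-site dispersion is a method-of-moments
estimate shrunk toward the genome-wide per-context mean, and each site gets
a Wald statistic

    W = (mu1 - mu2) / sqrt(Var(mu1) + Var(mu2)),

where Var(mu_g) is the variance of the window-pooled proportion with
beta-binomial inflation 1 + (n - 1) phi per replicate observation.  With a
single-site window and phi -> 0 this is exactly the two-proportion z-test.
Runs of significant same-sign sites are segmented into DMRs, merged across
small gaps, and filtered on length, site count and the fraction of
significant sites; genes whose body or 2-kb promoter overlaps a DMR are the
DMR-associated genes (DMGs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONTEXTS, GeneModel

DEFAULT_SMOOTH_WINDOWS = {"CG": 500, "CHG": 0, "CHH": 0}

DMR_COLUMNS = ["chrom", "start", "end", "context", "n_sites", "level1", "level2",
               "delta", "direction", "areaStat"]


@dataclass
class DMRParams:
    """Segmentation thresholds (DSS callDMR-style defaults)."""

    p_threshold: float = 1e-5
    delta_min: float = 0.1
    min_len: int = 50
    min_cg: int = 3
    merge_gap: int = 100
    pct_sig: float = 0.5


# ---------------------------------------------------------------------------
# per-site machinery


def _align_group(reports: list[pd.DataFrame], context: str, chrom: str,
                 index: pd.Index) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate (R x S) mc and total arrays aligned on a site index."""
    mc, nn = [], []
    for rep in reports:
        sub = rep[(rep["context"] == context) & (rep["chrom"] == chrom)]
        sub = sub.set_index(["pos", "strand"]).reindex(index)
        mc.append(sub["mc"].fillna(0).to_numpy(dtype=float))
        nn.append(sub["total"].fillna(0).to_numpy(dtype=float))
    return np.vstack(mc), np.vstack(nn)


def shrink_dispersion(
    mc_obs: np.ndarray, n_obs: np.ndarray, group_of_obs: np.ndarray,
    prior_sites: float = 20.0,
) -> np.ndarray:
    """Method-of-moments beta-binomial dispersion, shrunk toward the mean.

    ``mc_obs``/``n_obs`` are (observations x sites) count arrays where an
    observation is one replicate of either group; ``group_of_obs`` labels
    each row.  For each observation, E[(p_hat - mu)^2 * n / (mu(1-mu))] =
    1 + (n-1)phi; residuals use the group's pooled mean with a small-sample
    correction R/(R-1).  The site estimate is shrunk toward the
    information-weighted global mean with weight w = D/(D + k*Dbar), D =
    sum(n-1) over the site's observations and k = ``prior_sites`` average
    sites, then clamped to [1e-4, 0.5].
    """
    n_sites = mc_obs.shape[1]
    num = np.zeros(n_sites)
    n_used = np.zeros(n_sites)
    info = np.zeros(n_sites)
    for g in np.unique(group_of_obs):
        rows = group_of_obs == g
        mc_g, n_g = mc_obs[rows], n_obs[rows]
        pooled_n = n_g.sum(axis=0)
        pooled_mc = mc_g.sum(axis=0)
        # Anscombe-adjusted group mean keeps residual scaling finite at 0/N
        mu = (pooled_mc + 0.5) / (pooled_n + 1.0)
        r_eff = (n_g > 0).sum(axis=0).astype(float)
        corr = np.where(r_eff > 1, r_eff / np.maximum(r_eff - 1.0, 1.0), 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            phat = np.where(n_g > 0, mc_g / np.where(n_g > 0, n_g, 1.0), 0.0)
            s = (phat - mu) ** 2 * n_g / (mu * (1.0 - mu))
        s = np.where(n_g > 0, s * corr, 0.0)
        num += s.sum(axis=0)
        n_used += (n_g > 0).sum(axis=0)
        info += np.maximum(n_g - 1.0, 0.0).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        phi_site = np.where(info > 0, (num - n_used) / np.where(info > 0, info, 1.0), 0.0)
    phi_site = np.clip(phi_site, 0.0, 0.5)
    total_info = info.sum()
    if total_info > 0:
        phi_global = float((phi_site * info).sum() / total_info)
        d_bar = total_info / max((info > 0).sum(), 1)
        w = info / (info + prior_sites * d_bar)
    else:
        phi_global, w = 0.0, np.zeros(n_sites)
    return np.clip(w * phi_site + (1.0 - w) * phi_global, 1e-4, 0.5)


def _window_bounds(pos: np.ndarray, window_bp: int) -> tuple[np.ndarray, np.ndarray]:
    half = window_bp // 2
    lo = np.searchsorted(pos, pos - half, "left")
    hi = np.searchsorted(pos, pos + half, "right")
    return lo, hi


def _window_sum(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    csum = np.concatenate([[0.0], np.cumsum(x)])
    return csum[hi] - csum[lo]


def site_tests(
    group1: list[pd.DataFrame],
    group2: list[pd.DataFrame],
    context: str,
    smooth_window_bp: int | None = None,
    prior_sites: float = 20.0,
    phi_override: float | None = None,
) -> pd.DataFrame:
    """Smoothed beta-binomial Wald test at every covered site of one context.

    Returns one row per site: smoothed group means ``mu1``/``mu2``, shrunk
    dispersion ``phi``, ``wald``, two-sided normal ``p`` and a
    ``coverage_ok`` flag (False where a group has no reads in the window;
    such sites are skipped, not tested).  ``phi_override`` fixes the
    dispersion instead of estimating it (phi=0 recovers the binomial /
    two-proportion limit).
    """
    if not group1 or not group2:
        raise ValueError("each group needs at least one replicate")
    if smooth_window_bp is None:
        smooth_window_bp = DEFAULT_SMOOTH_WINDOWS.get(context, 0)

    chroms = sorted(
        set().union(*(set(r.loc[r["context"] == context, "chrom"].unique())
                      for r in group1 + group2))
    )
    frames = []
    for chrom in chroms:
        idx_parts = [
            r[(r["context"] == context) & (r["chrom"] == chrom)][["pos", "strand"]]
            for r in group1 + group2
        ]
        union = pd.concat(idx_parts).drop_duplicates().sort_values(["pos", "strand"])
        index = pd.MultiIndex.from_frame(union)
        if len(index) == 0:
            continue
        mc1, n1 = _align_group(group1, context, chrom, index)
        mc2, n2 = _align_group(group2, context, chrom, index)

        if phi_override is not None:
            phi = np.full(len(index), float(phi_override))
        else:
            mc_obs = np.vstack([mc1, mc2])
            n_all = np.vstack([n1, n2])
            group_of_obs = np.array([1] * len(group1) + [2] * len(group2))
            phi = shrink_dispersion(mc_obs, n_all, group_of_obs, prior_sites=prior_sites)

        pos = union["pos"].to_numpy()
        lo, hi = _window_bounds(pos, smooth_window_bp)
        rows = []
        for mc_g, n_g in ((mc1, n1), (mc2, n2)):
            pooled_mc, pooled_n = mc_g.sum(axis=0), n_g.sum(axis=0)
            v = (n_g * (1.0 + np.maximum(n_g - 1.0, 0.0) * phi)).sum(axis=0)
            sm_mc = _window_sum(pooled_mc, lo, hi)
            sm_n = _window_sum(pooled_n, lo, hi)
            sm_v = _window_sum(v, lo, hi)
            with np.errstate(divide="ignore", invalid="ignore"):
                mu = np.where(sm_n > 0, sm_mc / np.where(sm_n > 0, sm_n, 1.0), np.nan)
            # exact plug-in unless the pooled proportion is degenerate
            mu_var = mu.copy()
            degen = (sm_mc == 0) | (sm_mc == sm_n)
            mu_var[degen] = (sm_mc[degen] + 0.5) / (sm_n[degen] + 1.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                var = mu_var * (1.0 - mu_var) * sm_v / np.where(sm_n > 0, sm_n, 1.0) ** 2
            rows.append((mu, var, sm_n))
        (mu1, var1, smn1), (mu2, var2, smn2) = rows
        ok = (smn1 > 0) & (smn2 > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            wald = np.where(ok, (mu1 - mu2) / np.sqrt(var1 + var2), np.nan)
        p = np.where(ok, 2.0 * stats.norm.sf(np.abs(wald)), np.nan)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "strand": union["strand"].to_numpy(),
            "context": context, "mu1": mu1, "mu2": mu2, "phi": phi,
            "wald": wald, "p": p, "coverage_ok": ok,
            "raw_mc1": mc1.sum(axis=0), "raw_n1": n1.sum(axis=0),
            "raw_mc2": mc2.sum(axis=0), "raw_n2": n2.sum(axis=0),
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context", "mu1", "mu2",
                                     "phi", "wald", "p", "coverage_ok",
                                     "raw_mc1", "raw_n1", "raw_mc2", "raw_n2"])
    return pd.concat(frames, ignore_index=True)


def smooth_levels(
    group: list[pd.DataFrame], context: str, chrom: str, window_bp: int = 500
) -> pd.DataFrame:
    """Moving-average (read-pooled) group levels over +/- window/2 bp."""
    if not group:
        raise ValueError("empty group")
    idx_parts = [
        r[(r["context"] == context) & (r["chrom"] == chrom)][["pos", "strand"]]
        for r in group
    ]
    union = pd.concat(idx_parts).drop_duplicates().sort_values(["pos", "strand"])
    index = pd.MultiIndex.from_frame(union)
    mc, nn = _align_group(group, context, chrom, index)
    pos = union["pos"].to_numpy()
    lo, hi = _window_bounds(pos, window_bp)
    sm_mc = _window_sum(mc.sum(axis=0), lo, hi)
    sm_n = _window_sum(nn.sum(axis=0), lo, hi)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(sm_n > 0, sm_mc / np.where(sm_n > 0, sm_n, 1.0), np.nan)
    return pd.DataFrame({"chrom": chrom, "pos": pos,
                         "strand": union["strand"].to_numpy(), "smoothed": mu})


# ---------------------------------------------------------------------------
# segmentation


def call_dmrs(tests: pd.DataFrame, params: DMRParams | None = None) -> pd.DataFrame:
    """Segment per-site tests into DMRs.

    Maximal runs of consecutive tested sites with p < p_threshold,
    |mu1 - mu2| >= delta_min and a shared sign are found per chromosome and
    context; same-sign runs closer than ``merge_gap`` bp are merged.  A
    merged region is kept iff it spans >= min_len bp, contains >= min_cg
    sites and >= pct_sig of its contained sites are significant.  Direction
    is hyper when group 1 (the warm group by convention) is higher.
    """
    params = params or DMRParams()
    out = []
    for (chrom, context), sub in tests.groupby(["chrom", "context"], observed=True):
        sub = sub[sub["coverage_ok"]].sort_values("pos")
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        delta = (sub["mu1"] - sub["mu2"]).to_numpy()
        sig = (sub["p"].to_numpy() < params.p_threshold) & \
              (np.abs(delta) >= params.delta_min)
        sign = np.sign(delta)
        runs = _runs(sig, sign, pos, params.merge_gap)
        runs = _merge_runs(runs, pos, params.merge_gap)
        for i0, i1, s in runs:  # site-index span [i0, i1], inclusive
            span_lo, span_hi = int(pos[i0]), int(pos[i1])
            contained = slice(i0, i1 + 1)
            n_sites = i1 - i0 + 1
            n_sig = int((sig[contained] & (sign[contained] == s)).sum())
            if span_hi - span_lo + 1 < params.min_len:
                continue
            if n_sites < params.min_cg or n_sig / n_sites < params.pct_sig:
                continue
            raw = sub.iloc[contained]
            n1, n2 = raw["raw_n1"].sum(), raw["raw_n2"].sum()
            level1 = raw["raw_mc1"].sum() / n1 if n1 > 0 else np.nan
            level2 = raw["raw_mc2"].sum() / n2 if n2 > 0 else np.nan
            d = level1 - level2
            out.append({
                "chrom": chrom, "start": span_lo, "end": span_hi + 1,
                "context": context, "n_sites": n_sites,
                "level1": level1, "level2": level2, "delta": d,
                "direction": "hyper" if d > 0 else "hypo",
                "areaStat": float(raw["wald"].sum()),
            })
    df = pd.DataFrame(out, columns=DMR_COLUMNS)
    return df.sort_values(["chrom", "start", "context"]).reset_index(drop=True)


def _runs(sig, sign, pos, merge_gap) -> list[tuple[int, int, float]]:
    """Maximal runs of significant same-sign sites; a genomic gap of
    >= merge_gap bp between consecutive significant sites breaks a run."""
    runs, start, prev = [], None, None
    for i in range(len(sig)):
        if sig[i]:
            if start is None:
                start = i
            elif sign[i] != sign[start] or pos[i] - pos[prev] >= merge_gap:
                runs.append((start, prev, sign[start]))
                start = i
            prev = i
        elif start is not None:
            runs.append((start, prev, sign[start]))
            start = None
    if start is not None:
        runs.append((start, prev, sign[start]))
    return runs


def _merge_runs(runs, pos, merge_gap):
    merged = []
    for run in runs:
        if merged and run[2] == merged[-1][2] and \
                pos[run[0]] - pos[merged[-1][1]] < merge_gap:
            merged[-1] = (merged[-1][0], run[1], run[2])
        else:
            merged.append(run)
    return merged


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """BED6 rows: name = context:direction, score = round(1000*|delta|)."""
    if dmrs.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    return pd.DataFrame({
        "chrom": dmrs["chrom"], "start": dmrs["start"], "end": dmrs["end"],
        "name": dmrs["context"] + ":" + dmrs["direction"],
        "score": (1000 * dmrs["delta"].abs()).round().astype(int),
        "strand": ".",
    })


# ---------------------------------------------------------------------------
# DMR-associated genes


def annotate_dmgs(dmrs: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    """Genes whose body or promoter strictly overlaps a DMR (half-open).

    One row per (gene, DMR, region) association; touching intervals do not
    overlap.  A gene with both promoter and body hits appears with both tags.
    """
    rows = []
    for g in genes:
        sub = dmrs[dmrs["chrom"] == g.chrom]
        if sub.empty:
            continue
        for region, (lo, hi) in (("promoter", g.promoter), ("body", g.body)):
            if lo >= hi:
                continue  # fully clipped promoter
            hit = sub[(sub["start"] < hi) & (lo < sub["end"])]
            for _, d in hit.iterrows():
                rows.append({
                    "gene_id": g.gene_id, "region": region, "chrom": g.chrom,
                    "dmr_start": int(d["start"]), "dmr_end": int(d["end"]),
                    "context": d["context"], "direction": d["direction"],
                    "delta": float(d["delta"]),
                })
    return pd.DataFrame(
        rows, columns=["gene_id", "region", "chrom", "dmr_start", "dmr_end",
                       "context", "direction", "delta"],
    )


def run_dmr_analysis(
    group1: list[pd.DataFrame],
    group2: list[pd.DataFrame],
    contexts: tuple[str, ...] = CONTEXTS,
    params: DMRParams | None = None,
    smooth_windows: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Site tests + segmentation for each context; concatenated DMR table."""
    windows = smooth_windows or DEFAULT_SMOOTH_WINDOWS
    parts = []
    for ctx in contexts:
        tests = site_tests(group1, group2, ctx, smooth_window_bp=windows.get(ctx, 0))
        called = call_dmrs(tests, params)
        if not called.empty:
            parts.append(called)
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=DMR_COLUMNS)
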