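"""PWM scanning of promoter-DMR sequences against JASPAR-format motifs.

PFM counts become log-odds scores against a background distribution; every
window of a sequence is scored on both strands, and a hit is any window
whose relative score (min-max rescaled log-odds) reaches the threshold.
N bases contribute 0 (background-equivalent) and never disqualify a window.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import GeneModel, MotifPFM

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

HIT_COLUMNS = ["motif_id", "strand", "offset", "score", "rel_score"]


def pfm_to_pwm(
    pfm: MotifPFM,
    pseudocount: float = 0.25,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> np.ndarray:
    """Log2-odds matrix: log2(((count+pc)/(colsum+4pc)) / background)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 positive probabilities summing to 1")
    counts = pfm.counts
    colsum = counts.sum(axis=0)
    probs = (counts + pseudocount) / (colsum + 4.0 * pseudocount)
    return np.log2(probs / bg[:, None])


def reverse_complement_pwm(pwm: np.ndarray) -> np.ndarray:
    return pwm[::-1, ::-1]


def _encode(sequence: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, -1) for b in sequence.upper()], dtype=int)


def _window_scores(idx: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    """Score every offset; bases outside ACGT contribute 0."""
    w = pwm.shape[1]
    n_off = len(idx) - w + 1
    scores = np.zeros(n_off)
    for j in range(w):
        col_idx = idx[j:j + n_off]
        known = col_idx >= 0
        scores[known] += pwm[col_idx[known], j]
    return scores


def scan(
    sequence: str,
    pwm: np.ndarray,
    threshold: float = 0.85,
    both_strands: bool = True,
    motif_id: str = "",
) -> pd.DataFrame:
    """All hits of one PWM in one sequence.

    Offsets are 0-based positions of the window start in the given sequence
    for both strands; relative score = (score - min) / (max - min) over the
    PWM's attainable score range.
    """
    w = pwm.shape[1]
    if len(sequence) < w:
        warnings.warn(
            f"sequence shorter than motif width ({len(sequence)} < {w}); no hits",
            stacklevel=2,
        )
        return pd.DataFrame(columns=HIT_COLUMNS)
    lo = float(pwm.min(axis=0).sum())
    hi = float(pwm.max(axis=0).sum())
    span = hi - lo if hi > lo else 1.0
    idx = _encode(sequence)
    rows = []
    strands = [("+", pwm)]
    if both_strands:
        strands.append(("-", reverse_complement_pwm(pwm)))
    for strand, mat in strands:
        scores = _window_scores(idx, mat)
        rel = (scores - lo) / span
        for off in np.flatnonzero(rel >= threshold):
            rows.append({"motif_id": motif_id, "strand": strand, "offset": int(off),
                         "score": float(scores[off]), "rel_score": float(rel[off])})
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def scan_promoter_dmrs(
    promoter_dmgs: pd.DataFrame,
    genome: dict[str, str],
    pfms: list[MotifPFM],
    threshold: float = 0.85,
    pseudocount: float = 0.25,
    full_promoter: bool = False,
    genes: list[GeneModel] | None = None,
) -> pd.DataFrame:
    """Scan each promoter-associated DMR sequence with every motif.

    ``promoter_dmgs`` is the DMG association table restricted to promoter
    rows (columns gene_id, chrom, dmr_start, dmr_end).  With
    ``full_promoter`` the whole 2-kb promoter of each associated gene is
    scanned instead of the DMR interval alone.
    """
    assoc = promoter_dmgs[promoter_dmgs["region"] == "promoter"] \
        if "region" in promoter_dmgs.columns else promoter_dmgs
    if full_promoter:
        if genes is None:
            raise ValueError("full_promoter scanning needs the gene annotation")
        gene_map = {g.gene_id: g for g in genes}
    pwms = [(pfm.motif_id, pfm_to_pwm(pfm, pseudocount=pseudocount)) for pfm in pfms]
    rows = []
    seen = set()
    for _, a in assoc.iterrows():
        if full_promoter:
            g = gene_map[a["gene_id"]]
            lo, hi = g.promoter
            chrom = g.chrom
        else:
            chrom, lo, hi = a["chrom"], int(a["dmr_start"]), int(a["dmr_end"])
        key = (a["gene_id"], chrom, lo, hi)
        if key in seen:  # a gene can carry several promoter DMR associations
            continue
        seen.add(key)
        seq = genome[chrom][lo:hi]
        dmr_id = f"{chrom}:{lo}-{hi}"
        for motif_id, pwm in pwms:
            if len(seq) < pwm.shape[1]:
                continue
            hits = scan(seq, pwm, threshold=threshold, motif_id=motif_id)
            for _, h in hits.iterrows():
                rows.append({"gene_id": a["gene_id"], "dmr_id": dmr_id, **h.to_dict()})
    out = pd.DataFrame(rows, columns=["gene_id", "dmr_id", *HIT_COLUMNS])
    return out.sort_values(["gene_id", "dmr_id", "motif_id", "strand", "offset"]) \
        .reset_index(drop=True)


def summarize_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-gene table of motifs with at least one hit."""
    if hits.empty:
        return pd.DataFrame(columns=["gene_id", "motif_id", "n_hits", "best_rel_score"])
    out = (
        hits.groupby(["gene_id", "motif_id"], observed=True)
        .agg(n_hits=("offset", "size"), best_rel_score=("rel_score", "max"))
        .reset_index()
    )
    return out.sort_values(["gene_id", "motif_id"]).reset_index(drop=True)
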