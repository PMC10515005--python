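"""Readers and writers for the external formats the pipeline touches.

Every interval handed to the rest of the package is 0-based half-open.
Conversions from the 1-based inclusive conventions of GTF and Bismark
cytosine reports happen here and only here.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as _bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROMOTER_BP = 2000
CONTEXTS = ("CG", "CHG", "CHH")

#: column order of the Bismark CX-style cytosine report
CX_COLUMNS = ("chrom", "pos", "strand", "mc", "umc", "context", "trinucleotide")


class ParseError(ValueError):
    """Malformed external file; message carries the offending line number."""


@dataclass(frozen=True)
class GeneModel:
    """A gene body [start, end) with a strand-aware 2-kb promoter.

    ``start``/``end`` are 0-based half-open in genome coordinates; for a
    minus-strand gene the TSS sits at ``end`` (exclusive coordinate) and the
    promoter extends downstream in genome coordinates.  Promoters are clipped
    to chromosome bounds; a TSS at position 0 yields an empty promoter.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )

    @property
    def promoter(self) -> tuple[int, int]:
        """2-kb upstream of the TSS, clipped to the chromosome."""
        if self.strand == "+":
            return (max(0, self.start - PROMOTER_BP), self.start)
        hi = self.end + PROMOTER_BP
        if self.chrom_length is not None:
            hi = min(hi, self.chrom_length)
        return (self.end, hi)

    @property
    def downstream(self) -> tuple[int, int]:
        """2-kb downstream of the TES, clipped to the chromosome."""
        if self.strand == "+":
            hi = self.end + PROMOTER_BP
            if self.chrom_length is not None:
                hi = min(hi, self.chrom_length)
            return (self.end, hi)
        return (max(0, self.start - PROMOTER_BP), self.start)

    @property
    def body(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine site: strand, trinucleotide context and read counts."""

    chrom: str
    pos: int  # 0-based
    strand: str
    context: str
    mc: int
    total: int

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"invalid context {self.context!r}")
        if self.mc < 0 or self.mc > self.total:
            raise ValueError(f"require 0 <= mC <= total, got {self.mc}/{self.total}")

    @property
    def level(self) -> float:
        return self.mc / self.total if self.total > 0 else float("nan")


@dataclass
class MotifPFM:
    """A position frequency matrix over A,C,G,T (rows) x W columns."""

    motif_id: str
    name: str
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("PFM must be a 4 x W matrix (rows A,C,G,T)")
        if self.counts.shape[1] < 1:
            raise ValueError("PFM must have width >= 1")
        if np.any(self.counts < 0):
            raise ValueError("PFM counts must be nonnegative")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError("every PFM column needs at least one positive count")

    @property
    def width(self) -> int:
        return self.counts.shape[1]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GTF-like gene annotation (1-based inclusive on disk)


def read_gtf(path, chrom_lengths: dict[str, int] | None = None) -> list[GeneModel]:
    """Read gene features from a 9-column GTF-like file.

    Only ``feature == "gene"`` rows are used; transcripts and exons are
    ignored.  1-based inclusive coordinates are converted to 0-based
    half-open.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = parts
            if feature != "gene":
                continue
            gene_id = _parse_gene_id(attrs, path, lineno)
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i > end_i:
                raise ParseError(f"{path}:{lineno}: start {start_i} > end {end_i}")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            clen = chrom_lengths.get(chrom) if chrom_lengths else None
            genes.append(
                GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                          start=start_i - 1, end=end_i, chrom_length=clen)
            )
    return genes


def _parse_gene_id(attrs: str, path, lineno: int) -> str:
    for token in attrs.split(";"):
        token = token.strip()
        if token.startswith("gene_id"):
            return token.split(None, 1)[1].strip().strip('"')
    raise ParseError(f"{path}:{lineno}: missing gene_id attribute")


def write_gtf(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tthermomethyl\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Bismark CX-style cytosine report (1-based positions on disk)


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a 7-column CX report into a site table with 0-based positions.

    Columns on disk: chrom, 1-based position, strand, count methylated,
    count unmethylated, context (CG/CHG/CHH), trinucleotide.  Rows with zero
    total coverage are retained (they matter for missing-data handling).
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=list(CX_COLUMNS),
            dtype={"chrom": str, "strand": str, "context": str, "trinucleotide": str},
        )
    except pd.errors.EmptyDataError:
        return _empty_site_table()
    if df.shape[1] != 7:
        raise ParseError(f"{path}: expected 7 tab-separated columns")
    for col in ("pos", "mc", "umc"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            lineno = int(vals.isna().idxmax()) + 1
            raise ParseError(f"{path}:{lineno}: non-numeric {col!r}")
        df[col] = vals.astype(np.int64)
    for col in ("mc", "umc"):
        if (df[col] < 0).any():
            lineno = int((df[col] < 0).idxmax()) + 1
            raise ParseError(f"{path}:{lineno}: negative count in {col!r}")
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        lineno = int(bad_ctx.idxmax()) + 1
        raise ParseError(f"{path}:{lineno}: invalid context {df['context'][lineno - 1]!r}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        lineno = int(bad_strand.idxmax()) + 1
        raise ParseError(f"{path}:{lineno}: invalid strand")
    out = df.copy()
    out["pos"] = out["pos"] - 1  # to 0-based
    out["total"] = out["mc"] + out["umc"]
    return out[["chrom", "pos", "strand", "mc", "total", "context", "trinucleotide"]]


def _empty_site_table() -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64),
         "strand": pd.Series(dtype=str), "mc": pd.Series(dtype=np.int64),
         "total": pd.Series(dtype=np.int64), "context": pd.Series(dtype=str),
         "trinucleotide": pd.Series(dtype=str)}
    )


def write_cytosine_report(sites: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {"chrom": sites["chrom"], "pos": sites["pos"] + 1, "strand": sites["strand"],
         "mc": sites["mc"], "umc": sites["total"] - sites["mc"],
         "context": sites["context"], "trinucleotide": sites["trinucleotide"]}
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED / bedGraph (0-based half-open, as the formats themselves)


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write BED6; expects columns chrom, start, end, name, score, strand."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(sites: pd.DataFrame, path) -> None:
    """Per-site methylation levels as bedGraph (one basepair per record)."""
    covered = sites[sites["total"] > 0]
    out = pd.DataFrame(
        {"chrom": covered["chrom"], "start": covered["pos"], "end": covered["pos"] + 1,
         "level": (covered["mc"] / covered["total"]).round(6)}
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# JASPAR PFMs (delegates parsing/formatting to Bio.motifs)


def read_jaspar(path) -> list[MotifPFM]:
    with open(path) as fh:
        parsed = _bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        out.append(MotifPFM(motif_id=m.matrix_id or m.name, name=m.name, counts=counts))
    return out


def write_jaspar(pfms: list[MotifPFM], path) -> None:
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.motif_id} {pfm.name}\n")
            for i, base in enumerate("ACGT"):
                row = "  ".join(f"{v:g}" for v in pfm.counts[i])
                fh.write(f"{base}  [ {row} ]\n")


# ---------------------------------------------------------------------------
# Count matrices and generic TSV tables


def read_counts(path) -> pd.DataFrame:
    """Gene x sample integer count matrix, first column = gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and df.columns.empty:
        raise ParseError(f"{path}: empty count matrix")
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")
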