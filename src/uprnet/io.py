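"""Readers and writers for the tabular and sequence formats the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open ``[start, end)``.  GFF3 is
1-based closed and is converted at the boundary; BED and narrowPeak are
already 0-based half-open.  The transcription start site (TSS) of a gene is
``start`` on the + strand and ``end - 1`` on the − strand.

All TSV files are tab-separated, UTF-8, with ``#`` comment lines allowed.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import ConsistencyError, FormatError

SAMPLE_SHEET_COLUMNS = ["sample_id", "genotype", "timepoint", "treatment", "replicate"]

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signal", "pfloat", "qvalue", "summit_offset",
]


# ---------------------------------------------------------------------------
# counts and sample sheets
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples integer count table.

    First column is the gene identifier; remaining columns are samples in
    file order.  Raises :class:`FormatError` for non-integer or negative
    cells (naming the offending row and column) and for duplicated gene ids.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: counts table needs a gene column and >=1 sample")
    gene_col = df.columns[0]
    genes = df[gene_col]
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    out = {}
    for col in df.columns[1:]:
        try:
            vals = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()].index[0]
        else:
            frac = vals != vals.round()
            if frac.any():
                bad = frac[frac].index[0]
            elif (vals < 0).any():
                bad = vals[vals < 0].index[0]
            else:
                out[col] = vals.astype(int).to_numpy()
                continue
        raise FormatError(
            f"{path}: non-integer or negative count at gene {genes.iloc[bad]!r}, "
            f"column {col!r}"
        )
    counts = pd.DataFrame(out, index=pd.Index(genes, name=gene_col))
    return counts


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the sample sheet (sample_id, genotype, timepoint, treatment, replicate)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {missing}")
    df = df[SAMPLE_SHEET_COLUMNS].copy()
    df["replicate"] = df["replicate"].astype(int)
    key = df[["genotype", "timepoint", "treatment", "replicate"]]
    if key.duplicated().any():
        raise FormatError(f"{path}: duplicated (genotype, timepoint, treatment, replicate)")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated sample_id")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def check_design(counts: pd.DataFrame, sheet: pd.DataFrame) -> None:
    """Require one sample-sheet row per counts column."""
    absent = [c for c in counts.columns if c not in set(sheet["sample_id"])]
    if absent:
        raise ConsistencyError(f"counts columns missing from sample sheet: {absent}")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def _tss(start: int, end: int, strand: str) -> int:
    return start if strand == "+" else end - 1


def read_annotation(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read gene annotation from GFF3 or BED into the internal convention.

    Returns a DataFrame with columns gene_id, chrom, start, end, strand, tss
    (0-based half-open; GFF3's 1-based closed coordinates are converted).
    ``dialect`` is inferred from the file suffix when not given.
    """
    path = Path(path)
    if dialect is None:
        dialect = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "bed"
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if dialect == "gff3":
                if len(f) < 9:
                    raise FormatError(f"{path}:{lineno}: GFF3 line with <9 fields")
                chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
                if ftype != "gene":
                    continue  # only gene-level records carry the TSS we use
                gene_id = None
                for kv in attrs.split(";"):
                    if kv.startswith("ID="):
                        gene_id = kv[3:]
                if gene_id is None:
                    raise FormatError(f"{path}:{lineno}: gene record without ID attribute")
                start, end = int(start) - 1, int(end)
            else:
                if len(f) < 6:
                    raise FormatError(f"{path}:{lineno}: BED line needs 6 fields (strand required)")
                chrom, start, end, gene_id, _, strand = f[:6]
                start, end = int(start), int(end)
            if strand not in {"+", "-"}:
                raise FormatError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
            if not start < end:
                raise FormatError(f"{path}:{lineno}: start must be < end")
            rows.append((gene_id, chrom, start, end, strand, _tss(start, end, strand)))
    ann = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"])
    if ann["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated gene_id in annotation")
    return ann


def write_annotation(ann: pd.DataFrame, path: str | Path, dialect: str = "gff3") -> None:
    """Write annotation back out, restoring the dialect's native coordinates."""
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for r in ann.itertuples(index=False):
                fh.write(
                    f"{r.chrom}\tuprnet\tgene\t{r.start + 1}\t{r.end}\t.\t"
                    f"{r.strand}\t.\tID={r.gene_id}\n"
                )
        else:
            for r in ann.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    """A set of ChIP peaks with provenance.

    ``peaks`` columns: chrom, start, end, name, score, strand, signal,
    pfloat (−log10 p, narrowPeak column 8), qvalue, summit_offset, summit.
    """

    peaks: pd.DataFrame
    tf: str | None = None
    condition: str | None = None   # "Tm" | "mock"
    timepoint: object = None
    replicate: int | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def with_peaks(self, df: pd.DataFrame) -> "PeakSet":
        return replace(self, peaks=df.reset_index(drop=True))

    @property
    def ids(self) -> set[str]:
        return set(self.peaks["name"])


def empty_peak_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=NARROWPEAK_COLUMNS + ["summit"]).astype(
        {"start": int, "end": int, "summit_offset": int, "summit": int,
         "score": int, "signal": float, "pfloat": float, "qvalue": float}
    )


def read_narrowpeak(path: str | Path, **provenance) -> PeakSet:
    """Read an ENCODE narrowPeak (BED6+4) file.

    pfloat is column 8 (pValue, −log10 scale); summit = start + column 10.
    Peaks named "." get a stable id derived from the file stem and line index.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise FormatError(f"{path}:{lineno + 1}: narrowPeak needs 10 columns, got {len(f)}")
            chrom, start, end, name, score, strand, signal, pfloat, qvalue, offset = f[:10]
            start, end, offset = int(start), int(end), int(offset)
            if not 0 <= offset < end - start:
                raise FormatError(
                    f"{path}:{lineno + 1}: summit offset {offset} outside peak of length {end - start}"
                )
            if name == ".":
                name = f"{path.stem}_{lineno}"
            rows.append((chrom, start, end, name, int(score), strand,
                         float(signal), float(pfloat), float(qvalue), offset, start + offset))
    df = pd.DataFrame(rows, columns=NARROWPEAK_COLUMNS + ["summit"]) if rows else empty_peak_frame()
    return PeakSet(df, **provenance)


def write_narrowpeak(peakset: PeakSet, path: str | Path) -> None:
    df = peakset.peaks
    with open(path, "w") as fh:
        for r in df.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t{r.strand}\t"
                f"{r.signal:g}\t{r.pfloat:g}\t{r.qvalue:g}\t{r.summit_offset}\n"
            )


# ---------------------------------------------------------------------------
# network edge lists
# ---------------------------------------------------------------------------

def write_edge_list(grn, path: str | Path) -> None:
    """Write a GRN as a TSV edge list importable by network viewers.

    Columns: source, target, weight, source_bound_by (comma-joined TF names).
    Each undirected edge is emitted once, with source < target lexically.
    """
    rows = []
    for u, v, data in grn.graph.edges(data=True):
        a, b = sorted((u, v))
        bound = ",".join(sorted(grn.graph.nodes[a].get("bound_by", ())))
        rows.append((a, b, data.get("weight", 1.0), bound))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\tsource_bound_by\n")
        for a, b, w, bound in rows:
            fh.write(f"{a}\t{b}\t{w:.6g}\t{bound}\n")
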