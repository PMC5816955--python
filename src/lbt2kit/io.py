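"""Readers and writers for the formats the pipeline touches.

Internal convention: all coordinates are 0-based half-open. Conversion to and
from 1-based inclusive (GTF) happens only at the I/O boundary. Count matrices
are genes x units (cells or bulk samples) with string identifiers.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("lbt2kit")

FRAGMENT_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
NARROWPEAK_COLUMNS = FRAGMENT_COLUMNS + ["signal", "pvalue", "qvalue", "summit"]


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer gene x unit count matrix.

    Units are cells (barcodes) or bulk samples. ``unit_labels`` optionally
    carries a condition tag per unit (e.g. "vehicle"/"gnrh").
    """

    values: sp.spmatrix | np.ndarray
    gene_ids: np.ndarray
    unit_ids: np.ndarray
    unit_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.unit_ids = np.asarray(self.unit_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.unit_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.unit_ids)} units"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("duplicate unit identifiers")
        if self.unit_labels is not None:
            self.unit_labels = np.asarray(self.unit_labels, dtype=object)
            if len(self.unit_labels) != len(self.unit_ids):
                raise ValueError("unit_labels length mismatch")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def unit_totals(self) -> np.ndarray:
        return np.asarray(self.dense().sum(axis=0)).ravel()

    def gene_totals(self) -> np.ndarray:
        return np.asarray(self.dense().sum(axis=1)).ravel()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.gene_ids, columns=self.unit_ids)


@dataclass
class ExpressionMatrix:
    """Float gene x unit matrix (normalized expression such as SC-TPM)."""

    values: np.ndarray
    gene_ids: np.ndarray
    unit_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.unit_ids = np.asarray(self.unit_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.unit_ids)):
            raise ValueError("dimension mismatch")

    def log2p1(self) -> "ExpressionMatrix":
        return ExpressionMatrix(np.log2(self.values + 1.0), self.gene_ids, self.unit_ids)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """Single collapsed (union-exon) gene model.

    Coordinates 0-based half-open. TSS is ``start`` on + strand and
    ``end - 1`` on - strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end}) for {self.gene_id}")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"exon [{s}, {e}) outside span of {self.gene_id}")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# MatrixMarket triplet layout (Cell Ranger style)
# ---------------------------------------------------------------------------


def write_mtx_triplet(matrix: CountMatrix, outdir: str | Path) -> None:
    """Write matrix.mtx / features.tsv / barcodes.tsv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    values = matrix.values if sp.issparse(matrix.values) else sp.coo_matrix(matrix.values)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), values, field="integer")
    with open(outdir / "features.tsv", "w") as fh:
        for g in matrix.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(outdir / "barcodes.tsv", "w") as fh:
        for b in matrix.unit_ids:
            fh.write(f"{b}\n")


def read_mtx_triplet(indir: str | Path) -> CountMatrix:
    """Read a Cell Ranger-style triplet directory into a CountMatrix.

    Raises ValueError when the MatrixMarket header disagrees with the listed
    entries or with the feature/barcode tables.
    """
    indir = Path(indir)
    mtx_path = indir / "matrix.mtx"
    _validate_mtx_entry_count(mtx_path)
    values = scipy.io.mmread(str(mtx_path))
    genes = []
    with open(indir / "features.tsv") as fh:
        for line in fh:
            if line.strip():
                genes.append(line.rstrip("\n").split("\t")[0])
    barcodes = []
    with open(indir / "barcodes.tsv") as fh:
        for line in fh:
            if line.strip():
                barcodes.append(line.strip())
    if values.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix.mtx is {values.shape} but features/barcodes give "
            f"({len(genes)}, {len(barcodes)})"
        )
    values = sp.csr_matrix(values, dtype=np.int64)
    return CountMatrix(values, np.array(genes, dtype=object), np.array(barcodes, dtype=object))


def _validate_mtx_entry_count(path: Path) -> None:
    n_header = None
    n_entries = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("%") or not line.strip():
                continue
            if n_header is None:
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(f"malformed MatrixMarket size line: {line!r}")
                n_header = int(parts[2])
            else:
                n_entries += 1
    if n_header is None:
        raise ValueError(f"{path} has no size header")
    if n_header != n_entries:
        raise ValueError(
            f"{path}: header declares {n_header} entries but {n_entries} listed"
        )


# ---------------------------------------------------------------------------
# Bulk counts / generic tables
# ---------------------------------------------------------------------------


def write_counts_tsv(matrix: CountMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_counts_tsv(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(
        df.to_numpy(dtype=np.int64),
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
    )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def write_gtf(genes: Sequence[GeneModel], path: str | Path, source: str = "lbt2kit") -> None:
    """Write collapsed gene models as GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\t{source}\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for (s, e) in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a GTF into collapsed per-gene models.

    Transcripts are collapsed to a single union-exon model per gene; the span
    is the union of all exon/transcript records. Records with non-positive
    width or negative coordinates after conversion are rejected (negative
    coordinates raise; inverted intervals are dropped with a warning).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            chrom, _source, feature, start1, end1, _score, strand, _frame, attrs = parts[:9]
            start = int(start1) - 1  # to 0-based half-open
            end = int(end1)
            if start < 0:
                raise ValueError(f"negative coordinate in GTF record: {line!r}")
            if start >= end:
                logger.warning("dropping inverted GTF record: %s", line.strip())
                continue
            gene_id = _gtf_attr(attrs, "gene_id")
            if gene_id is None:
                continue
            rows.append((gene_id, chrom, strand, feature, start, end))
    genes: dict[str, dict] = {}
    for gene_id, chrom, strand, feature, start, end in rows:
        rec = genes.setdefault(
            gene_id, {"chrom": chrom, "strand": strand, "start": start, "end": end, "exons": []}
        )
        rec["start"] = min(rec["start"], start)
        rec["end"] = max(rec["end"], end)
        if feature == "exon":
            rec["exons"].append((start, end))
    out = []
    for gene_id, rec in genes.items():
        exons = _merge_intervals(rec["exons"]) or [(rec["start"], rec["end"])]
        out.append(
            GeneModel(gene_id, rec["chrom"], rec["strand"], rec["start"], rec["end"], exons)
        )
    out.sort(key=lambda g: (g.chrom, g.start))
    return out


def _gtf_attr(attrs: str, key: str) -> Optional[str]:
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key + " "):
            return chunk.split(" ", 1)[1].strip().strip('"')
    return None


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


# ---------------------------------------------------------------------------
# BED / narrowPeak (0-based half-open; no conversion needed)
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED(6) fragments. Returns chrom/start/end(/name/score/strand)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = FRAGMENT_COLUMNS[: df.shape[1]]
    df = _validate_intervals(df, "BED")
    return df.reset_index(drop=True)


def write_bed(fragments: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in FRAGMENT_COLUMNS if c in fragments.columns]
    fragments[cols].to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path: str | Path) -> pd.DataFrame:
    """Read ENCODE narrowPeak (BED6+4)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 10:
        raise ValueError(f"narrowPeak requires 10 columns, found {df.shape[1]}")
    df.columns = NARROWPEAK_COLUMNS
    df = _validate_intervals(df, "narrowPeak")
    return df.reset_index(drop=True)


def write_narrowpeak(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks[NARROWPEAK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def _validate_intervals(df: pd.DataFrame, what: str) -> pd.DataFrame:
    if (df["start"] < 0).any():
        raise ValueError(f"negative coordinate in {what} input")
    bad = df["start"] >= df["end"]
    if bad.any():
        logger.warning("dropping %d inverted %s records", int(bad.sum()), what)
        df = df[~bad]
    return df


# ---------------------------------------------------------------------------
# Run provenance logging
# ---------------------------------------------------------------------------


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def log_run(seed: Optional[int], config_text: str = "", inputs: Sequence[str | Path] = ()) -> None:
    """Log version, config hash, seed and input checksums for a CLI run."""
    from lbt2kit import __version__

    cfg_hash = hashlib.sha256(config_text.encode()).hexdigest()[:16]
    logger.info("lbt2kit %s | seed=%s | config_sha=%s", __version__, seed, cfg_hash)
    for p in inputs:
        p = Path(p)
        if p.is_file():
            logger.info("input %s sha256=%s", p, file_checksum(p))
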