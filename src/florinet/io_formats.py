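"""Readers and writers for the standard formats the pipeline touches.

Coordinate convention: GFF3 is 1-based inclusive on disk; every internal
coordinate in this package is 0-based half-open. The conversion happens here,
in :func:`read_gff3_genes`, and nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "SequenceRecord",
    "GeneRecord",
    "MotifModel",
    "CountMatrix",
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_meme_motifs",
    "write_meme_motifs",
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_tf_map",
    "write_tf_map",
    "write_edge_table",
    "read_edge_table",
    "write_graphml",
]

_VALID_SEQ = re.compile(r"^[ACGTN]+$")


class FormatError(ValueError):
    """A file violated its format contract; the message locates the offence."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N}, uppercased."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.sequence:
            raise FormatError(f"sequence record {self.id!r} is empty")


@dataclass(frozen=True)
class GeneRecord:
    """A gene locus. ``start``/``end`` are 0-based half-open on the + strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id!r}: strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id!r}: bad interval [{self.start},{self.end})"
            )

    @property
    def tss(self) -> int:
        """0-based transcription start coordinate (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class MotifModel:
    """A position probability matrix over A/C/G/T (rows = motif positions)."""

    motif_id: str
    matrix: np.ndarray  # (width, 4), rows sum to 1
    n_sites: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or len(self.matrix) < 1:
            raise FormatError(f"motif {self.motif_id!r}: matrix must be width x 4")
        if (self.matrix < 0).any():
            raise FormatError(f"motif {self.motif_id!r}: negative probability")
        sums = self.matrix.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-3
        if bad.any():
            row = int(np.argmax(bad))
            raise FormatError(
                f"motif {self.motif_id!r}: row {row} sums to {sums[row]:.4f}, not 1"
            )
        # published matrices carry rounded probabilities; renormalize exactly
        self.matrix = self.matrix / sums[:, None]

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def consensus(self) -> str:
        from .seqcodes import ALPHABET

        return "".join(ALPHABET[b] for b in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "MotifModel":
        return MotifModel(self.motif_id, self.matrix[::-1, ::-1].copy(), self.n_sites)


@dataclass
class CountMatrix:
    """Gene x sample read counts plus a sample -> condition labelling."""

    counts: pd.DataFrame  # index: gene ids, columns: sample ids, int values
    conditions: pd.Series  # index: sample ids, values: condition labels

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r} in count matrix")
        missing = [s for s in self.counts.columns if s not in self.conditions.index]
        if missing:
            raise FormatError(f"samples missing from condition map: {missing}")
        self.conditions = self.conditions.reindex(self.counts.columns)
        if (self.counts.values < 0).any():
            raise FormatError("negative count")
        self.counts = self.counts.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, *conditions: str) -> list[str]:
        keep = set(conditions)
        return [s for s in self.sample_ids if self.conditions[s] in keep]

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)].copy(), self.conditions[list(samples)])


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA; uppercase sequences; reject duplicates and illegal letters."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        if not seq:
            raise FormatError(f"record {rec.id!r} in {path} has an empty sequence")
        if not _VALID_SEQ.match(seq):
            offending = next(c for c in seq if c not in "ACGTN")
            raise FormatError(
                f"record {rec.id!r} in {path} contains illegal character {offending!r}"
            )
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTQ with uniform placeholder quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_reads(path: str | Path) -> list[str]:
    """Sequences from a FASTA or FASTQ file (format sniffed from first byte)."""
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]


# ---------------------------------------------------------------------------
# GFF3 (gene rows only)

_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_gff3_genes(path: str | Path) -> list[GeneRecord]:
    """Parse gene-feature rows of a GFF3 file into 0-based half-open records.

    Only rows whose type column is ``gene`` are consumed; everything else
    (mRNA/exon structure, comments) is ignored because promoters derive from
    the annotated gene start alone.
    """
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end1 < start1 or start1 < 1:
                raise FormatError(f"{path}:{lineno}: end {end1} < start {start1}")
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: strand must be + or -, got {strand!r}")
            m = _ID_RE.search(attrs)
            if not m:
                raise FormatError(f"{path}:{lineno}: gene row lacks an ID attribute")
            # 1-based inclusive -> 0-based half-open, once, here
            genes.append(GeneRecord(m.group(1), chrom, start1 - 1, end1, strand))
    return genes


def write_gff3_genes(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tflorinet\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Minimal MEME motif format


def read_meme_motifs(path: str | Path) -> list[MotifModel]:
    """Parse minimal MEME motif format (MOTIF blocks with probability rows).

    Validation is strict: probability rows must have 4 entries summing to
    1 +/- 1e-3 and, when the header declares ``w=``, the row count must match.
    """
    motifs: list[MotifModel] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: MOTIF line without an identifier")
            motif_id = parts[1]
            i += 1
            declared_w: int | None = None
            n_sites: int | None = None
            # find the letter-probability header (blank lines allowed between)
            while i < n and not lines[i].strip().startswith("letter-probability"):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"{path}: motif {motif_id!r} has no probability matrix")
                i += 1
            if i >= n:
                raise FormatError(f"{path}: motif {motif_id!r} has no probability matrix")
            header = lines[i]
            mw = re.search(r"\bw=\s*(\d+)", header)
            if mw:
                declared_w = int(mw.group(1))
            ms = re.search(r"\bnsites=\s*(\d+)", header)
            if ms:
                n_sites = int(ms.group(1))
            i += 1
            rows: list[list[float]] = []
            while i < n:
                row = lines[i].strip()
                if not row or not re.match(r"^[\d.eE+\-\s]+$", row):
                    break
                vals = [float(x) for x in row.split()]
                if len(vals) != 4:
                    raise FormatError(
                        f"{path}:{i + 1}: motif {motif_id!r} row has {len(vals)} entries, need 4"
                    )
                s = sum(vals)
                if abs(s - 1.0) > 1e-3:
                    raise FormatError(
                        f"{path}:{i + 1}: motif {motif_id!r} row sums to {s:.4f}, not 1"
                    )
                rows.append(vals)
                i += 1
            if not rows:
                raise FormatError(f"{path}: motif {motif_id!r} has an empty matrix")
            if declared_w is not None and declared_w != len(rows):
                raise FormatError(
                    f"{path}: motif {motif_id!r} declares w={declared_w} but has {len(rows)} rows"
                )
            motifs.append(MotifModel(motif_id, np.array(rows), n_sites))
        else:
            i += 1
    if not motifs:
        raise FormatError(f"no MOTIF blocks in {path}")
    return motifs


def write_meme_motifs(
    motifs: Iterable[MotifModel],
    path: str | Path,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*background)
        )
        for m in motifs:
            nsites = m.n_sites if m.n_sites is not None else 20
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} nsites= {nsites} E= 0\n"
            )
            for row in m.matrix:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# TSV tables


def read_count_matrix(path: str | Path, condition_map_path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV plus a sample->condition map TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        bad = df[col].astype(float) != np.floor(df[col].astype(float))
        if bad.any():
            gene = df.index[bad.argmax()]
            raise FormatError(
                f"{path}: non-integer count at gene {gene!r}, sample {col!r}"
            )
    cond = pd.read_csv(condition_map_path, sep="\t", index_col=0).iloc[:, 0]
    cond.index = cond.index.astype(str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df.astype(np.int64), cond.astype(str))


def write_count_matrix(cm: CountMatrix, counts_path: str | Path, conditions_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    cm.conditions.rename("condition").to_csv(conditions_path, sep="\t", index_label="sample")


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (set_name, gene_id) -> {name: members}; names unique per row group."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: gene-set table needs (set_name, gene_id) columns")
    sets: dict[str, set[str]] = {}
    for name, sub in df.groupby(df.columns[0], sort=False):
        members = set(sub.iloc[:, 1].astype(str))
        if not members:
            raise FormatError(f"{path}: gene set {name!r} is empty")
        sets[str(name)] = members
    if not sets:
        raise FormatError(f"{path}: no gene sets")
    return sets


def write_gene_sets(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("set_name\tgene_id\n")
        for name in sets:
            for gid in sorted(sets[name]):
                fh.write(f"{name}\t{gid}\n")


def read_tf_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (tf_gene_id, motif_id) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: TF map needs (tf, motif_id) columns")
    mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    if len(mapping) != len(df):
        raise FormatError(f"{path}: duplicate TF in TF->motif map")
    return mapping


def write_tf_map(tf_map: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf\tmotif_id\n")
        for tf in sorted(tf_map):
            fh.write(f"{tf}\t{tf_map[tf]}\n")


# ---------------------------------------------------------------------------
# Edge tables / network export

_EDGE_COLUMNS = [
    "tf",
    "target",
    "rho",
    "sign",
    "n_hits",
    "motif_hit",
    "coexpressed",
    "deg_criterion",
    "floral_criterion",
]


def write_edge_table(trn, path: str | Path) -> None:
    """Write a TRN's edges as a deterministic TSV sorted by (tf, target)."""
    df = trn.edges.copy()
    for col in _EDGE_COLUMNS:
        if col not in df.columns:
            df[col] = [] if df.empty else np.nan
    df = df[_EDGE_COLUMNS].sort_values(["tf", "target"], kind="mergesort")
    df["rho"] = df["rho"].map(lambda r: f"{r:.6f}")
    df.to_csv(path, sep="\t", index=False)


def read_edge_table(path: str | Path, comparison: str = ""):
    from .trn_build import TRN

    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str, "sign": str})
    if list(df.columns) != _EDGE_COLUMNS:
        raise FormatError(f"{path}: unexpected edge-table columns {list(df.columns)}")
    for col in ("motif_hit", "coexpressed", "deg_criterion", "floral_criterion"):
        df[col] = df[col].astype(bool)
    return TRN(comparison=comparison, edges=df)


def write_graphml(trn, path: str | Path) -> None:
    import networkx as nx

    g = nx.DiGraph(comparison=trn.comparison)
    for row in trn.edges.itertuples(index=False):
        g.add_edge(row.tf, row.target, rho=float(row.rho), sign=row.sign)
    nx.write_graphml(g, str(path))
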