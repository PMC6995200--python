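"""Tabular and sequence formats connecting the pipeline stages.

Gene positions travel as BED-like TSV (0-based half-open coordinates);
homologous pairs, collinear blocks and the event-related homology table
are plain TSV.  Lines starting with ``#`` carry provenance metadata
(seed, config hash) and are skipped by every reader.

Ranks -- the 0-based order index of a gene on its chromosome -- are the
coordinate system of all downstream analyses: collinearity gaps, sliding
windows and deletion runs are measured in genes, not base pairs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .collinearity import Anchor, CollinearBlock

GENE_COLUMNS = ["genome", "chrom", "start", "end", "strand", "gene_id"]

MISSING = "."


# ---------------------------------------------------------------------------
# GenomeTable


class GenomeTable:
    """Ordered gene models of one genome, grouped per chromosome.

    Wraps a DataFrame with columns ``gene_id, chrom, start, end, strand``
    (extra columns such as ``subgenome`` are preserved) plus a computed
    ``rank`` column: consecutive 0-based order per chromosome, sorted by
    start coordinate with ties broken by gene_id.
    """

    def __init__(self, genome: str, df: pd.DataFrame):
        required = {"gene_id", "chrom", "start", "end", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r} in genome {genome!r}")
        bad = df["start"] >= df["end"]
        if bad.any():
            g = df.loc[bad, "gene_id"].iloc[0]
            raise ValueError(f"gene {g!r}: start >= end")
        df = df.sort_values(["chrom", "start", "gene_id"], kind="stable").reset_index(drop=True)
        df["rank"] = df.groupby("chrom", sort=False).cumcount()
        self.genome = genome
        self.df = df

    # -- views ---------------------------------------------------------
    @property
    def chromosomes(self) -> List[str]:
        return sorted(self.df["chrom"].unique())

    @property
    def n_genes(self) -> int:
        return len(self.df)

    def genes(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def chrom_sizes(self) -> Dict[str, int]:
        return self.df.groupby("chrom").size().to_dict()

    def rank_index(self) -> Dict[str, Tuple[str, int]]:
        """gene_id -> (chrom, rank)."""
        return {
            g: (c, int(r))
            for g, c, r in zip(self.df["gene_id"], self.df["chrom"], self.df["rank"])
        }

    def gene_order(self, chrom: str) -> List[str]:
        return list(self.genes(chrom)["gene_id"])

    def subset(self, keep: Iterable[str]) -> "GenomeTable":
        """Survivor table after deleting all genes not in *keep* (ranks recomputed)."""
        keep = set(keep)
        return GenomeTable(self.genome, self.df[self.df["gene_id"].isin(keep)].drop(columns="rank"))

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenomeTable({self.genome!r}, {self.n_genes} genes, {len(self.chromosomes)} chromosomes)"


def read_gene_table(path) -> GenomeTable:
    """Read a BED-like gene TSV: genome, chrom, start, end, strand, gene_id.

    Parse errors report the offending 1-based line number; duplicate
    gene ids are reported by id.
    """
    rows = []
    header: Optional[List[str]] = None
    seen: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                idx = {}
                for col in GENE_COLUMNS:
                    if col not in header:
                        raise ValueError(f"{path}: missing column {col!r} in header")
                    idx[col] = header.index(col)
                continue
            try:
                start = int(fields[idx["start"]])
                end = int(fields[idx["end"]])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: bad coordinates ({exc})") from None
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
            gid = fields[idx["gene_id"]]
            if gid in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate gene_id {gid!r} (first at line {seen[gid]})")
            seen[gid] = lineno
            row = {col: fields[idx[col]] for col in GENE_COLUMNS}
            row["start"], row["end"] = start, end
            extras = [c for c in header if c not in GENE_COLUMNS]
            for c in extras:
                row[c] = fields[header.index(c)]
            rows.append(row)
    if header is None:
        raise ValueError(f"{path}: empty gene table")
    df = pd.DataFrame(rows)
    genome = df["genome"].iloc[0] if len(df) else ""
    return GenomeTable(genome, df.drop(columns=["genome"]))


def _write_meta(fh, meta: Optional[Mapping[str, object]]) -> None:
    if meta:
        for k in sorted(meta):
            fh.write(f"# {k}={meta[k]}\n")


def write_gene_table(table: GenomeTable, path, meta: Optional[Mapping[str, object]] = None) -> None:
    extras = [c for c in table.df.columns if c not in GENE_COLUMNS + ["rank"]]
    cols = ["chrom", "start", "end", "strand", "gene_id"] + extras
    with open(path, "w") as fh:
        _write_meta(fh, meta)
        fh.write("\t".join(["genome"] + cols) + "\n")
        for _, row in table.df.iterrows():
            fh.write("\t".join([table.genome] + [str(row[c]) for c in cols]) + "\n")


# ---------------------------------------------------------------------------
# Homologous gene pairs


def canonical_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize pair storage: gene_a < gene_b, self-pairs rejected."""
    if (df["gene_a"] == df["gene_b"]).any():
        bad = df.loc[df["gene_a"] == df["gene_b"], "gene_a"].iloc[0]
        raise ValueError(f"self-pair for gene {bad!r}")
    out = df.copy()
    swap = out["gene_a"] > out["gene_b"]
    out.loc[swap, ["gene_a", "gene_b"]] = out.loc[swap, ["gene_b", "gene_a"]].values
    return out.reset_index(drop=True)


def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise ValueError(f"{path}: pair table needs gene_a and gene_b columns")
    return canonical_pairs(df)


def write_pairs(df: pd.DataFrame, path, meta: Optional[Mapping[str, object]] = None) -> None:
    with open(path, "w") as fh:
        _write_meta(fh, meta)
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Collinear blocks

BLOCK_COLUMNS = [
    "block_id", "genome_a", "chrom_a", "genome_b", "chrom_b",
    "n_anchors", "orientation", "median_ks", "p_value", "anchors",
]


def _encode_anchors(block: CollinearBlock) -> str:
    parts = []
    for a in block.anchors:
        ks = "" if a.ks is None else repr(float(a.ks))
        parts.append(f"{a.rank_a}:{a.rank_b}:{a.gene_a}:{a.gene_b}:{ks}")
    return ";".join(parts)


def _decode_anchors(text: str) -> List[Anchor]:
    anchors = []
    for part in text.split(";"):
        ra, rb, ga, gb, ks = part.split(":")
        anchors.append(Anchor(int(ra), int(rb), ga, gb, float(ks) if ks else None))
    return anchors


def write_blocks(blocks: Sequence[CollinearBlock], path, meta: Optional[Mapping[str, object]] = None) -> None:
    with open(path, "w") as fh:
        _write_meta(fh, meta)
        fh.write("\t".join(BLOCK_COLUMNS) + "\n")
        for i, b in enumerate(blocks):
            mks = "" if b.median_ks is None else repr(float(b.median_ks))
            fh.write(
                "\t".join(
                    [
                        str(i), b.genome_a, b.chrom_a, b.genome_b, b.chrom_b,
                        str(b.n_anchors), b.orientation, mks, repr(float(b.p_value)),
                        _encode_anchors(b),
                    ]
                )
                + "\n"
            )


def read_blocks(path) -> List[CollinearBlock]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    blocks = []
    for _, row in df.iterrows():
        blocks.append(
            CollinearBlock(
                anchors=_decode_anchors(row["anchors"]),
                orientation=row["orientation"],
                chrom_a=row["chrom_a"],
                chrom_b=row["chrom_b"],
                genome_a=row["genome_a"],
                genome_b=row["genome_b"],
                median_ks=float(row["median_ks"]) if row["median_ks"] else None,
                p_value=float(row["p_value"]),
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# Event-related homology table


@dataclass
class EventTable:
    """Reference-anchored multi-genome homology matrix; ``.`` marks a missing cell.

    Rows are keyed by reference gene, in chromosome-then-rank order.  The
    reference carries 3 columns (the gene and its two hexaploidy
    paralogs); each of those heads one outgroup column per outgroup
    genome plus ``n_target_cols`` (= 2^d) target columns, so the total
    column count is 3 x (1 + n_outgroups + 2^d); 18 for one outgroup and
    d = 2 extra duplications.
    """

    df: pd.DataFrame
    ref_genome: str
    target_genome: str
    outgroups: Tuple[str, ...] = ()
    n_target_cols: int = 4

    @property
    def n_columns(self) -> int:
        return len(self.df.columns)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def target_column_names(self, ref_col: int) -> List[str]:
        """Names of the target columns headed by reference column *ref_col* (1-based)."""
        return [f"{self.target_genome}_{ref_col}_{s}" for s in range(1, self.n_target_cols + 1)]

    def presence(self, ref_col: int = 1) -> np.ndarray:
        """Boolean (n_rows, n_target_cols) presence matrix for one reference column."""
        cols = self.target_column_names(ref_col)
        return (self.df[cols] != MISSING).to_numpy()


def event_table_columns(ref: str, target: str, outgroups: Sequence[str], n_target_cols: int) -> List[str]:
    cols = [f"{ref}_{i}" for i in (1, 2, 3)]
    for i in (1, 2, 3):
        for og in outgroups:
            cols.append(f"{og}_{i}")
        cols.extend(f"{target}_{i}_{s}" for s in range(1, n_target_cols + 1))
    return cols


def write_event_table(table: EventTable, path, meta: Optional[Mapping[str, object]] = None) -> None:
    """Write the homology table as TSV; missing cells are a single dot."""
    full_meta = dict(meta or {})
    full_meta.update(
        ref_genome=table.ref_genome,
        target_genome=table.target_genome,
        outgroups=",".join(table.outgroups),
        n_target_cols=table.n_target_cols,
    )
    with open(path, "w") as fh:
        _write_meta(fh, full_meta)
        fh.write("\t".join(table.df.columns) + "\n")
        for _, row in table.df.iterrows():
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_event_table(path) -> EventTable:
    meta: Dict[str, str] = {}
    rows: List[List[str]] = []
    header: Optional[List[str]] = None
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val
                continue
            if not line:
                continue
            if header is None:
                header = line.split("\t")
            else:
                rows.append(line.split("\t"))
    if header is None:
        raise ValueError(f"{path}: empty event table")
    df = pd.DataFrame(rows, columns=header) if rows else pd.DataFrame(columns=header)
    outgroups = tuple(s for s in meta.get("outgroups", "").split(",") if s)
    return EventTable(
        df=df,
        ref_genome=meta.get("ref_genome", ""),
        target_genome=meta.get("target_genome", ""),
        outgroups=outgroups,
        n_target_cols=int(meta.get("n_target_cols", 4)),
    )


# ---------------------------------------------------------------------------
# Aligned CDS pairs


def read_fasta_pair(path) -> Tuple[str, str]:
    """Read a 2-record aligned-CDS FASTA; sequences uppercased, gaps kept as '-'."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 records, found {len(records)}")
    a, b = (str(r.seq).upper() for r in records)
    if len(a) != len(b):
        raise ValueError(f"{path}: length mismatch ({len(a)} vs {len(b)})")
    if len(a) % 3 != 0:
        raise ValueError(f"{path}: alignment length {len(a)} not divisible by 3")
    return a, b


def write_fasta_pair(path, name_a: str, seq_a: str, name_b: str, seq_b: str) -> None:
    with open(path, "w") as fh:
        for name, seq in ((name_a, seq_a), (name_b, seq_b)):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
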