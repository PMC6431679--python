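"""Readers and writers for the plain-text formats the pipeline exchanges.

GFF3 gene/repeat tables, FASTA (via Biopython), BLAST tabular (outfmt 6,
12 columns), TSV expression matrices, and CMAP-like label-map tables.
All writers produce deterministic byte streams for a fixed input.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from subgenomics.annotation import GenomeAnnotation

BLAST6_COLUMNS = [
    "query", "target", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "tstart", "tend", "evalue", "bitscore",
]

CMAP_COLUMNS = ["map_id", "length_bp", "label_index", "position_bp"]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(annot: GenomeAnnotation, path: str | Path) -> None:
    """Write gene models as GFF3 with ID/class/subgenome attributes."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for row in annot.genes.itertuples(index=False):
            attrs = (
                f"ID={row.gene_id};species={row.species};"
                f"homoeo_group={row.homoeo_group};subgenome={row.subgenome};"
                f"class={row.gene_class};anc_id={row.anc_id}"
            )
            fh.write(
                f"{row.chromosome}\tsubgenomics\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Read a GFF3 written by :func:`write_gff3` (or any gene-only GFF3)."""
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attr = (
                line.rstrip("\n").split("\t")
            )
            if ftype != "gene":
                continue
            fields = dict(
                item.split("=", 1) for item in attr.split(";") if "=" in item
            )
            rows.append(
                {
                    "gene_id": fields.get("ID", ""),
                    "chromosome": chrom,
                    "start": int(start),
                    "end": int(end),
                    "strand": strand,
                    "species": fields.get("species", ""),
                    "homoeo_group": int(fields.get("homoeo_group", 0)),
                    "subgenome": fields.get("subgenome", ""),
                    "gene_class": fields.get("class", "gene"),
                    "anc_id": int(fields.get("anc_id", -1)),
                }
            )
    return GenomeAnnotation(pd.DataFrame(rows))


def write_repeat_gff3(repeats: pd.DataFrame, path: str | Path) -> None:
    """Write repeat-element instances (chromosome, start, end, element_id)."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for i, row in enumerate(repeats.itertuples(index=False)):
            fh.write(
                f"{row.chromosome}\tsubgenomics\trepeat_region\t{row.start}\t{row.end}\t.\t+\t.\t"
                f"ID=rep{i:06d};element={row.element_id}\n"
            )


def read_repeat_gff3(path: str | Path) -> pd.DataFrame:
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _s, ftype, start, end, _sc, _st, _ph, attr = line.rstrip("\n").split("\t")
            if ftype != "repeat_region":
                continue
            fields = dict(item.split("=", 1) for item in attr.split(";") if "=" in item)
            rows.append(
                {"chromosome": chrom, "start": int(start), "end": int(end),
                 "element_id": fields.get("element", "")}
            )
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "element_id"])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

def write_blast6(hits: pd.DataFrame, path: str | Path) -> None:
    """Write a hit table as 12-column BLAST tabular.

    Missing alignment columns are filled with neutral placeholders; the
    columns the pipeline consumes are query, target and bitscore.
    """
    df = hits.copy()
    defaults = {
        "pident": 90.0, "length": 300, "mismatch": 0, "gapopen": 0,
        "qstart": 1, "qend": 300, "tstart": 1, "tend": 300, "evalue": 1e-50,
    }
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    df = df[BLAST6_COLUMNS]
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%g")


def read_blast6(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    """Gene x dataset matrix of FPKM-like values, gene ids as index."""
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# ---------------------------------------------------------------------------
# CMAP-like label maps
# ---------------------------------------------------------------------------

def write_cmap(maps: Iterable, path: str | Path) -> None:
    """Write label maps as a CMAP-like TSV (one row per label)."""
    rows = []
    for m in maps:
        for i, pos in enumerate(m.labels, start=1):
            rows.append((m.map_id, m.length, i, int(pos)))
    df = pd.DataFrame(rows, columns=CMAP_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_cmap(path: str | Path) -> list:
    from subgenomics.triomap import LabelMap

    df = pd.read_csv(path, sep="\t")
    maps = []
    for map_id, grp in df.groupby("map_id", sort=False):
        grp = grp.sort_values("label_index")
        maps.append(
            LabelMap(
                map_id=str(map_id),
                length=int(grp["length_bp"].iloc[0]),
                labels=grp["position_bp"].to_numpy(dtype=float),
            )
        )
    return maps
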