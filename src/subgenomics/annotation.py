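"""Ordered gene-model tables shared by every analysis module.

A :class:`GenomeAnnotation` wraps a pandas DataFrame of gene models with
1-based inclusive coordinates (GFF3 convention).  Gene order along a
chromosome is always the order of start coordinates; inter-gene distances
are measured between start nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every gene table carries.  `gene_class` distinguishes ordinary
#: protein-coding genes from labelled classes such as R genes ("R") or
#: repeat elements; `subgenome` is "D" (dominant) or "S" (subdominant);
#: `anc_id` is the simulator's ancestral-gene identity (-1 for real data).
GENE_COLUMNS = [
    "gene_id",
    "chromosome",
    "start",
    "end",
    "strand",
    "species",
    "homoeo_group",
    "subgenome",
    "gene_class",
    "anc_id",
]


@dataclass
class GenomeAnnotation:
    """Ordered gene models of one genome.

    Parameters
    ----------
    genes:
        DataFrame with at least ``gene_id, chromosome, start, end, strand``.
        Missing optional columns are filled with defaults.
    """

    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS))

    def __post_init__(self) -> None:
        df = self.genes.copy()
        defaults = {
            "strand": "+",
            "species": "",
            "homoeo_group": 0,
            "subgenome": "",
            "gene_class": "gene",
            "anc_id": -1,
        }
        for col, val in defaults.items():
            if col not in df.columns:
                df[col] = val
        missing = [c for c in ("gene_id", "chromosome", "start", "end") if c not in df.columns]
        if missing:
            raise ValueError(f"gene table lacks required columns: {missing}")
        df = df[GENE_COLUMNS]
        df = df.sort_values(["chromosome", "start"], kind="mergesort").reset_index(drop=True)
        if (df["start"] < 1).any() or (df["end"] < df["start"]).any():
            raise ValueError("coordinates must be 1-based with end >= start")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id: {dup}")
        self.genes = df

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.genes)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.genes["chromosome"].unique())

    def chromosome(self, name: str) -> pd.DataFrame:
        """Genes of one chromosome in start-coordinate order."""
        sub = self.genes[self.genes["chromosome"] == name]
        return sub.sort_values("start", kind="mergesort").reset_index(drop=True)

    def gene_order(self, name: str) -> pd.Series:
        """gene_id -> 0-based order rank along a chromosome."""
        chrom = self.chromosome(name)
        return pd.Series(np.arange(len(chrom)), index=chrom["gene_id"])

    def positions(self) -> pd.Series:
        """gene_id -> start coordinate over the whole genome."""
        return self.genes.set_index("gene_id")["start"]

    def subset(self, mask) -> "GenomeAnnotation":
        return GenomeAnnotation(self.genes[mask].reset_index(drop=True))

    def equals(self, other: "GenomeAnnotation") -> bool:
        return self.genes.equals(other.genes)
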