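"""Serialise a simulated study to standard plain-text formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from subgenomics import io as sgio
from subgenomics.annotation import GenomeAnnotation


def write_outputs(
    directory: str | Path,
    *,
    genomes: dict[str, GenomeAnnotation] | None = None,
    hits: dict[str, pd.DataFrame] | None = None,
    cds: dict[str, str] | None = None,
    expression: pd.DataFrame | None = None,
    repeats: dict[str, pd.DataFrame] | None = None,
    terminus_sequences: dict[str, str] | None = None,
    label_maps: dict[str, list] | None = None,
) -> dict[str, Path]:
    """Write every provided artifact; returns {name: path}.

    GFF3 for annotations, 12-column BLAST tabular for hit tables, FASTA
    for CDS and terminus sequences, TSV for the expression matrix, and
    CMAP-like TSV for label-map sets.  All writers round-trip losslessly
    through :mod:`subgenomics.io`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _record(name: str, path: Path, writer, *args) -> None:
        try:
            writer(*args, path)
        except OSError as exc:  # pragma: no cover - environment dependent
            raise OSError(f"failed writing {path}: {exc}") from exc
        written[name] = path

    for name, annot in (genomes or {}).items():
        _record(f"genome_{name}", directory / f"{name}.gff3",
                sgio.write_gff3, annot)
    for name, table in (hits or {}).items():
        _record(f"hits_{name}", directory / f"hits_{name}.tsv",
                sgio.write_blast6, table)
    if cds:
        _record("cds", directory / "cds.fasta", sgio.write_fasta, cds)
    if expression is not None:
        _record("expression", directory / "expression.tsv",
                sgio.write_expression, expression)
    for name, table in (repeats or {}).items():
        _record(f"repeats_{name}", directory / f"repeats_{name}.gff3",
                sgio.write_repeat_gff3, table)
    if terminus_sequences:
        _record("termini", directory / "termini.fasta",
                sgio.write_fasta, terminus_sequences)
    for name, maps in (label_maps or {}).items():
        _record(f"maps_{name}", directory / f"maps_{name}.cmap.tsv",
                sgio.write_cmap, maps)
    return written
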