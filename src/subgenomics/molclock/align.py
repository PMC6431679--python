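"""Codon-aware pairwise alignment: align proteins, back-translate to CDS."""

from __future__ import annotations

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_GAP = "-"


def _translate(cds: str, label: str) -> str:
    if len(cds) % 3:
        raise ValueError(f"{label}: CDS length {len(cds)} not a multiple of 3")
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
        cds_check = cds[:-3]
    else:
        cds_check = cds
    if "*" in protein:
        pos = (protein.index("*") + 1) * 3
        raise ValueError(f"{label}: internal stop codon at nt {pos}")
    return protein


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def codon_align(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Globally align two CDS at the protein level, back-translated.

    Returns two equal-length nucleotide strings whose gaps come in
    multiples of three and whose columns are intact codons.  Trailing
    stop codons are dropped; internal stops are rejected.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    prot_a = _translate(cds_a, "first sequence")
    prot_b = _translate(cds_b, "second sequence")
    aln = _make_aligner().align(prot_a, prot_b)[0]
    out_a, out_b = [], []
    ia = ib = 0
    col_a, col_b = aln[0], aln[1]
    for ra, rb in zip(col_a, col_b):
        if ra == _GAP:
            out_a.append(_GAP * 3)
        else:
            out_a.append(cds_a[3 * ia:3 * ia + 3])
            ia += 1
        if rb == _GAP:
            out_b.append(_GAP * 3)
        else:
            out_b.append(cds_b[3 * ib:3 * ib + 3])
            ib += 1
    return "".join(out_a), "".join(out_b)
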