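"""Chromosome landmark analyses: telomeres, centromeres, gene windows.

Telomeres are maximal perfect arrays of the plant telomeric repeat
(CCCTAAA) anchored at a chromosome terminus; the terminus has a
tripartite structure telomere -> heterochromatic subtelomere -> genes.
Centromeres are recognised as dense clusters of a centromeric
retrotransposon; between homoeologous chromosomes a centromere can be
conserved, repositioned by translocation of its repeat array, or
repositioned by an inversion with a breakpoint inside the array.
Window utilities support equal-gene-count window distributions (e.g. of
disease-resistance genes along the telomere-centromere axis) and
fixed-width density profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TELOMERE_MOTIF = "CCCTAAA"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TerminusStructure:
    """Tripartite structure of one chromosome terminus."""

    chromosome: str = ""
    terminus: str = "start"  # "start" (5') or "end" (3')
    telomere_span: int = 0
    n_copies: int = 0
    boundary_sharp: bool = False
    complete: bool = False
    subtelomere_span: int | None = None
    first_gene_position: int | None = None
    first_three_intergenic: list[int] = field(default_factory=list)


@dataclass
class RepeatCluster:
    element_id: str
    chromosome: str
    start: int
    end: int
    copy_count: int
    flank_gene_left: str | None = None
    flank_gene_right: str | None = None


# ---------------------------------------------------------------------------
# Telomeres
# ---------------------------------------------------------------------------

def detect_telomere_array(
    sequence: str,
    motif: str = TELOMERE_MOTIF,
    terminus: str = "start",
    *,
    max_mismatch_per_10_copies: int = 0,
) -> TerminusStructure:
    """Maximal run of perfect motif copies anchored at a terminus.

    At the 3' terminus the reverse-complement motif is counted from the
    sequence end.  The default demands perfect copies; the tolerance mode
    allows up to ``max_mismatch_per_10_copies`` mismatched bases per ten
    copies (for arrays interrupted by short insertions).
    """
    if len(sequence) < len(motif):
        return TerminusStructure(terminus=terminus)
    seq = sequence.upper()
    if terminus == "end":
        seq = _revcomp(seq)
    elif terminus != "start":
        raise ValueError("terminus must be 'start' or 'end'")
    m = len(motif)
    n_copies = 0
    mm_used = 0
    pos = 0
    while pos + m <= len(seq):
        window = seq[pos:pos + m]
        mm = sum(1 for a, b in zip(window, motif) if a != b)
        # integer budget: max_mismatch_per_10_copies mismatches per 10
        # accepted copies, accrued exactly
        if mm and 10 * (mm_used + mm) > n_copies * max_mismatch_per_10_copies:
            break
        mm_used += mm
        n_copies += 1
        pos += m
    span = n_copies * m
    partial = 0
    for p in range(m - 1, 0, -1):
        if seq[span:span + p] == motif[:p]:
            partial = p
            break
    return TerminusStructure(
        terminus=terminus, telomere_span=span, n_copies=n_copies,
        boundary_sharp=span > 0 and partial == 0, complete=span > 0,
    )


def classify_terminus(
    genes: pd.DataFrame,
    telomere: TerminusStructure,
    *,
    chromosome_length: int | None = None,
) -> TerminusStructure:
    """Fill in subtelomere span and the first three intergenic distances.

    ``genes`` are the gene models of the chromosome (any order); the
    subtelomere runs from the end of the telomeric array to the start of
    the first protein-coding gene.  Distances are measured between gene
    start nucleotides (for a 3' terminus, between gene ends mirrored on
    the reverse axis, requiring ``chromosome_length``).
    """
    out = TerminusStructure(**{**telomere.__dict__})
    if telomere.telomere_span == 0:
        out.complete = False
        return out
    df = genes.sort_values("start")
    if telomere.terminus == "start":
        pos = df["start"].to_numpy()
    else:
        if chromosome_length is None:
            raise ValueError("3' terminus requires chromosome_length")
        pos = np.sort(chromosome_length - df["end"].to_numpy() + 1)
    if len(pos) == 0:
        return out
    first3 = pos[:3]
    out.first_gene_position = int(first3[0])
    out.subtelomere_span = int(first3[0] - telomere.telomere_span)
    out.first_three_intergenic = list(np.diff(first3).astype(int))
    return out


# ---------------------------------------------------------------------------
# Centromeres
# ---------------------------------------------------------------------------

def detect_repeat_clusters(
    repeats: pd.DataFrame,
    element_id: str,
    min_copies: int = 10,
    max_within_gap: int = 100_000,
    genes: pd.DataFrame | None = None,
) -> list[RepeatCluster]:
    """Single-linkage clusters of a repeat element along chromosomes.

    Instances closer than ``max_within_gap`` (end-to-start) join a
    cluster; clusters with at least ``min_copies`` members are reported,
    with the nearest flanking genes when an annotation is supplied.
    """
    inst = repeats[repeats["element_id"] == element_id]
    clusters: list[RepeatCluster] = []
    for chrom, grp in inst.groupby("chromosome"):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        breaks = np.where(starts[1:] - ends[:-1] > max_within_gap)[0] + 1
        for block in np.split(np.arange(len(grp)), breaks):
            if len(block) < min_copies:
                continue
            c = RepeatCluster(
                element_id=element_id, chromosome=str(chrom),
                start=int(starts[block[0]]), end=int(ends[block[-1]]),
                copy_count=len(block),
            )
            if genes is not None:
                g = genes[genes["chromosome"] == chrom].sort_values("start")
                left = g[g["end"] < c.start]
                right = g[g["start"] > c.end]
                c.flank_gene_left = left["gene_id"].iloc[-1] if len(left) else None
                c.flank_gene_right = right["gene_id"].iloc[0] if len(right) else None
            clusters.append(c)
    return clusters


def classify_centromere_reposition(
    anchors: pd.DataFrame,
    cluster_a: tuple[int, int] | None,
    clusters_b: list[tuple[int, int]],
    *,
    boundary_tolerance: float | None = None,
) -> str:
    """Compare centromeric-array positions between two homoeologues.

    ``anchors`` holds collinear anchor pairs with columns ``anchor_id,
    pos_a, pos_b`` (coordinates on homoeologue A and B).  Returns
    ``conserved`` (arrays in corresponding anchor intervals),
    ``translocated`` (array moved, collinear order intact),
    ``inversion-split`` (two arrays, or an array abutting an inversion
    breakpoint), or ``unclassified`` when either array is missing.
    """
    if cluster_a is None or not clusters_b:
        return "unclassified"
    if len(clusters_b) >= 2:
        return "inversion-split"
    a = anchors.sort_values("pos_a").reset_index(drop=True)
    if boundary_tolerance is None:
        boundary_tolerance = float(np.median(np.diff(a["pos_a"])))
    cb = clusters_b[0]

    def flank_ids(df, col, lo, hi):
        left = df[df[col] < lo]
        right = df[df[col] > hi]
        return (left["anchor_id"].iloc[-1] if len(left) else None,
                right["anchor_id"].iloc[0] if len(right) else None)

    fa = flank_ids(a, "pos_a", *cluster_a)
    b_sorted = a.sort_values("pos_b").reset_index(drop=True)
    fb = flank_ids(b_sorted, "pos_b", *cb)
    if fa == fb or fa == (fb[1], fb[0]):
        return "conserved"

    # Reversed anchor runs mark inversions between the homoeologues; an
    # array abutting a reversal boundary was carried by that inversion.
    pb = a["pos_b"].to_numpy()
    n = len(pb)
    i = 0
    while i < n - 1:
        if pb[i + 1] < pb[i]:
            j = i
            while j < n - 1 and pb[j + 1] < pb[j]:
                j += 1
            lo, hi = float(pb[j]), float(pb[i])
            near = (abs(cb[0] - hi) <= boundary_tolerance
                    or abs(cb[1] - lo) <= boundary_tolerance
                    or abs(cb[0] - lo) <= boundary_tolerance
                    or abs(cb[1] - hi) <= boundary_tolerance)
            if near:
                return "inversion-split"
            i = j + 1
        else:
            i += 1
    return "translocated"


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def equal_gene_windows(
    genes: pd.DataFrame,
    n_windows: int = 20,
    class_label: str = "R",
) -> tuple[pd.DataFrame, float, float]:
    """Equal-gene-count windows along a telomere-to-centromere arm.

    ``genes`` must already be restricted to one arm and ordered from the
    telomere towards the centromere.  Window sizes differ by at most one
    gene; remainder genes go to the most distal (telomeric) windows.
    Returns the window table, the Spearman correlation of window rank
    vs class proportion, and its p-value.
    """
    n = len(genes)
    if n < n_windows:
        raise ValueError(f"need >= {n_windows} genes, got {n}")
    base, rem = divmod(n, n_windows)
    sizes = [base + 1 if w < rem else base for w in range(n_windows)]
    is_class = (genes["gene_class"] == class_label).to_numpy()
    rows = []
    start = 0
    for w, size in enumerate(sizes):
        block = is_class[start:start + size]
        rows.append({"window": w + 1, "n_genes": size,
                     "n_class": int(block.sum()),
                     "proportion": float(block.mean())})
        start += size
    table = pd.DataFrame(rows)
    if table["proportion"].nunique() < 2:
        return table, float("nan"), float("nan")
    rho, p = stats.spearmanr(table["window"], table["proportion"])
    return table, float(rho), float(p)


def density_profiles(
    features: dict[str, pd.DataFrame],
    window_bp: int = 1_000_000,
    step_bp: int | None = None,
    chromosome_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window feature counts per class along each chromosome.

    ``features`` maps a class name to a table with ``chromosome`` and
    ``start`` columns.  Windows default to non-overlapping.
    """
    step_bp = window_bp if step_bp is None else step_bp
    if step_bp <= 0 or window_bp <= 0:
        raise ValueError("window and step must be positive")
    if chromosome_lengths is None:
        chromosome_lengths = {}
        for df in features.values():
            for chrom, grp in df.groupby("chromosome"):
                chromosome_lengths[chrom] = max(
                    chromosome_lengths.get(chrom, 0), int(grp["start"].max()))
    rows = []
    for chrom in sorted(chromosome_lengths):
        length = chromosome_lengths[chrom]
        for ws in range(1, length + 1, step_bp):
            we = ws + window_bp - 1
            row = {"chromosome": chrom, "window_start": ws, "window_end": we}
            for cls, df in features.items():
                sub = df[df["chromosome"] == chrom]
                row[cls] = int(((sub["start"] >= ws) & (sub["start"] <= we)).sum())
            rows.append(row)
    return pd.DataFrame(rows)


def density_correlation(
    profile: pd.DataFrame, class_a: str, class_b: str
) -> tuple[float, float, bool]:
    """Pearson correlation between two feature classes across windows.

    Returns (r, p, defined); fewer than three windows or zero variance
    leaves the correlation undefined.
    """
    x = profile[class_a].to_numpy(dtype=float)
    y = profile[class_b].to_numpy(dtype=float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan"), False
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), True
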