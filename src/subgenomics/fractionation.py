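"""Asymmetric-fractionation statistics between homoeologous subgenomes.

Within each homoeologous chromosome pair the copy retaining more genes
is the dominant one.  The pair is subdivided into N intervals by N+1
collinear paralogue anchors; genes without a collinear partner
(singletons) are counted per interval on each homoeologue, per 2-Mb
window on dominant coordinates, and compared with a paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from subgenomics.annotation import GenomeAnnotation


@dataclass
class IntervalPartition:
    """Singleton counts in the anchor-delimited intervals of one pair."""

    pair_id: str
    chrom_dominant: str
    chrom_subdominant: str
    intervals: pd.DataFrame  # interval, dom/sub singleton counts and spans
    flank_dominant: tuple[int, int] = (0, 0)   # before first/after last anchor
    flank_subdominant: tuple[int, int] = (0, 0)
    n_anchors: int = 0


@dataclass
class FractionationStats:
    total_dominant: int
    total_subdominant: int
    mean_dominant: float
    mean_subdominant: float
    t_statistic: float
    p_value: float
    df: int
    n: int
    zero_variance: bool = False
    notes: list[str] = field(default_factory=list)


def assign_dominance(
    pairs: list[tuple[str, str]],
    gene_counts: dict[str, int],
) -> pd.DataFrame:
    """Label each chromosome pair's dominant/subdominant copy.

    The chromosome with more genes is dominant; equal counts break by
    chromosome id and are flagged.  Output rows are ordered by
    descending dominant gene count.
    """
    seen: set[str] = set()
    rows = []
    for a, b in pairs:
        for c in (a, b):
            if c in seen:
                raise ValueError(f"chromosome {c} appears in more than one pair")
            seen.add(c)
        ca, cb = gene_counts[a], gene_counts[b]
        tie = ca == cb
        if ca > cb or (tie and a < b):
            dom, sub = a, b
        else:
            dom, sub = b, a
        rows.append({"dominant": dom, "subdominant": sub,
                     "genes_dominant": gene_counts[dom],
                     "genes_subdominant": gene_counts[sub], "tie": tie})
    out = pd.DataFrame(rows).sort_values(
        ["genes_dominant", "dominant"], ascending=[False, True],
        kind="mergesort").reset_index(drop=True)
    out.insert(0, "pair_id", [f"pair{i + 1}" for i in range(len(out))])
    return out


def collinear_anchor_filter(
    annot: GenomeAnnotation,
    anchors: pd.DataFrame,
) -> pd.DataFrame:
    """Greedily keep anchors whose positions ascend on both homoeologues.

    Paralogue pairs inside rearranged segments violate the joint
    ordering that interval counting requires; walking the anchors in
    dominant order and keeping each pair that advances on both copies
    removes them.
    """
    pos = annot.positions()
    a = anchors.copy()
    a["_pd"] = a["gene_d"].map(pos)
    a["_ps"] = a["gene_s"].map(pos)
    a = a.sort_values("_pd")
    keep = []
    last_s = -np.inf
    for _, row in a.iterrows():
        if row["_ps"] > last_s:
            keep.append(row.name)
            last_s = row["_ps"]
    return anchors.loc[keep]


def singleton_intervals(
    annot: GenomeAnnotation,
    chrom_dominant: str,
    chrom_subdominant: str,
    anchors: pd.DataFrame,
    pair_id: str = "pair",
) -> IntervalPartition:
    """Count singletons in the intervals between collinear anchors.

    ``anchors`` needs columns ``gene_d`` / ``gene_s`` (collinear
    paralogue pairs), ordered consistently on both homoeologues; genes
    before the first or after the last anchor are reported as flanks.
    """
    if len(anchors) < 2:
        raise ValueError("need at least two anchors to form an interval")
    pos = annot.positions()
    a = anchors.copy()
    a["pos_d"] = a["gene_d"].map(pos)
    a["pos_s"] = a["gene_s"].map(pos)
    if a[["pos_d", "pos_s"]].isna().any().any():
        raise ValueError("anchor gene missing from the annotation")
    a = a.sort_values("pos_d").reset_index(drop=True)
    ds = np.diff(a["pos_s"])
    if not ((ds > 0).all() or (ds < 0).all()):
        raise ValueError("anchors are not consistently ordered on the "
                         "subdominant homoeologue")
    anchor_genes = set(a["gene_d"]) | set(a["gene_s"])

    def side_counts(chrom, col):
        genes = annot.chromosome(chrom)
        non_anchor = genes[~genes["gene_id"].isin(anchor_genes)]
        bounds = a[col].to_numpy()
        lo, hi = bounds.min(), bounds.max()
        asc = bounds[0] < bounds[-1]
        idx = np.searchsorted(np.sort(bounds), non_anchor["start"].to_numpy())
        before = int((non_anchor["start"] < lo).sum())
        after = int((non_anchor["start"] > hi).sum())
        interval_of = idx - 1  # 0..N-1 for interior
        counts = np.zeros(len(bounds) - 1, dtype=int)
        interior = (interval_of >= 0) & (interval_of < len(counts))
        for k in interval_of[interior]:
            counts[k] += 1
        if not asc:  # intervals numbered along the dominant orientation
            counts = counts[::-1]
        return counts, (before, after) if asc else (after, before)

    dom_counts, dom_flanks = side_counts(chrom_dominant, "pos_d")
    sub_counts, sub_flanks = side_counts(chrom_subdominant, "pos_s")
    spans_d = np.abs(np.diff(a["pos_d"])).astype(int)
    spans_s = np.abs(np.diff(a["pos_s"])).astype(int)
    intervals = pd.DataFrame({
        "interval": np.arange(1, len(dom_counts) + 1),
        "dominant_singletons": dom_counts,
        "subdominant_singletons": sub_counts,
        "span_dominant_bp": spans_d,
        "span_subdominant_bp": spans_s,
        "anchor_start_dominant": a["pos_d"].to_numpy()[:-1].astype(int),
    })
    return IntervalPartition(
        pair_id=pair_id, chrom_dominant=chrom_dominant,
        chrom_subdominant=chrom_subdominant, intervals=intervals,
        flank_dominant=dom_flanks, flank_subdominant=sub_flanks,
        n_anchors=len(a),
    )


def window_singletons(
    partition: IntervalPartition,
    annot: GenomeAnnotation,
    window_bp: int = 2_000_000,
) -> pd.DataFrame:
    """Singleton counts per non-overlapping window on dominant coordinates.

    Subdominant singletons are keyed to the dominant-coordinate start of
    their anchor interval.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    length = int(annot.chromosome(partition.chrom_dominant)["end"].max())
    n_windows = int(np.ceil(length / window_bp))
    dom = np.zeros(n_windows, dtype=int)
    sub = np.zeros(n_windows, dtype=int)
    iv = partition.intervals
    anchor_pos = iv["anchor_start_dominant"].to_numpy()
    # dominant singletons at their interval's dominant anchor span midpoint
    for k, row in iv.iterrows():
        w = min(int(anchor_pos[k] // window_bp), n_windows - 1)
        dom[w] += int(row["dominant_singletons"])
        sub[w] += int(row["subdominant_singletons"])
    return pd.DataFrame({
        "window": np.arange(1, n_windows + 1),
        "window_start": np.arange(n_windows) * window_bp + 1,
        "dominant_singletons": dom,
        "subdominant_singletons": sub,
    })


def paired_asymmetry_test(
    dominant_counts,
    subdominant_counts,
) -> FractionationStats:
    """Two-tailed paired t-test of dominant vs subdominant counts."""
    x = np.asarray(dominant_counts, dtype=float)
    y = np.asarray(subdominant_counts, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two paired observations")
    d = x - y
    sd = d.std(ddof=1)
    zero_var = sd == 0
    notes = []
    if zero_var:
        t = 0.0 if d.mean() == 0 else float("inf") * np.sign(d.mean())
        p = 1.0 if d.mean() == 0 else 0.0
        notes.append("zero variance of paired differences")
    else:
        t, p = stats.ttest_rel(x, y)
    return FractionationStats(
        total_dominant=int(x.sum()), total_subdominant=int(y.sum()),
        mean_dominant=float(x.mean()), mean_subdominant=float(y.mean()),
        t_statistic=float(t), p_value=float(p), df=n - 1, n=n,
        zero_variance=zero_var, notes=notes,
    )
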