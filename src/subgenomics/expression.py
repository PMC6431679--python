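"""Expression dominance between collinear homoeologous gene pairs.

A pair is differentially expressed in a dataset when the two copies
differ by more than a fold threshold (default two-fold, strict); the
higher-expressed copy is the dominant orthologue.  Subgenome-level bias
is tested by comparing, per homoeologous chromosome pair, the numbers
of dominant calls on the dominant vs subdominant chromosome with a
paired t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CALLS = ("dominant-copy", "subordinate-copy", "not-differential", "not-expressed")


def call_dominance(
    expr: pd.DataFrame,
    pairs: pd.DataFrame,
    fold_threshold: float = 2.0,
    floor: float = 0.1,
) -> pd.DataFrame:
    """Per-pair, per-dataset dominance calls.

    ``expr`` is a gene x dataset FPKM matrix; ``pairs`` has columns
    ``gene_d`` (dominant-chromosome copy) and ``gene_s``.  The fold is
    (x_d + floor) / (x_s + floor); a call is made only above the strict
    fold threshold, and pairs with both copies below ``floor`` are
    not-expressed.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    missing = [g for g in pd.concat([pairs["gene_d"], pairs["gene_s"]])
               if g not in expr.index]
    if missing:
        raise ValueError(f"genes absent from the matrix: {missing[:5]} ...")
    xd = expr.loc[pairs["gene_d"]].to_numpy(dtype=float)
    xs = expr.loc[pairs["gene_s"]].to_numpy(dtype=float)
    fold = (xd + floor) / (xs + floor)
    call = np.full(fold.shape, "not-differential", dtype=object)
    call[fold > fold_threshold] = "dominant-copy"
    call[fold < 1.0 / fold_threshold] = "subordinate-copy"
    call[(xd < floor) & (xs < floor)] = "not-expressed"
    n_pairs, n_ds = fold.shape
    out = pd.DataFrame({
        "gene_d": np.tile(pairs["gene_d"].to_numpy(), n_ds),
        "gene_s": np.tile(pairs["gene_s"].to_numpy(), n_ds),
        "dataset": np.repeat(expr.columns.to_numpy(), n_pairs),
        "call": call.ravel(order="F"),
        "fold": fold.ravel(order="F").astype(float),
    })
    for c in ("group", "species"):
        if c in pairs.columns:
            out[c] = np.tile(pairs[c].to_numpy(), n_ds)
    return out


def subgenome_bias_test(
    calls: pd.DataFrame,
    group_col: str = "group",
) -> dict:
    """Subgenome expression-bias test over homoeologous chromosome pairs.

    Counts dominant-copy vs subordinate-copy calls per chromosome pair
    and dataset, then applies a two-tailed paired t-test across pairs to
    the per-pair call totals (and reports the per-dataset count table).
    """
    if group_col not in calls.columns:
        raise ValueError(f"calls table lacks a '{group_col}' column")
    per_dataset = (
        calls.groupby([group_col, "dataset", "call"], sort=True)
        .size().unstack("call", fill_value=0).reset_index()
    )
    for c in CALLS:
        if c not in per_dataset.columns:
            per_dataset[c] = 0
    totals = (
        calls.groupby(group_col)["call"]
        .value_counts().unstack(fill_value=0)
    )
    for c in CALLS:
        if c not in totals.columns:
            totals[c] = 0
    if len(totals) < 2:
        raise ValueError("need at least two chromosome pairs")
    dom = totals["dominant-copy"].to_numpy(dtype=float)
    sub = totals["subordinate-copy"].to_numpy(dtype=float)
    d = dom - sub
    if d.std(ddof=1) == 0:
        t, p = (0.0, 1.0) if d.mean() == 0 else (float("inf"), 0.0)
    else:
        t, p = stats.ttest_rel(dom, sub)
    return {
        "per_dataset_counts": per_dataset,
        "per_pair_totals": totals.reset_index(),
        "t_statistic": float(t),
        "p_value": float(p),
        "n_pairs": int(len(totals)),
    }
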