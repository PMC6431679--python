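"""Collinearity: top-hit selection, RBH, tandem collapsing, chains.

The chain detector is checked against an independent re-implementation
of the chain rule (next-eligible-gene growth under the monotonicity,
gap, and interruption limits) on hundreds of random small tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from subgenomics.annotation import GenomeAnnotation
from subgenomics.collinearity import (
    collapse_tandem,
    detect_collinear_chains,
    orthologous_alignment,
    reciprocal_best_hits,
    select_top_hits,
)


def _annot(chrom_sizes: dict[str, int], prefix: str, spacing=100_000):
    rows = []
    for chrom, n in chrom_sizes.items():
        for i in range(n):
            rows.append({"gene_id": f"{prefix}{chrom}_{i:03d}",
                         "chromosome": chrom,
                         "start": (i + 1) * spacing,
                         "end": (i + 1) * spacing + 1000})
    return GenomeAnnotation(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Top hits / RBH
# ---------------------------------------------------------------------------

def test_select_top_hits_ranks_by_score():
    hits = pd.DataFrame({
        "query": ["q"] * 4,
        "target": ["t1", "t2", "t3", "t4"],
        "bitscore": [200.0, 150.0, 100.0, 50.0],
    })
    top3 = select_top_hits(hits, 3)
    assert top3["target"].tolist() == ["t1", "t2", "t3"]
    assert top3["rank"].tolist() == [1, 2, 3]
    top1 = select_top_hits(hits, 1)
    assert top1["target"].tolist() == ["t1"]
    assert select_top_hits(hits[hits["query"] == "absent"], 3).empty
    with pytest.raises(ValueError):
        select_top_hits(hits, 0)


def test_reciprocal_best_hits_examples():
    ab = pd.DataFrame({"query": ["a1", "a2"], "target": ["b1", "b2"],
                       "bitscore": [100.0, 90.0]})
    ba = pd.DataFrame({"query": ["b1", "b2"], "target": ["a1", "a1"],
                       "bitscore": [100.0, 80.0]})
    pairs = reciprocal_best_hits(ab, ba)
    assert pairs.values.tolist() == [["a1", "b1"]]  # a2<->b2 not mutual


def test_reciprocal_best_hits_matches_mutual_argmax_oracle():
    rng = np.random.default_rng(0)
    for _ in range(30):
        scores_ab = rng.random((10, 10))
        scores_ba = rng.random((10, 10))
        a_ids = [f"a{i}" for i in range(10)]
        b_ids = [f"b{j}" for j in range(10)]
        ab = pd.DataFrame([(a_ids[i], b_ids[j], scores_ab[i, j])
                           for i in range(10) for j in range(10)],
                          columns=["query", "target", "bitscore"])
        ba = pd.DataFrame([(b_ids[j], a_ids[i], scores_ba[j, i])
                           for j in range(10) for i in range(10)],
                          columns=["query", "target", "bitscore"])
        expected = {
            (a_ids[i], b_ids[j])
            for i in range(10) for j in range(10)
            if scores_ab[i].argmax() == j and scores_ba[j].argmax() == i
        }
        got = set(map(tuple, reciprocal_best_hits(ab, ba).values))
        assert got == expected


# ---------------------------------------------------------------------------
# Tandem collapsing
# ---------------------------------------------------------------------------

def test_collapse_tandem_prefers_the_collinear_copy():
    qa = _annot({"q1": 5}, "q")
    ta = _annot({"t1": 6}, "t")
    # queries 0..4 map to targets 0,1,(2 or 3),4,5; query 2 hits the
    # tandem copies t2/t3 with the non-collinear copy scoring higher.
    rows = []
    for qi, ti in [(0, 0), (1, 1), (3, 4), (4, 5)]:
        rows.append((f"qq1_{qi:03d}", f"tt1_{ti:03d}", 100.0))
    rows.append(("qq1_002", "tt1_002", 95.0))
    rows.append(("qq1_002", "tt1_003", 99.0))
    hits = pd.DataFrame(rows, columns=["query", "target", "bitscore"])
    out = collapse_tandem(qa, ta, hits)
    kept = out[out["query"] == "qq1_002"]["target"].tolist()
    assert kept == ["tt1_002"] or kept == ["tt1_003"]
    assert len(kept) == 1
    # copies on different chromosomes are not tandem: both retained
    ta2 = _annot({"t1": 3, "t2": 3}, "u")
    hits2 = pd.DataFrame([("qq1_000", "ut1_000", 90.0),
                          ("qq1_000", "ut2_000", 85.0)],
                         columns=["query", "target", "bitscore"])
    out2 = collapse_tandem(qa, ta2, hits2)
    assert len(out2) == 2


def test_collapse_tandem_recovers_true_copy_with_context():
    """With flanking collinear anchors the copy in collinear position is
    retained even when the other copy scores higher."""
    rng = np.random.default_rng(5)
    correct = 0
    trials = 40
    for _ in range(trials):
        qa = _annot({"q1": 9}, "q")
        ta = _annot({"t1": 10}, "t")
        dup_pos = int(rng.integers(2, 7))
        rows = []
        for qi in range(9):
            ti = qi if qi < dup_pos else qi + 1
            if qi == dup_pos:
                rows.append((f"qq1_{qi:03d}", f"tt1_{qi:03d}",
                             95.0 + rng.normal(0, 1)))
                rows.append((f"qq1_{qi:03d}", f"tt1_{qi + 1:03d}",
                             99.0 + rng.normal(0, 1)))
            else:
                rows.append((f"qq1_{qi:03d}", f"tt1_{ti:03d}",
                             100.0 + rng.normal(0, 1)))
        hits = pd.DataFrame(rows, columns=["query", "target", "bitscore"])
        out = collapse_tandem(qa, ta, hits)
        kept = out[out["query"] == f"qq1_{dup_pos:03d}"]["target"].tolist()
        correct += kept == [f"tt1_{dup_pos:03d}"]
    assert correct / trials >= 0.95


# ---------------------------------------------------------------------------
# Chains: examples
# ---------------------------------------------------------------------------

def _chain_inputs(target_starts, chrom="t1"):
    n = len(target_starts)
    qa = _annot({"q1": n}, "q")
    ta_rows = []
    for i, ts in enumerate(sorted(set(target_starts))):
        ta_rows.append({"gene_id": f"t_{ts}", "chromosome": chrom,
                        "start": ts, "end": ts + 100})
    ta = GenomeAnnotation(pd.DataFrame(ta_rows))
    hits = pd.DataFrame({
        "query": [f"qq1_{i:03d}" for i in range(n)],
        "target": [f"t_{ts}" for ts in target_starts],
        "bitscore": [100.0] * n,
    })
    return qa, ta, hits


@pytest.mark.parametrize("starts,orientation", [
    ([100_000, 200_000, 300_000], "ascending"),
    ([300_000, 200_000, 100_000], "descending"),
])
def test_minimal_three_gene_chain(starts, orientation):
    qa, ta, hits = _chain_inputs(starts)
    chains, summary = detect_collinear_chains(qa, ta, hits)
    assert len(chains) == 1
    assert chains[0].orientation == orientation
    assert len(chains[0]) == 3
    assert summary["collinear_percent"] == 100.0


def test_two_genes_are_not_a_chain():
    qa, ta, hits = _chain_inputs([100_000, 200_000])
    chains, summary = detect_collinear_chains(qa, ta, hits)
    assert chains == []
    assert summary["collinear_percent"] == 0.0


def test_gap_over_half_megabase_breaks_the_chain():
    qa, ta, hits = _chain_inputs(
        [100_000, 200_000, 300_000, 900_000, 1_000_000, 1_100_000])
    chains, _ = detect_collinear_chains(qa, ta, hits)
    assert sorted(len(c) for c in chains) == [3, 3]
    spans = sorted(c.target_span for c in chains)
    assert spans == [(100_000, 300_000), (900_000, 1_100_000)]


def test_interrupting_genes_are_tolerated_up_to_the_limit():
    # gene 1 hits a different chromosome: one interrupt, chain survives
    qa = _annot({"q1": 4}, "q")
    ta = _annot({"t1": 4, "t2": 2}, "t")
    hits = pd.DataFrame({
        "query": ["qq1_000", "qq1_001", "qq1_002", "qq1_003"],
        "target": ["tt1_000", "tt2_000", "tt1_001", "tt1_002"],
        "bitscore": [100.0] * 4,
    })
    chains, _ = detect_collinear_chains(qa, ta, hits, max_interrupt=1)
    t1 = [c for c in chains if c.target_chromosome == "t1"]
    assert len(t1) == 1 and len(t1[0]) == 3
    chains0, _ = detect_collinear_chains(qa, ta, hits, max_interrupt=0)
    assert [len(c) for c in chains0 if c.target_chromosome == "t1"] == []


def test_unbroken_simulated_chromosomes_give_single_chains(quiet_study):
    chains, summary = detect_collinear_chains(
        quiet_study["genome_r"], quiet_study["genome_m"],
        quiet_study["hits"])
    assert summary["collinear_percent"] == 100.0
    assert summary["n_chains"] == 4  # one per chromosome
    assert all(len(c) == 300 for c in chains)
    assert orthologous_alignment(chains) == {
        "R1D": "M1D", "R1S": "M1S", "R2D": "M2D", "R2S": "M2S"}


# ---------------------------------------------------------------------------
# Chains: oracle equivalence and properties
# ---------------------------------------------------------------------------

def _oracle_chains(qranks, tchroms, tstarts, min_genes, max_gap, max_intr):
    """Independent re-implementation of the chain rule.

    Returns a set of (orientation, member index tuple) over the input
    rows (which represent the query genes with hits, in query order).
    """
    found = []
    for tc in sorted(set(tchroms)):
        idx = [i for i in range(len(qranks)) if tchroms[i] == tc]
        used = set()
        for s_pos, seed in enumerate(idx):
            if seed in used:
                continue
            best = None
            for sign, orient in ((1, "ascending"), (-1, "descending")):
                chain = [seed]
                while True:
                    cur = chain[-1]
                    nxt = None
                    for j in idx:
                        if j <= cur or qranks[j] - qranks[cur] - 1 > max_intr:
                            continue
                        if abs(tstarts[j] - tstarts[cur]) >= max_gap:
                            continue
                        if sign * (tstarts[j] - tstarts[cur]) > 0:
                            nxt = j
                            break
                    if nxt is None:
                        break
                    chain.append(nxt)
                if best is None or len(chain) > len(best[1]):
                    best = (orient, chain)
            orient, chain = best
            if len(chain) >= min_genes:
                found.append((orient, tuple(chain)))
                used.update(chain)
    # containment filter
    out = set()
    for o, c in found:
        cs = set(c)
        if not any(set(c2) > cs for _, c2 in found):
            out.add((o, c))
    return out


@pytest.mark.parametrize("trial_block", range(4))
def test_chains_match_independent_oracle_on_random_tables(trial_block):
    """Detected chains equal the independent rule re-implementation on
    random small hit tables (cumulatively >= 200 tables)."""
    rng = np.random.default_rng(1000 + trial_block)
    for _ in range(60):
        n = int(rng.integers(4, 31))
        qa = _annot({"q1": n}, "q")
        n_t = int(rng.integers(1, 3))
        tchrom_names = [f"t{k}" for k in range(n_t)]
        tstart_pool = {}
        rows, tchroms, tstarts = [], [], []
        t_rows = []
        for i in range(n):
            tc = tchrom_names[int(rng.integers(n_t))]
            ts = int(rng.integers(1, 15)) * 100_000
            while (tc, ts) in tstart_pool:
                ts += 1  # unique target coordinates
            tstart_pool[(tc, ts)] = f"t_{tc}_{ts}"
            t_rows.append({"gene_id": tstart_pool[(tc, ts)],
                           "chromosome": tc, "start": ts, "end": ts + 10})
            rows.append((f"qq1_{i:03d}", tstart_pool[(tc, ts)], 100.0))
            tchroms.append(tc)
            tstarts.append(ts)
        ta = GenomeAnnotation(pd.DataFrame(t_rows))
        hits = pd.DataFrame(rows, columns=["query", "target", "bitscore"])
        min_genes = int(rng.integers(2, 4))
        max_intr = int(rng.integers(0, 4))
        chains, _ = detect_collinear_chains(
            qa, ta, hits, min_genes=min_genes, max_gap_bp=500_000,
            max_interrupt=max_intr)
        got = {
            (c.orientation,
             tuple(int(q[4:]) for q, _ in c.members))
            for c in chains
        }
        expected = _oracle_chains(list(range(n)), tchroms, tstarts,
                                  min_genes, 500_000, max_intr)
        assert got == expected


def test_chain_monotonicity_and_gap_invariants(event_study):
    chains, summary = detect_collinear_chains(
        event_study["genome_r"], event_study["genome_m"],
        event_study["hits"])
    tpos = event_study["genome_m"].positions()
    for c in chains:
        ts = [int(tpos[t]) for _, t in c.members]
        diffs = np.diff(ts)
        if c.orientation == "ascending":
            assert (diffs > 0).all()
        else:
            assert (diffs < 0).all()
        assert (np.abs(diffs) < 500_000).all()
    assert 0.0 <= summary["collinear_percent"] <= 100.0
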