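"""Collinear gene-chain detection from ranked homology hits.

Three or more query genes are collinear when the start nucleotides of
their top hits on one target chromosome follow a strictly ascending or
descending order, successive target starts are closer than a gap limit
(default 0.5 Mb), and at most a bounded number of non-collinear query
genes interrupt the run.  Chains are maximal: they can be extended by no
adjacent eligible gene and are not contained in any other chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from subgenomics.annotation import GenomeAnnotation


@dataclass
class CollinearChain:
    chain_id: str
    query_chromosome: str
    target_chromosome: str
    orientation: str  # "ascending" | "descending"
    members: list[tuple[str, str]]  # (query gene, target gene)
    query_span: tuple[int, int]
    target_span: tuple[int, int]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def query_genes(self) -> list[str]:
        return [q for q, _ in self.members]


# ---------------------------------------------------------------------------
# Hit-table preparation
# ---------------------------------------------------------------------------

def select_top_hits(
    hits: pd.DataFrame,
    n: int,
    target_annot: GenomeAnnotation | None = None,
) -> pd.DataFrame:
    """Per query, the ``n`` highest-scoring targets with a rank column.

    Ties break deterministically by descending score then target
    chromosome and start (when an annotation is supplied) or target id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    df = hits.copy()
    if target_annot is not None:
        pos = target_annot.genes.set_index("gene_id")[["chromosome", "start"]]
        df["_tchrom"] = df["target"].map(pos["chromosome"])
        df["_tstart"] = df["target"].map(pos["start"])
        df = df.sort_values(
            ["query", "bitscore", "_tchrom", "_tstart", "target"],
            ascending=[True, False, True, True, True], kind="mergesort",
        ).drop(columns=["_tchrom", "_tstart"])
    else:
        df = df.sort_values(["query", "bitscore", "target"],
                            ascending=[True, False, True], kind="mergesort")
    df["rank"] = df.groupby("query", sort=False).cumcount() + 1
    return df[df["rank"] <= n].reset_index(drop=True)


def reciprocal_best_hits(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame
) -> pd.DataFrame:
    """Mutual-best pairs (a, b) from the two directional hit tables."""
    best_ab = select_top_hits(hits_ab, 1).set_index("query")["target"]
    best_ba = select_top_hits(hits_ba, 1).set_index("query")["target"]
    rows = [
        (a, b) for a, b in best_ab.items()
        if b in best_ba.index and best_ba[b] == a
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b"])


def collapse_tandem(
    query_annot: GenomeAnnotation,
    target_annot: GenomeAnnotation,
    hits: pd.DataFrame,
    max_tandem_gap: int = 1,
) -> pd.DataFrame:
    """Collapse hits against tandem-duplicated target genes.

    When one query hits two or more targets lying within
    ``max_tandem_gap`` order ranks on one chromosome, only one copy is
    kept: the copy nearest the target position interpolated from the
    flanking query genes' top hits (a collinear position), or the
    highest-scoring copy when no context exists.
    """
    tpos = target_annot.genes.set_index("gene_id")[["chromosome", "start"]]
    trank = {}
    for chrom in target_annot.chromosomes:
        for r, g in enumerate(target_annot.chromosome(chrom)["gene_id"]):
            trank[g] = r
    top = select_top_hits(hits, 1).set_index("query")["target"]
    qorder = query_annot.genes.sort_values(["chromosome", "start"])

    # expected target rank per query from neighbouring queries' top hits
    expected: dict[str, tuple[str, float]] = {}
    for chrom, grp in qorder.groupby("chromosome"):
        ids = grp["gene_id"].tolist()
        for k, q in enumerate(ids):
            ctx = []
            for nb in ids[max(0, k - 2):k] + ids[k + 1:k + 3]:
                t = top.get(nb)
                if t is not None and t in tpos.index:
                    ctx.append((tpos.loc[t, "chromosome"], trank[t]))
            if ctx:
                chroms = pd.Series([c for c, _ in ctx])
                mode = chroms.mode().iloc[0]
                ranks = [r for c, r in ctx if c == mode]
                expected[q] = (mode, float(np.median(ranks)))

    keep_idx = []
    df = hits.reset_index(drop=True)
    df["_tchrom"] = df["target"].map(tpos["chromosome"])
    df["_trank"] = df["target"].map(pd.Series(trank))
    for q, grp in df.groupby("query", sort=False):
        grp = grp.sort_values(["_tchrom", "_trank"])
        used = np.zeros(len(grp), dtype=bool)
        rows = grp.reset_index()
        i = 0
        while i < len(rows):
            j = i
            while (j + 1 < len(rows)
                   and rows.loc[j + 1, "_tchrom"] == rows.loc[i, "_tchrom"]
                   and rows.loc[j + 1, "_trank"] - rows.loc[j, "_trank"]
                   <= max_tandem_gap):
                j += 1
            block = rows.iloc[i:j + 1]
            if len(block) == 1:
                keep_idx.append(int(block["index"].iloc[0]))
            else:
                exp = expected.get(q)
                if exp is not None and exp[0] == block["_tchrom"].iloc[0]:
                    pick = (block["_trank"] - exp[1]).abs().idxmin()
                else:
                    pick = block["bitscore"].idxmax()
                keep_idx.append(int(rows.loc[pick, "index"]))
            i = j + 1
    out = df.loc[sorted(set(keep_idx))].drop(columns=["_tchrom", "_trank"])
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Chain detection
# ---------------------------------------------------------------------------

def detect_collinear_chains(
    query_annot: GenomeAnnotation,
    target_annot: GenomeAnnotation,
    hits: pd.DataFrame,
    min_genes: int = 3,
    max_gap_bp: int = 500_000,
    max_interrupt: int = 3,
) -> tuple[list[CollinearChain], dict]:
    """Maximal collinear chains plus a collinearity summary.

    Only each query's top hit participates.  A chain is a subsequence of
    query genes (same target chromosome) whose target starts are
    strictly monotone with successive distances < ``max_gap_bp`` and at
    most ``max_interrupt`` consecutive intervening query genes skipped.
    Maximality is set-theoretic: no chain is a subset of another.
    """
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")
    top = select_top_hits(hits, 1, target_annot)
    tpos = target_annot.genes.set_index("gene_id")[["chromosome", "start"]]
    top = top[top["target"].isin(tpos.index)]
    tmap = top.set_index("query")["target"]

    chains: list[CollinearChain] = []
    qpos = query_annot.genes.set_index("gene_id")["start"]
    n_query_genes = len(query_annot)
    counter = 0
    for qchrom in query_annot.chromosomes:
        ids = query_annot.chromosome(qchrom)["gene_id"].tolist()
        nodes = []  # (query gene, qrank, target gene, tchrom, tstart)
        for r, q in enumerate(ids):
            t = tmap.get(q)
            if t is not None:
                nodes.append((q, r, t, tpos.loc[t, "chromosome"],
                              int(tpos.loc[t, "start"])))
        for tchrom in sorted({nd[3] for nd in nodes}):
            sub = [nd for nd in nodes if nd[3] == tchrom]
            for path, orientation in _greedy_chains(
                    sub, max_gap_bp, max_interrupt, min_genes):
                members = [(sub[i][0], sub[i][2]) for i in path]
                qspan = (int(qpos[members[0][0]]), int(qpos[members[-1][0]]))
                tstarts = [sub[i][4] for i in path]
                counter += 1
                chains.append(CollinearChain(
                    chain_id=f"chain{counter:05d}",
                    query_chromosome=qchrom, target_chromosome=tchrom,
                    orientation=orientation, members=members,
                    query_span=(min(qspan), max(qspan)),
                    target_span=(min(tstarts), max(tstarts)),
                ))
    chains = _drop_contained(chains)
    collinear_genes = sorted({q for c in chains for q in c.query_genes})
    summary = {
        "n_query_genes": n_query_genes,
        "n_collinear_genes": len(collinear_genes),
        "collinear_percent": 100.0 * len(collinear_genes) / n_query_genes
        if n_query_genes else 0.0,
        "n_chains": len(chains),
    }
    return chains, summary


def _eligible(a, b, orientation: str, max_gap_bp: int, max_interrupt: int) -> bool:
    """May chain member a be immediately followed by b?"""
    if b[1] - a[1] - 1 > max_interrupt:
        return False
    if abs(b[4] - a[4]) >= max_gap_bp:
        return False
    return b[4] > a[4] if orientation == "ascending" else b[4] < a[4]


def _extend_greedy(sub, start, orientation, max_gap_bp, max_interrupt):
    """Grow a chain from ``start`` by always taking the next (closest)
    eligible gene; genes skipped over are the interrupting genes."""
    chain = [start]
    cur = start
    n = len(sub)
    while True:
        nxt = None
        for j in range(cur + 1, n):
            if sub[j][1] - sub[cur][1] - 1 > max_interrupt:
                break
            if _eligible(sub[cur], sub[j], orientation, max_gap_bp,
                         max_interrupt):
                nxt = j
                break
        if nxt is None:
            return chain
        chain.append(nxt)
        cur = nxt


def _greedy_chains(sub, max_gap_bp, max_interrupt, min_genes):
    """Chains seeded left-to-right at genes not yet members of a chain.

    Both orientations are grown from each seed; the longer chain wins
    (ascending preferred on ties).
    """
    used: set[int] = set()
    out = []
    for seed in range(len(sub)):
        if seed in used:
            continue
        asc = _extend_greedy(sub, seed, "ascending", max_gap_bp, max_interrupt)
        desc = _extend_greedy(sub, seed, "descending", max_gap_bp, max_interrupt)
        path, orientation = ((asc, "ascending") if len(asc) >= len(desc)
                             else (desc, "descending"))
        if len(path) >= min_genes:
            out.append((path, orientation))
            used.update(path)
    return out


def _drop_contained(chains: list[CollinearChain]) -> list[CollinearChain]:
    """Remove chains whose member set is contained in another chain's."""
    sets = [frozenset(c.members) for c in chains]
    keep = []
    for i, c in enumerate(chains):
        contained = any(
            i != j and sets[i] < sets[j] or
            (i != j and sets[i] == sets[j] and j < i)
            for j in range(len(chains))
        )
        if not contained:
            keep.append(c)
    return keep


def orthologous_alignment(chains: list[CollinearChain]) -> dict[str, str]:
    """Per query chromosome, the target chromosome carrying the most
    collinear genes (the orthologous alignment); ties break by target
    chromosome id."""
    counts: dict[str, dict[str, set]] = {}
    for c in chains:
        counts.setdefault(c.query_chromosome, {}).setdefault(
            c.target_chromosome, set()).update(c.query_genes)
    return {
        q: sorted(tc.items(), key=lambda kv: (-len(kv[1]), kv[0]))[0][0]
        for q, tc in counts.items()
    }


def chains_table(chains: list[CollinearChain]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chain_id": c.chain_id, "query_chromosome": c.query_chromosome,
          "target_chromosome": c.target_chromosome,
          "orientation": c.orientation, "n_genes": len(c),
          "query_start": c.query_span[0], "query_end": c.query_span[1],
          "target_start": c.target_span[0], "target_end": c.target_span[1],
          "members": ";".join(f"{q}|{t}" for q, t in c.members)}
         for c in chains],
        columns=["chain_id", "query_chromosome", "target_chromosome",
                 "orientation", "n_genes", "query_start", "query_end",
                 "target_start", "target_end", "members"],
    )
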