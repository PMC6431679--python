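"""Classification of structural rearrangements between two gene orders.

Events are coded in the classic comparative-genomics scheme:

====  =====================================================
A     inversion of 2 genes
B     inversion of 3 genes
C     inversion of > 3 genes
D     translocation of 2 genes within a chromosome
E     translocation of 3 genes within a chromosome
F     translocation of > 3 genes within a chromosome
iT    interstitial translocation between chromosomes
T     terminal translocation
Dup   duplication of a segment
Del   deletion of a segment
====  =====================================================

The classifier works on the relative order of orthologous genes (top
homology hits): it rank-normalises the permutation of shared genes per
chromosome, decomposes it into monotone strips, and iteratively undoes
the most parsimonious event (smallest displaced block first, outermost
before nested) until the permutation is the identity.  Inter-chromosomal
runs, duplicate-copy blocks, and missing runs are handled before the
permutation stage.  Branches are assigned by three-genome parsimony
against an outgroup, and rearrangement rates count only the major codes
C, F and iT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from subgenomics.annotation import GenomeAnnotation

MAJOR_CODES = ("C", "F", "iT")


@dataclass
class RearrangementEvent:
    """One classified rearrangement."""

    code: str
    genes: list[str]
    chromosomes: tuple[str, str]
    branch: str = "unassigned"
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.genes)
        sizes = {"A": (2, 2), "B": (3, 3), "C": (4, None), "D": (2, 2),
                 "E": (3, 3), "F": (4, None)}
        if self.code in sizes:
            lo, hi = sizes[self.code]
            if n < lo or (hi is not None and n > hi):
                raise ValueError(f"code {self.code} incompatible with {n} genes")
        if self.code in ("iT", "T") and self.chromosomes[0] == self.chromosomes[1]:
            raise ValueError(f"{self.code} requires distinct chromosomes")


@dataclass
class RateEstimate:
    branch: str
    major_event_count: int
    branch_time: float  # million years
    rate: float         # events / MY


# ---------------------------------------------------------------------------
# Hit-table plumbing
# ---------------------------------------------------------------------------

def _primary_secondary(hits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    h = hits.sort_values(["query", "bitscore", "target"],
                         ascending=[True, False, True], kind="mergesort")
    primary = h.groupby("query", sort=False).nth(0)
    secondary = h.groupby("query", sort=False).nth(1)
    return primary.set_index("query") if "query" in primary.columns else primary, \
        secondary.set_index("query") if "query" in secondary.columns else secondary


def _target_ranks(target_annot: GenomeAnnotation) -> pd.DataFrame:
    """gene_id -> (chromosome, global order rank on that chromosome)."""
    df = target_annot.genes[["gene_id", "chromosome", "start"]].copy()
    df["trank"] = df.groupby("chromosome")["start"].rank(method="first").astype(int) - 1
    return df.set_index("gene_id")[["chromosome", "trank"]]


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------

def _strips(pi: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of +/-1 steps: list of (start, end_exclusive, direction)."""
    n = len(pi)
    if n == 0:
        return []
    out = []
    s = 0
    d = 0
    for i in range(1, n):
        step = pi[i] - pi[i - 1]
        if step == d and d in (1, -1):
            continue
        if step in (1, -1) and d == 0:
            d = step
            continue
        out.append((s, i, d))
        s, d = i, 0
    out.append((s, n, d))
    return out


def _candidate_events(pi: np.ndarray) -> list[dict]:
    """All single-event explanations visible in the current permutation."""
    n = len(pi)
    cands = []
    for s, e, d in _strips(pi):
        size = e - s
        if size < 2:
            continue
        lo, hi = int(pi[s:e].min()), int(pi[s:e].max())
        before = int(pi[s - 1]) if s > 0 else -1
        after = int(pi[e]) if e < n else n
        if d == -1 and before < lo and hi < after:
            cands.append({"kind": "inversion", "s": s, "e": e, "size": size})
        elif d == 1 and not (before < lo and hi < after):
            # displaced ascending block: does it fit elsewhere?
            rest = np.concatenate([pi[:s], pi[e:]])
            fit = None
            if lo == 0 and len(rest) and rest[0] == hi + 1:
                fit = 0
            elif hi == n - 1 and len(rest) and rest[-1] == lo - 1:
                fit = len(rest)
            else:
                for t in range(1, len(rest)):
                    if rest[t - 1] == lo - 1 and rest[t] == hi + 1:
                        fit = t
                        break
            if fit is not None:
                cands.append({"kind": "move", "s": s, "e": e, "size": size,
                              "fit": fit})
    return cands


def _undo(pi: np.ndarray, ev: dict) -> np.ndarray:
    s, e = ev["s"], ev["e"]
    if ev["kind"] == "inversion":
        out = pi.copy()
        out[s:e] = out[s:e][::-1]
        return out
    block = pi[s:e]
    rest = np.concatenate([pi[:s], pi[e:]])
    t = ev["fit"]
    return np.concatenate([rest[:t], block, rest[t:]])


def _inversion_code(size: int) -> str:
    return {2: "A", 3: "B"}.get(size, "C")


def _move_code(size: int) -> str:
    return {2: "D", 3: "E"}.get(size, "F")


# ---------------------------------------------------------------------------
# Event classification
# ---------------------------------------------------------------------------

def classify_events(
    query_annot: GenomeAnnotation,
    target_annot: GenomeAnnotation,
    hits: pd.DataFrame,
    *,
    dup_score_frac: float = 0.8,
    min_ortholog_frac: float = 0.7,
    max_iterations: int = 200,
) -> list[RearrangementEvent]:
    """Classify order differences between two genomes into event codes.

    ``hits`` is a ranked homology table (columns query, target, bitscore).
    The top hit per query defines the orthologous placement; a secondary
    hit scoring at least ``dup_score_frac`` of the primary is treated as a
    recent duplicate copy.  A best hit below ``min_ortholog_frac`` of the
    genome-wide median best score is treated as non-orthologous (the
    typical signature of a gene whose true orthologue was lost and whose
    best hit fell back to an ancient paralogue).
    """
    primary, secondary = _primary_secondary(hits)
    tranks = _target_ranks(target_annot)
    events: list[RearrangementEvent] = []

    top_by_query = hits.groupby("query")["bitscore"].max()
    score_floor = min_ortholog_frac * float(top_by_query.median())

    # Global bookkeeping across all query chromosomes:
    # - covered: target genes receiving any near-top-score hit (used to
    #   recognise genuinely unmatched target runs as deletions);
    # - t_mult: how many query genes hit each target near top score (a
    #   multiplicity >= 2 marks a query-side duplicate copy).
    covered: set = set()
    t_strong: dict[str, int] = {}
    strong = hits[(hits["bitscore"] >=
                   dup_score_frac * hits["query"].map(top_by_query))
                  & (hits["bitscore"] >= score_floor)]
    for t, grp in strong.groupby("target"):
        covered.add(t)
        t_strong[t] = len(grp)
    t_mult = {t: n for t, n in t_strong.items() if n >= 2}

    for qchrom in query_annot.chromosomes:
        qgenes = query_annot.chromosome(qchrom)
        rows = []
        for g in qgenes["gene_id"]:
            if g in primary.index:
                t = primary.loc[g, "target"]
                score = float(primary.loc[g, "bitscore"])
                if t in tranks.index and score >= score_floor:
                    rows.append((g, t, tranks.loc[t, "chromosome"],
                                 int(tranks.loc[t, "trank"]), score))
                    continue
            rows.append((g, None, None, -1, 0.0))
        hit_rows = [r for r in rows if r[1] is not None]
        if not hit_rows:
            continue
        chrom_counts = pd.Series([r[2] for r in hit_rows]).value_counts()
        main = chrom_counts.index[0]

        events.extend(_missing_runs(qchrom, rows, main, target_annot,
                                    covered))
        dup_events, dup_excluded = _duplicate_runs(qchrom, hit_rows, t_mult)
        events.extend(dup_events)
        events.extend(_offmain_runs(qchrom, hit_rows, main, dup_excluded))
        events.extend(_secondary_dup_runs(
            qchrom, hit_rows, secondary, tranks, dup_score_frac))

        # Permutation stage on genes whose primary hit is on the main
        # target chromosome, excluding genes already explained above.
        seq = [(g, tr) for g, t, tc, tr, _sc in hit_rows
               if tc == main and g not in dup_excluded]
        if len(seq) < 2:
            continue
        gene_ids = [g for g, _ in seq]
        ranks = np.array([tr for _, tr in seq])
        pi = np.argsort(np.argsort(ranks, kind="stable"), kind="stable")
        order = np.arange(len(pi))
        for _ in range(max_iterations):
            if np.array_equal(pi, np.arange(len(pi))):
                break
            cands = _candidate_events(pi)
            if not cands:
                break
            ev = min(cands, key=lambda c: (c["size"], c["s"]))
            s, e = ev["s"], ev["e"]
            member_ids = [gene_ids[order[j]] for j in range(s, e)]
            if ev["kind"] == "inversion":
                code = _inversion_code(ev["size"])
            else:
                code = _move_code(ev["size"])
            events.append(RearrangementEvent(
                code=code, genes=member_ids, chromosomes=(qchrom, qchrom),
                details={"target_chromosome": main}))
            pi = _undo(pi, ev)
            if ev["kind"] == "inversion":
                order[s:e] = order[s:e][::-1]
            else:
                block = order[s:e].copy()
                rest = np.concatenate([order[:s], order[e:]])
                t = ev["fit"]
                order = np.concatenate([rest[:t], block, rest[t:]])
    return events


def _missing_runs(qchrom, rows, main, target_annot, covered):
    """Del candidates: query runs with no hit between target-adjacent anchors,
    and target runs lying between query-adjacent anchors."""
    events = []
    # Query-side runs missing from the target.
    i = 0
    n = len(rows)
    while i < n:
        if rows[i][1] is None:
            j = i
            while j < n and rows[j][1] is None:
                j += 1
            left = rows[i - 1] if i > 0 else None
            right = rows[j] if j < n else None
            if (left is not None and right is not None
                    and left[2] == main and right[2] == main
                    and abs(right[3] - left[3]) == 1):
                events.append(RearrangementEvent(
                    code="Del", genes=[r[0] for r in rows[i:j]],
                    chromosomes=(qchrom, qchrom),
                    details={"missing_in": "target"}))
            i = j
        else:
            i += 1
    # Target-side runs absent from the query: adjacent query anchors whose
    # targets are separated by unmatched annotated genes.
    tchrom_genes = None
    for a, b in zip(rows, rows[1:]):
        if a[1] is None or b[1] is None or a[2] != main or b[2] != main:
            continue
        lo, hi = sorted((a[3], b[3]))
        if hi - lo <= 1:
            continue
        if tchrom_genes is None:
            tchrom_genes = target_annot.chromosome(main)["gene_id"].tolist()
        between = tchrom_genes[lo + 1:hi]
        if between and not any(t in covered for t in between):
            events.append(RearrangementEvent(
                code="Del", genes=list(between), chromosomes=(main, main),
                details={"missing_in": "query"}))
    return events


def _duplicate_runs(qchrom, hit_rows, t_mult):
    """Query-side Dup candidates: runs of query genes whose targets are
    each also hit near top score by another query gene.

    The run that sits in its collinear context (flank targets adjacent) is
    the original; a displaced run is the extra copy and becomes a Dup
    event.  Copy-run genes are excluded from downstream stages.
    """
    events = []
    excluded: set = set()
    i, n = 0, len(hit_rows)
    while i < n:
        if hit_rows[i][1] not in t_mult:
            i += 1
            continue
        tc = hit_rows[i][2]
        j = i
        while j < n and hit_rows[j][1] in t_mult and hit_rows[j][2] == tc:
            j += 1
        run = hit_rows[i:j]
        prev_row = hit_rows[i - 1] if i > 0 else None
        next_row = hit_rows[j] if j < n else None
        i = j
        if len(run) < 2:
            continue
        rks = sorted(r[3] for r in run)
        if rks[-1] - rks[0] != len(run) - 1:
            continue
        in_context = False
        for nb, edge in ((prev_row, rks[0]), (next_row, rks[-1])):
            if nb is not None and nb[2] == tc and abs(nb[3] - edge) <= 2:
                in_context = True
        if not in_context:
            events.append(RearrangementEvent(
                code="Dup", genes=[r[0] for r in run],
                chromosomes=(qchrom, tc),
                details={"duplicate_side": "query"}))
            excluded.update(r[0] for r in run)
    return events, excluded


def _offmain_runs(qchrom, hit_rows, main, dup_excluded):
    """iT candidates: runs of primaries off the main target chromosome
    that form a contiguous block there."""
    events = []
    rows = [r for r in hit_rows if r[0] not in dup_excluded]
    i = 0
    n = len(rows)
    while i < n:
        tc = rows[i][2]
        if tc == main:
            i += 1
            continue
        j = i
        while j < n and rows[j][2] == tc:
            j += 1
        run = rows[i:j]
        i = j
        if len(run) < 2:
            continue
        rks = sorted(r[3] for r in run)
        if rks[-1] - rks[0] != len(run) - 1:
            continue
        events.append(RearrangementEvent(
            code="iT", genes=[r[0] for r in run],
            chromosomes=(qchrom, tc)))
    return events


def _secondary_dup_runs(qchrom, hit_rows, secondary, tranks, dup_score_frac):
    """Target-side Dup candidates: runs of strong secondary hits forming a
    contiguous block somewhere in the target."""
    events = []
    seq = []
    for g, t, tc, tr, score in hit_rows:
        sec = None
        if g in secondary.index:
            srow = secondary.loc[g]
            starget = srow["target"]
            if (float(srow["bitscore"]) >= dup_score_frac * score
                    and starget in tranks.index):
                sec = (tranks.loc[starget, "chromosome"],
                       int(tranks.loc[starget, "trank"]))
        seq.append((g, sec))
    i = 0
    n = len(seq)
    while i < n:
        if seq[i][1] is None:
            i += 1
            continue
        tc = seq[i][1][0]
        j = i
        while j < n and seq[j][1] is not None and seq[j][1][0] == tc:
            j += 1
        run = seq[i:j]
        i = j
        if len(run) < 2:
            continue
        rks = sorted(r[1][1] for r in run)
        if rks[-1] - rks[0] != len(run) - 1:
            continue
        events.append(RearrangementEvent(
            code="Dup", genes=[r[0] for r in run],
            chromosomes=(qchrom, tc),
            details={"duplicate_side": "target"}))
    return events


# ---------------------------------------------------------------------------
# Branch assignment by outgroup parsimony
# ---------------------------------------------------------------------------

def assign_branches(
    events: list[RearrangementEvent],
    query_annot: GenomeAnnotation,
    target_annot: GenomeAnnotation,
    outgroup_annot: GenomeAnnotation,
    hits_query_out: pd.DataFrame,
    hits_target_out: pd.DataFrame,
    hits_query_target: pd.DataFrame | None = None,
    *,
    query_branch: str = "R",
    target_branch: str = "M",
) -> list[RearrangementEvent]:
    """Assign each event to the query, target, or shared branch.

    The lineage whose local gene order (or gene content) differs from the
    outgroup is the derived one; a derived order shared by both lineages
    is assigned to the pre-divergence branch; missing outgroup
    information leaves the event unassigned.
    """
    p_q, _ = _primary_secondary(hits_query_out)
    p_t, _ = _primary_secondary(hits_target_out)
    p_qt = (_primary_secondary(hits_query_target)[0]
            if hits_query_target is not None else None)
    oranks = _target_ranks(outgroup_annot)
    tranks = _target_ranks(target_annot)
    qpos = query_annot.genes.set_index("gene_id")[["chromosome", "start"]]

    def out_of(gene: str, table: pd.DataFrame):
        if gene in table.index:
            t = table.loc[gene, "target"]
            if t in oranks.index:
                return (oranks.loc[t, "chromosome"], int(oranks.loc[t, "trank"]))
        return None

    out = []
    for ev in events:
        branch = "unassigned"
        if ev.code == "Del":
            missing_in = ev.details.get("missing_in")
            table = p_q if missing_in == "target" else p_t
            opos = [out_of(g, table) for g in ev.genes]
            if all(p is not None for p in opos):
                branch = target_branch if missing_in == "target" else query_branch
        elif ev.code == "Dup":
            side = ev.details.get("duplicate_side")
            if side == "target":
                branch = target_branch
            elif side == "query":
                branch = query_branch
        elif ev.code in ("iT", "T"):
            branch = _assign_translocation(
                ev, p_q, oranks, qpos, query_branch, target_branch)
        else:
            branch = _assign_order_event(
                ev, query_annot, p_q, oranks, p_qt, tranks,
                query_branch, target_branch)
        ev.branch = branch
        out.append(ev)
    return out


def _window_genes(ev: RearrangementEvent, query_annot: GenomeAnnotation):
    """Event genes plus one flanking gene on each side, in query order."""
    chrom = query_annot.chromosome(ev.chromosomes[0])
    ids = chrom["gene_id"].tolist()
    idx = [ids.index(g) for g in ev.genes if g in ids]
    if not idx:
        return []
    lo, hi = min(idx), max(idx)
    window = ids[max(0, lo - 1):hi + 2]
    return window


def _assign_order_event(ev, query_annot, p_q, oranks, p_qt, tranks,
                        query_branch, target_branch):
    """Order-signature comparison of query / target / outgroup windows."""
    window = _window_genes(ev, query_annot)
    if len(window) < 3:
        return "unassigned"
    sig_o = _window_signature(window, p_q, oranks)
    if sig_o is None:
        return "unassigned"
    sig_q = tuple(range(len(window)))
    if p_qt is not None:
        sig_t = _window_signature(window, p_qt, tranks)
    else:
        # Fall back on reconstructing the target arrangement from the
        # event kind (exact for inversions, unavailable for moves).
        n = len(window)
        sig_t = ((0,) + tuple(reversed(range(1, n - 1))) + (n - 1,)
                 if ev.code in ("A", "B", "C") else None)
    if sig_o == sig_q and sig_o != sig_t:
        return target_branch
    if sig_t is not None and sig_o == sig_t and sig_o != sig_q:
        return query_branch
    if sig_t is not None and sig_q == sig_t and sig_o not in (sig_q,):
        return "shared"
    return "unassigned"


def _window_signature(window, hit_table, ranks):
    pos = []
    for g in window:
        if g in hit_table.index:
            t = hit_table.loc[g, "target"]
            if t in ranks.index:
                pos.append((ranks.loc[t, "chromosome"], int(ranks.loc[t, "trank"])))
                continue
        pos.append(None)
    if any(p is None for p in pos) or len({c for c, _ in pos}) != 1:
        return None
    return _rank_signature([r for _, r in pos])


def _rank_signature(ranks):
    order = np.argsort(np.argsort(ranks, kind="stable"), kind="stable")
    return tuple(int(x) for x in order)


def _assign_translocation(ev, p_q, oranks, qpos, query_branch, target_branch):
    """iT branch: does the outgroup keep the run beside its query flanks?"""
    genes = ev.genes
    opos = []
    for g in genes:
        if g in p_q.index:
            t = p_q.loc[g, "target"]
            if t in oranks.index:
                opos.append(oranks.loc[t, "chromosome"])
                continue
        opos.append(None)
    if any(p is None for p in opos):
        return "unassigned"
    # Outgroup chromosome of the query chromosome context: majority vote of
    # hits from genes flanking the run on the query chromosome.
    qchrom = ev.chromosomes[0]
    flank_chroms = []
    for g in p_q.index:
        if g in qpos.index and qpos.loc[g, "chromosome"] == qchrom and g not in genes:
            t = p_q.loc[g, "target"]
            if t in oranks.index:
                flank_chroms.append(oranks.loc[t, "chromosome"])
    if not flank_chroms:
        return "unassigned"
    context = pd.Series(flank_chroms).mode().iloc[0]
    run_chrom = pd.Series(opos).mode().iloc[0]
    if run_chrom == context:
        # outgroup keeps the run in its ancestral chromosome = query state
        return target_branch
    return query_branch


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def rearrangement_rate(
    events: list[RearrangementEvent],
    branch_times: dict[str, float],
) -> list[RateEstimate]:
    """Events per million years per branch, counting only C, F and iT."""
    out = []
    for branch, time_my in branch_times.items():
        if time_my <= 0:
            raise ValueError(f"branch time must be positive, got {time_my}")
        n = sum(1 for e in events if e.branch == branch and e.code in MAJOR_CODES)
        out.append(RateEstimate(branch=branch, major_event_count=n,
                                branch_time=time_my, rate=n / time_my))
    return out


def events_table(events: list[RearrangementEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"code": e.code, "branch": e.branch,
          "source_chromosome": e.chromosomes[0],
          "destination_chromosome": e.chromosomes[1],
          "n_genes": len(e.genes), "genes": ",".join(e.genes)}
         for e in events],
        columns=["code", "branch", "source_chromosome",
                 "destination_chromosome", "n_genes", "genes"],
    )
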