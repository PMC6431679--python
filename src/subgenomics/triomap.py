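"""Simplified optical-map trio analysis.

A label map is the ordered list of nicking-endonuclease recognition-site
positions along a DNA molecule plus its total length.  This module
provides in-silico digestion, a transparent dynamic-programming aligner
over inter-label interval chains (allowing missed/extra labels and
relative sizing error), detection of phased (diploid) regions by map
self-comparison, the haplotype-edited additivity check of a
parent/parent/hybrid trio, and allocation of hybrid scaffolds to
parental genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class LabelMap:
    """Ordered label positions (bp) on one map/molecule."""

    map_id: str
    length: int
    labels: np.ndarray
    channel: str = "BspQI"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        if self.labels.size and (np.diff(self.labels) <= 0).any():
            raise ValueError(f"{self.map_id}: labels must be strictly increasing")
        if self.labels.size and (
                self.labels[0] <= 0 or self.labels[-1] >= self.length):
            raise ValueError(f"{self.map_id}: labels must lie inside (0, length)")

    @property
    def n_labels(self) -> int:
        return int(self.labels.size)

    def intervals(self) -> np.ndarray:
        return np.diff(self.labels)

    def reversed(self) -> "LabelMap":
        return LabelMap(self.map_id + "_rev", self.length,
                        np.sort(self.length - self.labels), self.channel)

    def slice(self, start: float, end: float, map_id: str | None = None) -> "LabelMap":
        """Sub-map over [start, end], positions rebased to the slice."""
        mask = (self.labels > start) & (self.labels < end)
        return LabelMap(map_id or f"{self.map_id}[{int(start)}-{int(end)}]",
                        int(end - start), self.labels[mask] - start, self.channel)


@dataclass
class MapAlignment:
    query_id: str
    reference_id: str
    score: float
    orientation: str                      # "+" or "-"
    matched_pairs: list[tuple[int, int]]  # (query label idx, ref label idx)
    unmatched_query: int
    unmatched_reference: int
    offset_bp: float                      # reference coordinate of first match
    aligned: bool = True


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

def digest_in_silico(sequence: str, site: str, map_id: str = "digest",
                     channel: str | None = None) -> LabelMap:
    """Label positions at every occurrence of ``site`` on either strand.

    Positions are the 1-based start of the recognition-site match.
    """
    if not sequence or not site:
        raise ValueError("sequence and site must be non-empty")
    site = site.upper()
    if set(site) - set("ACGT"):
        raise ValueError(f"ambiguous bases in recognition site: {site}")
    seq = sequence.upper()
    rc = site.translate(_COMPLEMENT)[::-1]
    positions: set[int] = set()
    for probe in {site, rc}:
        start = seq.find(probe)
        while start != -1:
            positions.add(start + 1)
            start = seq.find(probe, start + 1)
    labels = np.array(sorted(p for p in positions if p < len(seq)), dtype=float)
    return LabelMap(map_id, len(seq), labels, channel or site)


# ---------------------------------------------------------------------------
# Dynamic-programming alignment
# ---------------------------------------------------------------------------

_MAX_SKIP = 3  # labels merged per DP move on either map


def _dp_fit(q_int: np.ndarray, r_int: np.ndarray, sizing_tolerance: float,
            miss_penalty: float, match_reward: float,
            traceback: bool) -> tuple[float, int, list | None]:
    """Fitting alignment of query intervals into reference intervals.

    Every query interval chain must be consumed; the reference end gaps
    are free.  Returns (best score, best end reference index, pairs).
    """
    m, n = len(q_int), len(r_int)
    NEG = -1e18
    S = np.full((m + 1, n + 1), NEG)
    S[0, :] = 0.0
    Q = np.concatenate([[0.0], np.cumsum(q_int)])
    R = np.concatenate([[0.0], np.cumsum(r_int)])
    bp = np.zeros((m + 1, n + 1), dtype=np.int8) if traceback else None
    for i in range(1, m + 1):
        best = np.full(n + 1, NEG)
        choice = np.zeros(n + 1, dtype=np.int8)
        for di in range(1, min(_MAX_SKIP, i) + 1):
            qs = Q[i] - Q[i - di]
            for dj in range(1, _MAX_SKIP + 1):
                if dj > n:
                    break
                rs = R[dj:] - R[:-dj]          # length n-dj+1, for j=dj..n
                rel = np.abs(qs - rs) / np.maximum(np.maximum(qs, rs), 1.0)
                sc = match_reward * (1.0 - rel / sizing_tolerance)
                np.clip(sc, -2.0 * match_reward, None, out=sc)
                cand = S[i - di, :n - dj + 1] + sc \
                    - miss_penalty * ((di - 1) + (dj - 1))
                upd = cand > best[dj:]
                if upd.any():
                    best[dj:][upd] = cand[upd]
                    choice[dj:][upd] = (di - 1) * _MAX_SKIP + (dj - 1) + 1
        S[i] = best
        if traceback:
            bp[i] = choice
    j_best = int(np.argmax(S[m]))
    score = float(S[m, j_best])
    pairs = None
    if traceback and score > NEG / 2:
        pairs = []
        i, j = m, j_best
        while i > 0 and bp[i, j]:
            code = int(bp[i, j]) - 1
            di, dj = code // _MAX_SKIP + 1, code % _MAX_SKIP + 1
            pairs.append((i, j))
            i, j = i - di, j - dj
        pairs.append((i, j))
        pairs.reverse()
    return score, j_best, pairs


def align_label_maps(
    query: LabelMap,
    reference: LabelMap,
    sizing_tolerance: float = 0.1,
    miss_penalty: float = 3.0,
    match_reward: float = 3.0,
    *,
    min_labels: int = 5,
    traceback: bool = True,
) -> MapAlignment:
    """Best fitting alignment of a query map inside a reference map.

    Both orientations are tried; scoring rewards interval chains whose
    lengths agree within ``sizing_tolerance`` (relative) and penalises
    merged (missed) labels on either map.  Queries with fewer than
    ``min_labels`` labels are flagged unalignable.
    """
    if query.n_labels < min_labels or reference.n_labels < 2:
        return MapAlignment(query.map_id, reference.map_id, float("-inf"),
                            "+", [], query.n_labels, reference.n_labels,
                            0.0, aligned=False)
    best = None
    for orient, q in (("+", query), ("-", query.reversed())):
        score, j_end, pairs = _dp_fit(
            q.intervals(), reference.intervals(), sizing_tolerance,
            miss_penalty, match_reward, traceback)
        if best is None or score > best[0]:
            best = (score, orient, pairs, j_end)
    score, orient, pairs, j_end = best
    matched = [(qi, rj) for qi, rj in (pairs or [])]
    offset = float(reference.labels[matched[0][1]]) if matched else 0.0
    return MapAlignment(
        query.map_id, reference.map_id, score, orient, matched,
        unmatched_query=query.n_labels - len(matched),
        unmatched_reference=reference.n_labels - len(matched),
        offset_bp=offset, aligned=True,
    )


def alignment_significance(
    query: LabelMap,
    reference: LabelMap,
    observed_score: float,
    rng: np.random.Generator,
    n_permutations: int = 200,
    **align_kwargs,
) -> float:
    """Permutation p-value of an alignment score.

    Query inter-label intervals are shuffled; the null distribution is
    the best fitting-alignment score of each shuffled map.
    """
    if query.n_labels < 2:
        return 1.0
    exceed = 0
    intervals = query.intervals()
    lead = float(query.labels[0])
    for _ in range(n_permutations):
        perm = rng.permutation(intervals)
        labels = lead + np.concatenate([[0.0], np.cumsum(perm)])
        shuffled = LabelMap("perm", query.length, labels, query.channel)
        aln = align_label_maps(shuffled, reference, traceback=False,
                               **align_kwargs)
        if aln.score >= observed_score:
            exceed += 1
    return (1 + exceed) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# Phased (diploid) regions
# ---------------------------------------------------------------------------

def detect_phased_regions(
    maps: list[LabelMap],
    sizing_tolerance: float = 0.1,
    *,
    min_labels: int = 5,
    min_matched_fraction: float = 0.6,
) -> list[dict]:
    """Diploid regions: intervals of a map covered by a near-identical
    second map in the same set (excluding identity).

    Returns records with the covered map, interval, and partner map.
    """
    out = []
    for alt in maps:
        for main in maps:
            if alt.map_id == main.map_id or alt.n_labels < min_labels:
                continue
            if alt.n_labels > main.n_labels or alt.length > main.length:
                continue
            aln = align_label_maps(alt, main, sizing_tolerance=sizing_tolerance,
                                   min_labels=min_labels)
            if not aln.aligned or not aln.matched_pairs:
                continue
            frac = len(aln.matched_pairs) / (alt.n_labels)
            if aln.score <= 0 or frac < min_matched_fraction:
                continue
            ref_idx = [rj for _, rj in aln.matched_pairs]
            start = float(main.labels[min(ref_idx)] - alt.labels[0])
            end = float(main.labels[max(ref_idx)]
                        + (alt.length - alt.labels[-1]))
            out.append({"map_id": main.map_id,
                        "start": max(0.0, start),
                        "end": min(float(main.length), end),
                        "partner": alt.map_id,
                        "score": aln.score})
    return out


# ---------------------------------------------------------------------------
# Additivity and allocation
# ---------------------------------------------------------------------------

@dataclass
class AdditivityReport:
    hybrid_length: float
    edited_parent_sum: float
    difference: float
    difference_percent: float
    removed_maps: list[str] = field(default_factory=list)
    unresolved: list[str] = field(default_factory=list)


def _best_score(query: LabelMap, references: list[LabelMap], **kw) -> float:
    best = float("-inf")
    for ref in references:
        aln = align_label_maps(query, ref, traceback=False, **kw)
        best = max(best, aln.score)
    return best


def additivity_check(
    hybrid_maps: list[LabelMap],
    parent_maps: dict[str, list[LabelMap]],
    phased: dict[str, list[dict]],
    sizing_tolerance: float = 0.1,
) -> AdditivityReport:
    """Haplotype-edited length additivity of the trio.

    For each phased region the haplotype absent from the hybrid (decided
    by alignment score against the hybrid maps) is disregarded; the
    edited parental length sum is then compared with the hybrid map
    length.
    """
    hybrid_length = float(sum(m.length for m in hybrid_maps))
    parent_sum = float(
        sum(m.length for maps in parent_maps.values() for m in maps))
    removed = 0.0
    removed_ids: list[str] = []
    unresolved: list[str] = []
    for parent, regions in phased.items():
        maps_by_id = {m.map_id: m for m in parent_maps[parent]}
        for reg in regions:
            main = maps_by_id[reg["map_id"]]
            alt = maps_by_id[reg["partner"]]
            hap1 = main.slice(reg["start"], reg["end"], "hap1_segment")
            s1 = _best_score(hap1, hybrid_maps, sizing_tolerance=sizing_tolerance)
            s2 = _best_score(alt, hybrid_maps, sizing_tolerance=sizing_tolerance)
            if s1 == s2:
                unresolved.append(alt.map_id)
            if s1 >= s2:
                removed += float(alt.length)
                removed_ids.append(alt.map_id)
            else:
                removed += float(reg["end"] - reg["start"])
                removed_ids.append(f"{main.map_id}[{reg['start']:.0f}-{reg['end']:.0f}]")
    edited = parent_sum - removed
    diff = abs(hybrid_length - edited)
    return AdditivityReport(
        hybrid_length=hybrid_length, edited_parent_sum=edited,
        difference=diff,
        difference_percent=100.0 * diff / hybrid_length if hybrid_length else 0.0,
        removed_maps=removed_ids, unresolved=unresolved,
    )


def allocate_scaffolds(
    scaffolds: list[LabelMap],
    parent_maps: dict[str, list[LabelMap]],
    sizing_tolerance: float = 0.1,
    *,
    min_labels: int = 5,
    margin: float = 1.05,
) -> pd.DataFrame:
    """Assign each scaffold digest to the better-aligning parent.

    Scaffolds with too few labels are flagged unalignable; near-equal
    scores (within ``margin``) are flagged ambiguous.
    """
    parents = sorted(parent_maps)
    rows = []
    for sc in scaffolds:
        scores = {}
        for p in parents:
            scores[p] = _best_score(sc, parent_maps[p],
                                    sizing_tolerance=sizing_tolerance,
                                    min_labels=min_labels)
        ranked = sorted(parents, key=lambda p: scores[p], reverse=True)
        best, second = ranked[0], ranked[1] if len(ranked) > 1 else None
        if sc.n_labels < min_labels or not np.isfinite(scores[best]):
            status, assigned = "unalignable", None
        elif second is not None and np.isfinite(scores[second]) and \
                scores[second] > 0 and scores[best] <= margin * scores[second]:
            status, assigned = "ambiguous", None
        elif scores[best] <= 0:
            status, assigned = "unalignable", None
        else:
            status, assigned = "assigned", best
        rows.append({"scaffold": sc.map_id, "assigned_parent": assigned,
                     "status": status,
                     **{f"score_{p}": scores[p] for p in parents}})
    return pd.DataFrame(rows)
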