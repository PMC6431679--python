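"""Synthetic chromosome landmarks: telomeric arrays, centromere clusters.

Terminus sequences follow the tripartite structure observed in
chromosome-scale tree-genome assemblies: a perfect telomeric CCCTAAA
array (about 8 kb), a heterochromatic subtelomere of microsatellite and
TE-like sequence (about 10 kb), then the first genes.  Centromeres carry
a dense cluster of a 12.5-kb Gypsy-type retroelement, plus a few
scattered copies elsewhere on the chromosome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from subgenomics.annotation import GenomeAnnotation
from subgenomics.landmarks import TELOMERE_MOTIF, _revcomp

CEN_ELEMENT = "CRT"        # centromeric retrotransposon label
CEN_ELEMENT_BP = 12_500
_SAT_MOTIFS = ["AT", "AAG", "AGGA", "ATCC"]


def _random_subtelomere(length: int, rng: np.random.Generator) -> str:
    """Microsatellite stretches interspersed with random (TE-like) runs."""
    parts: list[str] = []
    total = 0
    while total < length:
        if rng.random() < 0.5:
            motif = _SAT_MOTIFS[int(rng.integers(len(_SAT_MOTIFS)))]
            rep = int(rng.integers(10, 60))
            chunk = motif * rep
        else:
            chunk = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(200, 800))))
        parts.append(chunk)
        total += len(chunk)
    seq = "".join(parts)[:length]
    # never start with a telomere-motif prefix: keep the array boundary sharp
    if seq.startswith(TELOMERE_MOTIF[0]):
        seq = "G" + seq[1:]
    return seq


def simulate_landmarks(
    genome: GenomeAnnotation,
    telomere_bp: int = 8_001,
    centromere_copies: int = 62,
    rng: np.random.Generator | None = None,
    *,
    terminus_bp: int = 25_000,
    centromere_span_bp: int = 3_000_000,
    scattered_copies: int = 4,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Terminus sequences and a repeat annotation for every chromosome.

    Returns ``(sequences, repeats, truth)``: terminus FASTA-ready
    sequences named ``<chrom>_5prime`` / ``<chrom>_3prime`` (the 3'
    sequence ends in reverse-complement telomeric repeats), repeat-
    element instances, and a truth table of telomere spans and cluster
    intervals.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    n_copies = telomere_bp // len(TELOMERE_MOTIF)
    tel_span = n_copies * len(TELOMERE_MOTIF)
    if tel_span <= 0:
        raise ValueError("telomere_bp shorter than one motif copy")
    if tel_span >= terminus_bp:
        raise ValueError("telomeric array exceeds the terminus region")

    sequences: dict[str, str] = {}
    repeat_rows = []
    truth_rows = []
    for chrom in genome.chromosomes:
        cgenes = genome.chromosome(chrom)
        chrom_len = int(cgenes["end"].max()) + terminus_bp
        array = TELOMERE_MOTIF * n_copies
        five = array + _random_subtelomere(terminus_bp - tel_span, rng)
        three = _revcomp(array + _random_subtelomere(terminus_bp - tel_span, rng))
        sequences[f"{chrom}_5prime"] = five
        sequences[f"{chrom}_3prime"] = three
        truth_rows.append({"chromosome": chrom, "feature": "telomere",
                           "start": 1, "end": tel_span, "n_copies": n_copies})

        center = int(cgenes["start"].iloc[len(cgenes) // 2])
        margin = 600_000
        if chrom_len < centromere_span_bp + 2 * (margin + terminus_bp):
            raise ValueError(
                f"{chrom}: chromosome ({chrom_len} bp) too short for a "
                f"{centromere_span_bp} bp centromeric span; simulate more "
                "genes per chromosome or shrink centromere_span_bp")
        span_start = max(terminus_bp + margin, center - centromere_span_bp // 2)
        slack = centromere_span_bp - centromere_copies * CEN_ELEMENT_BP
        if slack <= 0:
            raise ValueError("centromere copies do not fit in the span")
        gaps = rng.multinomial(slack, np.full(centromere_copies + 1,
                                              1.0 / (centromere_copies + 1)))
        pos = span_start
        first = last = None
        for c in range(centromere_copies):
            pos += int(gaps[c])
            repeat_rows.append({"chromosome": chrom, "start": pos,
                                "end": pos + CEN_ELEMENT_BP - 1,
                                "element_id": CEN_ELEMENT})
            first = pos if first is None else first
            last = pos + CEN_ELEMENT_BP - 1
            pos += CEN_ELEMENT_BP
        truth_rows.append({"chromosome": chrom, "feature": "centromere",
                           "start": first, "end": last,
                           "n_copies": centromere_copies})
        # scattered copies well away from the cluster
        for _ in range(scattered_copies):
            for _try in range(1000):
                p = int(rng.integers(terminus_bp, chrom_len - CEN_ELEMENT_BP))
                if p + CEN_ELEMENT_BP < span_start - 500_000 or \
                        p > span_start + centromere_span_bp + 500_000:
                    break
            else:  # pragma: no cover - guarded by the length validation
                raise ValueError(f"{chrom}: no room for scattered copies")
            repeat_rows.append({"chromosome": chrom, "start": p,
                                "end": p + CEN_ELEMENT_BP - 1,
                                "element_id": CEN_ELEMENT})
    repeats = pd.DataFrame(
        repeat_rows, columns=["chromosome", "start", "end", "element_id"])
    truth = pd.DataFrame(truth_rows)
    return sequences, repeats, truth


def simulate_centromere_pair(
    scenario: str,
    rng: np.random.Generator,
    *,
    n_anchors: int = 30,
    spacing_bp: int = 1_000_000,
    cluster_bp: int = 750_000,
) -> dict:
    """One homoeologous chromosome pair with a known centromere fate.

    ``scenario`` is ``conserved``, ``translocated`` or
    ``inversion-split``; returns anchors (anchor_id, pos_a, pos_b), the
    A-side cluster interval, the B-side cluster interval list, and the
    truth label.
    """
    if scenario not in ("conserved", "translocated", "inversion-split"):
        raise ValueError(f"unknown scenario: {scenario}")
    jitter = lambda: rng.normal(0, spacing_bp * 0.05)
    pos_a = np.array([
        (i + 1) * spacing_bp + jitter() for i in range(n_anchors)
    ]).astype(int)
    ids = [f"anc{i:02d}" for i in range(n_anchors)]

    i_cluster = int(rng.integers(n_anchors // 3, 2 * n_anchors // 3))
    mid_a = (pos_a[i_cluster] + pos_a[i_cluster + 1]) // 2
    cluster_a = (int(mid_a - cluster_bp // 2), int(mid_a + cluster_bp // 2))

    order_b = list(range(n_anchors))
    clusters_b: list[tuple[int, int]] = []
    if scenario == "conserved":
        insert_after = {i_cluster: [cluster_bp]}
    elif scenario == "translocated":
        choices = [j for j in range(2, n_anchors - 2)
                   if abs(j - i_cluster) > 3]
        j = int(rng.integers(0, len(choices)))
        insert_after = {choices[j]: [cluster_bp]}
    else:
        # inversion with one breakpoint inside the A-side array position:
        # the segment [i_cluster+1 .. j_end] is inverted on B; half the
        # array stays at the proximal breakpoint, half moves with the
        # inversion (or, half the time, the whole array moves: a break
        # at the array's edge).
        j_end = min(n_anchors - 3, i_cluster + int(rng.integers(4, 8)))
        order_b = (order_b[:i_cluster + 1]
                   + list(reversed(order_b[i_cluster + 1:j_end + 1]))
                   + order_b[j_end + 1:])
        # in B order the reversed block runs j_end .. i_cluster+1, so the
        # distal breakpoint follows anchor i_cluster+1
        if rng.random() < 0.5:
            insert_after = {i_cluster: [cluster_bp // 2],
                            i_cluster + 1: [cluster_bp // 2]}
        else:
            insert_after = {i_cluster + 1: [cluster_bp]}

    # Lay out B coordinates walking the B anchor order; record clusters
    # where requested (keyed by the *preceding A-index* in B order).
    pos_b = np.zeros(n_anchors, dtype=int)
    cursor = spacing_bp
    for rank, a_idx in enumerate(order_b):
        pos_b[a_idx] = int(cursor + jitter())
        for width in insert_after.get(a_idx, []):
            cs = cursor + spacing_bp // 2
            clusters_b.append((int(cs), int(cs + width)))
            cursor += width
        cursor += spacing_bp
    anchors = pd.DataFrame({"anchor_id": ids, "pos_a": pos_a, "pos_b": pos_b})
    return {"anchors": anchors, "cluster_a": cluster_a,
            "clusters_b": clusters_b, "truth": scenario}
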