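"""Synthetic homology-hit tables for the simulated genomes.

Scores mimic protein bitscores under the simulated divergence structure:
orthologues (species split, recent) score highest, recent duplicate
copies slightly lower, WGD paralogues much lower, and hits into the
pre-WGD outgroup lower still.  Scores are drawn with Gaussian noise so
rank-based selection has realistic ties and near-ties.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from subgenomics.annotation import GenomeAnnotation
from subgenomics.simdata.params import EvolutionParams

_GENE_RE = re.compile(r"^([A-Z])(\d+)([DS]?)g(\d+)(?:d(\d+))?$")

SCORE_ORTHOLOG = 1400.0
SCORE_DUPLICATE = 1250.0
SCORE_PARALOG = 800.0
SCORE_OUTGROUP = 600.0
SCORE_SD = 25.0


def _parse(gene_id: str) -> tuple[int, str, int, int]:
    m = _GENE_RE.match(gene_id)
    if not m:
        raise ValueError(f"unparseable simulated gene id: {gene_id}")
    _sp, group, sub, anc, tag = m.groups()
    return int(group), sub, int(anc), int(tag) if tag else 0


def _index_by_key(annot: GenomeAnnotation) -> dict[tuple, list[str]]:
    """(group, subgenome, anc) -> gene ids (originals first)."""
    out: dict[tuple, list[str]] = {}
    for gid in annot.genes["gene_id"]:
        group, sub, anc, tag = _parse(gid)
        out.setdefault((group, sub, anc), []).append(gid)
    for v in out.values():
        v.sort(key=lambda g: _parse(g)[3])  # dup copies after originals
    return out


def make_cross_species_hits(
    query_annot: GenomeAnnotation,
    target_annot: GenomeAnnotation,
    rng: np.random.Generator,
    *,
    include_paralog_hits: bool = True,
) -> pd.DataFrame:
    """Hit table from one simulated species against the other.

    Per query gene: its surviving orthologue (same WGD copy), any recent
    duplicate copies of that orthologue, and optionally the orthologue's
    WGD paralogue on the homoeologous chromosome.
    """
    tindex = _index_by_key(target_annot)
    rows = []
    for gid in query_annot.genes["gene_id"]:
        group, sub, anc, tag = _parse(gid)
        mates = tindex.get((group, sub, anc), [])
        for t in mates:
            _, _, _, ttag = _parse(t)
            base = SCORE_ORTHOLOG if ttag == 0 else SCORE_DUPLICATE
            # a query duplicate copy diverged from every target copy
            if tag != 0:
                base = SCORE_DUPLICATE
            rows.append((gid, t, base + rng.normal(0.0, SCORE_SD)))
        if include_paralog_hits:
            other = "S" if sub == "D" else "D"
            for t in tindex.get((group, other, anc), []):
                rows.append((gid, t, SCORE_PARALOG + rng.normal(0.0, SCORE_SD)))
    df = pd.DataFrame(rows, columns=["query", "target", "bitscore"])
    return df.sort_values(["query", "bitscore"],
                          ascending=[True, False], kind="mergesort").reset_index(drop=True)


def make_paralogue_hits(
    annot: GenomeAnnotation,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Within-genome homoeologue (WGD paralogue) hit table, both directions,
    self-hits excluded."""
    index = _index_by_key(annot)
    rows = []
    for gid in annot.genes["gene_id"]:
        group, sub, anc, _tag = _parse(gid)
        other = "S" if sub == "D" else "D"
        for t in index.get((group, other, anc), []):
            rows.append((gid, t, SCORE_PARALOG + rng.normal(0.0, SCORE_SD)))
    df = pd.DataFrame(rows, columns=["query", "target", "bitscore"])
    return df.sort_values(["query", "bitscore"],
                          ascending=[True, False], kind="mergesort").reset_index(drop=True)


def make_outgroup(params: EvolutionParams) -> GenomeAnnotation:
    """Pre-WGD outgroup genome retaining the ancestral gene order.

    One copy per ancestral gene, one chromosome per ancestral chromosome;
    deterministic given the params seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xA11CE]))
    rows = []
    for k in range(1, params.n_chromosome_pairs + 1):
        gaps = rng.exponential(
            max(params.mean_intergenic_bp - params.gene_length_bp, 1.0),
            params.genes_per_chromosome,
        ) + params.gene_length_bp
        starts = 25_001 + np.concatenate([[0.0], np.cumsum(gaps[:-1])])
        for a, s in enumerate(starts.astype(np.int64)):
            rows.append({
                "gene_id": f"O{k}g{a:04d}", "chromosome": f"O{k}",
                "start": int(s), "end": int(s) + params.gene_length_bp - 1,
                "strand": "+", "species": "O", "homoeo_group": k,
                "subgenome": "", "gene_class": "gene",
                "anc_id": k * 100_000 + a,
            })
    return GenomeAnnotation(pd.DataFrame(rows))


def make_outgroup_hits(
    annot: GenomeAnnotation,
    outgroup: GenomeAnnotation,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Hits of a descendant genome against the pre-WGD outgroup.

    Both WGD copies of an ancestral gene hit the single outgroup copy.
    """
    oindex = {}
    for gid in outgroup.genes["gene_id"]:
        m = re.match(r"^O(\d+)g(\d+)$", gid)
        oindex[(int(m.group(1)), int(m.group(2)))] = gid
    rows = []
    for gid in annot.genes["gene_id"]:
        group, _sub, anc, _tag = _parse(gid)
        t = oindex.get((group, anc))
        if t is not None:
            rows.append((gid, t, SCORE_OUTGROUP + rng.normal(0.0, SCORE_SD)))
    df = pd.DataFrame(rows, columns=["query", "target", "bitscore"])
    return df.sort_values(["query", "bitscore"],
                          ascending=[True, False], kind="mergesort").reset_index(drop=True)
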