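"""Synthetic nicking-site label maps for a parent/parent/hybrid trio.

Nicking sites descend from a shared ancestral Poisson process with
per-species site turnover, so orthologous chromosomes of the two
parents have similar but not identical maps.  Each parent map is mostly
'haploid' (haplotypes collapsed) with a configurable fraction of
'diploid' (phased) regions where a second, diverged haplotype assembles
separately.  The hybrid inherits haplotype 1 of each parental
chromosome.  All maps carry per-interval relative sizing noise, and
hybrid chromosomes are additionally chopped into scaffold digests with
a known parent of origin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from subgenomics.annotation import GenomeAnnotation
from subgenomics.simdata.params import EvolutionParams
from subgenomics.triomap import LabelMap

_TERMINUS_BP = 25_000


def _measure(map_id: str, length: float, sites: np.ndarray, sd: float,
             rng: np.random.Generator) -> LabelMap:
    """Apply relative per-interval sizing noise to true site positions."""
    sites = np.asarray(sites, dtype=float)
    bounds = np.concatenate([[0.0], sites, [float(length)]])
    intervals = np.diff(bounds)
    if sd > 0:
        intervals = intervals * np.clip(rng.normal(1.0, sd, intervals.size),
                                        0.5, 1.5)
    positions = np.cumsum(intervals)
    measured_length = positions[-1]
    labels = positions[:-1]
    labels = labels[(labels > 0) & (labels < measured_length)]
    return LabelMap(map_id, int(round(measured_length)), labels)


def _species_sites(anc_rel: np.ndarray, length: float, turnover: float,
                   rate: float, rng: np.random.Generator) -> np.ndarray:
    keep = rng.random(anc_rel.size) >= turnover / 2.0
    sites = anc_rel[keep] * length
    n_new = rng.poisson(rate * length * turnover / 2.0)
    sites = np.concatenate([sites, rng.uniform(0, length, n_new)])
    sites = np.unique(np.round(np.sort(sites)))
    return sites[(sites > 0) & (sites < length)]


def simulate_label_maps(
    genome_r: GenomeAnnotation,
    genome_m: GenomeAnnotation,
    params: EvolutionParams,
    rng: np.random.Generator | None = None,
    *,
    scaffold_labels: int = 25,
    haplotype_divergence: float = 0.10,
) -> tuple[list[LabelMap], list[LabelMap], list[LabelMap],
           list[LabelMap], pd.DataFrame, list[dict]]:
    """Label maps of both parents, the hybrid, and hybrid scaffold digests.

    Returns ``(maps_r, maps_m, maps_hybrid, scaffolds, truth_allocation,
    phased_truth)``; the truth table records each scaffold's parent and
    chromosome, and ``phased_truth`` the simulated diploid intervals.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([params.seed, 0x10AB])) if rng is None else rng
    rate = params.label_density / 100_000.0
    sd = params.sizing_error_sd

    genomes = {"R": genome_r, "M": genome_m}
    lengths = {
        sp: {c: float(g.chromosome(c)["end"].max() + _TERMINUS_BP)
             for c in g.chromosomes}
        for sp, g in genomes.items()
    }
    # chromosomes correspond across species through (group, subgenome)
    def chrom_key(name: str) -> str:
        return name[1:]

    keys = sorted({chrom_key(c) for c in lengths["R"]} &
                  {chrom_key(c) for c in lengths["M"]})
    parent_maps: dict[str, list[LabelMap]] = {"R": [], "M": []}
    hybrid_maps: list[LabelMap] = []
    scaffolds: list[LabelMap] = []
    alloc_rows = []
    phased_truth: list[dict] = []

    for key in keys:
        mean_len = np.mean([lengths[sp]["R" + key if sp == "R" else "M" + key]
                            for sp in ("R", "M")])
        n_anc = rng.poisson(rate * mean_len)
        anc_rel = np.sort(rng.uniform(0, 1, n_anc))
        for sp in ("R", "M"):
            chrom = sp + key
            L = lengths[sp][chrom]
            sites = _species_sites(anc_rel, L, params.label_site_turnover,
                                   rate, rng)
            main_id = f"{sp}_{chrom}_h1"
            parent_maps[sp].append(_measure(main_id, L, sites, sd, rng))
            # phased (diploid) region: a second haplotype assembles apart
            if params.phased_fraction > 0:
                span = params.phased_fraction * L
                start = float(rng.uniform(0.1 * L, 0.9 * L - span))
                end = start + span
                h2 = sites[(sites > start) & (sites < end)] - start
                keep = rng.random(h2.size) >= haplotype_divergence / 2.0
                h2 = h2[keep]
                n_new = rng.poisson(rate * span * haplotype_divergence / 2.0)
                h2 = np.unique(np.sort(np.concatenate(
                    [h2, rng.uniform(0, span, n_new)])))
                h2 = h2[(h2 > 0) & (h2 < span)]
                parent_maps[sp].append(
                    _measure(f"{sp}_{chrom}_h2", span, h2, sd, rng))
                phased_truth.append({"parent": sp, "map_id": main_id,
                                     "start": start, "end": end,
                                     "partner": f"{sp}_{chrom}_h2"})
            # hybrid inherits haplotype 1, measured independently
            hybrid_maps.append(_measure(f"H_{chrom}", L, sites, sd, rng))
            # scaffold digests of the hybrid chromosome
            n_sc = max(1, sites.size // scaffold_labels)
            cut_idx = np.linspace(0, sites.size, n_sc + 1).astype(int)
            for k in range(n_sc):
                lo_i, hi_i = cut_idx[k], cut_idx[k + 1]
                if hi_i - lo_i < 2:
                    continue
                lo = 0.0 if k == 0 else (sites[lo_i - 1] + sites[lo_i]) / 2.0
                hi = L if k == n_sc - 1 else (sites[hi_i - 1] + sites[hi_i]) / 2.0
                sc_sites = sites[lo_i:hi_i] - lo
                sc_id = f"scf_{chrom}_{k:03d}"
                scaffolds.append(_measure(sc_id, hi - lo, sc_sites, sd, rng))
                alloc_rows.append({"scaffold": sc_id, "parent": sp,
                                   "chromosome": chrom,
                                   "start": lo, "end": hi})
    truth_alloc = pd.DataFrame(
        alloc_rows, columns=["scaffold", "parent", "chromosome", "start", "end"])
    return (parent_maps["R"], parent_maps["M"], hybrid_maps, scaffolds,
            truth_alloc, phased_truth)
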