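"""FPKM-like expression matrices with subgenome-biased paralogue pairs.

A configurable fraction of surviving homoeologous pairs is expression
biased: the copy on the dominant chromosome has a mean
``expression_dominant_fold`` times that of its subdominant partner
(above the standard two-fold dominance threshold).  All values carry
log-normal measurement noise per dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from subgenomics.annotation import GenomeAnnotation
from subgenomics.simdata.genome import SimTruth
from subgenomics.simdata.params import EvolutionParams


def simulate_expression(
    genome: GenomeAnnotation,
    truth: SimTruth,
    params: EvolutionParams,
    n_datasets: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix (gene x dataset) plus per-pair truth table.

    Returns ``(expr, bias_truth)`` where ``bias_truth`` records which
    pairs are truly dominant-biased.
    """
    species = genome.genes["species"].iloc[0]
    pairs = truth.paralogue_map
    pairs = pairs[pairs["species"] == species]
    if pairs.empty:
        raise ValueError("no surviving homoeologous pairs to simulate over")
    n_datasets = params.n_expression_datasets if n_datasets is None else n_datasets
    if n_datasets < 1:
        raise ValueError("need at least one dataset")
    rng = np.random.default_rng(
        np.random.SeedSequence([params.seed, 0xE54])) if rng is None else rng

    genes = genome.genes["gene_id"].tolist()
    base = pd.Series(
        np.exp(rng.normal(np.log(params.expression_mean_fpkm), 1.0, len(genes))),
        index=genes,
    )
    # Paired copies share their baseline; the dominant copy of a biased
    # pair is scaled up.
    biased = rng.random(len(pairs)) < params.expression_dominant_fraction
    fold = params.expression_dominant_fold
    rows = []
    for (_, row), is_biased in zip(pairs.iterrows(), biased):
        base[row["gene_s"]] = base[row["gene_d"]]
        if is_biased:
            base[row["gene_d"]] *= fold
        rows.append({"species": species, "group": row["group"],
                     "anc": row["anc"], "gene_d": row["gene_d"],
                     "gene_s": row["gene_s"], "biased": bool(is_biased)})
    noise = np.exp(rng.normal(
        0.0, params.expression_noise_sd_log, (len(genes), n_datasets)))
    expr = pd.DataFrame(
        base.to_numpy()[:, None] * noise,
        index=pd.Index(genes, name="gene_id"),
        columns=[f"dataset{j + 1:02d}" for j in range(n_datasets)],
    )
    return expr, pd.DataFrame(rows)
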