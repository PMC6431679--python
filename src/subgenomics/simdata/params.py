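"""Parameters of the synthetic evolutionary study.

Defaults describe a desk-scale version of a walnut-like history: a WGD at
the Cretaceous-Paleogene boundary (66 MYA), speciation of the two extant
species about 8 MYA, synonymous clock rate 2.5e-9 substitutions per
synonymous site per year, asymmetric fractionation that removes roughly a
third of the dominant-subgenome copies and half of the subdominant ones,
and the rearrangement spectrum observed between the two genomes
(28 large inversions, 21 segmental duplications, 3 intra- and 14
inter-chromosomal interstitial translocations).
"""

from __future__ import annotations

from dataclasses import dataclass, field


def _default_rearrangements() -> dict[str, int]:
    return {"C": 28, "Dup": 21, "F": 3, "iT": 14}


def _default_branch_probs() -> dict[str, float]:
    return {"R": 0.5, "M": 0.5, "RM": 0.0}


def _default_size_ranges() -> dict[str, tuple[int, int]]:
    # A/B/D/E have fixed sizes by definition; ranges below are for the
    # open-size codes.  Exposed because no size distribution is implied by
    # the code definitions themselves.
    return {"C": (4, 8), "F": (4, 8), "iT": (2, 6), "T": (2, 6),
            "Dup": (2, 5), "Del": (1, 4)}


_FIXED_EVENT_SIZES = {"A": 2, "B": 3, "D": 2, "E": 3}


@dataclass
class EvolutionParams:
    """Tunable knobs of the synthetic study.

    Times are in years, rates in substitutions/site/year, coordinates in
    bp.  ``deletion_prob_*`` are marginal per-gene-copy deletion
    probabilities accumulated over the whole post-WGD history.
    """

    n_chromosome_pairs: int = 8
    genes_per_chromosome: int = 1000
    mean_intergenic_bp: float = 16_900.0
    gene_length_bp: int = 3_000
    wgd_time: float = 66e6
    speciation_time: float = 8e6
    clock_rate_ks: float = 2.5e-9
    clock_rate_ka: float = 5.6e-10
    deletion_prob_dominant: float = 0.32
    deletion_prob_subdominant: float = 0.51
    deletion_run_mean: float = 1.5
    proximal_multiplier: float = 3.0
    rearrangement_counts: dict[str, int] = field(default_factory=_default_rearrangements)
    branch_probs: dict[str, float] = field(default_factory=_default_branch_probs)
    event_size_ranges: dict[str, tuple[int, int]] = field(default_factory=_default_size_ranges)
    ts_tv_ratio: float = 2.0
    cds_codons: int = 300
    expression_dominant_fraction: float = 0.3
    expression_dominant_fold: float = 2.5
    expression_noise_sd_log: float = 0.2
    expression_mean_fpkm: float = 20.0
    n_expression_datasets: int = 22
    r_gene_fraction: float = 0.03
    phased_fraction: float = 0.10
    label_density: float = 10.0  # labels per 100 kb
    label_site_turnover: float = 0.15  # per-species nicking-site gain/loss
    sizing_error_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "deletion_prob_dominant", "deletion_prob_subdominant",
            "expression_dominant_fraction", "phased_fraction",
            "label_site_turnover",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.wgd_time > self.speciation_time > 0:
            raise ValueError("need wgd_time > speciation_time > 0")
        if self.n_chromosome_pairs < 1 or self.genes_per_chromosome < 1:
            raise ValueError("counts must be positive")
        if self.deletion_run_mean < 1.0:
            raise ValueError("deletion_run_mean must be >= 1 gene")
        if self.proximal_multiplier < 1.0:
            raise ValueError("proximal_multiplier must be >= 1")
        if any(c < 0 for c in self.rearrangement_counts.values()):
            raise ValueError("rearrangement counts must be >= 0")
        bad = set(self.rearrangement_counts) - set("ABCDEF") - {"iT", "T", "Dup", "Del"}
        if bad:
            raise ValueError(f"unknown rearrangement codes: {sorted(bad)}")
        if self.sizing_error_sd < 0 or self.label_density <= 0:
            raise ValueError("label_density must be > 0 and sizing_error_sd >= 0")

    def event_size(self, code: str, rng) -> int:
        if code in _FIXED_EVENT_SIZES:
            return _FIXED_EVENT_SIZES[code]
        lo, hi = self.event_size_ranges[code]
        return int(rng.integers(lo, hi + 1))
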