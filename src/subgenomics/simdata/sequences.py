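"""Codon-level sequence divergence at a molecular-clock rate.

Each gene pair descends from a random ancestral CDS; both copies evolve
independently for the pair's divergence time under a continuous-time
codon process in which the total synonymous flux of a codon equals
``clock_rate_ks`` times its synonymous site count (and likewise for the
nonsynonymous flux), with transitions favoured over transversions by
``ts_tv_ratio`` within each class.  Changes creating stop codons are
forbidden, so sequences remain valid ORFs, and the expected pairwise Ks
at divergence time t is 2 * clock_rate_ks * t by construction.
"""

from __future__ import annotations

import numpy as np

from subgenomics.molclock.kaks import _CODE, _STOPS, codon_sites
from subgenomics.simdata.params import EvolutionParams

_BASES = "ACGT"
_PURINES = {"A", "G"}

_SENSE = sorted(_CODE)


def _change_table(kappa: float) -> dict[str, tuple[list[str], np.ndarray, np.ndarray]]:
    """codon -> (successor codons, per-change class (1=syn), ts/tv weights)."""
    table = {}
    for codon in _SENSE:
        succ, syn, weight = [], [], []
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1:]
                if alt in _STOPS:
                    continue
                succ.append(alt)
                syn.append(_CODE[alt] == _CODE[codon])
                is_ts = (codon[pos] in _PURINES) == (b in _PURINES)
                weight.append(kappa if is_ts else 1.0)
        table[codon] = (succ, np.array(syn, bool), np.array(weight, float))
    return table


_TABLE_CACHE: dict[float, dict] = {}


def _table(kappa: float) -> dict:
    if kappa not in _TABLE_CACHE:
        _TABLE_CACHE[kappa] = _change_table(kappa)
    return _TABLE_CACHE[kappa]


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random valid ORF of ``n_codons`` sense codons (no internal stops)."""
    if n_codons < 1:
        raise ValueError("need at least one codon")
    idx = rng.integers(0, len(_SENSE), n_codons)
    return "".join(_SENSE[i] for i in idx)


def _evolve_codon(codon: str, t: float, r_ks: float, r_ka: float,
                  kappa: float, rng: np.random.Generator) -> str:
    table = _table(kappa)
    remaining = t
    while True:
        succ, syn, weight = table[codon]
        s_sites, n_sites = codon_sites(codon)
        rate_s = r_ks * s_sites
        rate_n = r_ka * n_sites
        total = rate_s + rate_n
        if total <= 0:
            return codon
        wait = rng.exponential(1.0 / total)
        if wait > remaining:
            return codon
        remaining -= wait
        pick_syn = rng.random() < rate_s / total
        mask = syn if pick_syn else ~syn
        if not mask.any():
            continue
        w = weight * mask
        codon = succ[int(rng.choice(len(succ), p=w / w.sum()))]


def evolve_pair(ancestor: str, t: float, params: EvolutionParams,
                rng: np.random.Generator) -> tuple[str, str]:
    """Evolve two descendants of one ancestral CDS for time t each."""
    if len(ancestor) % 3:
        raise ValueError("ancestral CDS length must be a multiple of 3")
    if t < 0:
        raise ValueError("divergence time must be >= 0")
    out = []
    for _ in range(2):
        codons = [
            _evolve_codon(ancestor[i:i + 3], t, params.clock_rate_ks,
                          params.clock_rate_ka, params.ts_tv_ratio, rng)
            for i in range(0, len(ancestor), 3)
        ]
        out.append("".join(codons))
    return out[0], out[1]


def evolve_sequences(
    pairs,
    times,
    params: EvolutionParams,
    rng: np.random.Generator | None = None,
    n_codons: int | None = None,
) -> dict[str, str]:
    """CDS set for gene pairs diverging at given times.

    ``pairs`` is an iterable of (gene_a, gene_b) id tuples and ``times``
    the per-pair divergence times in years (scalar or sequence).
    Returns {gene_id: cds}.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    n_codons = params.cds_codons if n_codons is None else n_codons
    if n_codons < 1:
        raise ValueError("gene length must be positive")
    pairs = list(pairs)
    times_arr = np.broadcast_to(np.asarray(times, dtype=float), (len(pairs),))
    if (times_arr < 0).any():
        raise ValueError("divergence times must be >= 0")
    out: dict[str, str] = {}
    for (ga, gb), t in zip(pairs, times_arr):
        ancestor = random_cds(n_codons, rng)
        sa, sb = evolve_pair(ancestor, float(t), params, rng)
        out[ga] = sa
        out[gb] = sb
    return out


def simulate_ks_mixture(
    n: int,
    rng: np.random.Generator,
    modes: tuple[float, ...] = (0.04, 0.33, 1.5),
    weights: tuple[float, ...] | None = None,
    sdlog: float = 0.25,
) -> np.ndarray:
    """Trimodal (by default) Ks mixture mimicking a whole-genome homology
    search: orthologue, WGD-paralogue and older-triplication layers.

    Components are log-normal around each mode with log-scale sd
    ``sdlog``.
    """
    modes_arr = np.asarray(modes, dtype=float)
    if weights is None:
        w = np.full(len(modes_arr), 1.0 / len(modes_arr))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    comp = rng.choice(len(modes_arr), size=n, p=w)
    return np.exp(rng.normal(np.log(modes_arr[comp]), sdlog))
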