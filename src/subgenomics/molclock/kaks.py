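"""Ka/Ks estimation by site counting and mutation-path averaging.

Sites: at each codon position the three possible single-nucleotide
changes are classified as synonymous or nonsynonymous; changes that
create a stop codon are excluded from consideration, and the position
contributes the synonymous fraction of the remaining changes.  With this
convention synonymous + nonsynonymous sites always sum to 3 per codon.

Differences: for a codon pair differing at k positions, all k! orderings
of the single changes are enumerated; orderings passing through a stop
codon are discarded (unless none survives) and synonymous/nonsynonymous
(and transition/transversion) difference counts are averaged over the
remaining paths.

Correction: "NG86" applies the one-parameter (Jukes-Cantor style)
correction to the proportions; "K2P-weighted" separates transitions and
transversions and applies the Kimura two-parameter correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

_CODE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"
_PURINES = {"A", "G"}

SENSE_CODONS = tuple(sorted(_CODE))


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon."""
    if codon not in _CODE:
        raise ValueError(f"not a sense codon: {codon}")
    syn = 0.0
    for pos in range(3):
        changes = []
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in _STOPS:
                continue
            changes.append(_CODE[alt] == _CODE[codon])
        syn += sum(changes) / len(changes)
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float, float, float]:
    """(syn, nonsyn, syn_transitions, syn_transversions) averaged over
    all valid mutation paths from c1 to c2.

    Nonsynonymous transition/transversion splits follow from the totals;
    only the synonymous split is needed for the K2P-weighted correction
    of Ks, but both are derivable from the returned tuple and the number
    of differing positions.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0, 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                ok = False
                break
            syn = _CODE[nxt] == _CODE[cur]
            ts = _is_transition(cur[pos], c2[pos])
            steps.append((syn, ts))
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:  # all orderings pass through a stop; fall back on all
        for order in permutations(diff_pos):
            cur = c1
            steps = []
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                syn = nxt not in _STOPS and cur not in _STOPS and \
                    _CODE.get(nxt) == _CODE.get(cur)
                ts = _is_transition(cur[pos], c2[pos])
                steps.append((syn, ts))
                cur = nxt
            paths.append(steps)
    syn = float(np.mean([sum(1 for s, _ in p if s) for p in paths]))
    syn_ts = float(np.mean([sum(1 for s, t in p if s and t) for p in paths]))
    nonsyn = k - syn
    # transitions are a property of the site pair, not the path order
    total_ts = float(sum(1 for i in diff_pos if _is_transition(c1[i], c2[i])))
    return syn, nonsyn, syn_ts, total_ts


@dataclass
class KaKsResult:
    """Pairwise Ka/Ks estimate for one codon-aligned gene pair."""

    pair: tuple[str, str]
    ka: float
    ks: float
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int
    method: str
    saturated: bool = False


def _jc_correct(p: float) -> tuple[float, bool]:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return float("nan"), True
    d = -0.75 * float(np.log(arg))
    return (d if d != 0 else 0.0), False


def _k2p_correct(p_ts: float, p_tv: float) -> tuple[float, bool]:
    a1 = 1.0 - 2.0 * p_ts - p_tv
    a2 = 1.0 - 2.0 * p_tv
    if a1 <= 0 or a2 <= 0:
        return float("nan"), True
    d = -0.5 * float(np.log(a1)) - 0.25 * float(np.log(a2))
    return (d if d != 0 else 0.0), False


def compute_kaks(
    alignment: tuple[str, str],
    pair: tuple[str, str] = ("seq_a", "seq_b"),
    method: str = "K2P-weighted",
) -> KaKsResult:
    """Ka and Ks of a codon alignment (two equal-length nt strings).

    Codon columns containing gaps, ambiguity characters, or stop codons
    are excluded pairwise.
    """
    a, b = (s.upper() for s in alignment)
    if len(a) != len(b):
        raise ValueError("aligned sequences differ in length")
    if len(a) % 3:
        raise ValueError("alignment length not a multiple of 3")
    if method not in ("NG86", "K2P-weighted"):
        raise ValueError(f"unknown method: {method}")

    S = N = Sd = Nd = Sd_ts = 0.0
    n_codons = 0
    nonsyn_ts = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if ca not in _CODE or cb not in _CODE:
            continue
        n_codons += 1
        sa, _ = codon_sites(ca)
        sb, _ = codon_sites(cb)
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        syn, nonsyn, syn_ts, total_ts = _pair_differences(ca, cb)
        Sd += syn
        Nd += nonsyn
        Sd_ts += syn_ts
        nonsyn_ts += total_ts - syn_ts
    if n_codons == 0:
        raise ValueError("no comparable codon columns in alignment")

    saturated = False
    if method == "NG86":
        ks, sat1 = _jc_correct(Sd / S) if S > 0 else (float("nan"), True)
        ka, sat2 = _jc_correct(Nd / N) if N > 0 else (float("nan"), True)
        saturated = sat1 or sat2
    else:
        ks, sat1 = (_k2p_correct(Sd_ts / S, (Sd - Sd_ts) / S)
                    if S > 0 else (float("nan"), True))
        ka, sat2 = (_k2p_correct(nonsyn_ts / N, (Nd - nonsyn_ts) / N)
                    if N > 0 else (float("nan"), True))
        saturated = sat1 or sat2
    return KaKsResult(
        pair=pair, ka=ka, ks=ks, syn_sites=S, nonsyn_sites=N,
        syn_diffs=Sd, nonsyn_diffs=Nd, n_codons=n_codons, method=method,
        saturated=saturated,
    )
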