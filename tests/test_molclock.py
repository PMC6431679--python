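"""Ka/Ks engine, clock arithmetic, Ks peaks, and the NJ dendrogram.

The Ka/Ks estimator is validated against a brute-force oracle that
re-derives site counts from the genetic code and difference counts by
explicit enumeration of all mutation paths per codon pair.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subgenomics.molclock import (
    calibrate_clock,
    codon_align,
    compute_kaks,
    date_divergence,
    ks_peak_detect,
    nj_dendrogram,
)

_CODE = {}
_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
for b1 in _BASES:
    for b2 in _BASES:
        for b3 in _BASES:
            codon = b1 + b2 + b3
            if codon not in _STOPS:
                from Bio.Seq import Seq
                _CODE[codon] = str(Seq(codon).translate())
SENSE = sorted(_CODE)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def _oracle_sites(codon):
    syn = 0.0
    for pos in range(3):
        opts = []
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in _STOPS:
                continue
            opts.append(_CODE[alt] == _CODE[codon])
        syn += sum(opts) / len(opts)
    return syn


def _oracle_diffs(c1, c2):
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    valid, any_paths = [], []
    for order in permutations(pos):
        cur, steps, ok = c1, [], True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in _STOPS:
                ok = False
                break
            steps.append(_CODE[nxt] == _CODE[cur])
            cur = nxt
        if ok:
            valid.append(steps)
        any_paths.append(ok)
    paths = valid if valid else None
    if paths is None:
        return None  # oracle skips the no-valid-path corner case
    syn = float(np.mean([sum(p) for p in paths]))
    return syn, len(pos) - syn


def _random_codon_pair_alignment(rng, max_codons=30):
    n = int(rng.integers(1, max_codons + 1))
    a = "".join(SENSE[i] for i in rng.integers(0, len(SENSE), n))
    b = []
    for i in range(n):
        if rng.random() < 0.5:
            b.append(a[3 * i:3 * i + 3])
        else:
            b.append(SENSE[int(rng.integers(len(SENSE)))])
    return a, "".join(b)


def test_counts_match_brute_force_oracle_on_random_alignments():
    rng = np.random.default_rng(4)
    checked = 0
    while checked < 50:
        a, b = _random_codon_pair_alignment(rng)
        exp_S = exp_Sd = exp_Nd = 0.0
        skip = False
        for i in range(0, len(a), 3):
            ca, cb = a[i:i + 3], b[i:i + 3]
            d = _oracle_diffs(ca, cb)
            if d is None:
                skip = True
                break
            exp_S += (_oracle_sites(ca) + _oracle_sites(cb)) / 2
            exp_Sd += d[0]
            exp_Nd += d[1]
        if skip:
            continue
        res = compute_kaks((a, b), method="NG86")
        assert res.syn_sites == pytest.approx(exp_S, abs=1e-9)
        assert res.syn_diffs == pytest.approx(exp_Sd, abs=1e-9)
        assert res.nonsyn_diffs == pytest.approx(exp_Nd, abs=1e-9)
        ps, pn = exp_Sd / exp_S, exp_Nd / (3 * res.n_codons - exp_S)
        for p_hat, got in ((ps, res.ks), (pn, res.ka)):
            arg = 1 - 4 * p_hat / 3
            if arg > 0:
                assert got == pytest.approx(-0.75 * np.log(arg), abs=1e-9)
            else:
                assert np.isnan(got) and res.saturated
        checked += 1


def test_identical_sequences_have_zero_divergence():
    seq = "ATGGCTAAAGGT"
    res = compute_kaks((seq, seq))
    assert res.ka == 0.0 and res.ks == 0.0 and not res.saturated


def test_synonymous_only_change():
    """A TTT<->TTC (Phe/Phe) difference is purely synonymous."""
    a = "ATGGCTAAAGGTTTT" + "GAA" * 5
    b = "ATGGCTAAAGGTTTC" + "GAA" * 5
    res = compute_kaks((a, b), method="NG86")
    assert res.nonsyn_diffs == 0.0
    assert res.syn_diffs == 1.0
    assert res.ka == 0.0
    assert res.ks > 0.0


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_kaks_is_symmetric_in_its_sequences(seed):
    rng = np.random.default_rng(seed)
    a, b = _random_codon_pair_alignment(rng, max_codons=15)
    r1 = compute_kaks((a, b))
    r2 = compute_kaks((b, a))
    assert r1.syn_sites == pytest.approx(r2.syn_sites, abs=1e-12)
    assert r1.syn_diffs == pytest.approx(r2.syn_diffs, abs=1e-12)
    if not (r1.saturated or r2.saturated):
        assert r1.ks == pytest.approx(r2.ks, abs=1e-12)
        assert r1.ka == pytest.approx(r2.ka, abs=1e-12)


def test_site_counts_sum_to_three_per_codon():
    rng = np.random.default_rng(11)
    a, b = _random_codon_pair_alignment(rng, max_codons=20)
    res = compute_kaks((a, b))
    assert res.syn_sites + res.nonsyn_sites == pytest.approx(
        3.0 * res.n_codons, abs=1e-9)


def test_gapped_codons_are_excluded_pairwise():
    res = compute_kaks(("ATG---AAA", "ATGGGGAAA"))
    assert res.n_codons == 2


# ---------------------------------------------------------------------------
# codon alignment
# ---------------------------------------------------------------------------

def test_codon_align_identical_sequences():
    cds = "ATGGCTAAAGGTTTTGAA"
    a, b = codon_align(cds, cds)
    assert a == b == cds


def test_codon_align_single_amino_acid_deletion():
    full = "ATGGCTAAAGGTTTTGAA"
    deleted = "ATGGCTGGTTTTGAA"  # AAA codon removed
    a, b = codon_align(full, deleted)
    assert len(a) == len(b) == len(full)
    assert b.count("-") == 3
    i = b.index("---")
    assert i % 3 == 0


def test_codon_align_round_trips_to_protein_alignment():
    from Bio.Seq import Seq
    rng = np.random.default_rng(3)
    for _ in range(10):
        a = "".join(SENSE[i] for i in rng.integers(0, len(SENSE), 40))
        b = "".join(SENSE[i] for i in rng.integers(0, len(SENSE), 38))
        na, nb = codon_align(a, b)
        assert len(na) == len(nb) and len(na) % 3 == 0
        # every aligned column is an intact codon or a gap triplet
        for s, orig in ((na, a), (nb, b)):
            assert s.replace("-", "") == orig
            for i in range(0, len(s), 3):
                cod = s[i:i + 3]
                assert cod == "---" or "-" not in cod


def test_codon_align_rejects_internal_stops():
    with pytest.raises(ValueError, match="stop"):
        codon_align("ATGTAAGGG", "ATGCCCGGG")


# ---------------------------------------------------------------------------
# clock
# ---------------------------------------------------------------------------

def test_clock_calibration_examples():
    assert calibrate_clock(0.33, 6.6e7).r == pytest.approx(2.5e-9)
    assert calibrate_clock(0.0739, 6.6e7, basis="Ka").r == pytest.approx(
        5.6e-10, rel=1e-3)
    assert calibrate_clock(0.0, 1e6).r == 0.0


def test_dating_examples_and_round_trip():
    from subgenomics.molclock import ClockModel

    clock = ClockModel(r=2.5e-9, calibration_time=6.6e7)
    assert date_divergence(0.04, clock) == pytest.approx(8.0)
    assert date_divergence(0.0, clock) == 0.0
    # calibrate then date returns the calibration time exactly
    k, t = 0.123, 4.2e7
    model = calibrate_clock(k, t)
    assert date_divergence(k, model) * 1e6 == pytest.approx(t, rel=1e-12)
    with pytest.raises(ValueError):
        date_divergence(0.1, ClockModel(r=0.0, calibration_time=1.0))


def test_dating_a_vector_gives_mean_and_interval():
    from subgenomics.molclock import ClockModel

    clock = ClockModel(r=2.5e-9, calibration_time=6.6e7)
    out = date_divergence(np.array([0.03, 0.04, 0.05]), clock)
    assert out["t_my"] == pytest.approx(8.0)
    assert out["ci_low_my"] <= out["t_my"] <= out["ci_high_my"]


# ---------------------------------------------------------------------------
# Ks peaks
# ---------------------------------------------------------------------------

def test_trimodal_mixture_modes_recovered():
    from subgenomics.simdata import simulate_ks_mixture

    rng = np.random.default_rng(6)
    ks = simulate_ks_mixture(1000, rng)
    modes = ks_peak_detect(ks)
    assert len(modes) == 3
    for got, want in zip(modes, (0.04, 0.33, 1.5)):
        assert abs(got - want) / want <= 0.20


def test_single_component_gives_one_mode():
    rng = np.random.default_rng(8)
    ks = np.exp(rng.normal(np.log(0.3), 0.15, 500))
    modes = ks_peak_detect(ks)
    assert len(modes) == 1


def test_too_few_values_rejected():
    with pytest.raises(ValueError):
        ks_peak_detect(np.full(10, 0.3))


# ---------------------------------------------------------------------------
# NJ dendrogram
# ---------------------------------------------------------------------------

def test_three_taxon_branch_lengths_are_exact():
    d = pd.DataFrame([[0.0, 2.0, 3.0], [2.0, 0.0, 3.0], [3.0, 3.0, 0.0]],
                     index=list("ABC"), columns=list("ABC"))
    tree = nj_dendrogram(d)
    lengths = {tip.name: tip.length for tip in tree.tips()}
    assert lengths["A"] == pytest.approx(1.0)
    assert lengths["B"] == pytest.approx(1.0)
    assert lengths["C"] == pytest.approx(2.0)


def test_eight_taxon_additive_topology_recovered():
    """NJ on exactly additive distances from a four-cherry backbone tree
    recovers every cherry as a split of the unrooted tree."""
    import itertools

    names = [f"t{i}" for i in range(8)]
    dmat = pd.DataFrame(0.0, index=names, columns=names)
    topo_pairs = {
        ("t0", "t1"): 0.4, ("t2", "t3"): 0.6, ("t4", "t5"): 0.5,
        ("t6", "t7"): 0.3,
    }
    leaf_pos = {"t0": 0, "t1": 0, "t2": 1, "t3": 1, "t4": 2, "t5": 2,
                "t6": 3, "t7": 3}
    cherry_depth = {0: 0.2, 1: 0.3, 2: 0.25, 3: 0.15}
    spine = 1.0  # distance between adjacent cherries on the backbone
    for a, b in itertools.combinations(names, 2):
        ca, cb = leaf_pos[a], leaf_pos[b]
        if ca == cb:
            dmat.loc[a, b] = dmat.loc[b, a] = topo_pairs.get(
                (a, b), topo_pairs.get((b, a)))
        else:
            d = cherry_depth[ca] + cherry_depth[cb] + spine * abs(ca - cb)
            dmat.loc[a, b] = dmat.loc[b, a] = d
    tree = nj_dendrogram(dmat)
    # each cherry must be monophyletic in the unrooted tree: the split
    # {a,b} vs rest exists
    tip_sets = []
    for node in tree.non_tips(include_self=True):
        tip_sets.append(frozenset(t.name for t in node.tips()))
    all_names = frozenset(names)
    for (a, b) in topo_pairs:
        pair = frozenset((a, b))
        assert pair in tip_sets or (all_names - pair) in tip_sets


def test_invalid_distance_matrices_are_rejected():
    bad_diag = np.array([[1.0, 2.0], [2.0, 0.0]])
    with pytest.raises(ValueError):
        nj_dendrogram(bad_diag, ids=["a", "b"])
    asym = np.zeros((3, 3))
    asym[0, 1] = 1.0
    with pytest.raises(ValueError):
        nj_dendrogram(asym, ids=list("abc"))
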