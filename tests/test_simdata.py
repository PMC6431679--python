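"""Generator-level checks: determinism, conservation, truth bookkeeping."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from subgenomics.io import write_gff3
from subgenomics.simdata import (
    EvolutionParams,
    evolve_sequences,
    random_cds,
    simulate_evolution,
    simulate_expression,
    simulate_ks_mixture,
    simulate_label_maps,
    simulate_landmarks,
)
from subgenomics.simdata.sequences import evolve_pair


def test_same_seed_gives_identical_studies(tmp_path, quiet_params):
    a = simulate_evolution(quiet_params)
    b = simulate_evolution(quiet_params)
    assert a[0].equals(b[0]) and a[1].equals(b[1])
    assert a[2].deletion_log.equals(b[2].deletion_log)
    assert [e.genes for e in a[2].event_log] == [e.genes for e in b[2].event_log]
    pa, pb = tmp_path / "a.gff3", tmp_path / "b.gff3"
    write_gff3(a[0], pa)
    write_gff3(b[0], pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_null_process_conserves_every_gene(quiet_study):
    p = quiet_study["params"]
    expected = 2 * p.n_chromosome_pairs * p.genes_per_chromosome
    assert len(quiet_study["genome_r"]) == expected
    assert len(quiet_study["genome_m"]) == expected
    assert len(quiet_study["truth"].orthologue_map) == expected
    # every gene paired with its WGD partner
    assert len(quiet_study["truth"].paralogue_map) == expected  # both species


def test_gene_accounting_matches_deletion_and_event_logs(default_study):
    p = default_study["params"]
    truth = default_study["truth"]
    ancestors = 2 * p.n_chromosome_pairs * p.genes_per_chromosome
    log = truth.deletion_log
    for sp, genome in (("R", default_study["genome_r"]),
                       ("M", default_study["genome_m"])):
        deleted = len(log[log.species.isin(["RM", sp])])
        del_events = sum(len(e.genes) for e in truth.event_log
                         if e.code == "Del" and sp in e.branch)
        dup_genes = sum(len(e.genes) for e in truth.event_log
                        if e.code == "Dup" and sp in e.branch)
        assert len(genome) == ancestors - deleted - del_events + dup_genes


def test_requested_event_counts_are_honoured(event_study):
    counts = {}
    for e in event_study["truth"].event_log:
        counts[e.code] = counts.get(e.code, 0) + 1
    assert counts == {"C": 10, "iT": 5, "Dup": 5, "Del": 5, "A": 5}


def test_impossible_event_request_is_rejected():
    p = EvolutionParams(n_chromosome_pairs=1, genes_per_chromosome=12,
                        deletion_prob_dominant=0.0,
                        deletion_prob_subdominant=0.0,
                        rearrangement_counts={"C": 50}, seed=0)
    with pytest.raises(ValueError, match="exceed"):
        simulate_evolution(p)


def test_parameter_validation():
    with pytest.raises(ValueError):
        EvolutionParams(deletion_prob_dominant=1.5)
    with pytest.raises(ValueError):
        EvolutionParams(wgd_time=1e6, speciation_time=2e6)
    with pytest.raises(ValueError):
        EvolutionParams(rearrangement_counts={"X": 1})


# -- sequence divergence -----------------------------------------------------

def test_zero_time_divergence_keeps_sequences_identical():
    p = EvolutionParams(seed=3)
    cds = evolve_sequences([("a", "b")], 0.0, p, n_codons=100)
    assert cds["a"] == cds["b"]


def test_evolved_sequences_are_valid_orfs():
    p = EvolutionParams(seed=5)
    rng = np.random.default_rng(5)
    anc = random_cds(120, rng)
    sa, sb = evolve_pair(anc, 66e6, p, rng)
    from Bio.Seq import Seq
    for s in (sa, sb):
        assert len(s) % 3 == 0
        assert "*" not in str(Seq(s).translate())


def test_transition_bias_is_expressed_in_substitutions():
    """With ts/tv ratio 4 the pooled substitution spectrum favours
    transitions significantly over the 1:2 random expectation."""
    p = EvolutionParams(seed=9, ts_tv_ratio=4.0)
    rng = np.random.default_rng(9)
    ts = tv = 0
    purines = {"A", "G"}
    for _ in range(60):
        anc = random_cds(150, rng)
        sa, sb = evolve_pair(anc, 40e6, p, rng)
        for x, y in zip(sa, sb):
            if x != y:
                if (x in purines) == (y in purines):
                    ts += 1
                else:
                    tv += 1
    res = stats.binomtest(ts, ts + tv, p=1.0 / 3.0, alternative="greater")
    assert res.pvalue < 1e-6


def test_mean_ks_tracks_the_clock_expectation():
    """Over 300 pairs the realised mean Ks is within 10% of 2*r*t."""
    from subgenomics.molclock import compute_kaks

    p = EvolutionParams(seed=21)
    cds = evolve_sequences([(f"a{i}", f"b{i}") for i in range(300)], 66e6, p)
    ks = [compute_kaks((cds[f"a{i}"], cds[f"b{i}"]), method="NG86").ks
          for i in range(300)]
    expected = 2 * p.clock_rate_ks * 66e6
    assert np.mean(ks) == pytest.approx(expected, rel=0.10)


def test_ks_mixture_has_three_layers():
    rng = np.random.default_rng(2)
    ks = simulate_ks_mixture(3000, rng)
    assert (ks > 0).all()
    # component medians near the requested modes
    labels = np.digitize(np.log(ks), [np.log(0.12), np.log(0.7)])
    med = [np.median(ks[labels == i]) for i in range(3)]
    assert med == pytest.approx([0.04, 0.33, 1.5], rel=0.15)


# -- expression ---------------------------------------------------------------

def test_expression_values_nonnegative_and_shape(default_study):
    p = default_study["params"]
    expr, bias = simulate_expression(default_study["genome_r"],
                                     default_study["truth"], p)
    assert (expr.to_numpy() >= 0).all()
    assert expr.shape[1] == p.n_expression_datasets
    assert set(bias.columns) >= {"gene_d", "gene_s", "biased", "group"}


def test_biased_pair_fraction_matches_request(default_study):
    """Across-dataset mean folds recover the simulated biased fraction
    within sampling tolerance."""
    p = EvolutionParams(n_chromosome_pairs=4, genes_per_chromosome=500,
                        deletion_prob_dominant=0.0,
                        deletion_prob_subdominant=0.0,
                        rearrangement_counts={}, seed=31,
                        expression_dominant_fraction=0.3)
    genome_r, _, truth = simulate_evolution(p)
    expr, bias = simulate_expression(genome_r, truth, p)
    mean_d = expr.loc[bias["gene_d"]].mean(axis=1).to_numpy()
    mean_s = expr.loc[bias["gene_s"]].mean(axis=1).to_numpy()
    observed = float(np.mean(mean_d > 2.0 * mean_s))
    assert len(bias) == 2000
    assert abs(observed - 0.3) <= 0.03


# -- landmarks ----------------------------------------------------------------

def test_telomere_array_construction_is_exact(quiet_study):
    seqs, _, _ = simulate_landmarks(
        quiet_study["genome_r"], telomere_bp=35,
        rng=np.random.default_rng(4))
    five = seqs["R1D_5prime"]
    assert five.startswith("CCCTAAA" * 5)
    assert five[35:42] != "CCCTAAA"


def test_centromere_cluster_construction(quiet_study):
    _, repeats, truth = simulate_landmarks(
        quiet_study["genome_r"], centromere_copies=60,
        rng=np.random.default_rng(4))
    cen = truth[truth.feature == "centromere"]
    for _, row in cen.iterrows():
        inside = repeats[(repeats.chromosome == row.chromosome)
                         & (repeats.start >= row.start)
                         & (repeats.end <= row.end)]
        assert len(inside) == 60
        assert row.end - row.start <= 3_000_000


# -- label maps ---------------------------------------------------------------

def test_label_maps_zero_noise_zero_phasing_is_exactly_additive(quiet_study):
    p = EvolutionParams(n_chromosome_pairs=2, genes_per_chromosome=300,
                        rearrangement_counts={}, deletion_prob_dominant=0.0,
                        deletion_prob_subdominant=0.0, seed=7,
                        sizing_error_sd=0.0, phased_fraction=0.0)
    maps_r, maps_m, maps_h, _, _, phased = simulate_label_maps(
        quiet_study["genome_r"], quiet_study["genome_m"], p)
    assert not phased
    parent_sum = sum(m.length for m in maps_r) + sum(m.length for m in maps_m)
    hybrid_sum = sum(m.length for m in maps_h)
    assert parent_sum == hybrid_sum


def test_label_counts_follow_the_density(quiet_study):
    p = EvolutionParams(n_chromosome_pairs=2, genes_per_chromosome=300,
                        rearrangement_counts={}, deletion_prob_dominant=0.0,
                        deletion_prob_subdominant=0.0, seed=13,
                        phased_fraction=0.0, label_density=10.0)
    maps_r, _, _, _, _, _ = simulate_label_maps(
        quiet_study["genome_r"], quiet_study["genome_m"], p)
    total_len = sum(m.length for m in maps_r)
    total_labels = sum(m.n_labels for m in maps_r)
    lam = 10.0 / 100_000.0 * total_len
    assert abs(total_labels - lam) <= 3 * np.sqrt(lam)


def test_phased_fraction_of_map_length(quiet_study):
    p = EvolutionParams(n_chromosome_pairs=2, genes_per_chromosome=300,
                        rearrangement_counts={}, deletion_prob_dominant=0.0,
                        deletion_prob_subdominant=0.0, seed=17,
                        phased_fraction=0.10)
    maps_r, _, _, _, _, phased = simulate_label_maps(
        quiet_study["genome_r"], quiet_study["genome_m"], p)
    main_len = sum(m.length for m in maps_r if m.map_id.endswith("_h1"))
    dup_len = sum(rec["end"] - rec["start"] for rec in phased
                  if rec["parent"] == "R")
    assert abs(dup_len / main_len - 0.10) <= 0.02
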