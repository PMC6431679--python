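# subgenomics

Comparative genomics of a whole-genome-duplicated (WGD) genome pair —
the situation found in walnut-like tree genomes, where each species
carries two homoeologous subgenomes from a paleopolyploidy event and two
sibling species are compared against each other and a pre-WGD outgroup.

The package implements, as a tested library plus a thin CLI:

- **Collinearity** — maximal chains of ≥3 genes whose top-hit start
  coordinates run in ascending or descending order with gaps < 0.5 Mb
  and bounded interruptions; top-n hit selection, reciprocal best hits,
  tandem-copy collapsing (`subgenomics.collinearity`).
- **Rearrangements** — classification of gene-order differences into the
  codes A/B/C (inversions of 2/3/>3 genes), D/E/F (intra-chromosomal
  translocations), iT/T, Dup, Del; branch assignment by outgroup
  parsimony; rates counting the major codes C/F/iT per million years
  (`subgenomics.rearrangements`).
- **Fractionation** — dominant/subdominant subgenome assignment,
  singleton counts in anchor-delimited intervals and 2-Mb windows, and
  the paired t-test for asymmetric gene loss (`subgenomics.fractionation`).
- **Molecular clock** — Ka/Ks by degeneracy site counting and
  mutation-path averaging (NG86 or Kimura-two-parameter-weighted
  correction), clock calibration r = K/(2t), dating t = k/(2r), Ks-mode
  detection, and a neighbor-joining dendrogram from Ka distances
  (`subgenomics.molclock`).
- **Expression dominance** — strict two-fold dominance calls between
  homoeologous copies and the paired subgenome bias test
  (`subgenomics.expression`).
- **Landmarks** — telomeric CCCTAAA array detection and tripartite
  terminus structure, centromeric retrotransposon clusters and their
  repositioning class (conserved / translocated / inversion-split),
  equal-gene-count window distributions (e.g. of R genes) and density
  correlations (`subgenomics.landmarks`).
- **Optical-map trio** — in-silico digestion, a dynamic-programming
  label-map aligner with permutation significance, phased (diploid)
  region detection by self-alignment, haplotype-edited length additivity
  of a parent/parent/hybrid trio, and scaffold-to-parent allocation
  (`subgenomics.triomap`).
- **Synthetic data** — a seeded generator (`subgenomics.simdata`) that
  produces a complete study with ground truth: WGD + asymmetric
  run-deletion fractionation (elevated proximally), branch-assigned
  rearrangements, clock-calibrated codon divergence, biased expression,
  telomere/centromere landmarks, and trio label maps.

## Worked example

Simulate two ~2000-gene genomes that differ by a known set of
rearrangements, then recover and date them:

```python
import numpy as np
from subgenomics.simdata import (EvolutionParams, simulate_evolution,
                                 make_cross_species_hits)
from subgenomics.collinearity import detect_collinear_chains
from subgenomics.rearrangements import classify_events
from collections import Counter

params = EvolutionParams(
    n_chromosome_pairs=2, genes_per_chromosome=500,
    deletion_prob_dominant=0.0, deletion_prob_subdominant=0.0,
    rearrangement_counts={"C": 10, "iT": 5, "Dup": 5, "Del": 5, "A": 5},
    seed=42)
genome_r, genome_m, truth = simulate_evolution(params)
hits = make_cross_species_hits(genome_r, genome_m, np.random.default_rng(1))

chains, summary = detect_collinear_chains(genome_r, genome_m, hits)
print(round(summary["collinear_percent"], 1))   # 99.7
events = classify_events(genome_r, genome_m, hits)
print(Counter(e.code for e in events))
# Counter({'C': 10, 'Del': 5, 'A': 5, 'iT': 5, 'Dup': 5})
```

99.7% of query genes sit in collinear chains (the missing sliver flanks
the 30 simulated events), and every requested event is recovered with
its correct code.  Calibrating the clock on sequence pairs diverged for
66 My at the default synonymous rate:

```python
from subgenomics.simdata import evolve_sequences
from subgenomics.molclock import compute_kaks, calibrate_clock

pairs = [(f"a{i}", f"b{i}") for i in range(300)]
cds = evolve_sequences(pairs, 66e6, params)
ks = np.mean([compute_kaks((cds[a], cds[b]), method="NG86").ks
              for a, b in pairs])
print(f"{calibrate_clock(ks, 66e6).r:.2e}")     # 2.46e-09
```

The recovered rate, 2.46 × 10⁻⁹ substitutions per synonymous site per
year, matches the 2.5 × 10⁻⁹ the simulation was run at.

A full synthetic study (GFF3, BLAST-tabular hits, FPKM matrix, terminus
FASTA, CMAP-like label maps) can be written from the shell:

```sh
subgenomics simulate --seed 7 --out study/
subgenomics collinearity --query-gff study/R.gff3 --target-gff study/M.gff3 \
    --hits study/hits_R_vs_M.tsv --out chains.tsv
```

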