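"""Core genome simulator: WGD, asymmetric fractionation, rearrangements.

The simulated history is: an ancestral genome of ``n_chromosome_pairs``
chromosomes is duplicated (WGD) at ``wgd_time``; the duplicated gene
copies are then lost by short deletion runs (geometric lengths, initiation
probability elevated inside the proximal, centromere-flanking tenth of
each chromosome), partly before and partly after the speciation of the
two descendant species R and M at ``speciation_time``; finally,
structural rearrangements of the classic event codes are applied on the
R, M, or shared (RM) branches.  Everything is logged in a
:class:`SimTruth`.

Event codes: A/B/C = inversion of 2 / 3 / >3 genes; D/E/F = intra-
chromosomal translocation of 2 / 3 / >3 genes; iT = interstitial
translocation between chromosomes; T = terminal translocation;
Dup = segmental duplication; Del = segmental deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from subgenomics.annotation import GenomeAnnotation
from subgenomics.rearrangements import RearrangementEvent
from subgenomics.simdata.params import EvolutionParams

#: Deterministic order in which requested event codes are placed.
_CODE_ORDER = ["A", "B", "C", "D", "E", "F", "iT", "T", "Dup", "Del"]


@dataclass
class _Gene:
    """One gene copy while the simulation is running."""

    group: int
    subgenome: str  # "D" or "S"
    anc: int        # ancestral gene ordinal within its chromosome
    gene_class: str
    strand: str
    dup_tag: int = 0

    @property
    def key(self) -> tuple:
        return (self.group, self.subgenome, self.anc, self.dup_tag)

    def gene_id(self, species: str) -> str:
        base = f"{species}{self.group}{self.subgenome}g{self.anc:04d}"
        return base if self.dup_tag == 0 else f"{base}d{self.dup_tag}"


@dataclass
class SimTruth:
    """Ground truth of a simulated study."""

    deletion_log: pd.DataFrame
    event_log: list[RearrangementEvent]
    paralogue_map: pd.DataFrame   # species, group, anc, gene_d, gene_s
    orthologue_map: pd.DataFrame  # group, subgenome, anc, gene_r, gene_m
    true_divergence_times: dict[str, float]
    centromere_positions: dict[str, float] = field(default_factory=dict)
    phased_intervals: list = field(default_factory=list)

    def events_with_code(self, code: str) -> list[RearrangementEvent]:
        return [e for e in self.event_log if e.code == code]


def _hazard_split(p_total: float, frac_first: float) -> tuple[float, float]:
    """Split a marginal deletion probability into two time phases.

    Deletion is modelled as a constant-hazard process; ``frac_first`` is
    the fraction of total time elapsed in the first phase.
    """
    if p_total <= 0:
        return 0.0, 0.0
    lam = -np.log(1.0 - p_total)
    p1 = 1.0 - np.exp(-lam * frac_first)
    p2 = 1.0 - np.exp(-lam * (1.0 - frac_first))
    return p1, p2


def _deletion_runs(n: int, p_gene: float, run_mean: float,
                   prox_mult: float, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Sample deletion runs over ``n`` ordered gene slots.

    Runs start with per-gene probability ``p_gene / run_mean`` (multiplied
    by ``prox_mult`` inside the central 10% of the chromosome) and extend
    geometrically with mean ``run_mean`` genes.
    """
    if p_gene <= 0 or n == 0:
        return []
    p_init = min(1.0, p_gene / run_mean)
    lo, hi = 0.45 * n, 0.55 * n
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        p = p_init * (prox_mult if lo <= i < hi else 1.0)
        if rng.random() < min(1.0, p):
            length = int(rng.geometric(1.0 / run_mean))
            length = min(length, n - i)
            runs.append((i, length))
            i += length
        else:
            i += 1
    return runs


def _apply_deletions(chrom: list[_Gene], runs: list[tuple[int, int]],
                     species: str, chrom_name: str, log: list[dict],
                     phase: str) -> list[_Gene]:
    doomed = set()
    for run_id, (start, length) in enumerate(runs):
        for g in chrom[start:start + length]:
            doomed.add(g.key)
            log.append({
                "species": species, "chromosome": chrom_name,
                "group": g.group, "subgenome": g.subgenome, "anc": g.anc,
                "gene": g.gene_id(species if species != "RM" else "R"),
                "phase": phase, "run_start": start, "run_length": length,
                "cause": "fractionation",
            })
    return [g for g in chrom if g.key not in doomed]


# ---------------------------------------------------------------------------
# Rearrangement placement
# ---------------------------------------------------------------------------

class _EventPlacer:
    """Places requested events on the simulated genomes without overlap."""

    MARGIN = 2      # collinear anchor genes preserved on each side
    RETRIES = 500

    def __init__(self, genomes: dict[str, dict[tuple, list[_Gene]]],
                 params: EvolutionParams, rng: np.random.Generator):
        self.genomes = genomes
        self.params = params
        self.rng = rng
        self.used: dict[str, set] = {s: set() for s in genomes}
        self.dup_counter: dict[tuple, int] = {}

    # -- helpers ---------------------------------------------------------
    def _chrom_keys(self, species: str) -> list[tuple]:
        return sorted(self.genomes[species].keys())

    def _find_contiguous(self, species: str, run_keys: list[tuple]) -> tuple | None:
        """Locate a key run appearing contiguously (same order) in a genome."""
        want = run_keys
        for ck in self._chrom_keys(species):
            chrom = self.genomes[species][ck]
            keys = [g.key for g in chrom]
            n, m = len(keys), len(want)
            for i in range(n - m + 1):
                if keys[i:i + m] == want:
                    return ck, i
        return None

    def _run_free(self, species: str, chrom: list[_Gene], i: int, size: int) -> bool:
        lo = max(0, i - self.MARGIN)
        hi = min(len(chrom), i + size + self.MARGIN)
        return not any(g.key in self.used[species] for g in chrom[lo:hi])

    def _mark(self, species: str, genes: list[_Gene]) -> None:
        for g in genes:
            self.used[species].add(g.key)

    def _pick_run(self, species: str, size: int,
                  mirror: str | None = None) -> tuple[tuple, int, list[_Gene]]:
        rng = self.rng
        cks = self._chrom_keys(species)
        for _ in range(self.RETRIES):
            ck = cks[int(rng.integers(len(cks)))]
            chrom = self.genomes[species][ck]
            if len(chrom) < size + 2 * self.MARGIN + 2:
                continue
            i = int(rng.integers(self.MARGIN, len(chrom) - size - self.MARGIN))
            run = chrom[i:i + size]
            if not self._run_free(species, chrom, i, size):
                continue
            if mirror is not None:
                loc = self._find_contiguous(mirror, [g.key for g in run])
                if loc is None:
                    continue
                mck, mi = loc
                if not self._run_free(mirror, self.genomes[mirror][mck], mi, size):
                    continue
            return ck, i, run
        raise ValueError(
            "could not place rearrangement: requested events exceed the "
            "free gene runs available in the simulated genomes"
        )

    def _pick_insertion(self, species: str, exclude_ck: tuple | None,
                        same_ck: tuple | None = None,
                        avoid: tuple[tuple, int, int] | None = None,
                        mirror: str | None = None) -> tuple[tuple, int, tuple]:
        """Pick an insertion point, returned as (chrom_key, index, anchor_key).

        The anchor is the gene immediately preceding the insertion point;
        for shared (RM) events the anchor must exist in both species.
        ``avoid`` = (chrom_key, lo, hi) keeps the point away from a gene
        index range (the event's own source run).
        """
        rng = self.rng
        cks = self._chrom_keys(species)
        for _ in range(self.RETRIES):
            ck = same_ck if same_ck is not None else cks[int(rng.integers(len(cks)))]
            if exclude_ck is not None and ck == exclude_ck:
                continue
            chrom = self.genomes[species][ck]
            if len(chrom) < 2 * self.MARGIN + 2:
                continue
            j = int(rng.integers(self.MARGIN, len(chrom) - self.MARGIN))
            if avoid is not None and ck == avoid[0] and avoid[1] - 1 <= j <= avoid[2] + 1:
                continue
            anchor = chrom[j - 1]
            nxt = chrom[j]
            if anchor.key in self.used[species] or nxt.key in self.used[species]:
                continue
            if mirror is not None:
                loc = self._find_contiguous(mirror, [anchor.key, nxt.key])
                if loc is None:
                    continue
            return ck, j, anchor.key
        raise ValueError("could not place rearrangement insertion point")

    def _insert_at_anchor(self, species: str, anchor_key: tuple,
                          payload: list[_Gene]) -> tuple:
        loc = self._find_contiguous(species, [anchor_key])
        if loc is None:  # pragma: no cover - guarded by _pick_insertion
            raise RuntimeError("lost insertion anchor")
        ck, i = loc
        chrom = self.genomes[species][ck]
        self.genomes[species][ck] = chrom[:i + 1] + payload + chrom[i + 1:]
        return ck

    # -- event application ----------------------------------------------
    def apply(self, code: str, branch: str) -> RearrangementEvent:
        params = self.params
        size = params.event_size(code, self.rng)
        species_list = ["R", "M"] if branch == "RM" else [branch]
        lead = species_list[0]
        mirror = "M" if branch == "RM" else None

        ck, i, run = self._pick_run(lead, size, mirror=mirror)
        run_keys = [g.key for g in run]
        details: dict = {"size": size}

        # Freeze the run and its immediate flanking anchors in every
        # species before mutating, so later events cannot blur this one's
        # signature (flank adjacency is what the detectors key on).
        for sp in ("R", "M"):
            self._mark(sp, run)
            loc = self._find_contiguous(sp, run_keys) if sp != lead else (ck, i)
            if loc is None:
                continue
            sck, si = loc
            chrom = self.genomes[sp][sck]
            flanks = ([chrom[si - 1]] if si >= 1 else []) + (
                [chrom[si + size]] if si + size < len(chrom) else [])
            self._mark(sp, flanks)

        if code in ("A", "B", "C"):
            dest_ck = ck
            for sp in species_list:
                sck, si = (ck, i) if sp == lead else self._find_contiguous(sp, run_keys)
                chrom = self.genomes[sp][sck]
                seg = chrom[si:si + size]
                for g in seg:
                    g.strand = "-" if g.strand == "+" else "+"
                self.genomes[sp][sck] = chrom[:si] + seg[::-1] + chrom[si + size:]
        elif code in ("D", "E", "F", "iT", "T"):
            inter = code in ("iT", "T")
            _ck2, _j, anchor_key = self._pick_insertion(
                lead, exclude_ck=ck if inter else None,
                same_ck=None if inter else ck,
                avoid=None if inter else (ck, i, i + size),
                mirror=mirror,
            )
            dest_ck = None
            for sp in species_list:
                sck, si = (ck, i) if sp == lead else self._find_contiguous(sp, run_keys)
                chrom = self.genomes[sp][sck]
                seg = chrom[si:si + size]
                self.genomes[sp][sck] = chrom[:si] + chrom[si + size:]
                dest_ck = self._insert_at_anchor(sp, anchor_key, seg)
        elif code == "Dup":
            _ck2, _j, anchor_key = self._pick_insertion(
                lead, exclude_ck=None, avoid=(ck, i, i + size), mirror=mirror)
            dest_ck = None
            copies_by_species: dict[str, list[_Gene]] = {}
            tags = []
            for g in run:
                self.dup_counter[g.key] = self.dup_counter.get(g.key, 0) + 1
                tags.append(self.dup_counter[g.key])
            for sp in species_list:
                copies = [
                    _Gene(g.group, g.subgenome, g.anc, g.gene_class, g.strand, tag)
                    for g, tag in zip(run, tags)
                ]
                dest_ck = self._insert_at_anchor(sp, anchor_key, copies)
                copies_by_species[sp] = copies
                self._mark(sp, copies)
            details["copy_genes"] = {
                sp: [g.gene_id(sp) for g in copies_by_species[sp]]
                for sp in species_list
            }
        elif code == "Del":
            dest_ck = ck
            for sp in species_list:
                sck, si = (ck, i) if sp == lead else self._find_contiguous(sp, run_keys)
                chrom = self.genomes[sp][sck]
                self.genomes[sp][sck] = chrom[:si] + chrom[si + size:]
        else:  # pragma: no cover
            raise ValueError(f"unknown event code {code}")

        src_name = f"{lead}{ck[0]}{ck[1]}"
        dst_name = f"{lead}{dest_ck[0]}{dest_ck[1]}" if dest_ck else src_name
        return RearrangementEvent(
            code=code,
            genes=[g.gene_id(lead) for g in run],
            chromosomes=(src_name, dst_name),
            branch=branch,
            details=details,
        )


# ---------------------------------------------------------------------------
# Main entry point
# ---------------------------------------------------------------------------

def simulate_evolution(
    params: EvolutionParams,
) -> tuple[GenomeAnnotation, GenomeAnnotation, SimTruth]:
    """Simulate the full WGD + fractionation + rearrangement history.

    Returns the annotations of species R and M plus the ground truth.
    Identical ``params`` (including the seed) give byte-identical results.
    """
    rng = np.random.default_rng(params.seed)
    K, G = params.n_chromosome_pairs, params.genes_per_chromosome

    # R-gene labels are an ancestral property shared by all descendants.
    r_gene = rng.random((K, G)) < params.r_gene_fraction
    strands = np.where(rng.random((K, G)) < 0.5, "+", "-")

    # Post-WGD genome: two homoeologous copies per ancestral chromosome.
    post_wgd: dict[tuple, list[_Gene]] = {}
    for k in range(1, K + 1):
        for sub in ("D", "S"):
            post_wgd[(k, sub)] = [
                _Gene(k, sub, a, "R" if r_gene[k - 1, a] else "gene",
                      strands[k - 1, a])
                for a in range(G)
            ]

    frac_shared = (params.wgd_time - params.speciation_time) / params.wgd_time
    deletion_log: list[dict] = []

    # Shared fractionation (between WGD and speciation).
    p_probs = {"D": params.deletion_prob_dominant, "S": params.deletion_prob_subdominant}
    for ck in sorted(post_wgd):
        p1, _ = _hazard_split(p_probs[ck[1]], frac_shared)
        runs = _deletion_runs(len(post_wgd[ck]), p1, params.deletion_run_mean,
                              params.proximal_multiplier, rng)
        post_wgd[ck] = _apply_deletions(
            post_wgd[ck], runs, "RM", f"RM{ck[0]}{ck[1]}", deletion_log, "shared")

    # Speciation: deep-copy into R and M, then lineage-specific fractionation.
    genomes: dict[str, dict[tuple, list[_Gene]]] = {"R": {}, "M": {}}
    for sp in ("R", "M"):
        for ck, chrom in post_wgd.items():
            genomes[sp][ck] = [
                _Gene(g.group, g.subgenome, g.anc, g.gene_class, g.strand, g.dup_tag)
                for g in chrom
            ]
    for sp in ("R", "M"):
        for ck in sorted(genomes[sp]):
            _, p2 = _hazard_split(p_probs[ck[1]], frac_shared)
            runs = _deletion_runs(len(genomes[sp][ck]), p2, params.deletion_run_mean,
                                  params.proximal_multiplier, rng)
            genomes[sp][ck] = _apply_deletions(
                genomes[sp][ck], runs, sp, f"{sp}{ck[0]}{ck[1]}", deletion_log,
                "lineage")

    # Rearrangements.
    placer = _EventPlacer(genomes, params, rng)
    branches = sorted(params.branch_probs)
    probs = np.array([params.branch_probs[b] for b in branches], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("branch_probs must have positive mass")
    probs = probs / probs.sum()
    event_log: list[RearrangementEvent] = []
    for code in _CODE_ORDER:
        for _ in range(params.rearrangement_counts.get(code, 0)):
            branch = str(rng.choice(branches, p=probs))
            event_log.append(placer.apply(code, branch))

    # Final annotations with coordinates.
    annots = {}
    centromeres: dict[str, float] = {}
    for sp in ("R", "M"):
        rows = []
        for ck in sorted(genomes[sp]):
            chrom_name = f"{sp}{ck[0]}{ck[1]}"
            chrom = genomes[sp][ck]
            n = len(chrom)
            gaps = rng.exponential(
                max(params.mean_intergenic_bp - params.gene_length_bp, 1.0), n
            ) + params.gene_length_bp
            starts = 25_001 + np.concatenate([[0.0], np.cumsum(gaps[:-1])])
            starts = starts.astype(np.int64)
            for g, s in zip(chrom, starts):
                rows.append({
                    "gene_id": g.gene_id(sp), "chromosome": chrom_name,
                    "start": int(s), "end": int(s) + params.gene_length_bp - 1,
                    "strand": g.strand, "species": sp, "homoeo_group": ck[0],
                    "subgenome": ck[1], "gene_class": g.gene_class,
                    "anc_id": g.group * 100_000 + g.anc,
                })
            centromeres[chrom_name] = float(starts[n // 2]) if n else 0.0
        annots[sp] = GenomeAnnotation(pd.DataFrame(rows))

    truth = SimTruth(
        deletion_log=pd.DataFrame(
            deletion_log,
            columns=["species", "chromosome", "group", "subgenome", "anc",
                     "gene", "phase", "run_start", "run_length", "cause"],
        ),
        event_log=event_log,
        paralogue_map=_paralogue_map(genomes),
        orthologue_map=_orthologue_map(genomes),
        true_divergence_times={
            "ortholog": params.speciation_time,
            "paralog": params.wgd_time,
        },
        centromere_positions=centromeres,
    )
    return annots["R"], annots["M"], truth


def _paralogue_map(genomes: dict[str, dict[tuple, list[_Gene]]]) -> pd.DataFrame:
    rows = []
    for sp in ("R", "M"):
        surviving: dict[tuple, dict[str, str]] = {}
        for ck, chrom in genomes[sp].items():
            for g in chrom:
                if g.dup_tag == 0:
                    surviving.setdefault((g.group, g.anc), {})[g.subgenome] = g.gene_id(sp)
        for (group, anc), copies in sorted(surviving.items()):
            if "D" in copies and "S" in copies:
                rows.append({"species": sp, "group": group, "anc": anc,
                             "gene_d": copies["D"], "gene_s": copies["S"]})
    return pd.DataFrame(rows, columns=["species", "group", "anc", "gene_d", "gene_s"])


def _orthologue_map(genomes: dict[str, dict[tuple, list[_Gene]]]) -> pd.DataFrame:
    present: dict[str, set] = {}
    for sp in ("R", "M"):
        present[sp] = {
            g.key for chrom in genomes[sp].values() for g in chrom if g.dup_tag == 0
        }
    rows = []
    for key in sorted(present["R"] & present["M"]):
        group, sub, anc, _ = key
        g = _Gene(group, sub, anc, "gene", "+")
        rows.append({"group": group, "subgenome": sub, "anc": anc,
                     "gene_r": g.gene_id("R"), "gene_m": g.gene_id("M")})
    return pd.DataFrame(rows, columns=["group", "subgenome", "anc", "gene_r", "gene_m"])
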