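"""Score detected rearrangements against the simulator's truth log.

Gene identity across the two simulated species is carried by the id
suffix after the species letter (group, subgenome, ancestral ordinal),
so a truth event and a detected event are compared on suffix sets: a
truth event is recovered when some detected event has the same code and
covers at least ``min_overlap`` of its genes.
"""

from __future__ import annotations

from subgenomics.rearrangements import RearrangementEvent


def _suffixes(genes) -> set[str]:
    return {g[1:] for g in genes}


def _truth_gene_sets(event: RearrangementEvent) -> set[str]:
    s = _suffixes(event.genes)
    for genes in event.details.get("copy_genes", {}).values():
        s |= _suffixes(genes)
    return s


def event_recovery(
    truth_events: list[RearrangementEvent],
    detected_events: list[RearrangementEvent],
    min_overlap: float = 0.8,
) -> dict:
    """Fraction of truth events recovered with the correct code.

    Also reports branch-assignment accuracy over the recovered events
    whose detected counterpart carries a branch label.
    """
    recovered = 0
    branch_total = branch_correct = 0
    matches = []
    for te in truth_events:
        t_suf = _truth_gene_sets(te)
        n_core = max(len(_suffixes(te.genes)), 1)
        best = None
        for de in detected_events:
            if de.code != te.code:
                continue
            overlap = len((_suffixes(de.genes) | _truth_gene_sets(de)) & t_suf)
            if min(overlap, n_core) / n_core >= min_overlap:
                best = de
                break
        matches.append((te, best))
        if best is not None:
            recovered += 1
            if best.branch != "unassigned":
                branch_total += 1
                branch_correct += best.branch == te.branch
    return {
        "n_truth": len(truth_events),
        "n_detected": len(detected_events),
        "n_recovered": recovered,
        "recovery": recovered / len(truth_events) if truth_events else 1.0,
        "branch_accuracy": branch_correct / branch_total if branch_total else None,
        "n_branch_scored": branch_total,
        "matches": matches,
    }
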