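"""Convenience wrappers chaining the simulation and tree stages."""

from __future__ import annotations

from neoy import haplotypes as H
from neoy import trees as T
from neoy.simulate import Cohort


def cohort_pseudorefs(cohort: Cohort) -> dict[str, str]:
    """Haploid pseudo-reference sequences for every simulated haplotype."""
    return {lab: cohort.haplotype_sequence(lab).tobytes().decode()
            for lab in cohort.all_haplotypes()}


def cohort_window_trees(cohort: Cohort, window: int = 200_000,
                        ) -> tuple[list[T.WindowTree], list[T.TopologyClass], dict[str, str]]:
    """NJ trees and topology classes for every window of a cohort."""
    seqs = cohort_pseudorefs(cohort)
    groups = cohort.haplotype_class()
    outgroup = [lab for lab, cls in groups.items() if cls == "outgroup"]
    wts = [T.infer_tree(aln, outgroup) for aln in T.window_alignments(seqs, window)]
    topos = [T.classify_topology(wt, groups) for wt in wts if not wt.star]
    wts = [wt for wt in wts if not wt.star]
    return wts, topos, groups


def date_cohort(cohort: Cohort, window: int = 200_000, seed: int = 0,
                n_boot: int = 0) -> dict[str, H.AgeEstimate]:
    """Simulate-to-age shortcut used by recovery tests."""
    wts, topos, groups = cohort_window_trees(cohort, window)
    return H.date_haplotypes(wts, topos, groups,
                             species_split_kya=cohort.config.species_split_kya,
                             seed=seed, n_boot=n_boot)
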