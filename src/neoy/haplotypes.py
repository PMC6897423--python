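"""Haplotype painting along windows, breakpoints, and branch-length dating.

Each window tree is reduced to its maximal exclusively-neo-Y clades;
neo-Ys in the same clade share a haplotype label, labels are matched
across adjacent windows by member overlap, and solo windows flanked by
matching labels are smoothed over.  Dating takes, per eligible window,
the species-split node *s* and the node *h* separating a Y group from its
neo-X sister, and converts the median of h-to-tip / (s-to-h + h-to-tip)
into an age by multiplying by the assumed species-split time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

from neoy.trees import TopologyClass, WindowTree, _find_clade

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# clade counting and painting
# ---------------------------------------------------------------------------

def maximal_y_clades(tree: dendropy.Tree, y_tips: set[str]) -> list[frozenset[str]]:
    """Maximal clades whose leaves are exclusively neo-Y tips.

    A paraphyletic scatter of k singleton tips yields k clades.
    """
    if not y_tips:
        raise ValueError("no neo-Y tips")
    clades: list[frozenset[str]] = []

    def visit(node) -> None:
        leafset = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if leafset & y_tips and leafset <= y_tips:
            clades.append(leafset)
            return  # maximal: do not descend
        for ch in node.child_nodes():
            visit(ch)

    visit(tree.seed_node)
    return clades


def count_neoY_clades(tree: dendropy.Tree, y_tips: set[str]) -> int:
    return len(maximal_y_clades(tree, y_tips))


@dataclass
class HaplotypePainting:
    samples: list[str]
    windows: list[tuple[int, int]]
    labels: dict[str, list[str]]  # sample -> per-window label
    breakpoints: dict[str, list[int]] = field(default_factory=dict)

    def compute_breakpoints(self) -> None:
        self.breakpoints = {}
        for s in self.samples:
            labs = self.labels[s]
            bps = [self.windows[i][0] for i in range(1, len(labs))
                   if labs[i] != labs[i - 1]]
            self.breakpoints[s] = bps


def smooth_solo(labels: list[str]) -> list[str]:
    """Reassign any length-1 run flanked on both sides by one same label.

    The left flank is read from the already-smoothed output (single
    left-to-right pass), which makes the operation idempotent.
    """
    out = list(labels)
    for i in range(1, len(out) - 1):
        if (labels[i] != out[i - 1] and labels[i] != labels[i + 1]
                and out[i - 1] == labels[i + 1]):
            out[i] = out[i - 1]
    return out


def paint_haplotypes(window_trees: list[WindowTree], y_tips: set[str],
                     smooth: bool = True) -> HaplotypePainting:
    """Assign per-window haplotype labels to every neo-Y sample.

    Labels are persistent across windows: each window's maximal Y-only
    clades are matched to the previous window's by maximal member overlap
    (ties resolved toward the left window's label); unmatched clades open
    a fresh label.
    """
    samples = sorted(y_tips)
    windows = [(wt.start, wt.end) for wt in window_trees]
    per_window: list[dict[str, str]] = []
    prev: dict[frozenset[str], str] = {}
    counter = 0
    for wt in window_trees:
        clades = maximal_y_clades(wt.tree, y_tips)
        assignment: dict[frozenset[str], str] = {}
        # candidate matches ordered by overlap (desc), then left label order
        cands = sorted(
            ((len(c & p), lab, c) for c in clades for p, lab in prev.items() if c & p),
            key=lambda t: (-t[0], t[1]),
        )
        used_labels: set[str] = set()
        for _, lab, c in cands:
            if c in assignment or lab in used_labels:
                continue
            assignment[c] = lab
            used_labels.add(lab)
        for c in clades:
            if c not in assignment:
                assignment[c] = f"H{counter}"
                counter += 1
        per_window.append({s: lab for c, lab in assignment.items() for s in c})
        prev = {c: lab for c, lab in assignment.items()}
    labels = {s: [pw[s] for pw in per_window] for s in samples}
    if smooth:
        labels = {s: smooth_solo(v) for s, v in labels.items()}
    painting = HaplotypePainting(samples, windows, labels)
    painting.compute_breakpoints()
    return painting


# ---------------------------------------------------------------------------
# dating
# ---------------------------------------------------------------------------

@dataclass
class BranchLengthRecord:
    window: tuple[int, int]
    group: str
    s_to_h: float
    h_to_tip_neoX: float
    h_to_tip_neoY: float

    @property
    def normalized(self) -> float:
        denom = self.s_to_h + self.h_to_tip_neoX
        return self.h_to_tip_neoX / denom if denom > 0 else float("nan")


@dataclass
class AgeEstimate:
    group: str
    median_s_to_h: float
    median_h_to_tip: float
    normalized_fraction: float
    age_kya: float
    ci95_kya: tuple[float, float]
    n_windows: int


def haplotype_age(normalized_fraction: float, species_split_kya: float = 250.0) -> float:
    """Final dating step: age = normalized h-to-tip fraction x split age."""
    return normalized_fraction * species_split_kya


def _path_length(ancestor, descendant) -> float:
    total = 0.0
    node = descendant
    while node is not ancestor:
        total += node.edge.length or 0.0
        node = node.parent_node
        if node is None:
            raise ValueError("ancestor does not dominate descendant")
    return total


def branch_lengths_for_group(wt: WindowTree, topo: TopologyClass,
                             groups: dict[str, str], group: str,
                             neoX_class: str = "neoX",
                             outgroup_class: str = "outgroup",
                             ) -> BranchLengthRecord | None:
    """Measure s-to-h and h-to-tip lengths for one group in one window.

    Requires a species-sorted window with the group monophyletic; returns
    None otherwise.  h-to-tip lengths are averaged over tips; the neo-X
    variant averages over the neo-X tips of the group's sister clade.
    """
    if not topo.species_sorted or not topo.group_monophyly.get(group):
        return None
    tree = wt.tree
    tree.is_rooted = True
    tips = set(wt.tip_labels())
    g_tips = frozenset(t for t in tips if groups[t] == group)
    ingroup = frozenset(t for t in tips if groups[t] != outgroup_class)
    g_node = _find_clade(tree, g_tips)
    s_node = tree.mrca(taxon_labels=sorted(tips))
    h_node = g_node.parent_node
    if h_node is None:
        return None
    # s must dominate h
    try:
        s_to_h = _path_length(s_node, h_node)
    except ValueError:
        return None
    y_leaves = [lf for lf in g_node.leaf_iter()]
    h_to_tip_y = float(np.mean([_path_length(h_node, lf) for lf in y_leaves]))
    sister_leaves = [lf for ch in h_node.child_nodes() if ch is not g_node
                     for lf in ch.leaf_iter()]
    x_leaves = [lf for lf in sister_leaves if groups[lf.taxon.label] == neoX_class]
    if not x_leaves:
        return None  # no neo-X sister in this window: not datable
    h_to_tip_x = float(np.mean([_path_length(h_node, lf) for lf in x_leaves]))
    return BranchLengthRecord((wt.start, wt.end), group, s_to_h, h_to_tip_x, h_to_tip_y)


def date_haplotypes(window_trees: list[WindowTree], topologies: list[TopologyClass],
                    groups: dict[str, str], species_split_kya: float = 250.0,
                    restrict: tuple[int, int] | None = None,
                    n_boot: int = 1000, seed: int = 0,
                    neoX_class: str = "neoX", outgroup_class: str = "outgroup",
                    ) -> dict[str, AgeEstimate]:
    """Median-of-ratios dating of every Y group, with bootstrap 95% CI.

    Per eligible window the ratio h-to-tip / (s-to-h + h-to-tip) is formed
    (neo-X sister tips), the group's normalized fraction is the median over
    windows, and age = fraction x ``species_split_kya``.  The CI is a
    seeded nonparametric bootstrap over windows of that median-based age.
    ``restrict`` limits windows to a half-open bp interval.
    """
    y_groups = sorted(set(groups.values()) - {neoX_class, outgroup_class})
    rng = np.random.default_rng(seed)
    out: dict[str, AgeEstimate] = {}
    for g in y_groups:
        recs: list[BranchLengthRecord] = []
        for wt, topo in zip(window_trees, topologies):
            if wt.star:
                continue
            if restrict is not None and not (restrict[0] <= wt.start < restrict[1]):
                continue
            rec = branch_lengths_for_group(wt, topo, groups, g, neoX_class,
                                           outgroup_class)
            if rec is not None and np.isfinite(rec.normalized):
                recs.append(rec)
        if not recs:
            log.warning("group %s: no eligible windows for dating", g)
            out[g] = AgeEstimate(g, float("nan"), float("nan"), float("nan"),
                                 float("nan"), (float("nan"), float("nan")), 0)
            continue
        ratios = np.array([r.normalized for r in recs])
        frac = float(np.median(ratios))
        ages = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(ratios), size=len(ratios))
            ages.append(haplotype_age(float(np.median(ratios[idx])), species_split_kya))
        lo, hi = (np.percentile(ages, [2.5, 97.5]) if ages else (float("nan"),) * 2)
        out[g] = AgeEstimate(
            group=g,
            median_s_to_h=float(np.median([r.s_to_h for r in recs])),
            median_h_to_tip=float(np.median([r.h_to_tip_neoX for r in recs])),
            normalized_fraction=frac,
            age_kya=haplotype_age(frac, species_split_kya),
            ci95_kya=(float(lo), float(hi)),
            n_windows=len(recs),
        )
    return out
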