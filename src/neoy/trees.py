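"""Per-window alignments, distance trees, and topology classification.

Pseudo-references substitute each sample's variant alleles into the
reference, writing IUPAC ambiguity codes at heterozygous sites; windows
are positionally homologous slices, so no realignment is needed.  The
internal tree method is neighbor-joining on Jukes-Cantor-corrected
distances with IUPAC ambiguities scored as fractional matches; externally
computed newick trees can be imported per window instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

log = logging.getLogger(__name__)

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
_CODE_SETS = {v: set(k) for k, v in IUPAC.items()}

# 4-bit base masks: A=1 C=2 G=4 T=8; 0 = missing (N or gap)
_MASK = np.zeros(256, dtype=np.uint8)
for code, bases in _CODE_SETS.items():
    m = 0
    for b in bases:
        m |= {"A": 1, "C": 2, "G": 4, "T": 8}[b]
    _MASK[ord(code)] = m
    _MASK[ord(code.lower())] = m

# expected mismatch probability for every mask pair (ambiguities as
# fractional matches: P(diff) = 1 - |S1 & S2| / (|S1| * |S2|))
_DIFF = np.zeros((16, 16), dtype=np.float64)
_POP = np.array([bin(i).count("1") for i in range(16)])
for m1 in range(1, 16):
    for m2 in range(1, 16):
        _DIFF[m1, m2] = 1.0 - _POP[m1 & m2] / (_POP[m1] * _POP[m2])


def build_pseudoreference(reference: str | np.ndarray,
                          genotypes: dict[int, tuple[str, str] | str | None],
                          mask_missing: bool = False) -> str:
    """Substitute variants into the reference, IUPAC-coding heterozygotes.

    ``genotypes`` maps 1-based positions to either a diploid allele pair, a
    haploid allele, or ``None`` (missing).  Missing calls keep the reference
    base unless ``mask_missing`` is set, in which case they become ``N`` —
    used for neo-Y pseudo-haplotypes where missing sites were removed.
    Indel alleles (length != 1) are ignored.
    """
    seq = bytearray(reference.tobytes() if isinstance(reference, np.ndarray)
                    else reference.encode())
    L = len(seq)
    for pos, gt in genotypes.items():
        if not (1 <= pos <= L):
            raise ValueError(f"position {pos} outside reference")
        if gt is None:
            if mask_missing:
                seq[pos - 1] = ord("N")
            continue
        if isinstance(gt, str):
            a1 = a2 = gt
        else:
            a1, a2 = gt
        if a1 is None or a2 is None:
            if mask_missing:
                seq[pos - 1] = ord("N")
            continue
        if len(a1) != 1 or len(a2) != 1:
            continue  # indel: SNP-only substitution
        code = IUPAC.get(frozenset((a1, a2)))
        if code is None:
            continue  # unresolvable pair (e.g. with N)
        seq[pos - 1] = ord(code)
    return seq.decode()


@dataclass
class WindowAlignment:
    chrom: str
    start: int  # 0-based half-open
    end: int
    sequences: dict[str, str]

    @property
    def has_variation(self) -> bool:
        vals = list(self.sequences.values())
        return any(s != vals[0] for s in vals[1:])


def window_alignments(pseudorefs: dict[str, str], window: int = 200_000,
                      step: int | None = None, chrom: str = "neo") -> list[WindowAlignment]:
    """Coordinate-sliced per-window alignments (final window may be short)."""
    if step is None:
        step = window
    lengths = {len(s) for s in pseudorefs.values()}
    if len(lengths) != 1:
        raise ValueError("pseudo-references must be equal length")
    L = lengths.pop()
    out = []
    for start in range(0, L, step):
        end = min(start + window, L)
        out.append(WindowAlignment(chrom, start, end,
                                   {k: s[start:end] for k, s in pseudorefs.items()}))
        if end == L:
            break
    return out


# ---------------------------------------------------------------------------
# distances and neighbor-joining
# ---------------------------------------------------------------------------

def pairwise_distance(seq1: str, seq2: str, jc_correct: bool = True) -> float:
    m1 = _MASK[np.frombuffer(seq1.encode(), dtype=np.uint8)]
    m2 = _MASK[np.frombuffer(seq2.encode(), dtype=np.uint8)]
    valid = (m1 != 0) & (m2 != 0)
    n = int(valid.sum())
    if n == 0:
        return 0.0
    p = float(_DIFF[m1[valid], m2[valid]].sum()) / n
    if not jc_correct:
        return p
    if p >= 0.75:
        warnings.warn("saturated distance (p >= 0.75); using uncorrected p-distance")
        return p
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def distance_matrix(seqs: dict[str, str], jc_correct: bool = True
                    ) -> tuple[list[str], np.ndarray]:
    labels = sorted(seqs)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(seqs[labels[i]], seqs[labels[j]],
                                                  jc_correct)
    return labels, d


def neighbor_joining(labels: list[str], dist: np.ndarray) -> str:
    """Neighbor-joining returning an unrooted newick string.

    Ties in the Q criterion break on the lexicographically lowest tip pair
    (internal nodes keyed by their smallest descendant label), so output is
    deterministic.
    """
    n = len(labels)
    if n < 2:
        raise ValueError("need >= 2 tips")
    nodes = {i: (labels[i], labels[i]) for i in range(n)}  # id -> (newick, sort key)
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(n) if i < j}
    active = list(range(n))
    next_id = n

    def D(i, j):
        return d[(i, j) if i < j else (j, i)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D(i, j) - r[i] - r[j]
                key = tuple(sorted((nodes[i][1], nodes[j][1])))
                cand = (q, key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = max(0.0, D(i, j) / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2)))
        lj = max(0.0, D(i, j) - li)
        new_nwk = f"({nodes[i][0]}:{li:.10f},{nodes[j][0]}:{lj:.10f})"
        new_key = min(nodes[i][1], nodes[j][1])
        nodes[next_id] = (new_nwk, new_key)
        for k in active:
            if k in (i, j):
                continue
            dk = max(0.0, (D(i, k) + D(j, k) - D(i, j)) / 2.0)
            d[(min(next_id, k), max(next_id, k))] = dk
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    if len(active) == 2:
        i, j = active
        lij = max(0.0, D(i, j))
        return f"({nodes[i][0]}:{lij / 2.0:.10f},{nodes[j][0]}:{lij / 2.0:.10f});"
    # terminal trifurcation of the unrooted tree
    i, j, k = active
    li = max(0.0, (D(i, j) + D(i, k) - D(j, k)) / 2.0)
    lj = max(0.0, (D(i, j) + D(j, k) - D(i, k)) / 2.0)
    lk = max(0.0, (D(i, k) + D(j, k) - D(i, j)) / 2.0)
    parts = sorted(zip((nodes[i][1], nodes[j][1], nodes[k][1]),
                       (f"{nodes[i][0]}:{li:.10f}", f"{nodes[j][0]}:{lj:.10f}",
                        f"{nodes[k][0]}:{lk:.10f}")))
    return "(" + ",".join(p[1] for p in parts) + ");"


@dataclass
class WindowTree:
    chrom: str
    start: int
    end: int
    tree: dendropy.Tree
    star: bool = False  # no variation in the window
    method: str = "internal_nj"

    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


def root_on_outgroup(tree: dendropy.Tree, outgroup: list[str]) -> dendropy.Tree:
    """Root an unrooted tree on the edge separating the outgroup tips."""
    ogset = frozenset(outgroup)
    allset = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    target = None
    target_is_outgroup = True
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        leafset = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if leafset == ogset or leafset == allset - ogset:
            target = node
            target_is_outgroup = leafset == ogset
            break
    if target is None:  # outgroup not clean on the unrooted tree
        target = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label in ogset)
    # place the root at the ingroup end of the separating edge, so the whole
    # stem stays on the outgroup side and the root coincides with the
    # ingroup attachment (species-split) point
    length = target.edge.length or 0.0
    if target_is_outgroup:
        tree.reroot_at_edge(target.edge, length1=0.0, length2=length,
                            update_bipartitions=False)
    else:
        tree.reroot_at_edge(target.edge, length1=length, length2=0.0,
                            update_bipartitions=False)
    return tree


def infer_tree(alignment: WindowAlignment, outgroup: list[str] | str,
               method: str = "internal_nj", newick: str | None = None) -> WindowTree:
    """Build (or import) a rooted tree for one window."""
    if isinstance(outgroup, str):
        outgroup = [outgroup]
    if method == "external_newick":
        if newick is None:
            raise ValueError("external_newick requires a newick string")
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        tree = root_on_outgroup(tree, outgroup)
        return WindowTree(alignment.chrom, alignment.start, alignment.end, tree,
                          method=method)
    if method != "internal_nj":
        raise ValueError(f"unknown method {method!r}")
    if len(alignment.sequences) < 4:
        raise ValueError("need >= 4 tips")
    for og in outgroup:
        if og not in alignment.sequences:
            raise ValueError(f"outgroup {og} absent from alignment")
    if not alignment.has_variation:
        star = "(" + ",".join(f"{lab}:0.0" for lab in sorted(alignment.sequences)) + ");"
        tree = dendropy.Tree.get(data=star, schema="newick", preserve_underscores=True)
        return WindowTree(alignment.chrom, alignment.start, alignment.end, tree,
                          star=True)
    labels, d = distance_matrix(alignment.sequences)
    nwk = neighbor_joining(labels, d)
    tree = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
    tree = root_on_outgroup(tree, outgroup)
    return WindowTree(alignment.chrom, alignment.start, alignment.end, tree)


# ---------------------------------------------------------------------------
# topology classification
# ---------------------------------------------------------------------------

@dataclass
class TopologyClass:
    window: tuple[int, int]
    neoY_monophyletic: bool
    neoY_paraphyletic: bool
    group_monophyly: dict[str, bool]
    excl_monophyly: dict[str, bool] = field(default_factory=dict)
    placement: str = "unsorted"
    species_sorted: bool = False


def clade_sets(tree: dendropy.Tree) -> list[frozenset[str]]:
    out = []
    for node in tree.preorder_node_iter():
        out.append(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return out


def is_monophyletic(tree: dendropy.Tree, tips: set[str]) -> bool:
    if not tips:
        return False
    return frozenset(tips) in clade_sets(tree)


def _prune(tree: dendropy.Tree, drop: set[str]) -> dendropy.Tree:
    t = tree.clone(depth=1)
    keep = [tx for tx in t.taxon_namespace if tx.label not in drop]
    t.retain_taxa(keep)
    return t


def classify_topology(window_tree: WindowTree, groups: dict[str, str],
                      neoX_class: str = "neoX",
                      outgroup_class: str = "outgroup") -> TopologyClass:
    """Classify one window tree's topology.

    ``groups`` maps each tip label to a class: the neo-X class, the
    outgroup class, or a neo-Y group name.  Placement of a monophyletic
    neo-Y clade is read off its sister clade: a pure neo-X sister holding
    all neo-X tips gives ``sister_neoX`` (a subset gives ``within_neoX``),
    likewise for the outgroup/Chr.3; anything mixed is ``unsorted``.
    """
    tree = window_tree.tree
    tips = set(window_tree.tip_labels())
    unassigned = tips - set(groups)
    if unassigned:
        raise ValueError(f"unassigned tips: {sorted(unassigned)}")
    x_tips = {t for t in tips if groups[t] == neoX_class}
    og_tips = {t for t in tips if groups[t] == outgroup_class}
    y_groups = sorted({groups[t] for t in tips} - {neoX_class, outgroup_class})
    y_tips = {t for t in tips if groups[t] in y_groups}

    cs = set(clade_sets(tree))
    mono = frozenset(y_tips) in cs if y_tips else False
    group_mono = {
        g: frozenset(t for t in y_tips if groups[t] == g) in cs for g in y_groups
    }
    excl = {}
    for g in y_groups:
        g_tips = {t for t in y_tips if groups[t] == g}
        rest = y_tips - g_tips
        if rest and g_tips:
            pruned = _prune(tree, g_tips)
            excl[g] = is_monophyletic(pruned, rest)
    placement = _placement(tree, y_tips, x_tips, og_tips) if mono else "unsorted"
    ingroup = x_tips | y_tips
    species_sorted = bool(og_tips) and frozenset(og_tips) in cs and frozenset(ingroup) in cs
    return TopologyClass(
        window=(window_tree.start, window_tree.end),
        neoY_monophyletic=mono,
        neoY_paraphyletic=bool(y_tips) and not mono,
        group_monophyly=group_mono,
        excl_monophyly=excl,
        placement=placement,
        species_sorted=species_sorted,
    )


def _placement(tree: dendropy.Tree, y_tips: set[str], x_tips: set[str],
               og_tips: set[str]) -> str:
    node = _find_clade(tree, frozenset(y_tips))
    if node is None or node.parent_node is None:
        return "unsorted"
    parent = node.parent_node
    sister = {lf.taxon.label for ch in parent.child_nodes() if ch is not node
              for lf in ch.leaf_iter()}
    if sister and sister <= x_tips:
        return "sister_neoX" if sister == x_tips else "within_neoX"
    if sister and sister <= og_tips:
        return "sister_chr3" if sister == og_tips else "within_chr3"
    return "unsorted"


def _find_clade(tree: dendropy.Tree, tipset: frozenset[str]):
    for node in tree.preorder_node_iter():
        if frozenset(lf.taxon.label for lf in node.leaf_iter()) == tipset:
            return node
    return None
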