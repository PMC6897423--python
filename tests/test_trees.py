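import itertools

import dendropy
import numpy as np
import pytest

from neoy import trees as T


class TestPseudoReference:
    def test_hom_alt_substituted(self):
        seq = T.build_pseudoreference("AAAA", {2: ("G", "G")})
        assert seq == "AGAA"

    def test_het_becomes_iupac(self):
        seq = T.build_pseudoreference("AAAA", {2: ("A", "G")})
        assert seq == "ARAA"

    def test_no_variants_identity(self):
        assert T.build_pseudoreference("ACGT", {}) == "ACGT"

    def test_missing_keeps_reference_or_masks(self):
        assert T.build_pseudoreference("AAAA", {2: None}) == "AAAA"
        assert T.build_pseudoreference("AAAA", {2: None}, mask_missing=True) == "ANAA"

    def test_haploid_allele(self):
        assert T.build_pseudoreference("AAAA", {3: "T"}) == "AATA"

    def test_indels_ignored(self):
        assert T.build_pseudoreference("AAAA", {2: ("A", "AT")}) == "AAAA"

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            T.build_pseudoreference("AAAA", {5: ("G", "G")})


class TestWindowAlignments:
    def test_window_count(self):
        seqs = {"a": "A" * 1_000_000, "b": "A" * 1_000_000}
        alns = T.window_alignments(seqs, 200_000)
        assert len(alns) == 5

    def test_partition_identity(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=950))
        alns = T.window_alignments({"a": seq}, 200, step=200)
        assert "".join(a.sequences["a"] for a in alns) == seq
        assert alns[-1].end == 950

    def test_zero_variation_flagged(self):
        seqs = {k: "ACGT" * 25 for k in "abcd"}
        aln = T.window_alignments(seqs, 100)[0]
        assert not aln.has_variation
        wt = T.infer_tree(aln, "a")
        assert wt.star

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            T.window_alignments({"a": "AAA", "b": "AAAA"}, 2)


class TestDistances:
    def test_iupac_half_match(self):
        # R = {A,G} vs A: expected mismatch probability 1/2
        assert T.pairwise_distance("A", "R", jc_correct=False) == pytest.approx(0.5)
        assert T.pairwise_distance("R", "R", jc_correct=False) == pytest.approx(0.5)
        assert T.pairwise_distance("A", "A", jc_correct=False) == 0.0
        assert T.pairwise_distance("A", "G", jc_correct=False) == 1.0

    def test_n_and_gap_skipped(self):
        assert T.pairwise_distance("AN", "AG", jc_correct=False) == 0.0

    def test_jc_correction_value(self):
        p = 0.1
        seq1 = "A" * 100
        seq2 = "G" * 10 + "A" * 90
        d = T.pairwise_distance(seq1, seq2)
        assert d == pytest.approx(-0.75 * np.log(1 - 4 * p / 3))

    def test_saturation_fallback(self):
        with pytest.warns(UserWarning):
            d = T.pairwise_distance("A" * 10, "G" * 10)
        assert d == 1.0


def _ls_best_topology(labels, dist):
    """Least-squares fit of the 3 unrooted 4-taxon topologies (oracle)."""
    (a, b, c, d) = labels
    best, best_err = None, None
    for split in (((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))):
        # 5 branch lengths via least squares on the 6 distances
        import scipy.optimize as opt

        pairs = list(itertools.combinations(labels, 2))
        idx = {lab: i for i, lab in enumerate(labels)}

        def model(x, split=split):
            # x: 4 terminal lengths + 1 internal
            out = []
            for u, v in pairs:
                duv = x[idx[u]] + x[idx[v]]
                same_side = any(u in side and v in side for side in split)
                if not same_side:
                    duv += x[4]
                out.append(duv)
            return np.array(out)

        target = np.array([dist[(u, v)] for u, v in pairs])
        res = opt.least_squares(lambda x: model(x) - target, x0=np.ones(5),
                                bounds=(0, np.inf))
        err = float(np.sum(res.fun ** 2))
        if best_err is None or err < best_err:
            best, best_err = split, err
    return frozenset(frozenset(s) for s in best)


def _nj_split(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    for node in tree.preorder_node_iter():
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(leaves) == 2:
            return leaves
    return None


class TestNeighborJoining:
    def test_spec_matrix_recovers_ab_cd(self):
        labels = list("ABCD")
        dm = {("A", "B"): 2, ("A", "C"): 6, ("A", "D"): 6,
              ("B", "C"): 6, ("B", "D"): 6, ("C", "D"): 2}
        d = np.zeros((4, 4))
        for (u, v), val in dm.items():
            i, j = labels.index(u), labels.index(v)
            d[i, j] = d[j, i] = val
        nwk = T.neighbor_joining(labels, d)
        assert _nj_split(nwk) in (frozenset("AB"), frozenset("CD"))
        assert _ls_best_topology(labels, dm) == frozenset(
            (frozenset("AB"), frozenset("CD")))

    def test_random_additive_matrices_match_ls_oracle(self):
        rng = np.random.default_rng(7)
        labels = list("ABCD")
        n_checked = 0
        for _ in range(200):
            # generate an additive matrix from topology ((A,B),(C,D))
            term = rng.uniform(0.5, 3.0, size=4)
            internal = rng.uniform(0.5, 3.0)
            dm = {}
            for i, j in itertools.combinations(range(4), 2):
                d = term[i] + term[j]
                if {i, j} not in ({0, 1}, {2, 3}):
                    d += internal
                dm[(labels[i], labels[j])] = d
            mat = np.zeros((4, 4))
            for (u, v), val in dm.items():
                a, b = labels.index(u), labels.index(v)
                mat[a, b] = mat[b, a] = val
            nwk = T.neighbor_joining(labels, mat)
            split = _nj_split(nwk)
            assert split in (frozenset("AB"), frozenset("CD"))
            n_checked += 1
        assert n_checked == 200

    def test_ls_oracle_agrees_on_sample(self):
        # spot-check the independent least-squares oracle on 10 instances
        rng = np.random.default_rng(8)
        labels = list("ABCD")
        for _ in range(10):
            term = rng.uniform(0.5, 3.0, size=4)
            internal = rng.uniform(0.5, 3.0)
            dm = {}
            for i, j in itertools.combinations(range(4), 2):
                d = term[i] + term[j]
                if {i, j} not in ({0, 1}, {2, 3}):
                    d += internal
                dm[(labels[i], labels[j])] = d
            assert _ls_best_topology(labels, dm) == frozenset(
                (frozenset("AB"), frozenset("CD")))

    def test_identical_sequences_zero_branches(self):
        # identical a/b on additive p-distances: the tie resolves to the
        # lexicographically lowest pair, giving a zero-length cherry
        base = "ACGT" * 20
        c = "TT" + base[2:]
        d = base[:-4] + "GGCA"
        seqs = {"a": base, "b": base, "c": c, "d": d}
        labels, dm = T.distance_matrix(seqs, jc_correct=False)
        nwk = T.neighbor_joining(labels, dm)
        tree = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
        leafsets = {frozenset(lf.taxon.label for lf in n.leaf_iter()): n
                    for n in tree.preorder_node_iter()}
        cherry = leafsets.get(frozenset(("a", "b")))
        assert cherry is not None
        for lf in cherry.leaf_iter():
            assert (lf.edge.length or 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_too_few_tips(self):
        aln = T.WindowAlignment("neo", 0, 4, {"a": "ACGT", "b": "ACGA", "c": "ACGT"})
        with pytest.raises(ValueError):
            T.infer_tree(aln, "a")


def _wt(newick, start=0, end=100):
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return T.WindowTree("neo", start, end, tree)


GROUPS = {"Y1a": "Y1", "Y1b": "Y1", "Y2a": "Y2", "Y2b": "Y2",
          "Xa": "neoX", "Xb": "neoX", "N1": "outgroup", "N2": "outgroup"}


class TestClassifyTopology:
    def test_monophyletic_sister_neoX(self):
        tc = T.classify_topology(_wt("((Y1a,Y1b),(Xa,Xb));"), GROUPS)
        assert tc.neoY_monophyletic and not tc.neoY_paraphyletic
        assert tc.placement == "sister_neoX"

    def test_paraphyletic(self):
        tc = T.classify_topology(_wt("((Y1a,Xa),(Y1b,Xb));"), GROUPS)
        assert tc.neoY_paraphyletic and not tc.neoY_monophyletic
        assert tc.placement == "unsorted"

    def test_sister_chr3(self):
        tc = T.classify_topology(_wt("(((Y1a,Y1b),(N1,N2)),(Xa,Xb));"), GROUPS)
        assert tc.placement == "sister_chr3"

    def test_within_chr3(self):
        tc = T.classify_topology(_wt("((((Y1a,Y1b),N1),N2),(Xa,Xb));"), GROUPS)
        assert tc.placement == "within_chr3"

    def test_within_neoX(self):
        tc = T.classify_topology(_wt("((((Y1a,Y1b),Xa),Xb),(N1,N2));"), GROUPS)
        assert tc.placement == "within_neoX"

    def test_species_sorted(self):
        tc = T.classify_topology(_wt("(((Y1a,Y1b),(Xa,Xb)),(N1,N2));"), GROUPS)
        assert tc.species_sorted
        tc = T.classify_topology(_wt("(((Y1a,N1),(Xa,Xb)),(Y1b,N2));"), GROUPS)
        assert not tc.species_sorted

    def test_group_and_exclusion_monophyly(self):
        nwk = "(((Y1a,Y1b),(Y2a,Xa)),((Y2b,Xb),(N1,N2)));"
        tc = T.classify_topology(_wt(nwk), GROUPS)
        assert tc.group_monophyly == {"Y1": True, "Y2": False}
        # pruning Y2 leaves Y1 monophyletic
        assert tc.excl_monophyly["Y2"] is True

    def test_tip_order_invariance(self):
        tc1 = T.classify_topology(_wt("((Y1a,Y1b),(Xa,Xb));"), GROUPS)
        tc2 = T.classify_topology(_wt("((Xb,Xa),(Y1b,Y1a));"), GROUPS)
        assert tc1.neoY_monophyletic == tc2.neoY_monophyletic
        assert tc1.placement == tc2.placement

    def test_unassigned_tip_rejected(self):
        with pytest.raises(ValueError):
            T.classify_topology(_wt("((Y1a,ZZZ),(Xa,Xb));"), {**GROUPS})


class TestCohortTopologies:
    def test_group_monophyly_in_segments(self, tree_stage):
        # within group-specific segments, groups are monophyletic in >= 90%
        # of windows
        wts, topos, groups = tree_stage
        flags = [v for tc in topos for v in tc.group_monophyly.values()]
        assert np.mean(flags) >= 0.9

    def test_external_newick_round_trip(self, tree_stage):
        wts, topos, groups = tree_stage
        wt = wts[0]
        nwk = wt.tree.as_string(schema="newick", unquoted_underscores=True)
        aln = T.WindowAlignment("neo", wt.start, wt.end, {})
        og = [lab for lab, cls in groups.items() if cls == "outgroup"]
        wt2 = T.infer_tree(aln, og, method="external_newick", newick=nwk)
        tc1 = T.classify_topology(wt, groups)
        tc2 = T.classify_topology(wt2, groups)
        assert tc1.neoY_monophyletic == tc2.neoY_monophyletic
        assert tc1.group_monophyly == tc2.group_monophyly
        assert tc1.species_sorted == tc2.species_sorted
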