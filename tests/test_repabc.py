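"""Protein distances, neighbor joining, Robinson-Foulds, compatibility
groups, and palindrome detection."""

import itertools

import numpy as np
import pandas as pd
import pytest
import skbio

from repliconkit.assays import reverse_complement
from repliconkit.repabc import (
    PalindromeHit,
    ProteinFamily,
    compatibility_groups,
    find_palindromes,
    nj_tree,
    pairwise_distances,
    palindrome_consensus,
    rf_distance,
    tree_bipartitions,
)
from repliconkit.simulate import RepFamilyConfig, simulate_rep_families


def patristic(tree):
    tips = sorted(t.name for t in tree.tips())
    out = pd.DataFrame(0.0, index=tips, columns=tips)
    for a, b in itertools.combinations(tips, 2):
        d = tree.find(a).distance(tree.find(b))
        out.loc[a, b] = out.loc[b, a] = d
    return out


def random_tree(rng, n_leaves):
    nodes = [skbio.TreeNode(name=f"L{i}", length=float(rng.uniform(0.1, 2.0))) for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b, a = nodes.pop(j), nodes.pop(i)
        p = skbio.TreeNode(length=float(rng.uniform(0.1, 2.0)))
        p.extend([a, b])
        nodes.append(p)
    root = skbio.TreeNode()
    root.extend(nodes)
    return root


class TestPairwiseDistances:
    def test_identical_sequences_are_distance_zero(self):
        fam = ProteinFamily("RepA", {"a": "MKLV", "b": "MKLV"}, aligned=True)
        assert pairwise_distances(fam).loc["a", "b"] == 0.0

    def test_single_substitution_quarter_distance(self):
        fam = ProteinFamily("RepA", {"a": "AAAA", "b": "AAAT"}, aligned=True)
        assert pairwise_distances(fam).loc["a", "b"] == pytest.approx(0.25)

    def test_gap_columns_excluded_when_prealigned(self):
        fam = ProteinFamily("RepA", {"a": "AA-A", "b": "AATT"}, aligned=True)
        # 3 comparable columns, 1 mismatch
        assert pairwise_distances(fam).loc["a", "b"] == pytest.approx(1 / 3)

    def test_matrix_symmetric_zero_diagonal_unit_range(self, rng):
        seqs = {
            f"t{i}": "".join(rng.choice(list("ACDEFGHIKL"), size=30)) for i in range(5)
        }
        d = pairwise_distances(ProteinFamily("RepA", seqs))
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert ((d >= 0) & (d <= 1)).all().all()

    def test_alignment_score_matches_exhaustive_oracle(self, rng):
        """Global affine-gap alignment score equals the best score over all
        alignments enumerated recursively (tiny sequences)."""
        MATCH, MISMATCH, OPEN, EXTEND = 1.0, -1.0, -5.0, -1.0

        def best(a, b, prev_gap):
            # prev_gap: None | 'a' | 'b' -> which sequence the previous column gapped
            if not a and not b:
                return 0.0
            options = []
            if a and b:
                sub = MATCH if a[0] == b[0] else MISMATCH
                options.append(sub + best(a[1:], b[1:], None))
            if a:  # gap in b
                cost = EXTEND if prev_gap == "b" else OPEN
                options.append(cost + best(a[1:], b, "b"))
            if b:  # gap in a
                cost = EXTEND if prev_gap == "a" else OPEN
                options.append(cost + best(a, b[1:], "a"))
            return max(options)

        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = MATCH
        aligner.mismatch_score = MISMATCH
        aligner.open_gap_score = OPEN
        aligner.extend_gap_score = EXTEND
        for _ in range(8):
            a = "".join(rng.choice(list("ACDE"), size=int(rng.integers(2, 6))))
            b = "".join(rng.choice(list("ACDE"), size=int(rng.integers(2, 6))))
            assert aligner.score(a, b) == pytest.approx(best(a, b, None))

    def test_empty_sequence_is_fatal(self):
        with pytest.raises(ValueError, match="empty"):
            ProteinFamily("RepA", {"a": ""})


class TestNeighborJoining:
    ADDITIVE = pd.DataFrame(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
        index=list("ABCD"), columns=list("ABCD"), dtype=float,
    )

    def test_additive_matrix_recovered_exactly(self):
        """The four-point matrix from ((A:1,B:2):1,(C:3,D:4)) comes back with
        identical patristic distances and the AB|CD split."""
        tree = nj_tree(self.ADDITIVE)
        pd.testing.assert_frame_equal(patristic(tree), self.ADDITIVE, atol=1e-9)
        splits = {frozenset(min(s, key=len)) for s in tree_bipartitions(tree)}
        assert splits == {frozenset("AB")} or splits == {frozenset("CD")}

    def test_random_additive_matrices_recovered(self, rng):
        """Patristic matrices of random trees up to 12 leaves are exact NJ
        fixed points (topology and branch lengths)."""
        for _ in range(10):
            n = int(rng.integers(4, 13))
            truth = random_tree(rng, n)
            d = patristic(truth)
            est = nj_tree(d)
            pd.testing.assert_frame_equal(patristic(est), d, atol=1e-8)
            assert rf_distance(est, truth)[0] == 0

    def test_correct_split_for_two_far_pairs(self):
        d = pd.DataFrame(
            [[0, 1, 10, 10], [1, 0, 10, 10], [10, 10, 0, 1], [10, 10, 1, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        splits = tree_bipartitions(nj_tree(d))
        sides = {frozenset(min(s, key=len)) for s in splits}
        assert sides <= {frozenset("AB"), frozenset("CD")}

    def test_star_distances_resolve_deterministically(self):
        d = pd.DataFrame(2.0, index=list("ABCDE"), columns=list("ABCDE"))
        np.fill_diagonal(d.values, 0.0)
        t1, t2 = nj_tree(d), nj_tree(d.loc[list("EDCBA"), list("EDCBA")])
        assert rf_distance(t1, t2)[0] == 0

    def test_agrees_with_reference_nj_implementation(self, rng):
        """Cross-check topology against scikit-bio's neighbor joining on a
        noisy (non-additive) matrix."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        n = 8
        base = patristic(random_tree(rng, n))
        noise = rng.uniform(0, 0.05, size=(n, n))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        d = base + noise
        mine = nj_tree(d)
        ref = skbio_nj(DistanceMatrix(d.to_numpy(), ids=list(d.index)))
        assert rf_distance(mine, ref)[0] == 0

    def test_negative_branch_length_clamped_with_warning(self):
        d = pd.DataFrame(
            [[0, 0.1, 1, 1], [0.1, 0, 10, 10], [1, 10, 0, 2], [1, 10, 2, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        with pytest.warns(UserWarning, match="clamped"):
            tree = nj_tree(d)
        assert all((n.length or 0) >= 0 for n in tree.traverse())

    def test_asymmetric_matrix_is_fatal(self):
        d = self.ADDITIVE.copy()
        d.iloc[0, 1] = 99
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d)


class TestRobinsonFoulds:
    def test_identical_trees_distance_zero(self, rng):
        t = random_tree(rng, 7)
        assert rf_distance(t, t) == (0, 0.0)

    def test_five_leaf_hand_example(self):
        t1 = skbio.TreeNode.read(["((A,B),(C,D),E);"])
        t2 = skbio.TreeNode.read(["((A,C),(B,D),E);"])
        assert rf_distance(t1, t2)[0] == 4

    def test_disjoint_splits_attain_the_upper_bound(self):
        t1 = skbio.TreeNode.read(["(A,B,(C,(D,(E,F))));"])
        t2 = skbio.TreeNode.read(["(A,C,(E,(B,(D,F))));"])
        rf, norm = rf_distance(t1, t2)
        assert rf == 2 * (6 - 3)
        assert norm == 1.0

    def test_symmetry(self, rng):
        t1, t2 = random_tree(rng, 9), random_tree(rng, 9)
        t2 = _relabel_like(t2, t1)
        assert rf_distance(t1, t2)[0] == rf_distance(t2, t1)[0]

    def test_matches_dendropy_oracle(self, rng):
        import dendropy
        from dendropy.calculate import treecompare

        for _ in range(10):
            t1, t2 = random_tree(rng, 8), random_tree(rng, 8)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=str(t1), schema="newick", taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=str(t2), schema="newick", taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            expected = treecompare.symmetric_difference(d1, d2)
            assert rf_distance(t1, t2)[0] == expected

    def test_leaf_set_mismatch_is_fatal_and_lists_difference(self):
        t1 = skbio.TreeNode.read(["((A,B),(C,D),E);"])
        t2 = skbio.TreeNode.read(["((A,B),(C,D),F);"])
        with pytest.raises(ValueError, match="E.*F"):
            rf_distance(t1, t2)


def _relabel_like(tree, other):
    names = sorted(t.name for t in other.tips())
    for tip, name in zip(sorted(tree.tips(), key=lambda t: t.name), names):
        tip.name = name
    return tree


class TestCompatibilityGroups:
    def test_two_groups_without_repc_swap_are_fully_congruent(self):
        sim = simulate_rep_families(RepFamilyConfig(), seed=11)
        rep = compatibility_groups(
            sim.families["RepA"], sim.families["RepB"], cut_height=0.2,
            repc=sim.families["RepC"],
        )
        truth = {t: {"I": 0, "II": 1}[g] for t, g in sim.groups.items()}
        assert rep.groups == truth
        assert rep.rf_repa_repb == 0
        assert rep.rf_repab_repc == 0

    def test_repc_swap_produces_incongruence_but_not_between_repa_repb(self):
        sim = simulate_rep_families(RepFamilyConfig(repc_swaps=[("tA", "tE")]), seed=11)
        rep = compatibility_groups(
            sim.families["RepA"], sim.families["RepB"], cut_height=0.2,
            repc=sim.families["RepC"],
        )
        assert rep.rf_repa_repb == 0
        assert rep.rf_repab_repc > 0

    def test_all_identical_sequences_form_one_group(self):
        seqs = {f"t{i}": "MKLVNNPQ" * 10 for i in range(5)}
        rep = compatibility_groups(
            ProteinFamily("RepA", dict(seqs), aligned=True),
            ProteinFamily("RepB", dict(seqs), aligned=True),
            cut_height=0.1,
        )
        assert set(rep.groups.values()) == {0}

    def test_cut_height_outside_range_warns(self):
        sim = simulate_rep_families(RepFamilyConfig(), seed=3)
        with pytest.warns(UserWarning, match="cut height"):
            rep = compatibility_groups(
                sim.families["RepA"], sim.families["RepB"], cut_height=99.0
            )
        assert set(rep.groups.values()) == {0}


def brute_force_palindromes(seq, min_arm, max_loop, max_mismatch):
    """O(n^3) reference scan: every (start, arm, loop) triple is tested
    directly against the definition, keeping only outward-maximal hits."""
    seq = seq.upper()
    n = len(seq)

    def mism(i, a, loop):
        left = seq[i : i + a]
        right = seq[i + a + loop : i + 2 * a + loop]
        return sum(x != y for x, y in zip(left, reverse_complement(right)))

    hits = []
    for i in range(n):
        for loop in range(max_loop + 1):
            for a in range(min_arm, (n - i - loop) // 2 + 1):
                if mism(i, a, loop) > max_mismatch:
                    continue
                # maximal: the same center cannot support a wider arm
                grow_outward = (
                    i > 0
                    and i + 2 * (a + 1) + loop <= n + 1
                    and mism(i - 1, a + 1, loop) <= max_mismatch
                )
                if grow_outward:
                    continue
                hits.append((i, a, loop))
    return set(hits)


class TestPalindromes:
    def test_perfect_hexamer_inverted_repeat(self):
        hits = find_palindromes("AAACGCGTAAA", min_arm=3, max_loop=0, max_mismatch=0)
        assert [(h.position, h.arm_length, h.loop_length) for h in hits] == [(2, 3, 0)]
        assert hits[0].arm == "ACG"

    def test_looped_inverted_repeat(self):
        hits = find_palindromes("ACGAAACGT", min_arm=3, max_loop=3, max_mismatch=0)
        assert (0, 3, 3) in {(h.position, h.arm_length, h.loop_length) for h in hits}

    def test_matches_brute_force_on_random_sequences(self, rng):
        for trial in range(3):
            seq = "".join(rng.choice(list("ACGT"), size=400))
            mine = {
                (h.position, h.arm_length, h.loop_length)
                for h in find_palindromes(seq, min_arm=4, max_loop=6, max_mismatch=1)
            }
            assert mine == brute_force_palindromes(seq, 4, 6, 1)

    def test_reverse_complement_invariance(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        fwd = find_palindromes(seq, min_arm=4, max_loop=4, max_mismatch=0)
        rev = find_palindromes(reverse_complement(seq), min_arm=4, max_loop=4, max_mismatch=0)
        n = len(seq)
        mapped = {(n - h.end, h.arm_length, h.loop_length) for h in rev}
        assert {(h.position, h.arm_length, h.loop_length) for h in fwd} == mapped

    def test_mismatch_count_reported(self):
        # arms AACGC / GCGTA: revcomp(right) = TACGC, one mismatch to AACGC
        hits = find_palindromes("AACGCGCGTA", min_arm=5, max_loop=0, max_mismatch=1)
        assert any(h.mismatches == 1 for h in hits)

    def test_min_arm_below_three_is_fatal(self):
        with pytest.raises(ValueError):
            find_palindromes("ACGT", min_arm=2)


class TestConsensus:
    def test_majority_with_iupac_ties(self):
        assert palindrome_consensus(["ACGT", "ACGT", "ACGA"]) == "ACGT"
        assert palindrome_consensus(["ACGT", "ACGA"]) == "ACGW"

    def test_recovers_simulated_group_palindrome(self):
        cfg = RepFamilyConfig(palindrome_max_mut=0)
        sim = simulate_rep_families(cfg, seed=5)
        for group, taxa in cfg.groups.items():
            sites = []
            for taxon in taxa:
                seg = sim.palindrome_segments[taxon]
                hits = find_palindromes(seg, min_arm=cfg.palindrome_arm,
                                        max_loop=cfg.palindrome_loop, max_mismatch=0)
                best = max(hits, key=lambda h: h.arm_length)
                sites.append(best.site(seg))
            consensus = palindrome_consensus(sites)
            assert sim.group_palindromes[group] in consensus

    def test_empty_input_is_fatal(self):
        with pytest.raises(ValueError):
            palindrome_consensus([])
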