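"""Alignment/tree I/O, reference numbering, pruning likelihood, optimizer."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from rh2evol import (
    Alignment,
    PhyloTree,
    map_alignment_to_reference_numbering,
    optimize_branch_lengths,
    random_tree,
    read_fasta,
    simulate_alignment,
    site_log_likelihood,
    tree_log_likelihood,
    write_fasta,
)
from rh2evol.alphabet import AA_INDEX


# ---------------------------------------------------------------------------
# Independent brute-force likelihood oracle (exhaustive enumeration; uses
# scipy's expm, not the package's eigendecomposition path)
# ---------------------------------------------------------------------------


def brute_force_site_loglik(tree, states, Q, clamp=None):
    """Likelihood of one site by explicit enumeration over all internal-state
    assignments.  ``states`` maps tip label -> residue (or None = missing);
    ``clamp`` = (internal label, state index) restricts one node."""
    internals = [n for n in tree.preorder() if not n.is_leaf]
    P = {id(n): expm(Q.Q * n.length) for n in tree.preorder() if n.parent is not None}
    total = 0.0
    for combo in itertools.product(range(20), repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        if clamp is not None:
            node, state = clamp
            if assign[id(tree.node(node))] != state:
                continue
        prob = Q.pi[assign[id(tree.root)]]
        for n in tree.preorder():
            for child in n.children:
                a = assign[id(n)]
                if child.is_leaf:
                    obs = states[child.label]
                    prob *= 1.0 if obs is None else P[id(child)][a, AA_INDEX[obs]]
                else:
                    prob *= P[id(child)][a, assign[id(child)]]
        total += prob
    return np.log(total)


def _aln_from_states(states):
    return Alignment(
        names=list(states), rows=[(v if v is not None else "-") for v in states.values()]
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def test_fasta_roundtrip_and_normalization(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(">s1\nmlr.v\n>s2\nMLRGV\n")
    aln = read_fasta(path)
    assert aln.n_sequences == 2 and aln.length == 5
    assert aln.row("s1") == "MLR-V"  # uppercased, '.' -> '-'
    out = tmp_path / "out.fasta"
    write_fasta(aln, out)
    again = read_fasta(out)
    assert again.names == aln.names and again.rows == aln.rows


def test_ragged_alignment_names_offender():
    with pytest.raises(ValueError, match="s2"):
        Alignment(names=["s1", "s2"], rows=["MLRGV", "MLR"])


def test_duplicate_sequence_names_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        Alignment(names=["s1", "s1"], rows=["ML", "MV"])


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def test_newick_basic_topology():
    tree = PhyloTree.from_newick("((A:0.1,B:0.2):0.05,C:0.3);")
    assert sorted(tree.tip_labels()) == ["A", "B", "C"]
    assert len(tree.internal_nodes()) == 2
    assert tree.node("A").length == pytest.approx(0.1)


def test_newick_trifurcation_preserved():
    tree = PhyloTree.from_newick("(A:0.1,B:0.1,C:0.1);")
    assert len(tree.root.children) == 3


def test_newick_roundtrip_random_37_tip_tree():
    tree = random_tree(37, seed=9)
    again = PhyloTree.from_newick(tree.to_newick())
    assert again.to_newick() == tree.to_newick()
    a = {n.label: n.length for n in tree.preorder()}
    b = {n.label: n.length for n in again.preorder()}
    assert a.keys() == b.keys()
    for k in a:
        if a[k] is not None:
            assert b[k] == pytest.approx(a[k], rel=1e-9)  # 10 significant digits


def test_malformed_newick_rejected():
    with pytest.raises(ValueError):
        PhyloTree.from_newick("((A:0.1,B:0.2:0.05,C:0.3);")


def test_duplicate_tip_labels_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        PhyloTree.from_newick("((A:0.1,A:0.2):0.05,C:0.3);")


# ---------------------------------------------------------------------------
# Reference numbering
# ---------------------------------------------------------------------------


def test_reference_gap_columns_are_unnumbered():
    aln = Alignment(names=["ref", "x"], rows=["MN-GT", "MNAGT"])
    smap = map_alignment_to_reference_numbering(aln, "ref")
    assert list(smap.positions) == [1, 2, 0, 3, 4]
    assert smap.unnumbered == [2]


def test_window_31_311_on_354_residue_reference_keeps_281_sites():
    """A full-length (354 aa) ungapped reference numbered 1..354 leaves
    exactly 281 comparable sites inside the 31..311 window."""
    ref = ("ACDEFGHIKLMNPQRSTVWY" * 18)[:354]
    aln = Alignment(names=["bovineRH1", "x"], rows=[ref, ref])
    smap = map_alignment_to_reference_numbering(aln, "bovineRH1")
    assert len(smap.columns_in_window(31, 311)) == 281


def test_window_outside_reference_span_warns_and_is_empty():
    aln = Alignment(names=["ref", "x"], rows=["MNGT", "MNGT"])
    smap = map_alignment_to_reference_numbering(aln, "ref")
    with pytest.warns(UserWarning, match="no numbered columns"):
        assert smap.columns_in_window(31, 311) == []


def test_missing_reference_rejected():
    aln = Alignment(names=["a", "b"], rows=["MN", "MN"])
    with pytest.raises(KeyError):
        map_alignment_to_reference_numbering(aln, "bovineRH1")


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def test_degenerate_two_tip_tree_gives_log_pi(jtt):
    tree = PhyloTree.from_newick("(A:0.0,B:0.0);")
    aln = Alignment(names=["A", "B"], rows=["L", "L"])
    ll = site_log_likelihood(tree, aln, jtt, 0)
    assert ll == pytest.approx(np.log(jtt.pi[AA_INDEX["L"]]), abs=1e-12)


def test_three_taxon_site_likelihood_matches_enumeration(jtt):
    tree = PhyloTree.from_newick("((A:0.1,B:0.2)N1:0.15,C:0.3)R;")
    states = {"A": "L", "B": "M", "C": "V"}
    ll = site_log_likelihood(tree, _aln_from_states(states), jtt, 0)
    assert ll == pytest.approx(brute_force_site_loglik(tree, states, jtt), abs=1e-10)


def test_pruning_matches_enumeration_on_random_small_trees(jtt, rng):
    """Exhaustive-enumeration oracle agreement on 50 random <=4-taxon
    instances, including missing data at tips."""
    from rh2evol.alphabet import AMINO_ACIDS

    for rep in range(50):
        n = int(rng.integers(2, 5))
        tree = random_tree(n, rng=rng, mean_branch_length=0.3)
        states = {
            t: (None if rng.random() < 0.15 else AMINO_ACIDS[rng.integers(20)])
            for t in tree.tip_labels()
        }
        ll = site_log_likelihood(tree, _aln_from_states(states), jtt, 0)
        assert ll == pytest.approx(brute_force_site_loglik(tree, states, jtt), abs=1e-10)


def test_identical_site_more_likely_than_variable_site(jtt):
    tree = PhyloTree.from_newick("((A:0.05,B:0.05):0.05,C:0.05);")
    same = Alignment(names=["A", "B", "C"], rows=["L", "L", "L"])
    diff = Alignment(names=["A", "B", "C"], rows=["L", "L", "M"])
    assert site_log_likelihood(tree, same, jtt, 0) > site_log_likelihood(tree, diff, jtt, 0)


def test_tree_likelihood_sums_sites_and_is_order_invariant(jtt, rng):
    tree = random_tree(4, rng=rng, mean_branch_length=0.2)
    truth = simulate_alignment(tree, jtt, 10, seed=5)
    aln = truth.tip_alignment
    total = tree_log_likelihood(tree, aln, jtt)
    per_site = sum(site_log_likelihood(tree, aln, jtt, c) for c in range(10))
    assert total == pytest.approx(per_site, abs=1e-8)
    brute = sum(
        brute_force_site_loglik(tree, {t: aln.row(t)[c] for t in aln.names}, jtt)
        for c in range(10)
    )
    assert total == pytest.approx(brute, abs=1e-8)
    perm = list(rng.permutation(10))
    assert tree_log_likelihood(tree, aln, jtt, columns=perm) == pytest.approx(total, abs=1e-12)


def test_single_column_tree_likelihood_equals_site_likelihood(jtt):
    tree = PhyloTree.from_newick("((A:0.1,B:0.2):0.15,C:0.3);")
    aln = Alignment(names=["A", "B", "C"], rows=["L", "M", "V"])
    assert tree_log_likelihood(tree, aln, jtt) == pytest.approx(
        site_log_likelihood(tree, aln, jtt, 0), abs=1e-12
    )


def test_empty_column_selection_rejected(jtt):
    tree = PhyloTree.from_newick("(A:0.1,B:0.1);")
    aln = Alignment(names=["A", "B"], rows=["L", "M"])
    with pytest.raises(ValueError, match="no alignment columns"):
        tree_log_likelihood(tree, aln, jtt, columns=[])


def test_tip_without_sequence_rejected(jtt):
    tree = PhyloTree.from_newick("((A:0.1,B:0.2):0.15,C:0.3);")
    aln = Alignment(names=["A", "B"], rows=["L", "M"])
    with pytest.raises(ValueError, match="C"):
        tree_log_likelihood(tree, aln, jtt)


def test_likelihood_invariant_to_rerooting_along_branch(jtt):
    """Pulley principle: sliding the root along a branch leaves the
    likelihood of a reversible model unchanged."""
    aln = Alignment(names=["A", "B", "C"], rows=["LMV", "LIV", "MMV"])
    t1 = PhyloTree.from_newick("((A:0.1,B:0.2):0.15,C:0.30);")
    t2 = PhyloTree.from_newick("((A:0.1,B:0.2):0.40,C:0.05);")
    t3 = PhyloTree.from_newick("((A:0.1,B:0.2):0.01,C:0.44);")
    lls = [tree_log_likelihood(t, aln, jtt) for t in (t1, t2, t3)]
    assert lls[0] == pytest.approx(lls[1], abs=1e-8)
    assert lls[0] == pytest.approx(lls[2], abs=1e-8)


def test_no_underflow_on_40_taxa_281_sites(jtt):
    """Per-node scaling keeps a 40-taxon x 281-site likelihood finite."""
    tree = random_tree(40, seed=17, mean_branch_length=0.15)
    truth = simulate_alignment(tree, jtt, 281, seed=18)
    ll = tree_log_likelihood(tree, truth.tip_alignment, jtt)
    assert np.isfinite(ll) and ll < 0


# ---------------------------------------------------------------------------
# Branch-length optimization
# ---------------------------------------------------------------------------


def test_identical_sequences_drive_lengths_to_lower_bound(jtt):
    tree = PhyloTree.from_newick("(A:0.1,B:0.1);")
    aln = Alignment(names=["A", "B"], rows=["MLRGVCT" * 10] * 2)
    result = optimize_branch_lengths(tree, aln, jtt)
    for _, _, final in result.branch_table:
        assert final < 1e-6


def test_loglik_trace_is_nondecreasing(jtt):
    tree = random_tree(5, seed=2, mean_branch_length=0.2)
    truth = simulate_alignment(tree, jtt, 100, seed=3)
    result = optimize_branch_lengths(tree, truth.tip_alignment, jtt)
    trace = np.array(result.loglik_trace)
    assert np.all(np.diff(trace) >= -1e-9)
    assert result.log_likelihood >= trace[0]


def test_branch_length_recovery_on_simulated_data(jtt):
    """With 5000 sites on a 6-tip tree each true length is recovered within
    +/-20% or +/-0.02, whichever is larger."""
    tree = random_tree(6, seed=3, mean_branch_length=0.2)
    truth = simulate_alignment(tree, jtt, 5000, seed=11)
    result = optimize_branch_lengths(tree, truth.tip_alignment, jtt)
    est = {n.label: n.length for n in result.tree.preorder() if n.parent is not None}
    for node in tree.preorder():
        if node.parent is None:
            continue
        tol = max(0.2 * node.length, 0.02)
        assert abs(est[node.label] - node.length) <= tol, node.label
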