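"""λmax shifts, mutation explanation, critical-site tracing, site classes."""

import math

import pytest

from rh2evol import (
    PhyloTree,
    branch_shifts,
    classify_explained,
    classify_sites,
    count_shifts,
    fraction_explained,
    trace_site_substitutions,
)
from rh2evol.phylo_core import TreeNode
from rh2evol.spectral_tuning import MutationAssay, parse_mutation


def _annotated(newick, lambdas):
    tree = PhyloTree.from_newick(newick)
    for label, lam in lambdas.items():
        tree.node(label).lambda_max = lam
    return tree


# ---------------------------------------------------------------------------
# Shifts
# ---------------------------------------------------------------------------


def test_branch_shift_blue_shift_significant():
    """503 -> 488 across one branch is a -15 nm significant (not large) shift."""
    tree = _annotated("(AncJawedFish:1)AncAgnatha;", {"AncAgnatha": 503, "AncJawedFish": 488})
    records, skipped = branch_shifts(tree)
    (rec,) = records
    assert rec.delta == -15 and rec.significant and not rec.large
    assert not skipped


def test_zero_delta_not_significant():
    tree = _annotated("(child:1)parent;", {"parent": 488, "child": 488})
    (rec,) = branch_shifts(tree)[0]
    assert rec.delta == 0 and not rec.significant


def test_large_red_shift_flags_both():
    tree = _annotated(
        "(AncEuteleost4:1)AncEuteleost2;", {"AncEuteleost2": 489, "AncEuteleost4": 524}
    )
    (rec,) = branch_shifts(tree)[0]
    assert rec.delta == 35 and rec.significant and rec.large


def test_unannotated_endpoints_skipped_and_reported():
    tree = _annotated("((a:1,b:1)m:1)r;", {"r": 500, "m": 510, "a": 505})
    records, skipped = branch_shifts(tree)
    assert len(records) == 2
    assert skipped == [("m", "b")]


def test_tree_without_annotations_rejected():
    tree = PhyloTree.from_newick("(a:1,b:1)r;")
    with pytest.raises(ValueError, match="no λmax"):
        branch_shifts(tree)


def test_count_shifts_empty_input():
    assert count_shifts([]) == (0, 0, [])


def test_count_shifts_monotone_in_threshold(fig1):
    records, _ = branch_shifts(fig1.tree)
    counts = [count_shifts(records, significance=th)[0] for th in (5, 10, 15, 30, 50)]
    assert counts == sorted(counts, reverse=True)


def test_fig1_census_sixteen_significant_three_large(fig1):
    records, skipped = branch_shifts(fig1.tree)
    n_sig, n_large, listing = count_shifts(records)
    assert (n_sig, n_large) == (16, 3)
    assert not skipped
    assert abs(listing[0].delta) == 35  # sorted by |delta| descending


def test_fig1_significant_set_matches_thick_branch_flags(fig1):
    """The fixture's thick-branch metadata marks exactly the significant
    branches the census finds."""
    records, _ = branch_shifts(fig1.tree)
    sig = {r.descendant_id for r in records if r.significant}
    assert sig == fig1.thick_branches


def test_deltas_telescope_along_root_to_tip_paths(fig1):
    records, _ = branch_shifts(fig1.tree)
    delta = {r.descendant_id: r.delta for r in records}
    root = fig1.tree.root
    for tip in fig1.tree.tips():
        total, node = 0, tip
        while node is not root:
            total += delta[node.label]
            node = node.parent
        assert total == tip.lambda_max - root.lambda_max


def test_ancestral_lambda_range_474_to_524(fig1):
    """Descendant ancestral pigments (numbered nodes 2-13) span 474-524 nm."""
    lams = [fig1.tree.node(fig1.node_numbers[i]).lambda_max for i in range(2, 14)]
    assert min(lams) == 474 and max(lams) == 524
    assert fig1.tree.node(fig1.node_numbers[1]).lambda_max == 503


# ---------------------------------------------------------------------------
# Mutation explanation
# ---------------------------------------------------------------------------


def _assay(anc_lambda, label, mutant, desc_lambda, anc="X", desc="Y"):
    return MutationAssay(
        ancestral_id=anc,
        ancestral_lambda=anc_lambda,
        mutations=tuple(parse_mutation(m) for m in label.split("/")),
        mutant_lambda=mutant,
        descendant_id=desc,
        descendant_lambda=desc_lambda,
    )


def test_single_mutation_within_tolerance_is_explained():
    table, n_single, n_multi = classify_explained([_assay(503, "E122Q", 486, 488)])
    assert table.explained.iloc[0] and (n_single, n_multi) == (1, 0)


def test_mutation_outside_tolerance_not_explained():
    table, n_single, n_multi = classify_explained([_assay(488, "M207L", 480, 468)])
    assert not table.explained.iloc[0] and n_single == 0


def test_exact_match_explained_and_incomplete_row_unevaluable():
    rows = [
        _assay(500, "E122Q", 490, 490),
        MutationAssay("A", 500.0, (parse_mutation("E122Q"),), None, "B", 490.0),
    ]
    table, n_single, _ = classify_explained(rows)
    assert table.explained.iloc[0]
    assert not table.evaluable.iloc[1]
    assert n_single == 1


def test_tolerance_zero_and_infinite_bracket_the_classification(table1):
    strict, n1, n2 = classify_explained(table1, tolerance=0)
    assert n1 + n2 == 0  # no mutant exactly equals its descendant in the table
    loose, m1, m2 = classify_explained(table1, tolerance=math.inf)
    assert m1 + m2 == len(table1)


def test_table1_explained_pattern_matches_bold_rows(table1):
    """classify_explained reproduces the 8 bold rows of the assay table."""
    from rh2evol.synthetic_data import fixture_table1_frame

    table, n_single, n_multi = classify_explained(table1)
    assert n_single + n_multi == 8
    bold = fixture_table1_frame()["bold"].astype(bool).tolist()
    assert table.explained.tolist() == bold


@pytest.mark.parametrize(
    "mutant, expected_nm, expected_pct",
    [(504, 15, 43), (509, 20, 57), (510, 21, 60)],
)
def test_fraction_of_large_shift_explained(mutant, expected_nm, expected_pct):
    """Mutants of the 489 -> 524 nm transition explain 43/57/60% of 35 nm."""
    nm, pct = fraction_explained(489, mutant, 524)
    assert (nm, pct) == (expected_nm, expected_pct)


def test_fraction_explained_zero_contribution():
    assert fraction_explained(489, 489, 524) == (0, 0)


def test_fraction_explained_rounds_half_away_from_zero():
    assert fraction_explained(0, 1, 8)[1] == 13  # 12.5 -> 13
    assert fraction_explained(0, -1, 8)[1] == -13


def test_fraction_explained_zero_total_shift_rejected():
    with pytest.raises(ValueError):
        fraction_explained(488, 490, 488)


# ---------------------------------------------------------------------------
# Critical-site tracing
# ---------------------------------------------------------------------------


def test_single_substitution_event_emitted():
    tree = _annotated("(c:1)p;", {"p": 500, "c": 490})
    events, counts, skipped = trace_site_substitutions(
        tree, {"p": {122: "E"}, "c": {122: "Q"}}, sites=(122,)
    )
    assert [e.label for e in events] == ["E122Q"]
    assert counts["E122Q"] == 1 and not skipped


def test_identical_states_emit_no_events():
    tree = PhyloTree.from_newick("(c:1)p;")
    events, counts, _ = trace_site_substitutions(
        tree, {"p": {122: "E", 207: "M"}, "c": {122: "E", 207: "M"}}, sites=(122, 207)
    )
    assert not events and not counts


def test_missing_state_skips_branch_with_report():
    tree = PhyloTree.from_newick("(c:1)p;")
    _, _, skipped = trace_site_substitutions(tree, {"p": {122: "E"}}, sites=(122,))
    assert skipped == [("p", "c", 122)]


def test_invalid_state_rejected():
    tree = PhyloTree.from_newick("(c:1)p;")
    with pytest.raises(ValueError, match="invalid amino acid"):
        trace_site_substitutions(tree, {"p": {122: "E"}, "c": {122: "Z"}}, sites=(122,))


def test_fig1_critical_site_event_counts(fig1):
    """The composite tree carries E122Q x3, Q122E x4, M207L x2, A292S x1."""
    _, counts, skipped = trace_site_substitutions(fig1.tree, fig1.node_states)
    assert dict(counts) == {"E122Q": 3, "Q122E": 4, "M207L": 2, "A292S": 1}
    assert not skipped


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------


def test_identical_sequences_have_no_polymorphic_sites():
    n_poly, n_mono, frac, _ = classify_sites(
        {"a": "MLRGV", "b": "MLRGV"}, site_numbers=[31, 32, 33, 34, 35]
    )
    assert (n_poly, n_mono, frac) == (0, 5, 0.0)


def test_adaptive_fraction_hand_enumerated():
    """10 sites, 4 polymorphic, 1 of them critical -> 25.0%."""
    sites = [120, 121, 122, 123, 124, 125, 126, 127, 128, 129]
    seqs = {
        "a": "AAEAAAALMA",
        "b": "AAQAVAALIA",
        "c": "CAQAVAALMA",
    }
    n_poly, n_mono, frac, listing = classify_sites(seqs, sites)
    assert (n_poly, n_mono) == (4, 6)
    assert frac == 25.0
    assert set(listing[listing.polymorphic].site) == {120, 122, 124, 128}


def test_missing_states_do_not_create_polymorphism():
    n_poly, _, _, _ = classify_sites({"a": "M-", "b": "MX"}, site_numbers=[31, 32])
    assert n_poly == 0


def test_empty_window_rejected():
    with pytest.raises(ValueError):
        classify_sites({"a": "", "b": ""}, site_numbers=[])
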