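"""Synthetic data generators and packaged study fixtures.

Two kinds of synthetic truth make the pipeline testable end to end without
external sequence downloads:

* amino-acid alignments evolved along a known tree under a reversible
  empirical model, with every internal-node sequence recorded, so that
  ancestral reconstruction can be scored against the truth;
* λmax-annotated random trees with planted shifts of known branch and
  size, so that shift detection can be scored against the truth.

The packaged fixtures transcribe the study's annotated composite tree
(λmax per node, critical-site states, thick-branch and duplication flags)
and its 16-row mutagenesis assay table.  λmax values are integers in nm
throughout; entries legible only in the original figure rather than the
running text carry provenance "figure" in the fixture TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS
from .phylo_core import Alignment, PhyloTree, TreeNode
from .spectral_tuning import MutationAssay, parse_mutation
from .substitution_models import RateMatrix, transition_probabilities

__all__ = [
    "SimulationTruth",
    "simulate_alignment",
    "random_tree",
    "simulate_clock_tree",
    "simulate_annotated_tree",
    "AnnotatedTreeFixture",
    "read_annotated_tree",
    "fixture_fig1",
    "fixture_table1",
    "fixture_table1_frame",
]


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationTruth:
    """A simulated alignment together with its generating tree and the true
    (recorded) ancestral sequences."""

    tree: PhyloTree
    ancestral_sequences: dict[str, str]
    tip_alignment: Alignment
    model: str
    seed: int | None


def _sample_children(parent_states: np.ndarray, P: np.ndarray, rng) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(parent_states.shape[0])
    return (u[:, None] > cum[parent_states]).sum(axis=1)


def simulate_alignment(
    tree: PhyloTree,
    rate_matrix: RateMatrix,
    n_sites: int,
    seed: int | None = None,
    model_name: str = "",
) -> SimulationTruth:
    """Evolve an alignment along ``tree`` under the model.

    The root sequence is drawn site-independently from the stationary
    frequencies; each branch then resamples every site from the row of
    P(branch length) given by the parent state.  All internal states are
    recorded.  Replaying the seed reproduces the output bit-exactly.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be at least 1")
    work = tree.copy()
    work.ensure_internal_labels()
    for node in work.preorder():
        if node is not work.root and node.length is None:
            raise ValueError(f"unset branch length above {node.label!r}")
    rng = np.random.default_rng(seed)
    pi = rate_matrix.pi
    states: dict[int, np.ndarray] = {}
    order = work.preorder()
    states[id(work.root)] = rng.choice(20, size=n_sites, p=pi)
    for node in order:
        if node is work.root:
            continue
        P = transition_probabilities(rate_matrix, node.length)
        states[id(node)] = _sample_children(states[id(node.parent)], P, rng)

    def to_seq(v: np.ndarray) -> str:
        return "".join(AMINO_ACIDS[i] for i in v)

    ancestral = {n.label: to_seq(states[id(n)]) for n in order if not n.is_leaf}
    tips = work.tips()
    aln = Alignment(
        names=[t.label for t in tips], rows=[to_seq(states[id(t)]) for t in tips]
    )
    return SimulationTruth(
        tree=work, ancestral_sequences=ancestral, tip_alignment=aln,
        model=model_name, seed=seed,
    )


# ---------------------------------------------------------------------------
# Random trees
# ---------------------------------------------------------------------------


def random_tree(
    n_tips: int,
    seed: int | None = None,
    mean_branch_length: float = 0.1,
    rng: np.random.Generator | None = None,
) -> PhyloTree:
    """Random bifurcating tree: Yule-style recursive splitting with
    exponential branch lengths (no biological claim; property-test stock)."""
    if n_tips < 2:
        raise ValueError("need at least two tips")
    if rng is None:
        rng = np.random.default_rng(seed)
    counter = iter(range(1, n_tips + 1))

    def build(k: int) -> TreeNode:
        if k == 1:
            return TreeNode(label=f"t{next(counter)}")
        node = TreeNode()
        k1 = int(rng.integers(1, k))
        for kk in (k1, k - k1):
            child = build(kk)
            child.length = float(rng.exponential(mean_branch_length))
            node.add_child(child)
        return node

    tree = PhyloTree(build(n_tips))
    tree.ensure_internal_labels(warn=False)
    return tree


def simulate_clock_tree(
    n_tips: int, height: float, seed: int | None = None
) -> PhyloTree:
    """Ultrametric bifurcating tree: every root-to-tip path length equals
    ``height`` (expected substitutions per site)."""
    if n_tips < 2:
        raise ValueError("need at least two tips")
    if height <= 0:
        raise ValueError("height must be positive")
    rng = np.random.default_rng(seed)
    counter = iter(range(1, n_tips + 1))

    def build(k: int, age: float) -> TreeNode:
        if k == 1:
            leaf = TreeNode(label=f"t{next(counter)}")
            leaf.age = 0.0
            return leaf
        node = TreeNode()
        node.age = age
        child_age = age * float(rng.uniform(0.2, 0.8))
        k1 = int(rng.integers(1, k))
        for kk in (k1, k - k1):
            child = build(kk, child_age if kk > 1 else 0.0)
            child.length = age - child.age
            node.add_child(child)
        return node

    root = build(n_tips, height)
    tree = PhyloTree(root)
    tree.ensure_internal_labels(warn=False)
    return tree


# ---------------------------------------------------------------------------
# λmax-annotated trees with planted shifts
# ---------------------------------------------------------------------------


def simulate_annotated_tree(
    n_tips: int,
    root_lambda: int = 503,
    shift_prob: float = 0.15,
    shift_range: tuple[float, float] = (10.0, 35.0),
    jitter_sd: float = 1.0,
    seed: int | None = None,
) -> tuple[PhyloTree, list[tuple[str, str, int]]]:
    """Random tree whose nodes carry λmax accumulated from the root.

    Each branch receives, with probability ``shift_prob``, a signed planted
    shift of magnitude uniform in ``shift_range`` (rounded to integer nm),
    otherwise a small normal jitter (sd ``jitter_sd`` nm, rounded to
    integer).  Returns the tree and the planted shifts as
    (ancestor, descendant, signed shift) triples.
    """
    if not 0 <= shift_prob <= 1:
        raise ValueError("shift_prob must be in [0, 1]")
    low, high = shift_range
    if not (low >= 10 and high >= low):
        raise ValueError("shift_range must satisfy 10 <= low <= high")
    rng = np.random.default_rng(seed)
    tree = random_tree(n_tips, rng=rng)
    tree.root.lambda_max = int(root_lambda)
    planted: list[tuple[str, str, int]] = []
    for node in tree.preorder():
        for child in node.children:
            if rng.random() < shift_prob:
                magnitude = int(round(float(rng.uniform(low, high))))
                sign = 1 if rng.random() < 0.5 else -1
                delta = sign * magnitude
                planted.append((node.label, child.label, delta))
            else:
                delta = int(round(float(rng.normal(0.0, jitter_sd)))) if jitter_sd > 0 else 0
            child.lambda_max = int(node.lambda_max + delta)
    return tree, planted


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


@dataclass
class AnnotatedTreeFixture:
    """An annotated tree plus its sidecar metadata.

    ``node_states`` maps node label -> {site: amino acid} at the critical
    sites; ``thick_branches`` are the child labels of branches drawn thick
    (significant shifts) in the source figure; ``duplications`` mark gene
    duplication nodes; ``node_numbers`` maps the 13 numbered ancestral
    nodes to their labels.
    """

    tree: PhyloTree
    node_states: dict[str, dict[int, str]]
    thick_branches: set[str] = field(default_factory=set)
    duplications: set[str] = field(default_factory=set)
    node_numbers: dict[int, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)


def read_annotated_tree(newick_path, tsv_path) -> AnnotatedTreeFixture:
    """Load the newick + TSV sidecar dialect used by the shipped fixtures."""
    with open(newick_path) as fh:
        tree = PhyloTree.from_newick(fh.read())
    table = pd.read_csv(tsv_path, sep="\t", dtype={"node_label": str})
    node_states: dict[str, dict[int, str]] = {}
    thick: set[str] = set()
    dup: set[str] = set()
    numbers: dict[int, str] = {}
    provenance: dict[str, str] = {}
    site_cols = [
        (int(c[2:]), c) for c in table.columns if c.startswith("aa") and c[2:].isdigit()
    ]
    for _, row in table.iterrows():
        label = row["node_label"]
        node = tree.node(label)
        node.lambda_max = int(row["lambda_max_nm"])
        node.meta["thick_branch"] = bool(row["thick_branch"])
        node.meta["duplication"] = bool(row["duplication"])
        node_states[label] = {site: row[col] for site, col in site_cols}
        if row["thick_branch"]:
            thick.add(label)
        if row["duplication"]:
            dup.add(label)
        if not pd.isna(row["node_number"]):
            numbers[int(row["node_number"])] = label
        provenance[label] = str(row.get("provenance", ""))
    return AnnotatedTreeFixture(
        tree=tree, node_states=node_states, thick_branches=thick,
        duplications=dup, node_numbers=numbers, provenance=provenance,
    )


def _data_path(name: str):
    return resources.files("rh2evol.data").joinpath(name)


def fixture_fig1() -> AnnotatedTreeFixture:
    """The packaged transcription of the study's annotated composite tree:
    13 numbered ancestral pigments plus the λmax-annotated tips, with
    critical-site states and thick-branch/duplication flags."""
    import importlib.resources as ir

    with ir.as_file(_data_path("fig1_tree.nwk")) as nwk, ir.as_file(
        _data_path("fig1_annotations.tsv")
    ) as tsv:
        return read_annotated_tree(nwk, tsv)


def fixture_table1_frame() -> pd.DataFrame:
    import importlib.resources as ir

    with ir.as_file(_data_path("table1_assays.tsv")) as tsv:
        return pd.read_csv(tsv, sep="\t")


def fixture_table1() -> list[MutationAssay]:
    """The 16 mutagenesis assay rows: ancestral pigment and λmax, mutation
    list, engineered-mutant λmax, and the descendant pigment compared."""
    frame = fixture_table1_frame()
    assays = []
    for _, row in frame.iterrows():
        assays.append(
            MutationAssay(
                ancestral_id=row["ancestor"],
                ancestral_lambda=float(row["ancestral_lambda"]),
                mutations=tuple(parse_mutation(m) for m in row["mutations"].split("/")),
                mutant_lambda=float(row["mutant_lambda"]),
                descendant_id=row["descendant"],
                descendant_lambda=float(row["descendant_lambda"]),
            )
        )
    return assays
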