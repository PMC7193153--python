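"""Marginal ancestral-state reconstruction and reconstruction comparison.

For every internal node k and alignment site s the marginal posterior over
the 20 amino acids is

    PP(a) = P(state at k = a | data) ∝ L(data | node k clamped to a),

computed in a single inside/outside pass per site (equivalent to clamping
the node to each state in turn and renormalizing, which the tests verify
by brute force on small trees).  The per-node maximum-a-posteriori (MAP)
states form the reconstructed ancestral sequence; ties are broken by the
canonical alphabet order and flagged.

``concordance`` reproduces the cross-model/cross-dataset comparison style
of the study: per-site agreement of MAP states, binned by the smaller of
the two posteriors at thresholds (0.95, 0.70).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, N_STATES
from .phylo_core import Alignment, PhyloTree, PruningEngine
from .substitution_models import RateMatrix

__all__ = [
    "Reconstruction",
    "ConcordanceSummary",
    "marginal_reconstruction",
    "concordance",
    "site_state_report",
    "export_reconstruction_tsv",
    "export_map_fasta",
]


@dataclass
class Reconstruction:
    """Posterior reconstruction at every internal node.

    pp has shape (n_nodes, n_sites, 20); ``site_numbers`` carries the
    user-facing (reference, 1-based) number of each column.
    """

    node_ids: list[str]
    pp: np.ndarray
    map_sequences: dict[str, str]
    site_numbers: list[int]
    provenance: str = ""
    ties: list[tuple[str, int]] = field(default_factory=list)  # (node, site number)

    def node_index(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise KeyError(f"no internal node {node_id!r} in the reconstruction")

    def pp_vector(self, node_id: str, site_number: int) -> np.ndarray:
        k = self.node_index(node_id)
        try:
            s = self.site_numbers.index(site_number)
        except ValueError:
            raise KeyError(f"site {site_number} not in the reconstruction window")
        return self.pp[k, s]

    @property
    def n_sites(self) -> int:
        return len(self.site_numbers)


def marginal_reconstruction(
    tree: PhyloTree,
    aln: Alignment,
    rate_matrix: RateMatrix,
    columns: list[int] | None = None,
    provenance: str = "",
) -> Reconstruction:
    """Marginal posterior reconstruction at every internal node."""
    work = tree.copy()
    work.ensure_internal_labels()
    engine = PruningEngine(work, aln, rate_matrix, columns=columns)
    post = engine.marginal_posteriors()  # (nodes, 20, patterns)

    internal = [i for i, n in enumerate(engine.nodes) if not n.is_leaf]
    node_ids = [engine.nodes[i].label for i in internal]
    pat = engine.pattern_of_column  # per retained column
    n_sites = len(pat)

    if columns is None and aln.reference_name and aln.site_window:
        site_numbers = aln.retained_site_numbers()
    else:
        site_numbers = [c + 1 for c in engine.columns]

    pp = np.empty((len(internal), n_sites, N_STATES))
    for k, i in enumerate(internal):
        pp[k] = post[i][:, pat].T

    map_sequences: dict[str, str] = {}
    ties: list[tuple[str, int]] = []
    for k, nid in enumerate(node_ids):
        best = np.argmax(pp[k], axis=1)
        top = pp[k][np.arange(n_sites), best]
        # a tie exists where another state matches the maximum
        n_at_max = (np.abs(pp[k] - top[:, None]) < 1e-12).sum(axis=1)
        for s in np.nonzero(n_at_max > 1)[0]:
            ties.append((nid, site_numbers[s]))
        map_sequences[nid] = "".join(AMINO_ACIDS[b] for b in best)

    return Reconstruction(
        node_ids=node_ids,
        pp=pp,
        map_sequences=map_sequences,
        site_numbers=list(site_numbers),
        provenance=provenance,
        ties=ties,
    )


@dataclass
class ConcordanceSummary:
    n_sites: int
    n_identical_high: int
    n_identical_mid: int
    n_identical_low: int
    n_different: int
    thresholds: tuple[float, float] = (0.95, 0.70)
    detail: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        total = (
            self.n_identical_high
            + self.n_identical_mid
            + self.n_identical_low
            + self.n_different
        )
        if total != self.n_sites:
            raise ValueError("concordance categories must partition the sites")


def concordance(
    a: Reconstruction,
    b: Reconstruction,
    node: str,
    thresholds: tuple[float, float] = (0.95, 0.70),
) -> ConcordanceSummary:
    """Per-site MAP agreement between two reconstructions at one node,
    binned by min(PP) at the (high, mid) thresholds."""
    high, mid = thresholds
    if not (0 < mid < high < 1):
        raise ValueError("thresholds must satisfy 0 < mid < high < 1")
    if a.site_numbers != b.site_numbers:
        raise ValueError("reconstructions cover different site windows")
    ka, kb = a.node_index(node), b.node_index(node)
    seq_a, seq_b = a.map_sequences[node], b.map_sequences[node]
    rows = []
    n_high = n_mid = n_low = n_diff = 0
    for s, site in enumerate(a.site_numbers):
        sa, sb = seq_a[s], seq_b[s]
        ppa = float(a.pp[ka, s].max())
        ppb = float(b.pp[kb, s].max())
        mn = min(ppa, ppb)
        if sa != sb:
            cat = "different"
            n_diff += 1
        elif mn >= high:
            cat = "identical_high"
            n_high += 1
        elif mn >= mid:
            cat = "identical_mid"
            n_mid += 1
        else:
            cat = "identical_low"
            n_low += 1
        rows.append((site, sa, ppa, sb, ppb, mn, cat))
    detail = pd.DataFrame(
        rows, columns=["site", "state_a", "pp_a", "state_b", "pp_b", "min_pp", "category"]
    )
    return ConcordanceSummary(
        n_sites=len(a.site_numbers),
        n_identical_high=n_high,
        n_identical_mid=n_mid,
        n_identical_low=n_low,
        n_different=n_diff,
        thresholds=thresholds,
        detail=detail,
    )


def site_state_report(recon: Reconstruction, sites: list[int]) -> pd.DataFrame:
    """MAP state and PP for chosen reference sites at every node.

    Sites outside the reconstruction window are listed with state/PP absent
    rather than raising — the audit must show what is missing.
    """
    rows = []
    for node in sorted(recon.node_ids):
        k = recon.node_index(node)
        for site in sorted(sites):
            if site in recon.site_numbers:
                s = recon.site_numbers.index(site)
                vec = recon.pp[k, s]
                best = int(np.argmax(vec))
                rows.append((node, site, AMINO_ACIDS[best], float(vec[best]), True))
            else:
                rows.append((node, site, None, None, False))
    return pd.DataFrame(rows, columns=["node", "site", "map_state", "pp", "in_window"])


def export_reconstruction_tsv(recon: Reconstruction, path) -> None:
    cols = ["node", "site"] + [f"pp_{aa}" for aa in AMINO_ACIDS] + ["map_state"]
    rows = []
    for k, node in enumerate(recon.node_ids):
        for s, site in enumerate(recon.site_numbers):
            rows.append(
                [node, site, *(f"{p:.6f}" for p in recon.pp[k, s]), recon.map_sequences[node][s]]
            )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def export_map_fasta(recon: Reconstruction, path) -> None:
    with open(path, "w") as fh:
        for node in recon.node_ids:
            fh.write(f">{node}\n{recon.map_sequences[node]}\n")
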