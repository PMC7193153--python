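"""Spectral-tuning (λmax) analysis over an annotated phylogeny.

λmax is the wavelength of maximal absorption of a visual pigment, in
nanometres; here it is an integer-valued node annotation on the tree.  The
module computes per-branch shifts Δλmax = λ(descendant) − λ(ancestor)
(positive = red shift), flags significant (|Δ| ≥ 10 nm) and large
(|Δ| ≥ 30 nm) shifts, classifies mutagenesis assays as "fully explaining"
a shift when the engineered mutant lands within 4 nm of the descendant,
reports the percent of a shift a mutation accounts for, traces
substitutions at the tuning-critical sites (122, 207, 292 in bovine-RH1
numbering), and separates polymorphic from monomorphic sites.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .alphabet import AA_INDEX
from .phylo_core import PhyloTree

__all__ = [
    "SIGNIFICANCE_NM",
    "LARGE_SHIFT_NM",
    "EXPLAINED_TOLERANCE_NM",
    "CRITICAL_SITES",
    "ShiftRecord",
    "MutationAssay",
    "SubstitutionEvent",
    "branch_shifts",
    "count_shifts",
    "classify_explained",
    "fraction_explained",
    "trace_site_substitutions",
    "classify_sites",
    "shift_report_frame",
]

SIGNIFICANCE_NM = 10.0
LARGE_SHIFT_NM = 30.0
EXPLAINED_TOLERANCE_NM = 4.0
CRITICAL_SITES = (122, 207, 292)

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class ShiftRecord:
    """One branch's λmax change."""

    ancestor_id: str
    descendant_id: str
    lambda_anc: float
    lambda_desc: float
    delta: float
    significant: bool
    large: bool


@dataclass(frozen=True)
class Mutation:
    site: int
    from_state: str
    to_state: str

    @property
    def label(self) -> str:
        return f"{self.from_state}{self.site}{self.to_state}"


def parse_mutation(label: str) -> Mutation:
    m = _MUTATION_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse mutation label {label!r} (expected e.g. E122Q)")
    frm, site, to = m.group(1), int(m.group(2)), m.group(3)
    if frm not in AA_INDEX or to not in AA_INDEX:
        raise ValueError(f"mutation {label!r} uses a non-amino-acid letter")
    if not 1 <= site <= 354:
        raise ValueError(f"mutation site {site} outside the opsin range 1..354")
    return Mutation(site=site, from_state=frm, to_state=to)


@dataclass(frozen=True)
class MutationAssay:
    """One engineered-mutant measurement: ancestor, mutations, mutant λmax,
    and the descendant pigment the mutant is compared with."""

    ancestral_id: str
    ancestral_lambda: float | None
    mutations: tuple[Mutation, ...]
    mutant_lambda: float | None
    descendant_id: str
    descendant_lambda: float | None

    @property
    def mutation_label(self) -> str:
        return "/".join(m.label for m in self.mutations)

    @property
    def complete(self) -> bool:
        return None not in (self.ancestral_lambda, self.mutant_lambda, self.descendant_lambda)


@dataclass(frozen=True)
class SubstitutionEvent:
    ancestor_id: str
    descendant_id: str
    site: int
    from_state: str
    to_state: str

    def __post_init__(self) -> None:
        if self.from_state == self.to_state:
            raise ValueError("a substitution event needs distinct endpoint states")

    @property
    def label(self) -> str:
        return f"{self.from_state}{self.site}{self.to_state}"


# ---------------------------------------------------------------------------
# Shifts
# ---------------------------------------------------------------------------


def branch_shifts(
    tree: PhyloTree,
    significance: float = SIGNIFICANCE_NM,
    large: float = LARGE_SHIFT_NM,
) -> tuple[list[ShiftRecord], list[tuple[str, str]]]:
    """One ShiftRecord per branch whose two endpoints carry a λmax.

    Returns (records in preorder, skipped branches with a missing
    annotation).  A tree without any annotated node is rejected.
    """
    if all(n.lambda_max is None for n in tree.preorder()):
        raise ValueError("tree carries no λmax annotations")
    records: list[ShiftRecord] = []
    skipped: list[tuple[str, str]] = []
    for node in tree.preorder():
        for child in node.children:
            if node.lambda_max is None or child.lambda_max is None:
                skipped.append((node.label or "?", child.label or "?"))
                continue
            delta = child.lambda_max - node.lambda_max
            records.append(
                ShiftRecord(
                    ancestor_id=node.label,
                    descendant_id=child.label,
                    lambda_anc=node.lambda_max,
                    lambda_desc=child.lambda_max,
                    delta=delta,
                    significant=abs(delta) >= significance,
                    large=abs(delta) >= large,
                )
            )
    return records, skipped


def count_shifts(
    records: list[ShiftRecord],
    significance: float = SIGNIFICANCE_NM,
    large: float = LARGE_SHIFT_NM,
) -> tuple[int, int, list[ShiftRecord]]:
    """(n significant, n large, listing sorted by |Δ| descending)."""
    n_sig = sum(1 for r in records if abs(r.delta) >= significance)
    n_large = sum(1 for r in records if abs(r.delta) >= large)
    order = {id(r): i for i, r in enumerate(records)}  # preorder tiebreak
    listing = sorted(records, key=lambda r: (-abs(r.delta), order[id(r)]))
    return n_sig, n_large, listing


def shift_report_frame(records: list[ShiftRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.ancestor_id, r.descendant_id, r.lambda_anc, r.lambda_desc, r.delta, r.significant, r.large)
            for r in records
        ],
        columns=["ancestor", "descendant", "lambda_anc", "lambda_desc", "delta", "significant", "large"],
    )


# ---------------------------------------------------------------------------
# Mutation explanation
# ---------------------------------------------------------------------------


def classify_explained(
    assays: list[MutationAssay], tolerance: float = EXPLAINED_TOLERANCE_NM
) -> tuple[pd.DataFrame, int, int]:
    """Mark each assay explained iff |mutant λ − descendant λ| ≤ tolerance.

    Returns (per-row table, n explained among single-mutation rows,
    n explained among multi-mutation rows); incomplete rows are reported
    unevaluable and excluded from the counts.
    """
    rows = []
    n_single = n_multi = 0
    for a in assays:
        if not a.complete:
            rows.append((a.ancestral_id, a.mutation_label, a.mutant_lambda, a.descendant_id, a.descendant_lambda, None, False))
            continue
        diff = abs(a.mutant_lambda - a.descendant_lambda)
        explained = diff <= tolerance
        if explained:
            if len(a.mutations) == 1:
                n_single += 1
            else:
                n_multi += 1
        rows.append((a.ancestral_id, a.mutation_label, a.mutant_lambda, a.descendant_id, a.descendant_lambda, explained, True))
    table = pd.DataFrame(
        rows,
        columns=["ancestor", "mutations", "mutant_lambda", "descendant", "descendant_lambda", "explained", "evaluable"],
    )
    return table, n_single, n_multi


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def fraction_explained(
    lambda_anc: float, lambda_mutant: float, lambda_desc: float
) -> tuple[float, int]:
    """(nm contribution, percent of the total shift, rounded half-away).

    contribution = mutant − ancestor; percent = 100·contribution/total.
    """
    total = lambda_desc - lambda_anc
    if total == 0:
        raise ValueError("total shift is zero; the explained fraction is undefined")
    contribution = lambda_mutant - lambda_anc
    percent = _round_half_away(100.0 * contribution / total)
    return contribution, percent


# ---------------------------------------------------------------------------
# Critical-site tracing
# ---------------------------------------------------------------------------


def trace_site_substitutions(
    tree: PhyloTree,
    node_states: dict[str, dict[int, str]],
    sites: tuple[int, ...] = CRITICAL_SITES,
) -> tuple[list[SubstitutionEvent], Counter, list[tuple[str, str, int]]]:
    """Emit a SubstitutionEvent wherever parent and child states differ.

    ``node_states`` maps node label -> {site: amino acid}.  Branches where
    either endpoint lacks a state at a site are skipped and reported.
    Returns (events in preorder, Counter of '<from><site><to>' labels,
    skipped (ancestor, descendant, site) triples).
    """
    events: list[SubstitutionEvent] = []
    skipped: list[tuple[str, str, int]] = []
    for node in tree.preorder():
        for child in node.children:
            for site in sites:
                sa = node_states.get(node.label, {}).get(site)
                sd = node_states.get(child.label, {}).get(site)
                if sa is None or sd is None:
                    skipped.append((node.label or "?", child.label or "?", site))
                    continue
                for state in (sa, sd):
                    if state not in AA_INDEX:
                        raise ValueError(
                            f"invalid amino acid {state!r} at site {site} on branch "
                            f"{node.label}->{child.label}"
                        )
                if sa != sd:
                    events.append(
                        SubstitutionEvent(
                            ancestor_id=node.label,
                            descendant_id=child.label,
                            site=site,
                            from_state=sa,
                            to_state=sd,
                        )
                    )
    counts = Counter(e.label for e in events)
    return events, counts, skipped


# ---------------------------------------------------------------------------
# Polymorphic / adaptive site classification
# ---------------------------------------------------------------------------


def classify_sites(
    sequences: dict[str, str],
    site_numbers: list[int],
    critical_sites: tuple[int, ...] = CRITICAL_SITES,
) -> tuple[int, int, float, pd.DataFrame]:
    """Split sites into polymorphic/monomorphic across a pigment set.

    ``sequences`` maps pigment name -> string over the numbered sites (one
    character per entry of ``site_numbers``).  A site is polymorphic when
    ≥ 2 distinct non-missing states occur.  The adaptive fraction is the
    percent (one decimal) of polymorphic sites that are tuning-critical.
    """
    if len(sequences) < 2:
        raise ValueError("site classification needs at least two sequences")
    if not site_numbers:
        raise ValueError("empty site window")
    lengths = {len(s) for s in sequences.values()}
    if lengths != {len(site_numbers)}:
        raise ValueError("sequences and site_numbers must have matching lengths")
    rows = []
    n_poly = 0
    critical_poly = 0
    for i, site in enumerate(site_numbers):
        states = {s[i] for s in sequences.values()} - {"-", "X", "?"}
        poly = len(states) >= 2
        critical = site in critical_sites
        if poly:
            n_poly += 1
            if critical:
                critical_poly += 1
        rows.append((site, "".join(sorted(states)), poly, critical))
    n_mono = len(site_numbers) - n_poly
    fraction = round(100.0 * critical_poly / n_poly, 1) if n_poly else 0.0
    listing = pd.DataFrame(rows, columns=["site", "states", "polymorphic", "critical"])
    return n_poly, n_mono, fraction, listing
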