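#!/usr/bin/env python
"""Lineage-rate comparison on clock-simulated data with a planted
rate contrast.

Builds a two-lineage tree in which one lineage evolves three times faster
than the other (emulating the duplication-rich teleost lineage against the
background vertebrate rate), simulates an alignment, re-estimates branch
lengths, and compares the sequentially averaged lineage rates with
bootstrap SEs and the pooled-SE Z statistic.  The planted contrast should
be detected (Z large, p < 0.01) while each recovered rate stays within a
few SE of its planted value.
Writes results/lineage_rates.tsv and results/rate_comparison.tsv.
"""

from pathlib import Path

import pandas as pd

from rh2evol import (
    LineageRate,
    build_rate_matrix,
    compare_rates,
    get_model,
    optimize_branch_lengths,
    rate_se,
    sequential_average_depth,
    simulate_alignment,
    simulate_clock_tree,
)
from rh2evol.phylo_core import PhyloTree, TreeNode

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 7
ORIGIN_YEARS = 400e6
RATE_SLOW = 0.3e-9  # background vertebrate-like rate
RATE_FAST = 0.9e-9  # duplication-rich lineage


def main() -> None:
    jtt = build_rate_matrix(get_model("JTT"))
    root = TreeNode(label="root")
    planted = {}
    for prefix, rate in (("slow", RATE_SLOW), ("fast", RATE_FAST)):
        sub = simulate_clock_tree(5, height=rate * ORIGIN_YEARS, seed=SEED)
        for node in sub.preorder():
            node.label = f"{prefix}_{node.label}"
        sub.root.length = 0.02
        root.add_child(sub.root)
        planted[prefix] = (sub.root.label, rate)
    tree = PhyloTree(root)
    truth = simulate_alignment(tree, jtt, 281, seed=SEED + 1)
    fit = optimize_branch_lengths(tree, truth.tip_alignment, jtt)

    rows, rates = [], {}
    for i, (lineage, (focal, rate_true)) in enumerate(sorted(planted.items())):
        depth = sequential_average_depth(fit.tree, focal)
        se, _ = rate_se(fit.tree, focal, truth.tip_alignment, jtt, ORIGIN_YEARS,
                        n_boot=100, seed=SEED + 10 + i)
        rates[lineage] = LineageRate(
            lineage_id=lineage, depth=depth, origin_time=ORIGIN_YEARS,
            rate=depth / ORIGIN_YEARS, se=se, n_boot=100, seed=SEED + 10 + i,
        )
        rows.append((lineage, depth, ORIGIN_YEARS / 1e6, depth / ORIGIN_YEARS, se, rate_true))
        print(f"lineage {lineage}: rate {depth / ORIGIN_YEARS:.2e} +/- {se:.1e} "
              f"subs/site/year (planted {rate_true:.1e})")

    z, p, sig5, sig1 = compare_rates(rates["fast"], rates["slow"])
    print(f"fast vs slow: Z = {z:.2f}, p = {p:.2e}, significant at 1%: {sig1}")

    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows, columns=["lineage", "depth", "origin_MYA", "rate", "se", "planted_rate"]).to_csv(
        OUT / "lineage_rates.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [("fast", "slow", z, p, sig5, sig1)],
        columns=["lineage_1", "lineage_2", "Z", "p", "sig_5pct", "sig_1pct"],
    ).to_csv(OUT / "rate_comparison.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
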