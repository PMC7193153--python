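# Methods

## Substitution models and likelihood

The three empirical amino-acid replacement models (JTT, WAG, Dayhoff) are
shipped as plain-text data files in the de-facto interchange layout
(19 rows of lower-triangle exchangeabilities followed by 20 stationary
frequencies), in the canonical residue order
A R N D C Q E G H I L K M F P S T W Y V used by the original model
publications. Each file carries an md5 checksum enforced at load time; the
printed frequencies are renormalized to sum exactly to 1.

A model (S, π) becomes a rate matrix by `Q[i,j] = S[i,j]·π[j]` (i ≠ j),
diagonal set so rows sum to zero, then rescaled so the mean rate
`−Σ_i π_i Q[i,i]` is exactly 1 — branch lengths are therefore expected
substitutions per site. Frequencies default to the model's published
values; alignment-empirical ("+F") frequencies are an explicit option
(`frequencies_override` / `use_empirical_frequencies`), since either
convention is defensible and downstream users may need to match an
existing analysis. There is no among-site rate heterogeneity: all sites
evolve at the same rate (a gamma model is deliberately out of scope).

Transition probabilities use the symmetrized eigendecomposition that
reversibility affords: with `D = diag(√π)`, `B = D Q D⁻¹` is symmetric,
`B = U Λ Uᵀ`, and `P(t) = D⁻¹ U e^{Λt} Uᵀ D`. The decomposition is cached
per rate matrix; negative round-off (≲1e-12) is clipped to zero. The test
suite checks this path against scipy's scaling-and-squaring `expm` to
1e-9, plus Chapman–Kolmogorov and detailed-balance properties.

The tree likelihood is Felsenstein pruning over pattern-compressed columns
(unique site patterns with multiplicities), with per-node rescaling of the
partial-likelihood vectors to prevent underflow (verified finite on
40-taxon × 281-site data). Gaps, `X` and `?` at tips are missing data —
an all-ones partial vector, i.e. marginalized, never a 21st state. Columns
entering the likelihood are those whose bovine-RH1 reference position lies
in the configured window (default 31..311, which leaves 281 comparable
sites for a full-length 354-residue reference); without a reference, all
columns are used. Internally columns are 0-based; every user-facing site
number is a 1-based reference position, matching the vision-science
convention for the critical sites 122, 207 and 292.

## Branch-length optimization

Topology is always taken as given (the composite user tree, rooted by
outgroup choice upstream); only branch lengths are estimated. The
optimizer is deterministic coordinate ascent: for each branch, the
one-dimensional likelihood profile is computed from the inside (below the
branch) and outside (everything else) partial vectors, and maximized by
bounded Brent search in [1e-8, 10] substitutions/site; cycles over all
branches repeat until the log-likelihood gain falls below `tol`
(default 1e-6, max 200 cycles). Unset or nonpositive initial lengths
start at 0.1. The trajectory is monotone by construction (a proposed
update is applied only if it does not decrease the profile), and the
returned report records initial/final lengths per branch, cycle count and
final improvement. Under a reversible model the two branches meeting at
the root are only jointly identifiable (the pulley principle, which the
tests verify as likelihood invariance to re-rooting along a branch); the
coordinate search simply settles on one of the equivalent splits. No
stochastic restarts are used: on a fixed topology at these sizes the
likelihood is well-behaved, and determinism is worth more than a global
search.

## Marginal ancestral reconstruction

The posterior at internal node k, site s is marginal (per-node), not
joint, because the quantities of interest downstream are per-site
posterior probabilities per node. It is computed in one inside/outside
pass as `PP(a) ∝ A_k(a)·F_k(a)` — outside times inside — which equals the
defining quantity "clamp node k to state a, recompute the likelihood,
renormalize" (the suite verifies this against exhaustive enumeration on
≤4-taxon trees to 1e-9). MAP ties are broken by canonical alphabet order
and flagged in the result. Unlabelled internal nodes are auto-labelled by
preorder index with a warning, so results are always addressable.

Cross-reconstruction concordance compares MAP states site by site at one
node and bins agreements by the smaller of the two posteriors at
thresholds (0.95, 0.70). "Comparable sites" means columns carrying a
reference number inside the window in both reconstructions. Calibration on
synthetic truth: among sites called with PP ≥ 0.95, the true simulated
state is recovered ≥ 90% of the time (measured 99.7% on the 40-taxon,
281-site run in `analysis/03`), and accuracy in the 0.70–0.95 bin falls
inside that bin's nominal range.

## Spectral tuning

λmax values are integer nanometres throughout the fixtures; no
interpolation. The shift on a branch is descendant minus ancestor
(positive = red shift), and significance uses the absolute value,
|Δλmax| ≥ 10 nm — blue shifts count — with |Δλmax| ≥ 30 nm marking large
shifts. An assay row is "fully explained" when
|λ(mutant) − λ(descendant)| ≤ 4 nm; rows missing a λ value are reported
unevaluable and excluded from counts. Percent-of-shift-explained is
`100·(λ_mutant − λ_anc)/(λ_desc − λ_anc)` rounded half-away-from-zero to
the nearest integer (so 15/35 → 43%), and is undefined (rejected) for a
zero total shift. Substitution tracing emits an event wherever parent and
child states differ at a queried site; branches missing a state are
skipped and reported. Site classification marks a site polymorphic when
≥ 2 distinct non-missing states occur across the pigment set, and the
adaptive fraction is the percent (one decimal) of polymorphic sites that
are tuning-critical.

## Lineage rates

The depth of a focal ancestor is the sequential average of its children's
path lengths: `depth(tip) = 0`, `depth(node) = mean_children(branch +
depth(child))`, the unweighted mean over however many children (two or
three) the node has. On an ultrametric tree this equals every root-to-tip
path length exactly. Rate = depth / origin time; the shipped origin times
are 615, 230 and 413 MYA for the vertebrate (a), tetrapod (b) and
Clupeocephala (c) lineages, configuration constants of the study design.

The SE derivation is this package's own choice: a nonparametric bootstrap
over alignment columns, implemented as multinomial reweighting of site
patterns (equivalent to resampling columns with replacement) so each of
the `n_boot` replicates re-optimizes a weighted likelihood warm-started
from the full-data estimates (looser per-replicate tolerance, 1e-3, max 5
cycles — the bootstrap spread dominates any residual optimization error).
At least 50 replicates are required and at least 10 must succeed.
Coverage on clock simulations with a planted rate: the true rate lies
within ±3 SE in ≥ 90% of 50 seeded replicates (6 tips, 150 sites,
50-replicate bootstrap — sizes chosen to make the property cheap to
verify while leaving the estimator plainly identifiable).

Rates are compared with the pooled-SE statistic
`Z = |r₁ − r₂| / √(se₁² + se₂²)` against the standard normal, flagged at
5% and 1%. Note this formula is documented rather than asserted to match
any particular published Z value, because published rate/SE pairs do not
always determine the Z construction used.

## Synthetic data

`simulate_alignment` draws the root sequence site-independently from π
and evolves each branch by sampling from the parent-state row of
P(branch length), recording every internal sequence; seeded runs are
bit-reproducible, and long simulations match π within multinomial error.
Random trees are Yule-style recursive splits with exponential branch
lengths (a property-test stock, not a biological claim);
`simulate_clock_tree` produces ultrametric trees of exact height.
`simulate_annotated_tree` plants, per branch with probability
`shift_prob`, a signed shift of magnitude uniform in (10, 35) nm, and
otherwise integer-rounded normal jitter (sd 1 nm), accumulating λmax from
a root value of 503 nm — the generator's defaults mirror the annotated
composite tree it stands in for: planted shifts span the significant-to-
large range observed there, and jitter stays far below the 10 nm
threshold, so planted-truth recovery is exact for the tested seeds.

What the generators do **not** emulate: among-site rate variation,
alignment gaps and length variation, gene-duplication events as
sequence-level processes, any sequence→λmax mapping (planted shifts are
assigned, not caused by substitutions), and non-stationary composition.
Passing tests therefore certify the inference machinery against its own
model assumptions, not robustness to real-data violations of them.

## Fixtures

The composite-tree fixture (newick + TSV sidecar: label, λmax, aa122,
aa207, aa292, thick-branch flag, duplication flag, provenance) transcribes
the study tree restricted to λmax-annotated pigments: the 13 numbered
ancestral nodes and 24 annotated tips. Entries whose values are stated in
running text are marked `text`; the few legible only in the source figure
are marked `figure`, and any count that depends on them is cross-checked
against the thick-branch metadata (the set of significant branches found
by the census equals the thick-branch flags exactly). The assay-table
fixture carries all 16 mutagenesis rows with a transcribed bold flag; the
explanation classifier reproduces the bold/non-bold pattern exactly. Both
are data, not computation.

## Known limitations

* Real headline numbers that require the original GenBank alignment
  (cross-model concordance counts at the vertebrate root, the absolute
  lineage rates and their Z values, the polymorphic-site census over the
  15 fully-explained pigments) are covered by method-level property tests
  on synthetic data, not reproduced numerically.
* Marginal reconstruction only; no joint reconstruction, sampling of
  ancestral sequences, or model averaging.
* No topology search, no divergence-time estimation (ages are inputs),
  no rate heterogeneity, no codon models.
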