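# rh2evol

Molecular-evolution toolkit for green-sensitive (RH2) visual pigments:
maximum-likelihood ancestral protein reconstruction under empirical
amino-acid substitution models, spectral-tuning (λmax) shift analysis over
an annotated phylogeny, critical-site substitution tracing, and
lineage-specific substitution-rate comparison.

## The problem

RH2 cone opsins let non-mammalian vertebrates discriminate wavelengths in
the blue–green band (~450–530 nm) that dominates twilight and mid-depth
water. Understanding how their absorption peak (λmax, the wavelength of
maximal absorption) evolved requires reconstructing the pigments of
extinct ancestors and asking which amino-acid substitutions account for
each λmax shift. This package implements the computational side of that
programme for phylogeneticists and vision scientists:

* **Ancestral reconstruction.** For a fixed rooted topology with branch
  lengths *t*, tip sequences evolve under a reversible empirical model
  with rate matrix `Q[i,j] = S[i,j]·π[j]` (JTT, WAG or Dayhoff
  exchangeabilities *S* and frequencies *π*, normalized to mean rate 1 so
  branch lengths are expected substitutions per site). The likelihood is
  computed by Felsenstein's pruning algorithm with
  `P(t) = exp(Qt)` from the symmetric eigendecomposition that
  reversibility affords; branch lengths are maximized by deterministic
  coordinate ascent on the user tree. The marginal posterior of state *a*
  at internal node *k* and site *s* is
  `PP(a) ∝ L(data | node k clamped to a)`, computed in one inside/outside
  pass; the per-site argmax states form the MAP ancestral sequence.
  Site numbers follow the vision-science bovine-RH1 convention
  (window 31..311; the tuning-critical sites are 122, 207 and 292).
* **Spectral tuning.** Per-branch shifts `Δλmax = λ(descendant) −
  λ(ancestor)` (positive = red shift) are flagged significant at
  |Δ| ≥ 10 nm and large at |Δ| ≥ 30 nm. A mutagenesis assay "fully
  explains" a branch when the engineered mutant lands within 4 nm of the
  descendant pigment; otherwise the percent explained is
  `100·(λ_mutant − λ_anc)/(λ_desc − λ_anc)`.
* **Lineage rates.** A lineage's substitution depth is the sequential
  average from the tips up — `depth(node) = mean_children(branch +
  depth(child))` — divided by the lineage's origin time to give
  substitutions/site/year, with a site-bootstrap SE and pooled-SE
  Z comparisons `Z = |r₁ − r₂| / √(se₁² + se₂²)`.
* **Synthetic truth.** Generators evolve alignments along known trees with
  recorded ancestral states and plant λmax shifts of known size on random
  trees, so every stage is verified against ground truth without any
  sequence downloads.

## Worked example

The packaged fixtures transcribe the annotated composite RH2 phylogeny
(13 numbered ancestral pigments plus 24 λmax-annotated present-day
pigments) and the 16-row mutagenesis assay table.

```
$ python analysis/01_shift_census.py
branches with both endpoints annotated: 37 (skipped 0)
significant shifts (|d| >= 10 nm): 16
large shifts (|d| >= 30 nm): 3
  AncEuteleost2 (489) -> AncEuteleost4 (524): +35 nm
  AncEuteleost4 (524) -> medakaC (492): -32 nm
  AncSquamata (497) -> gecko (467): -30 nm
critical-site substitution counts: {'M207L': 2, 'E122Q': 3, 'Q122E': 4, 'A292S': 1}
```

Sixteen branches shift the absorption peak by at least 10 nm; three do so
by 30 nm or more, and the tuning-critical sites 122/207/292 change ten
times in total across the tree.

```
$ python analysis/02_mutation_explanations.py
fully explained (|mutant - descendant| <= 4 nm): 8 of 16
  single-mutation transitions: 8, multi-mutation: 0
  Q122E: +15 nm of +35 nm (43%)
  Y96T/Q122E/C213F: +20 nm of +35 nm (57%)
  V60F/F74Y/Y96T/Q122E/T209V/C213F/I255V/L259M/A273G: +21 nm of +35 nm (60%)
```

Eight of the sixteen engineered mutants land within 4 nm of their
descendant pigment — those branches' λmax shifts are fully explained by
one critical substitution each. The largest shift (489 → 524 nm) resists
explanation: even a nine-site mutant recovers only 60% of it.

`analysis/03_simulate_and_reconstruct.py` closes the loop on synthetic
truth (99.7% of PP ≥ 0.95 ancestral calls are correct on a 40-taxon,
281-site simulation; JTT and WAG reconstructions agree at 246/281 root
sites with PP ≥ 0.95), and `analysis/04_lineage_rates.py` detects a
planted 3× rate contrast between lineages (Z = 9.1, p < 0.01) while
recovering each planted rate within a few SE.

A `rh2evol` command-line interface exposes the same pipeline
(`rh2evol reconstruct | shifts | rates | simulate | fixtures`).

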