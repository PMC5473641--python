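# Methods

`cladecons` implements an inference stack for detecting *clade-specific
highly conserved elements* in multiple-species genome alignments and for
characterising them downstream: a neutral substitution model fitted to
putatively neutral sites, a two-state phylogenetic HMM that calls
conserved elements on the ingroup, outgroup-based classification of
lineage specificity, genomic annotation and enrichment statistics, and a
molecular-clock estimate of when an element's conservation began. A
synthetic-data module generates every input with known ground truth so
the full stack is testable without any external data.

## Neutral model and likelihoods

Substitution follows a reversible 4-state CTMC (JC69, HKY85 or GTR). The
rate matrix is built from equilibrium frequencies π and exchangeabilities,
normalised so −Σᵢ πᵢ qᵢᵢ = 1; branch lengths are therefore expected
substitutions per site. Transition kernels P(t) = exp(Qt) come from a
symmetric eigendecomposition cached per model (exact for reversible Q,
with an explicit identity at t = 0).

Column likelihoods use Felsenstein pruning over the distinct column
patterns of an alignment, with per-pattern rescaling for numerical
stability. Gaps and N are missing data and are marginalised; a column
missing at every leaf has probability exactly 1. Species present in the
tree but absent from an alignment contribute flat partials.

Model fitting maximises the product of column likelihoods by bounded
L-BFGS on log-parameters (branch lengths in [1e−9, 20], exchangeabilities
in [1e−3, 1e3]) from two deterministic starts (all branches 0.1 and 0.3);
convergence at Δlog-likelihood ~1e−12, fitted lengths below 1e−8 clamped
to zero, and an exact zero fit short-circuited when the alignment has no
variable columns. π is taken from observed base frequencies (with a flat
pseudocount), which is standard practice and removes four parameters from
the optimisation. The default family is HKY85: it captures the
transition/transversion bias that dominates nucleotide data with a single
extra parameter; GTR is available where more fidelity is wanted and JC69
for controlled experiments.

Two identifiability facts shape the code and tests. Under a reversible
model (i) the two branch lengths incident to a bifurcating root are only
jointly identifiable (their sum is), and (ii) with a single outgroup the
stem and outgroup branch lengths trade off freely. Branch-recovery tests
therefore compare the root-child sum rather than the two lengths, and
onset dating (below) holds outgroup-side branches at their neutral
lengths.

## Element calling (phylogenetic HMM)

A two-state HMM emits alignment columns either under the neutral tree
(state "nonconserved") or under the neutral tree with every branch scaled
by ρ ∈ (0,1] (state "conserved"). Transitions are μ
(conserved→nonconserved) and ν (nonconserved→conserved); 1/μ is the
expected element length in columns. Defaults are ρ = 0.3, expected length
45 columns and 5% stationary conserved coverage — tuning, not estimates;
all three are configurable, and `estimate_rho` refits (ρ, μ, ν) from data
by alternating a Baum–Welch transition update with a bounded 1-D
profile-likelihood search over ρ, which keeps the observed-data
log-likelihood non-decreasing.

Elements are maximal conserved runs of the Viterbi path (a
posterior-threshold mode is available through the posterior track),
mapped to reference coordinates. Columns without a reference coordinate
(reference gaps) cannot sit inside an element; runs are split there,
because elements are intervals on the reference genome. Runs shorter than
20 reference bases are discarded — short calls are unreliable — and the
element score is the summed per-column log-likelihood ratio
(conserved vs nonconserved) in nats; BED output rounds 10·log₁₀-odds to
an integer score.

Element calling runs on the *ingroup* alignment and the ingroup-restricted
tree: a clade-specific element is conserved only within the clade, so
including outgroups in the emission model would suppress exactly the
signal of interest. Outgroups enter at the classification stage.

## Lineage-specific classification

For each called element and each configured outgroup set:

* **presence** — an outgroup species counts as aligned when ≥ 10% of the
  element's columns are resolved (non-gap, non-N) for it (configurable);
* **Type I** — every outgroup species across the union of all sets is
  absent ("no outgroup sequence aligned");
* **Type II** — outgroup sequence is present in at least one set, and a
  one-sided subtree-rate likelihood-ratio test is significant in *all*
  sets. H0 fits one rate scale shared by all branches of the
  ingroup+outgroup-set tree; H1 fits separate scales for the ingroup
  clade (stem branch included — stem conservation is part of the clade
  signal) and the outgroup side. The acceleration p-value is the usual
  one-sided boundary mixture: p = 0.5·P(χ²₁ > Λ) when the fitted outgroup
  scale exceeds the ingroup scale, else p = 1. Benjamini–Hochberg FDR is
  computed within each outgroup set across its testable elements, and
  Type II requires q < 0.01 in every set.

Elements shorter than 5 columns are flagged untestable and excluded from
FDR; elements shorter than 20 bp are never labelled clade-specific.
Everything else is "non-specific" (conserved beyond the clade). Requiring
absence in *all* outgroups for Type I, and the per-set FDR, are the
stricter readings of the underlying design and are fixed here as such.

## Genomic annotation

Annotation classes follow the fixed priority coding > 5′/3′ 10 kb >
intronic > intergenic, strand-aware, with the 10 kb windows anchored at
the translation start/stop; "coding" means CDS (UTR-only overlap falls
through to the intronic/genic handling). Gene association instead uses
the nearest protein-coding gene within 10 kb of the *transcript* span
(distance 0 inside it), ties broken by distance then lexicographic gene
id. The two anchors are deliberately different — each matches the
analysis that consumes it — and are not unified. Genes are ranked by the
maximum element log-odds score among their associated elements. The SNP
density contrast builds the 2×2 position-by-membership table and applies
Pearson's χ² with 1 df, continuity-corrected only when an expected cell
drops below 5.

## Enrichment statistics

The interval permutation test re-places every query segment uniformly at
random within the workspace (lengths preserved; segments never cross
workspace gaps; placed segments may overlap) and recomputes the
nucleotide overlap with the annotation per simulation; the default is
100,000 simulations. Empirical p-values use the (1 + #{sim ≥ obs})/(n+1)
pseudocount form, so they are never 0, and both enrichment and depletion
p-values are reported with the fold (observed/expected). Term enrichment
is a per-term 2×2 χ² against a gene background with BH FDR across terms.
Fisher's exact test returns the two-sided hypergeometric p (degenerate
margins give p = 1, flagged). The tau specificity index is
τ = Σᵢ(1 − xᵢ/max x)/(N−1); genes with τ ≥ 0.8 (configurable — the
threshold is a convention, not an estimate) are called stage-specific at
their argmax stage. The cross-species candidate filter keeps genes that
are species-1 DEGs with fold change strictly > 5 in at least one
late-stage contrast whose species-2 ortholog stays strictly < 2-fold in
the corresponding contrast; genes without orthologs are reported
separately, not kept. Boundary values (exactly 5-fold, exactly 2-fold)
are excluded by the strict inequalities.

## Onset dating

For an element conserved in the ingroup, assume it evolved neutrally on
the stem branch (per-Myr rate r) until an onset age T and at rate ρ·r
afterwards, with crown branches at ρ·r throughout. The expected
element-specific stem length is then

    b(T) = r·(t0 − T) + ρ·r·(T − t1),   t1 ≤ T ≤ t0,

affine and strictly decreasing in T for ρ < 1 (t0 = ingroup/outgroup
split age, t1 = crown age). The estimator: (i) fit element-specific
branch lengths on the calibrated topology with outgroup-side branches
held at their neutral lengths (the model's own assumption, and the fix
for stem identifiability); (ii) r = neutral stem length / (t0 − t1);
(iii) ρ̂ = element crown length / neutral crown length (ratio of sums —
kept separate from T so the inversion stays closed-form; a joint-ML mode
was considered and rejected for this release); (iv) invert b(T) at the
fitted stem length, clamping to [t1, t0] with a flag rather than failing.
Uncertainty is a nonparametric bootstrap over alignment columns
(multinomial resampling of column-pattern counts, 200 replicates by
default, warm-started from the point fit); the s.e. is the bootstrap
standard deviation with clamped replicates included and the clamped
fraction reported as a quality metric. ρ̂ ≥ 1 (no ingroup conservation)
is an error; a perfectly invariant crown is treated as the ρ → 0
boundary.

## Synthetic data

Generators are pure functions of (parameters, seed); one global seed
expands into per-generator substreams via `SeedSequence.spawn` in a fixed
documented order, so adding a generator never perturbs another's stream.

* `simulate_alignment` — forward simulation: root states from π,
  propagation with P(t) per branch. No indels and no alignment error.
* `plant_elements` — re-simulates intervals with branch scales by type:
  shared (all branches × ρ), clade-specific type II (clade branches
  including the stem × ρ), type I (as II, plus whole-row gapping of every
  non-clade species — the simplest reading of "no outgroup sequence
  aligned").
* `simulate_stem_onset` — the dating model above, exactly.  The demo
  tree's outgroup side carries a small radiation shortly after the split
  plus a deep anchor: a single distant outgroup leaves the
  element-specific stem length badly resolved (its parent node's state is
  then nearly unobserved and the root split is degenerate), whereas dense
  sampling near the split — what real alignments provide — brings the
  stem-length standard error down to its binomial floor.
* `simulate_snps` — per-position Bernoulli (≈ Poisson) placement with
  separate inside/outside-element densities; the demo uses 1.27 and
  2.59 SNPs per kb, the densities reported for avian conserved elements
  versus the chicken genome average.
* `simulate_intervals`, `simulate_expression`, `simulate_fold_changes` —
  fixtures for the enrichment, tau and candidate-filter stages with the
  planted truth recorded.

The demo dataset (200 kb, 8 ingroup + 3 outgroup species, 30 planted
elements of the three types at ρ = 0.2, element lengths 60–250 bp) is the
standing end-to-end condition; the ingroup tree totals ≈ 1.9
substitutions/site. What passing tests show is recovery under the
generator's assumptions — independent sites, correct topology, no
indels/alignment error inside elements, known calibration ages. Real
alignments violate all of these to some degree; the tests bound
algorithmic correctness, not field performance.

## Numerical choices and limitations

* All internal coordinates are 0-based half-open; GFF3 (1-based closed)
  is converted at the boundary; BED is native.
* Likelihood recursions are rescaled per pattern; HMM recursions use
  scaled forward–backward and are stable at 10⁶ columns.
* Ties in gene ranking and association break deterministically (score
  desc, then gene id; distance, then gene id).
* Optimisers are deterministic (fixed starts); all Monte-Carlo components
  take explicit seeds, so pipeline runs are bit-reproducible.
* Not modelled: rate variation across sites (Gamma), indel evolution,
  amino-acid models, topology search, multi-state conservation HMMs, and
  phastCons-style coverage/length autotuning.
* Onset intervals: symmetric ±2·s.e. intervals undercover slightly when
  the point estimate clamps at a boundary of [t1, t0] (the bootstrap
  distribution piles up there and its s.d. shrinks).  The bootstrap
  s.e. itself is well calibrated away from the boundaries; the clamped
  fraction in the report flags the affected cases, and the percentile
  interval is returned alongside for boundary-heavy elements.
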