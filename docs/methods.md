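# Methods

This note records the models, defaults and numerical choices behind
repliconkit, and what the synthetic-data generators do and do not emulate.

## Codon usage and replicon classification

RSCU is computed on the bacterial code (translation table 11). The two
single-codon families (ATG/Met, TGG/Trp) carry no synonymous signal and are
excluded along with stop codons, leaving 59 informative codons. Replicon
profiles pool codon counts over all CDSs before normalizing — a deliberate
choice over averaging per-gene profiles, so that each codon observation
carries equal weight and short genes are not over-weighted. Codons containing
ambiguous (non-ACGT) bases are skipped rather than resolved; families with no
observation are recorded as missing and imputed at the no-bias value 1.0 only
at clustering time, keeping imputation explicit.

Clustering defaults to Euclidean distance with average linkage (UPGMA); both
are configurable. The agglomeration is implemented directly rather than
delegated to `scipy.cluster.hierarchy` because the classification rule needs
an order-independent tie-break (merge the lexicographically smallest label
pair among minimum-distance pairs) and label-keyed cophenetic distances; on
tie-free inputs the merge heights agree with scipy's, which the test suite
asserts. The chromid call — cophenetic distance to the chromosome ≤ τ × the
maximum merge height, default τ = 0.5 — replaces a visual reading of the
dendrogram with a reproducible rule. τ = 0.5 separates "joins the
chromosome's half of the tree" from "joins as distant as anything in the
genome"; it is a convention, not an estimate, and should be revisited for
genomes whose chromids are unusually diverged.

## Coverage, copy number and prevalence

The depth ratio uses medians of per-window depths (windows default to
1 kb), which are robust to repeat-driven pileups; no GC-bias correction is
applied. Confidence intervals are percentile bootstrap over windows (2,000
resamples, seeded). Decomposition of r into copy number × prevalence is
rule-based with a tolerance of 0.1 around integers (round half up, so
r = 2.5 resolves to 3 copies); the single-copy constraint is supplied by the
user (e.g. a list of RepABC replicons) and never inferred from sequence.
Cases matching neither rule are flagged `ambiguous` with c = round(r),
p = r/c, and in that mode p may exceed 1 — the flag, not the numbers, is the
result. The colony-assay consistency check is the exact two-sided binomial
test with minimum-likelihood summation (outcomes no more likely than the
observed one), which differs between packages and is therefore pinned down
here.

## Assay statistics and prevalence dynamics

All proportions get exact Clopper–Pearson intervals via Beta quantiles;
zero-event outcomes additionally report the rule-of-three bound 3/n. The
loss rate λ = 1 − R^(1/G) assumes a constant per-division loss probability
and exponential growth; its interval is the monotone transform of the
retention interval. G is a required input: generation counts depend on the
cultivation protocol and are not guessed. The prevalence recursion treats
selection as a relative fitness 1+s of plasmid-free cells applied after
segregational loss within one synchronized generation; with s = 0 it reduces
to p' = p(1−λ)/(1−pλ). It is deterministic — drift is modeled only in the
passaging simulator's transfer bottlenecks.

In-silico PCR matches primers by Hamming distance (no indels), the forward
primer on the plus strand and the reverse primer's reverse complement
downstream; no 3′-end weighting is applied (a deliberate simplification —
thermodynamic models are out of scope). Circular templates are scanned
across the origin by extending the sequence by one maximum product length
and deduplicating modular hits.

## RepABC typing

Distances are p-distances; unaligned proteins are first globally aligned
pairwise with match +1, mismatch −1, gap open −5, gap extend −1 (a
substitution-matrix-free default adequate for the distance scale involved;
the scores are configurable). Trees are built by neighbor joining with the
lexicographically smallest eligible pair joined on Q-criterion ties and
negative branch-length estimates clamped to zero with a warning; additive
matrices are recovered exactly (property-tested against random trees). NJ
with distance inputs replaces likelihood methods deliberately: the grouping
criterion — clade co-membership of RepA and RepB — survives this
simplification, and the result is fast and dependency-free. Bootstrap
support is out of scope.

Groups are flat clusters of the averaged RepA/RepB distance matrix
(average linkage) cut at a user-chosen height; RF(RepA, RepB) is reported as
a congruence check and RF(RepAB, RepC) as the incongruence score that
exposes replicase swapping. Robinson–Foulds is computed on non-trivial
bipartitions, maximum 2(n−3).

The palindrome scanner reports all maximal inverted repeats (arms ≥ 5,
loop ≤ 10, ≤ 1 mismatch by default — short-arm settings matched to
partitioning-site palindromes). Maximality is per center: the arm cannot be
widened without leaving the sequence or exceeding the mismatch budget.
Since inverted repeats are strand-symmetric, one scan covers both strands.
Consensus building center-aligns sites and reports per-column majorities,
with ties as IUPAC ambiguity codes.

## Regulon overlap

Significance defaults to raw p ≤ 0.05 with fold-change threshold 0; BH
adjustment is available and recommended when the gene universe is large —
both modes are provided because published thresholds often leave the
adjustment unstated. Correlation is Pearson on all shared genes (not only
significant ones). Enrichment is the upper-tail hypergeometric with BH
correction across categories. Venn partitions are capped at four sets for
readability.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure each analysis step
assumes, with defaults fixed at the study conditions the acceptance checks
run under:

* **Genome** (7 replicons): chromosome plus two chromids sharing its
  codon-bias vector and four plasmids drawing independent biases from a
  symmetric Dirichlet(α = 0.5) per amino-acid family — a strong but not
  extreme bias contrast. CDSs are codon-sampled (uniform amino acids),
  60 genes of 150 codons on the chromosome, 20 per ECR.
* **Depth**: window depths are Poisson with mean 100 × c × p per copy, 500
  windows per replicon. Defaults follow the coverage pattern of a
  six-plasmid genome: one near-duplicated chromid (c = 1.9), one
  elevated-copy plasmid (1.3), one single-copy plasmid at 50% prevalence.
  Real depth is overdispersed and GC-structured; Poisson is the
  no-overdispersion baseline, so passing recovery tests demonstrates
  estimator correctness, not robustness to mapping artifacts.
* **Assays**: Binomial(70, 0.5) colony screens; passaging runs the
  deterministic recursion for 50 generations (roughly one week of continuous
  culture at a few hours per doubling) at λ = 8 × 10⁻⁵ — the rate scale
  implied by near-complete retention of 450 colonies — with 10⁶-cell
  binomial bottlenecks every 25 generations and a final 450-colony screen.
* **DE tables**: 3,668 genes, a shared regulon of 809 with
  bivariate-normal effects (SD 2.0) against null noise (SD 0.5), the
  within-regulon correlation solved in closed form so the whole-table
  Pearson correlation has expectation 0.76. p-values are Beta(0.05, 1) for
  regulon genes and uniform otherwise — controllable, not a model of any
  particular DE test.
* **Rep families**: two compatibility groups of four taxa, random binary
  topology within groups (branch 0.03 expected substitutions/site, chosen
  together with the 0.4 between-group branch so between-group distances
  exceed within-group ones by ≥ 3×, the separation under which grouping is
  well-posed), protein length 300 (typical ParA-family partitioning
  proteins), site-independent uniform substitutions — only topology and
  distance signal, no rate heterogeneity or indels, which is all the typing
  pipeline consumes. RepC evolves on the guide topology with configured
  taxon swaps. Each group's partitioning segment carries a 6-4-6
  palindrome with at most one mutated position.

All generators are bit-deterministic under their seed.

## Problem sizes and tolerances

Acceptance-level checks run at desk scale: 20 seeded replicates for the
prevalence-recovery, loss-rate and grouping checks; 2,000 simulated screens
for Clopper–Pearson coverage; 2-kb sequences for the exhaustive palindrome
cross-check; random trees up to 12 leaves for NJ exactness. Monte-Carlo
tolerances are derived from the corresponding sampling errors (e.g. mean
recovered prevalence within 2 percentage points of 50% across 20
replicates; bootstrap CI coverage of at least 17/20). Numerical assertions
on closed-form quantities use machine-precision-scale tolerances.

## Known limitations

* The chromid threshold τ and the compatibility-group cut height are
  conventions exposed as parameters, not estimated quantities.
* Depth input is taken as given; ambiguous-read redistribution, duplicate
  removal and GC correction are upstream concerns.
* The prevalence recursion has no drift term; small-population dynamics need
  a stochastic model.
* Primer matching ignores indels and 3′-end effects.
* NJ trees carry no support values; deep typing questions warrant
  likelihood methods on curated alignments.
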