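# repliconkit

Toolkit for characterizing the extrachromosomal replicons (ECRs) of bacteria
with multipartite genomes — the chromids and plasmids that accompany the
chromosome in groups such as the marine *Rhodobacterales*. Given replicon
sequences, annotations, sequencing depth, colony-screen counts,
differential-expression tables and Rep-protein families, it answers five
questions an ECR study keeps running into:

1. **Is a replicon a chromid or a genuine plasmid?** Chromids carry a
   chromosome-like codon-usage imprint; xenologous plasmids do not. The
   relative synonymous codon usage (RSCU) of codon *c* in a synonymous family
   of size *n_aa* with counts *x* is

   RSCU_c = x_c · n_aa / Σ_family x,

   computed over the 59 informative sense codons (bacterial table 11, minus
   ATG, TGG and stops). Replicon RSCU vectors are clustered and each ECR is
   called a chromid when its cophenetic distance to the chromosome is at most
   τ (default 0.5) of the tree's maximum height.

2. **How many copies, in how many cells?** The depth ratio of a replicon to
   the chromosome satisfies r = c · p (copy number × population prevalence).
   `coverage` estimates r as a ratio of median window depths with a
   percentile-bootstrap CI and decomposes it: r near an integer means c
   copies in every cell; r < 1 for a known single-copy replicon means partial
   prevalence p = r. An exact binomial test checks the decomposition against
   a colony screen.

3. **Is the plasmid actually unstable?** Colony counts get exact
   Clopper–Pearson intervals (rule-of-three bound 3/n when nothing was
   lost). From retention R after G generations the segregational loss rate is
   λ = 1 − R^(1/G), and the deterministic recursion

   p' = p(1−λ) / [p(1−λ) + (1 − p(1−λ))(1+s)]

   projects the carrier fraction under loss λ and a fitness advantage s of
   plasmid-free cells — showing directly whether instability can explain an
   observed prevalence. `plasmid_burden` multiplies the genomic proportion by
   the DNA-synthesis energy fraction; `insilico_pcr` predicts colony-PCR
   products, including on circular templates.

4. **Which RepABC compatibility group?** RepA/RepB partitioning proteins
   evolve synchronously while the replicase RepC is swapped between modules,
   so typing rests on the partitioning proteins: p-distances,
   neighbor-joining trees, the Robinson–Foulds distance RF(RepA, RepB) as a
   congruence check and RF(RepAB, RepC) as the incongruence score, plus
   detection of the diagnostic palindromes (inverted repeats) that anchor
   RepB-mediated partitioning.

5. **Do strains share a regulon?** Significant gene sets (p ≤ α, optional
   BH adjustment), disjoint Venn partitions, whole-transcriptome Pearson
   correlation of log2 fold changes, upper-tail hypergeometric category
   enrichment, and per-replicon RPKM medians.

A `simulate` module generates all of these inputs with known truth
(codon-bias groups, depth from c × p, binomial assays, passaging with loss,
correlated DE tables, Rep families on congruent vs. swapped topologies), so
the entire pipeline is testable without any download.

## Worked example

Generate a synthetic six-ECR genome and run the pipeline:

```bash
repliconkit simulate --seed 3 --out-dir sim
repliconkit rscu --genome sim/genome.fasta --annotation sim/genome.cds.tsv \
    --chromosome-id chromosome --out-prefix rscu
repliconkit coverage --depth sim/depth.tsv --chromosome-id chromosome \
    --single-copy-list plasmid_102 --seed 3 --out cov.tsv
```

`cov.tsv` (the simulator's truth: chromid_153 at 1.9 copies, plasmid_86 at
1.3, plasmid_102 single-copy in half the cells):

```
replicon_id   r     ci_low  ci_high  c  p     mode
chromid_153   1.9   1.871   1.919    2  0.95  ambiguous
chromid_72    0.99  0.98    1.000    1  1.0   integer_copy
chromosome    1.0   1.0     1.0      1  1.0   integer_copy
plasmid_102   0.5   0.485   0.51     1  0.5   single_copy_partial
plasmid_126   1.0   0.99    1.020    1  1.0   integer_copy
plasmid_191   1.0   0.980   1.010    1  1.0   integer_copy
plasmid_86    1.3   1.277   1.32     1  1.3   ambiguous
```

The 0.5 ratio of `plasmid_102` is read as a single-copy replicon present in
50% of cells; the classification in `rscu.classification.tsv` calls both
chromids "chromid" and all four plasmids "plasmid". A colony screen of 35/70
positives is fully consistent with p = 0.5:

```bash
repliconkit assay --tested 70 --positive 35 --generations 50 --model 8.9e-5,0,1.0
```

```json
{
  "prevalence_pct": 50.0,
  "ci_pct": [37.80, 62.20],
  "stability": {"loss_rate_per_generation": ...},
  "projection_final_prevalence": 0.9911
}
```

The projection shows that a loss rate of 8.9e-5 per generation leaves more
than 99% of cells carrying the plasmid after 100 generations — segregational
instability cannot produce a 50% prevalence on laboratory timescales.

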