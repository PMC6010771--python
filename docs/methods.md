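# Methods

`snpbarcode` designs species-diagnostic SNP panels from short multi-species
RAD loci and evaluates them on diploid genotype matrices. This note records
the models, the defaults and why they are what they are, what the synthetic
data does and does not emulate, and the numerical choices a maintainer would
want to know about.

## Input model

A *locus* is an alignment of equal-length (default 85 bp) per-individual
consensus sequences over the IUPAC alphabet. One character encodes one
diploid genotype: `A` ≙ A/A, `R` ≙ A/G, and so on; `N` and `-` are missing.
Three- and four-allele ambiguity codes (`B`, `D`, `H`, `V`) cannot encode a
diploid call; they contribute no allele copies and raise a per-site flag.
Individuals map to *species groups* via a three-column table
(individual, species, group); the group is the unit of diagnosis, so
genetically indistinguishable sister taxa or a regional species complex can
be pooled. Coordinates are 0-based internally and 1-based in reports.

## F_ST scan

At every site of every locus, genotypes expand to allele copies per group
(`R` → one A + one G). For each pair of groups with at least 2 allele copies
each, F_ST is computed on the two most frequent alleles pooled across the
pair; sites with more alleles are flagged multiallelic (extension assays are
biallelic, so a third allele is a design liability, not extra signal).

Two estimators:

* **nei87** (default): `F_ST = (H_T − H_S)/H_T` with `H_S` the unweighted
  mean of the two within-group expected heterozygosities `2p(1−p)` and
  `H_T = 2p̄(1−p̄)` at the unweighted mean frequency. It is hand-checkable
  (9A/1T vs 1A/9T gives 0.64), equals 1 exactly when the groups are fixed
  for different alleles, and 0 at equal frequencies. `H_T = 0` returns 0.
* **wc84**: Weir–Cockerham θ from the a/b/c variance components for two
  populations, using observed heterozygote proportions (site tallies
  therefore keep genotype counts, not only allele counts). θ can be
  negative; the raw value is kept in the record and clipped to [0, 1] only
  for thresholding.

A group is emitted as the *target* of a candidate when its clipped F_ST
against **every** other group with data at the site is at or above the
threshold (default 0.95) — the operational meaning of "this allele singles
the group out". The per-site count of pairwise comparisons at/above the
threshold is recorded on the candidate. A consequence worth knowing: a
clade-level split (two groups vs the rest) does not emit candidates, because
neither side is differentiated from its clade-mates. Candidates are sorted
by (locus, site, group), which makes the scan independent of individual
ordering.

## Screening filters

* **Stringent**: reject the site if any individual of any group carries a
  heterozygote code there; require the diagnostic allele in ≥50% of the
  target group's individuals, counting missing individuals in the
  denominator (the conservative reading — an unsequenced individual is
  evidence of nothing).
* **Relaxed**: heterozygotes tolerated; every group with non-missing data at
  the site must have at least one homozygote, and at least one target-group
  homozygote must carry the diagnostic allele. All-missing groups are not
  held to the rule.
* **Flank rule**: ≥20 bp on both sides of the SNP (sites 20..L−21 of an
  L-bp locus), so amplification and extension primers fit.

Stringent passes are provably a subset of relaxed passes (no heterozygotes
⇒ every non-missing call is a homozygote), and the property is also checked
empirically on simulated sets.

Survivors are classed **fixed** (every non-missing target individual
homozygous for the diagnostic allele, zero carriers elsewhere) or **nearly
fixed** (carriers in >50% of non-missing target individuals and a
cross-group carrier fraction ≤ the leakage tolerance, default 0.05).
Candidates fitting neither class are dropped with a reason code.

## Duplicate-locus removal

Two de novo clustering pipelines run on the same reads recover overlapping
locus sets; shared loci must not enter the panel twice. Pairs are
pre-screened by exact 12-mer seeds on both strands (the BLAST word-seeding
idea: at ≥90% identity over ~85 bp a true pair shares a 12-mer with
probability ≈1, random pairs essentially never), then locally aligned with
match +2, mismatch −3, gap open −5, gap extend −2 per base, IUPAC codes
matching any compatible base. A pair is a duplicate when the alignment
covers ≥95% of the shorter locus at ≥90% identity *and* is the reciprocal
best hit in both directions. The second pipeline's copy is excluded by
convention (configurable). Coverage+identity+reciprocity replaces an
e-value cutoff: at this sequence length the e-value adds no discrimination
beyond these thresholds.

## Panel assembly

Verified candidates are ranked per group: fixed before nearly fixed, then
descending maximum pairwise F_ST, then descending number of threshold-level
comparisons, ties broken lexically by (locus, site) — fully deterministic.
Each group contributes up to the quota ceiling (default 5–6); groups with
too few candidates contribute all they have and the deficit is logged. If
quota ceilings exceed the global cap (default 80), the lowest-ranked surplus
above each group's quota minimum is trimmed. Greedy selection was chosen
over an ILP: instances are ≤10³ candidates and determinism is easier to
reason about and test.

Assay-design surrogates stand in for proprietary primer software (real
thermodynamics is a non-goal): a candidate is *compatible* when each 20-bp
flank of the locus consensus has ≤2 ambiguous/N positions and no gaps and
the focal site is biallelic. Multiplexing packs entries first-fit in rank
order into plexes of ≤40, where two entries conflict if the SNP-proximal
10 bp of their flanks contain reverse-complementary 8-mers (an
extension-primer-dimer surrogate). A new plex opens when needed; under an
explicit plex-count cap, entries conflicting everywhere are reported
unplaceable.

Assay export writes the focal SNP as `[X/Y]` (alleles in lexical order) and
masks every other polymorphic column with the minimal IUPAC code covering
the observed alleles; monomorphic columns emit the consensus base,
all-missing columns `N`.

## Admixture model and hybrid calling

For unlinked biallelic SNPs, individual *i* draws each of its two allele
copies at SNP *l* from cluster *k* with probability `q_ik`; the copy is the
diagnostic allele with probability `p_kl`:

    L = Σ_i Σ_l [ x_il log Σ_k q_ik p_kl + (2 − x_il) log Σ_k q_ik (1 − p_kl) ]

with `x_il` the diagnostic-allele dosage and missing calls skipped. The
likelihood is maximized by EM (multiplicative updates for Q and P, reduced
to matrix products); the ascent is monotone and is asserted per-iteration in
tests. Cluster frequencies are independent between clusters and population
labels never enter the fit. This is a deterministic-given-seed
point-estimate stand-in for MCMC samplers of the same likelihood; for
diagnostic panels with (nearly) fixed differences the likelihood is sharply
peaked and the MLE carries the same assignment information. The
conventional MCMC schedule (burn-in 100,000; 1,000,000 steps; λ = 1.0;
K = 1–6 with 5 replicates) is retained as configuration metadata for
provenance only.

Defaults: `admixture_em` uses 5 random restarts, tolerance 1e−6 (absolute
log-likelihood improvement per iteration), max 2,000 iterations; P is
clipped to [1e−9, 1−1e−9], so a "monotone" assertion tolerates 1e−6 slack.
Q rows of individuals with no data stay uniform. Monomorphic SNPs are
dropped with a warning; K larger than the sample size is an error. Q
columns are identifiable only up to permutation; comparisons against truth
use maximum-overlap bipartite matching.

**Cluster number** is chosen by Evanno's ΔK:
`ΔK(K) = |mean_L(K+1) − 2 mean_L(K) + mean_L(K−1)| / sd_L(K)` over
replicate fits, undefined at the endpoints and flagged (not infinite) when
the replicate SD is zero. `fit_k_range` therefore runs each replicate as
its own seeded fit (3 restarts, tolerance 1e−4, ≤500 iterations — ample for
model selection): the replicate spread reflects the multimodality of the
surface at that K, which is the signal ΔK normalizes by. One caveat is
inherent to pairing ΔK with a deterministic optimizer: on *perfectly* fixed
panels every replicate reaches the same optimum, sd_L = 0, and ΔK is
undefined; ΔK evaluation is meaningful in the nearly-fixed regime (which is
what real verified barcode SNPs mostly are), and the fixed-difference regime
is covered by direct ancestry-recovery checks instead.

**Hybrid calls**: an individual is *pure* when its majority ancestry is
≥ 1 − threshold (default threshold 0.05; the 95% boundary counts as pure,
since the rule is ">5% admixture"); contributors are clusters strictly above
the threshold.

**UPGMA trees** use the allele-sharing distance
`d = 1 − shared copies / (2 × SNPs compared)` (identical homozygotes share
2 copies, overlapping heterozygote/homozygote 1, disjoint genotypes 0;
missing SNPs excluded pairwise; a pair with no shared genotyped SNP is an
error naming the pair). Agglomeration is scipy average linkage with leaves
pre-sorted lexically, so ties resolve deterministically; node heights are
half the merge distance, giving an ultrametric Newick tree.

## Synthetic data

`simulate_locus_set` emulates the *output shape* of a de novo RAD clustering
pipeline on a multi-species sample: per-locus IUPAC consensus alignments,
default 85 bp, a few individuals per species. Exactly
`round(prop_diagnostic × n_loci)` loci carry one planted fixed difference
between a random target group and all others, placed where both 20-bp
flanks fit, so the flank rule never confounds recovery tests.
Within-species background polymorphism (rate `background_theta` per site per
species, default 0.02) is modelled as *segregating* variation: affected
individuals are heterozygous with probability `het_rate` (default 0.5) and
otherwise homozygous for the reference base, so the alternative allele never
fixes within a species. This caps background two-group Nei F_ST at 1/3 and
makes the planted sites exactly the set of threshold-0.95 hits — the
closed-loop property the discovery tests rely on. Missing data is i.i.d.
per base (default 0.02). Runs are bit-reproducible given the config.

`simulate_offspring` draws diploid genotypes from per-group panel allele
frequencies: *pure* (two gametes from one group), *F1* (one from each
parent), *BC1* (one from the recurrent parent, one from an F1 gamete), with
true ancestry (1, 0), (0.5, 0.5), (0.75, 0.25). `diagnostic_panel_frequencies`
builds the idealized panel from a planted-truth table — fixed by default,
or nearly fixed (e.g. 0.95 target / 0.02 leakage) for evaluations that need
realistic allele leakage or likelihood-surface variance (ΔK).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage between SNPs, coalescent/phylogenetic
correlation among species, shared ancestral polymorphism that *has* fixed
differentially (the real source of false positives between close relatives),
locus dropout correlated with restriction-site mutations, genotyping error,
and deeper pedigrees than one backcross. Recovery rates on this generator
are therefore upper bounds on field performance.

## Problem sizes used in the shipped checks

The acceptance script and end-to-end tests run at desk scale, chosen to
exercise every code path while staying light: 300 loci × 6 groups × 4
individuals for discovery; two 1,000-locus sets sharing 24 loci for
deduplication; 240 individuals × 66 diagnostic SNPs (6 groups, 30 pure each
plus 3 × 20 F1s) for ancestry recovery; K = 1..6 with 5 replicates for ΔK
on 2–4 group datasets. Headline counts from any particular sequencing
campaign depend on its data and vendor software and are not reproduced;
the bundled bookkeeping tables cover that arithmetic instead.

## Known limitations

* The scan's target rule intentionally misses clade-diagnostic (multi-group)
  alleles; diagnosing clades requires running with merged group codes.
* Surrogate assay rules are necessary conditions, not sufficient ones; real
  multiplex design still needs thermodynamic software.
* The admixture model assumes unlinked loci and independent cluster
  frequencies; with correlated frequencies (close relatives) minority
  ancestry is systematically easier to overcall at small panels.
* ΔK inherits its usual blind spots: undefined at K = 1 and at the ends of
  the scanned range, and degenerate when replicates agree exactly.
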