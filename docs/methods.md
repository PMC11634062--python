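# Methods

## Windows, coordinates and strand

All genomic coordinates are 1-based inclusive; BED input (0-based
half-open) is converted at the reader boundary. The scoring window around
an annotated 3'UTR cleavage site (CS) is the CS base extended by 102 nt
on both sides — 205 nt in total — reported in sense orientation: for
minus-strand sites the plus-strand slice is reverse-complemented so that
offset 0 is the CS and negative offsets are upstream in pre-mRNA
coordinates. Variant records stay in plus-strand VCF convention
throughout; ref/alt complementation for minus-strand sites happens at the
single point where a variant is substituted into its window. A window
that does not fit inside its contig is skipped with a logged warning and
counted in the QC report rather than aborting the run — one bad
annotation must not kill a cohort. A ref-mismatch between VCF and genome
excludes the record, again counted. Multi-allelic VCF records are split
into bi-allelic rows at the reader, each inheriting its own per-allele
allele count.

## Scoring and classification

A *scorer* is any object mapping a 205-nt window to an aggregate cleavage
probability strictly inside (0, 1); the variant effect is the difference
of logits, LOR = logit(mut) − logit(wt), which is antisymmetric and
finite on the open interval. External models can be plugged in as a
subprocess (FASTA in, two-column table out); probabilities returned at or
beyond 0/1 are clamped to [1e−9, 1 − 1e−9] with a logged warning because
the LOR is undefined at the boundary.

The built-in surrogate is a logistic model over PAS hexamer counts:
score = σ(−4 + 4·n_AATAAA + 2.5·n_ATTAAA + 0.5·n_background), where the
first two terms count overlapping AATAAA/ATTAAA start positions whose
offset lies in the proximal region [−40, −5] and the background term
counts AWTAAA starts anywhere else in the window. The coefficients are
calibrated so that a single proximal AATAAA yields probability 0.5 and
its loss LOR = −4, ATTAAA loss −2.5 — preserving the empirical ordering
that canonical-hexamer loss is the strongest single-nucleotide effect and
both fall well past the classification threshold — while background
hexamer changes (|LOR| = 0.5) never cross it. The surrogate is
deterministic and dependency-free by design: it makes the whole analysis
testable at desk scale, and it is *not* a re-implementation of any neural
cleavage model. Its positional assumption (signal weight tied to the
window centre being a CS) means that for SNV-centred windows, as used in
the annotated/non-annotated AWTAAA analysis, a scorer parameterized with
a proximal region reaching offset 0 should be supplied; the analysis
function itself is scorer-agnostic.

Classification is threshold-inclusive: UP iff LOR ≥ +1 **and** the
AWTAAA count strictly increases; DOWN iff LOR ≤ −1 **and** the count
strictly decreases; BG otherwise. Hexamer gain/loss is assessed over the
whole window — proximity enters through the window definition — and a
substitution converting AATAAA→ATTAAA leaves the count unchanged, hence
BG. Overlapping hexamer occurrences all count (every start position).

Deduplication keeps one record per unique (chrom, pos, ref, alt, cohort).
Among the multiple (variant, site) pairs of a variant lying near several
cleavage sites, the pair with maximal |LOR| is retained ("strongest
effect", interpreted symmetrically over gains and losses); ties break by
smaller |offset|, then lexicographic site id, then sample id, making the
output provably independent of input order. Recurrence is computed on the
somatic cohort only: `mut_recurrence` counts tumours carrying the exact
variant, `signal_recurrence` counts tumours in which the retained site is
hit by any DOWN variant.

## Statistics

All 2×2 contrasts use the two-tailed Fisher exact test and all
distributional contrasts the two-tailed Wilcoxon rank-sum test, except
the expression analysis, which is one-tailed by construction (the
hypothesis is a negative shift). Rank-sum ties are handled by mid-ranks
with the normal approximation above the exact-enumeration regime — the
standard convention. Variances are unbiased (n−1). Conservation is
summarized both at exact variant positions and as the mean over the
15-nt variant-centred window (±7 nt, forced by symmetry); positions
missing from the track are averaged over with a logged flag. Groups too
small for a test (fewer than two members, or an empty margin) report
missing values, never fabricated zeros.

The mutation-excess ratio for a gene category is
(Σobs/Σexp over category genes) / (Σobs/Σexp over non-Census genes),
computed within one mutation class; it is invariant to gene order and to
uniform rescaling of the expected counts. Its 95% CI comes from
resampling genes with replacement within each role stratum for 1000
iterations and taking the 2.5th/97.5th percentiles of the resampled
ratios (linear-interpolation percentile definition, stated for
reproducibility; the choice is a convention). Resamples with a zero
denominator are redrawn and logged. Genes labelled both tumour suppressor
and oncogene are excluded from the primary contrasts; config switches
allow analysing them separately or merging them into an extended
tumour-suppressor set.

Expression is normalized to a diploid reference, nFPKM = FPKM·2/CN, with
CN = 0 entries masked; no pseudocount is added — pairs where either
member has non-positive or masked nFPKM are dropped and counted, which
avoids pseudocount-driven artefacts in Δ medians. Eligibility requires a
tumour suppressor, detectably expressed (mean FPKM > 1 over its wild-type
samples, configurable), with ≥1 sample carrying a DOWN variant and no
damaging mutation, and ≥1 sample carrying no variant of any kind for that
gene. Every mutant×wild-type sample pair contributes one
ΔLog2(nFPKM); the pooled pairs are the test units (within-gene dependence
across pairs sharing a mutant sample is accepted, not corrected), and the
one-tailed signed-rank test asks for a negative shift.

## What the synthetic generator emulates — and what it does not

The generator produces one contig per gene (overlap bookkeeping is
irrelevant to the method), each with exactly one annotated CS and one
planted PAS hexamer whose start offset is drawn from [−30, −15]; 80% of
genes get AATAAA, the rest ATTAAA. Background sequence is uniform over
{A,C,G,T}; contigs with spurious AWTAAA starts in the proximal region
[−40, −5] are rejected and re-sampled so the planted signal is
unambiguous, while distal AWTAAA occurrences are allowed so the
surrogate's background term is exercised. Strands are assigned at random
so strand-handling is continuously tested.

Population allele counts follow the neutral infinite-sites expectation
P(AC = k) ∝ 1/k truncated at 2N (singletons dominate, as in real
cohorts); purifying selection is modelled as forced-singleton resampling
of DOWN variants with probability `sel_strength` rather than removal, so
the frequency signal is isolated from the abundance signal and DOWN
counts stay comparable across modes. Somatic cohorts draw
Poisson(`mut_per_tumour`) variants per tumour — the Poisson is a
modelling choice, not an empirical burden distribution; a fraction of
variants target planted hexamers, with the target gene drawn with weight
`tsg_boost` for tumour suppressors (renormalized), which implements
positive selection as boosted acceptance of signal-destroying candidates
in that stratum. Tumour-type labels default to a distribution placing
46% of samples in colorectal adenocarcinoma. Expression is log-normal
(gene-level means around 20 FPKM, entry noise `expr_sigma` = 0.4 on the
natural-log scale — a typical within-gene spread for bulk tumour FPKM),
scales linearly with CN/2 before the knockdown, and DOWN-carrying
(gene, sample) pairs are divided by `effect_fold`. Auxiliary tables:
damaging mutations are Bernoulli(0.1) with the probability multiplied by
`cooccur_boost` (capped at 1) in DOWN pairs; burden expected counts are
uniform on [5, 15] with observed ~ Poisson(expected × inflation);
conservation is 0.9 over planted hexamers and 0.1 elsewhere plus noise,
clipped to [0, 1]; CNV calls are gain/loss/neutral with 4:1 gain:loss
odds by default.

The generator reproduces the *statistical structure* the analysis
assumes, not real genomes: no mutational signatures, no linkage or
haplotype structure, no indels, no alternative polyadenylation isoform
competition, and hexamer placement is far more regular than in real
3'UTRs. Passing recovery tests therefore demonstrates that the pipeline
detects the effects it targets when they are present and stays quiet when
they are absent — not that any particular real-data estimate is correct.

## Experiment sizes and determinism

The reproduction experiments use cohorts of 100–200 genes and 100–150
tumours with 50–100 independent seeds per condition, and 500 replicates
for the bootstrap-coverage check; these sizes keep each experiment within
minutes on a single CPU while leaving the injected effects detectable in
essentially every seed (a priori power: the selection contrast compares
singleton fractions of ~0.83 vs ~0.15 with ≥40 DOWN variants per cohort;
the enrichment contrast yields median Fisher p < 0.01 at 200 genes).
Every generator draws from its own child seed stream, so regenerating one
table never perturbs another, and a fixed master seed makes every stage —
including file output — byte-identical across reruns.

## Known limitations

* The surrogate scorer is count-based: it cannot represent
  position-dependent efficiency within the proximal region, flanking
  U/GU-rich element effects, or isoform-level cleavage-probability
  vectors; only the window-aggregate probability is modelled.
* Expected mutation counts for the excess ratio are an input; the package
  does not model genomic mutation rates.
* Protein-level consequence classes (nonsense/missense/synonymous) are
  accepted as labels, not re-derived from sequence.
* Intronic or intergenic PAS discovery and GO-term enrichment are out of
  scope.
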