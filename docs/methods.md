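# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic-community generator does and does not
emulate, and the design decisions taken where the underlying procedure was
genuinely open.

## Synthetic community generator

The generator emulates the structure of a longitudinal six-arm rodent
virome study: treatments {Sham, LPS, monomer, monomer+LPS, PFF, PFF+LPS},
timepoints {Base, T1, T5}, animals housed two cages per arm with two–three
animals per cage (C\<cage\>-R\<rat\> codes). Defaults: 6 animals per arm
(3 in the demo and validation runs, which keeps the full round trip under
a minute on one CPU), 20 000 single-end error-free reads of 150 nt per
sample, genome lengths log-uniform on 1.5–50 kb, 20 % circular genomes,
10 % lysogenic phages (the real-data fraction of integrase/recombinase
carriers is of this order), negative-binomial count dispersion 0.1 (a
typical metagenomic overdispersion and the value assumed by the
differential-abundance stage).

**Topology.** Circular genomes are emitted linearized with their first
k = 20 bases duplicated at the 3′ terminus; k is one shared constant with
the circularity detector, since "analysis of sequence termini" admits many
encodings and an exact terminal direct repeat is the simplest testable one.

**Annotations.** Each viral genome receives length-tiered pVOG annotations
(always two above its curation threshold), three family votes for its true
family, and — if lysogenic — one integrase or recombinase gene. Genomes
sharing a planted cluster label draw pVOG identifiers from a common pool
whose first four members every cluster mate carries, so the gene-sharing
graph connects true clusters with certainty on clean annotations;
cross-cluster pools are disjoint. Bacterial contaminants carry ribosomal
proteins (plus sub-threshold pVOG noise), plasmid contaminants a
replication-protein hit scoring in [20, 80].

**Counts and reads.** Per sample, expected genome weights are the baseline
abundances (interpreted on the expected-count scale) multiplied by
2^log2FC for any (treatment, timepoint) effect, realized as
negative-binomial draws with the shared dispersion. Exactly
`reads_per_sample` reads are then emitted by a multinomial over those
weights: this reconciles NB overdispersion with exact per-sample read-count
conservation, at the cost of a small compositional coupling between
genomes (a strong spike slightly depresses everything else — exactly as in
real relative-abundance sequencing). Read start positions are uniform;
starts on circular genomes may wrap the origin. Reads are error-free and
forward-strand: quality trimming and alignment robustness are outside the
test surface, which is the presence filtering and the statistics.

Passing tests on this generator therefore demonstrate rule and statistical
correctness, not robustness to sequencing error, chimeric assembly,
strain-level microdiversity or host contamination, none of which are
simulated.

## Curation

Evidence pooling is a set union of five routes; the union is monotone in
the evidence by construction. Two conventions were open:

- *Circular auto-acceptance* applies only to virus-enriched assemblies,
  not WGS contigs (plasmids are circular too; the enrichment protocol is
  what justifies the shortcut).
- *Redundancy coverage* is computed relative to the shorter sequence
  (containment). Verification aligns the entire shorter sequence within
  the longer (both strands) using banded infix edit distance (edlib) and
  requires identity ≥ 90 % of the shorter's length; candidate pairs are
  prefiltered by shared canonical 15-mers. Containment matches the
  "retain the larger" intent; an alignment covering only part of the
  shorter sequence would not justify discarding it.

Merging is greedy by descending length with lexicographic contig-id
tie-break, which makes the surviving set independent of input order and
the operation idempotent. Tier boundaries are half-open [lower, upper):
5 000 bp falls in the ≥ 5 kb tier, 20 000 bp in the ≥ 20 kb tier, for both
the pVOG and the breadth tables.

## ORF calling and annotation

The ORF caller is deliberately minimal and deterministic: ATG-only starts,
standard stops, both strands, minimum 30 aa, maximal frames (first ATG
after the previous in-frame stop), calls suppressed if they span an
ambiguity run longer than 10 bases. GTG/TTG starts and ribosome-binding
models are omitted. Lifestyle is a pure function of the annotation table:
lysogenic iff any integrase or recombinase hit, with no score threshold
(none is established for this call). Family is a majority vote counting
proteins, not bit scores; ties are unclassified.

## Clustering

The gene-sharing graph links contigs sharing ≥ 2 protein families (edge
weight = shared-family count). Connected components of size ≥ 2 become
clusters; isolated contigs are unclustered; articulation points — contigs
whose removal disconnects their component — are flagged ambiguous. This
reproduces the three downstream statuses (clustered / ambiguous /
unclustered) that the abundance stage consumes; it is a structural
stand-in, not a reimplementation of network-clustering tools, and the
ambiguous flag is not equivalent to their outlier/overlap categories.
Cluster numbering follows the lexicographically smallest member, so output
is input-order invariant.

## Abundance

The internal mapper is exact-substring (seed 31-mer hash, verify, forward
then reverse complement), appropriate because simulated reads are
error-free; SAM ingestion is provided for externally aligned real data,
taking each alignment's reference span from its CIGAR. A read matching
several contigs is counted once, for the lexicographically smallest
contig id. Breadth is the fraction of reference positions covered by ≥ 1
read (interval union over placements); for circular contigs, positions are
folded onto the genome core (the emitted terminal duplication is excluded
from the denominator). The presence rule is conjunctive — at least 3 reads
AND tiered breadth — and failing cells are exactly zero. Aggregation into
clusters conserves per-sample totals. Marker-based contamination is the
fraction of a sample's reads mapping to a marker-gene database (e.g. the
bacterial housekeeping gene cpn60).

## Diversity

Counts are converted to relative abundances before Bray–Curtis (no
rarefaction; virome depth varies and the simulator conserves depth by
design). Shannon uses the natural log. PCoA drops negative eigenvalues
from both the retained axes and the variance-explained denominator (no
Lingoes/Cailliez correction), and fixes each axis sign by making its
largest-magnitude loading positive, for reproducible output. PERMANOVA
uses the standard one-factor sum-of-squares decomposition on squared
dissimilarities; the p value counts the observed statistic among the
permutations, p = (1 + #{F\* ≥ F}) / (n_perm + 1), with 999 permutations
and an explicit seed by default. The two-group "Wilcoxon" comparison is
the unpaired rank-sum (Mann–Whitney) test; Bonferroni multiplies by the
stated number of comparisons and caps at 1. The per-animal longitudinal
classification calls T5_more_dissimilar iff BC(Base, T5) > BC(Base, T1),
with exact equality a tie; animals missing a timepoint are skipped with a
warning.

## Differential abundance

Size factors are median-of-ratios (per sample, the median ratio of counts
to per-group geometric means over groups with no zeros; if no group is
all-nonzero, geometric means fall back to positive counts with a warning).
Each group is tested per treatment with a Wald z on the log₂ fold change
of normalized means, using the delta-method variance
Var(log μ̂) = 1/(n·μ) + α/n under Var = μ + αμ². Means carry a 0.5
pseudocount. Dispersion α is method-of-moments, floored at 10⁻⁸, and by
default *pooled*: the median per-group estimate is shared across all
groups of a contrast. With few replicates, per-group moment estimates are
far too unstable for a 10⁻⁵ significance threshold — groups whose sample
variance happens to fall below the mean would get near-Poisson standard
errors and flood the results with false positives — whereas the generator
and the model both assume a shared dispersion. A `per_group` mode is
retained. Full shrinkage machinery (empirical-Bayes dispersion trends,
outlier filtering, independent filtering, fold-change shrinkage) is
deliberately not reimplemented: the validation surface here is error
control and parameter recovery, not numerical identity with any specific
package. Bonferroni is applied within treatment over all groups ×
contrasts; contrasts are Base-vs-T1 and Base-vs-T5; treatments are tested
separately (separate runs can be pointed at virome-derived and WGS-derived
count tables). The ±2 log₂FC lines on volcano output are reporting
annotations, not filters.

## Validation problem sizes

The statistical suites use sizes chosen to make the checks sharp yet quick
on one CPU: PERMANOVA calibration on 200 null datasets (12 exchangeable
samples, two groups, 99 permutations — the discrete permutation p is then
exactly uniform on {0.01, …, 1.00}); NB false-positive control on 100 null
datasets of 500 groups × 18 samples; NB sensitivity on 100 datasets with
an 8-fold spike at both follow-up timepoints (6 vs 6 samples, mean 2000,
dispersion 0.1). The full synthetic round trip uses 50 viruses + 10
contaminants, 6 × 3 × 3 samples at 20 000 reads each.

## Known limitations

- The mapper requires exact matches; real reads must be aligned externally
  and ingested as SAM.
- The NB test is asymptotic (Wald); with very low counts or n = 2 its
  calibration degrades, and the pooled dispersion assumes groups share an
  overdispersion scale.
- Circularity detection requires an *exact* terminal repeat; assemblers
  that trim or rotate termini differently would need their own detector.
- The ambiguous-cluster flag is graph-structural and will not match
  network-clustering tools' outlier semantics on real data.
- PERMANOVA is one-factor; repeated measures across timepoints are treated
  as exchangeable samples, as in distance-based adonis practice.
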