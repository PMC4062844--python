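# Methods

## Methylation inference from CpG depletion

### Model

Germline DNA methylation in animals occurs almost exclusively at CpG
dinucleotides, and methylated cytosines deaminate to thymine at an elevated
rate. Over evolutionary time a methylated region therefore loses CpGs
relative to the neutral expectation given its base composition. For a
sequence unit we compute

    CpG O/E = P_CpG / (P_C · P_G),

where P_CpG is the frequency of CpG over overlapping dinucleotide windows and
P_C, P_G are the mononucleotide frequencies. GpC has the same composition but
no methylation-coupled mutation process, so GpC O/E serves as the negative
control for compositional confounding.

**Frequency denominators.** N (and any ambiguity code, which the FASTA reader
maps to N) is excluded everywhere: P_C and P_G use the non-N length L, and
P_CpG uses the number D of overlapping windows whose two members are both
non-N. Ratios are *undefined* — and the unit excluded, with a logged count —
when a sequence has no C, no G, or no valid window; undefined is never
conflated with zero.

### The permutation null and the caller

The null distribution is the multiset of CpG O/E (resp. GpC O/E) values of
non-overlapping 1,000-bp genomic tiles, taken from each contig start with the
trailing partial tile discarded and tiles more than 50% N dropped. Genic
regions are *included* in the background by default (an exclusion option
exists). The empirical p-value of a gene's concatenated CDS is the fraction
of tiles with a ratio *strictly* lower than the gene's; ties count as not
lower, which inflates p and is conservative for a depletion test. CpG and
GpC p-value families are Benjamini–Hochberg adjusted separately, and a gene
is a methylation candidate when

    q_CpG < α  and  not (q_GpC < α),       α = 0.2 by default.

Genes significant in both families are discarded as compositional artifacts,
so the candidate count is the CpG-significant count minus the
dual-significant count.

Because both O/E ratios correlate strongly (negatively) with G+C content,
summary comparisons are additionally stratified into five left-closed GC
bins — [0, 0.35), [0.35, 0.45), [0.45, 0.5), [0.5, 0.55), [0.55, 1] — with a
two-sided Mann–Whitney U test per stratum. The rank test uses the exact null
below a combined sample size of 12 when the pooled values are tie-free and
the tie-corrected normal approximation otherwise. Test units are per-gene
concatenated CDS (not individual exons), oriented by strand; both O/E ratios
are strand-symmetric anyway since CG and GC are reverse-complement
palindromes.

"Gene body" means the full transcript span including introns. UTRs are
pooled (5' + 3') into a single feature class. Each gene is represented by its
longest isoform (summed exon length; ties broken lexicographically by
transcript ID).

## Gene families from H-scores

All-vs-all protein alignment hits (any aligner emitting a raw score and
aligned fractions) are reduced to an undirected graph. Hits for the same
unordered pair are joined before the coverage test: aligned fractions are
summed per gene — treating the hits as non-overlapping alignment blocks —
and capped at 1, while raw scores are merged by maximum. An edge requires
strictly more than one-third of *both* genes aligned, weighted by the
H-score

    H = 100 · score(G1,G2) / max(score(G1,G1), score(G2,G2)) ∈ [0, 100].

Families are produced by average-linkage agglomeration on H-scores with
absent edges counting as 0. A merge is accepted only if the inter-cluster
average linkage exceeds 10 *and* the merged cluster's edge density (existing
edges over k(k−1)/2) exceeds 0.34; gating each merge, rather than pruning
afterwards, guarantees that every emitted multi-gene family satisfies both
constraints (the pairwise-mean linkage bound follows by induction over
accepted merges). Equal-linkage candidates are ordered by the
lexicographically smallest pair of cluster representatives, making the
partition invariant to input order. Cross-species sharing is summarized as
Venn cells: a family occupies a cell if it contains at least one gene of
each species in the subset.

## Divergence and polymorphism statistics

**Four-fold degenerate sites** are third codon positions whose codon family
encodes one amino acid for all four bases (standard nuclear code, via
Biopython's table); codons containing N or gaps are skipped. Watterson's
per-site estimator is Θ_W = S / (a_n · L) with a_n = Σ_{i<n} 1/i; the number
of chromosomes n is a parameter (two diploid individuals ≠ a fixed n, and
published analyses rarely state it).

**Ka/Ks** is Nei–Gojobori (1986) with Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3). Expected synonymous site fractions are averaged over
both sequences; observed differences in multi-hit codons are averaged over
all minimal substitution pathways, excluding pathways through stop codons
(all pathways are used if every one crosses a stop). One deliberate
convention: mutations *to* stop codons count as nonsynonymous in the site
tally, so synonymous + nonsynonymous sites equal exactly 3 per codon — some
NG86 descriptions instead drop stop mutations from the denominator, which
would make the two site classes sum below 3. Codon pairs containing a stop,
gap, or N are skipped with a warning. The correction is undefined at p ≥ 3/4
(flagged as saturated, not an error), and ω = Ka/Ks is undefined at Ks = 0.
Heavier-duty engines (e.g. maximum-likelihood mutation-selection models)
give slightly different absolute values; NG86 was chosen for transparency
and exhaustive testability — the implementation is verified against
brute-force pathway enumeration over all 61 × 61 sense-codon pairs.

Per-gene significance of ω ≠ 1 is a two-sided Fisher exact test on the 2×2
table of (differences, remaining sites) × (nonsynonymous, synonymous), with
fractional counts rounded to the nearest integer, BH-adjusted across genes.

**Variant bookkeeping.** SNP records fail the hard filter when *any* of
QD < 2.0, FS > 60.0, MQ < 40.0, HaplotypeScore > 13.0,
MappingQualityRankSum < −12.5, ReadPosRankSum < −8.0 holds; missing
annotations pass their criterion (the GATK convention), with a logged count,
and all violated criteria are reported per record. A site is private to
sample A when A carries a non-reference allele and B is homozygous
reference; sites with a missing genotype in either sample are excluded and
counted. Window scans use non-overlapping 100-kb tiles from each contig
start ("increments" read as step = width), emitting empty windows
explicitly.

## Enrichment

Per term, the 2×2 set-membership × annotation table is tested two-sided:
Fisher exact when any expected cell count is below 5 (Cochran's rule — the
switching criterion had to be fixed here), chi-square without continuity
correction otherwise. P-values are BH-adjusted across terms; default
reporting threshold q < 0.05. No ontology structure is used; term IDs are
opaque labels.

## The synthetic-data generator

Every generator is a deterministic function of (config, seed) through a
single `numpy.random.default_rng` stream; identical inputs give
byte-identical FASTA/GFF3/TSV/VCF/JSON output, and every simulation emits
its ground truth.

**Genome.** An i.i.d. background at configurable G+C (default 0.40, a
typical AT-rich insect genome) with embedded genes: intact ORFs (ATG, no
internal stops, terminal stop) whose codons are drawn base-wise at the
background composition with stop-codon rejection, so unmethylated CDS match
the background dinucleotide statistics up to the (small) stop-exclusion
bias. Default study conditions: 5 Mb, 200 genes, 50% methylated, δ = 0.5,
α = 0.2 — the conditions under which caller recovery is asserted
(sensitivity and specificity > 0.9). Gene geometry defaults — 300–700
codons, 3–6 exons, 80–500 bp introns, 50–300 bp UTRs, ≥ 200 bp intergenic
spacing, uniform placement over feasible positions — are insect-typical and
give CDS lengths (~0.9–2.1 kb) comparable in variance to the 1,000-bp
background tiles. Not emulated: splice motifs, repeats, codon-usage bias,
isochores, real CpG overabundance (an i.i.d. genome has O/E ≈ 1, whereas
real hymenopteran genomes can sit near 1.6); passing recovery tests
therefore demonstrates correctness of the inference machinery under the
stated statistical model, not performance on any real genome.

**Deamination** replaces the C of each CpG inside methylated genes' spans by
T independently with probability δ, on the forward strand only (CpG is its
own reverse complement, so this depletes CpG symmetrically). An optional
synonymous-preserving mode restricts edits to CDS CpGs whose C→T change is
silent, for both strands via the transcript coordinate map. A second-order
effect worth knowing: removing cytosines slightly *raises* GpC O/E
(~+0.01 at δ = 0.5 here) through the P_C denominator and GCG-context
clipping. The shift is deterministic — a paired test across many replicates
on one genome will detect it at any α — but it is far below per-gene
sampling noise, is in the harmless direction for a lower-tail control, and
never makes the within-replicate methylated-vs-unmethylated GpC comparison
significant; the control property is asserted in that per-replicate form.

**Divergent pairs** use rejection sampling, mirroring how the Ka/Ks engine
counts opportunity: each site proposes one of its three alternative bases
uniformly; the proposal is accepted with probability `syn_rate` if
synonymous, `nonsyn_rate` if nonsynonymous, never if it creates a stop.
Realized class-specific change rates are therefore proportional to NG86 site
fractions, and a 3:1 planted rate ratio (defaults 0.06 / 0.02 per site —
moderate divergence, well inside the Jukes–Cantor domain) yields median
ω ≈ 0.3.

**Hit tables** realize planted partitions directly in H-score space
(within-family H in [60, 90] with coverage > 1/3; one between-family hit per
family pair with H < 5 and coverage < 1/3; fixed self scores), which makes
exact recovery a sharp test of the graph construction and merge gating.
**Variant tables** plant private-to-A, private-to-B, and shared sites with
passing GATK annotations, optionally giving a configurable fraction one
violating annotation each (cycling through the six criteria).

## Problem sizes and runtimes

The test suite runs the full 5-Mb / 200-gene / 5,000-tile caller recovery,
the 61 × 61 codon-pair oracle, 100-gene ω recovery, and 230-record VCF round
trips in well under a minute on one CPU; these sizes were chosen as the
smallest at which the asserted recovery properties are statistically stable.

## Known limitations

- CpG O/E is an indirect, historical signal; the caller identifies
  *candidates* for methylation, not methylation states, and cannot see
  recent or tissue-specific methylation. No bisulfite processing is
  included.
- The empirical p-value has resolution 1/(number of tiles); with BH at
  α = 0.2 and few tiles, q-values saturate coarsely.
- NG86 Ka/Ks is less accurate than ML codon models at high divergence or
  strong codon bias; values are flagged, not corrected, at saturation.
- The clustering is O(k³)-ish in the number of connected genes and is meant
  for desk-scale and per-component use, not million-node graphs.
- VCF handling is limited to biallelic SNP records with the six filter
  annotations; genotype likelihoods, phasing, and indels are out of scope.
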