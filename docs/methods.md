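# Methods

This note documents the models, algorithms and numerical choices behind
each stage, what the synthetic-data generator does and does not emulate,
and the known limitations. It states no empirical number that the test
suite or `scripts/acceptance.py` does not itself recompute.

## Study design being emulated

The package targets studies of obligate, vertically transmitted bacterial
endosymbionts sequenced from two host-associated clades (here 5 + 2
ingroup isolates) plus outgroup relatives: genome-skimming community
profiles, a pangenome over closed genomes, SNP variation within the core
genome stratified by nutritional-pathway category (essential amino acid,
non-essential amino acid, vitamin/cofactor, background), genome-wide
association of sequence variants with host clade, GO enrichment of the
implicated genes, and selection analysis of the implicated pathways.

## Community profiling

Assemblers report kmer coverage `C_K`; for reads of length `R` and kmers
of length `K` the expected read coverage is `C = C_K · R / (R − K + 1)`,
exact under uniform read start positions. Hits are kept when identity is
strictly greater than 75% and the alignment is at least 100 bp — the
identity clause is read as strict and the length clause as inclusive;
both thresholds are configurable. Coverages of hits to the same species
within a sample are summed (combining variants) before relative
percentages are formed. Species→group assignment comes from an external
lookup table; unknown species fall into `other`.

## Core-genome SNP statistics

Alignment columns containing any gap or ambiguity character are excluded
from both SNP calling and the effective gene length, making density a
rate per comparable site; multi-allelic columns count once (site-level
density). Density is reported in SNPs per kb (the unit is a constant
factor and does not affect rank tests). Columns with gaps in strictly
more than 5% of sequences are removed before concatenated-alignment
analyses.

Category comparisons use the one-sided Mann–Whitney U: mid-ranks for
ties, tie-corrected variance, no continuity correction, sidedness taken
in the direction of the observed mean-rank difference, and the sign of Z
indicating that direction. For small samples (n1 + n2 ≤ 16) the p-value
is computed by complete enumeration of the permutation distribution
rather than the normal tail: the normal approximation errs by up to
~0.17 at n1 = n2 = 2 and is only trustworthy from roughly n1 = n2 = 8
upward (where the suite verifies agreement within 0.02). Real-data
comparisons over hundreds of genes always use the normal tail.

Pangenome summaries count core genes (present in every genome),
group-unique genes (present in at least one genome of a group and absent
outside it) and genes shared across a designated subset, with
percentages rounded to one decimal as conventionally printed. The clade
age extrapolation is a linear 16S clock — `age = 216 My · divergence% /
2.8%`, floored to whole My — and inherits all caveats of single-marker
linear clocks.

## De Bruijn kmer GWAS

The graph is built over canonical kmers (lexicographic minimum of kmer
and reverse complement; default k = 31, odd k avoids palindromes) with a
presence bit per genome. Edges are the (k−1)-overlaps actually observed
as consecutive windows in some input genome, stored with their
reverse-complement mirrors; this makes the graph invariant to input
order and to strand-flipping any genome, and avoids phantom hairpin
edges through reverse-complement-palindromic overlaps. Unitigs are
maximal non-branching paths additionally broken wherever the presence
vector changes, so each unitig has a single well-defined
presence/absence pattern.

Association uses a one-sided Fisher exact test of presence against the
two ingroup phenotypes (outgroups stay in the graph, out of the test),
toward the observed enrichment direction, with Benjamini–Hochberg FDR
across all informative unitigs. This replaces the lineage-aware linear
mixed models of full DBGWAS pipelines — a deliberate simplification: with
two clades and clade-fixed variants the problem reduces to a 2×2 table.
A consequence of small samples is that with n0 + n1 tested genomes the
smallest attainable p is `1/C(n0+n1, n1)` (0.0476 for 5 + 2), so an FDR
threshold of 0.05 is reachable only when nearly every tested unitig
carries signal. `select_associated` therefore falls back, when nothing
passes FDR, to the clade-perfect unitigs — those attaining that minimal
p, i.e. presence exactly tracking one clade — and labels which rule was
used. Significant unitigs are mapped to the gene containing the leftmost
exact match of any member kmer on a designated reference isolate (first
phenotype-0 genome by default); unmapped variants are reported as
intergenic. Variants private to the non-reference clade have no exact
match on the reference and land in the unmapped bucket; their
complementary reference-allele unitigs carry the same association signal
and do map, so gene-level recovery is unaffected.

## GO enrichment

Annotations are propagated to all `is_a` ancestors (true-path rule);
namespaces are analyzed independently. Each term's p is the upper tail
of the hypergeometric distribution. The elim correction processes terms
leaves-first (by longest path to a root) and, whenever a term's p is at
or below the threshold (default 0.05), removes that term's genes from
all strict ancestors before they are tested; both raw and elim p are
reported. The hybrid weight01 scheme of topGO is not reproduced — elim
is the implementable, well-specified member of that family — and
following the convention of topology-corrected GO tests, reported
p-values receive no further multiple-testing adjustment. The `expected`
column is `annotated · n_study / n_universe`, so expected/annotated is
constant within a namespace by construction.

## NG86 dN/dS

Per codon, synonymous site counts are the sum over positions of
(synonymous single-base changes) / (single-base changes not creating a
stop), with n = 3 − s; mutations to stop codons are thus excluded from
the opportunity space (implementations differ here — Biopython counts
them — producing few-percent differences in dN and dS; the test suite
pins this package's convention against an independent enumeration oracle
and cross-checks Biopython at loose tolerance). Differences between
codons are averaged over all minimal substitution pathways that avoid
stops (all pathways, if every one is blocked, with through-stop steps
counted nonsynonymous). Sites are averaged over the two sequences;
codon columns containing gaps, ambiguity or stops are skipped pairwise.
Distances use the Jukes–Cantor correction `d = −(3/4)·ln(1 − 4p/3)`,
undefined at p ≥ 3/4 (flagged, reported NA).

Pathway-level ratios pool counts (Nd, Sd, N, S summed over all
cross-clade pairs for `between`, within-clade pairs for `within`) before
forming dN/dS; per-pair averaging is available behind a flag. The ratio
is NA when both distances are zero or when dS is zero/undefined while
dN is positive, and exactly 0 when dN = 0 with synonymous divergence
present — never infinity.

## Codon site models (M7/M8)

The likelihood engine is a GY94-style model over the 61 sense codons:
single-nucleotide exchanges at rate `π_j · κ^[transition] · ω^[nonsyn]`,
F3x4 codon frequencies estimated from the data (with a pseudocount),
and ω per site class — M7 draws ω from Beta(p, q) discretized into 10
equal-probability classes whose rates are conditional bin means; M8 adds
an 11th class at ω_s ∈ (1, 50] with weight p1 = 1 − p0. Likelihoods come
from Felsenstein pruning with per-node rescaling, all classes batched;
transition matrices use the symmetric eigendecomposition available for
reversible rate matrices. Because one global rate multiplier is a free
parameter (input branch lengths are used up to this single scaler; full
branch-length optimization is omitted for tractability), the rate matrix
is left unnormalized — only relative rates between classes matter.

Optimization is bounded L-BFGS-B on log/logit-transformed parameters
(M7: p, q, κ, scaler; M8 adds p0 and ω_s), with a default start, an
optional caller-supplied start (M8 is normally started from the M7
optimum), and seeded random restarts (default 3 for exploratory fits;
the calibration studies use fewer, see below). For M8 the exact M7
optimum embedded at the p0 boundary is always evaluated as a candidate,
which guarantees the nesting property lnL(M8) ≥ lnL(M7) up to ~1e-8
regardless of optimizer behavior. The LRT statistic 2·(lnL8 − lnL7) is
clamped at zero and referred to χ² with 2 df — conservative under the
boundary null. Positively selected sites are reported by naive empirical
Bayes: posterior membership of the ω_s class above 0.95 (BEB is out of
scope).

## Synthetic data generator

The generator is the package's study-conditions definition, not a test
dial. Defaults: 5 + 2 ingroup isolates and 1 outgroup; 30 genes of 250
codons in six pathway groups (histidine/threonine EAA, serine non-EAA,
thiamine/riboflavin vitamin, 15 background genes) with ω between 0.10
and 0.25 (endosymbiont-typical purifying selection); κ = 2; ingroup
root-to-tip depth 0.05 substitutions/site; R = 150, K = 101 for the
coverage equation; four community species spanning both host groups.

Codon evolution is propose–filter: Poisson-many single-base proposals
per branch (transitions weighted κ), stop codons rejected, synonymous
changes accepted, nonsynonymous changes accepted with probability
min(1, ω); for ω > 1 the proposal rate is inflated by ω, so the realized
nonsynonymous/synonymous rate ratio tracks ω on both sides of 1. The
suite verifies NG86 recovers planted ω within ±0.1 on ~10 kb
concatenations and recovers the rank order of ω ∈ {0.05, 0.5, 1.5} in
≥90% of seeds. Clade-fixed variant sites are planted after evolution as
single-base codon differences, fixed within each clade (outgroups carry
the clade-A state), placed with enough margin from gene boundaries that
their k-long graph bubbles stay inside the gene. Genomes concatenate
genes with fixed 50-bp spacers shared across isolates (so spacer kmers
are non-informative); annotation coordinates are 1-based inclusive. The
mini GO DAG has three levels: root, a biosynthesis mid-level term, and
one term per pathway. Everything derives from one seeded generator;
identical config + seed reproduces byte-identical bundles.

What the generator does **not** emulate: sequencing reads and their
errors (genomes are exact), indels and recombination within genes,
horizontal transfer, gene gain/loss along the tree (the pangenome
summary operates on externally supplied presence/absence matrices), and
rate heterogeneity beyond the pathway/site-class structure. Passing
tests therefore demonstrate correctness of the statistical machinery
under the stated generative model, not robustness to alignment error or
assembly artifacts in real data.

For LRT calibration specifically, alignments are simulated under the
*same* GY94 process the fitter assumes (per-site ω drawn from the
discretized M7 or M8 mixtures; branch lengths normalized to expected
substitutions per codon): type-I calibration is only meaningful when the
generating process matches the null family. The propose–filter generator
remains the source of all pathway-level synthetic data.

## Calibration study sizes

Chosen once as desk-scale problem sizes: ω rank recovery uses 20 seeds
of 3 pathways × 4 genes × 250 codons on a 2+2+1 tree; LRT power uses 25
seeds of 300 codons on a 6-taxon tree with p0 = 0.8, ω_s = 5 (fits use
one start per model, M8 started from M7); the null study uses 200
replicates of 60 codons on a 4-taxon tree, with M7 optimized to
convergence and M8 given a reduced iteration budget from the M7 start —
under-optimizing M8 can only shrink the clamped statistic, so the
type-I estimate errs conservative. GWAS exactness uses the default
study layout with ingroup depth 1e-9 (effectively noise-free), where
the planted clade-fixed sites are the only between-clade differences.

## Known limitations

* The Fisher/BH association stage is a two-clade simplification; it does
  not model within-clade population structure and cannot reach FDR 0.05
  at seven genomes without the documented clade-perfect fallback.
* NEB site identification understates uncertainty relative to BEB.
* Branch lengths are trusted up to one multiplier; badly wrong input
  trees will bias site-model fits.
* The JC-corrected NG86 estimator saturates near p = 3/4; deeply
  diverged pairs return NA rather than a number.
* The elim procedure reproduces the spirit, not the exact output, of
  hybrid weight01-style topology corrections.
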