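# Methods

This note documents the models and procedures implemented in `wildcomp`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish
about real data.

## The synthetic study

`wildcomp.simulate` generates the full input set of a two-genotype
comparison from one ancestral genome. Genotype B is the ancestor plus
planted single-nucleotide substitutions; genotype A keeps the ancestral
sequence. Genotype-specific genes are planted as whole-gene deletions from
the *other* genotype (optionally as diverged-in-place copies, to exercise
the identity gate rather than the absence of a locus). Defaults and their
rationale:

| parameter | default | why |
|---|---|---|
| scaffolds × length | 2 × 300 kb | desk-scale stand-in for Mb-scale scaffolds |
| genes, length, spacing | 60 × 900 bp, 3 kb apart | gene-dense enough for multi-gene blocks |
| `snv_rate` | 0.003 /site | a few substitutions per kb, the right order for a wild-vs-cultivated pair of an inbreeding species |
| pericentromere | interval with 3× multiplier | emulates elevated pericentromeric divergence between wild and cultivated genotypes |
| reads | 100 bp single-end, 10×, 10⁻³ error | short-read resequencing of an inbred line; single-end because the SNV logic gains nothing from pairing |
| LTR pairs | ages 0.5–2 MYA, r = 1.3 × 10⁻⁸ | the grass LTR clock; ages bracket the wild/cultivated split |
| counts | 6 tissues × 2 reps, NB dispersion 0.05, gene means lognormal around ~1000, 10% of genes 4-fold tissue-specific | the transcriptome design of a six-tissue survey at moderate depth |

Randomness: one user seed; every stage draws from its own
`SeedSequence(seed, spawn_key=(stage,))` substream, so outputs are
byte-reproducible and adding a stage never perturbs earlier ones.

Genes are stop-free codon strings so ortholog pairs are valid Ka/Ks input;
planted substitutions are codon-blind, so a fraction of diverged ortholog
copies acquire in-frame stops and are skipped (and counted) by the dating
stage, as in real pipelines.

LTR pairs evolve each copy under an exact JC69 substitution process with
branch length r·T, so the JC-corrected pairwise distance is an unbiased
estimate of 2rT — the quantity the dating formula inverts. Ages for which
the *linear* expectation 2rT reaches 0.75 are refused at generation time.

**What the simulator does not model:** indels and structural variation
other than whole-gene PAV, heterozygosity (both genotypes are treated as
fully inbred), paired-end read geometry, base-quality decay, repeat
families beyond the LTR pairs themselves, GC bias, and expression
correlation between tissues. Tests passing on this generator therefore
establish algorithmic correctness and statistical calibration under
substitution-dominated divergence — not robustness to misassembly,
collapsed repeats or alignment around indels.

## Alignment

`align_local` is a seed-and-extend local aligner: exact k-mer seeds
(default k = 15 nucleotide / 5 amino acid), seed diagonals clustered within
the band width, and a banded Smith–Waterman extension (default band 32,
match +1 / mismatch −1 / gap −2, linear gaps) around each cluster. Within
the band the DP is exact (the in-row gap dependency is resolved with a
prefix-max scan, which is exact for linear gap costs), so on
substitution-dominated instances — where the optimal path stays near the
seed diagonal — the score equals the full quadratic Smith–Waterman
optimum; the test suite checks this against an unrestricted per-cell DP
oracle on >100 instances up to 2 kb. `N` never counts as a match.

Identity is matches over all alignment columns (gap columns included);
coverage is aligned query span over query length, matching the convention
of counting aligned cDNA/protein length against its total length. The
original study gated cross-genome placements by E-value as well; at desk
scale there is no database size against which an E-value is meaningful, so
the gates are score + identity + coverage, all config-exposed, with the
identity/coverage pair (80%/50%) carrying the decision semantics.

Contamination QC unions the assembly spans of all qualifying contaminant
alignments (no double counting) and reports matched bases over assembly
length; the published worked example (783,287 bp over 4.28 Gb → 0.02% at
two decimals) is reproduced by the reporting helper.

## Synteny

Homolog pairs are grouped per (scaffold, chromosome); a chain must be
strictly increasing in gene ordinal on genome A and strictly monotone
(increasing = `same`, decreasing = `inverted`) on genome B, with fewer than
`max_gap` (default 5) intervening genes between adjacent members *on both
genomes* — the stricter reading, since the criterion's side is not
specified — and at least `min_block_genes` (default 3) members. Gap counts
use raw ordinal differences; intervening genes are counted whether or not
they end up in some other block.

Blocks are extracted iteratively: the best remaining chain — maximum
length, then minimum summed gap, then lexicographically smallest ordinal
sequence (a fully deterministic refinement of "leftmost start") — is
emitted and its genes retired. This realises "overlapping candidates
resolved by preference" and guarantees no gene joins two blocks on the same
sequence pair. A backward DP computes optimal (length, gap) values and a
forward reconstruction picks the lexicographically smallest optimum; the
test suite proves equality with exhaustive chain enumeration plus the same
greedy selection on >100 random instances. A post-hoc validator re-checks
every emitted block against the printed criteria, replacing the original
manual-inspection step. Inversions are accepted by default
(`--no-inversions` to disable); a minimum scaffold length pre-filter is
available and off by default.

## PAV (genotype-specific) genes

Three steps, symmetric in the genotypes: (1) cDNA cross-placement with the
80%/50% gates — genes with no passing placement are candidates; (2)
candidates inside syntenic blocks are excluded (a collinear context
evidences a homologous locus the aligner missed); (3) the other genotype's
reads are mapped onto the focal genome and a candidate is confirmed
high-confidence specific iff the covered fraction of its gene body (a base
is covered at depth ≥ 1, configurable) is **strictly below 0.50**. The
source text's sentence literally defines high-confidence specific genes as
those with *more* than 50% coverage, which inverts the stated purpose of
the confirmation step (reads from the other genotype covering a locus are
evidence it is present there); the logically consistent direction is
implemented, with both threshold and direction exposed in configuration.
All accepted read placements count toward coverage, not only uniquely
mapping reads (the original filter is not described at that level of
detail). Coverage is computed over the gene's full genomic span.

## Molecular clocks

* JC69: K = −(3/4)·ln(1 − 4p/3); p ≥ 0.75 raises a saturation error — no
  silent clamping. (One spec'd spot value for p = 0.74 disagreed with the
  formula itself; the formula's value, 3.238, is what the implementation
  and tests use.)
* NG86: per-codon synonymous site fractions (changes to stop codons count
  as non-synonymous), difference counts averaged with equal weight over all
  minimal mutational pathways, pathways through stop codons excluded
  (waived if every pathway is blocked), JC-style correction of pS and pN.
  Verified exhaustively on all 61 × 61 sense-codon pairs against a
  recursive enumeration oracle built on Biopython's codon table, and
  against `Bio.codonalign`'s NG86 on a long diverged alignment. Pairwise
  NG86 is the deliberate desk-scale stand-in for branch-wise codon-model
  ML; the two are not interchangeable and no claim of equivalence is made.
* Ortholog divergence: T = mean Ks / (2 × 6.5 × 10⁻⁹) reported in MYA.
* LTR age: global alignment of the element's two LTRs → p over non-gap
  columns → K → T = K/(2 × 1.3 × 10⁻⁸). Equal-length LTRs are compared
  column-wise: that is the optimal global alignment whenever gaps cost more
  than mismatches, and it avoids a small systematic deflation of p that
  unit-cost edit-distance alignments introduce by trading mismatches for
  gap shifts inside repeats; unequal lengths fall back to edlib's NW
  alignment. Both raw p and corrected K are emitted so either convention of
  downstream summaries can be reproduced. Saturated pairs are returned
  flagged with infinite age rather than raising, since real surveys contain
  ancient elements.

## Variants

The mapper indexes all reference 31-mers (k = min(31, read_length //
(max_substitutions + 1))); by the pigeonhole principle a placement with at
most 2 substitutions leaves at least one of three disjoint seeds exact, so
the search is lossless within the cap. Candidates are verified by direct
comparison on both strands; each read keeps its minimum-mismatch placement,
and ties at distinct loci discard the read as ambiguous. This is a
documented stand-in for the original mapper's undocumented internals: the
depth/mismatch rules are preserved exactly, tie-breaking is made explicit.

Pileup calling: a site is an SNV iff depth ≥ 4 and the most frequent
non-reference allele reaches `min_alt_fraction` (default 0.9 — both
genotypes inbred, so true variants are homozygous; the original tool does
not print this parameter). Window densities tile each scaffold with
non-overlapping windows (default 10 Mb; the trailing partial window is kept
and flagged) and always sum to the SNV total. Internally coordinates are
0-based half-open; VCF is 1-based, BEDGRAPH 0-based.

A known, deliberate blind spot: three or more true variants within one
read length exceed the substitution cap for every spanning read, leaving
such sites uncovered; the perfect-recovery tests therefore condition on the
depth-≥ 4 precondition, and the density-ratio recovery uses divergence low
enough (~1.5/kb arms) for the effect to be negligible. Quality trimming is
reduced to an optional mean-quality filter because simulated reads carry
constant qualities.

## Expression

Size factors are median-of-ratios over genes positive in all samples,
rescaled to median 1 so an untouched sample has factor exactly 1. The
tissue-specific call takes each gene's highest-mean tissue as the only
possible candidate and tests it against every other tissue with a Wald test
on log2 fold change under Var(count) = μ + αμ²; α is a per-gene
method-of-moments estimate pooled over the non-candidate tissues (excluding
the candidate so a genuine shift cannot inflate its own test's variance)
and squeezed toward the genome-wide median with 10 prior degrees of freedom
— the standard moderated-dispersion idea, in its simplest form, rather than
a re-implementation of DESeq2's shrinkage machinery. p-values are
BH-adjusted across the full gene × comparison family (the family is not
specified by the source; this is the conservative documented choice), and a
gene is called iff **every** comparison satisfies both log2FC ≥ 1 and
padj ≤ 0.01 — the fold gate is hard, so arbitrarily significant sub-twofold
elevation is never called. Pairwise one-vs-one contrasts are used (the
all-pass rule); one-vs-pooled-rest is a config option. A gene can be
specific to at most one tissue by construction.

## Pipeline, configuration, formats

`run_pipeline` chains simulate → homology → synteny → PAV (both
directions) → Ka/Ks dating → LTR dating → read mapping/SNV/windows →
expression, writing every stage table plus a `summary.json` that records
every effective parameter (no silent defaults) and is byte-reproducible for
a fixed config. Configuration is TOML with unknown-key rejection; every CLI
flag overrides its key. FASTA/FASTQ I/O uses Biopython, GFF3 parsing uses
gffutils (1-based inclusive on disk, 0-based half-open in memory), VCF
output is minimal 8-column VCFv4.2 with DP/AF in INFO and parses with
pysam.

## Problem sizes used by the checks

The acceptance script and test suite run at desk scale, chosen so the
statistical checks are decisive: oracle equivalence on 100+ instances
(≤ 40 pairs per synteny instance, ≤ 2 kb per alignment, all 3721 codon
pairs); LTR recovery on 50 × 5-kb elements at 1.5 MYA (mean within 5%);
density-ratio recovery on an 800-kb scaffold at 30× error-free coverage
(ratio within 3 SDs of the planted 3×); PAV recovery on 2 × 100-kb genomes
at 10× (precision = recall = 1); tissue-specific recovery on 3 × 200 genes
(precision, recall ≥ 0.95). Published genome-scale totals (gene counts,
genome-wide SNV counts) require the real multi-Gb data and are out of
scope; the two in-text worked examples (contamination percentage, mean
genes per block) are recomputed from their published inputs instead.

## Known limitations

Linear (not affine) gap costs in the banded aligner; no spliced or
translated alignment; no indel calling; the NB Wald test is asymptotic and
with 2 replicates leans on the moderated dispersion; E-value semantics of
the original homology searches are intentionally replaced by explicit
gates; the block caller's both-sides gap rule is one documented reading of
an ambiguous criterion.
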