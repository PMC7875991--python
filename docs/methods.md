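# Methods

`mirtail` re-implements, as a tested and reusable library, a small RNA-seq
microtranscriptome analysis for studies of miRNA regulation: quantification
of mature miRNAs from hairpin-mapped reads, isomiR and nontemplated-tail
(NTA) calling, localization of uridylation to the precursor via the 5p/3p
arm contrast, surveillance statistics for short degradation fragments,
simplified negative-binomial differential expression, and promoter PWM
scanning. Every analysis is exercised on synthetic reads generated with
complete ground truth, so recovery of each effect can be verified
quantitatively.

## Read processing

Raw reads are processed in a fixed order: 3'-adapter clipping, quality
filtering, length filtering, redundancy collapsing.

* **Clipping** is exact-match: the insert ends at the leftmost occurrence of
  an adapter prefix of length ≥ `min_overlap` (default 8) that either spans
  the whole adapter or runs to the read end. No mismatches are tolerated in
  the adapter match; this is the simplest reproducible contract and the
  simulator emits error-free adapters by default. Reads without an adapter
  are set aside (adapterless) and excluded from both analysis branches.
* **Quality filter**: a read passes when ≥ 95% of its (clipped-insert) bases
  have Phred quality ≥ 20. The filter applies to the insert because the
  adapter bases are discarded anyway.
* **Length filter**: inserts shorter than 12 nt are discarded. Two branches
  then share the preprocessed reads: the *quantification branch* additionally
  caps insert length at 30 nt (emulating PAGE size selection of 10–30 nt
  libraries); the *modification branch* keeps everything ≥ 12 nt.
* **Collapsing** merges identical sequences, conserving the total count;
  output order is count-descending then lexicographic, so downstream results
  are deterministic.

Per-sample accounting is asserted after every run:
`reads_in = adapterless + clipped` and
`clipped = quality_failed + length_failed + kept`.

## Quantification: strict mapping and the ±2 nt window

Collapsed quantification-branch reads are mapped against the hairpin
reference in sense orientation with **no mismatches over the full read
length** (every exact occurrence is reported; the reference is at most a few
thousand short hairpins, so exhaustive substring scanning is exact and
fast). A hit is assigned to an annotated mature miRNA when *both* ends lie
independently within ±2 nt of the canonical ends — i.e. counts aggregate the
canonical sequence with up-to-2-nt-longer templated and up-to-2-nt-shorter
isoforms. Interval containment alone would admit 13–17 nt fragments into the
expression matrix; requiring both ends keeps the expression and surveillance
analyses disjoint. A read assigned to the same miRNA through several hairpin
loci counts once (per-locus hits go to a sidecar table); a read assigned to
distinct miRNAs counts once for each. Tailed reads carry nontemplated bases
and can never survive the exact-match contract — they are counted only by
the modification branch.

## IsomiR calling and tail decomposition

The modification branch decomposes each read into a hairpin-templated core
plus optional nontemplated 5'/3' additions.

**Alignment contract.** Every ungapped sense placement on every hairpin is
considered. Maximal runs of *terminal* mismatches are candidate NTA — up to
3 nt at the 5' end and up to 8 nt at the 3' end, where a 3' overhang beyond
the hairpin end is nontemplated by definition. At most 2 mismatches may
remain in the interior, and the templated core must keep ≥ 10 bases. The
mismatch budget deliberately applies to the interior only: an end-to-end
aligner with a hard total-mismatch cap of 2 cannot report reads carrying
3-nt-or-longer tails, yet oligo-U tails with modal length 3 are precisely
the species of interest.

**Selection** among qualifying placements is deterministic: fewest interior
mismatches, then fewest total mismatches, then smallest absolute 5' offset
of the implied mature, then lexicographically smallest hairpin id, then
leftmost start.

**Decomposition** follows maximal templated extension: walking the read's 3'
end backwards, trailing bases that mismatch the template form the 3' tail; a
tail base that happens to match the template is always attributed to the
template. This matches the definition of "templated" isoforms and makes
every call unique; the alternative (maximal NTA) would inflate uridylation
estimates. The 5' end is handled symmetrically. The implied mature is the
annotation on the aligned hairpin minimizing the absolute 5' offset
(rejected beyond 5 nt). Reads with residual interior mismatches more than
3 nt from both core ends are unclassifiable as end modifications and are
dropped from modification statistics rather than being counted as errors.

Tails are classified U (all T in DNA alphabet), A (all A), or mixed; mono vs
oligo splits at length 1 vs ≥ 2; lengths are reported up to 5 with longer
tails binned at 5. A (miRNA, modification signature) is kept only when its
summed read count is ≥ 2.

An independent brute-force enumerator (trying every hairpin/offset/tail
split and applying the same rules) is kept in the test suite and the
acceptance script; the caller must agree with it read-for-read.

## Modification statistics

* **Profiles.** Per sample, the frequencies of 3'-trimming, 3'-addition,
  5'-trimming and 5'-addition, plus U/A tail histograms. The denominator is
  the total count of mature-assigned *isoform* reads (canonical included).
  A read contributes to every class it exhibits. Calls that look like
  degradation fragments — 13–17 nt, 5'-anchored within ±2 nt, 3' end ≥ 3 nt
  inside the canonical end, untailed — are a separate species class with
  their own statistics and are excluded from the isoform denominator:
  fragment abundance is condition-dependent, and leaving fragments in the
  denominator would systematically dilute every tail frequency in the
  condition with more fragments, producing spurious "changes" in classes
  that did not change.
* **Arm localization.** All 3'-end modifications of a precursor surface on
  the mature 3p product but never on the 5p product, so the 3p/5p ratio of
  U-tail frequency localizes uridylation: a ratio ≫ 1 indicates
  precursor-level tailing, a ratio ≈ 1 (as for A-tails) indicates tailing of
  mature miRNAs. Alongside the plain ratio a continuity-corrected companion
  `((c3p + 0.5)/n3p) / ((c5p + 0.5)/n5p)` is reported, finite even at zero
  counts.
* **Fragments.** A fragment is an exactly-mapping read of insert length
  13–17 nt whose 5' end is within ±2 nt of a mature 5' end and whose 3' end
  is ≥ 3 nt inside the canonical end. Rates are counts per library size;
  the per-miRNA fold change between conditions is
  `(rate_B + pc) / (rate_A + pc)` on replicate-averaged rates with the
  pseudocount scaled to rate units (0.5 / mean library size), so no change
  equals exactly 1 and zero counts stay finite and symmetric.
* **Comparisons.** Unpaired two-sided t-tests per profile statistic across
  replicates, starred at 0.05/0.01/0.001. Zero-variance guard: equal
  constant groups give p = 1; unequal constant groups give p = 0 with an
  `infinite_t` flag.
* **ddCt.** `fold = 2^-((Ct_target,B - Ct_ref,B) - (Ct_target,A - Ct_ref,A))`
  is provided as a utility; qPCR chemistry is out of scope.

## Differential expression

A deliberately simplified, fully documented surrogate for a DESeq2-style
analysis. Dispersion shrinkage, Cook's filtering and independent filtering
are *not* reproduced; all claims are about this surrogate.

* **Size factors**: median-of-ratios (per sample, the median over
  all-nonzero miRNAs of the count ratio to the per-miRNA geometric mean).
* **Expression filter**: baseMean (mean of normalized counts over all
  samples) strictly greater than 10.
* **Test**: per miRNA, dispersion `α = max((s² − μ)/μ², 1e-8)` with `s²` the
  within-group pooled variance and `μ` the grand mean of normalized counts;
  `log2FC = log2((m_B + 0.5)/(m_A + 0.5))`; the delta-method standard error
  uses the NB variance `m + α m²` per group; Wald `z = log2FC/SE` with a
  two-sided standard-normal p-value. The normal reference (rather than a
  t reference) is used because the truncation of α at 1e-8 puts roughly
  half of null genes in a Poisson-variance branch where z is close to
  standard normal; a t(4) reference there is strongly conservative, and the
  normal reference keeps the empirical null type-I error at the nominal
  level (measured ≈ 0.03–0.05 at n = 3+3 over thousands of Poisson null
  genes).
* **Adjustment**: Benjamini–Hochberg (via statsmodels), checked against a
  hand-rolled step-up oracle in the tests.
* **Signature regression**: OLS of one experiment's log2FC on another's over
  miRNAs significant (padj < 0.05) in both, with concordant/discordant
  direction counts. An inverse relationship between two perturbations
  appears as a negative slope.

## Promoter motif scanning

`logodds[b][j] = log2(((counts[b][j] + pc)/(colsum_j + 4·pc)) / bg[b])` in
bits, pseudocount 0.25, uniform background by default; JASPAR-format count
matrices are read via Biopython. Every window of a region is scored on both
strands (reverse complement for minus); the top-k hits are returned with a
deterministic (position, strand) tie-break, and window scores are rounded at
1e-10 so ties break by position rather than floating-point summation order.
Instead of a promoter-corpus z-score background, an empirical p-value is
computed by comparing the region's best score against composition-preserving
shuffles (`p = (1 + exceedances)/(n + 1)`, seeded). No binary "site" call is
made; ranked hits with empirical p are reported.

## The synthetic-data generator

The generator emulates the design of a two-condition knockdown study:
2 conditions × 3 replicates, 200 000 reads per sample by default, over 30
hairpins of 60–90 nt each carrying a 5p mature (within ~[4, 27)) and a 3p
mature (ending 4 nt before the hairpin 3' end), lengths 20–23 nt.

Per-read generative model and the default study conditions:

| parameter | default | meaning |
|---|---|---|
| `isoform_mix` | canonical 0.60, +1 0.03, +2 0.02, −1 0.22, −2 0.13 | templated 3'-end isoform classes; 3'-trimming is the most frequent modification |
| `nta_u_rate` | 5p 0.003, 3p 0.03 | per-read U-tail probability by arm (10× more frequent on 3p: precursor-level tailing) |
| `nta_a_rate` | 5p 0.05, 3p 0.05 | A-tail probability, arm-symmetric (mature-level tailing, the most frequent tailing event) |
| `u_length_dist` | (0.15, 0.25, 0.35, 0.15, 0.10) | U-tail lengths 1–5, mode 3 |
| `a_length_dist` | (0.70, 0.15, 0.08, 0.05, 0.02) | A-tails mostly mono-adenylation |
| `fragment_rate` | 0.01 | probability of a 13–17 nt 5'-anchored 3'-truncation |
| `de_fraction`, `de_log2fc` | 0.2, ±1.0 | fraction of miRNAs differentially expressed in condition B, alternating signs |
| `u_rate_multiplier_B_3p` | 0.5 | condition B halves the 3p U-tail rate (impaired uridylation) |
| `fragment_multiplier_B` | 4.0 | condition B quadruples the fragment rate (impaired surveillance) |
| `seq_error_rate` | 0.0 | uniform substitutions within the insert, never in the adapter |
| `adapter_seq` | TruSeq small-RNA 3' adapter | appended after the tail, so clipping recovers tail-bearing inserts |

Abundances are lognormal(0, 1) shares; per-sample read counts are
multinomial at the configured depth. Tails are appended *before* the
adapter, matching library chemistry. Fragments are untailed 3'-truncations
anchored at the mature 5' end.

**Identifiability.** Hairpin bases in the window where tails can attach
(2 nt inside each mature 3' end through 7 nt downstream, clipped at the
hairpin end) are drawn from {C, G} only, so a U or A tail can never coincide
with the template and the templated/nontemplated decomposition of every
simulated read is unique under the maximal-templated-extension convention.
Real genomes do not have this property: when a genomic T follows the 3' end,
a 3-nt U-tail is indistinguishable from a templated extension plus a 2-nt
tail, and any convention (including the one used here) systematically
re-attributes such bases. The generator removes that ambiguity so that
ground truth is well defined; consequently the recovery tests quantify
pipeline correctness, not the (real-data) rate of template/tail confusions.
Additionally, the 13-nt 5' prefix of every mature is required to occur
exactly once across the reference, which makes every 5'-anchored read —
isoforms and fragments alike — map uniquely.

Determinism: the master seed drives per-sample and per-purpose RNG streams
(numpy `SeedSequence` spawning), and identical (config, seed) produces
byte-identical FASTQ and ground-truth files.

**What the generator does not model:** ligation bias, PCR duplication
structure, 5'-adapter read-through, randomized-end (4N) library chemistries,
chemistry-dependent differences in tail capture, A-to-I editing, and
genomic multi-mapping outside the hairpin reference. Passing recovery tests
therefore demonstrates correctness of the computational contracts, not
robustness to these real-data phenomena.

## Problem sizes used in tests and the acceptance script

The shipped analyses run at desk scale, chosen as the smallest sizes at
which every effect is comfortably detectable: 200 000 reads per sample
(2 × 3 samples, 30 hairpins / 60 miRNAs) for the principal study; 20
simulation seeds for the effect-detection check; 2 000 Poisson-null genes
for type-I calibration; NB dispersion 0.02 (typical residual dispersion of
deeply sequenced miRNA counts) for the power check; 100 000-read studies for
the signature regression; hundreds of randomized reads against the
brute-force caller oracle; 50–100 random 1 kb regions for the scanner
oracle.

## Known limitations

* The NB surrogate has no dispersion shrinkage; at n = 3 its per-gene
  dispersion estimates are noisy, and power/calibration claims hold in the
  tested regimes (moderate-to-large counts), not universally.
* The lenient-alignment contract is this package's own published rule, not a
  reimplementation of any specific aligner's behaviour.
* Fragment detection requires exact mapping; sequencing errors inside
  fragments (when enabled) reduce fragment recall.
* The scanner reports raw log-odds with shuffle-based p-values; scores are
  not calibrated against a genome-wide promoter corpus.
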