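# Methods

`mpracensus` implements a desk-scale version of the computational pipeline
used to census transcription-factor binding-site variants and measure
their allelic regulatory activity with a barcoded massively parallel
reporter assay (MPRA). This note records the models, the parameters that
matter, and the design choices made where more than one reasonable
implementation existed.

## Variant–motif census

ATF4-class bZIP dimers recognise a family of composite 10-mer elements.
We represent each element as a consensus over {A, C, G, T, N} with N
marking lenient positions: C/EBP-ATF `NTGATGNAAN`, CRE `NTGACGTCAN`,
BATF-ATF `NTGACGTGNC` and CREB-C/EBP `NTGACGNAAN`. A biallelic variant is
scanned by embedding each allele in 9 bp of flanking sequence and testing
every 10-bp window covering the variant base, on both strands. The
variant's position within a hit is reported in the consensus's own
orientation (1..10 along `NTGATGNAAN`), so positional summaries are
strand-free.

Classification condenses the two per-allele hit lists:

* **none** — no hits on either allele;
* **disruption** — exactly one allele carries hits; the other allele
  breaks a constrained position (the "intact" allele is recorded);
* **switch** — both alleles hit, but disjoint motif sets (e.g. a
  CREB-C/EBP on the reference allele becoming a C/EBP-ATF on the
  alternative);
* **lenient_change** — both alleles hit the same motif. For a SNP, a
  window shared between alleles necessarily places the variant on an N
  position. In the edge case where both alleles match the same motif name
  but at no shared (strand, offset) window, the motif is still present on
  both alleles and no direction can be predicted, so we classify it as
  `lenient_change` as well; the per-allele hit lists remain available for
  finer treatment downstream.

An optional PWM route scores the same windows by log-odds
(`sum log2(p/bg)`, probabilities floored at 1e-3). A 1:1 PWM built from a
consensus (0.997 on constrained bases) with its threshold set to the score
of the worst consensus-consistent 10-mer reproduces the consensus hit set
exactly; this matched-threshold construction is what the
consensus-vs-PWM comparison tests use, because the external tool's
automatically selected threshold is not available.

## Interval algebra

Coordinates are 0-based half-open throughout (BED convention); VCF I/O
converts to 1-based. Peak merging is the transitive closure of overlaps of
at least 1 bp — bookended intervals do not merge. Context annotation uses
the peak summit with priority promoter > exon > intron > TTS > intergenic;
the promoter is TSS ± 1000 bp with inclusive bounds. Jaccard similarity
optionally resizes every interval to centre ± halfwidth (centre =
floor((start+end)/2)) before self-merging each set. ABC linking retains
element-gene connections with score ≥ 0.015 overlapping a peak by ≥ 50 bp
and keeps up to three genes per peak by descending score, ties broken
lexically by gene id. All of these are verified against per-base
brute-force oracles on ≤ 10 kb fixtures.

## Library design

Oligos follow the fixed 230-nt architecture
`ACTGGCCGCTTCACTG-(175 nt query)-GGTACCTCTAGA-(10 nt barcode)-AGATCGGAAGAGCGTCG`,
the variant centred in the query with 87 nt of genomic flank per side.
KpnI (`GGTACC`), XbaI (`TCTAGA`) and SfiI (`GGCCNNNNNGGCC`) occurrences in
a query are removed one at a time: the earliest occurrence is edited at
the base furthest from the variant (never the variant base), choosing the
alphabetically first replacement that destroys the occurrence and creates
no new site. Promoter-resident variants are cloned on the strand of the
nearest TSS (equidistant opposite-strand ties resolve to "+"); all others
on the positive strand.

Barcodes are sampled uniformly from 10-mer space and filtered:
homopolymer runs > 3 bp; GC fraction outside [0.30, 0.60]; KpnI/XbaI
sites; the poly-adenylation signal `AATAAA`; consensus-motif matches
evaluated on the barcode flanked by 4 bp of vector context on both
strands (user-supplied PWMs are screened the same way); reverse
complements of supplied 7-nt miRNA seeds; and self-complementarity. On
self-complementarity: a hairpin rule of stem ≥ 4 with loop ≥ 3 cannot
geometrically fire inside a 10-mer (4+3+4 = 11 > 10), so the implemented
screen is the generic inverted-repeat check plus rejection of ≥ 6 bp
self-reverse-complement palindromic substrings, which is the form of
self-complementarity a 10-mer can actually express.

Surviving candidates are thinned greedily to minimum pairwise Hamming
distance 3. Two radius-1 Hamming balls intersect exactly when their
centres are within distance 2, so thinning maintains a hash of all ball
members and rejects any candidate whose ball collides — O(31) lookups per
candidate instead of a pairwise scan. Distance ≥ 3 guarantees by the
triangle inequality that a read barcode carrying at most one substitution
is within distance 1 of at most one pool member, which underwrites
unambiguous demultiplexing. Note that random greedy packing saturates
well below the combinatorial bound; pools beyond roughly ten thousand
barcodes may exhaust the sampling budget and raise a capacity error
reporting what was achieved.

Candidate alleles receive 6 barcodes each, controls (positive, negative,
scramble, viral/multimer) 3 each, assigned at random without reuse.
Scramble controls are dinucleotide-preserving shuffles of the reference
query (Eulerian-walk rejection sampling, exact dinucleotide counts
preserved).

## Quantification

Reads are trimmed to their first 35 nt (10-nt barcode + 25-nt constant
vector flank) and matched against the design's 35-mers with a total
budget of one mismatch; reads matching no reference, or more than one,
are tallied as unassigned or ambiguous respectively (assigned +
unassigned + ambiguous = total, always). UMI deduplication uses the
directional-adjacency rule: UMI *u* absorbs *v* when Hamming(u, v) ≤ 1
and count(u) ≥ 2·count(v) − 1, and the number of clusters reachable by
such directed growth is the molecule count. Known edge: the reference
directional implementations resolve long mutation chains with
node-by-node counts exactly as done here, but tie orderings may differ in
pathological multi-step chains; our ordering is by descending count then
lexicographic UMI.

A barcode is retained when it has ≥ 5 molecules in every DNA input
replicate and, in at least one condition, ≥ 5 molecules in every RNA
replicate of that condition. Counts are CPM-normalised per library; each
barcode's RNA CPM is divided by its mean DNA CPM across DNA replicates
(barcodes with zero DNA abundance are excluded and reported), then by the
median of scramble-control ratios within each RNA library — so scramble
activity is 1 by construction and the pipeline is invariant to per-sample
depth rescaling and global RNA-efficiency shifts. Surviving barcodes of a
(query, allele) are averaged into the per-sequence activity table.

## Statistics

**Allelic effects.** Barcode-aware generalised models (MPRAnalyze-style)
exist for this problem; this package uses a fixed-effects least-squares
contrast on log activities, with calibration and recovery on synthetic
truth as its correctness standard. One modelling point deserves emphasis:
every RNA replicate of a barcode shares the same DNA-input denominator,
so per-(barcode, replicate) log activities are strongly correlated within
barcode. Treating the 6 × 5 observations per allele as independent
inflates the allele-contrast precision roughly 2.5-fold and would yield a
type-I error near 0.2 at nominal 0.05. We therefore average log2 activity
within barcode across the condition's RNA replicates first (this also
absorbs additive replicate effects) and contrast alleles across barcodes
(6 vs 6), which is the correct experimental unit. Measured on the
reference simulation (1000 variants, 6 barcodes/allele, 5 replicates,
depth 500, NB dispersion 0.1): type-I 0.054 at nominal 0.05, bias 0.003,
RMSE 0.20 and power 0.993 for a planted log2FC of 1 at FDR 0.05. Fold
change is reference over alternative. Zero activities are floored at half
the smallest positive value and flagged; variants with fewer than two
barcodes on either allele are reported untestable.

**Treatment effects.** Per designed sequence, OLS of log2 activity on
condition + replicate over the per-replicate aggregated activities; the
condition coefficient is the treated-over-control log2 fold change.
Moderated/precision-weighted fitting is out of scope.

**FDR.** Benjamini–Hochberg step-up (statsmodels), computed within
condition across all testable variants; the test suite checks it against
an independent sort-and-cummin implementation.

**Concordance.** For significant (FDR < 0.05) disruption variants, the
effect is concordant when the higher-activity allele is the motif-intact
allele, under the assumption that the factor is a transcriptional
activator. Switch variants predict no direction under that assumption and
are excluded from the concordance denominator, as are lenient changes and
motif-negative variants. A second summary reports, over all variants
predicted to disrupt a motif, the fraction validated by a significant
concordant effect.

**Positional preference.** For each significant variant with a C/EBP-ATF
hit, the higher-activity allele's base (read in motif orientation) is
added to the Hi count at the variant's motif position, the lower-activity
base to Lo; per cell the statistic is log2((Hi+1)/(Lo+1)) and the
preferred 10-mer is the per-position argmax with ties reported as N. One
Hi and one Lo count per variant (unweighted). When both alleles carry
hits, the position shared between them is used; a variant whose two
alleles hit only at different positions is excluded and counted. In a
noise-free simulation whose activities follow match-to-`ATGATGCAAT`, the
procedure returns that string exactly.

**Enrichment and allele frequencies.** Fold enrichment is
(a/b)/(c/d) on the 2×2 of annotated/flagged variants over a defined pool,
with a two-sided Fisher exact p-value. Allele-frequency divergence flags:
common (> 0.05) in ≥ 1 population while rare (< 0.01) in ≥ 1 other
(strict inequalities), and ≥ 5-fold increase/decrease relative to the
reference population (default NFE); a zero reference frequency leaves the
fold-up flag undefined.

## Synthetic data

The generator emulates the reference study design: two conditions
(control and a stress treatment), 5 RNA replicates per condition, 3 DNA
input replicates (a typical number of input-library sequencing runs), 6 barcodes per candidate allele and
3 per control, a 20% scramble subset, and a mean depth of 500 reads per
barcode (a few million reads over several thousand barcodes, the scale
these experiments are usually sequenced at, gives the same order). Counts are negative binomial with dispersion 0.1 around
depth × barcode abundance (lognormal, σ = 0.5); allelic effects enter the
RNA mean as ± half the variant's log2FC per allele and treatment effects
as a per-sequence log2 shift in the treated condition. Default effect
scales: allelic log2FC ~ N(0, 0.5); treatment log2FC ~ N(1.0, 0.25) for
candidates (stress induction of stress-responsive elements) and 0 for
scrambles. Reads are barcode + constant flank + vector filler with a
random 12-nt UMI per molecule; PCR duplicates re-emit a molecule with its
UMI (geometric copy count with mean 1/(1−d)), and substitution errors hit
every base independently (default 1e-3).

Planted motifs: each in-motif variant sits at a sampled position (1..10)
of a realised consensus, uniform over the four motifs and both strands,
with the motif-intact allele randomised between reference and
alternative; realisations are rejection-sampled until the scanner
confirms the intended configuration (intact allele hits, disrupted allele
clean). A configurable fraction of variants is placed outside any motif
and verified to scan clean.

**What passing tests do and do not show.** The generator produces
independent barcodes, exchangeable replicates, homoscedastic NB noise and
error-free truth labels; real MPRA data add transfection batch effects,
barcode-specific RNA stability, amplification jackpots and reference
biases that are not modelled. Calibration and recovery results therefore
validate the implementation, not the adequacy of the linear model for any
particular real dataset.

**UMI information limit.** The directional rule merges any two singleton
UMIs at Hamming distance ≤ 1, so two distinct molecules of the same
barcode and library can be merged by chance even without PCR duplication:
the probability per molecule pair is 37/4^12 ≈ 2.2e-6, and the expected
number of such merges over a study is (number of cells) × C(m, 2) ×
2.2e-6 for per-cell depth m. At depth 500 this exceeds one; at the
round-trip test scale (8 variants, depth 20) it is ≈ 0.05. The bit-exact
round-trip guarantee is therefore stated in two parts: the pipeline
always reproduces the directional collapse of the simulator's true UMI
ledger exactly, and equals the raw molecule counts in the low-depth
regime where the UMI space is collision-free.

## Problem sizes and numerics

Default test-suite problem sizes: 1000 variants for calibration/power,
240 for positional preference, 120 for rank-correlation recovery, 8–10
variants at depth 15–25 for read-level tests, 10-kb chromosomes for
interval oracles. Large count-level simulations use enumerated (index-
encoded) barcodes rather than a filtered distance-3 pool, since they
never demultiplex reads; everything read-level uses real pools.
Degenerate inputs: empty interval sets give Jaccard 0 by convention;
zero-count library columns and exhausted barcode pools raise errors
naming the offender; a t-statistic with zero residual variance maps to
p = 1 when the contrast is 0 and p = 0 otherwise.

## Known limitations

Only substitutions are modelled end-to-end (indels are scanned by
first-altered-base convention but the simulator plants SNPs only); the
miRNA-seed and full motif-database barcode screens act on user-supplied
lists, none bundled; the treatment model is unweighted OLS without
variance moderation; interval operations are plain sweeps adequate for
desk-scale fixtures, not genome-scale workloads.
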