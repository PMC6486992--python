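# Methods

## Coordinates, identifiers and ChrUn

All coordinates are 1-based inclusive, so a circRNA identifier
`Chr2:1524236|1525777` names exactly its back-splice span and round-trips
through the CIRI2-style junction dialect unchanged; BED-like input/output
converts at the boundary. Unanchored scaffolds can be merged into a single
`ChrUn` pseudo-chromosome: scaffolds are concatenated in sorted name order
with a spacer of Ns between them (default 100; configurable, since the
appropriate spacer depends on the largest window any analysis uses), and a
scaffold map records offsets so positions lift and invert exactly.
Because the spacer is N and no sequence analysis in the package matches N,
windows that reach into a spacer contribute nothing — which is the
behaviour "truncate at the N boundary" would produce, without special
casing. Unknown strand is preserved as `unknown`, never coerced.

## Origin classification

Gene annotation gives interval trees of gene spans, exons and introns. The
precedence rule is: (1) exonic if both back-splice coordinates fall inside
exon intervals of one gene; (2) else intronic if the whole span lies inside
a single intron of one gene; (3) else intergenic, which deliberately
absorbs spans that cross gene boundaries or several genes. Parent-gene
ties on nested/overlapping genes go to the gene with the largest span
overlap, then lexicographically smallest gene id, making calls
deterministic. Exon position classes are assigned in transcript
orientation (the first exon of a minus-strand gene is the genomically last
one); a circ covering both terminal exons is reported as the separate
class `first_and_last` rather than folded into `first` or `last`. Lengths
use the spliced (exon-intersected) length where exon structure is known
and the genomic span otherwise; the length histogram bins at 200 nt by
default.

## Alternative circularization

Loci are parent genes for genic circs and connected components of >= 1 bp
span overlap for intergenic circs. A locus class is the common origin of
its members, or `mixture`. Dominance uses the mean SRPBM over all samples:
the dominant isoform must be at least twofold (>= 2x, inclusive) every
other member; a zero-expressed competitor is dominated by any positive
expression, and an all-zero locus has no dominant isoform. Ties at the
maximum cannot be dominant, so a locus has at most one dominant isoform.
Singleton loci are excluded from dominance reporting.

## Splice signals

Donor (`genome[end+1 .. end+2]`) and acceptor (`genome[start-2 ..
start-1]`) dinucleotides are always read on the plus strand and paired as
`donor/acceptor`; GT/AG and the minus-strand equivalent CT/AC are
canonical. No strand inference is attempted — the label spectrum is
reported exactly as read, matching how non-canonical pairs (CT/AT, GA/AG,
...) are conventionally listed. Positions beyond the chromosome degrade to
N, which is never canonical and folds into "Others". The canonical
percentage is printed at one decimal; other percentages at two. The
boundary position-frequency matrix covers `half_window` bases on each side
of both boundaries, each column normalised over counted (non-N) bases.

## Flanking complementary sequences and MITEs

Matching is exact and ungapped: a hit is a maximal substring of the
upstream window equal to the reverse complement of a substring of the
downstream window, length >= 18 by default ("at least 18 bp" and "longer
than 17 bp" being the same threshold on integers). The search
seed-and-extends over a k-mer index (k = min(min_len, 12)) of the
reverse-complemented downstream window, merges overlapping extensions per
diagonal, and suppresses contained matches; the test suite proves it
equivalent to a brute-force dynamic-programming scan on hundreds of random
fixtures. Windows are [start-window, start-1] and [end+1, end+window]
(default 1 kb), clamped at chromosome edges. MITE detection itself is out
of scope; intervals are consumed from BED, and a circ is flagged only when
both windows overlap at least one interval.

## SRPBM and differential expression

SRPBM = junction_reads / (mapped_reads / 1e9) / read_length, computed per
sample; condition summaries use replicate means. Fold changes are
log2((mean SRPBM_treated + c)/(mean SRPBM_control + c)) with pseudocount
c = 0.01 SRPBM to keep zero-count circs finite. Calls use the cut-offs
exactly as printed: |log2FC| > 1 (strict) and BH-FDR <= 0.05 (non-strict).

The test statistic compares pooled junction counts against pooled mapped
library sizes between conditions. With `dispersion=0` this is the
two-sided exact binomial test of the pooled proportion. That test assumes
counting noise only; replicated RNA-seq junction counts are biologically
overdispersed, and ignoring this inflates false discoveries severely (on
the simulated benchmark below, empirical FDR 0.46). The default therefore
estimates a common negative-binomial dispersion theta (var = mu + theta
mu^2) from within-condition replicate scatter — the ratio-of-sums moment
estimator sum(s^2 - m)/sum(m^2) over circs with mean count >= 5, which is
stable even with two replicates (it recovers theta = 0.196 for a true 0.2)
— and applies a Wald test on the log count-rate ratio with variance
1/(k_t + 1/2) + 1/(k_c + 1/2) + theta (1/n_t + 1/n_c): counting noise plus
the biological variance floor of the replicate design. When the estimate
is zero the exact binomial path is used, so p-values are super-uniform
under the pure counting null. Externally computed p-values (e.g. from an
empirical-Bayes NB model) can be substituted by calling `call_de` on them
directly; no empirical-Bayes model is replicated here.

Power at these design parameters is worth stating explicitly: with two
replicates per condition and dispersion 0.2, the variance of a log
fold-change estimate is bounded below by theta(1/2 + 1/2) = 0.2 however
deep the libraries are, so a 4-fold effect yields at most |z| =
log(4)/sqrt(0.2) = 3.1. Under BH at FDR <= 0.05 with 20% true effects this
caps the sensitivity of any calibrated caller near 0.7 (and in practice
lower; DESeq2 on the same simulated counts reaches sensitivity 0.32 at
empirical FDR 0.03, this package's caller 0.37 at 0.05). Large effects
(>= 8-fold) are detected with sensitivity >= 0.8 at controlled FDR. Calls
on 2-replicate designs at modest fold changes should be treated as
underpowered rather than clean.

The global abundance-shift comparison is a two-sided Wilcoxon rank-sum
test on per-circ log2(SRPBM+1) values (exact enumeration for combined
n <= 20 without ties, normal approximation with continuity and tie
correction otherwise; all-tied input returns p = 1).

## Enrichment

Per term with at least one differential parent gene, p = P(X >= k) from
the hypergeometric distribution over (N background genes, K with the term,
n differential), BH-adjusted, ascending-p order with term-id tie-break.
The background is the parent genes of all detected circRNAs in the
analysed tissue — the only defensible background when the universe is
circ-producing genes. Graph-aware decorrelation (topGO's elim/weight) is
deliberately not implemented; the module is a classic per-term test.

## miRNA target scoring

The penalty scheme follows the published plant-target convention:
mismatch 1.0, G:U wobble 0.5, gap 2.0 per position, all doubled over miRNA
positions 2-13 from the 5' end, hits kept at total penalty <= 4.0.
`score_site` computes a global minimum-penalty alignment (gaps allowed,
window length within +-4 of the miRNA); `scan_target` slides equal-length
windows scored gap-free, which is exact under the default cutoff because
an indel pair in an equal-length window already costs >= 4. Overlapping
candidate windows are resolved best-score-first. circRNA sequences are
scanned as the back-splice-joined molecule — spliced exons for exonic
circs, genomic span otherwise — with miRNA_length - 1 bases wrapped past
the junction so junction-spanning sites are visible (switchable). U and T
are equivalent on input. The network keeps circ-miRNA edges for
differential circs and miRNA-mRNA edges for miRNAs retained on the circ
side.

## Synthetic data

The generator is constructive so truth labels are exact, not approximate:

- Background sequence is i.i.d. uniform ACGT; repeats and motifs exist
  only where planted, so flank-search truth is unambiguous (the chance of
  a spurious 18-mer reverse-complement pair in two 1 kb windows is ~1e-8
  per circ).
- Discrete subsets — origin classes (default mix 79.5/4.9/15.6%),
  canonical signals (11.7%), planted flanks, MITE circs, differential
  circs — are allocated by largest-remainder rounding of the configured
  fractions, so cohort proportions match the configuration to within one
  circRNA; randomness enters through placement, sequence and counts.
- Exonic circs sit exactly on exon-boundary pairs, intronic circs strictly
  inside one intron, intergenic circs in gene-free gaps and on unanchored
  scaffolds. Boundary dinucleotides are overwritten with the drawn signal
  pair after placement; placements that would share a dinucleotide slot
  are rejected, so signal truth is exact.
- Planted inverted repeats (24 bp, comfortably above the 18 bp detection
  threshold) are placed inside the circ's own windows, avoiding signal
  slots and other planted sequence, with an explicit cross-talk check so
  no other circ's window pair can see the planted pair — making flank
  precision and recall 100% by construction.
- Junction counts are negative binomial with per-circ lognormal baselines
  (median 20 reads per library, spread sigma = 0.5 on the log scale — the
  junction-read depth per detected circ observed in real leaf (~12) and
  root (~32) libraries), tissue factors (a configurable fraction of circs
  is tissue-specific with a 0.02 factor in the other tissue), salt-induced
  fold changes on the differential subset applied in the treated
  condition, and library sizes lognormal around 5e7 mapped reads; a circ
  appears in a sample's junction table only with count >= 1, which makes
  detection — like real circRNA calling — depth-dependent.
- Parental-gene abundances are fabricated as the summed member-circ SRPBM
  times lognormal noise (sigma 0.6), which yields a clearly positive but
  noisy circ-parent correlation (r ~ 0.25-0.3 on default cohorts); the
  noise parameter controls the achievable r. Term annotations are random
  (1-3 of 15 terms per gene), so enrichment results on synthetic cohorts
  demonstrate mechanics, not biology.

What passing on synthetic data does *not* show: real genomes have repeat
landscapes (so real flank searches see background matches), real splice
sites have sequence context beyond the planted dinucleotides, real
expression has structured covariance, and real annotation terms are
correlated through the ontology graph. The generator validates the
algorithms' correctness, not their field performance.

Fixtures: `tiny` (2 chromosomes, 5 genes, 12 circs), `paper_mix` (the
default 600-circ study-condition cohort), `null_de` (no differential
truth), `de_benchmark` (single tissue, 500 circs, 20% differential at
4-fold, dispersion 0.2, 2 replicates), each at a fixed seed.

## Problem sizes and determinism

Default cohorts (600 circs, 2.1 Mb genome, 8 samples) run the full
pipeline in ~2 s; the test suite and the acceptance script each complete
in well under a minute. All randomness flows through one seeded
`numpy.random.Generator`; identical seeds give byte-identical output
files, which the determinism test asserts over the whole written bundle.
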