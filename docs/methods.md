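# Methods

`bsrwalk` re-implements, as one seeded and testable pipeline, the
computational route by which a recessive maize mutant is cloned from a
forward-genetics screen: bulked-segregant RNA-seq (BSR-Seq) linkage
mapping of the causal locus, followed by subtractive Seq-walking to find
the transposon insertion that tags the gene. Every input can be produced
by the built-in generator with known ground truth, so the whole chain is
checkable end to end without external data.

## The synthetic study

The generator emulates the essential structure of the real experiment at
desk scale. Its defaults define the study conditions used throughout the
tests and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| chromosome | 1 x 10 Mb | random sequence, 80 non-overlapping genes |
| centromere | 4-6 Mb, suppression 0.1 | cM/Mb inside = 0.1 x arm rate |
| arm recombination | 5 cM/Mb | total map length ~41 cM |
| SNP markers | 2,000 | biallelic, double as the genetic map |
| F2 population | 800 | makes a 123-individual mm bulk essentially certain (mm count 200 +- 12) |
| bulks | 123 mutant + 123 wild type | the published pool sizes |
| RNA-seq depth | Poisson(20) per SNP and bulk | free parameter of the study |
| read error | 0.01 per base | symmetric miscall |
| Seq-walking reads | 50,000 per library | flank length N(150, 40) in [30, 300] |
| barcodes | GTCGAT (mutant), CTGCTA (control) | the published library barcodes |
| TIR tag | 25 nt synthetic stand-in | real adapter chemistry not modelled |
| planted insertions | 1 causal + 20 shared + 9 control-private | causal is mutant-private, 10x read weight, inside a gene |

The 10 Mb chromosome is a deliberately compressed stand-in for a ~300 Mb
maize chromosome: per-Mb recombination is higher than real maize so that
the scan still has dynamic range across the chromosome, while the
centromeric suppression preserves the qualitative feature that matters —
a physically wide, genetically narrow mapping interval around a
centromeric locus. The causal gene is chosen nearest the centromere
midpoint, and planted insertion sites are kept >= 1 kb apart so each is
unambiguous at bin resolution.

**Inheritance model.** Gametes follow Haldane's model: parental origin is
a Markov chain along each chromosome, switching between adjacent markers
with probability r = (1 - e^(-2d/100))/2 for their cM distance d (a
Poisson crossover process on the genetic scale, no interference). The
causal locus must coincide with a map marker. Genotypes at that locus
therefore segregate 1:2:1 and the recessive phenotype 3:1.

**Count model.** Per SNP and bulk, read depth is Poisson(mean); each read
samples a uniformly random chromosome of the bulk and reports its allele,
miscalled with probability epsilon. This is exactly binomial read
sampling around the realised bulk allele frequency — no allele-specific
expression and no overdispersion beyond what the finite bulk itself
contributes.

**Read layout.** A Seq-walking read is `barcode + TIR tag + genomic
flank`, with the flank copied from the forward strand starting at the
insertion point. Qualities are constant; nothing downstream uses them.
Coordinates are 1-based inclusive; an insertion position is the first
flank base.

## The linkage model

With the mutant bulk containing only `mm` individuals, the mutant-donor
(P1) allele frequency among bulk chromosomes at a SNP with recombination
fraction r to the causal locus is

    f_m(r) = 1 - r          (mutant bulk)
    f_w(r) = 1/3 + r/3      (wild-type bulk: 1/3 ++, 2/3 m+)

Reads are binomial with a symmetric per-read miscall epsilon, so
p(read = P1) = f(1-eps) + (1-f)eps. The per-SNP posterior of linkage
mixes a prior mass pi on "linked, r uniform over a quadrature grid inside
(0, 1/2)" against the unlinked point r = 1/2:

    P(linked | k) = pi L_bar / (pi L_bar + (1 - pi) L(1/2)),
    L_bar = mean over the r grid of L(k | r).

Defaults: pi = 0.05, eps = 0.01, 64 grid points on (0.0005, 0.4995).
All likelihood work is in log space with log-sum-exp; a zero-depth SNP
returns exactly the prior, and impossible observations at eps = 0 give
-inf log-likelihoods without ever producing NaN.

**Finite-bulk mode.** The default likelihood evaluates frequencies at
their expectations. The exact mode additionally marginalises over the
Binomial(2N, f(r)) number of P1 chromosomes actually present among the 2N
sampled chromosomes of a bulk. This correction is not cosmetic: at depth
50 with N = 123 the variance inflation of the read counts reaches ~20%,
and for strongly unbalanced counts evaluated at the r = 1/2 null the two
modes differ by ~1 in log-likelihood and up to ~0.1 in posterior. The
exact mode is therefore the reference implementation (validated against a
brute-force linear-space enumeration to ~1e-14); the default mode is the
fast approximation used for whole-table scans, converging to the exact
mode as bulk size grows (tested). Interval recovery is insensitive to the
choice because window medians near the peak are saturated either way.

## Scan and interval call

The chromosome is scanned with windows of 100 SNPs stepped by 20; the
statistic is the window *median* posterior plotted at the position of the
window's 50th SNP (ceil(w/2); the median of an even window is the mean of
the two central order statistics — stated because it affects bit-exact
tests). The mapping interval is the maximal contiguous run of windows
with median >= tau containing the peak window, with
tau = max(0.95, 0.5 x peak) by default: the original boundary choice was
a manual marker-based step, replaced here by an automatic, conservative
rule. Ends are converted to cM by linear interpolation between map
markers (constant beyond the terminal markers). A flat profile returns an
explicit no-signal result rather than an interval.

## Seq-walking analysis

Demultiplexing is exact-prefix (6-nt barcodes leave no safe mismatch
margin); the TIR tag is trimmed allowing <= 2 substitutions; flanks must
be strictly longer than 90 bp ("longer than 90 bp" read as strict — the
inclusive variant is one argument away). The built-in mapper is a
deliberately minimal unique-exact-31-mer seed with ungapped extension and
a 5% mismatch budget, adequate for a random synthetic reference; site
tables from a real aligner can be imported via TSV instead. Multimapped
flanks are dropped rather than placed randomly, avoiding phantom sites.
Alignment start points are clustered into 100 bp bins (configurable; the
coarse bin also absorbs the 9 bp target-site duplication, which is not
modelled). Control subtraction removes any sample site within one bin of
a control site; surviving sites are restricted to the mapping interval
and ranked by supporting read count, ties broken towards the lower
coordinate, with the rank-1 site's overlapping gene as the candidate.

Read accounting is exact and asserted on every run:
input = assigned + unassigned; assigned = trimmed + rejected;
trimmed = kept + length-filtered; kept = mapped + unmapped + multimapped.

## qPCR utility

Standard-curve efficiency E = 10^(-1/slope) - 1 (slope of Ct vs
log10 dilution; must be negative), accepted when 0.85 <= E <= 1.05
(inclusive bounds). Relative expression uses the efficiency-corrected
single-calibrator ratio (1+E_t)^(-Ct_t) / (1+E_r)^(-Ct_r) — a
Pfaffl-style correction, chosen because per-primer efficiencies are
measured; with both efficiencies at 1 it reduces to 2^-dCt.

## Determinism and seeds

Every operation is byte-reproducible given its seed. The pipeline derives
one 32-bit seed per named stage from the master seed via
`numpy.random.SeedSequence`, so any stage can be re-run in isolation.
Experiments (recovery over 20 seeds, allele-frequency checks) derive
per-run master seeds the same way from a base seed.

## What passing tests do and do not show

The generator reproduces the design of the experiment, not its biology:
no transcript-level expression structure, no allele-specific expression,
no quality-dependent errors, no PCR duplicates, no paired ends, no
crossover interference, and a random (repeat-free) reference that makes
mapping far easier than a real genome. Recovery rates measured here
(interval containment and rank-1 candidate identification in >= 18/20
seeded runs) therefore validate the *inference machinery* under the
stated model; they are not estimates of power on real data. Problem sizes
(10 Mb / 2,000 SNPs / 50,000 reads, 20-seed experiments) are the
package's default desk-scale study and keep a full acceptance run in the
minutes range on one core.
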