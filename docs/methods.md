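# Methods

This note records the models behind each module, the defaults that
matter, and the design choices made where more than one reasonable
option existed.

## Synthetic genome, cross, and panel

**Meiosis.** Crossovers follow the Haldane model: counts per chromosome
are Poisson with mean equal to the genetic length (physical length ×
recombination rate, default 0.5 cM/Mb), positions uniform, no
interference. A carrier parent is heterozygous with the mutation on its
B6 haplotype; an offspring inherits the mutation iff the transmitted
gamete is B6 at the causal position, and is symptomatic with probability
`penetrance` (default 1) iff it carries at least one mutant allele.
Animals from deeper backcross generations are modelled by scaling the
carrier chromosome's genetic length by the number of meioses since the
founder hybrid (`meioses`); the default mapping cohort mixes 17
first-backcross animals with 7 advanced-generation animals (3 meioses),
matching the composition of the panel-mapped cohort this pipeline
emulates.

**Genome and panel.** The default genome is five chromosomes
(104–182 Mb) standing in for the genome-wide panel, with the causal locus
at chr12:20 Mb. Each chromosome carries 61 panel SNPs of which 35 are
informative between B6 and FVB — the genome-wide panel scale of 1449
SNPs / 833 informative, per chromosome arm. Informative SNPs are placed
one per equal-width stratum (linkage panels are designed for even
coverage; purely uniform placement produces occasional ≥8 Mb holes that
no real array would ship), uninformative SNPs uniformly. The causal
chromosome's proximal 11.9 Mb carries no informative SNPs, reproducing
the real panel's gap. Genotypes are `B6/FVB`, `FVB/FVB`, `B6/B6`, or
`NA`; 1% of calls are missing by default.

**Litters.** Conceived litter sizes are Poisson(`mean_litter_size`,
default 8). Offspring genotypes are Mendelian for the configured parents;
each conceived homozygote dies in utero with probability `lethality`
(default 1). Under full lethality the expected live-litter deficit of
het×het versus WT×het is 25%, and survivors split 1/3 WT : 2/3 het.

## Toy gene

The generator builds a multi-exon gene whose geometry carries exactly
the facts the annotation steps need: a 1786-residue protein; a TTG (Leu)
codon at residue 1730 whose second-position T>A creates TAG; the stop's
last base 36 nt upstream of the final exon–exon junction (penultimate
exon); and a 271-nt 5'UTR so the mutated base is spliced-transcript
position 5460. All of these are configurable; the constructor rejects
self-inconsistent geometries (codon beyond the protein, junction past
the transcript end, planted codon outside the penultimate exon). Filler
codons are random sense codons; the ±12 codons around the planted
mutation are constrained to give both 27-nt flanks 40–52% GC so that a
genotyping assay is designable at the site with ordinary primer lengths
— a property the real locus had. The nine-variant fixture plants the
stop-gain plus five exon-flanking intronic and three 3'UTR
substitutions.

## Locus mapping

Runs of concordant informative genotypes become strain blocks;
uninformative and missing SNPs never terminate a block. Three boundary
conventions are implemented:

* **carrier** (default): FVB-homozygous blocks span exactly their
  outermost concordant SNPs; carrier blocks absorb the inter-SNP gaps,
  and chromosome ends inherit the outermost run's label. Exclusion is
  thus conservative: a carrier animal's causal allele can only be placed
  in an FVB block by a double crossover hidden between two panel SNPs.
* **midpoint**: boundaries at the midpoint between the flanking
  informative SNPs — unbiased for breakpoint visualization, but it can
  clip the true locus out of a carrier block when the defining crossover
  shares an inter-SNP gap with it, so it is not used for candidate
  intersection.
* **flank**: blocks end at outermost concordant SNPs on both sides with
  explicit uninformative gaps.

The candidate locus is the intersection, over affected animals, of
carrier-compatible regions (everything not FVB-homozygous; uninformative
is compatible). A QC filter (`min_exclusion_span`, default off in the
library, 10 Mb in the pipeline) ignores interior FVB runs spanning less
than the threshold: under the no-interference Haldane model such short
runs arise from tight double crossovers that real meiosis (strong
positive interference) essentially never produces, and in genotyping
practice an isolated discordant stretch would be treated as artifact.
The filter acts only in the conservative direction — it can widen but
never narrow the candidate.

## Variant annotation

Classification re-translates the affected codon from the spliced mRNA
(standard nuclear code): synonymous, missense, stop-gain, or noncoding
(5'UTR / 3'UTR / intronic / intergenic). For a stop-gain at residue *r*
of an *L*-residue protein the truncation is *L − r + 1* residues. The
NMD rule is evaluated in spliced-transcript coordinates: the mRNA escapes
decay iff the distance from the stop codon's last base to the final
exon–exon junction is strictly less than 50 nt, or the stop lies in the
final exon. The candidate filter retains missense and stop-gain variants
inside the mapped interval and records a per-variant exclusion reason.
Substitutions that destroy the terminal stop codon fall outside the four
classes and are folded into missense.

## Primer design and in-silico genotyping

Allele-specific primers are anchored with their 3'-terminal base on the
mutated position (forward: upstream flank; reverse: reverse complement
of the downstream flank); length (18–28 nt) is chosen to bring the
nearest-neighbor Tm closest to the 62 °C target. `tm_window` bounds the
accepted deviation (default ±2 °C); because the anchored primers have
only length as a free variable, composition-extreme sites can be
infeasible at ±2 °C, and the pipeline uses a permissive window — the
assay then simply runs at the Tm the site permits. Outside primers are
searched in the flanks (40–260 bp from the mutation) and must match the
inner primers' mean Tm within ±2 °C; the control amplicon spans the
mutation. An optional destabilizing G-for-C substitution at −2 of the WT
reverse primer is applied by flag. Tm uses the Wallace rule (2·AT+4·GC)
below 14 nt and otherwise the SantaLucia nearest-neighbor model under
PCR-like conditions (250 nM primer, 50 mM monovalent salt, 1.5 mM Mg²⁺
with the Owczarzy correction).

In-silico PCR uses a discrete, exactly testable priming rule: a primer
primes a site iff its 3'-terminal base matches and it has at most one
internal mismatch (configurable); products are enumerated for both
primer orientations up to 5 kb. Genotyping runs two tubes — outside
control and outside-F + mutant-R — calling carrier / non-carrier / fail
from product presence; the two-tube scheme cannot distinguish
heterozygous from homozygous mutant, so an optional third WT-allele tube
(off by default) refines carrier calls.

## Segregation statistics

Transmission and penetrance use the exact binomial test with two-sided
p by tail doubling (capped at 1) and Clopper–Pearson 95% intervals. The
litter comparison is the unpaired two-tailed Student t-test (pooled
variance), with a permutation alternative behind a flag; the model
expectation reported alongside is `lethality × 25%`. Degenerate
(zero-variance) inputs yield an exact-equality report instead of a t
statistic.

## Spike trains and firing statistics

**Generator.** Baseline interspike intervals are a gamma renewal process
(shape k, mean 1/rate): k = 1 is Poisson firing (CV ISI = 1), large k
approaches periodicity (CV → 0). Bursts start at Poisson times, contain
a geometric number of spikes (mean `burst_length_mean`), and use
intra-burst ISIs jittered 5% around `intra_burst_isi`. The six
calibrated presets (DCN and Purkinje × WT / mutant-normal-posture /
mutant-abnormal-posture) were fixed so that cohorts at the recorded
group sizes (26/42/56 DCN, 61/76/45 Purkinje cells) reproduce the
published group means of predominant firing rate and CV ISI; burst-free
groups follow the gamma identities (CV = k^−1/2, modal rate =
k·rate/(k−1)), bursty groups pin the ISI mode with the intra-burst
interval. Calibration targets are the *cohort means* of the estimators,
not the analytic identities alone: the reciprocal of a histogram-mode
estimate is upward-biased (Jensen) and, for flat-peaked gamma densities,
wanders across neighboring bins, so baseline rates were centered by
Monte Carlo against the estimator actually used. Default recording
duration is 300 s per cell — a typical stable single-unit epoch — which
keeps the across-cohort spread of every calibrated group mean a few
percent while a full six-group cohort simulates in seconds.

**Statistics.** Average firing rate is spike count over recorded time.
Predominant firing rate is the reciprocal of the ISI-histogram mode:
1 ms linear bins on [0, 1 s] (the bin width is configurable; published
analyses rarely state it, so modal rates are comparable only within
tolerance), the mode taken as the center of the fullest bin with ties
broken toward the shortest ISI (burst-sensitive). The bin-center
convention quantizes the modal rate — an exactly periodic 100 ms train
reads 9.95 Hz, one bin away from 10 — which is why calibration targets
are stated within tolerance, never exactly. CV ISI uses the sample
(n−1) standard deviation over the mean. Cells need ≥10 spikes to enter
summaries; each cell belongs to exactly one posture group. Group
comparisons offer the two-sample KS test and Mann–Whitney; p-values are
exact (equivalent to full permutation enumeration) when both samples
have ≤8 observations (Mann–Whitney: and no ties), asymptotic otherwise.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analyses assume:
Mendelian segregation, Haldane recombination with an informative-SNP
panel, a single fully penetrant locus, ISI distributions with the
published group means. It does not emulate genotyping error beyond
missingness, crossover interference, phenocopies or incomplete
penetrance (unless configured), real exome noise (the variant table
contains exactly the nine in-locus variants), polymerase kinetics (the
priming rule is a discrete 3'-match criterion), or non-stationary firing
within a recording. Passing tests therefore demonstrate correctness of
the computations under the stated models, not robustness to every
pathology of real data.

## Numerical choices and problem sizes

All randomness flows from one root seed through `numpy` SeedSequence
fan-out; identical seed and configuration give byte-identical outputs.
Interval arithmetic is 0-based half-open internally, 1-based in
GFF3/VCF-style files, 0-based in BED. The test and acceptance runs use:
10,000 offspring for sampling-bound checks, 100 seeded cohorts of 24
affected animals for mapping reliability, 1,000 null replicates for
test-calibration, full recorded group sizes (306 cells × 60 s) for the
firing-table recovery — sizes chosen so each check resolves its target
comfortably while the whole suite stays quick.
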