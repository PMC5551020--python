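# Methods

## Scope and model

`canegbs` implements the computational core of a polyploid GBS study:
read preprocessing, in-silico digestion, a binomial depth model for allele
detectability, multi-caller SNP analytics, and PAV/CNV calling from region
read counts. Alignment and the variant callers themselves are out of scope;
the package consumes caller VCFs and region count matrices, and its
synthetic generator stands in for raw data.

## Binomial detectability model (`depth`)

Reads covering a locus are assumed independent draws over the ploidy-many
chromosome copies, so the count of reads carrying an allele at genotype
frequency *x* out of total depth *n* is Binomial(*n*, *x*). The detection
probability for ≥ *k* supporting reads is the upper binomial tail,
evaluated with the scipy survival function; `prob_by_summation` is an
independent term-by-term evaluation with exact integer binomial
coefficients, used as an oracle in tests (agreement ≤ 1e−12 for n ≤ 200 is
asserted).

Assumptions: no sequencing error (reads are "clean"), no allelic mapping
bias, all chromosome copies equally sampled. Under error, the required
depths are underestimates; the model is a lower bound.

`min_depth` inverts the tail by linear search from *n = k*; the tail is
non-decreasing in *n*, so the first *n* reaching the confidence level is
the exact minimum (a weak inequality: P = 0.95 counts as attained — the
computed minima 27/37/56 for ploidy 6/8/12 at k = 2 are consistent with
this reading). Direct evaluation gives **46** for a decaploid; figures of
this quantity are sometimes read as 48, but both evaluation routes here
agree on 46 and the tests assert only route agreement for that ploidy.

`subsample_saturation` subsamples a read multiset without replacement
(ten replicates per fraction by default), maps each subset to a discovered
SNP set via a caller-surrogate rule (≥ 2 reads per locus unless a custom
callable is supplied), and fits an unweighted least-squares line through
(fraction, mean recovery). The line is a local summary for reading off the
fraction needed for a target recovery; the underlying curve is concave, so
extrapolation far outside the sampled fractions is not meaningful.

## Digestion (`digest`)

A sliding scan reports every recognition-site occurrence (overlaps
included; irrelevant for palindromic CTGCAG), with cut coordinate
`site start + cut_offset` (PstI: CTGCA^G, offset 5). A sequence with *c*
cuts yields *c* + 1 fragments that tile it; genome-wide,
`fragments == cut sites + sequences`, asserted on every synthetic genome.
Size selection is inclusive at both bounds (default 51–500 bp). `N` runs
never match but do not split fragments.

One subtlety: because the palindromic site is cut asymmetrically, digesting
the reverse complement mirrors the *interior* fragment lengths exactly
while the two terminal fragments shift by the cut-offset asymmetry (4 bp
for PstI); the tests assert the interior form.

Genic overlap means ≥ 1 bp intersection with any gene interval
(`gene`-type features on GFF3 import; coordinates converted to 0-based
half-open at the boundary). Interval queries use an interval tree;
correctness is checked against a brute-force all-pairs scan.

## Read preprocessing (`reads`)

A read is kept iff it begins with exactly one barcode immediately followed
by the enzyme remnant; the barcode is stripped, the remnant retained
(the convention of tag-based GBS pipelines; configurable). Matching is
exact — no mismatch tolerance — and barcode sets must be prefix-free,
which rules out ambiguity for validated sets; the ambiguous counter still
exists for unvalidated input. The remnant defaults to the full recognition
site `CTGCAG`; biochemically a PstI ligation remnant is often `TGCAG`, so
it is a parameter. Kept reads are trimmed to 64 bp or right-padded with
`A` (pad positions get the lowest quality symbol to keep FASTQ validity).
Reads shorter than barcode+remnant are rejected, not padded: padding
applies only after demultiplexing.

## Variant analytics (`variants`)

SNP identity is (sequence, position, ref, alt-set): matching on position
alone would conflate different substitutions. Concordance tallies, for
every caller subset, the keys found by exactly that subset; cells partition
the non-redundant union.

Dosage classes from a genotype's allele→copy map (which must sum to the
ploidy): one allele → homozygous; two alleles with the rarer at one copy →
single dose; two alleles both ≥ 2 copies → multi dose; ≥ 3 alleles →
multi-allelic. The minor allele is the lower-dosage one; ties break
lexicographically (a tie can never be single dose, so this affects
reporting only). Multi-allelic is a per-sample property of the genotype,
not of the site.

Per-accession summaries use the accession's non-missing loci as the
denominator: heterozygosity % = het loci/loci, SD % = single-dose
loci/loci, multi-allelic % likewise. Ts/Tv counts transitions (A↔G, C↔T)
vs transversions over bi-allelic sites; per-sample mode restricts to sites
where that sample carries ≥ 1 non-reference allele, so accessions can
differ. Zero transversions yield an infinity marker rather than an error.

The depth filter's "minimum per sample" is read strictly — every
non-missing sample must reach the threshold — with an `any` scope option
since the phrase admits both readings.

## PAV / CNV (`pavcnv`)

Normalized depth = 10⁹ · count / (total mapped reads · region length);
invariant under joint scaling of an accession's counts and total. A region
is a PAV when some accession has zero reads while another has ≥ 5
(thresholds configurable), judged on raw counts.

CNVs come from per-pair log2 ratios of normalized depth. Design choices
where the procedure is underdetermined:

- statistics are computed **per accession pair** (each pair has its own
  library-size and noise structure); a pooled mode exists behind a flag;
- regions with a zero raw count in either accession are excluded from that
  pair by default — zeros are PAV signal, not copy number; alternatively a
  pseudocount in each accession's own normalization units keeps them;
- the literal mean ± 3 sd rule is applied (for a Gaussian this is the
  99.73% range, despite often being described as "99%"); sd is the sample
  standard deviation (n−1); pairs with sd = 0 flag nothing;
- a region flagged in ≥ 1 pair counts once toward the CNV total.

## Synthetic data (`simulate`)

Defaults emulate the target study design: a 14-accession panel (four 6x,
six 8x, four 12x) with each accession's observed per-dose depth and
library size; PstI digestion with one site per ~3.4 kb; 100-bp reads of
which 74% are clean; five callers with sensitivities spanning 0.22–0.76;
~20% PAV and ~2.6% CNV region load with 4-fold changes. Heterozygosity
0.25, single-dose 0.125 and multi-allelic 0.02 per locus/accession are
mid-range values for such panels; they are per-locus category
probabilities (homozygous = 1 − het; multi-dose is the heterozygous
remainder). The site-level alternate allele is a transition with
probability 0.62 (Ts/Tv ≈ 1.66).

Generators and their truths:

- genomes have recognition sites planted by a fixed or geometric spacing
  model over a uniform background, with a rejection pass mutating any
  accidental occurrence — a scan recovers exactly the planted sites;
- total depth per locus is Poisson around the accession mean (a fixed-depth
  mode exists for exact binomial checks); allele reads are multinomial with
  probabilities dosage/ploidy — precisely the model `depth` assumes, which
  makes the coupling test between the two modules meaningful;
- caller VCFs include each truth locus with the caller's sensitivity
  (independent Bernoulli) plus caller-specific false positives at positions
  disjoint from the truth set, so the all-caller intersection stays
  interpretable;
- region counts have expectation ∝ region length × library size around a
  configurable background mean, multiplied by log-normal noise
  (sd in log2 units) and an implanted fold for CNV regions, zeroed for PAV
  regions, then Poisson-sampled.

Everything is deterministic under a fixed seed (byte-identical files).

What the generator does **not** emulate: sequencing error, mapping
ambiguity and reference bias, correlated caller behaviour (real callers
share error modes, so real concordance cells are not products of
independent sensitivities), linkage between loci, and GC- or
methylation-dependent coverage. Passing tests therefore validate the
*computations* under their stated models, not caller or aligner behaviour
on real reads.

## Numerical and test-design choices

- Tail probabilities use `binom.sf` (stable beyond n = 10⁴); the
  term-summation oracle is exact-integer based and independent.
- The CNV null-calibration tests run at a background mean of 500 expected
  reads per cell: the Gaussian-tail prediction 2·Φ(−s) for the flag rate
  applies when the log-normal noise dominates, and at shallow coverage the
  Poisson counting layer adds enough kurtosis to distort the 3-sd tail.
  The package default background (60) reflects realistic GBS coverage and
  is used everywhere calibration is not being measured.
- Problem sizes in tests (10⁴ loci or regions for stochastic checks,
  50 genomes for digestion invariants, 2 × 10⁴ reads for demultiplexing)
  keep the full suite under ~10 s while leaving 3-sigma bands narrow
  enough to be informative.
- Statistical assertions use 3 standard errors around the analytic
  expectation (2 sd for saturation, which averages replicate draws); all
  stochastic tests are seeded and therefore reproducible.

## Known limitations

- `min_depth`'s linear search is O(n) per query; fine for realistic
  confidences, guarded at 10⁶.
- The CNV rule is a marginal outlier test per pair; it does not segment,
  does not model shared copy-number states across pairs, and its null
  calibration degrades at shallow coverage (see above).
- VCF ingestion requires GT (with ploidy-many slots) and honours DP/AD;
  genotype likelihoods are ignored.
- The saturation analysis treats the whole supplied read set as the
  discoverable universe; it cannot see SNPs the whole set misses.
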