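# canegbs

Genotyping-by-sequencing (GBS) analytics for highly polyploid genomes, built
around the questions a sugarcane-type panel raises: how deep must one
sequence to see a single-dose allele among 6–12 chromosome copies, which
restriction fragments does a PstI library actually interrogate, how well do
different variant callers agree, and which target regions show
presence/absence or copy-number differences between accessions.

The package is organised as an analysis project: the library under
`src/canegbs/` holds every computation, the numbered scripts under
`analysis/` drive the study end to end on synthetic data with known ground
truth, and `tests/` checks each piece against independent oracles.

## The core model

At a bi-allelic locus the reads supporting each allele are a binomial sample
of the total depth *n*. For an allele at frequency *x* in the genotype
(*x* = 1/*p* for a single-dose allele at ploidy *p*), the probability of
sampling at least *k* supporting reads is

P = 1 − Σᵢ₌₀^{k−1} C(n, i) · xⁱ · (1−x)^{n−i}

Inverting this tail for the smallest *n* with P ≥ 0.95 gives the
minimum usable sequencing depth per ploidy. For two reads of a single-dose
minor allele at 95% confidence: **27** reads suffice for a hexaploid, **37**
for an octoploid, **46** for a decaploid, and **56** for a dodecaploid — so
depth 56 covers the whole panel up to 12x.

Around this sit the other pipeline stages:

- `reads` — barcode demultiplexing (exact match, prefix-free sets) with the
  enzyme-remnant check (`CTGCAG`), then trimming/A-padding to 64 bp;
- `digest` — in-silico restriction digestion (PstI default, registry for
  others), 51–500 bp size selection, genic-overlap annotation, fragment
  density;
- `depth` — the binomial model, depth tables, and subsample-saturation
  analysis with a fitted recovery line;
- `variants` — multi-caller VCF normalization, Venn-style concordance,
  per-sample depth filters, dosage classification (homozygous /
  single-dose / multi-dose / multi-allelic), heterozygosity %, SD %,
  multi-allelic % and Ts/Tv per accession;
- `pavcnv` — region read-count normalization
  (10⁹·count/(total·length)), the zero-vs-≥5-reads PAV rule, and the
  per-pair mean ± 3 sd log2-ratio CNV rule;
- `simulate` — deterministic generators for every input above, with truth
  tables, defaulting to a 14-accession panel at ploidies 6x/8x/12x.

## Worked example

```sh
python analysis/04_depth_model.py --seed 1
```

prints

```
minimum depth for 2 minor-allele reads at 95% confidence:
ploidy
6     27
8     37
10    46
12    56
P(>=2 minor reads | depth 56, dodecaploid) = 0.9534
```

i.e. a dodecaploid single-dose SNP (minor-allele frequency 1/12) needs 56
reads before the minor allele is seen at least twice with 95% probability,
and at exactly 56 reads that probability is 95.34%. The same script runs
the saturation analysis on a synthetic read set and reports the fitted
recovery line and the read fraction needed to recover 90% of discoverable
SNPs. The remaining drivers (`01`–`06`) generate the synthetic study,
digest the reference, demultiplex the lane, analyse caller concordance and
per-accession dosage features, and call PAVs/CNVs, writing their tables to
`results/`.

## Layout

```
src/canegbs/      library: reads, digest, depth, variants, pavcnv, simulate
analysis/         numbered drivers over the library, tables to results/
tests/            pytest suite incl. oracle-based acceptance checks
scripts/          acceptance.py
docs/methods.md   model assumptions, parameter choices, limitations
```
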