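"""Synthetic GBS data with known ground truth.

Generates every input the pipeline consumes: toy genomes with planted
restriction sites, gene models, polyploid dosage genotypes with binomially
sampled allele reads, multi-caller VCFs with controlled overlap, barcoded
FASTQ reads, and region count matrices with implanted presence/absence and
copy-number regions over a multiplicative log-normal null.

Defaults emulate the study panel this pipeline targets: 14 sugarcane-complex
accessions at ploidies 6x/8x/12x with their observed library sizes and
per-dose depths, PstI digestion, 74% clean-read rate, five callers with
concordance in the observed range, and a ~20% PAV / ~2.6% CNV region load.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .digest import PSTI, GeneInterval, RestrictionEnzyme
from .pavcnv import RegionCountMatrix
from .reads import DEFAULT_REMNANT, BarcodeSpec
from .variants import DosageGenotype, SnpKey, SnpRecord

__all__ = [
    "SimConfig",
    "TruthTable",
    "Locus",
    "simulate_genome",
    "simulate_genes",
    "simulate_genotypes",
    "simulate_allele_reads",
    "emit_caller_vcfs",
    "truth_records",
    "simulate_fastq",
    "simulate_region_counts",
    "write_genome",
    "write_gff3",
]

#: Study panel: accession -> ploidy (four hexaploids, six octoploids,
#: four dodecaploid hybrids).
PANEL_PLOIDY: dict[str, int] = {
    "IND81-14": 6, "US57-060": 6, "US61-037": 6, "Kalimpon": 6,
    "SES196": 8, "TekchaOk": 8, "NG57-054": 8, "P-MAG-84": 8,
    "Pathri": 8, "NG96-024": 8,
    "Q050": 12, "R570": 12, "CP95-1039": 12, "CP88-1762": 12,
}

#: Observed mean sequencing depth per allele dose for each accession.
PANEL_DEPTH_PER_DOSE: dict[str, float] = {
    "IND81-14": 7.0, "US57-060": 5.8, "US61-037": 5.8, "Kalimpon": 5.8,
    "SES196": 4.8, "TekchaOk": 4.8, "NG57-054": 7.9, "P-MAG-84": 5.3,
    "Pathri": 7.0, "NG96-024": 5.3,
    "Q050": 2.9, "R570": 4.1, "CP95-1039": 9.3, "CP88-1762": 10.8,
}

#: Uniquely mapped reads per accession (library-size totals).
PANEL_MAPPED_READS: dict[str, int] = {
    "IND81-14": 1_400_000, "US57-060": 1_300_000, "US61-037": 1_200_000,
    "Kalimpon": 1_200_000, "SES196": 1_300_000, "TekchaOk": 1_300_000,
    "NG57-054": 2_100_000, "P-MAG-84": 1_400_000, "Pathri": 1_900_000,
    "NG96-024": 1_400_000,
    "Q050": 1_400_000, "R570": 1_600_000, "CP95-1039": 3_700_000,
    "CP88-1762": 4_300_000,
}

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = ("A", "C", "G", "T")


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with defaults matching its design."""

    rng_seed: int = 0
    # genome
    n_sequences: int = 10
    seq_length: int = 50_000
    site_spacing: str = "geometric"  # or "fixed"
    spacing_mean: float = 3400.0  # one PstI site per ~3.4 kb
    genes_per_seq: int = 8
    gene_len_range: tuple[int, int] = (500, 3000)
    # genotypes
    n_loci: int = 5000
    ploidy: dict[str, int] = field(default_factory=lambda: dict(PANEL_PLOIDY))
    depth_per_dose: dict[str, float] = field(
        default_factory=lambda: dict(PANEL_DEPTH_PER_DOSE)
    )
    het_rate: float = 0.25
    sd_fraction: float = 0.125
    multi_allelic_fraction: float = 0.02
    ts_fraction: float = 0.62  # Ts/Tv ~ 1.66 among variant sites
    # callers
    n_callers: int = 5
    caller_sensitivity: tuple[float, ...] = (0.76, 0.60, 0.31, 0.31, 0.22)
    caller_fp_fraction: float = 0.02
    # reads
    n_reads: int = 100_000
    clean_fraction: float = 0.74
    read_length: int = 100
    short_read_fraction: float = 0.05
    remnant: str = DEFAULT_REMNANT
    # regions
    n_regions: int = 2000
    pav_fraction: float = 0.197
    cnv_fraction: float = 0.026
    cnv_fold: float = 4.0
    noise_sd_log2: float = 0.25
    region_background_mean: float = 60.0
    totals: dict[str, int] = field(
        default_factory=lambda: dict(PANEL_MAPPED_READS)
    )

    def __post_init__(self) -> None:
        for name in (
            "het_rate", "sd_fraction", "multi_allelic_fraction", "ts_fraction",
            "clean_fraction", "pav_fraction", "cnv_fraction",
            "caller_fp_fraction", "short_read_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.sd_fraction + self.multi_allelic_fraction > self.het_rate:
            raise ValueError(
                "sd_fraction + multi_allelic_fraction must not exceed het_rate"
            )
        if self.cnv_fraction > 0 and self.cnv_fold == 1.0:
            raise ValueError("cnv_fold == 1 makes implanted CNVs unidentifiable")
        if len(self.caller_sensitivity) < self.n_callers:
            raise ValueError("need one sensitivity per caller")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "SimConfig":
        names = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in names})


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# Genome with planted restriction sites


def _plant_positions(config: SimConfig, site_len: int,
                     rng: np.random.Generator) -> list[int]:
    L, mean = config.seq_length, config.spacing_mean
    if mean <= site_len:
        raise ValueError("site spacing too tight to fit recognition sites")
    if config.site_spacing == "fixed":
        step = int(mean)
        return [p for p in range(step, L, step) if p + site_len <= L]
    positions, pos = [], 0
    while True:
        gap = int(rng.geometric(1.0 / mean))
        pos += gap + (site_len if positions else 0)
        if pos + site_len > L:
            break
        positions.append(pos)
    return positions


def simulate_genome(
    config: SimConfig,
    enzyme: RestrictionEnzyme = PSTI,
    rng=None,
) -> tuple[dict[str, str], dict[str, list[int]]]:
    """Random genome with recognition sites planted at known positions.

    Background bases are uniform ACGT with a rejection pass mutating any
    accidental recognition occurrence, so the planted positions are exactly
    the occurrences a scan will find.  Returns (sequences, per-sequence
    site start positions).
    """
    rng = _rng(config.rng_seed if rng is None else rng)
    site = enzyme.recognition
    genome: dict[str, str] = {}
    sites: dict[str, list[int]] = {}
    for s in range(config.n_sequences):
        seq_id = f"chr{s + 1}"
        arr = rng.choice(list(_BASES), size=config.seq_length)
        planted = _plant_positions(config, len(site), rng)
        covered = set()
        for p in planted:
            arr[p:p + len(site)] = list(site)
            covered.update(range(p, p + len(site)))
        # scrub accidental occurrences without touching planted footprints
        for _ in range(50):
            text = "".join(arr)
            accidental = []
            i = text.find(site)
            while i != -1:
                if i not in planted:
                    accidental.append(i)
                i = text.find(site, i + 1)
            if not accidental:
                break
            for a in accidental:
                free = [p for p in range(a, a + len(site)) if p not in covered]
                if not free:  # pragma: no cover - overlapping-with-planted corner
                    continue
                p = int(rng.choice(free))
                arr[p] = rng.choice([b for b in _BASES if b != arr[p]])
        else:  # pragma: no cover
            raise RuntimeError("could not scrub accidental recognition sites")
        genome[seq_id] = "".join(arr)
        sites[seq_id] = planted
    return genome, sites


def write_genome(genome: Mapping[str, str], sites: Mapping[str, list[int]],
                 fasta_path, bed_path, enzyme: RestrictionEnzyme = PSTI) -> None:
    with open(fasta_path, "w") as fh:
        for seq_id, seq in genome.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    with open(bed_path, "w") as fh:
        for seq_id, positions in sites.items():
            for p in positions:
                fh.write(f"{seq_id}\t{p}\t{p + len(enzyme.recognition)}\t{enzyme.name}\n")


def simulate_genes(config: SimConfig, genome: Mapping[str, str],
                   rng=None) -> list[GeneInterval]:
    """Random non-overlapping gene intervals on the simulated genome."""
    rng = _rng(config.rng_seed + 1 if rng is None else rng)
    lo, hi = config.gene_len_range
    genes = []
    for seq_id, seq in genome.items():
        starts = np.sort(rng.integers(0, max(1, len(seq) - hi),
                                      size=config.genes_per_seq))
        prev_end = 0
        for g, start in enumerate(starts):
            start = max(int(start), prev_end)
            length = int(rng.integers(lo, hi + 1))
            end = min(start + length, len(seq))
            if end <= start:
                continue
            genes.append(GeneInterval(seq_id, start, end, f"{seq_id}.g{g + 1}"))
            prev_end = end
    return genes


def write_gff3(genes: Iterable[GeneInterval], path,
               contigs: Mapping[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contigs:
            for seq_id, length in contigs.items():
                fh.write(f"##sequence-region {seq_id} 1 {length}\n")
        for g in genes:
            fh.write(
                f"{g.seq_id}\tcanegbs-sim\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t"
                f"ID={g.feature_id}\n"
            )


# ---------------------------------------------------------------------------
# Polyploid genotypes, allele reads, caller VCFs


@dataclass(frozen=True)
class Locus:
    """A simulated variant site; ``alt2`` is present only where some
    accession carries a third allele."""

    locus_id: str
    seq_id: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt2: str | None = None


@dataclass
class TruthTable:
    """Ground-truth genotypes for every (locus, accession) pair."""

    loci: list[Locus]
    genotypes: dict[str, dict[str, DosageGenotype]]  # locus_id -> sample -> g
    ploidy: dict[str, int]
    contigs: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for locus in self.loci:
            for sample, g in self.genotypes[locus.locus_id].items():
                rows.append({
                    "locus_id": locus.locus_id,
                    "seq_id": locus.seq_id,
                    "pos": locus.pos,
                    "ref": locus.ref,
                    "alt": locus.alt,
                    "alt2": locus.alt2 or "",
                    "sample": sample,
                    "ploidy": g.ploidy,
                    "dosage": ",".join(
                        f"{a}:{c}" for a, c in sorted(g.dosage.items())
                    ),
                    "total_depth": g.total_depth,
                    "allele_depths": ",".join(
                        f"{a}:{c}" for a, c in sorted(g.allele_depths.items())
                    ),
                })
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _draw_alt(ref: str, ts_fraction: float, rng: np.random.Generator) -> str:
    if rng.random() < ts_fraction:
        return _TRANSITION[ref]
    tv = [b for b in _BASES if b != ref and b != _TRANSITION[ref]]
    return str(rng.choice(tv))


def simulate_genotypes(
    config: SimConfig, genome: Mapping[str, str] | None = None, rng=None
) -> TruthTable:
    """Draw per-accession dosage genotypes at ``n_loci`` sites.

    Per locus and accession the genotype is homozygous-reference with
    probability 1 - het_rate; heterozygous genotypes are single dose
    (sd_fraction), multi-allelic (multi_allelic_fraction) or multi dose
    (the remainder).  The site's alternate allele is a transition of the
    reference with probability ``ts_fraction``, a transversion otherwise.
    """
    rng = _rng(config.rng_seed + 2 if rng is None else rng)
    if genome is not None:
        contigs = {s: len(seq) for s, seq in genome.items()}
    else:
        contigs = {"chr1": max(10 * config.n_loci, 1000)}
    seq_ids = sorted(contigs)

    # distinct positions per contig
    per_seq = {s: [] for s in seq_ids}
    chosen: set[tuple[str, int]] = set()
    while len(chosen) < config.n_loci:
        s = seq_ids[int(rng.integers(len(seq_ids)))]
        pos = int(rng.integers(1, contigs[s] + 1))
        if (s, pos) not in chosen:
            chosen.add((s, pos))
            per_seq[s].append(pos)

    loci: list[Locus] = []
    genotypes: dict[str, dict[str, DosageGenotype]] = {}
    i = 0
    for s in seq_ids:
        for pos in sorted(per_seq[s]):
            ref = genome[s][pos - 1] if genome is not None else str(rng.choice(_BASES))
            alt = _draw_alt(ref, config.ts_fraction, rng)
            locus_id = f"L{i:06d}"
            i += 1
            alt2_used: str | None = None
            per_sample: dict[str, DosageGenotype] = {}
            for sample, p in config.ploidy.items():
                u = rng.random()
                if u < config.sd_fraction:
                    dosage = {ref: p - 1, alt: 1}
                elif u < config.sd_fraction + config.multi_allelic_fraction:
                    if alt2_used is None:
                        others = [b for b in _BASES if b not in (ref, alt)]
                        alt2_used = str(rng.choice(others))
                    dosage = {ref: p - 2, alt: 1, alt2_used: 1}
                elif u < config.het_rate:
                    m = int(rng.integers(2, p - 1))  # both alleles >= 2 copies
                    dosage = {ref: p - m, alt: m}
                else:
                    dosage = {ref: p}
                per_sample[sample] = DosageGenotype(
                    sample_id=sample, ploidy=p, dosage=dosage
                )
            loci.append(Locus(locus_id, s, pos, ref, alt, alt2_used))
            genotypes[locus_id] = per_sample
    return TruthTable(loci=loci, genotypes=genotypes,
                      ploidy=dict(config.ploidy), contigs=contigs)


def simulate_allele_reads(
    truth: TruthTable,
    config: SimConfig,
    rng=None,
    fixed_depth: int | None = None,
) -> TruthTable:
    """Sample per-allele read depths into the truth table, in place.

    Total depth per (locus, accession) is Poisson around the accession's
    mean (depth per dose x ploidy), or exactly ``fixed_depth`` when given;
    allele reads are multinomial with probabilities dosage/ploidy — the
    binomial read-sampling model the depth analysis assumes.
    """
    rng = _rng(config.rng_seed + 3 if rng is None else rng)
    for locus in truth.loci:
        site_alleles = [locus.ref, locus.alt] + (
            [locus.alt2] if locus.alt2 else []
        )
        for sample, g in truth.genotypes[locus.locus_id].items():
            if fixed_depth is not None:
                n = fixed_depth
            else:
                mean = config.depth_per_dose[sample] * g.ploidy
                n = int(rng.poisson(mean))
            alleles = sorted(g.dosage)
            probs = np.array([g.dosage[a] for a in alleles], dtype=float)
            draws = rng.multinomial(n, probs / probs.sum())
            depths = dict.fromkeys(site_alleles, 0)
            depths.update({a: int(d) for a, d in zip(alleles, draws)})
            g.total_depth = n
            g.allele_depths = depths
    return truth


def _vcf_header(contigs: Mapping[str, int], samples: Sequence[str]) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=canegbs-sim"]
    for seq_id, length in sorted(contigs.items()):
        lines.append(f"##contig=<ID={seq_id},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    return "\n".join(lines) + "\n"


def _format_sample(g: DosageGenotype, alleles: Sequence[str]) -> str:
    slots = []
    for idx, a in enumerate(alleles):
        slots.extend([str(idx)] * g.dosage.get(a, 0))
    gt = "/".join(slots)
    ad = ",".join(str(g.allele_depths.get(a, 0)) for a in alleles)
    return f"{gt}:{g.total_depth}:{ad}"


def _write_vcf(path, truth: TruthTable, loci: Sequence[Locus],
               samples: Sequence[str]) -> None:
    ordered = sorted(loci, key=lambda l: (l.seq_id, l.pos))
    with open(path, "w") as fh:
        fh.write(_vcf_header(truth.contigs, samples))
        for locus in ordered:
            alleles = [locus.ref, locus.alt] + ([locus.alt2] if locus.alt2 else [])
            alt_col = ",".join(alleles[1:])
            cols = [
                locus.seq_id, str(locus.pos), locus.locus_id, locus.ref,
                alt_col, ".", "PASS", ".", "GT:DP:AD",
            ]
            for sample in samples:
                cols.append(_format_sample(truth.genotypes[locus.locus_id][sample],
                                           alleles))
            fh.write("\t".join(cols) + "\n")


def emit_caller_vcfs(
    truth: TruthTable,
    config: SimConfig,
    out_dir,
    rng=None,
) -> tuple[dict[str, Path], Path, dict[str, list[Locus]]]:
    """Write one VCF per simulated caller plus the truth VCF.

    Each caller reports a truth locus with its configured sensitivity
    (independent Bernoulli per locus) and adds ``caller_fp_fraction`` x
    n_loci caller-specific false positives at positions absent from the
    truth set.  Returns (caller -> path, truth path, caller -> FP loci).
    """
    rng = _rng(config.rng_seed + 4 if rng is None else rng)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = sorted(truth.ploidy)
    taken = {(l.seq_id, l.pos) for l in truth.loci}
    seq_ids = sorted(truth.contigs)

    paths: dict[str, Path] = {}
    fp_truth: dict[str, list[Locus]] = {}
    n_fp = int(round(config.caller_fp_fraction * len(truth.loci)))
    for c in range(config.n_callers):
        name = f"caller{c + 1}"
        sens = config.caller_sensitivity[c]
        included = [l for l in truth.loci if rng.random() < sens]
        # caller-specific false positives at fresh positions
        fps: list[Locus] = []
        while len(fps) < n_fp:
            s = seq_ids[int(rng.integers(len(seq_ids)))]
            pos = int(rng.integers(1, truth.contigs[s] + 1))
            if (s, pos) in taken:
                continue
            taken.add((s, pos))
            ref = str(rng.choice(_BASES))
            alt = _draw_alt(ref, config.ts_fraction, rng)
            fp = Locus(f"{name}.fp{len(fps)}", s, pos, ref, alt)
            fps.append(fp)
            truth.genotypes[fp.locus_id] = {
                sample: DosageGenotype(
                    sample_id=sample, ploidy=p,
                    dosage={ref: p - 1, alt: 1},
                    total_depth=0, allele_depths={ref: 0, alt: 0},
                )
                for sample, p in truth.ploidy.items()
            }
        fp_truth[name] = fps
        path = out / f"{name}.vcf"
        _write_vcf(path, truth, included + fps, samples)
        paths[name] = path
    truth_path = out / "truth.vcf"
    _write_vcf(truth_path, truth, truth.loci, samples)
    return paths, truth_path, fp_truth


def truth_records(truth: TruthTable) -> list[SnpRecord]:
    """Truth table rendered as normalized SNP records (no file round trip)."""
    records = []
    for locus in truth.loci:
        alts = frozenset([locus.alt] + ([locus.alt2] if locus.alt2 else []))
        key = SnpKey(locus.seq_id, locus.pos, locus.ref, alts)
        records.append(
            SnpRecord(
                key=key,
                genotypes=dict(truth.genotypes[locus.locus_id]),
                callers={"truth"},
            )
        )
    return records


# ---------------------------------------------------------------------------
# FASTQ reads


def simulate_fastq(
    config: SimConfig,
    barcodes: Sequence[BarcodeSpec],
    out_path,
    rng=None,
) -> dict[str, str]:
    """Barcoded GBS reads plus junk, with per-read truth.

    A clean read is barcode + enzyme remnant + random insert at the
    configured read length (a small fraction truncated short, to exercise
    padding); junk reads are random sequence guaranteed not to start with
    any barcode+remnant.  Returns read id -> sample id or 'junk'.
    """
    if not barcodes:
        raise ValueError("at least one barcode required")
    rng = _rng(config.rng_seed + 5 if rng is None else rng)
    remnant = config.remnant
    prefixes = [b.barcode + remnant for b in barcodes]
    truth: dict[str, str] = {}
    with open(out_path, "w") as fh:
        for i in range(config.n_reads):
            read_id = f"read{i:07d}"
            if rng.random() < config.clean_fraction:
                spec = barcodes[int(rng.integers(len(barcodes)))]
                if rng.random() < config.short_read_fraction:
                    total = int(rng.integers(
                        len(spec.barcode) + len(remnant) + 5,
                        len(spec.barcode) + 64,
                    ))
                else:
                    total = config.read_length
                insert_len = total - len(spec.barcode) - len(remnant)
                insert = "".join(rng.choice(list(_BASES), size=insert_len))
                seq = spec.barcode + remnant + insert
                truth[read_id] = spec.sample_id
            else:
                while True:
                    seq = "".join(rng.choice(list(_BASES),
                                             size=config.read_length))
                    if not any(seq.startswith(p) for p in prefixes):
                        break
                truth[read_id] = "junk"
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    return truth


# ---------------------------------------------------------------------------
# Region counts with implanted PAVs and CNVs


def simulate_region_counts(
    config: SimConfig, rng=None
) -> tuple[RegionCountMatrix, pd.DataFrame]:
    """Region x accession counts over a multiplicative log-normal null.

    Baseline expectation per cell scales with region length and accession
    library size around ``region_background_mean``; each cell gets
    independent log-normal noise of sd ``noise_sd_log2`` (log2 units) and a
    Poisson draw.  PAV regions have expectation zero in their affected
    accessions; CNV regions are multiplied by ``cnv_fold`` (gain) or
    1/``cnv_fold`` (loss) in one accession.  Returns the matrix and a truth
    table (region_id, cls, affected, fold).
    """
    if config.n_regions < 10:
        raise ValueError("n_regions must be >= 10")
    rng = _rng(config.rng_seed + 6 if rng is None else rng)
    accs = sorted(config.totals)
    totals = np.array([config.totals[a] for a in accs], dtype=float)
    n, m = config.n_regions, len(accs)

    lengths = rng.integers(51, 501, size=n)
    starts = np.cumsum(lengths + rng.integers(200, 2000, size=n)) - lengths
    regions = pd.DataFrame({
        "region_id": [f"R{i:05d}" for i in range(n)],
        "seq_id": "chr1",
        "start": starts,
        "end": starts + lengths,
        "length": lengths,
    })

    base = (
        config.region_background_mean
        * (lengths[:, None] / lengths.mean())
        * (totals[None, :] / totals.mean())
    )
    noise = np.exp2(rng.normal(0.0, config.noise_sd_log2, size=(n, m)))
    lam = base * noise

    cls = np.full(n, "normal", dtype=object)
    affected: list[str] = [""] * n
    fold = np.ones(n)
    u = rng.random(n)
    for i in range(n):
        if u[i] < config.pav_fraction:
            cls[i] = "pav"
            k = int(rng.integers(1, max(2, m // 4)))
            hit = rng.choice(m, size=k, replace=False)
            lam[i, hit] = 0.0
            affected[i] = ",".join(accs[j] for j in sorted(hit))
        elif u[i] < config.pav_fraction + config.cnv_fraction:
            cls[i] = "cnv"
            j = int(rng.integers(m))
            f = config.cnv_fold if rng.random() < 0.5 else 1.0 / config.cnv_fold
            lam[i, j] *= f
            affected[i] = accs[j]
            fold[i] = f

    counts = rng.poisson(lam)
    matrix = RegionCountMatrix(
        regions=regions,
        counts=pd.DataFrame(counts, index=regions["region_id"], columns=accs),
        totals=pd.Series(totals, index=accs),
    )
    truth = pd.DataFrame({
        "region_id": regions["region_id"],
        "cls": cls,
        "affected": affected,
        "fold": fold,
    })
    return matrix, truth
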