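"""Multi-caller SNP normalization, concordance, dosage and sequence features.

Polyploid genotypes carry allele *dosage*: a hexaploid heterozygote may be
AAAAAC (single dose), AAACCC (multi dose), or even tri-allelic.  Single-dose
(SD) SNPs — exactly one copy of one allele — segregate 1:1 and are the
marker class of choice for polyploid linkage work, so classifying genotypes
by dosage is central here.

The module parses per-caller VCFs into dosage genotypes, intersects call
sets across callers (Venn-style concordance), applies per-sample minimum
depth filters, and computes per-accession heterozygosity, SD%,
multi-allelic% and the transition/transversion ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .digest import GeneInterval, genic_overlap, Fragment

logger = logging.getLogger(__name__)

__all__ = [
    "SnpKey",
    "DosageGenotype",
    "DosageClass",
    "Dosage",
    "SnpRecord",
    "SampleSummary",
    "ConcordanceResult",
    "load_caller_vcf",
    "concordance",
    "depth_filter",
    "classify_dosage",
    "sample_summary",
    "tstv",
    "annotate_genic",
]

TRANSITIONS = {frozenset({"A", "G"}), frozenset({"C", "T"})}


@dataclass(frozen=True)
class SnpKey:
    """Identity of a variant site: position plus the substitution itself."""

    seq_id: str
    pos: int  # 1-based, as in VCF
    ref: str
    alts: frozenset[str]

    def __post_init__(self) -> None:
        if self.ref in self.alts:
            raise ValueError("ref allele cannot appear among alts")


@dataclass
class DosageGenotype:
    """Per-sample allele copy counts at one locus, summing to the ploidy."""

    sample_id: str
    ploidy: int
    dosage: dict[str, int]
    total_depth: int = 0
    allele_depths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.dosage.values()) != self.ploidy:
            raise ValueError(
                f"dosage {self.dosage} does not sum to ploidy {self.ploidy}"
            )


class DosageClass(Enum):
    MISSING = "missing"
    HOMOZYGOUS = "homozygous"
    SINGLE_DOSE = "single_dose"
    MULTI_DOSE = "multi_dose"
    MULTI_ALLELIC = "multi_allelic"


@dataclass(frozen=True)
class Dosage:
    """Classification of one genotype with its minor/major alleles."""

    dosage_class: DosageClass
    minor_allele: str | None = None
    major_allele: str | None = None

    @property
    def is_heterozygous(self) -> bool:
        return self.dosage_class in (
            DosageClass.SINGLE_DOSE,
            DosageClass.MULTI_DOSE,
            DosageClass.MULTI_ALLELIC,
        )


@dataclass
class SnpRecord:
    """A normalized site with per-sample genotypes and caller provenance."""

    key: SnpKey
    genotypes: dict[str, DosageGenotype | None]
    callers: set[str] = field(default_factory=set)


@dataclass
class SampleSummary:
    """Per-accession sequence-variation features over non-missing loci."""

    sample_id: str
    n_loci: int
    heterozygosity_pct: float
    sd_pct: float
    multi_allelic_pct: float
    tstv: float


def classify_dosage(g: DosageGenotype) -> Dosage:
    """Classify a genotype by its allele dosage pattern.

    One allele at full ploidy -> homozygous; two alleles with the rarer at
    exactly one copy -> single dose; two alleles, both >= 2 copies ->
    multi dose; three or more alleles -> multi allelic.  The minor allele is
    the lower-dosage one (lexicographic tie-break for equal dosage, which
    can never be a single-dose call).
    """
    present = {a: c for a, c in g.dosage.items() if c > 0}
    if not present:
        return Dosage(DosageClass.MISSING)
    if len(present) == 1:
        (allele,) = present
        return Dosage(DosageClass.HOMOZYGOUS, minor_allele=None, major_allele=allele)
    if len(present) >= 3:
        ordered = sorted(present.items(), key=lambda ac: (ac[1], ac[0]))
        return Dosage(
            DosageClass.MULTI_ALLELIC,
            minor_allele=ordered[0][0],
            major_allele=ordered[-1][0],
        )
    (a1, c1), (a2, c2) = sorted(present.items(), key=lambda ac: (ac[1], ac[0]))
    cls = DosageClass.SINGLE_DOSE if c1 == 1 else DosageClass.MULTI_DOSE
    return Dosage(cls, minor_allele=a1, major_allele=a2)


# ---------------------------------------------------------------------------
# VCF ingestion


def load_caller_vcf(
    path,
    caller_name: str,
    ploidy_map: Mapping[str, int] | None = None,
) -> dict[SnpKey, SnpRecord]:
    """Parse a caller's VCF into normalized SNP records.

    Only true SNPs (1-bp ref, all alts 1 bp) are loaded.  Genotype strings
    with ploidy-many allele slots become dosage maps; missing genotypes
    (any '.' slot) are stored as None.  When ``ploidy_map`` is given,
    genotypes whose arity disagrees with the declared ploidy are flagged,
    logged, and excluded (stored missing).
    """
    from pysam import VariantFile

    records: dict[SnpKey, SnpRecord] = {}
    n_skipped = n_arity = 0
    with VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            alts = [a for a in rec.alts if a is not None]
            if len(rec.ref) != 1 or any(len(a) != 1 for a in alts) or not alts:
                n_skipped += 1
                continue
            key = SnpKey(rec.chrom, rec.pos, rec.ref.upper(),
                         frozenset(a.upper() for a in alts))
            alleles = [rec.ref.upper()] + [a.upper() for a in alts]
            genotypes: dict[str, DosageGenotype | None] = {}
            for sample_id, sd in rec.samples.items():
                gt = sd.get("GT")
                if gt is None or any(a is None for a in gt):
                    genotypes[sample_id] = None
                    continue
                if ploidy_map is not None and len(gt) != ploidy_map[sample_id]:
                    n_arity += 1
                    genotypes[sample_id] = None
                    continue
                dosage: dict[str, int] = {}
                for idx in gt:
                    allele = alleles[idx]
                    dosage[allele] = dosage.get(allele, 0) + 1
                dp = sd.get("DP") or 0
                ad = sd.get("AD")
                allele_depths = (
                    {alleles[i]: int(d) for i, d in enumerate(ad) if d is not None}
                    if ad is not None
                    else {}
                )
                genotypes[sample_id] = DosageGenotype(
                    sample_id=sample_id,
                    ploidy=len(gt),
                    dosage=dosage,
                    total_depth=int(dp),
                    allele_depths=allele_depths,
                )
            records[key] = SnpRecord(key=key, genotypes=genotypes,
                                     callers={caller_name})
    if n_skipped or n_arity:
        logger.warning(
            "%s: skipped %d non-SNP records, %d genotypes with unexpected arity",
            caller_name, n_skipped, n_arity,
        )
    return records


# ---------------------------------------------------------------------------
# Concordance


@dataclass
class ConcordanceResult:
    """Venn accounting of SNP keys across callers.

    ``cells`` maps each caller subset to the number of keys found by
    exactly those callers; cells partition the non-redundant union.
    """

    cells: dict[frozenset[str], int]
    union_size: int
    concordant_all: int
    per_caller_total: dict[str, int]
    per_caller_pct_concordant: dict[str, float]


def concordance(callsets: Mapping[str, set]) -> ConcordanceResult:
    """Exact-subset intersection counts over >= 2 caller call sets."""
    if len(callsets) < 2:
        raise ValueError("concordance needs at least two callsets")
    callers = sorted(callsets)
    union = set().union(*callsets.values())
    cells: dict[frozenset[str], int] = {
        frozenset(s): 0
        for r in range(1, len(callers) + 1)
        for s in combinations(callers, r)
    }
    for key in union:
        members = frozenset(c for c in callers if key in callsets[c])
        cells[members] += 1
    all_set = frozenset(callers)
    concordant = cells[all_set]
    totals = {c: len(callsets[c]) for c in callers}
    pct = {
        c: (100.0 * concordant / totals[c]) if totals[c] else 0.0 for c in callers
    }
    return ConcordanceResult(
        cells=cells,
        union_size=len(union),
        concordant_all=concordant,
        per_caller_total=totals,
        per_caller_pct_concordant=pct,
    )


# ---------------------------------------------------------------------------
# Filtering and per-sample features


def depth_filter(
    records: Iterable[SnpRecord], min_depth: int, scope: str = "all"
) -> list[SnpRecord]:
    """Keep records meeting a per-sample total-depth threshold.

    ``scope='all'``: every non-missing sample must reach ``min_depth``
    (the strict per-sample reading); ``scope='any'``: at least one does.
    Missing genotypes are ignored by the rule.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    if scope not in ("all", "any"):
        raise ValueError("scope must be 'all' or 'any'")
    out = []
    for rec in records:
        depths = [g.total_depth for g in rec.genotypes.values() if g is not None]
        if not depths:
            continue
        ok = (
            all(d >= min_depth for d in depths)
            if scope == "all"
            else any(d >= min_depth for d in depths)
        )
        if ok:
            out.append(rec)
    return out


def sample_summary(records: Sequence[SnpRecord], sample_id: str) -> SampleSummary:
    """Heterozygosity %, SD %, multi-allelic % and Ts/Tv for one accession.

    All percentages use the accession's non-missing loci as denominator:
    heterozygosity = het loci / loci, SD% = single-dose loci / loci,
    multi-allelic% = >=3-allele loci / loci, each x100.
    """
    n = n_het = n_sd = n_ma = 0
    for rec in records:
        g = rec.genotypes.get(sample_id)
        if g is None:
            continue
        n += 1
        d = classify_dosage(g)
        if d.is_heterozygous:
            n_het += 1
        if d.dosage_class is DosageClass.SINGLE_DOSE:
            n_sd += 1
        elif d.dosage_class is DosageClass.MULTI_ALLELIC:
            n_ma += 1
    if n == 0:
        raise ValueError(f"no non-missing genotypes for sample {sample_id}")
    return SampleSummary(
        sample_id=sample_id,
        n_loci=n,
        heterozygosity_pct=100.0 * n_het / n,
        sd_pct=100.0 * n_sd / n,
        multi_allelic_pct=100.0 * n_ma / n,
        tstv=tstv(records, sample_id),
    )


def _is_transition(a: str, b: str) -> bool:
    return frozenset({a, b}) in TRANSITIONS


def tstv(records: Iterable[SnpRecord], sample_id: str | None = None) -> float:
    """Transition/transversion ratio over bi-allelic SNP sites.

    Global mode (``sample_id=None``) counts every bi-allelic site once.
    Per-sample mode counts only sites where that sample's genotype carries
    at least one non-reference allele, so accessions can differ.  With zero
    transversions the ratio is ``inf``.
    """
    ts = tv = 0
    for rec in records:
        if len(rec.key.alts) != 1:
            continue
        (alt,) = rec.key.alts
        if sample_id is not None:
            g = rec.genotypes.get(sample_id)
            if g is None or g.dosage.get(alt, 0) == 0:
                continue
        if _is_transition(rec.key.ref, alt):
            ts += 1
        else:
            tv += 1
    if tv == 0:
        return math.inf
    return ts / tv


def annotate_genic(
    records: Sequence[SnpRecord], genes: Iterable[GeneInterval]
) -> tuple[list[bool], float]:
    """Flag variants falling inside gene models; returns (flags, percent).

    VCF positions are 1-based; each variant is treated as the 1-bp
    half-open interval [pos-1, pos) for the overlap test.
    """
    points = [Fragment(r.key.seq_id, r.key.pos - 1, r.key.pos) for r in records]
    flags, _, pct = genic_overlap(points, genes)
    return flags, pct
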