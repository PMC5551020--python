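"""In-silico restriction digestion, fragment size selection, and genic overlap.

GBS reduces genome complexity by cutting DNA with a rare-cutting enzyme and
sequencing the fragment ends; which fragments a protocol interrogates is
therefore predictable from the reference alone.  This module scans a genome
for recognition sites (PstI, CTGCAG, by default), splits each sequence into
the resulting fragments, applies the size-selection window of the library
protocol, and annotates fragments with overlap against gene models.

Coordinates are 0-based half-open throughout; GFF3 input (1-based inclusive)
is converted at import.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "RestrictionEnzyme",
    "PSTI",
    "ENZYMES",
    "Fragment",
    "GeneInterval",
    "find_cut_sites",
    "digest",
    "size_select",
    "genic_overlap",
    "fragment_density",
    "read_fasta",
    "read_gff3_genes",
    "read_bed_intervals",
    "write_fragments_bed",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease: recognition site plus top-strand cut offset.

    ``cut_offset`` is the position within the recognition site after which
    the top strand is cut; PstI (CTGCA^G) cuts after offset 5.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not set(self.recognition) <= set("ACGT"):
            raise ValueError("recognition site must be over {A,C,G,T}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset must lie within the recognition site")

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == reverse_complement(self.recognition)


PSTI = RestrictionEnzyme("PstI", "CTGCAG", 5)

#: Registry for enzymes addressable by name (e.g. from the CLI).
ENZYMES: dict[str, RestrictionEnzyme] = {
    "PstI": PSTI,
    "EcoRI": RestrictionEnzyme("EcoRI", "GAATTC", 1),
    "ApeKI": RestrictionEnzyme("ApeKI", "GCAGC", 1),
}


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment as a half-open interval on one sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("fragment requires 0 <= start < end")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class GeneInterval:
    """A gene model interval, half-open, 0-based."""

    seq_id: str
    start: int
    end: int
    feature_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("gene interval requires start < end")


def find_cut_sites(sequence: str, enzyme: RestrictionEnzyme = PSTI) -> list[int]:
    """All top-strand cut coordinates of ``enzyme`` in ``sequence``.

    Each occurrence of the recognition site at index ``i`` contributes cut
    coordinate ``i + cut_offset``.  Occurrences are found by a sliding scan
    so overlapping occurrences (possible for non-palindromic repeats) are
    each reported.  Windows containing ``N`` never match.
    """
    seq = sequence.upper()
    site = enzyme.recognition
    cuts = []
    i = seq.find(site)
    while i != -1:
        cuts.append(i + enzyme.cut_offset)
        i = seq.find(site, i + 1)
    return cuts


def digest(
    genome: Mapping[str, str], enzyme: RestrictionEnzyme = PSTI
) -> list[Fragment]:
    """Completely digest every sequence of ``genome``.

    A sequence with ``c`` cut sites yields exactly ``c + 1`` fragments that
    tile it; across the genome the fragment count equals the total cut-site
    count plus the number of (non-empty) sequences.
    """
    if not genome:
        raise ValueError("genome must contain at least one sequence")
    fragments: list[Fragment] = []
    for seq_id, seq in genome.items():
        if len(seq) == 0:
            logger.warning("sequence %s is empty; no fragments produced", seq_id)
            continue
        cuts = find_cut_sites(seq, enzyme)
        bounds = [0] + [c for c in cuts if 0 < c < len(seq)] + [len(seq)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            fragments.append(Fragment(seq_id, a, b))
    return fragments


def size_select(
    fragments: Iterable[Fragment], min_len: int = 51, max_len: int = 500
) -> list[Fragment]:
    """Fragments within the library size-selection window, bounds inclusive."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return [f for f in fragments if min_len <= f.length <= max_len]


def _gene_trees(genes: Iterable[GeneInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.seq_id, IntervalTree()).addi(g.start, g.end, g.feature_id)
    return trees


def genic_overlap(
    fragments: Sequence[Fragment],
    genes: Iterable[GeneInterval],
    known_seq_ids: set[str] | None = None,
) -> tuple[list[bool], int, float]:
    """Flag fragments overlapping any gene interval by at least 1 bp.

    Returns (per-fragment flags, genic count, percent genic).  Genes on
    sequences absent from ``known_seq_ids`` (when given) are ignored with a
    warning.
    """
    genes = list(genes)
    if known_seq_ids is not None:
        unknown = {g.seq_id for g in genes} - known_seq_ids
        if unknown:
            logger.warning("ignoring genes on unknown sequences: %s", sorted(unknown))
            genes = [g for g in genes if g.seq_id in known_seq_ids]
    trees = _gene_trees(genes)
    flags = []
    for f in fragments:
        tree = trees.get(f.seq_id)
        flags.append(bool(tree is not None and tree.overlap(f.start, f.end)))
    n_genic = sum(flags)
    pct = 100.0 * n_genic / len(fragments) if fragments else 0.0
    return flags, n_genic, pct


def fragment_density(
    fragments: Iterable[Fragment], bin_size: int
) -> dict[str, np.ndarray]:
    """Per-sequence counts of fragment midpoints in fixed-width bins.

    Bin ``i`` covers ``[i*bin_size, (i+1)*bin_size)``; bin counts for a
    sequence sum to its fragment count.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    by_seq: dict[str, list[int]] = {}
    for f in fragments:
        by_seq.setdefault(f.seq_id, []).append(int(f.midpoint // bin_size))
    return {
        seq_id: np.bincount(np.asarray(bins, dtype=int))
        for seq_id, bins in by_seq.items()
    }


# ---------------------------------------------------------------------------
# I/O boundary


def read_fasta(path) -> dict[str, str]:
    """Load a (multi-record, possibly line-wrapped) FASTA into a dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gff3_genes(path, feature_type: str = "gene") -> list[GeneInterval]:
    """Gene intervals from GFF3, converting 1-based inclusive to half-open."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != feature_type:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            genes.append(
                GeneInterval(
                    seq_id=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    feature_id=attrs.get("ID", ""),
                )
            )
    return genes


def read_bed_intervals(path) -> list[GeneInterval]:
    """Intervals from BED (already 0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.rstrip("\n").split("\t")
            name = cols[3] if len(cols) > 3 else ""
            out.append(GeneInterval(cols[0], int(cols[1]), int(cols[2]), name))
    return out


def write_fragments_bed(fragments: Iterable[Fragment], path) -> None:
    """Fragments as BED: chrom, start, end, fragment id, length."""
    with open(path, "w") as fh:
        for i, f in enumerate(fragments):
            fh.write(f"{f.seq_id}\t{f.start}\t{f.end}\tfrag{i}\t{f.length}\n")


def density_frame(density: Mapping[str, np.ndarray], bin_size: int) -> pd.DataFrame:
    rows = [
        {"seq_id": seq_id, "bin_start": i * bin_size, "count": int(c)}
        for seq_id, counts in density.items()
        for i, c in enumerate(counts)
    ]
    return pd.DataFrame(rows, columns=["seq_id", "bin_start", "count"])
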