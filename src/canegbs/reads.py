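"""GBS raw-read preprocessing: barcode demultiplexing and 64-bp normalization.

GBS libraries pool many samples per lane, each tagged with a short inline
barcode; a genuine read begins with exactly one barcode followed by the
remnant the restriction enzyme leaves at the ligation junction (CTGCAG for
PstI by default).  Reads failing that structure are discarded.  Kept reads
are stripped of their barcode (the remnant is retained), then trimmed or
A-padded to a fixed 64 bp so downstream tools see uniform-length tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "BarcodeSpec",
    "CleanRead",
    "ReadStats",
    "validate_barcodes",
    "load_barcodes",
    "filter_reads",
    "trim_pad",
    "process_fastq",
    "write_demultiplexed",
]

DEFAULT_REMNANT = "CTGCAG"
PAD_QUALITY = "!"  # lowest Phred+33 symbol for padded positions
_DNA = set("ACGT")


@dataclass(frozen=True)
class BarcodeSpec:
    """An inline sample barcode (4-10 bp DNA)."""

    sample_id: str
    barcode: str

    def __post_init__(self) -> None:
        if not 4 <= len(self.barcode) <= 10:
            raise ValueError("barcode length must be 4-10")
        if not set(self.barcode) <= _DNA:
            raise ValueError("barcode must be over {A,C,G,T}")


@dataclass(frozen=True)
class CleanRead:
    """A demultiplexed read normalized to a fixed length.

    ``was_padded`` marks reads shorter than the target length whose suffix
    was filled with 'A'.
    """

    sample_id: str
    sequence: str
    was_padded: bool
    read_id: str = ""
    quality: str = ""


@dataclass
class ReadStats:
    """Accounting of a demultiplexing pass; categories partition the input."""

    total: int = 0
    kept: int = 0
    rejected: int = 0
    ambiguous: int = 0
    per_sample: dict[str, int] = field(default_factory=dict)

    @property
    def kept_fraction(self) -> float:
        return self.kept / self.total if self.total else 0.0


def validate_barcodes(barcodes: Iterable[BarcodeSpec]) -> list[BarcodeSpec]:
    """Check uniqueness and prefix-freeness of a barcode set.

    A barcode that is a prefix of another would make demultiplexing
    ambiguous, so sets violating this are refused outright.
    """
    specs = list(barcodes)
    seen = {}
    for s in specs:
        if s.barcode in seen:
            raise ValueError(f"duplicate barcode {s.barcode}")
        seen[s.barcode] = s.sample_id
    codes = sorted(seen)
    for a, b in zip(codes[:-1], codes[1:]):
        if b.startswith(a):
            raise ValueError(f"barcode {a} is a prefix of {b}")
    return specs


def load_barcodes(path) -> list[BarcodeSpec]:
    """Read a 2-column TSV (sample_id, barcode); '#' lines are comments."""
    specs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sample_id, barcode = line.split()[:2]
            specs.append(BarcodeSpec(sample_id, barcode.upper()))
    return validate_barcodes(specs)


def filter_reads(
    reads: Iterable[tuple[str, str, str]],
    barcodes: Iterable[BarcodeSpec],
    remnant: str = DEFAULT_REMNANT,
) -> tuple[list[tuple[str, str, str, str]], ReadStats]:
    """Keep reads beginning with exactly one barcode followed by ``remnant``.

    ``reads`` yields (read_id, sequence, quality) triples.  Returns
    (kept records, stats) where each kept record is
    (sample_id, read_id, sequence-with-barcode-stripped, quality); the
    remnant is retained at the start of the sequence.  Reads matching two
    barcodes are counted ``ambiguous``; reads whose matched prefix contains
    non-ACGT characters, or matching no barcode+remnant, are ``rejected``.
    """
    if not remnant or not set(remnant) <= _DNA:
        raise ValueError("remnant must be a nonempty DNA string")
    specs = list(barcodes)
    stats = ReadStats()
    kept: list[tuple[str, str, str, str]] = []
    for read_id, seq, qual in reads:
        if not seq:
            raise ValueError(f"read {read_id} has empty sequence")
        stats.total += 1
        seq_u = seq.upper()
        matches = [s for s in specs if seq_u.startswith(s.barcode + remnant)]
        if len(matches) > 1:
            stats.ambiguous += 1
            continue
        if not matches:
            stats.rejected += 1
            continue
        spec = matches[0]
        prefix_len = len(spec.barcode) + len(remnant)
        if not set(seq_u[:prefix_len]) <= _DNA:
            stats.rejected += 1
            continue
        stats.kept += 1
        stats.per_sample[spec.sample_id] = stats.per_sample.get(spec.sample_id, 0) + 1
        start = len(spec.barcode)
        kept.append((spec.sample_id, read_id, seq_u[start:], qual[start:]))
    return kept, stats


def trim_pad(sequence: str, target_len: int = 64, pad_char: str = "A") -> str:
    """Trim to ``target_len`` or right-pad with ``pad_char`` up to it."""
    if not sequence:
        raise ValueError("sequence must be nonempty")
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    if len(sequence) >= target_len:
        return sequence[:target_len]
    return sequence + pad_char * (target_len - len(sequence))


def _trim_pad_quality(quality: str, target_len: int) -> str:
    if len(quality) >= target_len:
        return quality[:target_len]
    return quality + PAD_QUALITY * (target_len - len(quality))


def parse_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Stream (read_id, sequence, quality) from a Phred+33 FASTQ file."""
    from Bio import SeqIO
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq, qual


def process_fastq(
    fastq_path,
    barcodes: Iterable[BarcodeSpec],
    remnant: str = DEFAULT_REMNANT,
    trim_to: int = 64,
) -> tuple[dict[str, list[CleanRead]], ReadStats]:
    """Demultiplex a FASTQ file and normalize kept reads to ``trim_to`` bp."""
    specs = validate_barcodes(barcodes)
    kept, stats = filter_reads(parse_fastq(fastq_path), specs, remnant)
    by_sample: dict[str, list[CleanRead]] = {}
    for sample_id, read_id, seq, qual in kept:
        padded = len(seq) < trim_to
        by_sample.setdefault(sample_id, []).append(
            CleanRead(
                sample_id=sample_id,
                sequence=trim_pad(seq, trim_to),
                was_padded=padded,
                read_id=read_id,
                quality=_trim_pad_quality(qual, trim_to),
            )
        )
    return by_sample, stats


def write_demultiplexed(
    by_sample: dict[str, list[CleanRead]], stats: ReadStats, out_dir
) -> None:
    """One FASTQ per sample plus a demux_stats.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sample_id, records in by_sample.items():
        with open(out / f"{sample_id}.fastq", "w") as fh:
            for r in records:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
    with open(out / "demux_stats.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"total\t{stats.total}\n")
        fh.write(f"kept\t{stats.kept}\n")
        fh.write(f"rejected\t{stats.rejected}\n")
        fh.write(f"ambiguous\t{stats.ambiguous}\n")
        fh.write(f"kept_fraction\t{stats.kept_fraction:.6f}\n")
        for sample_id, n in sorted(stats.per_sample.items()):
            fh.write(f"sample:{sample_id}\t{n}\n")
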