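"""Presence/absence and copy-number variation from region read counts.

The region universe is the size-selected restriction-fragment set; per
region and accession the raw aligned-read count is normalized for library
size and region length as

    depth = 1e9 * count / (total_mapped_reads * region_length)

A region is a PAV when at least one accession has zero reads while another
has a robust signal (>= 5 reads by default).  CNVs are flagged from log2
ratios of normalized depth between accession pairs: within each pair, a
region whose log2 ratio falls outside mean +/- 3 sd of that pair's ratios
is called.  Zero-count regions are the PAV signal and are excluded from a
pair's CNV statistics by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .digest import Fragment, GeneInterval, genic_overlap

__all__ = [
    "RegionCountMatrix",
    "PavCall",
    "CnvCall",
    "CnvResult",
    "normalize",
    "call_pav",
    "call_cnv",
    "pavcnv_report",
]


@dataclass
class RegionCountMatrix:
    """Region x accession raw read counts plus per-accession library sizes.

    ``regions`` carries columns region_id, seq_id, start, end, length;
    ``counts`` is indexed by region_id with one column per accession;
    ``totals`` maps accession -> total mapped reads.
    """

    regions: pd.DataFrame
    counts: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        self.totals = pd.Series(self.totals, dtype=float)[self.counts.columns]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.totals <= 0).any():
            raise ValueError("total mapped reads must be positive")
        lengths = self.regions["length"]
        if (lengths <= 0).any():
            raise ValueError("region lengths must be positive")
        if not (self.regions["region_id"].to_numpy() == self.counts.index.to_numpy()).all():
            raise ValueError("regions and counts must list identical region ids")

    @property
    def accessions(self) -> list[str]:
        return list(self.counts.columns)

    @classmethod
    def from_tsv(cls, counts_path, totals_path) -> "RegionCountMatrix":
        """Load from a region-count TSV plus a (accession, total) TSV."""
        df = pd.read_csv(counts_path, sep="\t")
        meta_cols = ["region_id", "seq_id", "start", "end", "length"]
        regions = df[meta_cols].copy()
        counts = df.drop(columns=meta_cols[1:]).set_index("region_id")
        totals = pd.read_csv(
            totals_path, sep="\t", index_col=0
        ).iloc[:, 0]
        return cls(regions=regions, counts=counts, totals=totals)

    def to_tsv(self, counts_path, totals_path) -> None:
        out = self.regions.merge(
            self.counts, left_on="region_id", right_index=True
        )
        out.to_csv(counts_path, sep="\t", index=False)
        self.totals.rename("total_mapped_reads").to_csv(
            totals_path, sep="\t", index_label="accession"
        )


def normalize(matrix: RegionCountMatrix) -> pd.DataFrame:
    """Length- and library-size-normalized depth: 1e9*c/(total*length).

    Invariant under jointly scaling one accession's counts and total; zero
    counts map to zero depth.
    """
    lengths = matrix.regions.set_index("region_id")["length"].astype(float)
    return 1e9 * matrix.counts.div(matrix.totals, axis=1).div(lengths, axis=0)


@dataclass(frozen=True)
class PavCall:
    """A presence/absence call: zero reads somewhere, solid signal elsewhere."""

    region_id: str
    absent_in: frozenset[str]
    present_in: frozenset[str]


def call_pav(matrix: RegionCountMatrix, min_reads: int = 5) -> list[PavCall]:
    """Regions with zero reads in >=1 accession and >= ``min_reads`` in another."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    calls = []
    counts = matrix.counts
    zero = counts.eq(0)
    solid = counts.ge(min_reads)
    eligible = zero.any(axis=1) & solid.any(axis=1)
    for region_id in counts.index[eligible]:
        row = counts.loc[region_id]
        calls.append(
            PavCall(
                region_id=str(region_id),
                absent_in=frozenset(row.index[row == 0]),
                present_in=frozenset(row.index[row >= min_reads]),
            )
        )
    return calls


@dataclass(frozen=True)
class CnvCall:
    """A copy-number call: outlier log2 depth ratio in >= 1 accession pair."""

    region_id: str
    flagged_pairs: frozenset[tuple[str, str]]
    log2_values: dict = field(hash=False, compare=False, default=None)


@dataclass
class CnvResult:
    """CNV calls plus per-pair log2-ratio statistics.

    ``pair_stats`` rows: acc_a, acc_b, n_eligible, mean, sd, n_flagged —
    the inputs to and outcome of the mean +/- sd_mult*sd rule per pair.
    """

    calls: list[CnvCall]
    pair_stats: pd.DataFrame


def call_cnv(
    matrix: RegionCountMatrix,
    sd_mult: float = 3.0,
    exclude_pav: bool = True,
    pseudocount: float = 0.5,
    pooled: bool = False,
) -> CnvResult:
    """Flag regions whose pairwise log2 depth ratio is a mean±sd outlier.

    For each unordered accession pair the per-region ratio
    r = log2(depth_a / depth_b) is computed over eligible regions.  With
    ``exclude_pav`` (default) regions with a zero raw count in either
    accession are excluded from that pair — zeros are PAV signal, not copy
    number; otherwise ``pseudocount`` reads (in each accession's own
    normalization units) are added so the log is defined.  A region is
    flagged in a pair when |r - mean| > sd_mult * sd, with sd the sample
    standard deviation of that pair's ratios (pairs with sd == 0 flag
    nothing).  ``pooled`` computes one mean/sd over all pairs instead.
    A region is a CNV when flagged in at least one pair.
    """
    accs = matrix.accessions
    if len(accs) < 2:
        raise ValueError("CNV calling needs at least two accessions")
    norm = normalize(matrix)
    lengths = matrix.regions.set_index("region_id")["length"].astype(float)

    ratios: dict[tuple[str, str], pd.Series] = {}
    for a, b in combinations(accs, 2):
        if exclude_pav:
            mask = (matrix.counts[a] > 0) & (matrix.counts[b] > 0)
            da, db = norm[a][mask], norm[b][mask]
        else:
            if pseudocount <= 0:
                zero_rows = (matrix.counts[[a, b]] == 0).any(axis=1)
                if zero_rows.any():
                    raise ValueError(
                        "zero counts with exclude_pav=False require pseudocount > 0"
                    )
            unit_a = 1e9 * pseudocount / (matrix.totals[a] * lengths)
            unit_b = 1e9 * pseudocount / (matrix.totals[b] * lengths)
            da, db = norm[a] + unit_a, norm[b] + unit_b
        ratios[(a, b)] = np.log2(da / db)

    if pooled:
        pool = np.concatenate([r.to_numpy() for r in ratios.values()])
        pool_mean = float(np.mean(pool))
        pool_sd = float(np.std(pool, ddof=1)) if len(pool) > 1 else 0.0

    flagged: dict[str, dict[tuple[str, str], float]] = {}
    stats_rows = []
    for (a, b), r in ratios.items():
        if len(r) < 3:
            stats_rows.append((a, b, len(r), np.nan, np.nan, 0))
            continue
        mean = pool_mean if pooled else float(r.mean())
        sd = pool_sd if pooled else float(r.std(ddof=1))
        if sd == 0:
            n_flag = 0
        else:
            outliers = r[(r - mean).abs() > sd_mult * sd]
            n_flag = len(outliers)
            for region_id, val in outliers.items():
                flagged.setdefault(str(region_id), {})[(a, b)] = float(val)
        stats_rows.append((a, b, len(r), mean, sd, n_flag))

    calls = [
        CnvCall(
            region_id=rid,
            flagged_pairs=frozenset(pairs),
            log2_values=dict(pairs),
        )
        for rid, pairs in sorted(flagged.items())
    ]
    pair_stats = pd.DataFrame(
        stats_rows, columns=["acc_a", "acc_b", "n_eligible", "mean", "sd", "n_flagged"]
    )
    return CnvResult(calls=calls, pair_stats=pair_stats)


def pavcnv_report(
    pav_calls: Sequence[PavCall],
    cnv_result: CnvResult | Sequence[CnvCall],
    matrix: RegionCountMatrix,
    genes: Iterable[GeneInterval] = (),
) -> pd.DataFrame:
    """Summary table: totals, percent genic, per-accession absence counts."""
    cnv_calls = (
        cnv_result.calls if isinstance(cnv_result, CnvResult) else list(cnv_result)
    )
    regions = matrix.regions.set_index("region_id")
    genes = list(genes)

    def pct_genic(region_ids: list[str]) -> float:
        if not region_ids or not genes:
            return 0.0
        frags = [
            Fragment(regions.loc[r, "seq_id"],
                     int(regions.loc[r, "start"]),
                     int(regions.loc[r, "end"]))
            for r in region_ids
        ]
        _, _, pct = genic_overlap(frags, genes)
        return pct

    rows = [
        {"metric": "n_pav", "value": float(len(pav_calls))},
        {"metric": "n_cnv", "value": float(len(cnv_calls))},
        {"metric": "pav_pct_genic",
         "value": pct_genic([c.region_id for c in pav_calls])},
        {"metric": "cnv_pct_genic",
         "value": pct_genic([c.region_id for c in cnv_calls])},
    ]
    absence: dict[str, int] = {a: 0 for a in matrix.accessions}
    for c in pav_calls:
        for a in c.absent_in:
            absence[a] += 1
    for a, n in absence.items():
        rows.append({"metric": f"absent_in:{a}", "value": float(n)})
    return pd.DataFrame(rows, columns=["metric", "value"])
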