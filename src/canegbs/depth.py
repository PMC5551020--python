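"""Binomial read-depth model for minor-allele detectability in polyploids.

At a bi-allelic locus the reads covering each allele are a binomial sample
of the total depth ``n`` with success probability equal to the allele's
frequency in the genotype.  For a single-dose allele in a ploidy-``p``
individual that frequency is ``x = 1/p``, so the probability of seeing at
least ``k`` supporting reads is the upper binomial tail

    P = 1 - sum_{i=0}^{k-1} C(n, i) x^i (1-x)^(n-i)

This module evaluates that tail, inverts it for the minimum depth reaching a
confidence level, tabulates the requirement across ploidies, and runs the
subsample-saturation analysis that relates read-set size to the fraction of
variants recovered.

Sequencing error is deliberately ignored: reads are assumed clean, so the
model is a lower bound on the depth a noisy caller would need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Collection, Hashable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "prob_at_least_k",
    "min_depth",
    "depth_table",
    "DepthRequirement",
    "SaturationResult",
    "subsample_saturation",
]

_MAX_DEPTH_SEARCH = 10**6


def prob_at_least_k(n: int, x: float, k: int) -> float:
    """Probability of drawing >= ``k`` reads of an allele at frequency ``x``
    from ``n`` total reads.

    Computed as the binomial survival function ``1 - CDF(k-1; n, x)``, which
    is numerically stable for ``n`` well beyond 10^4.  Degenerate inputs
    follow the model: ``k > n`` or ``x == 0`` give 0; ``x == 1`` gives 1
    whenever ``n >= k``.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 <= x <= 1.0:
        raise ValueError("allele frequency x must lie in [0, 1]")
    if k > n:
        return 0.0
    return float(stats.binom.sf(k - 1, n, x))


def min_depth(x: float, k: int, confidence: float = 0.95) -> int:
    """Smallest total depth ``n`` with ``prob_at_least_k(n, x, k) >= confidence``.

    The tail probability is non-decreasing in ``n`` for fixed ``x`` and
    ``k``, so an incremental search from ``n = k`` returns the exact
    minimum.  ``confidence`` is a weak inequality: a tail probability equal
    to the confidence level counts as attained.
    """
    if not 0.0 < x < 1.0:
        raise ValueError("allele frequency x must lie strictly in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie strictly in (0, 1)")
    n = k
    while prob_at_least_k(n, x, k) < confidence:
        n += 1
        if n > _MAX_DEPTH_SEARCH:  # pragma: no cover - guard only
            raise RuntimeError("depth search exceeded guard of 1e6 reads")
    return n


@dataclass(frozen=True)
class DepthRequirement:
    """Minimum total depth needed for a single-dose minor allele.

    ``min_depth`` is the smallest ``n`` at which the probability of seeing
    at least ``k`` minor-allele reads (frequency ``1/ploidy``) reaches
    ``confidence``.
    """

    ploidy: int
    k: int
    confidence: float
    min_depth: int


def depth_table(
    ploidies: Sequence[int],
    ks: Sequence[int] = (1, 2, 3, 4, 5),
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Tabulate ``min_depth`` over ploidy x required-read-count combinations.

    A single-dose allele at ploidy ``p`` has frequency ``1/p``, so the
    required depth grows with both ploidy and ``k``.
    """
    rows = []
    for p in ploidies:
        if p < 2:
            raise ValueError("ploidy must be >= 2")
        for k in ks:
            rows.append(
                DepthRequirement(
                    ploidy=p,
                    k=k,
                    confidence=confidence,
                    min_depth=min_depth(1.0 / p, k, confidence),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class SaturationResult:
    """Outcome of the subsample-saturation analysis.

    ``fractions`` are the subsampling fractions of the whole read set;
    ``mean_recovery`` / ``sd_recovery`` the mean and sample sd over
    replicates of |variants(subset)| / |variants(whole)|; ``slope`` and
    ``intercept`` the ordinary least-squares line through
    (fraction, mean recovery).
    """

    fractions: list[float]
    mean_recovery: list[float]
    sd_recovery: list[float]
    slope: float
    intercept: float
    n_whole: int = 0
    recoveries: dict[float, list[float]] = field(default_factory=dict, repr=False)

    def required_fraction_for(self, target: float) -> float:
        """Read-set fraction at which the fitted line reaches ``target`` recovery."""
        return (target - self.intercept) / self.slope

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": self.fractions,
                "mean_recovery": self.mean_recovery,
                "sd_recovery": self.sd_recovery,
            }
        )


def _default_discover(reads: Sequence[Hashable], min_reads: int = 2) -> set:
    """Thresholded discovery rule: a locus is found when >= ``min_reads`` of
    its reads are present in the subset."""
    counts: dict[Hashable, int] = {}
    for locus in reads:
        counts[locus] = counts.get(locus, 0) + 1
    return {locus for locus, c in counts.items() if c >= min_reads}


def subsample_saturation(
    reads: Sequence[Hashable],
    fractions: Sequence[float] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    reps: int = 10,
    rng_seed: int = 0,
    discover: Callable[[Sequence[Hashable]], Collection] | None = None,
    min_reads: int = 2,
) -> SaturationResult:
    """Recovery of the variant set under random read subsampling.

    ``reads`` lists the locus id covered by each read of the whole set;
    ``discover`` maps a read subset to the set of variants it supports
    (default: loci with at least ``min_reads`` reads).  For each fraction,
    ``reps`` subsets are drawn without replacement and the recovered
    fraction of the whole-set variants recorded; a line is then fit through
    the per-fraction means so the fraction needed for a target recovery
    (e.g. 90%) can be read off.
    """
    if discover is None:
        discover = lambda subset: _default_discover(subset, min_reads)
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"subsampling fraction {f} outside (0, 1]")
    rng = np.random.default_rng(rng_seed)
    reads = list(reads)
    whole = set(discover(reads))
    if not whole:
        raise ValueError("no variants discovered in the whole read set")
    n = len(reads)

    means, sds, recov_by_f = [], [], {}
    for f in fractions:
        if f == 1.0:
            recov = [1.0] * reps
        else:
            m = int(round(f * n))
            recov = []
            for _ in range(reps):
                idx = rng.choice(n, size=m, replace=False)
                subset = [reads[i] for i in idx]
                found = set(discover(subset)) & whole
                recov.append(len(found) / len(whole))
        means.append(float(np.mean(recov)))
        sds.append(float(np.std(recov, ddof=1)) if reps > 1 else 0.0)
        recov_by_f[f] = recov

    fit = stats.linregress(list(fractions), means)
    return SaturationResult(
        fractions=list(fractions),
        mean_recovery=means,
        sd_recovery=sds,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_whole=len(whole),
        recoveries=recov_by_f,
    )


def prob_by_summation(n: int, x: float, k: int) -> float:
    """Direct term-by-term evaluation of the tail formula.

    Independent of the scipy route: sums C(n,i) x^i (1-x)^(n-i) for
    i < k with exact integer binomial coefficients.  Intended as an oracle
    for ``prob_at_least_k`` at moderate ``n``.
    """
    if k > n:
        return 0.0
    total = 0.0
    for i in range(k):
        total += math.comb(n, i) * (x**i) * ((1.0 - x) ** (n - i))
    return 1.0 - total
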