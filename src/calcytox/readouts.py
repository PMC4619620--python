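"""Percent-specific-lysis readouts and the paired method comparison.

Two readouts of the same wells:

* release method::

      % lysis = 100 x (test release - spontaneous release)
                     / (maximum release - spontaneous release)

* imaging (counting) method::

      % lysis = 100 x (spontaneous live count - test live count)
                     / spontaneous live count

The release formula is invariant to rescaling all three fluorescence values
by a common positive constant, so the supernatant sampling fraction cancels;
the imaging formula is invariant (in expectation) to the field-sampling
fraction, since the same fraction applies to test and spontaneous wells.

Values below 0% or above 100% are reported unmodified — clamping would hide
assay failures — and callers flag them via :func:`qc_flag`.

The two methods are compared with the Wilcoxon matched-pairs signed-rank
test, exact for n <= 25 pairs (zero differences dropped per Wilcoxon's
original convention, ties mid-ranked) and a continuity-corrected normal
approximation above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.special import ndtr

from .errors import InvalidParameterError

__all__ = [
    "ReleaseTriplet",
    "CountPair",
    "MethodComparison",
    "percent_lysis_release",
    "percent_lysis_imaging",
    "dynamic_range",
    "wilcoxon_signed_rank",
    "compare_methods",
    "qc_flag",
]

#: Largest n for which the exact signed-rank null distribution is used.
EXACT_WILCOXON_MAX_N = 25


@dataclass
class ReleaseTriplet:
    """Replicate-averaged fluorescence inputs to the release formula (AU)."""

    test_release: float
    spontaneous_release: float
    maximum_release: float


@dataclass
class CountPair:
    """Live-count inputs to the imaging formula."""

    spontaneous_live_count: float
    test_live_count: float


@dataclass
class MethodComparison:
    """Wilcoxon matched-pairs comparison of the two readouts."""

    pairs: pd.DataFrame  # columns: release_pct, imaging_pct
    statistic: float  # W = min(W+, W-)
    w_plus: float
    w_minus: float
    p_value: float
    median_release: float
    median_imaging: float
    n_pairs: int
    n_zero_differences: int = 0
    flag: str = ""


def percent_lysis_release(t: ReleaseTriplet) -> float:
    """Release-based percent specific lysis; may fall outside [0, 100]."""
    rng = t.maximum_release - t.spontaneous_release
    if rng <= 0:
        raise InvalidParameterError(
            "undefined dynamic range: maximum_release must exceed "
            f"spontaneous_release (max={t.maximum_release}, "
            f"spont={t.spontaneous_release})")
    return 100.0 * (t.test_release - t.spontaneous_release) / rng


def percent_lysis_imaging(c: CountPair) -> float:
    """Count-based percent specific lysis; may fall below 0."""
    if c.spontaneous_live_count <= 0:
        raise InvalidParameterError(
            "spontaneous_live_count must be > 0 to normalize the imaging "
            "readout")
    return (100.0 * (c.spontaneous_live_count - c.test_live_count)
            / c.spontaneous_live_count)


def dynamic_range(maximum_release: float, spontaneous_release: float
                  ) -> tuple[float, float]:
    """Return ``(spont_pct_of_max, dynamic_range_pct)``.

    Maximum release is normalized to 100%; the spontaneous release expressed
    as a percent of maximum bounds the usable signal window from below, so
    the dynamic range is its complement.
    """
    if maximum_release <= 0:
        raise InvalidParameterError("maximum_release must be > 0")
    spont_pct = 100.0 * spontaneous_release / maximum_release
    return spont_pct, 100.0 - spont_pct


def qc_flag(value: float) -> str:
    """Flag percent-lysis values outside the physically expected range."""
    if value < 0:
        return "below_zero"
    if value > 100:
        return "above_hundred"
    return ""


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for W+ via DP over doubled ranks.

    Mid-ranks are half-integers at worst, so doubling makes every rank an
    integer; the null distribution of 2*W+ over all sign assignments is
    built by dynamic programming (subset-sum counts).
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts += shifted
    denom = counts.sum()  # == 2**n
    w2 = int(np.rint(2.0 * w_plus))
    cdf = counts[: w2 + 1].sum() / denom
    sf = counts[w2:].sum() / denom
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(differences: Sequence[float]
                         ) -> tuple[float, float, float, float, int, str]:
    """Wilcoxon signed-rank test on paired differences.

    Returns ``(W, W+, W-, p_two_tailed, n_used, flag)`` where ``W`` is
    ``min(W+, W-)`` and ``n_used`` counts nonzero differences. Exact null
    distribution for ``n_used <= 25``; otherwise a normal approximation with
    tie correction and continuity correction.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise InvalidParameterError("at least one pair is required")
    nz = d[d != 0]
    n = nz.size
    if n == 0:
        return 0.0, 0.0, 0.0, 1.0, 0, "no effect detectable"
    ranks = rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    w_minus = float(ranks[nz < 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts ** 3 - tie_counts) / 48.0).sum())
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (abs(w_plus - mean) - 0.5) / np.sqrt(var)
        p = float(min(1.0, 2.0 * (1.0 - ndtr(z))))
    return min(w_plus, w_minus), w_plus, w_minus, p, n, ""


def compare_methods(release_pct: Sequence[float],
                    imaging_pct: Sequence[float]) -> MethodComparison:
    """Paired Wilcoxon comparison of imaging vs release percent lysis.

    Differences are ``imaging - release`` per replicate pair; a positive
    shift means the counting method reports higher specific lysis than the
    release method on the same wells.
    """
    release = np.asarray(release_pct, dtype=float)
    imaging = np.asarray(imaging_pct, dtype=float)
    if release.size != imaging.size:
        raise InvalidParameterError("paired samples must have equal length")
    if release.size == 0:
        raise InvalidParameterError("at least one pair is required")
    diffs = imaging - release
    w, w_plus, w_minus, p, n_used, flag = wilcoxon_signed_rank(diffs)
    pairs = pd.DataFrame({"release_pct": release, "imaging_pct": imaging})
    return MethodComparison(
        pairs=pairs,
        statistic=w,
        w_plus=w_plus,
        w_minus=w_minus,
        p_value=p,
        median_release=float(np.median(release)),
        median_imaging=float(np.median(imaging)),
        n_pairs=int(release.size),
        n_zero_differences=int(release.size - n_used),
        flag=flag,
    )
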