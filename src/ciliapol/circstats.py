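"""Circular descriptive statistics and two-sample inference.

Angles are degrees in ``[-180, 180)`` throughout.  The circular standard
deviation (CSD) follows the standard definition ``sqrt(-2 ln R)`` expressed
in degrees, where ``R`` is the mean resultant length of the sample: a CSD of
0 means perfectly aligned angles, and the CSD diverges as the sample
approaches uniformity.  A sample with exactly zero resultant carries no
directional information; its mean is undefined and its CSD is reported as
the ``inf`` sentinel.

The Watson U² statistic compares two circular samples through their pooled
empirical distribution functions and is invariant under a common rotation of
both samples, which makes it the natural two-sample test for polarity angles
whose zero direction is an arbitrary convention.  p-values are obtained by
seeded permutation of the pooled sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

__all__ = [
    "CircularSummary",
    "WatsonResult",
    "TTestResult",
    "wrap_angle",
    "angular_difference",
    "circular_summary",
    "csd_from_resultant",
    "watson_u2",
    "watson_u2_test",
    "csd_histogram",
    "two_sample_t",
]

_RAD = math.pi / 180.0
_DEG = 180.0 / math.pi
# below this resultant length the mean direction is numerically meaningless
_R_UNDEFINED = 1e-12


def wrap_angle(deg):
    """Wrap angle(s) in degrees into ``[-180, 180)``.

    Accepts scalars or arrays; raises on non-finite input.
    """
    arr = np.asarray(deg, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("cannot wrap non-finite angle")
    wrapped = (arr + 180.0) % 360.0 - 180.0
    if arr.ndim == 0:
        return float(wrapped)
    return wrapped


def angular_difference(a, b):
    """Signed shortest angular difference ``a - b`` in ``[-180, 180)`` degrees."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def csd_from_resultant(r: float) -> float:
    """Circular standard deviation in degrees from a mean resultant length."""
    if r <= _R_UNDEFINED:
        return math.inf
    if r >= 1.0:
        return 0.0
    return _DEG * math.sqrt(-2.0 * math.log(r))


@dataclass(frozen=True)
class CircularSummary:
    """Mean direction, resultant length and CSD of an angular sample."""

    mean_deg: float  # NaN when the resultant length is (numerically) zero
    resultant_length: float
    csd_deg: float  # inf sentinel when resultant_length is zero
    n: int

    @property
    def mean_defined(self) -> bool:
        return not math.isnan(self.mean_deg)


def circular_summary(angles_deg) -> CircularSummary:
    """Circular mean, resultant length and circular standard deviation.

    ``mean_deg = atan2(mean sin, mean cos)``; ``R`` is the length of the mean
    unit vector; ``csd = sqrt(-2 ln R)`` in degrees.  For ``R == 0`` the mean
    is NaN and the CSD is the ``inf`` sentinel.
    """
    a = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("circular summary of an empty sample")
    a = wrap_angle(a)
    rad = a * _RAD
    c = float(np.mean(np.cos(rad)))
    s = float(np.mean(np.sin(rad)))
    r = min(math.hypot(c, s), 1.0)
    if r <= _R_UNDEFINED:
        mean = math.nan
    else:
        mean = wrap_angle(math.degrees(math.atan2(s, c)))
    return CircularSummary(mean, r, csd_from_resultant(r), int(a.size))


# ---------------------------------------------------------------------------
# Watson two-sample U^2
# ---------------------------------------------------------------------------


def _tie_last_index(sorted_vals: np.ndarray) -> np.ndarray:
    """For each position in a sorted array, the index of the last tied entry."""
    _, inverse, counts = np.unique(sorted_vals, return_inverse=True, return_counts=True)
    last = np.cumsum(counts) - 1
    return last[inverse]


def _u2_from_labels(z: np.ndarray, tie_last: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """U² for one or many label vectors over a fixed pooled sorted sample.

    ``z`` is a (..., N) 0/1 array in pooled-sorted order (1 = first sample).
    ECDF differences are evaluated after consuming all observations tied at a
    value; each of the N pooled observations contributes its shared d once.
    """
    n = n1 + n2
    f1 = np.cumsum(z, axis=-1) / n1
    f2 = np.cumsum(1.0 - z, axis=-1) / n2
    d = (f1 - f2)[..., tie_last]
    sum_d = d.sum(axis=-1)
    sum_d2 = (d * d).sum(axis=-1)
    return (n1 * n2) / float(n) ** 2 * (sum_d2 - sum_d * sum_d / n)


def watson_u2(angles1_deg, angles2_deg) -> float:
    """Watson's two-sample U² statistic for circular data.

    Rotation of both samples by a common angle leaves the statistic
    unchanged; identical samples give exactly 0 under the tie rule.
    """
    a1 = wrap_angle(np.atleast_1d(np.asarray(angles1_deg, dtype=float)))
    a2 = wrap_angle(np.atleast_1d(np.asarray(angles2_deg, dtype=float)))
    n1, n2 = a1.size, a2.size
    if n1 < 2 or n2 < 2:
        raise ValueError(f"Watson U2 needs >= 2 observations per sample, got {n1}, {n2}")
    pooled = np.concatenate([a1, a2])
    order = np.argsort(pooled, kind="stable")
    z = (order < n1).astype(float)
    tie_last = _tie_last_index(pooled[order])
    return float(_u2_from_labels(z, tie_last, n1, n2))


@dataclass(frozen=True)
class WatsonResult:
    u2: float
    p_value: float
    n1: int
    n2: int
    n_permutations: int
    seed: int


def watson_u2_test(
    angles1_deg, angles2_deg, n_permutations: int = 999, seed: int = 0
) -> WatsonResult:
    """Watson U² with a permutation p-value.

    The pooled angles are randomly relabeled into groups of the original
    sizes; ``p = (1 + #{permuted U² >= observed}) / (1 + n_permutations)``,
    which is exact-level for any sample size and deterministic given ``seed``.
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations for a meaningful p-value")
    a1 = wrap_angle(np.atleast_1d(np.asarray(angles1_deg, dtype=float)))
    a2 = wrap_angle(np.atleast_1d(np.asarray(angles2_deg, dtype=float)))
    n1, n2 = a1.size, a2.size
    if n1 < 2 or n2 < 2:
        raise ValueError(f"Watson U2 needs >= 2 observations per sample, got {n1}, {n2}")
    pooled = np.concatenate([a1, a2])
    order = np.argsort(pooled, kind="stable")
    sorted_vals = pooled[order]
    tie_last = _tie_last_index(sorted_vals)
    observed = float(_u2_from_labels((order < n1).astype(float), tie_last, n1, n2))

    rng = np.random.default_rng(seed)
    labels = np.zeros((n_permutations, n1 + n2))
    labels[:, :n1] = 1.0
    labels = rng.permuted(labels, axis=1)
    permuted = _u2_from_labels(labels, tie_last, n1, n2)
    # tolerance so that ties with the observed value count as >=
    n_ge = int(np.sum(permuted >= observed - 1e-12))
    p = (1.0 + n_ge) / (1.0 + n_permutations)
    return WatsonResult(observed, p, n1, n2, n_permutations, seed)


# ---------------------------------------------------------------------------
# CSD histogram and the linear t test
# ---------------------------------------------------------------------------


def csd_histogram(csd_values_deg) -> np.ndarray:
    """Counts of CSD values in ten bins [0,10), ..., [90,100) plus overflow.

    Values >= 100, including the ``inf`` sentinel of zero-resultant cells,
    accumulate in the 11th (overflow) bin.  Counts sum to ``len(values)``.
    """
    v = np.atleast_1d(np.asarray(csd_values_deg, dtype=float))
    if v.size and np.any(v < 0):
        raise ValueError("CSD values must be non-negative")
    counts = np.zeros(11, dtype=int)
    if v.size:
        finite_in_range = v[v < 100.0]
        counts[:10], _ = np.histogram(finite_in_range, bins=np.arange(0.0, 101.0, 10.0))
        counts[10] = int(np.sum(v >= 100.0))
    return counts


@dataclass(frozen=True)
class TTestResult:
    t: float
    p_value: float
    n1: int
    n2: int


def two_sample_t(values1, values2) -> TTestResult:
    """Classical pooled-variance two-sample t test, two-tailed."""
    v1 = np.atleast_1d(np.asarray(values1, dtype=float))
    v2 = np.atleast_1d(np.asarray(values2, dtype=float))
    if v1.size < 2 or v2.size < 2:
        raise ValueError("t test needs >= 2 observations per sample")
    ss = np.sum((v1 - v1.mean()) ** 2) + np.sum((v2 - v2.mean()) ** 2)
    if ss <= 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    res = _scipy_stats.ttest_ind(v1, v2, equal_var=True)
    return TTestResult(float(res.statistic), float(res.pvalue), v1.size, v2.size)
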