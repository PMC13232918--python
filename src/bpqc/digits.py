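"""Terminal-digit preference audit.

Human transcription of device read-outs heaps on round numbers: values
ending in 0 (and, less strongly, 5) occur more often than the 10% expected
of each terminal digit when the underlying distribution is smooth.  This
module extracts terminal digits, tallies them, and tests the observed
proportion of 0s and 5s against the uniform-digit expectation with a
one-sample proportion test.

Averaged visit values can be half-integers (x.5 mm Hg); their terminal
"digit" is the sentinel :data:`HALF`.  By default HALF values stay in the
denominator but can never count as a 0 or a 5 — they are genuinely neither,
and keeping them reproduces the dilution toward 10% that averaging produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_model import ALPHA

#: Sentinel digit class for half-integer (x.5) averaged values.
HALF = "HALF"

#: Null probability of each terminal digit under uniformity.
EXPECTED_UNIFORM = 0.10

_DIGIT_KEYS = [str(d) for d in range(10)] + [HALF]


def terminal_digit(value: float) -> int | str:
    """Terminal digit of a non-negative mm Hg value that is a multiple of 0.5.

    Integers map to their last decimal digit; half-integers map to
    :data:`HALF`.  Anything else (negative, or not a multiple of 0.5) is a
    contract violation.
    """
    if value < 0:
        raise ValueError(f"negative BP value {value!r}")
    doubled = 2 * value
    if doubled != int(doubled):
        raise ValueError(f"value {value!r} is not a multiple of 0.5 mm Hg")
    if value == int(value):
        return int(value) % 10
    return HALF


def digit_distribution(values) -> dict[str, int]:
    """Counts over terminal-digit classes {0..9, HALF}; sums to ``len(values)``."""
    v = np.asarray(values, dtype=float)
    counts = dict.fromkeys(_DIGIT_KEYS, 0)
    if v.size == 0:
        return counts
    if (v < 0).any():
        raise ValueError("negative BP value")
    doubled = 2 * v
    if not np.all(doubled == np.floor(doubled)):
        raise ValueError("values must be multiples of 0.5 mm Hg")
    is_int = v == np.floor(v)
    digits = (v[is_int].astype(np.int64) % 10)
    binc = np.bincount(digits, minlength=10)
    for d in range(10):
        counts[str(d)] = int(binc[d])
    counts[HALF] = int((~is_int).sum())
    return counts


def proportion_test(
    k: int, n: int, p0: float = EXPECTED_UNIFORM, exact: bool = False
) -> tuple[float, float]:
    """One-sample test of a binomial proportion against ``p0``.

    Default is the two-sided normal (score) test without continuity
    correction: ``z = (k/n − p0) / sqrt(p0 (1−p0) / n)``.  With
    ``exact=True`` the two-sided exact binomial test is used instead and the
    returned ``z`` is the same score statistic (reported for reference).

    ``n == 0`` gives ``(nan, nan)`` — the proportion is undefined.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if k < 0 or k > n:
        raise ValueError("need 0 <= k <= n")
    if n == 0:
        return float("nan"), float("nan")
    z = (k / n - p0) / np.sqrt(p0 * (1 - p0) / n)
    if exact:
        p = stats.binomtest(k, n, p0).pvalue
    else:
        p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class DigitPreferenceResult:
    """Terminal-digit audit of one stratum of values."""

    n: int
    count_per_digit: dict[str, int]
    prop0: float
    prop5: float
    z0: float
    p0: float
    z5: float
    p5: float
    expected: float
    alpha: float
    significant0: bool
    significant5: bool
    half_policy: str

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "count_per_digit": dict(self.count_per_digit),
            "prop0": self.prop0,
            "prop5": self.prop5,
            "z0": self.z0,
            "p0": self.p0,
            "z5": self.z5,
            "p5": self.p5,
            "expected": self.expected,
            "alpha": self.alpha,
            "significant0": self.significant0,
            "significant5": self.significant5,
            "half_policy": self.half_policy,
        }


def digit_preference_audit(
    values,
    alpha: float = ALPHA,
    expected: float = EXPECTED_UNIFORM,
    exact: bool = False,
    half_policy: str = "denominator",
) -> DigitPreferenceResult:
    """Full terminal-digit audit of one stratum.

    ``half_policy`` controls half-integer averaged values: ``"denominator"``
    (default) keeps them in ``n`` but never in the 0/5 numerators;
    ``"drop"`` removes them entirely (sensitivity analysis).
    """
    counts = digit_distribution(values)
    n = sum(counts.values())
    if half_policy == "drop":
        n -= counts[HALF]
        counts = dict(counts)
        counts[HALF] = 0
    elif half_policy != "denominator":
        raise ValueError(f"unknown half policy {half_policy!r}")
    k0, k5 = counts["0"], counts["5"]
    if n > 0:
        prop0, prop5 = k0 / n, k5 / n
        z0, p0v = proportion_test(k0, n, expected, exact=exact)
        z5, p5v = proportion_test(k5, n, expected, exact=exact)
    else:
        prop0 = prop5 = z0 = p0v = z5 = p5v = float("nan")
    return DigitPreferenceResult(
        n=n,
        count_per_digit=counts,
        prop0=prop0,
        prop5=prop5,
        z0=z0,
        p0=p0v,
        z5=z5,
        p5=p5v,
        expected=expected,
        alpha=alpha,
        significant0=bool(n > 0 and p0v < alpha),
        significant5=bool(n > 0 and p5v < alpha),
        half_policy=half_policy,
    )
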