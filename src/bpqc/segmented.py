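"""Threshold preference/avoidance via segmented Poisson regression.

Clinical cut-offs (140 mm Hg systolic, 90 mm Hg diastolic) mandate a
response, and recorders sometimes nudge borderline values just below the
line (avoidance) or onto it (preference).  Either behaviour shows up as a
discontinuity in the per-mm Hg frequency histogram at the cut-off.

The detection model is a log-linear Poisson regression of counts per
1-mm Hg level on a window around the threshold T:

    log E[count at level L] = b0 + b1*x + b2*z + b3*x*z,
    x = L - T (centred level),  z = 1[L >= T]

so ``b2`` is the log-scale jump exactly at the cut-off.  The segmentation
(b2, b3 jointly) is tested against the smooth reduced model (b0, b1) with a
2-degree-of-freedom likelihood-ratio test; a significant negative jump is
labelled avoidance, a positive one preference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .io_model import ALPHA

#: Default half-width (mm Hg) of the fitting window around the threshold.
#: The window materially affects the fitted slope; it is a modelling choice,
#: not a property of the data, and is exposed everywhere.
DEFAULT_WINDOW = 20


@dataclass
class LevelHistogram:
    """Counts of integer readings per 1-mm Hg level in a window."""

    levels: np.ndarray  # contiguous integer levels
    counts: np.ndarray  # non-negative ints, zero-filled
    threshold: int
    n_excluded_non_integer: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict:
        return {
            "levels": self.levels.tolist(),
            "counts": self.counts.tolist(),
            "threshold": self.threshold,
            "n_excluded_non_integer": self.n_excluded_non_integer,
        }


def level_counts(values, threshold: int, window_halfwidth: int = DEFAULT_WINDOW) -> LevelHistogram:
    """Histogram of integer values on [threshold−w, threshold+w], zero-filled.

    Half-integer (averaged) values fall between 1-mm Hg levels and are
    excluded; their number is reported so the exclusion is auditable.
    Raises if no value lands in the window (the caller should widen it).
    """
    if window_halfwidth < 5:
        raise ValueError("window_halfwidth must be >= 5")
    v = np.asarray(values, dtype=float)
    is_int = v == np.floor(v)
    in_window = is_int & (v >= threshold - window_halfwidth) & (v <= threshold + window_halfwidth)
    n_excl = int((~is_int & (v >= threshold - window_halfwidth) & (v <= threshold + window_halfwidth)).sum())
    levels = np.arange(threshold - window_halfwidth, threshold + window_halfwidth + 1)
    if not in_window.any():
        raise ValueError(
            f"no integer values within {window_halfwidth} mm Hg of {threshold}; widen the window"
        )
    idx = (v[in_window].astype(np.int64) - levels[0]).astype(np.int64)
    counts = np.bincount(idx, minlength=levels.size)
    return LevelHistogram(levels=levels, counts=counts, threshold=threshold,
                          n_excluded_non_integer=n_excl)


@dataclass
class PoissonFit:
    """Maximum-likelihood log-linear Poisson fit."""

    beta: np.ndarray
    loglik: float
    fitted: np.ndarray
    converged: bool
    iterations: int
    grad_norm: float

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "iterations": self.iterations,
            "grad_norm": self.grad_norm,
        }


def poisson_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Poisson log-likelihood sum_i (y_i eta_i − exp(eta_i) − log y_i!)."""
    eta = X @ beta
    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1)))


def poisson_fit(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> PoissonFit:
    """Fit a Poisson GLM with log link by Newton–Raphson with step halving.

    Starts from an intercept at log(mean(y)) (slopes 0).  Converges when the
    relative change in log-likelihood drops below ``tol``.  Separation or a
    singular information matrix yields ``converged=False`` so callers can
    suppress downstream likelihood-ratio tests.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    n, p = X.shape
    beta = np.zeros(p)
    has_intercept = np.allclose(X[:, 0], 1.0)
    if has_intercept:
        beta[0] = np.log(max(y.mean(), 1e-8))
    ll = poisson_loglik(beta, X, y)
    converged = False
    it = 0
    grad = np.full(p, np.nan)
    for it in range(1, max_iter + 1):
        mu = np.exp(X @ beta)
        grad = X.T @ (y - mu)
        info = (X * mu[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # step halving keeps the likelihood non-decreasing
        t = 1.0
        for _ in range(50):
            cand = beta + t * step
            ll_new = poisson_loglik(cand, X, y)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-14:
                break
            t /= 2
        else:
            break
        beta, ll_old, ll = cand, ll, ll_new
        if abs(ll - ll_old) <= tol * (abs(ll_old) + 1.0):
            converged = True
            break
    mu = np.exp(X @ beta)
    grad = X.T @ (y - mu)
    return PoissonFit(
        beta=beta,
        loglik=float(poisson_loglik(beta, X, y)),
        fitted=mu,
        converged=converged,
        iterations=it,
        grad_norm=float(np.linalg.norm(grad)),
    )


def segmented_design(levels: np.ndarray, threshold: int) -> tuple[np.ndarray, np.ndarray]:
    """Full ([1, x, z, x*z]) and reduced ([1, x]) design matrices."""
    x = np.asarray(levels, dtype=float) - threshold
    z = (np.asarray(levels) >= threshold).astype(float)
    full = np.column_stack([np.ones_like(x), x, z, x * z])
    reduced = full[:, :2]
    return full, reduced


@dataclass
class SegmentedResult:
    """Segmented-vs-smooth Poisson comparison at one threshold."""

    threshold: int
    full: PoissonFit
    reduced: PoissonFit
    lrt_stat: float
    df: int
    p_value: float
    direction: str  # "preference" | "avoidance" | "none" | "undefined"
    alpha: float
    window_halfwidth: int
    n_excluded_non_integer: int = 0
    fitted_curve: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "full": self.full.to_dict(),
            "reduced": self.reduced.to_dict(),
            "lrt_stat": self.lrt_stat,
            "df": self.df,
            "p_value": self.p_value,
            "direction": self.direction,
            "alpha": self.alpha,
            "window_halfwidth": self.window_halfwidth,
            "n_excluded_non_integer": self.n_excluded_non_integer,
            "fitted_curve": {k: list(v) for k, v in self.fitted_curve.items()},
        }


def segmented_threshold_test(
    hist: LevelHistogram,
    alpha: float = ALPHA,
    step_only: bool = False,
) -> SegmentedResult:
    """Likelihood-ratio test for a discontinuity at the histogram's threshold.

    Full model: intercept, centred level, step at the threshold, and the
    step×level interaction; reduced model drops the step and interaction.
    Default is the 2-df joint test; ``step_only=True`` drops the interaction
    from the full model and tests the step alone on 1 df.

    direction is "avoidance" when the step coefficient is negative and the
    test is significant at ``alpha``, "preference" when positive and
    significant, "none" otherwise, and "undefined" if either fit failed.
    """
    below = (hist.levels < hist.threshold).sum()
    above = (hist.levels >= hist.threshold).sum()
    if below < 3 or above < 3:
        raise ValueError("histogram must span >= 3 levels on each side of the threshold")
    full_X, red_X = segmented_design(hist.levels, hist.threshold)
    if step_only:
        full_X = full_X[:, :3]
    y = hist.counts.astype(float)
    full = poisson_fit(full_X, y)
    reduced = poisson_fit(red_X, y)
    df = full_X.shape[1] - red_X.shape[1]
    if not (full.converged and reduced.converged):
        lrt = float("nan")
        p = float("nan")
        direction = "undefined"
    else:
        lrt = max(0.0, 2.0 * (full.loglik - reduced.loglik))
        p = float(chi2.sf(lrt, df))
        b2 = full.beta[2]
        if p < alpha:
            direction = "preference" if b2 > 0 else "avoidance"
        else:
            direction = "none"
    return SegmentedResult(
        threshold=hist.threshold,
        full=full,
        reduced=reduced,
        lrt_stat=lrt,
        df=df,
        p_value=p,
        direction=direction,
        alpha=alpha,
        window_halfwidth=int((hist.levels.size - 1) // 2),
        n_excluded_non_integer=hist.n_excluded_non_integer,
        fitted_curve={
            "levels": hist.levels.tolist(),
            "observed": hist.counts.tolist(),
            "fitted_full": full.fitted.tolist(),
            "fitted_reduced": reduced.fitted.tolist(),
        },
    )


def classify_all(
    vt_raw: pd.DataFrame,
    averaged: pd.DataFrame,
    thresholds: dict[str, int] | None = None,
    alpha: float = ALPHA,
    window_halfwidth: int = DEFAULT_WINDOW,
) -> dict:
    """Run the threshold test for every stratum of a study.

    Strata are cohort × measure (sbp@140, dbp@90 by default) × stage
    (raw readings / protocol-averaged values), plus a pooled stratum per
    measure × stage.  Returns a nested dict of
    :class:`SegmentedResult`-dicts; a stratum whose window is empty or
    too sparse records the error string instead.
    """
    thresholds = thresholds or {"sbp": 140, "dbp": 90}
    out: dict = {}
    cohorts = sorted(vt_raw["cohort_id"].unique()) if len(vt_raw) else []
    for stage, frame, cols in (
        ("raw", vt_raw, {"sbp": "sbp", "dbp": "dbp"}),
        ("averaged", averaged, {"sbp": "sbp_avg", "dbp": "dbp_avg"}),
    ):
        for measure, thr in thresholds.items():
            for cohort in [*cohorts, "pooled"]:
                if cohort == "pooled":
                    vals = frame[cols[measure]]
                else:
                    vals = frame.loc[frame["cohort_id"] == cohort, cols[measure]]
                key = f"{stage}/{measure}@{thr}/{cohort}"
                try:
                    hist = level_counts(vals, thr, window_halfwidth)
                    out[key] = segmented_threshold_test(hist, alpha=alpha).to_dict()
                except ValueError as exc:
                    out[key] = {"error": str(exc)}
    return out
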