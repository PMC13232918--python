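"""Generative model of the BP measurement-and-transcription process.

Emulates the data-quality phenomena the audits detect, on top of a clean
physiological core, so every pipeline stage can be exercised end to end
with known ground truth:

* a correlated bivariate-normal "true" (sBP, dBP) per visit, with
  independent within-visit reading noise;
* a device-algorithm artifact that displays one fixed diastolic value
  (62 mm Hg) for a band of true pressures;
* observer digit heaping: transcribing the nearest multiple of 10
  (probability ``theta0``) or, failing that, the nearest value ending in 5
  (probability ``theta5``);
* threshold displacement on systolic values around the referral cut-off
  ``T``: readings just at/above T pushed below it (``phi_avoid``) or
  readings just below pulled onto it (``psi_prefer``);
* the triplicate protocol itself — a third reading is generated through
  the same pipeline whenever the first two displayed readings differ by
  more than 10 mm Hg in either component.

Mechanisms apply per displayed reading in a fixed order (artifact →
heaping → displacement), which keeps the closed-form digit expectations in
:func:`expected_digit_excess` exact.  Generation is a deterministic
function of (config, seed); each visit draws from its own substream of the
master seed, so enlarging a cohort never perturbs earlier visits.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .averaging import requires_third_reading
from .io_model import VISIT_COLUMNS

__all__ = ["SimConfig", "simulate_cohort", "expected_digit_excess", "make_fixture", "FIXTURES"]


@dataclass(frozen=True)
class SimConfig:
    """All generative parameters of the synthetic observer-behaviour model.

    Defaults describe a young-adult (largely pregnant) population measured
    with moderate device/observer noise and *no* behavioural mechanisms;
    each mechanism is switched on by raising its probability.
    """

    n_visits: int = 1000
    cohort_id: str = "SIM"
    # true-BP distribution (mm Hg)
    mu_sbp: float = 115.0
    sd_sbp: float = 12.0
    mu_dbp: float = 70.0
    sd_dbp: float = 9.0
    rho: float = 0.6          # sBP-dBP correlation
    sigma_within: float = 4.0  # reading-to-reading noise SD
    # observer digit heaping
    theta0: float = 0.0  # P(transcribe nearest multiple of 10)
    theta5: float = 0.0  # P(transcribe nearest value ending in 5 | not heaped to 10)
    # threshold displacement on sBP around T
    phi_avoid: float = 0.0   # P(reading in [T, T+w_b] displaced into [T-w_b, T-1])
    psi_prefer: float = 0.0  # P(reading in [T-w_b, T-1] displaced to exactly T)
    w_b: int = 4             # behaviour band half-width, mm Hg
    threshold: int = 140
    # device artifact
    pi62: float = 0.0        # P(dBP displayed as 62 | true dBP in [55, 75])
    artifact_band: tuple[float, float] = (55.0, 75.0)
    artifact_value: int = 62
    seed: int = 0

    def validate(self) -> None:
        for name in ("theta0", "theta5", "phi_avoid", "psi_prefer", "pi62", "rho"):
            v = getattr(self, name)
            lo = -1.0 if name == "rho" else 0.0
            if not lo <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [{lo}, 1]")
        if abs(self.rho) >= 1.0:
            raise ValueError("rho must be in (-1, 1)")
        if self.sd_sbp <= 0 or self.sd_dbp <= 0 or self.sigma_within < 0:
            raise ValueError("scale parameters must be positive")
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["artifact_band"] = list(self.artifact_band)
        return d


def _nearest_ten(v: int) -> int:
    return ((v + 5) // 10) * 10  # ties (x5) round up


def _nearest_five_ending(v: int) -> int:
    return (v // 10) * 10 + 5  # nearest value ending in 5; ties (x0) round up


def _transcribe(value: int, u_ten: float, u_five: float, cfg: SimConfig) -> int:
    """Apply observer digit heaping to one displayed integer value."""
    if u_ten < cfg.theta0:
        return _nearest_ten(value)
    if u_five < cfg.theta5:
        return _nearest_five_ending(value)
    return value


def _make_reading(
    rng: np.random.Generator,
    true_sbp: float,
    true_dbp: float,
    in_band: bool,
    cfg: SimConfig,
) -> tuple[int, int]:
    # Every reading consumes a fixed block of draws (2 noise + 7 uniforms),
    # whether or not each mechanism fires: toggling one mechanism therefore
    # never perturbs the realisation of the others — the no-cross-talk
    # property the audits are tested against.
    eps = rng.normal(size=2)
    u = rng.random(7)
    s = int(np.rint(true_sbp + cfg.sigma_within * eps[0]))
    d = int(np.rint(true_dbp + cfg.sigma_within * eps[1]))
    # 1. device artifact on the diastolic display
    if in_band and u[0] < cfg.pi62:
        d = cfg.artifact_value
    # 2. observer digit heaping, each component transcribed independently
    s = _transcribe(s, u[1], u[2], cfg)
    d = _transcribe(d, u[3], u[4], cfg)
    # 3. threshold displacement on the systolic value
    T, w = cfg.threshold, cfg.w_b
    if T <= s <= T + w:
        if u[5] < cfg.phi_avoid:
            s = T - w + int(u[6] * w)  # uniform on [T-w, T-1]
    elif T - w <= s <= T - 1:
        if u[5] < cfg.psi_prefer:
            s = T
    # physiological clamps keep every generated visit valid downstream
    s = int(np.clip(s, 40, 300))
    d = int(np.clip(d, 20, 200))
    if d >= s:
        s = d + 1
    return s, d


def simulate_cohort(cfg: SimConfig) -> pd.DataFrame:
    """Generate a long-format visit table from the observer-behaviour model.

    One participant per visit.  Readings 1 and 2 are always produced; a
    third is produced by the same mechanism whenever readings 1 and 2
    differ by more than 10 mm Hg in either component (the triplicate rule).
    Deterministic in (config, seed): each visit uses the substream
    ``SeedSequence(seed, spawn_key=(visit,))``.
    """
    cfg.validate()
    lo, hi = cfg.artifact_band
    rows: list[tuple] = []
    chol_off = cfg.rho
    for i in range(cfg.n_visits):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(i,)))
        z1, z2 = rng.normal(size=2)
        true_s = cfg.mu_sbp + cfg.sd_sbp * z1
        true_d = cfg.mu_dbp + cfg.sd_dbp * (chol_off * z1 + np.sqrt(1 - chol_off**2) * z2)
        in_band = lo <= true_d <= hi
        pid = f"P{i:06d}"
        r1 = _make_reading(rng, true_s, true_d, in_band, cfg)
        r2 = _make_reading(rng, true_s, true_d, in_band, cfg)
        rows.append((cfg.cohort_id, pid, "V1", 1, r1[0], r1[1]))
        rows.append((cfg.cohort_id, pid, "V1", 2, r2[0], r2[1]))
        if requires_third_reading(r1, r2):
            r3 = _make_reading(rng, true_s, true_d, in_band, cfg)
            rows.append((cfg.cohort_id, pid, "V1", 3, r3[0], r3[1]))
    return pd.DataFrame(rows, columns=VISIT_COLUMNS)


def _band_prob(a: float, b: float, mu: float, sd: float) -> float:
    """P(a <= round(X) <= b) for X ~ N(mu, sd), integer band edges."""
    return float(norm.cdf((b + 0.5 - mu) / sd) - norm.cdf((a - 0.5 - mu) / sd))


def expected_digit_excess(cfg: SimConfig) -> dict[str, dict[str, float]]:
    """Closed-form expected terminal-digit 0/5 proportions per measure.

    Under the generator the terminal digit of an un-heaped displayed reading
    is uniform to within a negligible discretisation error (the reading SD
    far exceeds one digit cycle), so with ``b0``/``b5`` the pre-heaping
    digit-0/5 probabilities:

        prop0 = theta0 + (1-theta0)(1-theta5) * b0   [+ displacement terms]
        prop5 = (1-theta0) * [theta5 + (1-theta5) * b5]

    For diastolic values the device artifact first moves a fraction
    ``pi62 * P(true dBP in band)`` of readings onto 62 (terminal digit 2),
    shrinking ``b0`` and ``b5`` proportionally.  For systolic values the
    threshold displacement (applied after heaping) removes digit-0 mass at
    the cut-off level T with probability ``phi_avoid`` and adds it with
    ``psi_prefer``; both corrections use the smooth level probabilities of
    the displayed-reading distribution.
    """
    cfg.validate()
    t0, t5 = cfg.theta0, cfg.theta5
    keep = (1 - t0) * (1 - t5)

    # --- diastolic ---
    q_lat = float(norm.cdf((cfg.artifact_band[1] - cfg.mu_dbp) / cfg.sd_dbp)
                  - norm.cdf((cfg.artifact_band[0] - cfg.mu_dbp) / cfg.sd_dbp))
    q = cfg.pi62 * q_lat
    b0_d = 0.1 * (1 - q)
    b5_d = 0.1 * (1 - q)
    dbp0 = t0 + keep * b0_d
    dbp5 = (1 - t0) * t5 + keep * b5_d

    # --- systolic ---
    sd_read = float(np.hypot(cfg.sd_sbp, cfg.sigma_within))
    T, w = cfg.threshold, cfg.w_b
    # post-heaping probability of sitting exactly on the cut-off level T
    p_at_T = (
        t0 * _band_prob(T - 5, T + 4, cfg.mu_sbp, sd_read)
        + keep * _band_prob(T, T, cfg.mu_sbp, sd_read)
    )
    # post-heaping probability of the band just below T (never a heap target)
    p_below = keep * _band_prob(T - w, T - 1, cfg.mu_sbp, sd_read)
    sbp0 = t0 + keep * 0.1 - cfg.phi_avoid * p_at_T + cfg.psi_prefer * p_below
    sbp5 = (1 - t0) * t5 + keep * 0.1
    return {
        "sbp": {"prop0": sbp0, "prop5": sbp5},
        "dbp": {"prop0": dbp0, "prop5": dbp5},
    }


#: Small deterministic cohorts with documented generating parameters.
FIXTURES: dict[str, SimConfig] = {
    "null": SimConfig(n_visits=300, cohort_id="NULL", seed=20260901),
    "heaped": SimConfig(n_visits=400, cohort_id="HEAPED", theta0=0.15, theta5=0.05, seed=20260902),
    "avoidant": SimConfig(n_visits=500, cohort_id="AVOID", phi_avoid=0.5, seed=20260903),
    "spiked": SimConfig(n_visits=400, cohort_id="SPIKED", pi62=0.3, seed=20260904),
    "mixed": SimConfig(
        n_visits=500, cohort_id="MIXED", theta0=0.15, theta5=0.05,
        phi_avoid=0.3, psi_prefer=0.1, pi62=0.3, seed=20260905,
    ),
}


def make_fixture(name: str) -> pd.DataFrame:
    """Regenerate one of the registered small test cohorts by name."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    return simulate_cohort(FIXTURES[name])
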