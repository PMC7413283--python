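"""Synthetic actigraphy generator.

Emits complete subject-day records with the statistical structure real
minute-level activity counts exhibit: a diurnal intensity profile (night
trough near zero, waking plateau between 9 AM and 9 PM), zero inflation that
is strongest at night and arrives in clustered sedentary runs, negative-
binomial overdispersion (real count data have SD far above the mean), smooth
within-day intensity modulation (activity is bout-structured, with strong
minute-scale autocorrelation), bursty high-intensity (MVPA-like) episodes,
and lognormal between-subject heterogeneity.  Defaults are calibrated so the
overall mean count is close to 344 counts/min, the scale of population
waist-worn uniaxial actigraphy.

Two latent AR(1) Gaussian processes carry the temporal dependence: one,
exponentiated with a unit-mean correction, modulates the intensity on a
~30-minute correlation time; the other is thresholded through a Gaussian
copula to produce structural zeros with the exact time-varying marginal
probability but an ~8-minute correlation time, so zeros cluster into
realistic sedentary runs instead of salt-and-pepper noise.

Counts are nonnegative integers; generation is a deterministic function of
``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter
from scipy.stats import norm

from .records import (
    FULL_DAY_MINUTES,
    ActivityRecord,
    RecordSet,
    detect_missing_intervals,
)


def default_diurnal_profile(minute: np.ndarray) -> np.ndarray:
    """Piecewise base intensity (counts/min): night trough, day plateau.

    0:00-6:00 ~ 5 counts; ramp to the plateau by 9:00; 800 counts 9:00-21:00;
    ramp back down 21:00-24:00.
    """
    minute = np.asarray(minute, dtype=float)
    trough, plateau = 5.0, 800.0
    out = np.empty_like(minute)
    night = minute < 360
    morning = (minute >= 360) & (minute < 540)
    day = (minute >= 540) & (minute < 1260)
    evening = minute >= 1260
    out[night] = trough
    out[morning] = trough + (plateau - trough) * (minute[morning] - 360) / 180.0
    out[day] = plateau
    out[evening] = plateau + (trough - plateau) * (minute[evening] - 1260) / 180.0
    return out


def default_zero_inflation(minute: np.ndarray) -> np.ndarray:
    """Probability of a structural zero per minute; high at night, lower by day."""
    minute = np.asarray(minute, dtype=float)
    out = np.full(minute.shape, 0.5)
    out[minute < 360] = 0.8
    out[(minute >= 540) & (minute < 1260)] = 0.35
    return out


@dataclass
class SynthParams:
    """Generator settings; the defaults define the standard study conditions."""

    n_subjects: int = 50
    days_per_subject: int = 4
    diurnal_profile: object = default_diurnal_profile       # minute -> counts/min
    zero_inflation: object = default_zero_inflation         # minute -> prob in [0,1]
    dispersion: float = 5.0         # negative-binomial size; smaller = more overdispersed
    mvpa_bout_rate: float = 1.5     # expected high-intensity bouts per day
    mvpa_intensity: float = 2500.0  # counts/min during a bout (above the 1267 cutoff)
    subject_sd: float = 0.4         # between-subject SD of log intensity
    intensity_sd: float = 0.6       # SD of the within-day log-intensity modulation
    intensity_corr_minutes: float = 30.0  # correlation time of that modulation
    zero_corr_minutes: float = 8.0  # correlation time of the sedentary (zero) process
    axis_kind: str = "uniaxial"
    complete_only: bool = True      # guarantee no >=30-min zero run
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.days_per_subject < 1:
            raise ValueError("need at least one subject-day")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.mvpa_bout_rate < 0 or self.mvpa_intensity < 0:
            raise ValueError("MVPA parameters must be nonnegative")
        if self.subject_sd < 0 or self.intensity_sd < 0:
            raise ValueError("subject_sd and intensity_sd must be nonnegative")
        if self.intensity_corr_minutes <= 0 or self.zero_corr_minutes <= 0:
            raise ValueError("correlation times must be positive")
        minutes = np.arange(FULL_DAY_MINUTES)
        pi = np.asarray(self.zero_inflation(minutes), dtype=float)
        if np.any(pi < 0) or np.any(pi > 1):
            raise ValueError("zero_inflation must lie in [0, 1]")
        mu = np.asarray(self.diurnal_profile(minutes), dtype=float)
        if np.any(mu < 0) or not np.all(np.isfinite(mu)):
            raise ValueError("diurnal_profile must be finite and nonnegative")

    def expected_mean(self) -> float:
        """Closed-form overall per-minute mean of the generator (excl. MVPA bouts
        it is (1-pi)*mu averaged over the day; bouts add rate*len*intensity/1440)."""
        minutes = np.arange(FULL_DAY_MINUTES)
        mu = np.asarray(self.diurnal_profile(minutes), dtype=float)
        pi = np.asarray(self.zero_inflation(minutes), dtype=float)
        base = float(np.mean((1.0 - pi) * mu))
        bout = self.mvpa_bout_rate * 15.0 * self.mvpa_intensity / FULL_DAY_MINUTES
        return base + bout


def generate_zip_table(n: int, pi: float, lam: float, rng_seed: int = 0) -> np.ndarray:
    """I.i.d. zero-inflated Poisson draws: 0 with probability pi, else Poisson(lam)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= pi <= 1.0):
        raise ValueError("pi must lie in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    rng = np.random.default_rng(rng_seed)
    structural = rng.random(n) < pi
    counts = rng.poisson(lam, size=n)
    counts[structural] = 0
    return counts


def _break_long_zero_runs(values: np.ndarray, mu: np.ndarray, rng: np.random.Generator) -> None:
    """Insert a nonzero count inside every >=30-minute zero run (in place)."""
    for start, length in detect_missing_intervals(values, min_run=30):
        # one interruption every 29 minutes keeps all residual runs < 30
        for pos in range(start + 14, start + length, 29):
            values[pos] = max(1, int(rng.poisson(max(mu[pos], 1.0))))
        # the tail after the last interruption may still be long
        while detect_missing_intervals(values[start : start + length], min_run=30):
            sub = detect_missing_intervals(values[start : start + length], min_run=30)[0]
            pos = start + sub[0] + sub[1] // 2
            values[pos] = max(1, int(rng.poisson(max(mu[pos], 1.0))))


def _ar1(n: int, corr_minutes: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary standard-Gaussian AR(1) path with lag-1 corr exp(-1/tau)."""
    rho = math.exp(-1.0 / corr_minutes)
    innovations = rng.standard_normal(n)
    innovations[1:] *= math.sqrt(1.0 - rho * rho)  # keep path[0] standard normal
    return lfilter([1.0], [1.0, -rho], innovations)


def generate_dataset(params: SynthParams) -> RecordSet:
    """Draw ``n_subjects * days_per_subject`` complete full-day records."""
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    minutes = np.arange(FULL_DAY_MINUTES)
    mu_base = np.asarray(params.diurnal_profile(minutes), dtype=float)
    pi = np.asarray(params.zero_inflation(minutes), dtype=float)
    r = params.dispersion
    zero_threshold = norm.ppf(np.clip(pi, 0.0, 1.0))

    records: list[ActivityRecord] = []
    for s in range(params.n_subjects):
        # lognormal subject effect with unit mean
        effect = float(
            np.exp(rng.normal(-0.5 * params.subject_sd**2, params.subject_sd))
        )
        for d in range(params.days_per_subject):
            # smooth within-day modulation: unit-mean lognormal AR(1)
            w = _ar1(FULL_DAY_MINUTES, params.intensity_corr_minutes, rng)
            modulation = np.exp(params.intensity_sd * w - 0.5 * params.intensity_sd**2)
            mu = np.maximum(mu_base * effect * modulation, 1e-9)
            # zero-inflated negative binomial via gamma-Poisson mixture
            gamma_rate = rng.gamma(shape=r, scale=mu / r)
            counts = rng.poisson(gamma_rate).astype(float)
            # clustered structural zeros: Gaussian-copula thresholding keeps
            # the exact marginal pi(t) but correlates neighbouring minutes
            z = _ar1(FULL_DAY_MINUTES, params.zero_corr_minutes, rng)
            counts[z < zero_threshold] = 0.0
            # inject contiguous MVPA bouts during the waking window
            n_bouts = rng.poisson(params.mvpa_bout_rate)
            for _ in range(n_bouts):
                length = int(rng.integers(10, 21))
                start = int(rng.integers(540, 1260 - length))
                burst = rng.poisson(params.mvpa_intensity, size=length).astype(float)
                counts[start : start + length] = burst
            if params.complete_only:
                _break_long_zero_runs(counts, mu, rng)
            records.append(
                ActivityRecord(
                    subject_id=f"S{s:04d}",
                    day_index=d,
                    values=counts,
                    axis_kind=params.axis_kind,
                )
            )
    return RecordSet(records)
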