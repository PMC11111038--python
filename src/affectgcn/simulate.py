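"""Synthetic ESM cohort generator.

Emulates the sampling design of a mindfulness-trial ESM study: each patient
rates six feelings on a 1-7 Likert scale at 10 random beeps per day over 6
days.  Latent affect follows a per-patient lag-1 vector autoregression
(VAR(1)); subject heterogeneity enters through random deviations of the
lag-coefficient matrix, and a configurable "prone" subset receives an
upward shift of negative affect on the final day (the day used for
labeling downstream).

The latent-to-Likert mapping is a fixed affine map: latent deviations from
the base stationary mean are added to the scale midpoint 4, rounded to the
nearest integer and clamped to [1, 7].  With the default innovation SD of
1 the stationary SD is near 1, so +/-3 SD spans the whole scale and
clamping is rare.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov

from .items import FEELINGS, N_FEELINGS, NEGATIVE_IDX, LIKERT_MIN, LIKERT_MAX

__all__ = ["CohortSpec", "default_transition_matrix", "generate_cohort"]

_MID = (LIKERT_MIN + LIKERT_MAX) / 2  # Likert scale midpoint


def default_transition_matrix() -> np.ndarray:
    """Default generating lag-1 coefficient matrix.

    Diagonal autoregression 0.3, +0.1 cross-lags within a polarity block,
    -0.1 across polarities; spectral radius 0.8 (stationary).  Qualitatively
    mimics empirical affect networks: inertia on the diagonal, mutual
    amplification within negative/positive affect, mutual damping between.
    """
    J = np.ones((3, 3))
    return 0.2 * np.eye(6) + 0.1 * np.block([[J, -J], [-J, J]])


def spectral_radius(m: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(m, dtype=float)))))


@dataclass
class CohortSpec:
    """Generating parameters for a synthetic ESM cohort.

    Parameters
    ----------
    n_patients, n_days, beeps_per_day
        Cohort dimensions; defaults mirror the reference sampling design
        (126 patients, 6 days, 10 beeps/day).
    fixed_matrix
        6x6 population lag-1 coefficient matrix; entry [j, k] is the effect
        of feeling k at the previous beep on feeling j.  Must be stationary
        (spectral radius < 1).
    fixed_intercepts
        Population VAR intercepts (latent units).
    random_slope_sd
        SD of i.i.d. subject deviations added to every coefficient.
    noise_sd
        SD of the VAR innovations (latent units).
    prone_fraction
        Probability that a patient is "prone": negative affect shifted
        upward on the final day.
    day6_negative_shift
        Latent-mean shift added to the three negative feelings on the final
        day for prone patients; one latent unit ~ one Likert point.
    prone_autocorr_shift
        Added to the diagonal coefficients of the three negative feelings
        for prone patients, planting a network-level signature of proneness
        (0 disables; the shifted matrix must stay stationary).
    prone_baseline_shift
        Latent-mean shift of the three negative feelings on *all* days for
        prone patients (tonic negative-affect elevation).  Leaves the IDF
        ratio near 1 absent a day-6 shift (numerator and denominator move
        together) but makes prone patients' node features separable.
    missing_rate
        Per-rating probability of a missing response (MCAR).
    seed
        RNG seed; identical spec + seed reproduces the panel exactly.
    """

    n_patients: int = 126
    n_days: int = 6
    beeps_per_day: int = 10
    fixed_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    fixed_intercepts: np.ndarray = field(default_factory=lambda: np.zeros(6))
    random_slope_sd: float = 0.05
    noise_sd: float = 1.0
    prone_fraction: float = 0.3
    day6_negative_shift: float = 1.0
    prone_autocorr_shift: float = 0.0
    prone_baseline_shift: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.fixed_matrix = np.asarray(self.fixed_matrix, dtype=float)
        self.fixed_intercepts = np.asarray(self.fixed_intercepts, dtype=float)
        if self.fixed_matrix.shape != (N_FEELINGS, N_FEELINGS):
            raise ValueError("fixed_matrix must be 6x6")
        if self.fixed_intercepts.shape != (N_FEELINGS,):
            raise ValueError("fixed_intercepts must have 6 entries")
        if spectral_radius(self.fixed_matrix) >= 1.0:
            raise ValueError(
                "fixed_matrix is non-stationary (spectral radius "
                f"{spectral_radius(self.fixed_matrix):.3f} >= 1)"
            )
        if self.prone_autocorr_shift:
            shifted = self.fixed_matrix.copy()
            shifted[NEGATIVE_IDX, NEGATIVE_IDX] += self.prone_autocorr_shift
            if spectral_radius(shifted) >= 1.0:
                raise ValueError("prone_autocorr_shift makes the prone matrix non-stationary")
        if not 0.0 <= self.prone_fraction <= 1.0:
            raise ValueError("prone_fraction must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.random_slope_sd < 0:
            raise ValueError("random_slope_sd must be nonnegative")
        for name in ("n_patients", "n_days", "beeps_per_day"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def stationary_mean(self) -> np.ndarray:
        """Stationary mean of the base latent process."""
        return np.linalg.solve(np.eye(N_FEELINGS) - self.fixed_matrix, self.fixed_intercepts)


def _patient_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"p{i + 1:0{width}d}" for i in range(n)]


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a long-format ESM panel from a :class:`CohortSpec`.

    Returns a DataFrame with columns ``patient_id, day, beep`` followed by
    the six feeling columns in canonical order (nullable integers 1-7,
    ``pd.NA`` for missing).  The latent chain restarts from its stationary
    mean at every day boundary (no overnight carry-over), matching the
    within-day lag convention used when the networks are estimated.
    """
    rng = np.random.default_rng(spec.seed)
    mu = spec.stationary_mean()
    prone = rng.random(spec.n_patients) < spec.prone_fraction

    shift_vec = np.zeros(N_FEELINGS)
    shift_vec[NEGATIVE_IDX] = spec.day6_negative_shift

    n_beeps = spec.n_days * spec.beeps_per_day
    ratings = np.empty((spec.n_patients, n_beeps, N_FEELINGS))
    for i in range(spec.n_patients):
        phi = spec.fixed_matrix.copy()
        if prone[i] and spec.prone_autocorr_shift:
            phi[NEGATIVE_IDX, NEGATIVE_IDX] += spec.prone_autocorr_shift
        if spec.random_slope_sd > 0:
            phi = phi + rng.normal(0.0, spec.random_slope_sd, (N_FEELINGS, N_FEELINGS))
        latent = np.empty((n_beeps, N_FEELINGS))
        for d in range(spec.n_days):
            z = mu.copy()  # chain restarts at the stationary mean each morning
            for b in range(spec.beeps_per_day):
                z = spec.fixed_intercepts + phi @ z + rng.normal(0.0, spec.noise_sd, N_FEELINGS)
                latent[d * spec.beeps_per_day + b] = z
        if prone[i] and spec.prone_baseline_shift:
            latent[:, NEGATIVE_IDX] += spec.prone_baseline_shift
        if prone[i] and spec.day6_negative_shift:
            latent[(spec.n_days - 1) * spec.beeps_per_day:] += shift_vec
        ratings[i] = latent

    # fixed affine Likert map: midpoint + deviation from base stationary mean
    scaled = _MID + (ratings - mu)
    likert = np.clip(np.rint(scaled), LIKERT_MIN, LIKERT_MAX).astype(int)

    pids = _patient_ids(spec.n_patients)
    days = np.repeat(np.arange(1, spec.n_days + 1), spec.beeps_per_day)
    beeps = np.tile(np.arange(1, spec.beeps_per_day + 1), spec.n_days)
    frame = pd.DataFrame(
        {
            "patient_id": np.repeat(pids, n_beeps),
            "day": np.tile(days, spec.n_patients),
            "beep": np.tile(beeps, spec.n_patients),
        }
    )
    flat = likert.reshape(-1, N_FEELINGS)
    for j, name in enumerate(FEELINGS):
        frame[name] = pd.array(flat[:, j], dtype="Int64")
    if spec.missing_rate > 0:
        mask = rng.random(flat.shape) < spec.missing_rate
        for j, name in enumerate(FEELINGS):
            col = frame[name].copy()
            col[mask[:, j]] = pd.NA
            frame[name] = col
    return frame
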