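"""Per-patient affect networks from multilevel lag-1 VAR.

Each patient's day-1..5 mood log is reduced to a 6x6 directed weighted
network.  For every outcome feeling j a linear mixed model is fitted
across all patients:

    y[j, t] = (a_j + u[i, j]) + sum_k (Phi[j, k] + b[i, j, k]) * y[k, t-1] + e

with a random intercept and six random slopes per subject (diagonal
random-effects covariance), estimated by REML.  A patient's network is the
fixed-effect matrix plus their predicted (BLUP) slope deviations:
A_i[j, k] = Phi[j, k] + b[i, j, k], the lagged effect of feeling k on
feeling j.  Lag pairs are formed only between consecutive beeps within the
same day — overnight gaps are hours long and carry no lag-1 meaning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .items import FEELINGS, N_FEELINGS, NEGATIVE_IDX

__all__ = [
    "LaggedDesign",
    "FixedEffects",
    "PatientNetwork",
    "build_lagged_design",
    "fit_multilevel_var",
    "subject_networks",
    "compute_node_features",
]

logger = logging.getLogger(__name__)

DEFAULT_DAYS = (1, 5)  # networks use days 1-5; day 6 is reserved for labeling
MIN_ROWS_PER_PATIENT = 8


@dataclass
class LaggedDesign:
    """Stacked per-patient regression rows for the lag-1 mixed models.

    ``frame`` columns: patient_id, day, y_<feeling> (outcome at t) and
    lag_<feeling> (predictor at t-1).  ``excluded`` lists patients dropped
    for having fewer usable rows than the configured minimum.
    """

    frame: pd.DataFrame
    excluded: list[str] = field(default_factory=list)

    @property
    def patients(self) -> list[str]:
        return list(pd.unique(self.frame["patient_id"]))

    def row_counts(self) -> pd.Series:
        return self.frame.groupby("patient_id", sort=False).size()


@dataclass
class FixedEffects:
    """Population-level VAR estimates: coef[j, k] = effect of k(t-1) on j(t)."""

    coef: np.ndarray
    intercepts: np.ndarray


@dataclass
class PatientNetwork:
    """Subject-specific 6x6 lag-1 coefficient matrix (fixed effect + BLUP)."""

    patient_id: str
    matrix: np.ndarray


def build_lagged_design(
    panel: pd.DataFrame,
    days: tuple[int, int] = DEFAULT_DAYS,
    min_rows: int = MIN_ROWS_PER_PATIENT,
) -> LaggedDesign:
    """Form (y_t, y_{t-1}) rows from consecutive same-day beeps.

    Rows require complete ratings at both beeps; pairs never span a day
    boundary; only days in the inclusive range ``days`` contribute.
    Patients with fewer than ``min_rows`` usable rows are excluded with a
    warning (mirroring the exclusion of insufficiently sampled
    participants upstream of network estimation).
    """
    lo, hi = days
    sub = panel[(panel["day"] >= lo) & (panel["day"] <= hi)].sort_values(
        ["patient_id", "day", "beep"], kind="mergesort"
    )
    cur = sub.reset_index(drop=True)
    nxt = cur.shift(-1)
    same_series = (cur["patient_id"] == nxt["patient_id"]) & (cur["day"] == nxt["day"])
    consecutive = nxt["beep"] == cur["beep"] + 1
    complete = cur[list(FEELINGS)].notna().all(axis=1) & nxt[list(FEELINGS)].notna().all(axis=1)
    keep = (same_series & consecutive & complete).to_numpy()

    rows = pd.DataFrame(
        {
            "patient_id": cur.loc[keep, "patient_id"].to_numpy(),
            "day": cur.loc[keep, "day"].to_numpy(),
        }
    )
    for name in FEELINGS:
        rows[f"y_{name}"] = nxt.loc[keep, name].astype(float).to_numpy()
        rows[f"lag_{name}"] = cur.loc[keep, name].astype(float).to_numpy()

    counts = rows.groupby("patient_id", sort=False).size()
    all_patients = list(pd.unique(panel["patient_id"].astype(str)))
    excluded = [p for p in all_patients if counts.get(p, 0) < min_rows]
    if excluded:
        logger.warning(
            "excluding %d patient(s) with fewer than %d usable lag pairs: %s",
            len(excluded), min_rows, ", ".join(map(str, excluded)),
        )
        rows = rows[~rows["patient_id"].isin(excluded)].reset_index(drop=True)
    if rows.empty:
        raise ValueError("no usable lag-1 pairs in the requested day range")
    return LaggedDesign(frame=rows, excluded=excluded)


def _design_arrays(design: LaggedDesign, center: bool):
    frame = design.frame
    lag = frame[[f"lag_{n}" for n in FEELINGS]].to_numpy(dtype=float)
    if center:  # person-mean centering of the predictors
        pm = frame.groupby("patient_id", sort=False)[[f"lag_{n}" for n in FEELINGS]].transform("mean")
        lag = lag - pm.to_numpy(dtype=float)
    exog = np.column_stack([np.ones(len(frame)), lag])
    groups = frame["patient_id"].to_numpy()
    return exog, groups


def fit_multilevel_var(
    design: LaggedDesign,
    center: bool = False,
    reml: bool = True,
) -> tuple[FixedEffects, dict[str, np.ndarray]]:
    """Fit the six per-outcome mixed models and predict subject deviations.

    Returns the population :class:`FixedEffects` and a dict mapping
    patient_id to a 6x6 matrix of predicted slope deviations (BLUPs);
    deviation[j, k] is the subject's departure from Phi[j, k].  Estimation
    is deterministic given the design.

    Raises on an ill-conditioned design (e.g. a constant predictor) or on
    an outcome whose optimizer fails to converge under every fallback.
    """
    if design.frame["patient_id"].nunique() < 2:
        raise ValueError("multilevel VAR needs at least 2 patients")
    exog, groups = _design_arrays(design, center)
    cond = np.linalg.cond(exog)
    if not np.isfinite(cond) or cond > 1e8:
        sds = exog[:, 1:].std(axis=0)
        flat = [FEELINGS[k] for k in range(N_FEELINGS) if sds[k] == 0]
        detail = f"constant predictor(s): {', '.join(flat)}" if flat else f"condition number {cond:.2e}"
        raise ValueError(f"ill-conditioned lagged design ({detail})")

    patients = list(pd.unique(groups))
    coef = np.zeros((N_FEELINGS, N_FEELINGS))
    intercepts = np.zeros(N_FEELINGS)
    deviations = {p: np.zeros((N_FEELINGS, N_FEELINGS)) for p in patients}

    # random intercept + 6 random slopes, diagonal covariance
    free = MixedLMParams.from_components(
        fe_params=np.ones(N_FEELINGS + 1), cov_re=np.eye(N_FEELINGS + 1)
    )
    for j, name in enumerate(FEELINGS):
        endog = design.frame[f"y_{name}"].to_numpy(dtype=float)
        ols_fe, *_ = np.linalg.lstsq(exog, endog, rcond=None)
        model = MixedLM(endog, exog, groups=groups, exog_re=exog)
        result = None
        errors: list[str] = []
        with warnings.catch_warnings():
            # boundary fits (slope variance ~ 0) warn but are legitimate
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            start = None
            try:
                first = model.fit(free=free, reml=reml, method="lbfgs", maxiter=300)
                if np.all(np.isfinite(first.fe_params)):
                    result, start = first, first.params_object
            except (np.linalg.LinAlgError, ValueError, OverflowError) as exc:
                errors.append(f"lbfgs: {exc}")
            # refine with derivative-free powell: on this 8-parameter REML
            # surface lbfgs can report convergence short of the optimum
            for powell_start in (start, None):
                try:
                    refined = model.fit(
                        free=free, reml=reml, method="powell", maxiter=300,
                        start_params=powell_start,
                    )
                except (np.linalg.LinAlgError, ValueError, OverflowError) as exc:
                    errors.append(f"powell: {exc}")
                    continue
                if np.all(np.isfinite(refined.fe_params)):
                    result = refined
                    if refined.converged:
                        break
        if result is None:
            detail = "; ".join(errors) or "no optimizer produced finite estimates"
            raise ValueError(
                f"mixed-model estimation did not converge for outcome {name!r} "
                f"(tried lbfgs + powell refinement, maxiter=300; {detail})"
            )
        # sanity check on the lag coefficients only: the fixed intercept can
        # legitimately drift against the random-intercept mean, the slopes
        # (the network backbone) must stay near their pooled-OLS anchor
        if not result.converged and float(np.max(np.abs(result.fe_params[1:] - ols_fe[1:]))) >= 0.3:
            raise ValueError(
                f"mixed-model estimation did not converge for outcome {name!r}: "
                "optimizer stopped far from the pooled-OLS reference "
                f"(fe={np.round(result.fe_params, 3)}, ols={np.round(ols_fe, 3)})"
            )
        if not result.converged:
            logger.warning(
                "outcome %s: optimizer stopped at a boundary; estimates agree "
                "with pooled OLS and are retained", name,
            )
        intercepts[j] = result.fe_params[0]
        coef[j] = result.fe_params[1:]
        for pid, re in result.random_effects.items():
            deviations[pid][j] = np.asarray(re, dtype=float)[1:]
    return FixedEffects(coef=coef, intercepts=intercepts), deviations


def subject_networks(
    fixed: FixedEffects, deviations: dict[str, np.ndarray]
) -> list[PatientNetwork]:
    """Combine fixed effects and BLUP deviations into per-patient networks."""
    nets = []
    for pid, dev in deviations.items():
        dev = np.asarray(dev, dtype=float)
        if dev.shape != (N_FEELINGS, N_FEELINGS):
            raise ValueError(f"deviation matrix for patient {pid} is not 6x6")
        a = fixed.coef + dev
        if not np.all(np.isfinite(a)):
            raise ValueError(f"non-finite network entries for patient {pid}")
        nets.append(PatientNetwork(patient_id=str(pid), matrix=a))
    return nets


def compute_node_features(
    panel: pd.DataFrame,
    days: tuple[int, int] = DEFAULT_DAYS,
    negative_only: bool = False,
) -> dict[str, np.ndarray]:
    """Per-patient node features: mean rating of each feeling over the day range.

    With ``negative_only`` the three positive-feeling entries are zeroed,
    preserving the literal "average value of negative feelings" reading;
    by default every node carries its own feeling's mean.
    """
    lo, hi = days
    sub = panel[(panel["day"] >= lo) & (panel["day"] <= hi)]
    feats: dict[str, np.ndarray] = {}
    for pid, grp in sub.groupby("patient_id", sort=False):
        x = np.zeros(N_FEELINGS)
        for j, name in enumerate(FEELINGS):
            vals = grp[name].dropna()
            if vals.empty:
                raise ValueError(
                    f"patient {pid}: no observations of {name!r} in days {lo}-{hi}"
                )
            x[j] = float(vals.astype(float).mean())
        if negative_only:
            mask = np.zeros(N_FEELINGS, dtype=bool)
            mask[NEGATIVE_IDX] = True
            x[~mask] = 0.0
        feats[str(pid)] = x
    return feats
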