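"""Shared fixtures: synthetic panels and one fitted planted-signal cohort."""

import numpy as np
import pandas as pd
import pytest

from affectgcn import CASES, CohortSpec, generate_cohort, samples_from_panel
from affectgcn.items import FEELINGS


def make_panel(rows: list[tuple]) -> pd.DataFrame:
    """Build a panel from (patient_id, day, beep, r0..r5) tuples; None = missing."""
    frame = pd.DataFrame(rows, columns=["patient_id", "day", "beep", *FEELINGS])
    for name in FEELINGS:
        frame[name] = frame[name].astype("Int64")
    return frame


def constant_panel(pid: str, value: int = 4, n_days: int = 6, beeps: int = 10) -> list[tuple]:
    return [
        (pid, d, b, *([value] * 6))
        for d in range(1, n_days + 1)
        for b in range(1, beeps + 1)
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """20-patient cohort with subject heterogeneity, no planted proneness."""
    spec = CohortSpec(
        n_patients=20,
        random_slope_sd=0.05,
        prone_fraction=0.0,
        day6_negative_shift=0.0,
        seed=3,
    )
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def planted_cohort():
    """Planted-signal cohort: prone patients carry tonic negative-affect
    elevation and stronger negative-feeling autocorrelation; a day-6 shift
    drives the labels.  Fitted once per session (the multilevel VAR is the
    expensive step)."""
    spec = CohortSpec(
        n_patients=126,
        seed=2,
        prone_fraction=0.5,
        prone_autocorr_shift=0.2,
        prone_baseline_shift=1.0,
        day6_negative_shift=1.5,
        noise_sd=1.0,
        random_slope_sd=0.02,
    )
    panel = generate_cohort(spec)
    samples, labels = samples_from_panel(panel, CASES[2])
    return spec, panel, samples, labels


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
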