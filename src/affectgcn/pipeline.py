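"""End-to-end helpers: ESM panel -> labeled graph samples -> evaluation."""

from __future__ import annotations

import pandas as pd

from .labeling import CaseSpec, assign_labels, compute_idf_all
from .networks import (
    build_lagged_design,
    compute_node_features,
    fit_multilevel_var,
    subject_networks,
)
from .samples import GraphSample, build_samples

__all__ = ["networks_from_panel", "samples_from_panel"]


def networks_from_panel(
    panel: pd.DataFrame,
    days: tuple[int, int] = (1, 5),
    min_rows: int = 8,
    center: bool = False,
):
    """Fit the multilevel VAR on days 1-5 and return per-patient networks.

    Returns ``(networks, fixed_effects, excluded_patient_ids)``.
    """
    design = build_lagged_design(panel, days=days, min_rows=min_rows)
    fixed, deviations = fit_multilevel_var(design, center=center)
    return subject_networks(fixed, deviations), fixed, design.excluded


def samples_from_panel(
    panel: pd.DataFrame,
    case: CaseSpec,
    days: tuple[int, int] = (1, 5),
    min_rows: int = 8,
    center: bool = False,
    negative_only_features: bool = False,
) -> tuple[list[GraphSample], pd.DataFrame]:
    """Full data-preparation path: networks + node features + IDF labels.

    Returns the original (replicate-0) graph samples for the case and the
    labels frame (patient_id, idf, case_id, threshold, label).  Patients
    excluded from network estimation carry no sample but keep their IDF
    row.
    """
    networks, _, excluded = networks_from_panel(
        panel, days=days, min_rows=min_rows, center=center
    )
    features = compute_node_features(panel, days=days, negative_only=negative_only_features)
    idfs = compute_idf_all(panel)
    labels_frame, _ = assign_labels(idfs, case)
    labels = dict(zip(labels_frame["patient_id"], labels_frame["label"]))
    samples = build_samples(networks, features, labels)
    return samples, labels_frame
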