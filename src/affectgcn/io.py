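"""Readers and writers for every on-disk format used by the pipeline.

Formats (all plain text, UTF-8, comma-separated unless noted):

* ESM panel — long CSV: ``patient_id, day, beep`` + six feeling columns in
  canonical order; missing ratings are empty fields.
* Patient networks — JSON: list of ``{patient_id, nodes, matrix, features}``
  where ``matrix[j][k]`` is the lagged effect of feeling ``k`` (source, at
  t-1) on feeling ``j`` (target, at t).
* Labels — CSV: ``patient_id, idf, case_id, threshold, label``.
* Graph samples — JSON lines, one sample per line.
* Results — TSV per repetition plus a TSV summary.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .items import FEELINGS, LIKERT_MIN, LIKERT_MAX
from .samples import GraphSample

__all__ = [
    "write_panel",
    "read_panel",
    "validate_panel",
    "write_networks",
    "read_networks",
    "write_labels",
    "read_labels",
    "write_graph_samples",
    "read_graph_samples",
    "write_results",
    "write_provenance",
    "PanelFormatError",
]

PANEL_COLUMNS = ["patient_id", "day", "beep", *FEELINGS]

# Orientation reminder embedded in every network artifact.
EDGE_CONVENTION = "matrix[j][k] = effect of feeling k at lag 1 (column, source) on feeling j (row, target)"


class PanelFormatError(ValueError):
    """Raised when an ESM panel file violates the format contract."""


def validate_panel(panel: pd.DataFrame, source: str = "panel") -> pd.DataFrame:
    """Validate panel structure; returns the panel with canonical dtypes.

    Checks column set, day/beep ranges, Likert bounds and
    (patient_id, day, beep) uniqueness; error messages name the offending
    row (0-based data row index).
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise PanelFormatError(f"{source}: missing columns {missing}")
    panel = panel[PANEL_COLUMNS].copy()
    panel["patient_id"] = panel["patient_id"].astype(str)
    for col in ("day", "beep"):
        try:
            panel[col] = panel[col].astype(int)
        except (ValueError, TypeError) as exc:
            raise PanelFormatError(f"{source}: non-integer values in column {col!r}") from exc
    for name in FEELINGS:
        try:
            panel[name] = panel[name].astype("Int64")
        except (ValueError, TypeError) as exc:
            raise PanelFormatError(f"{source}: non-integer rating in column {name!r}") from exc
        vals = panel[name]
        bad = vals.notna() & ((vals < LIKERT_MIN) | (vals > LIKERT_MAX))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise PanelFormatError(
                f"{source}: rating {vals.iloc[row]} outside [{LIKERT_MIN}, {LIKERT_MAX}] "
                f"in column {name!r} at row {row}"
            )
    bad_day = (panel["day"] < 1)
    if bad_day.any():
        row = int(np.flatnonzero(bad_day.to_numpy())[0])
        raise PanelFormatError(f"{source}: day {panel['day'].iloc[row]} < 1 at row {row}")
    bad_beep = (panel["beep"] < 1)
    if bad_beep.any():
        row = int(np.flatnonzero(bad_beep.to_numpy())[0])
        raise PanelFormatError(f"{source}: beep {panel['beep'].iloc[row]} < 1 at row {row}")
    dup = panel.duplicated(subset=["patient_id", "day", "beep"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        key = panel.loc[panel.index[row], ["patient_id", "day", "beep"]].tolist()
        raise PanelFormatError(f"{source}: duplicate (patient_id, day, beep) = {tuple(key)} at row {row}")
    return panel


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    """Write an ESM panel as long CSV (missing ratings = empty fields)."""
    panel = validate_panel(panel, source="panel")
    panel.to_csv(path, index=False, lineterminator="\n")


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read and validate an ESM panel CSV written by :func:`write_panel`."""
    try:
        raw = pd.read_csv(path, dtype={"patient_id": str})
    except Exception as exc:  # malformed CSV
        raise PanelFormatError(f"{path}: unreadable panel CSV ({exc})") from exc
    return validate_panel(raw, source=str(path))


# ---------------------------------------------------------------------------
# networks


def write_networks(networks, features, path: str | Path) -> None:
    """Write patient networks (+ optional node features) as JSON.

    ``networks`` is a sequence of objects with ``patient_id`` and ``matrix``
    attributes; ``features`` maps patient_id -> length-6 vector (may be
    ``None``).
    """
    payload = {
        "edge_convention": EDGE_CONVENTION,
        "nodes": list(FEELINGS),
        "networks": [
            {
                "patient_id": net.patient_id,
                "matrix": np.asarray(net.matrix, dtype=float).tolist(),
                "features": (
                    None
                    if features is None or net.patient_id not in features
                    else np.asarray(features[net.patient_id], dtype=float).tolist()
                ),
            }
            for net in networks
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_networks(path: str | Path):
    """Read a networks JSON file; returns (list of PatientNetwork, features dict)."""
    from .networks import PatientNetwork  # local import to avoid a cycle

    payload = json.loads(Path(path).read_text())
    if payload.get("nodes") != list(FEELINGS):
        raise ValueError(f"{path}: node order does not match the canonical feeling order")
    nets, feats = [], {}
    for entry in payload["networks"]:
        m = np.asarray(entry["matrix"], dtype=float)
        if m.shape != (6, 6):
            raise ValueError(f"{path}: matrix for {entry['patient_id']} is not 6x6")
        nets.append(PatientNetwork(patient_id=str(entry["patient_id"]), matrix=m))
        if entry.get("features") is not None:
            feats[str(entry["patient_id"])] = np.asarray(entry["features"], dtype=float)
    return nets, feats


# ---------------------------------------------------------------------------
# labels


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path, index=False, lineterminator="\n")


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "idf", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: labels CSV must contain columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# graph samples (JSON lines)


def write_graph_samples(samples, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f'{{"edge_convention": {json.dumps(EDGE_CONVENTION)}}}\n')
        for s in samples:
            fh.write(json.dumps(s.to_dict()) + "\n")


def read_graph_samples(path: str | Path) -> list[GraphSample]:
    samples = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            if "patient_id" not in obj:  # header line
                continue
            samples.append(GraphSample.from_dict(obj))
    return samples


# ---------------------------------------------------------------------------
# results + provenance


def write_results(per_repeat: pd.DataFrame, summary: pd.DataFrame, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_repeat.to_csv(out / "repetitions.tsv", sep="\t", index=False, lineterminator="\n")
    summary.to_csv(out / "summary.tsv", sep="\t", index=False, lineterminator="\n")


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def write_provenance(out_dir: str | Path, config: dict, seed: int | None = None) -> None:
    """Record what produced the artifacts in a directory (config hash + seed + version)."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = {
        "affectgcn_version": __version__,
        "config_sha256": config_hash(config),
        "seed": seed,
        "config": config,
    }
    (out / "provenance.json").write_text(json.dumps(record, indent=1, default=str) + "\n")
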