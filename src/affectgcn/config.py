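"""YAML run configuration: one file drives the whole pipeline.

Sections (all optional unless noted): ``cohort`` (CohortSpec fields, for
synthetic data), ``esm_csv`` / ``networks_json`` (real-data inputs;
exactly one data source must be given), ``case`` (case id 1-3 or an
explicit ``threshold``), ``augment``, ``gcn`` and ``protocol``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .augment import AugmentConfig
from .evaluate import EvalProtocol
from .labeling import CASES, CaseSpec
from .simulate import CohortSpec

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised on an invalid or contradictory run configuration."""


@dataclass
class RunConfig:
    cohort: CohortSpec | None
    esm_csv: str | None
    networks_json: str | None
    case: CaseSpec
    protocol: EvalProtocol
    negative_only_features: bool
    center_predictors: bool
    min_rows: int
    raw: dict

    def data_source(self) -> str:
        for name in ("cohort", "esm_csv", "networks_json"):
            if getattr(self, name) is not None:
                return name
        raise ConfigError("no data source configured")


def _case_from(cfg: dict) -> CaseSpec:
    section = cfg.get("case", {})
    if isinstance(section, int):
        section = {"id": section}
    if "threshold" in section:
        return CaseSpec(int(section.get("id", 0)), float(section["threshold"]))
    case_id = int(section.get("id", 2))
    if case_id not in CASES:
        raise ConfigError(f"unknown case id {case_id}; choose 1, 2 or 3 or give a threshold")
    return CASES[case_id]


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sources = [k for k in ("cohort", "esm_csv", "networks_json") if raw.get(k) is not None]
    if len(sources) != 1:
        raise ConfigError(
            "exactly one data source is required (cohort | esm_csv | networks_json); "
            f"got {sources or 'none'}"
        )
    cohort = None
    if raw.get("cohort") is not None:
        section = dict(raw["cohort"])
        for key in ("fixed_matrix", "fixed_intercepts"):
            if key in section:
                section[key] = np.asarray(section[key], dtype=float)
        try:
            cohort = CohortSpec(**section)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid cohort section: {exc}") from exc
    try:
        augment = AugmentConfig(**raw.get("augment", {}))
        protocol = EvalProtocol(augment=augment, **raw.get("protocol", {}), gcn=raw.get("gcn", {}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid augment/protocol/gcn section: {exc}") from exc
    prep = raw.get("preparation", {})
    return RunConfig(
        cohort=cohort,
        esm_csv=raw.get("esm_csv"),
        networks_json=raw.get("networks_json"),
        case=_case_from(raw),
        protocol=protocol,
        negative_only_features=bool(prep.get("negative_only_features", False)),
        center_predictors=bool(prep.get("center_predictors", False)),
        min_rows=int(prep.get("min_rows", 8)),
        raw=raw,
    )
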