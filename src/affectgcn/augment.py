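"""Bounded-uniform edge augmentation.

Small clinical cohorts (here 126 networks) are far too small for a neural
classifier, so the graph set is expanded by jittering edge weights: each
edge independently receives additive noise drawn uniformly from
[-bound * |edge|, +bound * |edge|] (default bound 1%).  Zero edges stay
exactly zero, node features and labels are copied verbatim, and with the
default factor of 50 the 126 originals become 6,300 samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .samples import GraphSample

__all__ = ["AugmentConfig", "perturb_matrix", "augment_samples"]


@dataclass
class AugmentConfig:
    factor: int = 50
    bound: float = 0.01
    seed: int = 0
    include_originals: bool = True

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ValueError("factor must be >= 1")
        if not 0.0 < self.bound <= 1.0:
            raise ValueError("bound must lie in (0, 1]")


def perturb_matrix(matrix: np.ndarray, bound: float, rng: np.random.Generator) -> np.ndarray:
    """Jitter each entry by an independent Uniform(-bound*|a|, +bound*|a|) draw.

    Negative edges perturb symmetrically (the bound scales with the
    absolute value), zero entries remain exactly zero, and for bound < 1
    no entry can change sign.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("network contains non-finite entries")
    scale = bound * np.abs(matrix)
    noise = rng.uniform(-1.0, 1.0, size=matrix.shape) * scale
    return matrix + noise


def augment_samples(samples: list[GraphSample], cfg: AugmentConfig) -> list[GraphSample]:
    """Expand originals to ``factor x len(samples)`` graph samples.

    Each original contributes itself (when ``include_originals``) plus
    perturbed replicates, all sharing its label and node features; output
    order is deterministic given the seed (originals grouped with their
    replicates, input order preserved).
    """
    if not samples:
        raise ValueError("no samples to augment")
    if any(s.replicate != 0 for s in samples):
        raise ValueError("augment_samples expects original (replicate-0) samples")
    rng = np.random.default_rng(cfg.seed)
    n_perturbed = cfg.factor - 1 if cfg.include_originals else cfg.factor
    out: list[GraphSample] = []
    for s in samples:
        if cfg.include_originals:
            out.append(s)
        for r in range(n_perturbed):
            out.append(
                GraphSample(
                    patient_id=s.patient_id,
                    replicate=r + 1,
                    matrix=perturb_matrix(s.matrix, cfg.bound, rng),
                    features=s.features.copy(),
                    label=s.label,
                )
            )
    return out
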