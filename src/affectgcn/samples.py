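"""Graph samples: the unit of data fed to the classifier.

A :class:`GraphSample` bundles a patient's 6x6 affect network, the six
node features (day-1..5 feeling means), a binary risk label and
provenance (source patient, replicate index; replicate 0 is the original,
higher indices are augmented copies).

For interoperability with scikit-learn, samples pack into a flat
``(n_samples, 42)`` array: 36 adjacency entries (row-major) followed by
the 6 node features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GraphSample", "pack_samples", "unpack_matrix", "unpack_features", "build_samples"]

N_NODES = 6
FLAT_DIM = N_NODES * N_NODES + N_NODES  # 42


@dataclass
class GraphSample:
    patient_id: str
    replicate: int
    matrix: np.ndarray  # 6x6, [j, k] = effect of k at t-1 on j
    features: np.ndarray  # length 6
    label: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.features = np.asarray(self.features, dtype=float)
        if self.matrix.shape != (N_NODES, N_NODES):
            raise ValueError("matrix must be 6x6")
        if self.features.shape != (N_NODES,):
            raise ValueError("features must have 6 entries")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "replicate": int(self.replicate),
            "matrix": self.matrix.tolist(),
            "features": self.features.tolist(),
            "label": int(self.label),
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "GraphSample":
        return cls(
            patient_id=str(obj["patient_id"]),
            replicate=int(obj["replicate"]),
            matrix=np.asarray(obj["matrix"], dtype=float),
            features=np.asarray(obj["features"], dtype=float),
            label=int(obj["label"]),
        )

    def flat(self) -> np.ndarray:
        return np.concatenate([self.matrix.ravel(), self.features])


def pack_samples(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pack samples into (X, y, groups): X is (n, 42), groups are patient ids."""
    X = np.stack([s.flat() for s in samples])
    y = np.array([s.label for s in samples], dtype=int)
    groups = np.array([s.patient_id for s in samples])
    return X, y, groups


def unpack_matrix(row: np.ndarray) -> np.ndarray:
    return np.asarray(row[: N_NODES * N_NODES], dtype=float).reshape(N_NODES, N_NODES)


def unpack_features(row: np.ndarray) -> np.ndarray:
    return np.asarray(row[N_NODES * N_NODES:], dtype=float)


def build_samples(networks, features: dict, labels: dict) -> list[GraphSample]:
    """Assemble original (replicate-0) samples from networks, features, labels.

    ``networks`` is a list of PatientNetwork; ``features`` and ``labels``
    map patient_id to the node-feature vector and the binary label.
    Patients missing a feature vector or a label raise KeyError.
    """
    out = []
    for net in networks:
        pid = net.patient_id
        if pid not in features:
            raise KeyError(f"no node features for patient {pid}")
        if pid not in labels:
            raise KeyError(f"no label for patient {pid}")
        out.append(
            GraphSample(
                patient_id=pid,
                replicate=0,
                matrix=np.asarray(net.matrix, dtype=float),
                features=np.asarray(features[pid], dtype=float),
                label=int(labels[pid]),
            )
        )
    return out
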