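"""Shared lattice substrate for all simulation stages.

Every stage of the pipeline (rasterization, capillary seeding, Potts growth,
oxygen transport, viability analysis) operates on the same object: a 3-D
integer label lattice with 1 µm cubic voxels, where label 0 is interstitial
medium, labels 1..N are endocrine cells and labels > N are capillaries.
A voxel ``(i, j, k)`` spans ``[i, i+1) x [j, j+1) x [k, k+1)`` µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Entity *type* codes (distinct from entity IDs / labels).
MEDIUM = 0
ALPHA = 1
BETA = 2
DELTA = 3
CAPILLARY = 4

TYPE_NAMES = {MEDIUM: "medium", ALPHA: "alpha", BETA: "beta", DELTA: "delta",
              CAPILLARY: "capillary"}
NAME_TO_TYPE = {v: k for k, v in TYPE_NAMES.items()}

#: lattice spacing, µm
VOXEL_SIZE = 1.0


@dataclass
class LabeledGrid:
    """Integer label lattice plus the label -> type lookup table.

    Parameters
    ----------
    labels : ndarray of int32, shape (nx, ny, nz)
        Entity ID per voxel; 0 is medium.
    type_of : ndarray of int8, shape (max_label + 1,)
        Type code (MEDIUM/ALPHA/BETA/DELTA/CAPILLARY) for each entity ID.
    """

    labels: np.ndarray
    type_of: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int32)
        if self.type_of is None:
            self.type_of = np.zeros(int(self.labels.max()) + 1, dtype=np.int8)
        else:
            self.type_of = np.asarray(self.type_of, dtype=np.int8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if int(self.labels.max()) >= self.type_of.size:
            raise ValueError("type_of table shorter than max label + 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def voxel_types(self) -> np.ndarray:
        """Per-voxel type codes (same shape as ``labels``)."""
        return self.type_of[self.labels]

    def medium_mask(self) -> np.ndarray:
        return self.labels == 0

    def ids_of_type(self, type_code: int) -> np.ndarray:
        """Entity IDs of a given type that are present on the lattice."""
        ids = np.flatnonzero(self.type_of == type_code)
        present = np.isin(ids, np.unique(self.labels))
        return ids[present]

    def cell_ids(self) -> np.ndarray:
        return np.flatnonzero(np.isin(self.type_of, (ALPHA, BETA, DELTA)))

    def capillary_ids(self) -> np.ndarray:
        return np.flatnonzero(self.type_of == CAPILLARY)

    def copy(self) -> "LabeledGrid":
        return LabeledGrid(self.labels.copy(), self.type_of.copy())

    def with_entities(self, new_ids: np.ndarray, new_types: np.ndarray) -> "LabeledGrid":
        """Return a grid whose type table is extended to cover ``new_ids``."""
        top = max(int(self.type_of.size) - 1, int(np.max(new_ids)) if len(new_ids) else 0)
        table = np.zeros(top + 1, dtype=np.int8)
        table[: self.type_of.size] = self.type_of
        table[np.asarray(new_ids, dtype=np.int64)] = np.asarray(new_types, dtype=np.int8)
        return LabeledGrid(self.labels.copy(), table)
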