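"""Cell viability classification and vascular morphometry.

Each endocrine cell is classified from the mean oxygen partial pressure over
its own voxels: functional above 10 mmHg, hypoxic between 0.45 and 10 mmHg,
non-viable below 0.45 mmHg (boundary values go to the lower class); viable
means functional or hypoxic.  Morphometric measures mirror the histology
protocol: capillary diameters as wall-to-wall profile chords through
cross-section centroids on the middle z slice, and vascular density as the
capillary area percentage of the islet area on that slice.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import closing, convex_hull_image, disk

from .core import ALPHA, BETA, CAPILLARY, DELTA, TYPE_NAMES, LabeledGrid
from .oxygen import OxygenField, mean_medium_concentration

log = logging.getLogger(__name__)

FUNCTIONAL_PO2 = 10.0   # mmHg
HYPOXIC_PO2 = 0.45      # mmHg

STATES = ("functional", "hypoxic", "nonviable")


def classify_cell(mean_po2: float) -> str:
    """State of a cell from its mean PO2 (mmHg); boundaries to lower class."""
    if mean_po2 < 0:
        raise ValueError("mean PO2 must be non-negative")
    if mean_po2 > FUNCTIONAL_PO2:
        return "functional"
    if mean_po2 > HYPOXIC_PO2:
        return "hypoxic"
    return "nonviable"


def cell_oxygen_table(grid: LabeledGrid, field: OxygenField) -> pd.DataFrame:
    """One row per endocrine cell: mean PO2 over its voxels and its state."""
    cell_ids = grid.cell_ids()
    po2 = field.po2()
    means = ndimage.mean(po2, labels=grid.labels, index=cell_ids)
    return pd.DataFrame({
        "cell_id": cell_ids,
        "cell_type": [TYPE_NAMES[int(t)] for t in grid.type_of[cell_ids]],
        "mean_po2": means,
        "state": [classify_cell(m) for m in means],
    })


@dataclass
class ViabilityReport:
    """Per-cell states plus per-stratum proportions and medium oxygen."""

    per_cell: pd.DataFrame
    proportions: dict            # stratum -> {functional, hypoxic, nonviable, viable}
    mean_medium_oxygen_um: float
    metadata: dict

    def viable_fraction(self, stratum: str = "islet") -> float:
        return self.proportions[stratum]["viable"]

    def save(self, table_path, summary_path) -> None:
        self.per_cell.to_csv(table_path, index=False)
        payload = {"proportions": self.proportions,
                   "mean_medium_oxygen_um": self.mean_medium_oxygen_um,
                   "metadata": self.metadata}
        with open(summary_path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _proportions(states: pd.Series) -> dict[str, float]:
    n = len(states)
    out = {s: float((states == s).sum()) / n for s in STATES}
    out["viable"] = out["functional"] + out["hypoxic"]
    return out


def summarize(grid: LabeledGrid, field: OxygenField,
              metadata: dict | None = None) -> ViabilityReport:
    """Aggregate cell states into whole-islet and per-type proportions.

    Strata with no cells are omitted (undefined, not zero).  Also reports the
    mean oxygen concentration over medium voxels (µM).
    """
    table = cell_oxygen_table(grid, field)
    if len(table) == 0:
        raise ValueError("grid contains no endocrine cells")
    props = {"islet": _proportions(table["state"])}
    for name in ("alpha", "beta", "delta"):
        sub = table.loc[table["cell_type"] == name, "state"]
        if len(sub):
            props[name] = _proportions(sub)
    return ViabilityReport(table, props, mean_medium_concentration(grid, field),
                           dict(metadata or {}))


# ---------------------------------------------------------------------------
# Morphometry on the middle z slice

def extract_mid_slice(grid: LabeledGrid) -> np.ndarray:
    """Label image of the z = floor(Nz/2) plane."""
    return grid.labels[:, :, grid.shape[2] // 2]


def islet_mask(slice_labels: np.ndarray, type_of: np.ndarray,
               mask_rule: str = "hull", closing_radius: float = 5.0) -> np.ndarray:
    """Deterministic surrogate for the manually drawn whole-islet area.

    ``hull`` (default): convex hull of the endocrine-cell pixels, emulating
    the islet area delineated by the insulin stain.  ``closing``:
    morphological closing (disc of ``closing_radius`` µm) of the union of
    cell and capillary pixels; at mid-plane the sphere cross-sections of a
    packed islet are sparse, so this rule yields a fragmented under-mask and
    is kept only for sensitivity analysis.
    """
    types = type_of[slice_labels]
    if mask_rule == "hull":
        cells = np.isin(types, (ALPHA, BETA, DELTA))
        if not cells.any():
            raise ValueError("slice contains no islet pixels")
        return convex_hull_image(cells)
    if mask_rule == "closing":
        tissue = types != 0
        if not tissue.any():
            raise ValueError("slice contains no islet pixels")
        return closing(tissue, disk(int(round(closing_radius)))).astype(bool)
    raise ValueError(f"unknown mask rule {mask_rule!r}")


def vascular_density(slice_labels: np.ndarray, type_of: np.ndarray,
                     mask_rule: str = "hull", closing_radius: float = 5.0) -> float:
    """Capillary area as a percentage of the islet area in a slice."""
    mask = islet_mask(slice_labels, type_of, mask_rule, closing_radius)
    if not mask.any():
        raise ValueError("empty islet mask")
    types = type_of[slice_labels]
    cap = (types == CAPILLARY) & mask
    return 100.0 * float(cap.sum()) / float(mask.sum())


def vascular_density_stack(grid: LabeledGrid, n_slices: int = 10,
                           mask_rule: str = "hull") -> float:
    """Mean vascular density over ``n_slices`` sequential mid-islet z planes.

    The histology protocol quantifies density on a stack of ten sequential
    z sections (1 µm apart) through the middle of the islet; averaging over
    the stack also suppresses the large slice-to-slice fluctuations a single
    plane shows in small simulated islets.
    """
    mid = grid.shape[2] // 2
    lo = max(0, mid - n_slices // 2)
    hi = min(grid.shape[2], lo + n_slices)
    vals = [vascular_density(grid.labels[:, :, z], grid.type_of, mask_rule)
            for z in range(lo, hi)]
    return float(np.mean(vals))


def _chord_length(mask: np.ndarray, centroid, angle: float,
                  step: float = 0.25) -> float:
    """Wall-to-wall profile-line chord through ``centroid`` at ``angle``."""
    ux, uy = math.cos(angle), math.sin(angle)
    nx, ny = mask.shape
    ends = []
    for sign in (1.0, -1.0):
        t = 0.0
        while True:
            t += step
            px = int(math.floor(centroid[0] + sign * t * ux))
            py = int(math.floor(centroid[1] + sign * t * uy))
            if px < 0 or px >= nx or py < 0 or py >= ny or not mask[px, py]:
                break
        ends.append(t)
    return ends[0] + ends[1]


def capillary_cross_sections(slice_labels: np.ndarray, type_of: np.ndarray,
                             min_area: int = 5):
    """Connected components of each capillary label in the slice.

    Components touching the slice border are skipped (and logged), as are
    components below ``min_area`` pixels: the profile protocol measures the
    distance between the two vessel-wall peaks, which sub-resolution
    fragments of one or two pixels do not produce.
    """
    comps = []
    skipped = 0
    for cap_id in np.unique(slice_labels):
        if cap_id == 0 or type_of[cap_id] != CAPILLARY:
            continue
        lab = cc_label(slice_labels == cap_id, connectivity=1)
        for c in range(1, lab.max() + 1):
            mask = lab == c
            xs, ys = np.nonzero(mask)
            if len(xs) < min_area:
                continue
            if (xs.min() == 0 or ys.min() == 0
                    or xs.max() == mask.shape[0] - 1 or ys.max() == mask.shape[1] - 1):
                skipped += 1
                continue
            comps.append((mask, (xs.mean() + 0.5, ys.mean() + 0.5)))
    if skipped:
        log.debug("skipped %d border-touching capillary cross-sections", skipped)
    return comps


def measure_capillary_diameters(slice_labels: np.ndarray, type_of: np.ndarray,
                                n_samples: int, rng: np.random.Generator,
                                min_area: int = 5) -> list[float]:
    """Profile-line diameter estimates (µm) of capillary cross-sections.

    Each sample picks a random cross-section and casts a profile line at a
    random orientation through its centroid; the chord between the two wall
    crossings is the diameter estimate.  Empty capillary set -> empty list.
    """
    comps = capillary_cross_sections(slice_labels, type_of, min_area)
    if not comps:
        return []
    out = []
    for _ in range(n_samples):
        mask, centroid = comps[int(rng.integers(len(comps)))]
        angle = float(rng.uniform(0.0, math.pi))
        out.append(_chord_length(mask, centroid, angle))
    return out
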