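"""Islet architectures: loading, synthesis, overlap-minimizing packing, rasterization.

An islet architecture is a set of spherical endocrine cells (alpha, beta,
delta) with centers and radii in µm, placed in a rectangular simulation
environment obtained from the cell bounding box plus a 30 µm buffer on every
side.  Architectures can be loaded from delimited cell tables (columns
``x, y, z, type[, radius]``), synthesized from size/composition statistics,
relaxed to an overlap-free packing by simulated-annealing-style optimization,
and rasterized onto the 1 µm voxel lattice shared by all downstream stages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import truncnorm

from .core import ALPHA, BETA, DELTA, NAME_TO_TYPE, TYPE_NAMES, LabeledGrid

#: buffer added around the cell bounding box on every side, µm
DEFAULT_BUFFER = 30.0

#: default endocrine compositions (fractions of alpha/beta/delta cells)
HUMAN_COMPOSITION = {"alpha": 0.29, "beta": 0.53, "delta": 0.18}
MOUSE_COMPOSITION = {"alpha": 0.25, "beta": 0.75, "delta": 0.0}

_CELL_TYPES = ("alpha", "beta", "delta")


@dataclass(frozen=True)
class CellRecord:
    """A single endocrine cell as a typed sphere in µm space."""

    cell_id: int
    cell_type: str
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.cell_type not in _CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        if not self.radius > 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class RadiiDistribution:
    """Distribution of cell radii (µm): truncated normal or empirical table.

    Defaults are a stand-in distribution (mean 5.5, sd 0.8, support
    [3.5, 8] µm) sized so that typical human cell counts fit their
    environments; replace with an empirical table when one is available.
    """

    family: str = "truncated_normal"
    mean: float = 5.5
    sd: float = 0.8
    lower: float = 3.5
    upper: float = 8.0
    samples: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("truncated_normal", "empirical"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "truncated_normal":
            if not (0 < self.lower <= self.upper):
                raise ValueError("need 0 < lower <= upper")
        elif not self.samples or min(self.samples) <= 0:
            raise ValueError("empirical family needs positive samples")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "empirical":
            return rng.choice(np.asarray(self.samples, dtype=float), size=n)
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        r = truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)
        return np.clip(r, self.lower, self.upper)


class IsletArchitecture:
    """Ordered collection of cell spheres plus its simulation environment.

    Internally array-backed: ``centers`` (n, 3), ``radii`` (n,), ``types``
    (n,) int8 type codes, with cell IDs 1..n in order.
    """

    def __init__(self, centers, radii, types, *, species: str = "human",
                 buffer: float = DEFAULT_BUFFER, env_dims=None, meta=None):
        self.centers = np.asarray(centers, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(radii, dtype=float).ravel()
        self.types = np.asarray(types, dtype=np.int8).ravel()
        self.species = species
        self.buffer = float(buffer)
        self.meta = dict(meta or {})
        n = len(self.radii)
        if self.centers.shape != (n, 3) and n > 0:
            raise ValueError("centers must have shape (n, 3)")
        if n and not np.all(self.radii > 0):
            raise ValueError("all radii must be positive")
        if species not in ("human", "mouse"):
            raise ValueError(f"unknown species {species!r}")
        if species == "mouse" and np.any(self.types == DELTA):
            raise ValueError("mouse architectures carry no delta cells")
        if env_dims is None:
            self._shift_to_origin()
            env_dims = self._env_from_extent()
        self.env_dims = tuple(int(d) for d in env_dims)
        if n and not self._inside_env():
            raise ValueError("cell spheres must lie inside env_dims")

    # -- construction helpers -------------------------------------------------

    def _shift_to_origin(self) -> None:
        if len(self.radii) == 0:
            return
        lo = (self.centers - self.radii[:, None]).min(axis=0)
        self.centers = self.centers - lo + self.buffer

    def _env_from_extent(self) -> tuple[int, int, int]:
        if len(self.radii) == 0:
            side = int(math.ceil(2 * self.buffer))
            return (side, side, side)
        hi = (self.centers + self.radii[:, None]).max(axis=0)
        return tuple(int(math.ceil(h + self.buffer)) for h in hi)

    def _inside_env(self) -> bool:
        lo = (self.centers - self.radii[:, None]).min(axis=0)
        hi = (self.centers + self.radii[:, None]).max(axis=0)
        return bool(np.all(lo >= -1e-9) and np.all(hi <= np.array(self.env_dims) + 1e-9))

    # -- views ----------------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.radii)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(1, self.n_cells + 1)

    def counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.types == code))
                for code, name in ((ALPHA, "alpha"), (BETA, "beta"), (DELTA, "delta"))}

    def cells(self) -> list[CellRecord]:
        return [CellRecord(i + 1, TYPE_NAMES[int(t)], tuple(c), float(r))
                for i, (c, r, t) in enumerate(zip(self.centers, self.radii, self.types))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.cell_ids,
            "x": self.centers[:, 0], "y": self.centers[:, 1], "z": self.centers[:, 2],
            "type": [TYPE_NAMES[int(t)] for t in self.types],
            "radius": self.radii,
        })

    def summary(self) -> dict:
        return {
            "species": self.species,
            "n_cells": self.n_cells,
            **{f"n_{k}": v for k, v in self.counts().items()},
            "env_dims": list(self.env_dims),
            "buffer_um": self.buffer,
            "overlaps": count_overlaps(self),
        }

    def save_cells(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def save_summary(self, path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))

    def replace(self, centers=None, radii=None, **meta) -> "IsletArchitecture":
        return IsletArchitecture(
            self.centers if centers is None else centers,
            self.radii if radii is None else radii,
            self.types, species=self.species, buffer=self.buffer,
            meta={**self.meta, **meta})


# ---------------------------------------------------------------------------
# Loading

def load_cells(path, species: str = "human", *,
               radii: RadiiDistribution | None = None,
               buffer: float = DEFAULT_BUFFER, seed: int = 0) -> IsletArchitecture:
    """Read a delimited cell table (columns x, y, z, type[, radius]).

    Missing radii are drawn from ``radii`` (default stand-in distribution)
    using ``seed``.  Unknown type tokens and non-finite coordinates are
    rejected with the offending row named.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"x", "y", "z", "type"}
    if not required.issubset(df.columns):
        raise ValueError(f"cell table must have columns {sorted(required)}")
    if len(df) == 0:
        raise ValueError(f"empty cell table: {path}")
    tokens = df["type"].astype(str).str.strip().str.lower()
    bad = ~tokens.isin(_CELL_TYPES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unknown cell type {tokens.iloc[row]!r} in row {row} of {path}")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        row = int(np.flatnonzero(~np.isfinite(coords).all(axis=1))[0])
        raise ValueError(f"non-finite coordinates in row {row} of {path}")
    types = tokens.map(NAME_TO_TYPE).to_numpy(dtype=np.int8)
    if "radius" in df.columns and df["radius"].notna().all():
        r = df["radius"].to_numpy(dtype=float)
    else:
        dist = radii or RadiiDistribution()
        rng = np.random.default_rng(seed)
        r = dist.sample(len(df), rng)
        if "radius" in df.columns:
            given = df["radius"].notna().to_numpy()
            r[given] = df.loc[given, "radius"].to_numpy(dtype=float)
    return IsletArchitecture(coords, r, types, species=species, buffer=buffer)


# ---------------------------------------------------------------------------
# Overlap counting and packing optimization

def count_overlaps(arch: IsletArchitecture) -> int:
    """Number of unordered cell pairs with center distance strictly below
    the sum of radii (tangent spheres do not overlap)."""
    return _count_overlaps_arrays(arch.centers, arch.radii)


def _count_overlaps_arrays(centers: np.ndarray, radii: np.ndarray) -> int:
    n = len(radii)
    if n < 2:
        return 0
    tree = cKDTree(centers)
    pairs = tree.query_pairs(r=2.0 * float(radii.max()), output_type="ndarray")
    if len(pairs) == 0:
        return 0
    d = np.linalg.norm(centers[pairs[:, 0]] - centers[pairs[:, 1]], axis=1)
    return int(np.sum(d < radii[pairs[:, 0]] + radii[pairs[:, 1]] - 1e-12))


def _hits_of(i: int, centers: np.ndarray, radii: np.ndarray,
             center: np.ndarray, radius: float) -> np.ndarray:
    """Boolean overlap vector of sphere ``(center, radius)`` vs all cells but i."""
    d2 = np.sum((centers - center) ** 2, axis=1)
    s = radii + radius
    # epsilon slightly looser than count_overlaps' so that an incremental
    # zero always implies a zero KD-tree recount (tangency never flagged)
    hits = d2 < (s * s - 1e-12)
    hits[i] = False
    return hits


def optimize_packing(arch: IsletArchitecture, radii: RadiiDistribution | None = None,
                     max_iter: int = 100_000, seed: int = 0, *,
                     p0: float = 0.5, gamma: float | None = None,
                     ball: tuple | None = None) -> IsletArchitecture:
    """Reduce sphere overlaps by random single-cell moves with a decaying
    accept-worse probability.

    Each iteration picks one cell involved in an overlap (uniformly among
    all cells when none is), proposes a new center (uniform offset in
    [-r, r]^3) and a radius redrawn from ``radii``; a proposal that lowers
    the best-recorded overlap count is accepted, otherwise it is accepted
    with probability ``p0 * gamma**k``.  Terminates at zero overlaps or
    ``max_iter``.  The best-so-far trajectory and convergence status are
    recorded in ``meta['packing']``.

    ``ball=(center, radius)`` constrains proposals so every sphere stays
    inside the given ball (used by synthesis to keep the islet compact).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    dist = radii or RadiiDistribution()
    rng = np.random.default_rng(seed)
    # radius draws are consumed from batches (per-draw rvs overhead dominates
    # the iteration otherwise)
    radius_buf: list = []

    def draw_radius() -> float:
        if not radius_buf:
            radius_buf.extend(dist.sample(4096, rng)[::-1])
        return float(radius_buf.pop())
    centers = arch.centers.copy()
    rad = arch.radii.copy()
    n = arch.n_cells
    # per-cell overlap counts, maintained incrementally
    per_cell = np.zeros(n, dtype=np.int64)
    for i in range(n):
        per_cell[i] = int(_hits_of(i, centers, rad, centers[i], rad[i]).sum())
    total = int(per_cell.sum()) // 2
    best = total
    best_centers, best_rad = centers.copy(), rad.copy()
    if gamma is None:
        # accept-worse probability ~1e-3 halfway through the budget
        gamma = (1e-3 / p0) ** (2.0 / max_iter)
    trajectory = [best]
    it = 0
    if n > 0 and best > 0:
        for it in range(1, max_iter + 1):
            bad = np.flatnonzero(per_cell > 0)
            pool = bad if len(bad) else np.arange(n)
            i = int(pool[rng.integers(len(pool))])
            old_hits = _hits_of(i, centers, rad, centers[i], rad[i])
            new_center = centers[i] + rng.uniform(-rad[i], rad[i], size=3)
            new_radius = draw_radius()
            if ball is not None:
                bc, br = ball
                # centers confined to the ball; spheres may protrude by up
                # to one radius, like boundary cells on a real islet surface
                if np.linalg.norm(new_center - np.asarray(bc)) > br:
                    trajectory.append(best)
                    continue
            new_hits = _hits_of(i, centers, rad, new_center, new_radius)
            old_ov = int(old_hits.sum())
            new_ov = int(new_hits.sum())
            cand = total - old_ov + new_ov
            # non-worsening moves are always taken (plateau diffusion);
            # worsening moves with the decaying probability
            if cand <= total or rng.random() < p0 * gamma ** it:
                centers[i] = new_center
                rad[i] = new_radius
                per_cell += new_hits.astype(np.int64) - old_hits.astype(np.int64)
                per_cell[i] = new_ov
                total = cand
                if total < best:
                    best = total
                    best_centers[:] = centers
                    best_rad[:] = rad
            trajectory.append(best)
            if best == 0:
                break
    out = arch.replace(centers=best_centers, radii=best_rad)
    out.meta["packing"] = {
        "converged": best == 0,
        "final_overlaps": int(best),
        "iterations": int(it),
        "best_trajectory": np.asarray(trajectory, dtype=np.int64),
    }
    return out


# ---------------------------------------------------------------------------
# Synthesis

def synthesize_islet(n_cells: int, species: str = "human",
                     composition: dict[str, float] | None = None,
                     radii: RadiiDistribution | None = None,
                     target_diameter: float = 100.0, seed: int = 0, *,
                     buffer: float = DEFAULT_BUFFER,
                     max_iter_per_cell: int = 600) -> IsletArchitecture:
    """Generate an overlap-free synthetic islet.

    Cells are placed uniformly inside a ball of ``target_diameter``, typed by
    multinomial draws from ``composition`` (species defaults), then relaxed
    to zero overlaps.  Densities above 0.64 of the ball volume are rejected
    as infeasible before optimizing.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    comp = dict(composition if composition is not None
                else (HUMAN_COMPOSITION if species == "human" else MOUSE_COMPOSITION))
    fracs = np.array([comp.get(t, 0.0) for t in _CELL_TYPES], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("composition fractions must sum to 1")
    if species == "mouse" and fracs[2] > 0:
        raise ValueError("mouse composition cannot include delta cells")
    dist = radii or RadiiDistribution()
    rng = np.random.default_rng(seed)
    types = rng.choice(np.array([ALPHA, BETA, DELTA], dtype=np.int8),
                       size=n_cells, p=fracs)
    rad = dist.sample(n_cells, rng)
    ball_volume = math.pi / 6.0 * target_diameter ** 3
    sphere_volume = float(np.sum(4.0 / 3.0 * math.pi * rad ** 3))
    if sphere_volume > 0.64 * ball_volume:
        raise ValueError(
            f"infeasible density: total sphere volume {sphere_volume:.0f} µm³ "
            f"exceeds 0.64 x ball volume {0.64 * ball_volume:.0f} µm³")
    # uniform points in a ball: random direction x cube-root radial law
    u = rng.normal(size=(n_cells, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = 0.5 * target_diameter * rng.random(n_cells) ** (1.0 / 3.0)
    centers = u * r[:, None]
    arch = IsletArchitecture(centers, rad, types, species=species, buffer=buffer,
                             meta={"seed": seed, "target_diameter": target_diameter})
    for attempt in range(3):
        lo = (arch.centers - arch.radii[:, None]).min(axis=0)
        hi = (arch.centers + arch.radii[:, None]).max(axis=0)
        ball = (0.5 * (lo + hi), 0.5 * target_diameter)
        arch = optimize_packing(arch, dist, max_iter=max_iter_per_cell * n_cells,
                                seed=int(rng.integers(2**31)), ball=ball)
        if arch.meta["packing"]["converged"]:
            return arch
    raise RuntimeError(
        f"packing did not reach zero overlaps "
        f"({arch.meta['packing']['final_overlaps']} remain after 3 rounds)")


# ---------------------------------------------------------------------------
# Rasterization

def rasterize(arch: IsletArchitecture) -> LabeledGrid:
    """Map cell spheres onto the 1 µm lattice (voxel-center-in-sphere rule).

    Voxel ``(i, j, k)`` (center at i+0.5, ...) is assigned to cell ID ``c``
    when its center lies within cell c's sphere; all other voxels are medium
    (label 0).  Requires an overlap-free architecture.
    """
    if count_overlaps(arch) > 0:
        raise ValueError("architecture must be overlap-free before rasterization")
    labels = np.zeros(arch.env_dims, dtype=np.int32)
    for cid, (c, r) in enumerate(zip(arch.centers, arch.radii), start=1):
        lo = np.maximum(np.floor(c - r).astype(int), 0)
        hi = np.minimum(np.ceil(c + r).astype(int), arch.env_dims)
        if np.any(hi <= lo):
            continue
        ii, jj, kk = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        d2 = ((ii + 0.5 - c[0]) ** 2 + (jj + 0.5 - c[1]) ** 2
              + (kk + 0.5 - c[2]) ** 2)
        mask = d2 <= r * r
        box = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        if np.any(box[mask] != 0):
            raise RuntimeError(
                f"internal consistency error: voxel claimed by two cells "
                f"(cell {cid} vs {int(box[mask][box[mask] != 0][0])})")
        box[mask] = cid
    type_of = np.zeros(arch.n_cells + 1, dtype=np.int8)
    type_of[1:] = arch.types
    return LabeledGrid(labels, type_of)
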