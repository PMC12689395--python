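"""Initial capillary centerlines by greedy best-first search on the voxel lattice.

Capillary seeds are 1-voxel-wide, collision-free tracks between random
points on opposite faces of the simulation grid.  Endocrine-cell voxels are
the only obstacles; paths may cross each other.  Steps use 6-connectivity so
the later Potts growth starts from watertight centerlines.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass

import numpy as np

from .core import CAPILLARY, LabeledGrid

_AXES = {"x": 0, "y": 1, "z": 2}
# fixed neighbor ordering: +x, -x, +y, -y, +z, -z (tie-break reproducibility)
_STEPS = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                   [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=np.int64)


@dataclass
class CapillaryPath:
    """A 6-connected, obstacle-free voxel track between opposite grid faces."""

    path_id: int
    axis: str
    voxels: np.ndarray  # (L, 3) int32
    start: tuple[int, int, int]
    goal: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.voxels)

    def audit(self, grid: LabeledGrid) -> None:
        """Raise AssertionError unless contiguity, obstacle avoidance and
        face anchoring all hold voxel-by-voxel."""
        v = self.voxels
        assert tuple(v[0]) == tuple(self.start), "path does not begin at start"
        assert tuple(v[-1]) == tuple(self.goal), "path does not end at goal"
        ax = _AXES[self.axis]
        lo, hi = sorted((self.start[ax], self.goal[ax]))
        assert lo == 0 and hi == grid.shape[ax] - 1, "endpoints not on opposite faces"
        steps = np.abs(np.diff(v.astype(np.int64), axis=0)).sum(axis=1)
        assert np.all(steps == 1), "consecutive voxels are not 6-neighbors"
        labels = grid.labels[v[:, 0], v[:, 1], v[:, 2]]
        types = grid.type_of[labels]
        assert np.all((types == 0) | (types == CAPILLARY)), \
            "path crosses an endocrine-cell voxel"


def sample_endpoint_pair(grid: LabeledGrid, axis: str, rng: np.random.Generator):
    """Uniform medium voxel on the axis-min face and one on the axis-max face."""
    ax = _AXES[axis]
    free = grid.medium_mask()
    pair = []
    for face_index in (0, grid.shape[ax] - 1):
        face = np.take(free, face_index, axis=ax)
        idx = np.argwhere(face)
        if len(idx) == 0:
            raise RuntimeError(f"face {axis}={face_index} has no medium voxels")
        pick = idx[int(rng.integers(len(idx)))]
        point = list(pick)
        point.insert(ax, face_index)
        pair.append(tuple(int(c) for c in point))
    return pair[0], pair[1]


def best_first_path(grid: LabeledGrid, start, goal,
                    path_id: int = 0, axis: str = "x") -> CapillaryPath | None:
    """Greedy best-first search from start to goal, or None if unreachable.

    The frontier is ordered by Euclidean distance to the goal with FIFO
    tie-breaking; neighbors are pushed in the fixed +x,-x,+y,-y,+z,-z order.
    Complete: explores until the frontier exhausts, so failure implies the
    goal is genuinely unreachable through medium voxels.
    """
    labels = grid.labels
    nx, ny, nz = labels.shape
    types = grid.type_of
    for name, p in (("start", start), ("goal", goal)):
        if types[labels[p]] not in (0, CAPILLARY):
            raise ValueError(f"{name} voxel {p} lies inside a cell")
    blocked = ~((types[labels] == 0) | (types[labels] == CAPILLARY))
    flat_blocked = blocked.ravel()
    syz, sz = ny * nz, nz
    gx, gy, gz = goal
    gflat = gx * syz + gy * sz + gz
    sflat = start[0] * syz + start[1] * sz + start[2]
    parent = {sflat: -1}
    counter = 0
    h0 = math.dist(start, goal)
    frontier = [(h0, counter, sflat)]
    dflat = (syz, -syz, sz, -sz, 1, -1)
    while frontier:
        _, _, cur = heapq.heappop(frontier)
        if cur == gflat:
            return _reconstruct(parent, cur, labels.shape, path_id, axis, start, goal)
        cx, r = divmod(cur, syz)
        cy, cz = divmod(r, sz)
        for k in range(6):
            if k == 0 and cx + 1 >= nx:
                continue
            if k == 1 and cx == 0:
                continue
            if k == 2 and cy + 1 >= ny:
                continue
            if k == 3 and cy == 0:
                continue
            if k == 4 and cz + 1 >= nz:
                continue
            if k == 5 and cz == 0:
                continue
            nb = cur + dflat[k]
            if nb in parent or flat_blocked[nb]:
                continue
            parent[nb] = cur
            nnx = cx + (k == 0) - (k == 1)
            nny = cy + (k == 2) - (k == 3)
            nnz = cz + (k == 4) - (k == 5)
            counter += 1
            h = math.sqrt((nnx - gx) ** 2 + (nny - gy) ** 2 + (nnz - gz) ** 2)
            heapq.heappush(frontier, (h, counter, nb))
    return None


def _reconstruct(parent, node, shape, path_id, axis, start, goal) -> CapillaryPath:
    syz, sz = shape[1] * shape[2], shape[2]
    chain = []
    while node != -1:
        x, r = divmod(node, syz)
        y, z = divmod(r, sz)
        chain.append((x, y, z))
        node = parent[node]
    chain.reverse()
    return CapillaryPath(path_id, axis, np.array(chain, dtype=np.int32),
                         tuple(start), tuple(goal))


def generate_initial_capillaries(grid: LabeledGrid, n_per_axis: int = 100,
                                 seed: int = 0, *, retry_cap: int = 50
                                 ) -> list[CapillaryPath]:
    """Exactly ``n_per_axis`` successful paths per axis (3x total), with
    endpoint resampling on failure.  Capillary labels start just above the
    highest cell ID."""
    if n_per_axis < 1:
        raise ValueError("n_per_axis must be >= 1")
    rng = np.random.default_rng(seed)
    next_id = int(grid.type_of.size)  # max cell id + 1
    paths: list[CapillaryPath] = []
    for axis in ("x", "y", "z"):
        got = 0
        while got < n_per_axis:
            path = None
            for _ in range(retry_cap):
                start, goal = sample_endpoint_pair(grid, axis, rng)
                path = best_first_path(grid, start, goal, path_id=next_id, axis=axis)
                if path is not None:
                    break
            if path is None:
                raise RuntimeError(
                    f"no collision-free {axis}-axis path found after "
                    f"{retry_cap} endpoint resamples")
            paths.append(path)
            next_id += 1
            got += 1
    return paths


def select_capillary_subset(paths: list[CapillaryPath], n: int,
                            seed: int = 0) -> list[CapillaryPath]:
    """Uniform sample of n paths without replacement (deterministic in seed)."""
    if not 0 <= n <= len(paths):
        raise ValueError(f"cannot select {n} of {len(paths)} paths")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(paths), size=n, replace=False)
    return [paths[int(i)] for i in idx]


# ---------------------------------------------------------------------------
# JSON-lines export (run-length-encoded step directions)

_DIR_CODES = {tuple(s): i for i, s in enumerate(_STEPS.tolist())}


def _rle_encode(voxels: np.ndarray) -> list[list[int]]:
    steps = np.diff(voxels.astype(np.int64), axis=0)
    codes = [_DIR_CODES[tuple(s)] for s in steps.tolist()]
    out: list[list[int]] = []
    for c in codes:
        if out and out[-1][0] == c:
            out[-1][1] += 1
        else:
            out.append([c, 1])
    return out


def _rle_decode(start, rle) -> np.ndarray:
    pts = [list(start)]
    for code, count in rle:
        step = _STEPS[code]
        for _ in range(count):
            pts.append([pts[-1][i] + int(step[i]) for i in range(3)])
    return np.array(pts, dtype=np.int32)


def save_paths(paths: list[CapillaryPath], fp) -> None:
    with open(fp, "w") as fh:
        for p in paths:
            fh.write(json.dumps({
                "path_id": p.path_id, "axis": p.axis,
                "start": list(p.start), "goal": list(p.goal),
                "rle": _rle_encode(p.voxels)}) + "\n")


def load_paths(fp) -> list[CapillaryPath]:
    out = []
    with open(fp) as fh:
        for line in fh:
            rec = json.loads(line)
            voxels = _rle_decode(rec["start"], rec["rle"])
            out.append(CapillaryPath(rec["path_id"], rec["axis"], voxels,
                                     tuple(rec["start"]), tuple(rec["goal"])))
    return out
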