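"""End-to-end orchestration: single runs and capillary-count sweeps.

A run executes geometry -> capillary seeding -> Potts growth -> oxygen ->
viability in order, persisting every stage artifact plus a manifest with
SHA-256 hashes and timings.  A sweep re-uses one 300-path pool per islet
across all capillary counts and glucose conditions (capillary positions held
constant so oxygenation effects are isolated), producing tidy sweep records
that feed the sigmoid viability fit directly.

All stage seeds derive deterministically from one master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import LabeledGrid
from .cpm import CPMConfig, evolve_capillaries
from .geometry import (IsletArchitecture, RadiiDistribution, load_cells,
                       rasterize, synthesize_islet)
from .oxygen import OxygenParams, relax_to_steady_state
from .seeding import generate_initial_capillaries, save_paths, select_capillary_subset
from .sigmoid import CapillaryViabilityResults, fit_viability_model
from .viability import summarize

log = logging.getLogger(__name__)

#: environment dimensions (µm) of the six published human islets
HUMAN_ENVIRONMENTS = ((227, 208, 164), (309, 364, 196), (340, 388, 225),
                      (359, 389, 237), (282, 263, 219), (313, 307, 230))
#: mean environment dimensions of the published human islets (µm)
HUMAN_REFERENCE_ENV = (305.0, 319.8, 211.8)

DEFAULT_SWEEP_COUNTS = (5, 10, 25, 50, 100, 200, 300)

def mean_face_area(env_dims) -> float:
    """Mean cross-sectional (face) area of the environment box, µm^2."""
    x, y, z = env_dims
    return (x * y + y * z + x * z) / 3.0


#: mean face area of the published human islet environments, µm^2
REFERENCE_FACE_AREA = float(np.mean(
    [mean_face_area(e) for e in HUMAN_ENVIRONMENTS]))


def derive_seed(master_seed: int, *tags) -> int:
    """Stable per-stage seed below 2^31 derived from the master seed."""
    key = zlib.crc32("/".join(str(t) for t in tags).encode())
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key])
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def equivalent_capillary_count(env_dims, n_full: int,
                               reference_area: float = REFERENCE_FACE_AREA
                               ) -> int:
    """Capillary count for a scaled-down grid that preserves capillaries per
    unit cross-sectional (face) area relative to the full-size human average.

    Seed endpoints are uniform over the grid faces, so the count per face
    area fixes both the areal capillary density within the islet (what the
    vascular-density measurement reports) and the through-islet capillary
    spacing (what oxygenation depends on).
    """
    scale = mean_face_area(env_dims) / reference_area
    return max(1, int(round(n_full * scale)))


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class SynthesisSpec:
    """Parameters of one synthetic islet."""

    n_cells: int
    target_diameter: float
    species: str = "human"
    composition: dict | None = None


@dataclass
class RunConfig:
    """Configuration of a single end-to-end run."""

    outdir: str
    cell_table: str | None = None
    species: str = "human"
    synthesis: SynthesisSpec | None = None
    n_capillaries: int = 100
    scale_count_to_env: bool = False
    pool_per_axis: int = 100
    glucose: tuple = ("G6", "G20")
    master_seed: int = 0
    cpm: CPMConfig = field(default_factory=CPMConfig)
    oxygen: OxygenParams = field(default_factory=OxygenParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "synthesis" in raw and raw["synthesis"] is not None:
            raw["synthesis"] = SynthesisSpec(**raw["synthesis"])
        if "cpm" in raw:
            raw["cpm"] = CPMConfig(**raw["cpm"])
        if "oxygen" in raw:
            raw["oxygen"] = OxygenParams(**raw["oxygen"])
        if "glucose" in raw:
            raw["glucose"] = tuple(raw["glucose"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["cpm"]["J"] = np.asarray(self.cpm.J).tolist()
        d["oxygen"]["consumption"] = {f"{t}:{g}": v for (t, g), v
                                      in self.oxygen.consumption.items()}
        return d


@dataclass
class SweepConfig:
    """Configuration of a capillary-count sweep over several islets."""

    outdir: str
    islets: list = field(default_factory=list)     # SynthesisSpec per islet
    counts: tuple = DEFAULT_SWEEP_COUNTS
    scale_counts_to_env: bool = False
    glucose: tuple = ("G6", "G20")
    n_replicates: int = 1
    pool_per_axis: int = 100
    master_seed: int = 0
    cpm: CPMConfig = field(default_factory=CPMConfig)
    oxygen: OxygenParams = field(default_factory=OxygenParams)


# ---------------------------------------------------------------------------
# Artifact helpers

def save_labeled_volume(prefix: Path, grid: LabeledGrid, extra: dict | None = None):
    """Labeled volume as .npy plus a JSON sidecar with per-entity metadata."""
    np.save(f"{prefix}.npy", grid.labels)
    volumes = np.bincount(grid.labels.ravel(), minlength=grid.type_of.size)
    meta = {"shape": list(grid.shape),
            "type_of": grid.type_of.tolist(),
            "entity_volumes": volumes.tolist(),
            **(extra or {})}
    Path(f"{prefix}.meta.json").write_text(json.dumps(meta))
    return [Path(f"{prefix}.npy"), Path(f"{prefix}.meta.json")]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: dict):
        self.outdir = outdir
        self.data = {"config": config, "artifacts": {}, "timings_s": {}}

    def add(self, name: str, paths) -> None:
        for p in np.atleast_1d(paths):
            p = Path(p)
            self.data["artifacts"][f"{name}:{p.name}"] = {
                "path": str(p.relative_to(self.outdir)), "sha256": _sha256(p)}

    def time(self, stage: str, seconds: float) -> None:
        self.data["timings_s"][stage] = round(seconds, 3)

    def write(self) -> Path:
        p = self.outdir / "manifest.json"
        p.write_text(json.dumps(self.data, indent=2))
        return p


class _Stage:
    """Context manager: stage logging, timing, and error attribution."""

    def __init__(self, name: str, manifest: _Manifest):
        self.name, self.manifest = name, manifest

    def __enter__(self):
        log.info("stage %s: start", self.name)
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        self.manifest.time(self.name, dt)
        if exc_type is not None:
            self.manifest.write()  # persist partial artifacts + timings
            log.error("stage %s: failed after %.1fs (%s)", self.name, dt, exc)
            raise RuntimeError(f"pipeline stage '{self.name}' failed: {exc}") from exc
        log.info("stage %s: done in %.1fs", self.name, dt)
        return False


# ---------------------------------------------------------------------------
# Single run

def _build_architecture(cfg, tag) -> IsletArchitecture:
    if cfg.cell_table is not None:
        return load_cells(cfg.cell_table, cfg.species,
                          seed=derive_seed(cfg.master_seed, tag, "radii"))
    spec = cfg.synthesis or SynthesisSpec(n_cells=300, target_diameter=92.0)
    return synthesize_islet(spec.n_cells, spec.species, spec.composition,
                            RadiiDistribution(), spec.target_diameter,
                            seed=derive_seed(cfg.master_seed, tag, "synth"))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and return the manifest dictionary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, cfg.to_jsonable())
    (outdir / "config.json").write_text(json.dumps(cfg.to_jsonable(), indent=2))
    manifest.add("config", outdir / "config.json")

    with _Stage("geometry", manifest):
        arch = _build_architecture(cfg, "run")
        arch.save_cells(outdir / "cells.csv")
        arch.save_summary(outdir / "architecture.json")
        manifest.add("geometry", [outdir / "cells.csv", outdir / "architecture.json"])

    with _Stage("rasterize", manifest):
        grid = rasterize(arch)

    with _Stage("seeding", manifest):
        pool = generate_initial_capillaries(
            grid, cfg.pool_per_axis, seed=derive_seed(cfg.master_seed, "pool"))
        save_paths(pool, outdir / "capillary_pool.jsonl")
        manifest.add("seeding", outdir / "capillary_pool.jsonl")

    with _Stage("cpm", manifest):
        n_cap = cfg.n_capillaries
        if cfg.scale_count_to_env:
            n_cap = equivalent_capillary_count(grid.shape, n_cap)
        subset = select_capillary_subset(pool, n_cap,
                                         seed=derive_seed(cfg.master_seed, "subset"))
        vgrid, cpm_report = evolve_capillaries(
            grid, subset, cfg.cpm, seed=derive_seed(cfg.master_seed, "cpm"))
        paths = save_labeled_volume(outdir / "vascularized", vgrid,
                                    {"n_capillaries": n_cap,
                                     "cpm_converged": cpm_report["converged"]})
        manifest.add("cpm", paths)

    results = {}
    field_prev = None
    for glucose in cfg.glucose:
        with _Stage(f"oxygen:{glucose}", manifest):
            params = replace(cfg.oxygen, glucose=glucose)
            f = relax_to_steady_state(vgrid, params, initial=field_prev)
            field_prev = f.concentration
            np.save(outdir / f"oxygen_{glucose}.npy", f.concentration)
            sidecar = {"glucose": glucose, "converged": f.converged,
                       "iterations": f.iterations, "residual": f.residual,
                       "units": "uM", "D_um2_per_ms": params.D,
                       "solubility_uM_per_mmHg": params.solubility,
                       "mean_uM": float(f.concentration.mean()),
                       "mean_mmHg": float(f.po2().mean())}
            (outdir / f"oxygen_{glucose}.json").write_text(json.dumps(sidecar))
            manifest.add(f"oxygen:{glucose}",
                         [outdir / f"oxygen_{glucose}.npy",
                          outdir / f"oxygen_{glucose}.json"])
        with _Stage(f"viability:{glucose}", manifest):
            report = summarize(vgrid, f, metadata={
                "n_capillaries": n_cap, "glucose": glucose,
                "master_seed": cfg.master_seed})
            report.save(outdir / f"viability_{glucose}.csv",
                        outdir / f"viability_{glucose}.json")
            manifest.add(f"viability:{glucose}",
                         [outdir / f"viability_{glucose}.csv",
                          outdir / f"viability_{glucose}.json"])
            results[glucose] = report

    manifest.data["results"] = {
        g: {"proportions": r.proportions,
            "mean_medium_oxygen_um": r.mean_medium_oxygen_um}
        for g, r in results.items()}
    manifest.write()
    return manifest.data


# ---------------------------------------------------------------------------
# Sweeps

def vascularize_islet(spec: SynthesisSpec, master_seed: int, islet_id: int,
                      pool_per_axis: int = 100):
    """Synthesize one islet, rasterize it and build its capillary pool."""
    arch = synthesize_islet(spec.n_cells, spec.species, spec.composition,
                            target_diameter=spec.target_diameter,
                            seed=derive_seed(master_seed, "islet", islet_id))
    grid = rasterize(arch)
    pool = generate_initial_capillaries(
        grid, pool_per_axis, seed=derive_seed(master_seed, "pool", islet_id))
    return arch, grid, pool


def sweep_capillary_counts(cfg: SweepConfig) -> pd.DataFrame:
    """One record per (islet x count x glucose x replicate).

    The per-islet path pool is fixed across counts and glucose conditions;
    oxygen solves warm-start from the previous count's steady field.
    """
    records = []
    for islet_id, spec in enumerate(cfg.islets):
        arch, grid, pool = vascularize_islet(spec, cfg.master_seed, islet_id,
                                             cfg.pool_per_axis)
        counts = sorted(cfg.counts)
        if cfg.scale_counts_to_env:
            # scaled equivalents, deduplicated (small islets map several
            # full-size counts onto the same small integer)
            counts = sorted({equivalent_capillary_count(grid.shape, c)
                             for c in counts})
        for rep in range(cfg.n_replicates):
            warm: dict[str, np.ndarray] = {}
            for n_cap in counts:
                subset = select_capillary_subset(
                    pool, n_cap,
                    seed=derive_seed(cfg.master_seed, "subset", islet_id, n_cap, rep))
                vgrid, _ = evolve_capillaries(
                    grid, subset, cfg.cpm,
                    seed=derive_seed(cfg.master_seed, "cpm", islet_id, n_cap, rep))
                first_field = None
                for glucose in cfg.glucose:
                    params = replace(cfg.oxygen, glucose=glucose)
                    # warm start: same-count field of the first glucose
                    # condition, else the previous count's field
                    init = first_field if first_field is not None \
                        else warm.get(glucose)
                    f = relax_to_steady_state(vgrid, params, initial=init)
                    warm[glucose] = f.concentration
                    if first_field is None:
                        first_field = f.concentration
                    rep_seed = derive_seed(cfg.master_seed, "rep", islet_id, n_cap, rep)
                    report = summarize(vgrid, f)
                    p = report.proportions["islet"]
                    records.append({
                        "islet_id": islet_id, "species": spec.species,
                        "glucose": glucose, "n_capillaries": n_cap,
                        "n_cells": arch.n_cells,
                        "viable_proportion": p["viable"],
                        "functional_proportion": p["functional"],
                        "nonviable_proportion": p["nonviable"],
                        "mean_medium_oxygen_um": report.mean_medium_oxygen_um,
                        "replicate_seed": rep_seed,
                    })
                    log.info("islet %d n_cap %d %s: viable %.3f",
                             islet_id, n_cap, glucose, p["viable"])
    df = pd.DataFrame.from_records(records)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / "sweep_records.csv", index=False)
    aggregate_sweep(df).to_csv(outdir / "sweep_aggregate.csv", index=False)
    return df


def aggregate_sweep(records: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SEM of the viable proportion across islets per (count, glucose)."""
    g = records.groupby(["glucose", "n_capillaries"])["viable_proportion"]
    out = g.agg(mean="mean", sem=lambda s: s.sem() if len(s) > 1 else 0.0,
                n="count").reset_index()
    return out


def fit_sweep(records: pd.DataFrame, glucose: str = "G6",
              seed: int = 0) -> CapillaryViabilityResults:
    """Fit the sigmoid viability model to one glucose condition of a sweep."""
    sub = records[records["glucose"] == glucose]
    return fit_viability_model(sub, seed=seed)
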