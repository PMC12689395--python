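"""Reduced-scale study protocols.

Full-size simulated islets (~3e7 voxels) exceed desk scale, so the
morphometry, viability and sweep studies run on scaled-down synthetic human
islets whose capillary loading preserves capillaries per unit grid
cross-sectional area relative to the full-size human average.  The problem
sizes here (cell counts, ball diameters, Monte Carlo steps) are the
package's reference desk-scale conditions; docs/methods.md discusses what
they do and do not preserve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cpm import CPMConfig, evolve_capillaries
from .oxygen import OxygenParams, relax_to_steady_state
from .pipeline import (SweepConfig, SynthesisSpec, derive_seed,
                       equivalent_capillary_count, sweep_capillary_counts,
                       vascularize_islet)
from .viability import (extract_mid_slice, measure_capillary_diameters,
                        summarize, vascular_density_stack)

log = logging.getLogger(__name__)

#: scaled human-style islets for morphometry/viability: ~30 % sphere packing
#: (the packing fraction of the published reconstructed islets), environment
#: ~165 µm per side
MORPHOMETRY_SPEC = SynthesisSpec(n_cells=200, target_diameter=98.0)

#: scaled islet sizes for the capillary-count sweep.  These pack cells at
#: ~52 % (vs ~30 % for the morphometry islets): the oxygen penetration depth
#: (~13 µm at 6 mM glucose) does not shrink with the islet, so small islets
#: only reach the oxygen-starved arm of the dose-response when their
#: radius-to-penetration-depth ratio is restored by a higher volumetric
#: consumption, i.e. denser cells
SWEEP_SPECS = (SynthesisSpec(30, 43.0), SynthesisSpec(60, 54.0),
               SynthesisSpec(90, 61.0))

#: study solver tolerance, µM/ms — the viability classification margin is
#: ~0.1 µM, four orders above the steady-state error this leaves
STUDY_TOL = 1e-5

#: full-size capillary counts whose scaled equivalents are swept
FULL_SIZE_COUNTS = (5, 10, 25, 50, 100, 200, 300)


@dataclass
class IsletStudyResult:
    """One vascularized islet with its morphometry and viability readouts."""

    n_cells: int
    n_capillaries: int
    diameters_um: list
    density_pct: float
    viability: dict          # glucose -> ViabilityReport


def vascularized_islet_study(master_seed: int, n_islets: int = 3,
                             spec: SynthesisSpec = MORPHOMETRY_SPEC,
                             full_size_count: int = 100, n_mcs: int = 300,
                             diameter_samples: int = 60,
                             glucose=("G6", "G20")) -> list[IsletStudyResult]:
    """Grow scaled islets at a full-size-equivalent capillary loading and
    measure mid-slice morphometry plus per-glucose viability."""
    out = []
    cfg = CPMConfig(n_mcs=n_mcs)
    for i in range(n_islets):
        arch, grid, pool = vascularize_islet(spec, master_seed, i)
        n_cap = equivalent_capillary_count(grid.shape, full_size_count)
        subset_seed = derive_seed(master_seed, "subset", i)
        from .seeding import select_capillary_subset
        subset = select_capillary_subset(pool, n_cap, seed=subset_seed)
        vgrid, _ = evolve_capillaries(grid, subset, cfg,
                                      seed=derive_seed(master_seed, "cpm", i))
        sl = extract_mid_slice(vgrid)
        rng = np.random.default_rng(derive_seed(master_seed, "diam", i))
        diam = measure_capillary_diameters(sl, vgrid.type_of,
                                           diameter_samples, rng)
        dens = vascular_density_stack(vgrid)   # ten mid-islet z sections
        viability = {}
        warm = None
        for g in glucose:
            f = relax_to_steady_state(vgrid,
                                      OxygenParams(glucose=g, tol=STUDY_TOL),
                                      initial=warm)
            warm = f.concentration
            viability[g] = summarize(vgrid, f, metadata={
                "glucose": g, "n_capillaries": n_cap})
        out.append(IsletStudyResult(arch.n_cells, n_cap, diam, dens, viability))
        log.info("islet %d: n_cap=%d density=%.2f%% mean_diam=%.2f", i, n_cap,
                 dens, float(np.mean(diam)) if diam else float("nan"))
    return out


def morphometry_summary(results: list[IsletStudyResult]) -> dict:
    """Pooled diameter mean and across-islet density mean."""
    diam = np.concatenate([r.diameters_um for r in results])
    dens = np.array([r.density_pct for r in results])
    return {"mean_diameter_um": float(diam.mean()),
            "sd_diameter_um": float(diam.std(ddof=1)),
            "n_diameters": int(diam.size),
            "mean_density_pct": float(dens.mean()),
            "n_islets": len(results)}


def viability_summary(results: list[IsletStudyResult], glucose: str) -> dict:
    """Across-islet mean percentages of viable/functional/non-viable cells."""
    viable = [r.viability[glucose].proportions["islet"]["viable"]
              for r in results]
    functional = [r.viability[glucose].proportions["islet"]["functional"]
                  for r in results]
    nonviable = [r.viability[glucose].proportions["islet"]["nonviable"]
                 for r in results]
    n_cells = sum(r.n_cells for r in results)
    return {"viable_pct": 100.0 * float(np.mean(viable)),
            "functional_pct": 100.0 * float(np.mean(functional)),
            "nonviable_pct": 100.0 * float(np.mean(nonviable)),
            "n_cells": n_cells, "n_islets": len(results)}


def scaled_sweep(master_seed: int, outdir, specs=SWEEP_SPECS, n_mcs: int = 100,
                 full_size_counts=FULL_SIZE_COUNTS,
                 glucose=("G6", "G20")) -> pd.DataFrame:
    """Capillary-count sweep with counts scaled per grid cross-section.

    Scaled counts are deduplicated per islet (tiny islets map several
    full-size counts onto the same small integer).
    """
    cfg = SweepConfig(outdir=str(outdir), islets=list(specs),
                      counts=tuple(full_size_counts), scale_counts_to_env=True,
                      glucose=tuple(glucose), master_seed=master_seed,
                      cpm=CPMConfig(n_mcs=n_mcs),
                      oxygen=OxygenParams(tol=STUDY_TOL))
    return sweep_capillary_counts(cfg)
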