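"""Sigmoidal model linking cell viability to capillary count and islet size.

The viable-cell proportion V of an islet with N_cap capillaries and N_cells
cells follows a modified two-factor Hill sigmoid

    V = V_min + (V_max - V_min) / (1 + (C50/N_cap)^n_C * (N50/N_cells)^n_N)

where C50 and N50 are the half-maximal capillary count and cell number and
n_C, n_N the respective steepness exponents (n_C > 0: capillaries help;
n_N < 0: size hurts).  At N_cap = C50 and N_cells = N50 the model passes
exactly through (V_min + V_max)/2.

Fitting follows the statsmodels convention: build a
``CapillaryViabilityModel`` from sweep records, call ``fit()`` and read the
estimates, goodness of fit and ``summary()`` off the returned
``CapillaryViabilityResults``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

_PARAM_NAMES = ("v_min", "v_max", "c50", "n50", "n_c", "n_n")


@dataclass(frozen=True)
class ViabilityParams:
    """The six sigmoid parameters (proportions, counts, exponents)."""

    v_min: float
    v_max: float
    c50: float
    n50: float
    n_c: float
    n_n: float

    def __post_init__(self) -> None:
        if self.v_min > self.v_max:
            raise ValueError("v_min must not exceed v_max")
        if self.c50 <= 0 or self.n50 <= 0:
            raise ValueError("C50 and N50 must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in _PARAM_NAMES], dtype=float)

    def as_dict(self) -> dict:
        return asdict(self)


#: published human parameter sets by glucose condition
HUMAN_PARAMS = {
    "G6": ViabilityParams(0.13, 1.00, 6.82, 669.16, 1.92, -1.70),
    "G20": ViabilityParams(0.12, 1.00, 14.23, 1271.88, 1.77, -1.60),
}

#: fitted range of the published sweeps (extrapolation warning outside)
FITTED_NCAP_RANGE = (5.0, 300.0)
FITTED_NCELLS_RANGE = (583.0, 3516.0)


def _eval(theta: np.ndarray, n_cap, n_cells):
    v_min, v_max, c50, n50, n_c, n_n = theta
    logterm = n_c * (np.log(c50) - np.log(n_cap)) + n_n * (np.log(n50) - np.log(n_cells))
    return v_min + (v_max - v_min) / (1.0 + np.exp(np.clip(logterm, -700, 700)))


def evaluate_viability(n_cap, n_cells, params: ViabilityParams):
    """Viable proportion predicted for positive N_cap, N_cells."""
    n_cap = np.asarray(n_cap, dtype=float)
    n_cells = np.asarray(n_cells, dtype=float)
    if np.any(n_cap <= 0) or np.any(n_cells <= 0):
        raise ValueError("N_cap and N_cells must be positive")
    out = _eval(params.as_array(), n_cap, n_cells)
    return float(out) if out.ndim == 0 else out


class CapillaryViabilityModel:
    """Nonlinear least-squares model of viable proportion vs (N_cap, N_cells).

    Parameters
    ----------
    n_cap, n_cells, viable : array-like
        One entry per sweep record: capillary count, islet cell number and
        observed viable proportion in [0, 1].
    """

    def __init__(self, n_cap, n_cells, viable):
        self.n_cap = np.asarray(n_cap, dtype=float).ravel()
        self.n_cells = np.asarray(n_cells, dtype=float).ravel()
        self.viable = np.asarray(viable, dtype=float).ravel()
        if not (len(self.n_cap) == len(self.n_cells) == len(self.viable)):
            raise ValueError("inputs must have equal length")
        if np.any(self.n_cap <= 0) or np.any(self.n_cells <= 0):
            raise ValueError("N_cap and N_cells must be positive")
        if np.any((self.viable < 0) | (self.viable > 1)):
            raise ValueError("viable proportions must lie in [0, 1]")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CapillaryViabilityModel":
        """Build from a sweep-record table with columns ``n_capillaries``,
        ``n_cells`` and ``viable_proportion``."""
        return cls(df["n_capillaries"], df["n_cells"], df["viable_proportion"])

    def default_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Parameter box spanning the observed data ranges."""
        lo = np.array([0.0, 0.8, 0.5 * self.n_cap.min(), 0.5 * self.n_cells.min(),
                       0.5, -4.0])
        hi = np.array([0.5, 1.0, 2.0 * self.n_cap.max(), 2.0 * self.n_cells.max(),
                       4.0, -0.5])
        return lo, hi

    def _check_design(self) -> None:
        if len(self.viable) < 10:
            raise ValueError("need at least 10 sweep records to fit")
        if len(np.unique(self.n_cap)) < 3:
            raise ValueError("need at least 3 distinct capillary counts")
        if len(np.unique(self.n_cells)) < 2:
            raise ValueError("need at least 2 distinct islet sizes")

    def fit(self, init: ViabilityParams | None = None, bounds=None,
            n_starts: int = 16, seed: int = 0) -> "CapillaryViabilityResults":
        """Multi-start nonlinear least squares (deterministic under seed).

        Starting points are a Latin hypercube over ``bounds`` (defaults
        derived from the data ranges), plus ``init`` when given.  Raises on
        constant-response data (R^2 undefined) and when no start converges.
        """
        self._check_design()
        lo, hi = bounds if bounds is not None else self.default_bounds()
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        ss_tot = float(np.sum((self.viable - self.viable.mean()) ** 2))
        if np.ptp(self.viable) == 0 or ss_tot <= 1e-14 * len(self.viable):
            raise ValueError("constant viability data: R^2 undefined (degenerate)")

        def resid(theta):
            return _eval(theta, self.n_cap, self.n_cells) - self.viable

        sampler = qmc.LatinHypercube(d=6, seed=seed)
        starts = [qmc.scale(s[None, :], lo, hi)[0] for s in sampler.random(n_starts)]
        if init is not None:
            starts.append(np.clip(init.as_array(), lo, hi))
        best = None
        n_ok = 0
        for x0 in starts:
            try:
                sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
            except Exception:
                continue
            if not sol.success:
                continue
            n_ok += 1
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError(
                f"no converged fit from {len(starts)} starts "
                f"(bounds lo={lo.tolist()}, hi={hi.tolist()})")
        params = ViabilityParams(*best.x)
        fitted = _eval(best.x, self.n_cap, self.n_cells)
        ss_res = float(np.sum((fitted - self.viable) ** 2))
        return CapillaryViabilityResults(
            model=self, params=params, fitted=fitted,
            ss_res=ss_res, ss_tot=ss_tot, n_starts_converged=n_ok)


@dataclass
class CapillaryViabilityResults:
    """Fit results: estimates, goodness of fit, diagnostics."""

    model: CapillaryViabilityModel
    params: ViabilityParams
    fitted: np.ndarray
    ss_res: float
    ss_tot: float
    n_starts_converged: int

    @property
    def nobs(self) -> int:
        return len(self.model.viable)

    @property
    def mse(self) -> float:
        return self.ss_res / self.nobs

    @property
    def r_squared(self) -> float:
        return 1.0 - self.ss_res / self.ss_tot

    def predict(self, n_cap, n_cells):
        return evaluate_viability(n_cap, n_cells, self.params)

    @property
    def log_gauge(self) -> float:
        """The identifiable half-maximum combination n_C*ln(C50) + n_N*ln(N50).

        The sigmoid depends on C50 and N50 only through the product
        C50^n_C * N50^n_N, so the two half-maximum constants are determined
        jointly but not individually; reported values of either depend on
        the fitting bounds and start.
        """
        p = self.params
        return p.n_c * np.log(p.c50) + p.n_n * np.log(p.n50)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Capillary viability model (two-factor Hill sigmoid)",
            "=" * 51,
            f"observations: {self.nobs:5d}   converged starts: {self.n_starts_converged}",
            f"R-squared:    {self.r_squared:8.4f}   MSE: {self.mse:.5f}",
            "-" * 51,
            f"V_min {p.v_min:10.4f}    V_max {p.v_max:10.4f}",
            f"C50   {p.c50:10.4f}    N50   {p.n50:10.2f}",
            f"n_C   {p.n_c:10.4f}    n_N   {p.n_n:10.4f}",
        ]
        return "\n".join(lines)

    def save_params(self, path, species: str = "human", glucose: str = "G6") -> None:
        payload = {"species": species, "glucose": glucose,
                   "params": self.params.as_dict(),
                   "r_squared": self.r_squared, "mse": self.mse,
                   "n_obs": self.nobs}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def fit_viability_model(records: pd.DataFrame, init: ViabilityParams | None = None,
                        bounds=None, seed: int = 0) -> CapillaryViabilityResults:
    """Convenience wrapper: fit the sigmoid to a sweep-record table."""
    return CapillaryViabilityModel.from_dataframe(records).fit(
        init=init, bounds=bounds, seed=seed)


def load_params(path) -> tuple[ViabilityParams, dict]:
    with open(path) as fh:
        payload = json.load(fh)
    return ViabilityParams(**payload["params"]), payload


def predict_viability(n_cap: float, n_cells: float, glucose: str = "G6",
                      species: str = "human", params_file=None) -> dict:
    """Viability prediction report for the interactive predictor.

    Uses the bundled published human parameter sets, or a user-fitted
    parameter file (required for mouse, whose parameters were not
    published).  Flags extrapolation outside the fitted input ranges.
    """
    if params_file is not None:
        params, meta = load_params(params_file)
        source = str(params_file)
    elif species == "human" and glucose in HUMAN_PARAMS:
        params = HUMAN_PARAMS[glucose]
        source = f"published human {glucose} parameters"
    else:
        raise ValueError(
            f"no bundled parameter set for species={species!r}, glucose={glucose!r}; "
            "fit your own sweep and pass params_file (mouse parameters were not "
            "published)")
    v = evaluate_viability(n_cap, n_cells, params)
    extrapolating = not (FITTED_NCAP_RANGE[0] <= n_cap <= FITTED_NCAP_RANGE[1]
                         and FITTED_NCELLS_RANGE[0] <= n_cells <= FITTED_NCELLS_RANGE[1])
    return {"viable_proportion": v, "n_cap": n_cap, "n_cells": n_cells,
            "glucose": glucose, "species": species,
            "params": params.as_dict(), "params_source": source,
            "extrapolation": extrapolating}
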