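"""Survivorship-shape x fecundity-exponent grid scans.

For each point of a (c, f) grid, sixteen theoretical species are built with
the real maturities and lifespans of the packaged trait table, a Weibull
survivorship of shape ``c`` (scaled to 1% survival at the lifespan) and an
age-fecundity model with shape constant ``f``.  The analytic engine then
yields an Ne/N ratio per species, and the slope, R² and p-value of the OLS
regression of Ne/N on adult lifespan summarize how strongly adult lifespan
depresses the effective-to-census size ratio under that life-history
regime.

The regression uses the annual-basis ratio (per-year effective size over
the annual adult census) by default; the per-generation basis is available
through ``ratio_basis``.  See docs/methods.md for the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .agene_core import effective_size_ratio
from .inference_stats import ols_slope_r2
from .life_tables import AgeFecundityModel, build_theoretical_life_table
from .synthetic_data import table1_fixture


def default_c_grid(n: int = 60, extra: Sequence[float] = (0.01, 0.1, 1.03)) -> np.ndarray:
    """Log-spaced survivorship shapes over [0.01, 30] plus key printed values."""
    grid = np.logspace(np.log10(0.01), np.log10(30.0), n)
    return np.unique(np.concatenate([grid, np.asarray(extra, dtype=float)]))


def default_f_grid(n: int = 41) -> np.ndarray:
    """Linear fecundity shape constants over [-1, 1]."""
    return np.linspace(-1.0, 1.0, n)


def default_species_set() -> list[tuple[float, int]]:
    """(maturity, lifespan) pairs of the packaged 16-species fixture."""
    return [(t.maturity, int(t.lifespan)) for t in table1_fixture()]


@dataclass
class GridSpec:
    """Configuration of a grid scan."""

    c_values: np.ndarray = field(default_factory=default_c_grid)
    f_values: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    fecundity_model: Literal[
        "constant", "exponential", "powerlaw", "linear", "polynomial"
    ] = "constant"
    species_set: list = field(default_factory=default_species_set)
    phi: float = 1.0
    ratio_basis: Literal["year", "generation"] = "year"

    def __post_init__(self) -> None:
        self.c_values = np.asarray(self.c_values, dtype=float)
        self.f_values = np.asarray(self.f_values, dtype=float)
        if self.c_values.size == 0 or self.f_values.size == 0:
            raise ValueError("grids must be non-empty")
        if np.any(self.c_values <= 0):
            raise ValueError("all c values must be positive")
        if not self.species_set:
            raise ValueError("species_set must be non-empty")


@dataclass
class GridSurface:
    """Long-format slope/R²/p surface over the (c, f) grid."""

    table: pd.DataFrame
    spec: GridSpec

    def cell(self, c: float, f: float) -> pd.Series:
        t = self.table
        i = ((t["c"] - c).abs() + (t["f"] - f).abs()).idxmin()
        return t.loc[i]


def species_ratios(
    c: float,
    f: float,
    fecundity_model: str,
    species_set: Sequence[tuple[float, int]],
    phi: float = 1.0,
    ratio_basis: str = "year",
) -> tuple[np.ndarray, np.ndarray]:
    """(adult lifespans, Ne/N ratios) for one grid cell."""
    if fecundity_model == "constant":
        fec = AgeFecundityModel("constant")
    else:
        fec = AgeFecundityModel(fecundity_model, f=f)
    adl, ratios = [], []
    for maturity, lifespan in species_set:
        table = build_theoretical_life_table(maturity, lifespan, c, fec)
        res = effective_size_ratio(table, table, phi=phi)
        adl.append(lifespan - maturity)
        ratios.append(res.ratio_annual if ratio_basis == "year" else res.ratio)
    return np.asarray(adl, dtype=float), np.asarray(ratios, dtype=float)


def scan_grid(spec: GridSpec) -> GridSurface:
    """Slope/R²/p of OLS(Ne/N ~ adult lifespan) for every (c, f) cell.

    Fully deterministic; failed cells are recorded with NaN entries and a
    ``failed`` flag rather than silently dropped.
    """
    f_values = spec.f_values if spec.fecundity_model != "constant" else np.array([0.0])
    rows = []
    for c in spec.c_values:
        for f in f_values:
            row = {"c": float(c), "f": float(f), "model": spec.fecundity_model}
            try:
                adl, ratios = species_ratios(
                    c, f, spec.fecundity_model, spec.species_set,
                    phi=spec.phi, ratio_basis=spec.ratio_basis,
                )
                fit = ols_slope_r2(adl, ratios)
                row.update(slope=fit.slope, R2=fit.R2, p=fit.p_slope, failed=False)
            except (ValueError, RuntimeError) as exc:
                row.update(slope=np.nan, R2=np.nan, p=np.nan, failed=True)
                import logging

                logging.getLogger("agestruct").warning(
                    "grid cell (c=%g, f=%g) failed: %s", c, f, exc
                )
            rows.append(row)
    return GridSurface(table=pd.DataFrame(rows), spec=spec)


def summarize_extremes(surface: GridSurface, alpha: float = 0.05) -> dict:
    """Steepest negative slope, best R², and positive-slope region report."""
    t = surface.table.dropna(subset=["slope"])
    if t.empty:
        raise ValueError("surface contains no successful cells")
    i_min = t["slope"].idxmin()
    i_r2 = t["R2"].idxmax()
    pos = t[(t["slope"] > 0) & (t["p"] < alpha)]
    return {
        "steepest_slope": float(t.loc[i_min, "slope"]),
        "steepest_at": (float(t.loc[i_min, "c"]), float(t.loc[i_min, "f"])),
        "max_R2": float(t.loc[i_r2, "R2"]),
        "max_R2_at": (float(t.loc[i_r2, "c"]), float(t.loc[i_r2, "f"])),
        "positive_cells": [
            (float(r["c"]), float(r["f"]), float(r["slope"])) for _, r in pos.iterrows()
        ],
    }
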