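"""Synthetic inputs and the packaged species-trait fixture.

The packaged fixture is the 16-species marine-teleost trait table (median
genome-wide heterozygosity plus life-history covariates).  The generators
emulate the two other inputs the pipeline consumes: noisy Von Bertalanffy
age-length observations, and species sets whose diversity responds to adult
lifespan on the logit scale with beta-distributed noise — the same
mean/precision parameterization the beta-regression estimator assumes, so
parameter-recovery tests are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Literal

import numpy as np
import pandas as pd

from .life_tables import GrowthModel

PARENTAL_CARE_LEVELS = ("none", "nest_guarder", "brood_pouch")
HERMAPHRODITISM_LEVELS = ("none", "protogynous", "protandrous", "rudimentary")


@dataclass(frozen=True)
class SpeciesTraits:
    """One row of the trait table.

    ``diversity`` is the heterozygous fraction of sites as a proportion in
    (0, 1) (the printed percentage divided by 100).
    """

    name: str
    diversity: float
    body_size: float
    trophic_level: float
    fecundity: float  # eggs/day; NaN where unreported
    propagule_size: float
    maturity: float
    lifespan: float
    adult_lifespan: float
    parental_care: str
    hermaphroditism: str

    def __post_init__(self) -> None:
        if not (0.0 < self.diversity < 1.0):
            raise ValueError(f"{self.name}: diversity must lie in (0,1)")
        if self.maturity < 0.5:
            raise ValueError(f"{self.name}: maturity must be >= 0.5")
        if self.lifespan < self.maturity:
            raise ValueError(f"{self.name}: lifespan must be >= maturity")
        if abs(self.adult_lifespan - (self.lifespan - self.maturity)) > 1e-9:
            raise ValueError(f"{self.name}: adult_lifespan != lifespan - maturity")
        if self.parental_care not in PARENTAL_CARE_LEVELS:
            raise ValueError(f"{self.name}: bad parental_care {self.parental_care!r}")
        if self.hermaphroditism not in HERMAPHRODITISM_LEVELS:
            raise ValueError(f"{self.name}: bad hermaphroditism {self.hermaphroditism!r}")

    @property
    def is_brooder(self) -> bool:
        """Species providing parental care (nest guarding or brood pouch)."""
        return self.parental_care != "none"


def _row_to_traits(row: pd.Series) -> SpeciesTraits:
    return SpeciesTraits(
        name=str(row["species"]),
        diversity=float(row["diversity"]),
        body_size=float(row["body_size"]),
        trophic_level=float(row["trophic_level"]),
        fecundity=float(row["fecundity"]) if pd.notna(row["fecundity"]) else float("nan"),
        propagule_size=float(row["propagule_size"]),
        maturity=float(row["maturity"]),
        lifespan=float(row["lifespan"]),
        adult_lifespan=float(row["adult_lifespan"]),
        parental_care=str(row["parental_care"]),
        hermaphroditism=str(row["hermaphroditism"]),
    )


def table1_fixture() -> list[SpeciesTraits]:
    """The packaged 16-species trait table as validated records."""
    df = table1_frame()
    return [_row_to_traits(row) for _, row in df.iterrows()]


def table1_frame() -> pd.DataFrame:
    """The packaged 16-species trait table as a DataFrame."""
    with resources.files("agestruct.data").joinpath("table1.tsv").open("rb") as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])


def traits_to_frame(traits: list[SpeciesTraits]) -> pd.DataFrame:
    """Trait records to the TSV-dialect DataFrame."""
    return pd.DataFrame(
        {
            "species": [t.name for t in traits],
            "diversity": [t.diversity for t in traits],
            "body_size": [t.body_size for t in traits],
            "trophic_level": [t.trophic_level for t in traits],
            "fecundity": [t.fecundity for t in traits],
            "propagule_size": [t.propagule_size for t in traits],
            "maturity": [t.maturity for t in traits],
            "lifespan": [t.lifespan for t in traits],
            "adult_lifespan": [t.adult_lifespan for t in traits],
            "parental_care": [t.parental_care for t in traits],
            "hermaphroditism": [t.hermaphroditism for t in traits],
        }
    )


def write_traits_tsv(path, traits: list[SpeciesTraits]) -> None:
    traits_to_frame(traits).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_traits_tsv(path) -> list[SpeciesTraits]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return [_row_to_traits(row) for _, row in df.iterrows()]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_age_length_data(
    growth: GrowthModel,
    ages,
    noise_sd: float,
    n_per_age: int,
    seed: int,
    species: str = "synthetic",
    sex: Literal["m", "f", "both"] = "both",
) -> pd.DataFrame:
    """Noisy age-length observations around a Von Bertalanffy curve.

    Lengths are the growth-curve mean plus independent Gaussian noise of
    standard deviation ``noise_sd`` cm; reproducible under ``seed``.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("ages must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_per_age < 1:
        raise ValueError("n_per_age must be at least 1")
    rng = np.random.default_rng(seed)
    rep_ages = np.repeat(ages, n_per_age)
    lengths = growth.length_at_age(rep_ages) + rng.normal(0.0, noise_sd, rep_ages.size)
    return pd.DataFrame(
        {
            "species": species,
            "sex": sex,
            "age_years": rep_ages,
            "length_cm": lengths,
        }
    )


def default_maturity_rule(lifespan: float) -> float:
    """Default maturity from lifespan: max(0.5, 0.2 * lifespan).

    Loosely mimics the empirical maturity/lifespan ratios of the fixture.
    """
    return max(0.5, 0.2 * lifespan)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Configuration of a synthetic species set.

    ``slope_true`` is the logit-scale effect of adult lifespan on expected
    diversity; ``precision_true`` the beta precision (variance decreases as
    precision grows); ``intercept_true`` the logit-scale intercept.
    """

    n_species: int
    lifespan_range: tuple[float, float] = (3.0, 21.0)
    maturity_rule: Callable[[float], float] = default_maturity_rule
    slope_true: float = -0.10
    intercept_true: float = -4.2
    precision_true: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        lo, hi = self.lifespan_range
        if lo <= 0 or hi <= 0:
            raise ValueError("lifespan_range must be positive")
        if self.precision_true <= 0:
            raise ValueError("precision_true must be positive")


def gen_synthetic_species_set(spec: SyntheticCohortSpec) -> list[SpeciesTraits]:
    """Synthetic species with logit-linear diversity-lifespan dependence.

    Lifespans are drawn uniformly over ``lifespan_range`` (rounded to whole
    years), maturity from ``maturity_rule``, and diversity from a beta
    distribution with mean ``sigmoid(intercept + slope * adult_lifespan)``
    and precision ``precision_true``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.lifespan_range
    lifespans = np.round(rng.uniform(lo, hi, spec.n_species)).clip(1.0)
    if np.unique(lifespans).size < 2:
        raise ValueError(
            "degenerate lifespan range: all sampled lifespans are equal; "
            "widen lifespan_range"
        )
    traits = []
    for i, L in enumerate(lifespans):
        m = min(float(spec.maturity_rule(float(L))), float(L))
        adl = float(L) - m
        mu = 1.0 / (1.0 + np.exp(-(spec.intercept_true + spec.slope_true * adl)))
        a, b = mu * spec.precision_true, (1.0 - mu) * spec.precision_true
        div = float(np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6))
        traits.append(
            SpeciesTraits(
                name=f"synthetic_{i:03d}",
                diversity=div,
                body_size=float(10 + 5 * L),
                trophic_level=3.5,
                fecundity=float(rng.lognormal(5, 2)),
                propagule_size=float(rng.lognormal(0, 0.5)),
                maturity=m,
                lifespan=float(L),
                adult_lifespan=adl,
                parental_care="none",
                hermaphroditism="none",
            )
        )
    return traits
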