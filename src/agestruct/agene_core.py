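"""Lifetime variance in reproductive success and the Ne/N ratio.

Analytic engine in the Hill/Felsenstein tradition for populations with
overlapping generations at stable age structure.  A cohort of ``N1``
newborns per year moves through a life table; age-specific fecundities are
rescaled so every newborn expects exactly two lifetime offspring
(replacement).  The lifetime number of offspring ``K`` then has mean 2 and
variance

    Vk = sum_x d_x * [ sum_{j<=x} phi_j * b_j  +  (K_x - 2)^2 ]

by the law of total variance over the age at death ``x`` (``d_x`` the
probability that ``x`` is the final age, ``K_x`` the cumulative expected
offspring through age ``x``, ``phi_j`` the within-age variance-to-mean
ratio, 1 for Poisson reproduction).  The per-generation effective size is

    Ne = 4 * N1 * T / (Vk + 2)

with ``T`` the generation length (mean age of parents), and the ratio is
reported against the adult census ``N = N1 * sum_{x >= maturity} l_x``.
Because both Ne and N scale with ``N1``, the ratio is independent of it.

A Monte-Carlo cohort simulator provides an independent check of the
analytic moments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .life_tables import LifeTable


@dataclass
class CohortSchedule:
    """Scaled per-age schedule of one sex's cohort.

    ``l_x`` cumulative survivorship (l_1 = 1), ``b_x`` scaled mean offspring
    per year, ``d_x`` probability that age x is the final age, ``K_x``
    cumulative expected lifetime offspring, ``phi_x`` within-age
    variance-to-mean ratio.
    """

    ages: np.ndarray
    l_x: np.ndarray
    b_x: np.ndarray
    d_x: np.ndarray
    K_x: np.ndarray
    phi_x: np.ndarray

    def validate(self, atol: float = 1e-9) -> None:
        assert abs(self.d_x.sum() - 1.0) < atol
        assert abs((self.l_x * self.b_x).sum() - 2.0) < atol
        assert np.all(np.diff(self.K_x) >= -atol)
        assert np.all(self.phi_x >= 0)


@dataclass
class AgeNeResult:
    """Two-sex effective-size summary of a life-table pair."""

    Vk_f: float
    Vk_m: float
    k_bar: float
    T: float
    N1: float
    Ne: float
    N_adult: float
    ratio: float           # Ne / N_adult (per-generation Ne over annual adult census)
    ratio_annual: float    # (Ne / T) / N_adult (annual effective size basis)
    T_f: float = float("nan")
    T_m: float = float("nan")


def scale_fecundities(table: LifeTable, phi: float = 1.0) -> CohortSchedule:
    """Schedule with fecundities rescaled to lifetime replacement.

    ``b_x = C * f_x`` with ``C`` chosen so that ``sum_x l_x b_x = 2``.
    Scaling is invariant to the absolute scale of the input fecundities.
    """
    if phi < 0:
        raise ValueError("phi must be non-negative")
    l = table.survivorship()
    f = table.rel_fecundity
    denom = float((l * f).sum())
    if denom <= 0:
        raise ValueError("all-zero fecundity schedule cannot be scaled")
    b = (2.0 / denom) * f
    d = l - np.append(l[1:], 0.0)
    K = np.cumsum(b)
    return CohortSchedule(
        ages=table.ages.copy(),
        l_x=l,
        b_x=b,
        d_x=d,
        K_x=K,
        phi_x=np.full(table.ages.size, float(phi)),
    )


def generation_length(schedule: CohortSchedule) -> float:
    """Mean age of parents at stable age structure.

    ``T = sum_x x * l_x * b_x / sum_x l_x * b_x`` (denominator 2 after
    scaling).
    """
    return float((schedule.ages * schedule.l_x * schedule.b_x).sum() / 2.0)


def lifetime_rs_moments(schedule: CohortSchedule) -> tuple[float, float]:
    """Mean and variance of lifetime reproductive success.

    Law of total variance over the age at death: within-lifetime
    (accumulated Poisson-like) variance plus between-ages-at-death variance
    of the cumulative means.  The mean is 2 by the replacement scaling.
    """
    k_bar = float((schedule.d_x * schedule.K_x).sum())
    within = np.cumsum(schedule.phi_x * schedule.b_x)
    Vk = float((schedule.d_x * (within + (schedule.K_x - k_bar) ** 2)).sum())
    return k_bar, Vk


def effective_size_ratio(
    table_f: LifeTable,
    table_m: LifeTable | None = None,
    N1: float = 1000.0,
    sex_ratio: float = 0.5,
    phi: float = 1.0,
    adult_census: Literal["mature", "all"] = "mature",
) -> AgeNeResult:
    """Vk, generation length, Ne and Ne/N from a two-sex life-table pair.

    Per-sex schedules are scaled to replacement separately; the combined
    ``Vk`` is the sex-ratio-weighted mean of per-sex variances (both sexes
    share mean 2, so no between-sex mean component arises at a 0.5 ratio),
    ``T`` the weighted mean of per-sex generation lengths, and
    ``Ne = 4 N1 T / (Vk + 2)``.  ``N_adult`` counts individuals at ages at
    or above the (ceiling of the) age at maturity; ``adult_census='all'``
    counts every age class from 1.  The result is invariant to ``N1``.

    Tables of different maximum age are combined by padding the shorter
    table with zero survival (no change to its schedule).
    """
    if N1 <= 0:
        raise ValueError("N1 must be positive")
    if not (0.0 < sex_ratio < 1.0):
        raise ValueError("sex_ratio must lie in (0, 1)")
    if table_m is None:
        table_m = table_f

    sched_f = scale_fecundities(table_f, phi=phi)
    sched_m = scale_fecundities(table_m, phi=phi)
    w_f, w_m = sex_ratio, 1.0 - sex_ratio

    kbar_f, Vk_f = lifetime_rs_moments(sched_f)
    kbar_m, Vk_m = lifetime_rs_moments(sched_m)
    T_f = generation_length(sched_f)
    T_m = generation_length(sched_m)

    Vk = w_f * Vk_f + w_m * Vk_m
    T = w_f * T_f + w_m * T_m
    k_bar = w_f * kbar_f + w_m * kbar_m
    Ne = 4.0 * N1 * T / (Vk + 2.0)

    N_adult = 0.0
    for sched, tab, w in ((sched_f, table_f, w_f), (sched_m, table_m, w_m)):
        if adult_census == "mature":
            mask = sched.ages >= tab.maturity_class
        else:
            mask = np.ones(sched.ages.size, dtype=bool)
        N_adult += N1 * w * float(sched.l_x[mask].sum())
    if N_adult <= 0:
        raise ValueError("adult census is zero; check maturity and survival")

    ratio = Ne / N_adult
    return AgeNeResult(
        Vk_f=Vk_f, Vk_m=Vk_m, k_bar=k_bar, T=T, N1=N1, Ne=Ne,
        N_adult=N_adult, ratio=ratio, ratio_annual=ratio / T,
        T_f=T_f, T_m=T_m,
    )


def monte_carlo_cohort_vk(
    table: LifeTable,
    n: int = 200_000,
    phi: float = 1.0,
    seed: int = 0,
    n_boot: int = 200,
) -> dict:
    """Empirical lifetime reproductive-success moments of a cohort.

    Simulates ``n`` independent individuals through the scaled schedule:
    each year alive at age ``x`` the individual produces ``Poisson(b_x)``
    offspring (``phi = 1``) or exactly ``b_x`` (``phi = 0``), then survives
    to the next age with probability ``s_x``.  Returns empirical mean and
    variance of lifetime totals with bootstrap standard errors.

    This is the independent oracle for `lifetime_rs_moments`; it shares no
    code path with the analytic decomposition.
    """
    if n < 1000:
        raise ValueError("cohort size n must be at least 1000")
    if phi not in (0.0, 1.0):
        raise ValueError("the Monte-Carlo oracle supports phi of 0 or 1 only")
    rng = np.random.default_rng(seed)
    sched = scale_fecundities(table, phi=phi)

    k_tot = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    for i, age in enumerate(sched.ages):
        if not alive.any():
            break
        n_alive = int(alive.sum())
        if phi == 1.0:
            k_tot[alive] += rng.poisson(sched.b_x[i], n_alive)
        else:
            k_tot[alive] += sched.b_x[i]
        survive = rng.random(n_alive) < table.survival[i]
        idx = np.flatnonzero(alive)
        alive[idx[~survive]] = False

    k_bar_emp = float(k_tot.mean())
    Vk_emp = float(k_tot.var(ddof=1))
    boot_mean = np.empty(n_boot)
    boot_var = np.empty(n_boot)
    for b in range(n_boot):
        res = k_tot[rng.integers(0, n, n)]
        boot_mean[b] = res.mean()
        boot_var[b] = res.var(ddof=1)
    return {
        "k_bar": k_bar_emp,
        "Vk": Vk_emp,
        "se_k_bar": float(boot_mean.std(ddof=1)),
        "se_Vk": float(boot_var.std(ddof=1)),
        "n": n,
    }
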