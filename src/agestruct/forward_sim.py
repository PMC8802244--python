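"""Individual-based forward simulator with overlapping generations.

Tracks ``N_total`` diploid individuals carrying two haplotypes of
``L_sites`` biallelic sites.  Each year every individual first reproduces
(parents are sampled proportionally to the age- and sex-specific fecundity
of their life table) and then survives to the next year, or not, with its
age- and sex-specific survival probability; exactly as many newborns are
created as individuals died, so population size is constant by
construction.  Each offspring haplotype is one intact parental haplotype
(no within-locus recombination) plus ``Poisson(mu * L_sites)`` new
mutations that flip the allele at uniformly chosen sites.  The mean
fraction of heterozygous sites per individual is recorded yearly; the
trailing equilibrium window summarizes mutation-drift equilibrium, where
heterozygosity is expected near ``4 * Ne * mu`` for small ``4 Ne mu``.

The year loop is compiled with numba; a single integer seed makes every
trajectory reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

from .life_tables import LifeTable

_EXTINCT = 1
_OK = 0

_POPCOUNT = np.array([bin(i).count("1") for i in range(256)], dtype=np.int64)


@njit(cache=True)
def _year_loop(seed, years, N, L, mu_L, s_f, s_m, fec_f, fec_m, popcnt):
    """Simulate `years` yearly cycles; return (H per year, status, year).

    Haplotypes are bit-packed (8 sites per byte); per-individual
    heterozygous-site counts are maintained incrementally, so recording H
    is O(N) per year.
    """
    np.random.seed(seed)
    omega_f = s_f.shape[0] - 1
    omega_m = s_m.shape[0] - 1
    LB = (L + 7) // 8
    haps = np.zeros((N, 2, LB), dtype=np.uint8)
    het = np.zeros(N, dtype=np.int64)
    ages = np.ones(N, dtype=np.int64)
    sexes = np.zeros(N, dtype=np.uint8)  # 0 female, 1 male
    for i in range(N):
        if np.random.random() < 0.5:
            sexes[i] = 1
        # spread starting ages over the first few classes to soften the
        # initial cohort pulse
        ages[i] = 1 + np.random.randint(0, min(3, omega_f))

    H = np.zeros(years)
    weights = np.empty(N)
    dead = np.empty(N, dtype=np.int64)
    mothers = np.empty(N, dtype=np.int64)
    fathers = np.empty(N, dtype=np.int64)
    f_idx = np.empty(N, dtype=np.int64)
    m_idx = np.empty(N, dtype=np.int64)
    f_cum = np.empty(N)
    m_cum = np.empty(N)
    newhaps = np.empty((N, 2, LB), dtype=np.uint8)
    newhet = np.empty(N, dtype=np.int64)

    for t in range(years):
        # fecundity weights of the pre-death population, by sex
        nf = 0
        nm = 0
        wf_tot = 0.0
        wm_tot = 0.0
        for i in range(N):
            if sexes[i] == 0:
                a = ages[i] if ages[i] <= omega_f else omega_f
                w = fec_f[a]
                wf_tot += w
                f_idx[nf] = i
                f_cum[nf] = wf_tot
                nf += 1
            else:
                a = ages[i] if ages[i] <= omega_m else omega_m
                w = fec_m[a]
                wm_tot += w
                m_idx[nm] = i
                m_cum[nm] = wm_tot
                nm += 1
        if wf_tot <= 0.0 or wm_tot <= 0.0:
            return H, _EXTINCT, t

        # survival draws
        n_dead = 0
        for i in range(N):
            if sexes[i] == 0:
                a = ages[i] if ages[i] <= omega_f else omega_f
                s = s_f[a]
            else:
                a = ages[i] if ages[i] <= omega_m else omega_m
                s = s_m[a]
            if np.random.random() >= s:
                dead[n_dead] = i
                n_dead += 1

        # sample parents (pre-death population; dying parents still breed)
        for d in range(n_dead):
            u = np.random.random() * wf_tot
            mothers[d] = f_idx[min(np.searchsorted(f_cum[:nf], u), nf - 1)]
            u = np.random.random() * wm_tot
            fathers[d] = m_idx[min(np.searchsorted(m_cum[:nm], u), nm - 1)]

        # stage newborn haplotypes and their heterozygosity counts
        for d in range(n_dead):
            hm = np.random.randint(0, 2)
            hf = np.random.randint(0, 2)
            hcount = 0
            for j in range(LB):
                a = haps[mothers[d], hm, j]
                b = haps[fathers[d], hf, j]
                newhaps[d, 0, j] = a
                newhaps[d, 1, j] = b
                hcount += popcnt[a ^ b]
            for h in range(2):
                n_mut = np.random.poisson(mu_L)
                for _ in range(n_mut):
                    site = np.random.randint(0, L)
                    j = site >> 3
                    mask = np.uint8(1 << (site & 7))
                    same = (newhaps[d, 0, j] & mask) == (newhaps[d, 1, j] & mask)
                    newhaps[d, h, j] ^= mask
                    if same:
                        hcount += 1
                    else:
                        hcount -= 1
            newhet[d] = hcount

        # age survivors, insert newborns
        for i in range(N):
            ages[i] += 1
        for d in range(n_dead):
            i = dead[d]
            for j in range(LB):
                haps[i, 0, j] = newhaps[d, 0, j]
                haps[i, 1, j] = newhaps[d, 1, j]
            het[i] = newhet[d]
            ages[i] = 1
            sexes[i] = 1 if np.random.random() < 0.5 else 0

        # record mean individual heterozygosity
        tot = 0
        for i in range(N):
            tot += het[i]
        H[t] = tot / (N * L)

    return H, _OK, years


@dataclass
class SimConfig:
    """Forward-simulation settings.

    ``mu`` is the mutation rate per site per birth (per generation);
    ``eq_window`` the number of trailing years averaged for the equilibrium
    summary.
    """

    table_f: LifeTable
    table_m: LifeTable | None = None
    N_total: int = 2000
    mu: float = 1e-7
    L_sites: int = 10_000
    years_total: int = 100_000
    eq_window: int = 10_000
    replicates: int = 50
    seed: int = 0
    ignore_maturity: bool = True

    def __post_init__(self) -> None:
        if self.table_m is None:
            self.table_m = self.table_f
        if self.N_total < 10:
            raise ValueError("N_total must be at least 10")
        if self.eq_window >= self.years_total:
            raise ValueError("eq_window must be shorter than years_total")


def _sim_arrays(table: LifeTable, ignore_maturity: bool) -> tuple[np.ndarray, np.ndarray]:
    s = np.concatenate([[0.0], table.survival]).astype(np.float64)
    f = np.concatenate([[0.0], table.rel_fecundity]).astype(np.float64)
    if ignore_maturity:
        nz = np.nonzero(f)[0]
        if nz.size and nz[0] > 1:
            f[1:nz[0]] = f[nz[0]]
    return s, f


@dataclass
class DiversityTrajectory:
    """Yearly mean heterozygosity with an equilibrium summary."""

    H: np.ndarray
    eq_mean: float
    eq_sd: float
    converged: bool
    replicate: int
    seed: int
    equilibrated: bool = True
    meta: dict = field(default_factory=dict)


def equilibrium_summary(H, window: int) -> dict:
    """Trailing-window mean, SD and a no-trend convergence flag.

    The flag is a two-sided t-test of the linear trend inside the window at
    the 5% level (a flat or stationary trajectory passes).
    """
    H = np.asarray(H, dtype=float)
    if window > H.size:
        raise ValueError("window is longer than the trajectory")
    tail = H[-window:]
    mean = float(tail.mean())
    sd = float(tail.std(ddof=1)) if window > 1 else 0.0
    if sd <= 1e-12 * max(abs(mean), 1.0):
        return {"mean": mean, "sd": 0.0, "converged": True, "trend_p": 1.0}
    res = stats.linregress(np.arange(window), tail)
    return {
        "mean": mean,
        "sd": sd,
        "converged": bool(res.pvalue > 0.05),
        "trend_p": float(res.pvalue),
    }


def simulate_diversity(config: SimConfig, replicate: int = 0) -> DiversityTrajectory:
    """One forward replicate under `config`.

    Raises RuntimeError if the population loses all reproductive capacity
    (both-sex fecundity extinction).
    """
    s_f, fec_f = _sim_arrays(config.table_f, config.ignore_maturity)
    s_m, fec_m = _sim_arrays(config.table_m, config.ignore_maturity)
    seed = (config.seed + 1_000_003 * replicate) % (2**31 - 1)
    H, status, t_stop = _year_loop(
        seed, config.years_total, config.N_total, config.L_sites,
        config.mu * config.L_sites, s_f, s_m, fec_f, fec_m, _POPCOUNT,
    )
    if status == _EXTINCT:
        raise RuntimeError(
            f"population lost all reproductive capacity in year {t_stop}; "
            "check fecundity schedules and N_total"
        )
    summ = equilibrium_summary(H, config.eq_window)
    burn = config.years_total - config.eq_window
    return DiversityTrajectory(
        H=H,
        eq_mean=summ["mean"],
        eq_sd=summ["sd"],
        converged=summ["converged"],
        replicate=replicate,
        seed=seed,
        equilibrated=burn >= 8 * config.N_total,
        meta={"trend_p": summ["trend_p"], "burn_in_years": burn},
    )


def simulate_replicates(config: SimConfig) -> dict:
    """All replicates plus the replicate-level equilibrium summary."""
    trajs = [simulate_diversity(config, r) for r in range(config.replicates)]
    means = np.array([t.eq_mean for t in trajs])
    return {
        "trajectories": trajs,
        "eq_mean": float(means.mean()),
        "eq_se": float(means.std(ddof=1) / np.sqrt(means.size)) if means.size > 1 else 0.0,
        "eq_means": means,
    }


def wright_fisher_control(
    N: int,
    mu: float,
    L_sites: int,
    years: int,
    replicates: int,
    seed: int,
    eq_window: int | None = None,
) -> dict:
    """Age-structure-free control: one age class, equal reproduction.

    Every individual reproduces with equal weight and dies after one year,
    so years coincide with generations and the expected equilibrium
    heterozygosity is ``4 N mu`` for ``4 N mu << 1``.
    """
    wf_table = LifeTable(
        ages=np.array([1]), survival=np.array([0.0]),
        rel_fecundity=np.array([1.0]), maturity=1.0, sex="both",
    )
    window = eq_window if eq_window is not None else max(years // 5, 1)
    config = SimConfig(
        table_f=wf_table, table_m=wf_table, N_total=N, mu=mu, L_sites=L_sites,
        years_total=years, eq_window=window, replicates=replicates, seed=seed,
    )
    out = simulate_replicates(config)
    out["theta"] = 4.0 * N * mu
    out["equilibrated"] = all(t.equilibrated for t in out["trajectories"])
    return out
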