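"""End-to-end orchestration: empirical, grid and forward stages.

Every stage takes a configuration mapping (usually loaded from YAML),
writes TSV outputs with a provenance header (config hash, seed, package
version) and returns the in-memory results.  Deterministic stages are
byte-reproducible under identical configurations.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agene_core import effective_size_ratio
from .forward_sim import SimConfig, simulate_replicates
from .grid_scan import GridSpec, scan_grid
from .inference_stats import fit_beta_regression
from .life_tables import (
    enumerate_toggle_models,
    read_life_table_tsv,
    toggle_life_table_components,
)
from .synthetic_data import table1_fixture

logger = logging.getLogger("agestruct")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _provenance(config: dict) -> str:
    return (
        f"# agestruct {__version__}\n"
        f"# config_hash: {config_hash(config)}\n"
        f"# seed: {config.get('seed', 'none')}\n"
    )


def _write_tsv(path: Path, df: pd.DataFrame, config: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", index=False)


def run_empirical(config: dict, out_dir: str | Path) -> pd.DataFrame:
    """Toggle-model Ne/N per species plus diversity regressions.

    For each of the 16 component-toggle life-table models, computes Ne/N
    for every species with available life-table inputs, then regresses
    max-scaled observed diversity on max-scaled Ne/N (beta regression,
    refitted on the scaled response) for all species and for nonbrooders
    only.  Species without life-table inputs are skipped with a warning.
    """
    t0 = time.time()
    out_dir = Path(out_dir)
    traits = {t.name: t for t in table1_fixture()}
    tables_dir = config.get("tables_dir")
    species_tables = {}
    if tables_dir:
        for path in sorted(Path(tables_dir).glob("*.tsv")):
            name = path.stem.replace("_", " ")
            try:
                species_tables[name] = read_life_table_tsv(path)
            except Exception as exc:  # degraded inputs are reported, not fatal
                logger.warning("could not read life table %s: %s", path, exc)
    missing = sorted(set(traits) - set(species_tables))
    if missing:
        logger.warning("no life-table inputs for %d species: %s", len(missing), missing)

    shared_max = max(int(t.lifespan) for t in traits.values())
    N1 = float(config.get("n1", 1000.0))
    phi = float(config.get("phi", 1.0))
    sex_ratio = float(config.get("sex_ratio", 0.5))

    rows = []
    for model in enumerate_toggle_models():
        for name, trait in traits.items():
            tabs = species_tables.get(name)
            if tabs is None and any(
                model["toggles"][k] for k in ("age_survival", "age_fecundity", "sex_specific")
            ):
                continue
            species = {
                "maturity": trait.maturity,
                "lifespan": int(trait.lifespan),
                "table_f": (tabs or {}).get("female") or (tabs or {}).get("both"),
                "table_m": (tabs or {}).get("male") or (tabs or {}).get("both"),
            }
            pair = toggle_life_table_components(
                species, model["toggles"], shared_max_lifespan=shared_max
            )
            res = effective_size_ratio(
                pair["female"], pair["male"], N1=N1, sex_ratio=sex_ratio, phi=phi
            )
            rows.append(
                {
                    "model_id": model["model_id"],
                    "species": name,
                    "diversity": trait.diversity,
                    "brooder": trait.is_brooder,
                    "Vk_f": res.Vk_f,
                    "Vk_m": res.Vk_m,
                    "T": res.T,
                    "Ne": res.Ne,
                    "N_adult": res.N_adult,
                    "ratio": res.ratio,
                }
            )
    results = pd.DataFrame(rows)
    _write_tsv(out_dir / "toggle_ratios.tsv", results, config)

    # scaled beta regressions per model
    reg_rows = []
    for model_id, grp in results.groupby("model_id"):
        for subset, sub in (("all", grp), ("nonbrooders", grp[~grp["brooder"]])):
            if len(sub) < 3:
                continue
            y = (sub["diversity"] / sub["diversity"].max()).to_numpy()
            x = (sub["ratio"] / sub["ratio"].max()).to_numpy()
            # max-scaling puts one observation on the boundary; compress
            # into (0,1) before the beta refit (Smithson-Verkuilen)
            n_obs = y.size
            y = (y * (n_obs - 1) + 0.5) / n_obs
            try:
                fit = fit_beta_regression(y, np.column_stack([np.ones(len(sub)), x]))
                reg_rows.append(
                    {
                        "model_id": model_id,
                        "subset": subset,
                        "slope": fit.coefficients[1],
                        "pseudo_R2": fit.pseudo_R2,
                        "p": fit.wald_p[1],
                        "n": fit.n,
                    }
                )
            except (RuntimeError, ValueError) as exc:
                logger.warning("regression failed (model %s, %s): %s", model_id, subset, exc)
    regs = pd.DataFrame(reg_rows)
    _write_tsv(out_dir / "toggle_regressions.tsv", regs, config)
    logger.info("run_empirical: %d models in %.1fs", results["model_id"].nunique(), time.time() - t0)
    return results


def run_grid(config: dict, out_dir: str | Path) -> pd.DataFrame:
    """Grid scan stage; writes the long-format surface TSV."""
    t0 = time.time()
    out_dir = Path(out_dir)
    kwargs = {}
    if "c_values" in config:
        kwargs["c_values"] = np.asarray(config["c_values"], dtype=float)
    if "f_values" in config:
        kwargs["f_values"] = np.asarray(config["f_values"], dtype=float)
    if "fecundity_model" in config:
        kwargs["fecundity_model"] = config["fecundity_model"]
    if "ratio_basis" in config:
        kwargs["ratio_basis"] = config["ratio_basis"]
    if "species_set" in config:
        kwargs["species_set"] = [tuple(p) for p in config["species_set"]]
    surface = scan_grid(GridSpec(**kwargs))
    _write_tsv(out_dir / "grid_surface.tsv", surface.table, config)
    logger.info("run_grid: %d cells in %.1fs", len(surface.table), time.time() - t0)
    return surface.table


def run_forward(config: dict, out_dir: str | Path) -> dict:
    """Forward-simulation stage; writes per-replicate trajectories."""
    from .life_tables import AgeFecundityModel, build_theoretical_life_table

    t0 = time.time()
    out_dir = Path(out_dir)
    if "c" in config:
        table = build_theoretical_life_table(
            float(config.get("maturity", 1.0)),
            int(config["lifespan"]),
            float(config["c"]),
            AgeFecundityModel(config.get("fecundity_model", "constant"), f=float(config.get("f", 0.0))),
        )
    else:
        tabs = read_life_table_tsv(config["table"])
        table = tabs.get("both") or tabs.get("female")
    sim = SimConfig(
        table_f=table,
        N_total=int(config.get("n_total", 500)),
        mu=float(config.get("mu", 4e-7)),
        L_sites=int(config.get("l_sites", 10_000)),
        years_total=int(config.get("years", 20_000)),
        eq_window=int(config.get("window", 4_000)),
        replicates=int(config.get("replicates", 2)),
        seed=int(config.get("seed", 0)),
    )
    out = simulate_replicates(sim)
    for traj in out["trajectories"]:
        df = pd.DataFrame({"year": np.arange(1, traj.H.size + 1), "H": traj.H})
        _write_tsv(out_dir / f"trajectory_rep{traj.replicate}.tsv", df, config)
    summary = pd.DataFrame(
        {
            "replicate": [t.replicate for t in out["trajectories"]],
            "eq_mean": [t.eq_mean for t in out["trajectories"]],
            "eq_sd": [t.eq_sd for t in out["trajectories"]],
            "converged": [t.converged for t in out["trajectories"]],
            "seed": [t.seed for t in out["trajectories"]],
        }
    )
    _write_tsv(out_dir / "forward_summary.tsv", summary, config)
    logger.info("run_forward: %d replicates in %.1fs", sim.replicates, time.time() - t0)
    return out
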