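"""Named end-to-end experiments and the flat config dialect.

The bundled scenarios wire the canonical node/internode parameter sets
through each engine:

* ``fig1_six_phospho_mc``  — Monte Carlo, six-state + phospho overlay
* ``fig3_eight_pde``       — PDE equilibrium, eight-state
* ``fig5_eight_mc``        — Monte Carlo, eight-state
* ``fig2_ratio_curves``    — analytic mixture ratio vs speed factor n
* ``fig6_fig7_surfaces``   — eight-state ratio vs gamma_on2 scaling and r

Parameter sets travel as flat key–value YAML; ``canonical_defaults()``
returns the bundled canonical values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .kinetics import (
    EightStateRates,
    KineticRates,
    PhosphoKinetics,
    SixPhosphoRates,
    mm_per_day_to_um_per_s,
)
from .mc import McConfig, replicate_seeds, run_axon, write_census_csv
from .pde import Grid, field_to_csv, run_to_equilibrium
from .rate_design import (
    AxonGeometry,
    SpatialRateProfile,
    build_profile,
    gamma_on2_from_velocity,
    ratio_curve_table,
)
from .summarize import (
    plot_distribution,
    summarize_census,
    summarize_field,
    write_bin_csv,
    write_summary_json,
)

__all__ = [
    "Scenario",
    "SCENARIOS",
    "load_config",
    "dump_config",
    "canonical_defaults",
    "base_rates_from_config",
    "canonical_geometry",
    "canonical_profile_six_phospho",
    "canonical_profile_eight",
    "profile_to_config",
    "profile_from_config",
    "run_scenario",
]

logger = logging.getLogger("nfsim")


# ---------------------------------------------------------------------------
# config dialect
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Read a flat key–value YAML/JSON parameter file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def canonical_defaults() -> dict:
    """The bundled canonical parameter set (rates in s^-1, speeds um/s)."""
    ref = resources.files("nfsim").joinpath("data/canonical_defaults.yaml")
    with ref.open() as fh:
        return yaml.safe_load(fh)


def base_rates_from_config(cfg: dict, gamma_on: float | None = None) -> KineticRates:
    return KineticRates(
        gamma_10=cfg["gamma_10"],
        gamma_01=cfg["gamma_01"],
        gamma_on=gamma_on if gamma_on is not None else cfg["gamma_on_internode"],
        gamma_off=cfg["gamma_off"],
        gamma_ar=cfg["gamma_ar"],
        gamma_ra=cfg["gamma_ra"],
        v_a=cfg["v_a"],
        v_r=cfg["v_r"],
    )


def canonical_geometry(cfg: dict | None = None) -> AxonGeometry:
    cfg = cfg or canonical_defaults()
    return AxonGeometry(
        length=cfg["axon_length"],
        node_start=cfg["node_start"],
        node_end=cfg["node_end"],
    )


def canonical_profile_six_phospho(cfg: dict | None = None) -> SpatialRateProfile:
    """Canonical six-with-phospho profile: the on-track rate is selected by
    the phospho label; node and internode differ only in the phospho
    rates (0.8/0.1 swapped)."""
    cfg = cfg or canonical_defaults()
    base = base_rates_from_config(cfg)
    common = dict(
        base=base,
        gamma_on_ph=cfg["gamma_on_internode"],
        gamma_on_de=cfg["gamma_on_node"],
    )
    internode = SixPhosphoRates(
        phospho=PhosphoKinetics(
            gamma_ph=cfg["gamma_ph_internode"], gamma_de=cfg["gamma_de_internode"]
        ),
        **common,
    )
    node = SixPhosphoRates(
        phospho=PhosphoKinetics(
            gamma_ph=cfg["gamma_ph_node"], gamma_de=cfg["gamma_de_node"]
        ),
        **common,
    )
    return build_profile(canonical_geometry(cfg), node, internode)


def canonical_profile_eight(
    cfg: dict | None = None, reconstruct: bool = True
) -> SpatialRateProfile:
    """Canonical eight-state profile.

    With ``reconstruct`` (default) the dephosphorylated on-track rate
    ``gamma_on2`` of each region is recomputed from the target regional
    velocities (the continuity-equation construction); otherwise the
    quoted values are used directly.
    """
    cfg = cfg or canonical_defaults()
    base = base_rates_from_config(cfg)
    ph_inter = PhosphoKinetics(
        gamma_ph=cfg["gamma_ph_internode"], gamma_de=cfg["gamma_de_internode"]
    )
    ph_node = PhosphoKinetics(
        gamma_ph=cfg["gamma_ph_node"], gamma_de=cfg["gamma_de_node"]
    )
    gon1 = cfg["gamma_on1"]
    if reconstruct:
        v_inter = mm_per_day_to_um_per_s(cfg["v_internode_mm_day"])
        v_node = cfg["v_node_factor"] * v_inter
        gon2_inter = gamma_on2_from_velocity(v_inter, base, ph_inter, gon1)
        gon2_node = gamma_on2_from_velocity(v_node, base, ph_node, gon1)
    else:
        gon2_inter = cfg["gamma_on2_internode"]
        gon2_node = cfg["gamma_on2_node"]
    internode = EightStateRates(
        base=base, gamma_on1=gon1, gamma_on2=gon2_inter, phospho=ph_inter
    )
    node = EightStateRates(
        base=base, gamma_on1=gon1, gamma_on2=gon2_node, phospho=ph_node
    )
    return build_profile(canonical_geometry(cfg), node, internode)


def profile_to_config(profile: SpatialRateProfile) -> dict:
    """Flatten a spatial rate profile into the key-value config dialect."""
    g = profile.geometry
    cfg = {
        "variant": profile.variant,
        "axon_length": g.length,
        "node_start": g.node_start,
        "node_end": g.node_end,
    }
    for region in ("internode", "node"):
        r = profile.rates_for(region)
        base = r if isinstance(r, KineticRates) else r.base
        cfg.update(
            {
                "gamma_10": base.gamma_10,
                "gamma_01": base.gamma_01,
                "gamma_off": base.gamma_off,
                "gamma_ar": base.gamma_ar,
                "gamma_ra": base.gamma_ra,
                "v_a": base.v_a,
                "v_r": base.v_r,
            }
        )
        if isinstance(r, KineticRates):
            cfg[f"gamma_on_{region}"] = r.gamma_on
        elif isinstance(r, SixPhosphoRates):
            cfg[f"gamma_ph_{region}"] = r.phospho.gamma_ph
            cfg[f"gamma_de_{region}"] = r.phospho.gamma_de
            cfg["gamma_on_internode"] = r.gamma_on_ph
            cfg["gamma_on_node"] = r.gamma_on_de
            cfg["exchange_off_track"] = r.exchange_off_track
        else:  # EightStateRates
            cfg[f"gamma_ph_{region}"] = r.phospho.gamma_ph
            cfg[f"gamma_de_{region}"] = r.phospho.gamma_de
            cfg["gamma_on1"] = r.gamma_on1
            cfg[f"gamma_on2_{region}"] = r.gamma_on2
    return cfg


def profile_from_config(cfg: dict) -> SpatialRateProfile:
    """Rebuild a spatial rate profile from the key-value config dialect."""
    variant = cfg.get("variant", "eight")
    geometry = AxonGeometry(
        length=cfg["axon_length"],
        node_start=cfg["node_start"],
        node_end=cfg["node_end"],
    )
    base = base_rates_from_config({**cfg, "gamma_on_internode": cfg.get(
        "gamma_on_internode", KineticRates().gamma_on
    )})
    if variant == "six":
        internode = replace_gamma_on(base, cfg["gamma_on_internode"])
        node = replace_gamma_on(base, cfg["gamma_on_node"])
    elif variant == "six_phospho":
        common = dict(
            base=base,
            gamma_on_ph=cfg["gamma_on_internode"],
            gamma_on_de=cfg["gamma_on_node"],
            exchange_off_track=cfg.get("exchange_off_track", False),
        )
        internode = SixPhosphoRates(
            phospho=PhosphoKinetics(
                cfg["gamma_ph_internode"], cfg["gamma_de_internode"]
            ),
            **common,
        )
        node = SixPhosphoRates(
            phospho=PhosphoKinetics(cfg["gamma_ph_node"], cfg["gamma_de_node"]),
            **common,
        )
    elif variant == "eight":
        internode = EightStateRates(
            base=base,
            gamma_on1=cfg["gamma_on1"],
            gamma_on2=cfg["gamma_on2_internode"],
            phospho=PhosphoKinetics(
                cfg["gamma_ph_internode"], cfg["gamma_de_internode"]
            ),
        )
        node = EightStateRates(
            base=base,
            gamma_on1=cfg["gamma_on1"],
            gamma_on2=cfg["gamma_on2_node"],
            phospho=PhosphoKinetics(cfg["gamma_ph_node"], cfg["gamma_de_node"]),
        )
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return build_profile(geometry, node, internode)


def replace_gamma_on(base: KineticRates, gamma_on: float) -> KineticRates:
    return base.with_gamma_on(gamma_on)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    name: str
    variant: str
    engine: str  # analytic | pde | mc
    description: str
    params: dict = field(default_factory=dict)


SCENARIOS = {
    s.name: s
    for s in [
        Scenario(
            "fig1_six_phospho_mc",
            "six_phospho",
            "mc",
            "NF distribution along the axon, six-state chain with "
            "phosphorylation overlay (Monte Carlo)",
        ),
        Scenario(
            "fig3_eight_pde",
            "eight",
            "pde",
            "Equilibrium NF distribution of the eight-state chain (PDE)",
        ),
        Scenario(
            "fig5_eight_mc",
            "eight",
            "mc",
            "NF distribution along the axon, eight-state chain (Monte Carlo)",
        ),
        Scenario(
            "fig2_ratio_curves",
            "six_phospho",
            "analytic",
            "Node:internode velocity ratio of the phospho mixture vs the "
            "bare speed factor n, for several phospho-rate ratios r",
        ),
        Scenario(
            "fig6_fig7_surfaces",
            "eight",
            "analytic",
            "Eight-state node:internode velocity ratio vs gamma_on2 "
            "scaling and vs r",
        ),
    ]
}


def _run_mc_scenario(scenario, out_dir: Path, seed: int, n_replicates, overrides):
    if scenario.variant == "six_phospho":
        profile = canonical_profile_six_phospho()
    else:
        profile = canonical_profile_eight()
    cfg_kwargs = dict(seed=seed)
    if n_replicates is not None:
        cfg_kwargs["n_replicates"] = n_replicates
    for key in ("t_total", "burn_in", "t_observe", "dt", "injection_interval"):
        if key in overrides:
            cfg_kwargs[key] = overrides[key]
    config = McConfig(**cfg_kwargs)
    census = run_axon(config, profile)
    summary = summarize_census(census)
    write_summary_json(summary, out_dir / "summary.json")
    write_bin_csv(summary, out_dir / "bins.csv")
    write_census_csv(census, out_dir / "census.csv")
    plot_distribution(summary, out_dir / "distribution.png")
    meta = {
        "scenario": scenario.name,
        "seed": seed,
        "replicate_seeds": [int(x) for x in replicate_seeds(seed, config.n_replicates)],
        "n_replicates": config.n_replicates,
        "profile": profile_to_config(profile),
        "velocity_ratio": summary.velocity_ratio,
        "population_ratio": summary.population_ratio,
        "continuity_residual": summary.continuity_residual,
        "converged": True,
    }
    return meta, summary


def _run_pde_scenario(scenario, out_dir: Path, overrides):
    profile = canonical_profile_eight()
    grid = Grid(
        length=profile.geometry.length,
        dx=overrides.get("dx", 0.1),
        dt=overrides.get("dt", 0.1),
    )
    result = run_to_equilibrium(
        profile,
        grid,
        influx_rate=overrides.get("influx_rate", 1.0),
        t_max=overrides.get("t_max", 3.6e5),
        tol=overrides.get("tol", 1e-6),
    )
    summary = summarize_field(result.field, profile)
    write_summary_json(summary, out_dir / "summary.json")
    write_bin_csv(summary, out_dir / "bins.csv")
    field_to_csv(result.field, out_dir / "field.csv")
    plot_distribution(summary, out_dir / "distribution.png")
    meta = {
        "scenario": scenario.name,
        "grid": {"dx": grid.dx, "dt": grid.dt, "n_cells": grid.n_cells},
        "profile": profile_to_config(profile),
        "converged": result.converged,
        "t_end": result.t_end,
        "max_window_change": result.max_window_change,
        "velocity_ratio": summary.velocity_ratio,
        "population_ratio": summary.population_ratio,
        "continuity_residual": summary.continuity_residual,
    }
    return meta, summary


def _run_analytic_scenario(scenario, out_dir: Path):
    if scenario.name == "fig2_ratio_curves":
        table = ratio_curve_table(
            r_values=[8.0, 9.0, 10.0], x_values=np.arange(1.0, 101.0), kind="six"
        )
        table.to_csv(out_dir / "curves.csv", index=False)
        meta = {"scenario": scenario.name, "rows": len(table), "converged": True}
    else:
        b = 4.98e-3
        fig6 = ratio_curve_table(
            r_values=[2.0, 4.0, 8.0, 16.0, 30.0],
            x_values=b * np.linspace(1.0, 10.0, 19),
            kind="eight",
        )
        fig6.to_csv(out_dir / "surface_gamma_on2.csv", index=False)
        frames = []
        for node_scale in (0.5, 1.0, 2.0, 5.0, 10.0):
            t = ratio_curve_table(
                r_values=np.linspace(1.0, 40.0, 40),
                x_values=[b],
                kind="eight",
                node_scale=node_scale,
            )
            t["node_scale"] = node_scale
            frames.append(t)
        import pandas as pd

        pd.concat(frames, ignore_index=True).to_csv(
            out_dir / "surface_r.csv", index=False
        )
        meta = {"scenario": scenario.name, "converged": True}
    return meta, None


def run_scenario(
    name_or_config,
    out_dir,
    seed: int = 0,
    n_replicates: int | None = None,
    **overrides,
):
    """Execute a bundled scenario (by name or config mapping/file).

    Writes ``summary.json``/CSV/figure artifacts plus ``run_meta.json``
    into ``out_dir`` and returns the metadata dict (whose ``converged``
    flag the CLI maps onto its exit status).
    """
    if isinstance(name_or_config, dict):
        cfg = dict(name_or_config)
        name = cfg.pop("scenario", None)
    elif str(name_or_config) in SCENARIOS:
        name = str(name_or_config)
        cfg = {}
    elif Path(str(name_or_config)).exists():
        cfg = load_config(name_or_config)
        name = cfg.pop("scenario", None)
    else:
        name = str(name_or_config)
        cfg = {}
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        )
    unknown = set(cfg) - {
        "seed",
        "n_replicates",
        "t_total",
        "burn_in",
        "t_observe",
        "dt",
        "dx",
        "t_max",
        "tol",
        "influx_rate",
        "injection_interval",
    }
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    seed = cfg.pop("seed", seed)
    n_replicates = cfg.pop("n_replicates", n_replicates)
    overrides = {**cfg, **overrides}

    scenario = SCENARIOS[name]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("running scenario %s -> %s", name, out_dir)
    if scenario.engine == "mc":
        meta, _ = _run_mc_scenario(scenario, out_dir, seed, n_replicates, overrides)
    elif scenario.engine == "pde":
        meta, _ = _run_pde_scenario(scenario, out_dir, overrides)
    else:
        meta, _ = _run_analytic_scenario(scenario, out_dir)
    with open(out_dir / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    logger.info("scenario %s done: %s", name, meta)
    return meta
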