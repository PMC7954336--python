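"""Stochastic per-particle simulation of NF transport along the axon.

Each NF is an independent continuous-time Markov walker: a fixed-step
kinetic Monte Carlo scheme (one candidate transition per step, sampled
from the per-transition probabilities ``rate * dt``) moves particles
between states, while running states advance the position by ``v * dt``
using the rate set at the pre-step position.  NFs are injected at the
proximal end in the running-anterograde state at a fixed interval and
removed once they leave the axon.  Replicates run on independent RNG
streams derived from one seed, so results do not depend on scheduling.

The per-replicate inner loop is compiled with numba; the scalar
:func:`step_particle` is the uncompiled reference used by the unit
tests — both consume the same transition tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from numba import njit

from .kinetics import (
    ConfigurationError,
    RateSet,
    StateDistribution,
    mean_velocity,
    state_labels,
    state_velocities,
    steady_state_numeric,
    transition_matrix,
)
from .rate_design import SpatialRateProfile

__all__ = [
    "Particle",
    "McConfig",
    "McCensus",
    "step_particle",
    "run_axon",
    "default_burn_in",
    "injection_state_index",
    "transition_tables",
    "replicate_seeds",
    "write_census_csv",
]

#: per-step transition probability ceiling for the first-order scheme
_MAX_STEP_PROB = 0.1


@dataclass
class Particle:
    """One NF walker: position (um), state index, and in-domain flag."""

    position: float
    state: int
    alive: bool = True


@dataclass(frozen=True)
class McConfig:
    """Protocol parameters of the particle simulation.

    ``burn_in`` and ``t_total`` default to ``None`` and are then derived
    from the profile: burn-in is the internode transit time plus five
    off-track pool turnover times (see :func:`default_burn_in`), and
    ``t_total`` adds ``t_observe`` seconds of sampling on top.
    """

    injection_interval: float = 10.0
    n_replicates: int = 300
    t_total: Optional[float] = None
    burn_in: Optional[float] = None
    t_observe: float = 6000.0
    dt: float = 0.1
    seed: int = 0
    bin_width: float = 2.0
    sample_interval: float = 10.0
    inject_phospho: str = "de"
    exclude_boundary_zones: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.injection_interval <= 0:
            raise ConfigurationError("dt and injection_interval must be > 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.inject_phospho not in ("ph", "de"):
            raise ConfigurationError("inject_phospho must be 'ph' or 'de'")


@dataclass
class McCensus:
    """Time-averaged census of all replicates.

    ``bin_counts``: (n_replicates, n_bins) mean NF count per spatial bin;
    ``region_state_counts``: (n_replicates, 2, n_states) mean counts per
    region (0 = internode, 1 = node) and state, tallied over the region
    interiors (one bin width trimmed at every domain and region boundary
    unless ``exclude_boundary_zones`` is off, so that the occupancy and
    population estimators sample the same cells); bookkeeping totals
    check particle conservation.
    """

    config: McConfig
    profile: SpatialRateProfile
    labels: tuple
    bin_counts: np.ndarray
    bin_state_counts: np.ndarray
    region_state_counts: np.ndarray
    n_injected: np.ndarray
    n_removed: np.ndarray
    n_alive: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.bin_counts.shape[1]

    def mean_bin_counts(self) -> np.ndarray:
        return self.bin_counts.mean(axis=0)

    def sd_bin_counts(self) -> np.ndarray:
        return self.bin_counts.std(axis=0, ddof=1)

    def region_fractions(self, region: str) -> StateDistribution:
        """Mean per-state occupancy fractions in ``'internode'``/``'node'``."""
        reg = {"internode": 0, "node": 1}[region]
        counts = self.region_state_counts[:, reg, :].mean(axis=0)
        total = counts.sum()
        if total <= 0:
            raise ConfigurationError(f"no particles observed in {region}")
        return StateDistribution(
            labels=self.labels,
            probabilities=counts / total,
            model_variant=self.profile.variant,
        )


# ---------------------------------------------------------------------------
# transition tables
# ---------------------------------------------------------------------------

def transition_tables(profile: SpatialRateProfile) -> tuple:
    """(labels, velocities, trans) for a profile.

    ``trans[region, s_from, s_to]`` is the off-diagonal transition rate,
    region 0 = internode, 1 = node.
    """
    labels = state_labels(profile.internode_rates)

    def table(rates: RateSet) -> np.ndarray:
        M = transition_matrix(rates)
        T = M.T.copy()
        np.fill_diagonal(T, 0.0)
        return T

    trans = np.stack([table(profile.internode_rates), table(profile.node_rates)])
    velocities = state_velocities(profile.internode_rates)
    return labels, velocities, trans


def injection_state_index(profile: SpatialRateProfile, inject_phospho: str = "de") -> int:
    """Index of the running-anterograde state at injection.

    In the six-with-phospho variant newly entering NFs carry the chosen
    phospho label (dephosphorylated by default — NFs become highly
    phosphorylated only after entering the axon).
    """
    labels = state_labels(profile.internode_rates)
    target = f"Pa_{inject_phospho}" if profile.variant == "six_phospho" else "Pa"
    return labels.index(target)


def _validate_dt(trans: np.ndarray, dt: float) -> None:
    exit_rates = trans.sum(axis=2)
    worst = float(exit_rates.max())
    if worst * dt > _MAX_STEP_PROB + 1e-12:
        raise ConfigurationError(
            f"dt={dt} too large: max total exit rate {worst:.4g}/s gives "
            f"per-step probability {worst * dt:.3f} > {_MAX_STEP_PROB}"
        )


def default_burn_in(profile: SpatialRateProfile) -> float:
    """Burn-in estimate: internode transit time + 5 off-track turnovers.

    The axon fills advectively in ``length / vbar_internode`` seconds,
    but the census equilibrates only once the off-track pool has turned
    over; the pool turnover time is its steady-state occupancy divided by
    the steady-state flux into it.  Five turnovers leave <1% residual.
    """
    rates = profile.internode_rates
    v = mean_velocity(rates)
    transit = profile.geometry.length / v if v > 0 else 0.0
    dist = steady_state_numeric(rates)
    M = transition_matrix(rates)
    labels = state_labels(rates)
    off = np.array([lab.startswith(("Pap", "Prp")) for lab in labels])
    p = dist.probabilities
    p_off = p[off].sum()
    influx = float((M[np.ix_(off, ~off)] @ p[~off]).sum()) if off.any() else 0.0
    turnover = p_off / influx if influx > 0 else 0.0
    return transit + 5.0 * turnover


# ---------------------------------------------------------------------------
# single-particle stepping (reference implementation)
# ---------------------------------------------------------------------------

def step_particle(
    particle: Particle,
    profile: SpatialRateProfile,
    dt: float,
    rng: np.random.Generator,
    tables: tuple | None = None,
) -> Particle:
    """Advance one particle by one step (position first, then at most one
    state transition, both using the pre-step position's rate set)."""
    if not particle.alive:
        return particle
    labels, velocities, trans = tables if tables is not None else transition_tables(profile)
    _validate_dt(trans, dt)
    g = profile.geometry
    x = particle.position
    region = 1 if g.node_start <= x < g.node_end else 0
    s = particle.state
    v = velocities[s]
    if v != 0.0:
        x = x + v * dt
        if x < 0.0 or x > g.length:
            return replace(particle, alive=False)
    u = rng.random()
    acc = 0.0
    new_s = s
    for s2 in range(trans.shape[1]):
        r = trans[region, s, s2]
        if r > 0.0:
            acc += r * dt
            if u < acc:
                new_s = s2
                break
    return Particle(position=x, state=new_s, alive=True)


# ---------------------------------------------------------------------------
# compiled replicate loop
# ---------------------------------------------------------------------------

@njit(cache=False)
def _run_replicate(
    seed,
    trans,
    velocities,
    inject_state,
    dt,
    n_steps,
    inject_every,
    burn_steps,
    sample_every,
    length,
    node_start,
    node_end,
    bin_width,
    n_bins,
    margin,
):
    np.random.seed(seed)
    n_states = trans.shape[1]
    cap = n_steps // inject_every + 2
    pos = np.zeros(cap)
    state = np.zeros(cap, np.int64)
    alive = np.zeros(cap, np.bool_)
    n_part = 0
    n_inj = 0
    n_rem = 0
    bin_state = np.zeros((n_bins, n_states))
    region_state = np.zeros((2, n_states))
    n_samples = 0
    for t in range(n_steps):
        if t % inject_every == 0:
            pos[n_part] = 0.0
            state[n_part] = inject_state
            alive[n_part] = True
            n_part += 1
            n_inj += 1
        for i in range(n_part):
            if not alive[i]:
                continue
            x = pos[i]
            s = state[i]
            region = 1 if (node_start <= x < node_end) else 0
            v = velocities[s]
            if v != 0.0:
                x += v * dt
                if x < 0.0 or x > length:
                    alive[i] = False
                    n_rem += 1
                    continue
                pos[i] = x
            u = np.random.random()
            acc = 0.0
            for s2 in range(n_states):
                r = trans[region, s, s2]
                if r > 0.0:
                    acc += r * dt
                    if u < acc:
                        state[i] = s2
                        break
        if t >= burn_steps and (t - burn_steps) % sample_every == 0:
            n_samples += 1
            for i in range(n_part):
                if alive[i]:
                    x = pos[i]
                    b = int(x / bin_width)
                    if b >= n_bins:
                        b = n_bins - 1
                    bin_state[b, state[i]] += 1.0
                    if node_start <= x < node_end:
                        if node_start + margin <= x < node_end - margin:
                            region_state[1, state[i]] += 1.0
                    elif (margin <= x < node_start - margin) or (
                        node_end + margin <= x < length - margin
                    ):
                        region_state[0, state[i]] += 1.0
    if n_samples > 0:
        bin_state /= n_samples
        region_state /= n_samples
    n_alive = 0
    for i in range(n_part):
        if alive[i]:
            n_alive += 1
    return bin_state, region_state, n_inj, n_rem, n_alive


def run_axon(config: McConfig, profile: SpatialRateProfile) -> McCensus:
    """Run all replicates and return the time-averaged census."""
    labels, velocities, trans = transition_tables(profile)
    _validate_dt(trans, config.dt)
    g = profile.geometry
    n_bins_f = g.length / config.bin_width
    if abs(n_bins_f - round(n_bins_f)) > 1e-9:
        raise ConfigurationError(
            f"bin_width={config.bin_width} does not divide axon length {g.length}"
        )
    n_bins = int(round(n_bins_f))

    burn_in = config.burn_in if config.burn_in is not None else default_burn_in(profile)
    t_total = config.t_total if config.t_total is not None else burn_in + config.t_observe
    if t_total <= burn_in:
        raise ConfigurationError("t_total must exceed burn_in")

    dt = config.dt
    n_steps = int(round(t_total / dt))
    burn_steps = int(round(burn_in / dt))
    inject_every = max(1, int(round(config.injection_interval / dt)))
    sample_every = max(1, int(round(config.sample_interval / dt)))

    inject_state = injection_state_index(profile, config.inject_phospho)
    margin = config.bin_width if config.exclude_boundary_zones else 0.0
    if g.node_end - g.node_start <= 2 * margin and g.node_end > g.node_start:
        margin = 0.0  # node too narrow to trim; fall back to full regions

    n_rep = config.n_replicates
    seeds = replicate_seeds(config.seed, n_rep)
    bin_state_counts = np.zeros((n_rep, n_bins, len(labels)))
    region_state = np.zeros((n_rep, 2, len(labels)))
    n_injected = np.zeros(n_rep, dtype=np.int64)
    n_removed = np.zeros(n_rep, dtype=np.int64)
    n_alive = np.zeros(n_rep, dtype=np.int64)
    for r in range(n_rep):
        bs, rs, ninj, nrem, nal = _run_replicate(
            int(seeds[r]),
            trans,
            velocities,
            inject_state,
            dt,
            n_steps,
            inject_every,
            burn_steps,
            sample_every,
            g.length,
            g.node_start,
            g.node_end,
            config.bin_width,
            n_bins,
            margin,
        )
        bin_state_counts[r] = bs
        region_state[r] = rs
        n_injected[r] = ninj
        n_removed[r] = nrem
        n_alive[r] = nal
    return McCensus(
        config=config,
        profile=profile,
        labels=labels,
        bin_counts=bin_state_counts.sum(axis=2),
        bin_state_counts=bin_state_counts,
        region_state_counts=region_state,
        n_injected=n_injected,
        n_removed=n_removed,
        n_alive=n_alive,
    )


def replicate_seeds(seed: int, n_replicates: int) -> np.ndarray:
    """Independent per-replicate RNG seeds derived from the master seed."""
    return np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)


def write_census_csv(census: McCensus, path) -> None:
    """Tidy census CSV: one row per (replicate, bin, state) with the
    time-averaged count."""
    import pandas as pd

    n_rep, n_bins, n_states = census.bin_state_counts.shape
    rep, b, st_idx = np.meshgrid(
        np.arange(n_rep), np.arange(n_bins), np.arange(n_states), indexing="ij"
    )
    pd.DataFrame(
        {
            "replicate": rep.ravel(),
            "bin": b.ravel(),
            "state": np.asarray(census.labels)[st_idx.ravel()],
            "count": census.bin_state_counts.ravel(),
        }
    ).to_csv(path, index=False)
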