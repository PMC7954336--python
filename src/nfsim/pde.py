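"""Deterministic advection–reaction solver for NF transport on a 1-D axon.

The population in each kinetic state is a concentration field on a
uniform grid; only the running states advect (anterograde at ``v_a``,
retrograde at ``v_r``), all states react through the spatially
piecewise-constant rate matrix of the local region.  The semi-discrete
system uses first-order upwind differences (direction per the sign of
each state's velocity) and is advanced with explicit Euler under a CFL
constraint.  NFs enter continuously at the proximal end in the
running-anterograde state; the proximal ghost cell is empty and the
distal boundary is zero-gradient (outflow).

A direct sparse solve of the discrete steady state is also provided and
doubles as an independent oracle for the time integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .kinetics import (
    ConfigurationError,
    DomainError,
    StateDistribution,
    state_labels,
    state_velocities,
    transition_matrix,
)
from .rate_design import SpatialRateProfile

__all__ = [
    "Grid",
    "FieldState",
    "PdeResult",
    "rhs",
    "run_to_equilibrium",
    "equilibrium_direct",
    "state_fractions",
    "total_density",
    "flux_profile",
    "mass_balance_residual",
    "field_to_csv",
]


@dataclass(frozen=True)
class Grid:
    """Uniform spatial grid with explicit-Euler time step.

    ``dx`` must divide the axon length and both node boundaries so that
    region edges coincide with cell edges; the CFL number
    ``max(|v_a|, |v_r|) dt / dx`` must not exceed one.
    """

    length: float
    dx: float = 0.1
    dt: float = 0.1

    def __post_init__(self) -> None:
        n = self.length / self.dx
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"dx={self.dx} does not divide the axon length {self.length}"
            )
        if self.dt <= 0 or self.dx <= 0:
            raise ConfigurationError("dx and dt must be positive")

    @property
    def n_cells(self) -> int:
        return int(round(self.length / self.dx))

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) * self.dx

    def check_cfl(self, v_max: float) -> None:
        cfl = abs(v_max) * self.dt / self.dx
        if cfl > 1.0 + 1e-12:
            raise ConfigurationError(
                f"CFL number {cfl:.3f} exceeds 1; reduce dt or coarsen dx"
            )

    def check_alignment(self, profile: SpatialRateProfile) -> None:
        for name, edge in (
            ("node_start", profile.geometry.node_start),
            ("node_end", profile.geometry.node_end),
        ):
            k = edge / self.dx
            if abs(k - round(k)) > 1e-9:
                raise ConfigurationError(
                    f"{name}={edge} does not fall on a cell edge for dx={self.dx}"
                )


@dataclass
class FieldState:
    """Per-state concentration fields (NF per um) at one instant."""

    grid: Grid
    labels: tuple
    values: np.ndarray  # shape (n_states, n_cells)
    model_variant: str
    time: float = 0.0

    def total(self) -> np.ndarray:
        """Total NF density summed over states (NF per um)."""
        return self.values.sum(axis=0)


@dataclass
class PdeResult:
    """Outcome of :func:`run_to_equilibrium`."""

    field: FieldState
    converged: bool
    t_end: float
    influx_rate: float
    max_window_change: float


class _Discretization:
    """Precompiled per-region matrices and masks for one profile/grid."""

    def __init__(self, profile: SpatialRateProfile, grid: Grid):
        grid.check_alignment(profile)
        rates = profile.internode_rates
        self.labels = state_labels(rates)
        self.velocities = state_velocities(rates)
        grid.check_cfl(np.max(np.abs(self.velocities)))
        self.M_inter = transition_matrix(profile.internode_rates)
        self.M_node = transition_matrix(profile.node_rates)
        x = grid.centers
        g = profile.geometry
        self.node_mask = (x >= g.node_start) & (x < g.node_end)
        self.inter_idx = np.where(~self.node_mask)[0]
        self.node_idx = np.where(self.node_mask)[0]
        self.advecting = [
            (i, v) for i, v in enumerate(self.velocities) if v != 0.0
        ]
        self.grid = grid


def _rhs_values(values: np.ndarray, disc: _Discretization) -> np.ndarray:
    """dP/dt of the semi-discrete system (reaction + upwind advection)."""
    out = np.empty_like(values)
    out[:, disc.inter_idx] = disc.M_inter @ values[:, disc.inter_idx]
    out[:, disc.node_idx] = disc.M_node @ values[:, disc.node_idx]
    dx = disc.grid.dx
    for i, v in disc.advecting:
        p = values[i]
        if v > 0:
            # upwind from the left; proximal ghost cell is empty
            out[i, 0] += -v * p[0] / dx
            out[i, 1:] += -v * (p[1:] - p[:-1]) / dx
        else:
            # upwind from the right; distal ghost is zero-gradient
            out[i, :-1] += -v * (p[1:] - p[:-1]) / dx
            # last cell: ghost equals the cell itself, difference vanishes
    return out


def rhs(field: FieldState, profile: SpatialRateProfile) -> FieldState:
    """Instantaneous rate of change of a field under a profile."""
    disc = _Discretization(profile, field.grid)
    if disc.labels != field.labels:
        raise ConfigurationError("field and profile use different state spaces")
    return FieldState(
        grid=field.grid,
        labels=field.labels,
        values=_rhs_values(field.values, disc),
        model_variant=field.model_variant,
        time=field.time,
    )


def _initial_field(
    disc: _Discretization,
    profile: SpatialRateProfile,
    influx_rate: float,
    init: str,
) -> np.ndarray:
    from .kinetics import mean_velocity, steady_state

    n = disc.grid.n_cells
    values = np.zeros((len(disc.labels), n))
    if init == "zero":
        return values
    if init != "equilibrium":
        raise ConfigurationError(f"unknown init {init!r}")
    # local closed-form equilibrium: density = flux / vbar, split by the
    # local steady-state fractions
    for idx, region in ((disc.inter_idx, "internode"), (disc.node_idx, "node")):
        if idx.size == 0:
            continue
        r = profile.rates_for(region)
        frac = steady_state(r, method="auto").probabilities
        v = mean_velocity(r)
        if v <= 0:
            continue
        values[:, idx] = np.outer(frac, np.full(idx.size, influx_rate / v))
    return values


def run_to_equilibrium(
    profile: SpatialRateProfile,
    grid: Grid,
    influx_rate: float = 1.0,
    t_max: float = 3.6e5,
    tol: float = 1e-6,
    init: str = "equilibrium",
    check_window: float = 60.0,
) -> PdeResult:
    """Integrate until the spatial distribution stops changing.

    ``influx_rate`` NFs per second are deposited into the
    running-anterograde state of the first interior cell.  Convergence is
    declared when the maximum relative change of the total per-cell
    density over a ``check_window`` seconds of model time falls below
    ``tol``; if ``t_max`` is reached first the result is returned with
    ``converged=False`` (flagged, not raised).
    """
    if influx_rate < 0:
        raise ConfigurationError("influx_rate must be >= 0")
    disc = _Discretization(profile, grid)
    values = _initial_field(disc, profile, influx_rate, init)
    dt, dx = grid.dt, grid.dx
    n_steps = int(round(t_max / dt))
    win = max(1, int(round(check_window / dt)))
    src = influx_rate * dt / dx  # concentration added per step in cell 0
    prev_total = values.sum(axis=0).copy()
    max_change = np.inf
    converged = False
    step = 0
    for step in range(1, n_steps + 1):
        values += dt * _rhs_values(values, disc)
        values[0, 0] += src
        if step % win == 0:
            total = values.sum(axis=0)
            denom = np.maximum(total, 1e-300)
            max_change = float(np.max(np.abs(total - prev_total) / denom))
            prev_total = total.copy()
            if max_change < tol:
                converged = True
                break
    field = FieldState(
        grid=grid,
        labels=disc.labels,
        values=values,
        model_variant=profile.variant,
        time=step * dt,
    )
    return PdeResult(
        field=field,
        converged=converged,
        t_end=step * dt,
        influx_rate=influx_rate,
        max_window_change=max_change,
    )


def equilibrium_direct(
    profile: SpatialRateProfile,
    grid: Grid,
    influx_rate: float = 1.0,
) -> FieldState:
    """Exact steady state of the discrete system by sparse linear solve.

    Solves ``0 = A P + s`` for the same upwind/Euler spatial operator
    ``A`` and source ``s`` as the time integration; independent of the
    stepping, it serves as an oracle for :func:`run_to_equilibrium`.
    """
    disc = _Discretization(profile, grid)
    S, n = len(disc.labels), grid.n_cells
    dx = grid.dx

    rows, cols, vals = [], [], []
    for region_idx, M in ((disc.inter_idx, disc.M_inter), (disc.node_idx, disc.M_node)):
        for s in range(S):
            for s2 in range(S):
                if M[s, s2] != 0.0:
                    for i in region_idx:
                        rows.append(s * n + i)
                        cols.append(s2 * n + i)
                        vals.append(M[s, s2])
    for s, v in disc.advecting:
        if v > 0:
            for i in range(n):
                rows.append(s * n + i)
                cols.append(s * n + i)
                vals.append(-v / dx)
                if i > 0:
                    rows.append(s * n + i)
                    cols.append(s * n + i - 1)
                    vals.append(v / dx)
        else:
            for i in range(n - 1):
                rows.append(s * n + i)
                cols.append(s * n + i + 1)
                vals.append(-v / dx)
                rows.append(s * n + i)
                cols.append(s * n + i)
                vals.append(v / dx)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(S * n, S * n))
    src = np.zeros(S * n)
    src[0] = influx_rate / dx
    P = spla.spsolve(A.tocsc(), -src)
    return FieldState(
        grid=grid,
        labels=disc.labels,
        values=P.reshape(S, n),
        model_variant=profile.variant,
        time=np.inf,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def total_density(field: FieldState) -> np.ndarray:
    return field.total()


def flux_profile(field: FieldState, v_a: float, v_r: float) -> np.ndarray:
    """Local NF flux v_a * P_running_antero + v_r * P_running_retro (NF/s)."""
    labels = field.labels
    flux = np.zeros(field.grid.n_cells)
    for i, lab in enumerate(labels):
        if lab == "Pa" or lab.startswith("Pa_"):
            flux += v_a * field.values[i]
        elif lab == "Pr" or lab.startswith("Pr_"):
            flux += v_r * field.values[i]
    return flux


def _region_mask(field: FieldState, region, profile: SpatialRateProfile | None):
    x = field.grid.centers
    if isinstance(region, tuple):
        lo, hi = region
        return (x >= lo) & (x < hi)
    if profile is None:
        raise ValueError("named regions require the profile")
    g = profile.geometry
    node = (x >= g.node_start) & (x < g.node_end)
    if region == "node":
        return node
    if region == "internode":
        return ~node
    raise ValueError(f"unknown region {region!r}")


def state_fractions(
    field: FieldState,
    region,
    profile: SpatialRateProfile | None = None,
) -> StateDistribution:
    """Per-state mass fractions within a region of an (equilibrated) field.

    ``region`` is ``'node'``, ``'internode'`` (requires ``profile``) or an
    explicit ``(lo, hi)`` interval in um.
    """
    mask = _region_mask(field, region, profile)
    if not mask.any():
        raise DomainError(f"region {region!r} contains no grid cells")
    mass = field.values[:, mask].sum(axis=1)
    total = mass.sum()
    if total <= 0:
        raise DomainError(f"region {region!r} holds no NF mass")
    return StateDistribution(
        labels=field.labels,
        probabilities=mass / total,
        model_variant=field.model_variant,
    )


def mass_balance_residual(
    field: FieldState,
    profile: SpatialRateProfile,
    influx_rate: float,
) -> float:
    """Relative discrete mass-balance error of one Euler step.

    Advances the field by one step and compares the change of total mass
    with ``(influx - boundary outflux) * dt``.  The boundary fluxes are
    those implied by the upwind stencils: anterograde outflow
    ``v_a P_a[last]``, retrograde outflow ``|v_r| P_r[0]`` and the
    zero-gradient distal ghost inflow ``|v_r| P_r[last]``.
    """
    disc = _Discretization(profile, field.grid)
    dx, dt = field.grid.dx, field.grid.dt
    values = field.values
    mass0 = values.sum() * dx
    new = values + dt * _rhs_values(values, disc)
    new[0, 0] += influx_rate * dt / dx
    mass1 = new.sum() * dx
    boundary = 0.0
    for s, v in disc.advecting:
        if v > 0:
            boundary -= v * values[s, -1]  # outflow, distal
        else:
            boundary -= -v * values[s, 0]  # outflow, proximal
            boundary += -v * values[s, -1]  # ghost inflow, distal
    expected = (influx_rate + boundary) * dt
    scale = max(abs(mass0), abs(expected), 1e-300)
    return abs((mass1 - mass0) - expected) / scale


def field_to_csv(field: FieldState, path) -> None:
    """Write the field as CSV: x, one column per state, total."""
    import pandas as pd

    data = {"x": field.grid.centers}
    for i, lab in enumerate(field.labels):
        data[lab] = field.values[i]
    data["total"] = field.total()
    pd.DataFrame(data).to_csv(path, index=False)
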