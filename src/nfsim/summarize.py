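"""Headline quantities from censuses and fields.

Turns Monte Carlo censuses and PDE equilibrium fields into the numbers
the transport analysis is about: regional populations N, regional mean
velocities V (from the occupancy estimator V = p_a v_a + p_r v_r), the
node:internode velocity ratio, the internode:node population ratio, and
the continuity-equation residual |N1 V1 - N2 V2| / (N1 V1) that checks
flux constancy at equilibrium.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .kinetics import (
    ConfigurationError,
    DomainError,
    StateDistribution,
    um_per_s_to_mm_per_day,
)
from .mc import McCensus
from .pde import FieldState, state_fractions, total_density
from .rate_design import AxonGeometry, SpatialRateProfile

__all__ = [
    "SimulationSummary",
    "bin_census",
    "regional_velocity",
    "continuity_check",
    "summarize_census",
    "summarize_field",
    "interior_bins",
    "write_summary_json",
    "write_bin_csv",
    "plot_distribution",
]


@dataclass
class SimulationSummary:
    """Regional populations, velocities, flux and their consistency."""

    variant: str
    engine: str
    bin_width: float
    bin_mean: list
    bin_sd: list
    n_internode: float
    n_node: float
    v_internode_um_s: float
    v_node_um_s: float
    v_internode_mm_day: float
    v_node_mm_day: float
    flux_internode: float
    flux_node: float
    velocity_ratio: float      # node / internode
    population_ratio: float    # internode / node
    continuity_residual: float

    def to_dict(self) -> dict:
        return asdict(self)


def bin_census(
    positions: np.ndarray,
    geometry: AxonGeometry,
    bin_width: float,
) -> np.ndarray:
    """Counts of particles per half-open bin [i*w, (i+1)*w).

    ``bin_width`` must divide the axon length exactly.
    """
    n_bins_f = geometry.length / bin_width
    if abs(n_bins_f - round(n_bins_f)) > 1e-9:
        raise ConfigurationError(
            f"bin_width={bin_width} does not divide axon length {geometry.length}"
        )
    n_bins = int(round(n_bins_f))
    positions = np.asarray(positions, dtype=float)
    inside = (positions >= 0) & (positions <= geometry.length)
    idx = np.minimum((positions[inside] / bin_width).astype(int), n_bins - 1)
    return np.bincount(idx, minlength=n_bins).astype(float)


def interior_bins(
    geometry: AxonGeometry,
    bin_width: float,
    region: str,
    exclude_boundary_bins: bool = True,
) -> np.ndarray:
    """Bin indices belonging to a region's interior.

    With ``exclude_boundary_bins`` (default) one bin adjacent to each
    domain boundary and each node/internode boundary is dropped, which
    suppresses injection/outflow and region-transition transients.
    """
    n_bins = int(round(geometry.length / bin_width))
    centers = (np.arange(n_bins) + 0.5) * bin_width
    node = (centers >= geometry.node_start) & (centers < geometry.node_end)
    mask = node if region == "node" else ~node
    if region not in ("node", "internode"):
        raise ValueError(f"unknown region {region!r}")
    if exclude_boundary_bins:
        keep = mask.copy()
        idx = np.where(mask)[0]
        for i in idx:
            neighbours = []
            if i > 0:
                neighbours.append(mask[i - 1])
            else:
                neighbours.append(False)  # domain boundary
            if i < n_bins - 1:
                neighbours.append(mask[i + 1])
            else:
                neighbours.append(False)
            if not all(neighbours):
                keep[i] = False
        mask = keep
    return np.where(mask)[0]


def regional_velocity(
    source,
    region: str,
    v_a: float,
    v_r: float,
    profile: Optional[SpatialRateProfile] = None,
) -> float:
    """Occupancy-based mean velocity V = p_a v_a + p_r v_r (um/s).

    ``source`` may be a :class:`McCensus`, a PDE :class:`FieldState`
    (``profile`` then required) or a :class:`StateDistribution`.
    """
    if isinstance(source, StateDistribution):
        dist = source
    elif isinstance(source, McCensus):
        dist = source.region_fractions(region)
    elif isinstance(source, FieldState):
        dist = state_fractions(source, region, profile)
    else:
        raise TypeError(f"unsupported source {type(source)!r}")
    return dist.velocity(v_a, v_r)


def continuity_check(summary: SimulationSummary) -> tuple:
    """(residual, velocity_ratio, population_ratio) of a summary.

    The residual is |N1 V1 - N2 V2| / (N1 V1) with 1 = internode and
    2 = node; at a true dynamic equilibrium the flux N V is the same in
    both regions and the residual vanishes.
    """
    flux1 = summary.n_internode * summary.v_internode_um_s
    flux2 = summary.n_node * summary.v_node_um_s
    if flux1 == 0:
        raise DomainError("internode flux is zero; continuity undefined")
    residual = abs(flux1 - flux2) / abs(flux1)
    return residual, summary.velocity_ratio, summary.population_ratio


def _assemble(
    variant: str,
    engine: str,
    bin_width: float,
    bin_mean: np.ndarray,
    bin_sd: np.ndarray,
    geometry: AxonGeometry,
    v_inter: float,
    v_node: float,
    exclude_boundary_bins: bool,
) -> SimulationSummary:
    ii = interior_bins(geometry, bin_width, "internode", exclude_boundary_bins)
    ni = interior_bins(geometry, bin_width, "node", exclude_boundary_bins)
    n1 = float(bin_mean[ii].mean())
    n2 = float(bin_mean[ni].mean())
    return SimulationSummary(
        variant=variant,
        engine=engine,
        bin_width=bin_width,
        bin_mean=[float(v) for v in bin_mean],
        bin_sd=[float(v) for v in bin_sd],
        n_internode=n1,
        n_node=n2,
        v_internode_um_s=float(v_inter),
        v_node_um_s=float(v_node),
        v_internode_mm_day=um_per_s_to_mm_per_day(float(v_inter)),
        v_node_mm_day=um_per_s_to_mm_per_day(float(v_node)),
        flux_internode=n1 * float(v_inter),
        flux_node=n2 * float(v_node),
        velocity_ratio=float(v_node / v_inter) if v_inter != 0 else float("nan"),
        population_ratio=float(n1 / n2) if n2 != 0 else float("nan"),
        continuity_residual=(
            abs(n1 * v_inter - n2 * v_node) / abs(n1 * v_inter)
            if n1 * v_inter != 0
            else float("nan")
        ),
    )


def summarize_census(
    census: McCensus,
    exclude_boundary_bins: bool = True,
) -> SimulationSummary:
    """Headline quantities of a Monte Carlo census."""
    profile = census.profile
    rates = profile.internode_rates
    v_inter = regional_velocity(census, "internode", rates.v_a, rates.v_r)
    v_node = regional_velocity(census, "node", rates.v_a, rates.v_r)
    return _assemble(
        variant=profile.variant,
        engine="mc",
        bin_width=census.config.bin_width,
        bin_mean=census.mean_bin_counts(),
        bin_sd=census.sd_bin_counts(),
        geometry=profile.geometry,
        v_inter=v_inter,
        v_node=v_node,
        exclude_boundary_bins=exclude_boundary_bins,
    )


def summarize_field(
    field: FieldState,
    profile: SpatialRateProfile,
    bin_width: float = 2.0,
    exclude_boundary_bins: bool = True,
) -> SimulationSummary:
    """Headline quantities of a PDE equilibrium field.

    The density field is aggregated into bins of ``bin_width`` (mean NF
    per bin) so the same regional estimators apply to both engines.
    """
    rates = profile.internode_rates
    v_inter = regional_velocity(field, "internode", rates.v_a, rates.v_r, profile)
    v_node = regional_velocity(field, "node", rates.v_a, rates.v_r, profile)
    total = total_density(field)
    x = field.grid.centers
    n_bins = int(round(profile.geometry.length / bin_width))
    bin_mean = np.zeros(n_bins)
    for b in range(n_bins):
        m = (x >= b * bin_width) & (x < (b + 1) * bin_width)
        bin_mean[b] = total[m].mean() * bin_width  # NF per bin
    return _assemble(
        variant=profile.variant,
        engine="pde",
        bin_width=bin_width,
        bin_mean=bin_mean,
        bin_sd=np.zeros(n_bins),
        geometry=profile.geometry,
        v_inter=v_inter,
        v_node=v_node,
        exclude_boundary_bins=exclude_boundary_bins,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_summary_json(summary: SimulationSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)


def write_bin_csv(summary: SimulationSummary, path) -> None:
    n = len(summary.bin_mean)
    df = pd.DataFrame(
        {
            "bin": np.arange(n),
            "x_center": (np.arange(n) + 0.5) * summary.bin_width,
            "mean": summary.bin_mean,
            "sd": summary.bin_sd,
        }
    )
    df.to_csv(path, index=False)


def plot_distribution(summary: SimulationSummary, path) -> None:
    """Bar plot (mean ± sd) of the NF distribution along the axon."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(summary.bin_mean)
    x = (np.arange(n) + 0.5) * summary.bin_width
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(
        x,
        summary.bin_mean,
        width=0.9 * summary.bin_width,
        yerr=summary.bin_sd,
        capsize=2,
        color="tab:blue",
        ecolor="black",
    )
    ax.set_xlabel("position along axon (um)")
    ax.set_ylabel("NF count per bin")
    ax.set_title(f"{summary.variant} / {summary.engine}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
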