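"""On-track-rate reconstruction and node:internode velocity-ratio curves.

At dynamic equilibrium the NF flux ``N(x) * vbar(x)`` is constant along
the axon (continuity equation), so a target regional velocity pins down
the regional on-track rate.  This module inverts the closed-form mean
velocity for ``gamma_on`` (six-state) and ``gamma_on2`` (eight-state),
builds piecewise-constant spatial rate profiles (node of Ranvier vs
internode), and evaluates the analytic node:internode velocity-ratio
curves as functions of the phosphorylation-rate ratio ``r``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import (
    DomainError,
    EightStateRates,
    InvalidParameterError,
    KineticRates,
    PhosphoKinetics,
    RateSet,
    mean_velocity,
    variant_of,
)

__all__ = [
    "AxonGeometry",
    "SpatialRateProfile",
    "gamma_on_from_velocity",
    "gamma_on2_from_velocity",
    "build_profile",
    "ratio_curve_six",
    "solve_n_for_ratio",
    "ratio_surface_eight",
    "ratio_curve_table",
]


@dataclass(frozen=True)
class AxonGeometry:
    """A single axon of ``length`` um with one node of Ranvier.

    The node occupies the half-open interval [node_start, node_end); the
    remainder is myelinated internode.  ``node_start == node_end`` is the
    degenerate all-internode axon.
    """

    length: float = 50.0
    node_start: float = 20.0
    node_end: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.node_start <= self.node_end < self.length):
            raise InvalidParameterError(
                "require 0 < node_start <= node_end < length, got "
                f"{self.node_start}, {self.node_end}, {self.length}"
            )

    def region_at(self, x: float) -> str:
        """'node' or 'internode' at position ``x`` (um)."""
        if not 0 <= x <= self.length:
            raise DomainError(
                f"x={x} outside the axon [0, {self.length}]"
            )
        return "node" if self.node_start <= x < self.node_end else "internode"


@dataclass(frozen=True)
class SpatialRateProfile:
    """Piecewise-constant rate sets along the axon: one per region."""

    geometry: AxonGeometry
    internode_rates: RateSet
    node_rates: RateSet

    def __post_init__(self) -> None:
        if variant_of(self.internode_rates) != variant_of(self.node_rates):
            raise InvalidParameterError(
                "node and internode rate sets must share the model variant"
            )

    @property
    def variant(self) -> str:
        return variant_of(self.internode_rates)

    def rates_at(self, x: float) -> RateSet:
        return (
            self.node_rates
            if self.geometry.region_at(x) == "node"
            else self.internode_rates
        )

    def rates_for(self, region: str) -> RateSet:
        if region == "node":
            return self.node_rates
        if region == "internode":
            return self.internode_rates
        raise ValueError(f"unknown region {region!r}")


def build_profile(
    geometry: AxonGeometry,
    node_params: RateSet,
    internode_params: RateSet,
) -> SpatialRateProfile:
    """Assemble a :class:`SpatialRateProfile` from per-region rate sets."""
    return SpatialRateProfile(
        geometry=geometry,
        internode_rates=internode_params,
        node_rates=node_params,
    )


# ---------------------------------------------------------------------------
# inverse velocity formulas
# ---------------------------------------------------------------------------

def _admissible_vmax(rates: KineticRates) -> float:
    q1 = rates.gamma_10 / rates.gamma_01
    q3 = rates.gamma_ar / rates.gamma_ra
    return (rates.v_a + q3 * rates.v_r) / ((1.0 + q3) * (1.0 + q1))


def gamma_on_from_velocity(v_target: float, rates: KineticRates) -> float:
    """On-track rate that yields mean velocity ``v_target`` (um/s).

    Inverts the six-state closed form:

        gamma_on = gamma_off * v (1+q3) q1 / (v_a + q3 v_r - v (1+q3)(1+q1))

    ``v_target`` must lie in the open interval (0, v_max) with
    v_max = (v_a + q3 v_r) / ((1+q3)(1+q1)), the velocity of a chain that
    never pauses off-track.
    """
    q1 = rates.gamma_10 / rates.gamma_01
    q3 = rates.gamma_ar / rates.gamma_ra
    vmax = _admissible_vmax(rates)
    if not 0 < v_target < vmax:
        raise DomainError(
            f"target velocity {v_target:.6g} um/s outside the admissible "
            f"interval (0, {vmax:.6g}) um/s"
        )
    numer = rates.gamma_off * v_target * (1.0 + q3) * q1
    denom = rates.v_a + q3 * rates.v_r - v_target * (1.0 + q3) * (1.0 + q1)
    return numer / denom


def gamma_on2_from_velocity(
    v_target: float,
    base: KineticRates,
    phospho: PhosphoKinetics,
    gamma_on1: float = 2.75e-4,
) -> float:
    """Dephosphorylated on-track rate reaching ``v_target`` (um/s).

    First inverts the mean-velocity formula for the effective q2,

        q2 = [ (v_a + q3 v_r) / ((1+q3) v) - 1 ] / q1 - 1,

    then solves q2 = 2 gamma_off / (alpha1 gamma_on1 + alpha2 gamma_on2)
    for gamma_on2.  Raises :class:`DomainError` when the target is
    unreachable for the given ``gamma_on1`` and phospho rates (the
    implied gamma_on2 would be non-positive).
    """
    q1 = base.gamma_10 / base.gamma_01
    q3 = base.gamma_ar / base.gamma_ra
    vmax = _admissible_vmax(base)
    if not 0 < v_target < vmax:
        raise DomainError(
            f"target velocity {v_target:.6g} um/s outside the admissible "
            f"interval (0, {vmax:.6g}) um/s"
        )
    A = (base.v_a + q3 * base.v_r) / ((1.0 + q3) * v_target)
    q2 = (A - 1.0) / q1 - 1.0
    gamma_on2 = (2.0 * base.gamma_off / q2 - phospho.alpha1 * gamma_on1) / phospho.alpha2
    if gamma_on2 <= 0:
        raise DomainError(
            f"target velocity {v_target:.6g} um/s unreachable: implied "
            f"gamma_on2 = {gamma_on2:.6g} <= 0 for gamma_on1 = {gamma_on1:.6g}"
        )
    return gamma_on2


# ---------------------------------------------------------------------------
# analytic ratio curves
# ---------------------------------------------------------------------------

def ratio_curve_six(n: float, r: float) -> float:
    """Node:internode velocity ratio of the phospho-weighted mixture.

    With fast:slow speed factor ``n``, internode phospho ratio
    r = gamma_ph/gamma_de and the node ratio its inverse, the mixture
    velocities give

        V_node : V_internode = (n r + 1) / (r + n).

    The curve saturates at ``r`` for n -> infinity and never exceeds the
    bare factor ``n``.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    if r <= 0:
        raise DomainError(f"r must be > 0, got {r}")
    return (n * r + 1.0) / (r + n)


def solve_n_for_ratio(target_ratio: float, r: float) -> float:
    """Speed factor ``n`` for which the mixture ratio equals ``target_ratio``.

    Closed-form inverse of :func:`ratio_curve_six`:
    n = (target_ratio * r - 1) / (r - target_ratio).  The ratio saturates
    at ``r``, so ``target_ratio`` must satisfy 1 < target_ratio < r.
    """
    if not 1 < target_ratio < r:
        raise DomainError(
            f"target ratio {target_ratio} unreachable: the curve saturates "
            f"at r = {r}; require 1 < target_ratio < r"
        )
    return (target_ratio * r - 1.0) / (r - target_ratio)


def ratio_surface_eight(
    r: float,
    gamma_on2_node: float,
    gamma_on2_internode: float,
    base: KineticRates | None = None,
    gamma_on1: float = 2.75e-4,
) -> float:
    """Node:internode velocity ratio of the eight-state chain.

    The internode phospho ratio is ``r`` (gamma_ph = r * gamma_de) and
    the node ratio is its inverse; ``gamma_on1`` is held fixed.  Computed
    from two closed-form mean velocities.
    """
    if r <= 0 or gamma_on2_node <= 0 or gamma_on2_internode <= 0:
        raise InvalidParameterError("r and both gamma_on2 values must be > 0")
    if base is None:
        base = KineticRates()
    v_inter = mean_velocity(
        EightStateRates(
            base=base,
            gamma_on1=gamma_on1,
            gamma_on2=gamma_on2_internode,
            phospho=PhosphoKinetics(gamma_ph=r, gamma_de=1.0),
        )
    )
    v_node = mean_velocity(
        EightStateRates(
            base=base,
            gamma_on1=gamma_on1,
            gamma_on2=gamma_on2_node,
            phospho=PhosphoKinetics(gamma_ph=1.0, gamma_de=r),
        )
    )
    return v_node / v_inter


def ratio_curve_table(
    r_values,
    x_values,
    kind: str = "six",
    **kwargs,
) -> pd.DataFrame:
    """Tabulate ratio curves as tidy rows (x, r, ratio).

    ``kind='six'`` sweeps the speed factor ``n`` (x = n) through
    :func:`ratio_curve_six`; ``kind='eight'`` sweeps a common gamma_on2
    (x = gamma_on2, applied to node and internode alike unless a
    ``node_scale`` keyword rescales the node value) through
    :func:`ratio_surface_eight`.
    """
    rows = []
    if kind == "six":
        for r in r_values:
            for x in x_values:
                rows.append({"x": x, "r": r, "ratio": ratio_curve_six(x, r)})
    elif kind == "eight":
        node_scale = kwargs.pop("node_scale", 1.0)
        for r in r_values:
            for x in x_values:
                rows.append(
                    {
                        "x": x,
                        "r": r,
                        "ratio": ratio_surface_eight(
                            r, node_scale * x, x, **kwargs
                        ),
                    }
                )
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return pd.DataFrame(rows)
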