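"""Parameter containers, rate matrices and closed-form kinetics.

Neurofilaments (NFs) undergo "stop-and-go" slow axonal transport: brief
runs driven by kinesin/dynein separated by long on-track and off-track
pauses.  The classic description is a six-state continuous-time Markov
chain — running, on-track pausing and off-track pausing, each in an
anterograde and a retrograde flavour.  This module adds the two
phosphorylation-aware extensions of that chain:

* ``six``          — the plain six-state chain with a single on-track
                     rate ``gamma_on``;
* ``six_phospho``  — every kinetic state is duplicated into a
                     phosphorylated/dephosphorylated pair (12 labelled
                     states) and the on-track rate is selected by the
                     phospho label;
* ``eight``        — only the off-track pausing states are split by
                     phosphorylation, giving eight states with two
                     on-track rates ``gamma_on1`` (phosphorylated, slow)
                     and ``gamma_on2`` (dephosphorylated, fast).

Everything downstream (the PDE solver, the Monte Carlo engine, the rate
reconstruction helpers) consumes the rate matrices built here, so the
transition structure is defined exactly once.

Units: all rates are s^-1, all speeds are micrometres per second.  Use
:func:`mm_per_day_to_um_per_s` / :func:`um_per_s_to_mm_per_day` at the
interface boundary when a quantity is quoted in mm/day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

__all__ = [
    "InvalidParameterError",
    "DomainError",
    "ConfigurationError",
    "KineticRates",
    "PhosphoKinetics",
    "SixPhosphoRates",
    "EightStateRates",
    "QCoefficients",
    "StateDistribution",
    "RateSet",
    "SIX_STATE_LABELS",
    "EIGHT_STATE_LABELS",
    "SIX_PHOSPHO_LABELS",
    "mm_per_day_to_um_per_s",
    "um_per_s_to_mm_per_day",
    "state_labels",
    "state_velocities",
    "transition_matrix",
    "variant_of",
    "q_coefficients_six",
    "q2_eight",
    "steady_state",
    "steady_state_numeric",
    "mean_velocity",
    "phospho_equilibrium",
    "phospho_weighted_velocity",
]

#: seconds per day / micrometres per millimetre
_MM_PER_DAY = 1000.0 / 86400.0  # 1 mm/day in um/s


class InvalidParameterError(ValueError):
    """A rate or speed violates its sign/positivity constraint."""


class DomainError(ValueError):
    """An input lies outside the mathematically admissible domain."""


class ConfigurationError(ValueError):
    """A simulation configuration is internally inconsistent."""


def mm_per_day_to_um_per_s(v: float) -> float:
    """Convert a speed from mm/day to um/s (factor 1000/86400)."""
    return v * _MM_PER_DAY


def um_per_s_to_mm_per_day(v: float) -> float:
    """Convert a speed from um/s to mm/day (factor 86400/1000)."""
    return v / _MM_PER_DAY


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise InvalidParameterError(
                f"{name} must be strictly positive, got {value!r}"
            )


@dataclass(frozen=True)
class KineticRates:
    """Rates and speeds of the six-state stop-and-go chain.

    Defaults are the literature values for rat sympathetic neurons:
    reversal rates ``gamma_10``/``gamma_01`` between running and on-track
    pausing, off-track exchange ``gamma_off``/``gamma_on``, and the very
    slow anterograde/retrograde direction reversal ``gamma_ar``/``gamma_ra``.
    ``v_a`` is the anterograde run speed (positive), ``v_r`` the retrograde
    run speed (negative).
    """

    gamma_10: float = 0.14
    gamma_01: float = 0.064
    gamma_on: float = 2.75e-4
    gamma_off: float = 4.45e-3
    gamma_ar: float = 4.2e-6
    gamma_ra: float = 1.4e-5
    v_a: float = 0.52
    v_r: float = -0.36

    def __post_init__(self) -> None:
        _require_positive(
            gamma_10=self.gamma_10,
            gamma_01=self.gamma_01,
            gamma_on=self.gamma_on,
            gamma_off=self.gamma_off,
            gamma_ar=self.gamma_ar,
            gamma_ra=self.gamma_ra,
        )
        if not self.v_a > 0:
            raise InvalidParameterError(f"v_a must be > 0, got {self.v_a!r}")
        if not self.v_r < 0:
            raise InvalidParameterError(f"v_r must be < 0, got {self.v_r!r}")

    def with_gamma_on(self, gamma_on: float) -> "KineticRates":
        return replace(self, gamma_on=gamma_on)


@dataclass(frozen=True)
class PhosphoKinetics:
    """Phosphorylation (``gamma_ph``) and dephosphorylation (``gamma_de``)
    rates of the NF side arms, modelled as a two-state switch.

    ``alpha1`` is the equilibrium phosphorylated fraction and ``alpha2``
    the dephosphorylated fraction; they sum to one by construction.
    """

    gamma_ph: float
    gamma_de: float

    def __post_init__(self) -> None:
        _require_positive(gamma_ph=self.gamma_ph, gamma_de=self.gamma_de)

    @property
    def alpha1(self) -> float:
        """Equilibrium phosphorylated fraction gamma_ph/(gamma_ph+gamma_de)."""
        return self.gamma_ph / (self.gamma_ph + self.gamma_de)

    @property
    def alpha2(self) -> float:
        """Equilibrium dephosphorylated fraction gamma_de/(gamma_ph+gamma_de)."""
        return self.gamma_de / (self.gamma_ph + self.gamma_de)


@dataclass(frozen=True)
class SixPhosphoRates:
    """Six-state chain with a phosphorylation overlay on every state.

    Each of the six kinetic states carries a phospho label; the on-track
    rate is ``gamma_on_ph`` while phosphorylated and ``gamma_on_de`` while
    dephosphorylated.  ``gamma_on`` of ``base`` is unused.

    ``exchange_off_track`` controls whether the phospho label keeps
    switching during an off-track pause.  The default ``False`` freezes
    the label for the duration of each off-track dwell, which places the
    chain in the slow-exchange regime that the analytic velocity mixture
    (and the node:internode ratio it predicts) assumes; set ``True`` for
    label switching in every state.
    """

    base: KineticRates = field(default_factory=KineticRates)
    phospho: PhosphoKinetics = field(
        default_factory=lambda: PhosphoKinetics(gamma_ph=0.8, gamma_de=0.1)
    )
    gamma_on_ph: float = 2.75e-4
    gamma_on_de: float = 5.16e-3
    exchange_off_track: bool = False

    def __post_init__(self) -> None:
        _require_positive(gamma_on_ph=self.gamma_on_ph, gamma_on_de=self.gamma_on_de)

    @property
    def v_a(self) -> float:
        return self.base.v_a

    @property
    def v_r(self) -> float:
        return self.base.v_r


@dataclass(frozen=True)
class EightStateRates:
    """Eight-state chain: off-track pausing split by phosphorylation.

    ``gamma_on1`` is the on-track rate from the phosphorylated off-track
    sub-state, ``gamma_on2`` from the dephosphorylated one.  ``gamma_on``
    of ``base`` is unused.  Phosphorylation is expected to lower the
    on-track rate (``gamma_on1 <= gamma_on2``); a violation is allowed
    (parameter sweeps explore it) but triggers a warning.
    """

    base: KineticRates = field(default_factory=KineticRates)
    gamma_on1: float = 2.75e-4
    gamma_on2: float = 5.16e-3
    phospho: PhosphoKinetics = field(
        default_factory=lambda: PhosphoKinetics(gamma_ph=0.8, gamma_de=0.1)
    )

    def __post_init__(self) -> None:
        _require_positive(gamma_on1=self.gamma_on1, gamma_on2=self.gamma_on2)
        if self.gamma_on1 > self.gamma_on2:
            warnings.warn(
                "gamma_on1 > gamma_on2: phosphorylation normally lowers the "
                "on-track rate",
                stacklevel=2,
            )

    @property
    def v_a(self) -> float:
        return self.base.v_a

    @property
    def v_r(self) -> float:
        return self.base.v_r


RateSet = Union[KineticRates, SixPhosphoRates, EightStateRates]


@dataclass(frozen=True)
class QCoefficients:
    """Dimensionless occupancy ratios of the stop-and-go chain.

    ``q1`` = pausing:running, ``q2`` = off-track:on-track-pausing,
    ``q3`` = retrograde:anterograde.
    """

    q1: float
    q2: float
    q3: float

    def __post_init__(self) -> None:
        for name in ("q1", "q2", "q3"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    @property
    def rho(self) -> float:
        """Normalisation 1 / ((1 + q1(1+q2)) (1 + q3))."""
        return 1.0 / ((1.0 + self.q1 * (1.0 + self.q2)) * (1.0 + self.q3))


@dataclass(frozen=True)
class StateDistribution:
    """Per-state occupancy probabilities for one model variant."""

    labels: tuple
    probabilities: np.ndarray
    model_variant: str

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if len(self.labels) != p.size:
            raise InvalidParameterError("labels and probabilities differ in length")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise InvalidParameterError("probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-10:
            raise InvalidParameterError(
                f"probabilities must sum to 1 (got {p.sum()!r})"
            )

    def __getitem__(self, label: str) -> float:
        return float(self.probabilities[self.labels.index(label)])

    def as_dict(self) -> dict:
        return {l: float(p) for l, p in zip(self.labels, self.probabilities)}

    @property
    def p_running_anterograde(self) -> float:
        return float(
            sum(p for l, p in zip(self.labels, self.probabilities) if l.startswith("Pa_") or l == "Pa")
        )

    @property
    def p_running_retrograde(self) -> float:
        return float(
            sum(p for l, p in zip(self.labels, self.probabilities) if l.startswith("Pr_") or l == "Pr")
        )

    def velocity(self, v_a: float, v_r: float) -> float:
        """Occupancy-weighted mean velocity p_a v_a + p_r v_r (um/s)."""
        return self.p_running_anterograde * v_a + self.p_running_retrograde * v_r


# ---------------------------------------------------------------------------
# state spaces and rate matrices
# ---------------------------------------------------------------------------

SIX_STATE_LABELS = ("Pa", "Pr", "Pa0", "Pr0", "Pap", "Prp")
EIGHT_STATE_LABELS = ("Pa", "Pr", "Pa0", "Pr0", "Pap1", "Pap2", "Prp1", "Prp2")
_SIX_KINETIC = ("Pa", "Pr", "Pa0", "Pr0", "Pap", "Prp")
SIX_PHOSPHO_LABELS = tuple(
    f"{k}_{p}" for k in _SIX_KINETIC for p in ("ph", "de")
)


def variant_of(rates: RateSet) -> str:
    """Model variant name (``six``/``six_phospho``/``eight``) of a rate set."""
    if isinstance(rates, EightStateRates):
        return "eight"
    if isinstance(rates, SixPhosphoRates):
        return "six_phospho"
    if isinstance(rates, KineticRates):
        return "six"
    raise TypeError(f"unsupported rate set {type(rates)!r}")


def state_labels(rates: RateSet) -> tuple:
    return {
        "six": SIX_STATE_LABELS,
        "six_phospho": SIX_PHOSPHO_LABELS,
        "eight": EIGHT_STATE_LABELS,
    }[variant_of(rates)]


def state_velocities(rates: RateSet) -> np.ndarray:
    """Speed of each state (um/s); only the running states move."""
    labels = state_labels(rates)
    v = np.zeros(len(labels))
    for i, lab in enumerate(labels):
        if lab == "Pa" or lab.startswith("Pa_"):
            v[i] = rates.v_a
        elif lab == "Pr" or lab.startswith("Pr_"):
            v[i] = rates.v_r
    return v


def _six_edges(r: KineticRates, gamma_on: float) -> list:
    return [
        ("Pa", "Pa0", r.gamma_10),
        ("Pa0", "Pa", r.gamma_01),
        ("Pr", "Pr0", r.gamma_10),
        ("Pr0", "Pr", r.gamma_01),
        ("Pa0", "Pr0", r.gamma_ar),
        ("Pr0", "Pa0", r.gamma_ra),
        ("Pap", "Prp", r.gamma_ar),
        ("Prp", "Pap", r.gamma_ra),
        ("Pa0", "Pap", r.gamma_off),
        ("Pap", "Pa0", gamma_on),
        ("Pr0", "Prp", r.gamma_off),
        ("Prp", "Pr0", gamma_on),
    ]


def transition_matrix(rates: RateSet) -> np.ndarray:
    """Generator matrix ``M`` of the chain: ``dp/dt = M @ p``.

    ``M[i, j]`` is the rate from state ``j`` into state ``i`` for
    ``i != j``; the columns sum to zero (probability conservation).
    """
    labels = state_labels(rates)
    index = {lab: i for i, lab in enumerate(labels)}
    M = np.zeros((len(labels), len(labels)))

    def add(src: str, dst: str, rate: float) -> None:
        M[index[dst], index[src]] += rate
        M[index[src], index[src]] -= rate

    if isinstance(rates, EightStateRates):
        b = rates.base
        for src, dst, rt in [
            ("Pa", "Pa0", b.gamma_10),
            ("Pa0", "Pa", b.gamma_01),
            ("Pr", "Pr0", b.gamma_10),
            ("Pr0", "Pr", b.gamma_01),
            ("Pa0", "Pr0", b.gamma_ar),
            ("Pr0", "Pa0", b.gamma_ra),
            # the off-track split: Pa0 feeds both phospho sub-states
            ("Pa0", "Pap1", b.gamma_off),
            ("Pa0", "Pap2", b.gamma_off),
            ("Pap1", "Pa0", rates.gamma_on1),
            ("Pap2", "Pa0", rates.gamma_on2),
            ("Pr0", "Prp1", b.gamma_off),
            ("Pr0", "Prp2", b.gamma_off),
            ("Prp1", "Pr0", rates.gamma_on1),
            ("Prp2", "Pr0", rates.gamma_on2),
            ("Pap1", "Prp1", b.gamma_ar),
            ("Prp1", "Pap1", b.gamma_ra),
            ("Pap2", "Prp2", b.gamma_ar),
            ("Prp2", "Pap2", b.gamma_ra),
            # phospho exchange within the off-track pool
            ("Pap1", "Pap2", rates.phospho.gamma_de),
            ("Pap2", "Pap1", rates.phospho.gamma_ph),
            ("Prp1", "Prp2", rates.phospho.gamma_de),
            ("Prp2", "Prp1", rates.phospho.gamma_ph),
        ]:
            add(src, dst, rt)
    elif isinstance(rates, SixPhosphoRates):
        for suffix, gon in (("ph", rates.gamma_on_ph), ("de", rates.gamma_on_de)):
            for src, dst, rt in _six_edges(rates.base, gon):
                add(f"{src}_{suffix}", f"{dst}_{suffix}", rt)
        for kin in _SIX_KINETIC:
            if kin in ("Pap", "Prp") and not rates.exchange_off_track:
                continue
            add(f"{kin}_ph", f"{kin}_de", rates.phospho.gamma_de)
            add(f"{kin}_de", f"{kin}_ph", rates.phospho.gamma_ph)
    elif isinstance(rates, KineticRates):
        for src, dst, rt in _six_edges(rates, rates.gamma_on):
            add(src, dst, rt)
    else:
        raise TypeError(f"unsupported rate set {type(rates)!r}")
    return M


# ---------------------------------------------------------------------------
# closed-form kinetics
# ---------------------------------------------------------------------------

def q_coefficients_six(rates: KineticRates) -> QCoefficients:
    """Occupancy ratios q1 = g10/g01, q2 = goff/gon, q3 = gar/gra."""
    if not isinstance(rates, KineticRates):
        raise TypeError("q_coefficients_six expects plain KineticRates")
    return QCoefficients(
        q1=rates.gamma_10 / rates.gamma_01,
        q2=rates.gamma_off / rates.gamma_on,
        q3=rates.gamma_ar / rates.gamma_ra,
    )


def q2_eight(rates: EightStateRates) -> float:
    """Effective off-track:on-track ratio of the eight-state chain.

    q2 = 2 gamma_off / (alpha1 gamma_on1 + alpha2 gamma_on2) with the
    equilibrium phospho fractions alpha1, alpha2.  The factor two comes
    from the on-track pausing state feeding both off-track sub-states.
    """
    ph = rates.phospho
    denom = ph.alpha1 * rates.gamma_on1 + ph.alpha2 * rates.gamma_on2
    if not denom > 0:
        raise InvalidParameterError(
            "alpha1*gamma_on1 + alpha2*gamma_on2 must be positive"
        )
    return 2.0 * rates.base.gamma_off / denom


def _q_for(rates: RateSet) -> QCoefficients:
    if isinstance(rates, EightStateRates):
        b = rates.base
        return QCoefficients(
            q1=b.gamma_10 / b.gamma_01,
            q2=q2_eight(rates),
            q3=b.gamma_ar / b.gamma_ra,
        )
    if isinstance(rates, KineticRates):
        return q_coefficients_six(rates)
    raise TypeError("no closed-form q-coefficients for this rate set")


def steady_state_numeric(rates: RateSet) -> StateDistribution:
    """Steady state as the null eigenvector of the full rate matrix.

    Solves ``M p = 0`` with the normalisation ``sum(p) = 1`` by least
    squares; exact (to numerical precision) for every variant, including
    ``six_phospho`` for which no closed form exists.
    """
    M = transition_matrix(rates)
    n = M.shape[0]
    A = np.vstack([M, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    return StateDistribution(
        labels=state_labels(rates), probabilities=p, model_variant=variant_of(rates)
    )


def steady_state(rates: RateSet, method: str = "auto") -> StateDistribution:
    """Steady-state occupancy of the chain.

    ``method='closed_form'`` uses the analytic solution

        pa = rho, pr = q3 rho, pa0 = q1 rho, pr0 = q1 q3 rho,
        pap = q1 q2 rho, prp = q1 q2 q3 rho

    (for ``eight``, the off-track entries are additionally split by the
    equilibrium phospho fractions: Pap1 = alpha1 Pap, Pap2 = alpha2 Pap).
    That split is exact only when phospho exchange is fast compared with
    the on/off-track rates; ``method='numeric'`` returns the exact null
    eigenvector instead.  ``'auto'`` uses the closed form where one
    exists and falls back to numeric for ``six_phospho``.
    """
    variant = variant_of(rates)
    if method == "numeric" or (method == "auto" and variant == "six_phospho"):
        return steady_state_numeric(rates)
    if method not in ("auto", "closed_form"):
        raise ValueError(f"unknown method {method!r}")
    if variant == "six_phospho":
        raise DomainError("no closed-form steady state for six_phospho")
    q = _q_for(rates)
    rho = q.rho
    pap = q.q1 * q.q2 * rho
    if variant == "six":
        p = np.array([rho, q.q3 * rho, q.q1 * rho, q.q1 * q.q3 * rho, pap, q.q3 * pap])
        labels = SIX_STATE_LABELS
    else:
        a1, a2 = rates.phospho.alpha1, rates.phospho.alpha2
        p = np.array(
            [
                rho,
                q.q3 * rho,
                q.q1 * rho,
                q.q1 * q.q3 * rho,
                a1 * pap,
                a2 * pap,
                a1 * q.q3 * pap,
                a2 * q.q3 * pap,
            ]
        )
        labels = EIGHT_STATE_LABELS
    p = p / p.sum()  # remove last-digit rounding so the invariant is exact
    return StateDistribution(labels=labels, probabilities=p, model_variant=variant)


def mean_velocity(rates: RateSet, units: str = "um/s") -> float:
    """Long-run mean transport velocity of the chain.

    For ``six`` and ``eight`` this is the closed form
    ``v = rho (v_a + q3 v_r)`` with the variant-appropriate q2; for
    ``six_phospho`` it is computed from the numeric steady state as
    ``p_a v_a + p_r v_r``.  ``units`` may be ``"um/s"`` or ``"mm/day"``.
    """
    if isinstance(rates, SixPhosphoRates):
        v = steady_state_numeric(rates).velocity(rates.v_a, rates.v_r)
    else:
        q = _q_for(rates)
        v = q.rho * (rates.v_a + q.q3 * rates.v_r)
    if units == "um/s":
        return float(v)
    if units == "mm/day":
        return um_per_s_to_mm_per_day(float(v))
    raise ValueError(f"unknown units {units!r}")


def phospho_equilibrium(ph: PhosphoKinetics) -> tuple:
    """Equilibrium (dephosphorylated, phosphorylated) fractions.

    The two-state switch relaxes to P_de : P_ph = gamma_de : gamma_ph.
    """
    total = ph.gamma_de + ph.gamma_ph
    return ph.gamma_de / total, ph.gamma_ph / total


def phospho_weighted_velocity(
    v_fast: float, v_slow: float, ph: PhosphoKinetics
) -> float:
    """Mean velocity of a population split between a fast (dephosphorylated)
    and a slow (phosphorylated) transport mode:

        V = v_fast * f_de + v_slow * f_ph

    Valid when the phospho label persists over full transport cycles, so
    that each sub-population moves at its own equilibrium velocity.
    """
    if v_fast < v_slow:
        raise InvalidParameterError("v_fast must be >= v_slow")
    f_de, f_ph = phospho_equilibrium(ph)
    return v_fast * f_de + v_slow * f_ph
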