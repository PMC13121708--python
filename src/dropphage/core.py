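"""Closed-form encapsulation statistics and lysis kinetics for droplet phage assays.

A droplet of volume ``V`` formed from a phage-side solution (volume fraction
``alpha``, phage titer ``c_p``) and a bacteria-side solution (fraction
``1 - alpha``, density ``c_b``) encapsulates Poisson-distributed numbers of
phages and bacteria with means

    lambda_p = alpha * c_p * V,      lambda_b = (1 - alpha) * c_b * V.

A droplet shows a lysis event iff it holds at least one bacterium and at
least one (adsorbed) phage, giving the positive-droplet probability

    P_L = (1 - exp(-lambda_p)) * (1 - exp(-lambda_b)),

which for large lambda_b reduces to ``1 - exp(-lambda_p)`` and is inverted to
turn an observed positive fraction into a digital titer.  The kinetic variant
replaces lambda_p by ``lambda_p * A(t)`` with the delayed mass-action
adsorption fraction ``A(t) = 1 - exp(-(1-alpha) * k * c_b * (t - tau))``.

Units: titers in PFU/mL, densities in cells/mL, droplet volumes in pL, time
in minutes.  The pL -> mL conversion happens in exactly one place
(:data:`PL_TO_ML`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "PL_TO_ML",
    "RHO_CELLS_PER_OD_DEFAULT",
    "LARGE_LAMBDA_B",
    "InfeasiblePositiveFraction",
    "ModelParams",
    "KineticParams",
    "DropletCounts",
    "expected_lambdas",
    "p_lysis",
    "p_lysis_large_lambda_b",
    "invert_p_lysis",
    "titer_from_lambda",
    "p_lysis_kinetic",
    "adsorption_rate_from_effective",
    "dynamic_range",
]

#: Single unit-conversion constant: 1 pL = 1e-9 mL.
PL_TO_ML = 1e-9

#: Default OD600 -> cells/mL conversion factor.
RHO_CELLS_PER_OD_DEFAULT = 8e8

#: Occupancy threshold above which the bacterial factor of P_L is treated as
#: saturated (occupancy deficit exp(-10) < 5e-5).
LARGE_LAMBDA_B = 10.0


class InfeasiblePositiveFraction(ValueError):
    """Observed positive fraction at or above the bacterial-occupancy ceiling.

    The positive fraction can never exceed ``1 - exp(-lambda_b)`` (the
    probability that a droplet holds any bacterium at all); an observed value
    at or above this ceiling cannot be inverted to a phage occupancy and
    usually indicates upstream misclassification.
    """


def _check_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ValueError(f"{name} must be nonnegative, got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of one droplet population.

    ``lambda_p`` and ``lambda_b`` are derived on construction and always
    consistent with the primary fields.
    """

    alpha: float
    volume_pl: float
    c_p: float
    c_b: float
    lambda_p: float = field(init=False)
    lambda_b: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha!r}")
        if self.volume_pl <= 0:
            raise ValueError(f"volume_pl must be positive, got {self.volume_pl!r}")
        _check_nonneg(c_p=self.c_p, c_b=self.c_b)
        lp, lb = expected_lambdas(self.alpha, self.c_p, self.c_b, self.volume_pl)
        object.__setattr__(self, "lambda_p", lp)
        object.__setattr__(self, "lambda_b", lb)


@dataclass(frozen=True)
class KineticParams:
    """Adsorption kinetics on top of :class:`ModelParams`.

    ``k_cb_per_min`` is the effective first-order rate constant k*c_b (the
    product actually identified by a time-course fit); ``tau_min`` is the
    maturation/lag time before the first positives appear.  The second-order
    constant ``k_ml_per_min`` is optional and derived, not fitted.
    """

    model: ModelParams
    k_cb_per_min: float
    tau_min: float
    k_ml_per_min: float | None = None

    def __post_init__(self) -> None:
        _check_nonneg(k_cb_per_min=self.k_cb_per_min, tau_min=self.tau_min)


@dataclass(frozen=True)
class DropletCounts:
    """Realized encapsulation counts of a single droplet."""

    n_bacteria: int
    n_phages: int

    def __post_init__(self) -> None:
        _check_nonneg(n_bacteria=self.n_bacteria, n_phages=self.n_phages)


def expected_lambdas(
    alpha: float, c_p: float, c_b: float, volume_pl: float
) -> tuple[float, float]:
    """Expected phage and bacterium counts per droplet.

    Parameters
    ----------
    alpha : mixing fraction of the phage-side solution, in [0, 1].
    c_p : phage titer of the phage-side solution, PFU/mL.
    c_b : bacterial density of the bacteria-side solution, cells/mL.
    volume_pl : droplet volume, pL.

    Returns
    -------
    (lambda_p, lambda_b)
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha!r}")
    _check_nonneg(c_p=c_p, c_b=c_b, volume_pl=volume_pl)
    v_ml = volume_pl * PL_TO_ML
    return alpha * c_p * v_ml, (1.0 - alpha) * c_b * v_ml


def p_lysis(lambda_p: float, lambda_b: float) -> float:
    """Probability that a droplet holds >= 1 phage and >= 1 bacterium."""
    _check_nonneg(lambda_p=lambda_p, lambda_b=lambda_b)
    return -math.expm1(-lambda_p) * -math.expm1(-lambda_b)


def p_lysis_large_lambda_b(lambda_p: float) -> float:
    """Large-bacterial-occupancy limit of :func:`p_lysis`: 1 - exp(-lambda_p)."""
    _check_nonneg(lambda_p=lambda_p)
    return -math.expm1(-lambda_p)


def invert_p_lysis(p_l: float, lambda_b: float) -> float:
    """Invert Eq.-1-style statistics: positive fraction -> phage occupancy.

    ``lambda_b`` may be ``math.inf`` to request the large-occupancy limit.

    Raises
    ------
    InfeasiblePositiveFraction
        If ``p_l`` is at or above the ceiling ``1 - exp(-lambda_b)``.
    """
    _check_nonneg(p_l=p_l, lambda_b=lambda_b)
    ceiling = 1.0 if math.isinf(lambda_b) else -math.expm1(-lambda_b)
    if p_l == 0.0:
        return 0.0
    if p_l >= ceiling:
        raise InfeasiblePositiveFraction(
            f"observed positive fraction {p_l:.6g} exceeds the bacterial-occupancy "
            f"ceiling 1 - exp(-lambda_b) = {ceiling:.6g} (lambda_b = {lambda_b:.6g})"
        )
    return -math.log1p(-p_l / ceiling)


def titer_from_lambda(lambda_p: float, alpha: float, volume_pl: float) -> float:
    """Convert a phage occupancy into a digital titer c_p = lambda_p / (alpha V)."""
    _check_nonneg(lambda_p=lambda_p)
    if alpha <= 0 or volume_pl <= 0:
        raise ValueError("alpha and volume_pl must be positive to convert to a titer")
    return lambda_p / (alpha * volume_pl * PL_TO_ML)


def adsorption_fraction(t_min: float, kinetic: KineticParams) -> float:
    """Fraction A(t) of phages adsorbed by time t under delayed mass action.

    A(t) = 1 - exp(-(1 - alpha) * k c_b * (t - tau)) for t > tau, else 0.
    """
    if t_min < 0:
        raise ValueError(f"t_min must be nonnegative, got {t_min!r}")
    dt = t_min - kinetic.tau_min
    if dt <= 0:
        return 0.0
    return -math.expm1(-(1.0 - kinetic.model.alpha) * kinetic.k_cb_per_min * dt)


def p_lysis_kinetic(t_min: float, kinetic: KineticParams) -> float:
    """Time-resolved positive fraction P_L(t) = 1 - exp(-lambda_p * A(t)).

    Valid in the large-lambda_b regime (virtually every droplet holds
    bacteria); a warning is emitted when the configured occupancy is below
    :data:`LARGE_LAMBDA_B`.
    """
    if kinetic.model.lambda_b < LARGE_LAMBDA_B:
        warnings.warn(
            f"kinetic positive-fraction model assumes lambda_b >= {LARGE_LAMBDA_B:g}; "
            f"configured lambda_b = {kinetic.model.lambda_b:.3g}",
            stacklevel=2,
        )
    return -math.expm1(-kinetic.model.lambda_p * adsorption_fraction(t_min, kinetic))


def adsorption_rate_from_effective(
    k_cb_per_min: float, c_b_nominal: float, effective_fraction: float
) -> float:
    """Second-order adsorption constant k from the fitted effective rate k*c_b.

    The time-course fit identifies ``k * c_b_effective``; dividing by the
    effective (infection-competent) density ``effective_fraction *
    c_b_nominal`` recovers k in mL/min.
    """
    _check_nonneg(k_cb_per_min=k_cb_per_min)
    if c_b_nominal <= 0 or not 0.0 < effective_fraction <= 1.0:
        raise ValueError(
            "c_b_nominal must be positive and effective_fraction in (0, 1]"
        )
    return k_cb_per_min / (effective_fraction * c_b_nominal)


def dynamic_range(
    alpha: float,
    volume_pl: float,
    lambda_b: float,
    p_min: float = 0.01,
    p_max: float = 0.99,
) -> tuple[float, float]:
    """Titer range mapped onto positive fractions [p_min, p_max].

    Outside this band small changes in the positive fraction translate into
    large titer swings, so it brackets the assay's usable dynamic range.
    """
    if not 0.0 < p_min < p_max:
        raise ValueError("need 0 < p_min < p_max")
    lo = titer_from_lambda(invert_p_lysis(p_min, lambda_b), alpha, volume_pl)
    hi = titer_from_lambda(invert_p_lysis(p_max, lambda_b), alpha, volume_pl)
    return lo, hi
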