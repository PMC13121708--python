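"""Turn per-population positive fractions into scientific quantities.

* digital titers with confidence intervals (Wilson CI on P_L propagated
  through the monotone occupancy inversion),
* lysis-completion analysis f = P_L^exp / P_L^th across alpha groups,
* joint continuous-alpha fit of (c_p, effective c_b) to
  P_L(alpha) = (1 - exp(-alpha c_p V)) (1 - exp(-(1-alpha) c_b V)),
* kinetic fit of (c_p, tau, k*c_b) to
  P_L(t) = 1 - exp(-alpha c_p V (1 - exp(-(1-alpha) k c_b (t - tau)))),
* per-time digital-titer courses and the plate-count (DLA) reference titer.

Both nonlinear fits are weighted least squares with binomial weights
n / (P (1 - P) + eps) and a fixed multistart grid, so results are
deterministic given the data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.stats.proportion import proportion_confint

from . import core
from .core import (
    PL_TO_ML,
    RHO_CELLS_PER_OD_DEFAULT,
    InfeasiblePositiveFraction,
)

__all__ = [
    "TiterEstimate",
    "AlphaFit",
    "KineticFit",
    "LysisCompletion",
    "DlaMeasurement",
    "AlphaLysisModel",
    "LysisKineticsModel",
    "digital_titer",
    "lysis_completion_analysis",
    "fit_alpha_curve",
    "fit_kinetics",
    "titer_timecourse",
    "dla_titer",
]

WEIGHT_EPS = 1e-6


@dataclass(frozen=True)
class TiterEstimate:
    """Digital titer with CI, plus the inputs it was derived from."""

    lambda_p: float
    c_p: float
    ci_low: float
    ci_high: float
    alpha: float
    volume_pl: float
    lambda_b: float
    P_L: float
    n: int
    infeasible_upper: bool = False


@dataclass(frozen=True)
class DlaMeasurement:
    """Double-layer agar plaque counts; titer = mean(n) * dilution / volume."""

    plaque_counts: tuple
    dilution_factor: float
    plated_volume_ml: float = 0.1

    def __post_init__(self) -> None:
        if len(self.plaque_counts) < 1:
            raise ValueError("need at least one replicate plaque count")
        if self.plated_volume_ml <= 0:
            raise ValueError("plated volume must be positive")

    @property
    def titer(self) -> float:
        return float(np.mean(self.plaque_counts)) * self.dilution_factor / self.plated_volume_ml


@dataclass
class LysisCompletion:
    """Per-population lysis completion f = P_L^exp / P_L^th and its trend."""

    table: pd.DataFrame  # columns: alpha, lambda_b, p_exp, p_th, f, n
    slope: float
    intercept: float


@dataclass
class AlphaFit:
    """Joint fit of phage titer and effective bacterial density over alpha."""

    c_p: float
    c_b_effective: float
    od_effective: float
    effective_fraction: float | None
    r_squared: float
    volume_pl: float
    bins: pd.DataFrame  # alpha, P_L, n, fitted, residual
    sse: float
    n_starts: int


@dataclass
class KineticFit:
    """Fit of the delayed mass-action lysis model to a P_L time course."""

    c_p: float
    tau_min: float
    k_cb_per_min: float
    alpha: float
    volume_pl: float
    r_squared: float
    points: pd.DataFrame  # t, P_L, n, fitted, residual
    sse: float
    k_ml_per_min: float | None = None

    @property
    def plateau(self) -> float:
        return -math.expm1(-self.alpha * self.c_p * self.volume_pl * PL_TO_ML)

    def with_adsorption_constant(self, c_b_nominal: float,
                                 effective_fraction: float) -> "KineticFit":
        k = core.adsorption_rate_from_effective(
            self.k_cb_per_min, c_b_nominal, effective_fraction
        )
        return KineticFit(**{**self.__dict__, "k_ml_per_min": k})


def dla_titer(meas: DlaMeasurement) -> float:
    """Plate-count titer in PFU/mL."""
    return meas.titer


def digital_titer(
    P_L: float,
    ci: tuple[float, float],
    alpha: float,
    volume_pl: float,
    lambda_b: float,
) -> TiterEstimate:
    """Digital titer and CI from an observed positive fraction.

    The Wilson CI endpoints are mapped through the same monotone inversion as
    the point estimate; an upper endpoint at or above the occupancy ceiling
    yields an infinite upper bound with a flag rather than an error.
    """
    lam = core.invert_p_lysis(P_L, lambda_b)
    c_p = core.titer_from_lambda(lam, alpha, volume_pl)
    lo, hi = ci
    c_lo = core.titer_from_lambda(core.invert_p_lysis(max(lo, 0.0), lambda_b),
                                  alpha, volume_pl)
    infeasible_upper = False
    try:
        c_hi = core.titer_from_lambda(core.invert_p_lysis(hi, lambda_b),
                                      alpha, volume_pl)
    except InfeasiblePositiveFraction:
        c_hi, infeasible_upper = math.inf, True
    return TiterEstimate(
        lambda_p=lam, c_p=c_p, ci_low=c_lo, ci_high=c_hi,
        alpha=alpha, volume_pl=volume_pl, lambda_b=lambda_b,
        P_L=P_L, n=0, infeasible_upper=infeasible_upper,
    )


def lysis_completion_analysis(
    groups, dla_titer_pfu_ml: float, c_b_nominal: float, volume_pl: float
) -> LysisCompletion:
    """Completion fractions f per alpha group and their linear trend in lambda_b.

    ``groups`` is an iterable of (alpha, P_L_exp, n).  The theoretical
    positive fraction uses the plate-count titer and the nominal (OD-derived)
    bacterial density, so f < 1 reveals incomplete lysis or a lower effective
    density.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least two alpha groups")
    rows = []
    for alpha, p_exp, n in groups:
        lp, lb = core.expected_lambdas(alpha, dla_titer_pfu_ml, c_b_nominal, volume_pl)
        p_th = core.p_lysis(lp, lb)
        if p_th == 0:
            raise ValueError(f"theoretical P_L is zero at alpha={alpha}; f undefined")
        rows.append({"alpha": alpha, "lambda_b": lb, "p_exp": p_exp,
                     "p_th": p_th, "f": p_exp / p_th, "n": n})
    table = pd.DataFrame(rows)
    slope, intercept = np.polyfit(table["lambda_b"], table["f"], 1)
    return LysisCompletion(table=table, slope=float(slope), intercept=float(intercept))


def _binomial_weights(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    return n / (p * (1.0 - p) + WEIGHT_EPS)


def _weighted_r2(obs: np.ndarray, fit: np.ndarray, w: np.ndarray) -> float:
    ss_res = float(np.sum(w * (obs - fit) ** 2))
    mean = float(np.sum(w * obs) / np.sum(w))
    ss_tot = float(np.sum(w * (obs - mean) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


class AlphaLysisModel(BaseEstimator, RegressorMixin):
    """Weighted NLS fit of the co-encapsulation curve P_L(alpha).

    Model: ``P_L = (1 - exp(-alpha * a)) * (1 - exp(-(1 - alpha) * b))`` with
    ``a = c_p * V`` and ``b = c_b * V`` (droplet-scale occupancies), so the
    two concentrations decouple from the unit system during optimization.

    Parameters
    ----------
    volume_pl : droplet volume used to convert occupancies to concentrations.
    rho_cells_per_od : OD600 conversion factor for reporting the effective
        density as an optical density.
    c_b_nominal : optional nominal density; enables ``effective_fraction_``.
    a_grid, b_grid : multistart grids for the two occupancies.

    Attributes (after fit)
    ----------------------
    c_p_ : fitted phage titer, PFU/mL.
    c_b_effective_ : fitted effective bacterial density, cells/mL.
    effective_fraction_ : c_b_effective_ / c_b_nominal (None without nominal).
    r_squared_ : weighted coefficient of determination.
    result_ : AlphaFit record.
    """

    _a_grid_default = (0.01, 0.1, 1.0, 10.0)
    _b_grid_default = (1.0, 10.0, 100.0)

    def __init__(self, volume_pl: float,
                 rho_cells_per_od: float = RHO_CELLS_PER_OD_DEFAULT,
                 c_b_nominal: float | None = None,
                 a_grid: tuple = _a_grid_default,
                 b_grid: tuple = _b_grid_default) -> None:
        self.volume_pl = volume_pl
        self.rho_cells_per_od = rho_cells_per_od
        self.c_b_nominal = c_b_nominal
        self.a_grid = a_grid
        self.b_grid = b_grid

    @staticmethod
    def _model(alpha: np.ndarray, a: float, b: float) -> np.ndarray:
        return -np.expm1(-alpha * a) * -np.expm1(-(1.0 - alpha) * b)

    def fit(self, X, y, sample_weight=None):
        """Fit to per-bin data: X = alpha values, y = P_L, sample_weight = n."""
        alpha = np.asarray(X, dtype=float).ravel()
        p = np.asarray(y, dtype=float).ravel()
        n = (np.ones_like(p) if sample_weight is None
             else np.asarray(sample_weight, dtype=float).ravel())
        if alpha.size < 10:
            raise ValueError("need at least 10 usable bins")
        if np.ptp(alpha) < 0.2:
            raise ValueError("alpha range too narrow (< 0.2) to identify both densities")
        if np.all(p <= 0) or np.all(p >= 1):
            raise ValueError("degenerate data: all bins fully negative or positive")
        w = _binomial_weights(p, n)
        sw = np.sqrt(w)

        def residuals(theta):
            a, b = np.exp(theta)
            return sw * (self._model(alpha, a, b) - p)

        best = None
        for a0 in self.a_grid:
            for b0 in self.b_grid:
                try:
                    res = least_squares(residuals, x0=np.log([a0, b0]), method="lm")
                except Exception:
                    continue
                sse = float(np.sum(res.fun ** 2))
                cand = (sse, float(np.exp(res.x[0])), float(np.exp(res.x[1])), res)
                if (best is None or sse < best[0] - 1e-12
                        or (abs(sse - best[0]) <= 1e-12 and cand[1] < best[1])):
                    best = cand
        if best is None or not best[3].success:
            raise RuntimeError("alpha-curve fit failed to converge from any start")
        sse, a_hat, b_hat, _ = best

        v_ml = self.volume_pl * PL_TO_ML
        fitted = self._model(alpha, a_hat, b_hat)
        self.c_p_ = a_hat / v_ml
        self.c_b_effective_ = b_hat / v_ml
        self.effective_fraction_ = (
            None if self.c_b_nominal is None else self.c_b_effective_ / self.c_b_nominal
        )
        self.r_squared_ = _weighted_r2(p, fitted, w)
        self.result_ = AlphaFit(
            c_p=self.c_p_,
            c_b_effective=self.c_b_effective_,
            od_effective=self.c_b_effective_ / self.rho_cells_per_od,
            effective_fraction=self.effective_fraction_,
            r_squared=self.r_squared_,
            volume_pl=self.volume_pl,
            bins=pd.DataFrame({"alpha": alpha, "P_L": p, "n": n,
                               "fitted": fitted, "residual": p - fitted}),
            sse=sse,
            n_starts=len(self.a_grid) * len(self.b_grid),
        )
        return self

    def predict(self, X) -> np.ndarray:
        v_ml = self.volume_pl * PL_TO_ML
        return self._model(np.asarray(X, dtype=float).ravel(),
                           self.c_p_ * v_ml, self.c_b_effective_ * v_ml)


class LysisKineticsModel(BaseEstimator, RegressorMixin):
    """Weighted NLS fit of the delayed mass-action lysis time course.

    Model: ``P_L(t) = 1 - exp(-a * A(t))`` with ``a = alpha c_p V`` and
    ``A(t) = 1 - exp(-r (t - tau)_+)``, ``r = (1 - alpha) k c_b``.  Assumes
    the large-bacterial-occupancy regime; a warning fires if ``lambda_b``
    (when provided) is below the saturation threshold.

    Attributes (after fit): ``c_p_``, ``tau_min_``, ``k_cb_per_min_``,
    ``r_squared_``, ``result_`` (a :class:`KineticFit`).
    """

    _a_grid_default = (0.01, 0.1, 1.0, 10.0)
    _r_grid_default = (1e-4, 1e-3, 1e-2, 1e-1)

    def __init__(self, alpha: float, volume_pl: float,
                 lambda_b: float | None = None,
                 a_grid: tuple = _a_grid_default,
                 r_grid: tuple = _r_grid_default,
                 n_tau_starts: int = 5) -> None:
        self.alpha = alpha
        self.volume_pl = volume_pl
        self.lambda_b = lambda_b
        self.a_grid = a_grid
        self.r_grid = r_grid
        self.n_tau_starts = n_tau_starts

    @staticmethod
    def _model(t: np.ndarray, a: float, tau: float, r: float) -> np.ndarray:
        at = -np.expm1(-r * np.maximum(t - tau, 0.0))
        return -np.expm1(-a * at)

    def fit(self, X, y, sample_weight=None):
        """Fit to per-time data: X = times (min), y = P_L, sample_weight = n."""
        t = np.asarray(X, dtype=float).ravel()
        p = np.asarray(y, dtype=float).ravel()
        n = (np.ones_like(p) if sample_weight is None
             else np.asarray(sample_weight, dtype=float).ravel())
        if t.size < 4:
            raise ValueError("need at least 4 time points")
        if self.lambda_b is not None and self.lambda_b < core.LARGE_LAMBDA_B:
            warnings.warn(
                f"kinetic fit assumes lambda_b >= {core.LARGE_LAMBDA_B:g}; "
                f"configured lambda_b = {self.lambda_b:.3g}", stacklevel=2,
            )
        pos = p > 0
        if not pos.any():
            raise ValueError("no positive time points; kinetics unidentifiable")
        p_max_model = p[pos].max()
        if p.min() >= 0.95 * p_max_model and t.size >= 4 and np.ptp(p) < 0.02:
            raise ValueError("all points at plateau; tau unidentifiable")
        tau_hi = float(t[pos].min())
        tau_starts = np.linspace(0.0, tau_hi, self.n_tau_starts)
        w = _binomial_weights(p, n)
        sw = np.sqrt(w)

        def residuals(theta):
            a, r = np.exp(theta[0]), np.exp(theta[2])
            tau = theta[1]
            return sw * (self._model(t, a, tau, r) - p)

        best = None
        for a0 in self.a_grid:
            for r0 in self.r_grid:
                for tau0 in tau_starts:
                    res = least_squares(
                        residuals,
                        x0=[math.log(a0), tau0, math.log(r0)],
                        bounds=([-30.0, 0.0, -30.0], [30.0, tau_hi, 10.0]),
                        method="trf",
                    )
                    if not res.success:
                        continue
                    sse = float(np.sum(res.fun ** 2))
                    a_hat = float(np.exp(res.x[0]))
                    cand = (sse, a_hat, float(res.x[1]), float(np.exp(res.x[2])))
                    if (best is None or sse < best[0] - 1e-12
                            or (abs(sse - best[0]) <= 1e-12 and a_hat < best[1])):
                        best = cand
        if best is None:
            raise RuntimeError("kinetic fit failed to converge from any start")
        sse, a_hat, tau_hat, r_hat = best

        v_ml = self.volume_pl * PL_TO_ML
        self.c_p_ = a_hat / (self.alpha * v_ml)
        self.tau_min_ = tau_hat
        self.k_cb_per_min_ = r_hat / (1.0 - self.alpha)
        fitted = self._model(t, a_hat, tau_hat, r_hat)
        self.r_squared_ = _weighted_r2(p, fitted, w)
        self.result_ = KineticFit(
            c_p=self.c_p_, tau_min=self.tau_min_, k_cb_per_min=self.k_cb_per_min_,
            alpha=self.alpha, volume_pl=self.volume_pl, r_squared=self.r_squared_,
            points=pd.DataFrame({"t_min": t, "P_L": p, "n": n,
                                 "fitted": fitted, "residual": p - fitted}),
            sse=sse,
        )
        return self

    def predict(self, X) -> np.ndarray:
        v_ml = self.volume_pl * PL_TO_ML
        return self._model(
            np.asarray(X, dtype=float).ravel(),
            self.alpha * self.c_p_ * v_ml, self.tau_min_,
            (1.0 - self.alpha) * self.k_cb_per_min_,
        )


def fit_alpha_curve(
    bins, volume_pl: float,
    rho_cells_per_od: float = RHO_CELLS_PER_OD_DEFAULT,
    c_b_nominal: float | None = None,
) -> AlphaFit:
    """Fit (c_p, effective c_b) to per-bin (alpha, P_L, n) triples."""
    bins = list(bins)
    alpha = [b[0] for b in bins]
    p = [b[1] for b in bins]
    n = [b[2] for b in bins]
    model = AlphaLysisModel(volume_pl=volume_pl, rho_cells_per_od=rho_cells_per_od,
                            c_b_nominal=c_b_nominal)
    return model.fit(alpha, p, sample_weight=n).result_


def fit_kinetics(points, alpha: float, volume_pl: float,
                 lambda_b: float | None = None) -> KineticFit:
    """Fit (c_p, tau, k*c_b) to per-time (t, P_L, n) triples."""
    points = list(points)
    t = [q[0] for q in points]
    p = [q[1] for q in points]
    n = [q[2] for q in points]
    model = LysisKineticsModel(alpha=alpha, volume_pl=volume_pl, lambda_b=lambda_b)
    return model.fit(t, p, sample_weight=n).result_


def titer_timecourse(
    points, alpha: float, volume_pl: float, lambda_b: float
) -> list[TiterEstimate | None]:
    """Per-time digital titers; infeasible or zero points yield None entries.

    Each entry is the naive end-point digital titer at that exposure time; the
    sequence rises toward the true titer as lysis completes.
    """
    out: list[TiterEstimate | None] = []
    for t, p, n in points:
        try:
            lo, hi = proportion_confint(round(p * n), n, method="wilson")
            est = digital_titer(p, (float(lo), float(hi)), alpha, volume_pl, lambda_b)
            out.append(est)
        except InfeasiblePositiveFraction:
            out.append(None)
    return out
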