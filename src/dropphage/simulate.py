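"""Stochastic droplet-emulsion simulator.

Generates droplet event tables with the statistical structure the analysis
pipeline assumes, standing in for the microfluidic production/scanning
instrument:

* Poisson co-encapsulation of phages and bacteria at occupancies set by the
  mixing fraction ``alpha``, droplet volume and stock concentrations;
* per-phage adsorption with a maturation delay ``tau`` (mean-field bulk rate
  by default, an optional per-droplet mass-action variant);
* log-normal green fluorescence with one mode per completed lysis tier, a
  spontaneous-lysis tail and a secondary (progeny-driven) lysis shift;
* a red reference channel encoding ``alpha`` (peak) and droplet size (width);
* coalescence outliers with multiplied volume.

Ground truth (counts, realized alpha and volume, lysis outcome, artifact
flags) is returned alongside the events so recovery tests are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PL_TO_ML

__all__ = [
    "EmulsionSpec",
    "FluorescenceModel",
    "KineticTruth",
    "Trace",
    "simulate_emulsion",
    "simulate_timecourse",
    "simulate_trace",
]

TRUTH_COLUMNS = [
    "droplet_id",
    "alpha",
    "volume_pl",
    "n_bacteria",
    "n_phages",
    "n_adsorbed",
    "n_lysed",
    "tier",
    "is_positive",
    "spontaneous",
    "secondary",
    "coalesced",
]


@dataclass(frozen=True)
class KineticTruth:
    """Generative adsorption kinetics: effective rate k*c_b_eff and lag tau."""

    k_cb_per_min: float
    tau_min: float
    per_droplet: bool = False

    def __post_init__(self) -> None:
        if self.k_cb_per_min < 0 or self.tau_min < 0:
            raise ValueError("kinetic parameters must be nonnegative")


@dataclass(frozen=True)
class EmulsionSpec:
    """Ground-truth parameterization of one simulated emulsion.

    ``alpha_mode`` is one of ``fixed`` (alpha_values: float),
    ``discrete_set`` (list of (alpha, weight)) or ``continuous_uniform``
    ((low, high) range).  ``volume_modes`` is a list of (volume_pl, weight)
    pairs; one entry gives a monodisperse emulsion, two a bimodal one.
    ``c_b_effective`` is the density of infection-competent cells actually
    driving lysis; ``c_b_nominal`` is what a bulk OD measurement would claim.
    """

    n_droplets: int
    alpha_mode: str
    alpha_values: object
    volume_modes: tuple
    c_p: float
    c_b_nominal: float
    c_b_effective: float | None = None
    kinetics: KineticTruth | None = None
    incubation_min: float = float("inf")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if self.alpha_mode not in ("fixed", "discrete_set", "continuous_uniform"):
            raise ValueError(f"unknown alpha_mode {self.alpha_mode!r}")
        vols = np.asarray([v for v, _ in self.volume_modes], dtype=float)
        wts = np.asarray([w for _, w in self.volume_modes], dtype=float)
        if np.any(vols <= 0):
            raise ValueError("droplet volumes must be positive")
        if not math.isclose(wts.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("volume-mode weights must sum to 1")
        if self.c_p < 0 or self.c_b_nominal < 0:
            raise ValueError("concentrations must be nonnegative")
        if self.c_b_eff > self.c_b_nominal:
            raise ValueError("c_b_effective cannot exceed c_b_nominal")

    @property
    def c_b_eff(self) -> float:
        return self.c_b_nominal if self.c_b_effective is None else self.c_b_effective


@dataclass(frozen=True)
class FluorescenceModel:
    """Signal model turning lysis outcomes into two-channel fluorescence.

    Green: log-normal with natural-log mean ``green_log_mean_neg + tier *
    green_log_shift`` (tier = completed lysis events up to ``tier_cap``) plus
    ``multicycle_log_shift`` when secondary, progeny-driven lysis occurred.
    Red: peak = ``red_offset + red_gain * alpha`` and width =
    ``red_width_coeff * (6 V / pi)**(1/3)``, both with multiplicative
    log-normal noise of the given coefficient of variation.
    """

    green_log_mean_neg: float = 5.0
    green_log_sd: float = 0.15
    green_log_shift: float = 1.0
    tier_cap: int = 2
    multicycle_log_shift: float = 1.0
    burst_period_min: float = 30.0
    spontaneous_lysis_prob: float = 1e-5
    red_gain: float = 1.0
    red_offset: float = 0.1
    red_width_coeff: float = 10.0
    red_noise_sd: float = 0.02
    green_noise_sd: float = 0.0
    coalescence_prob: float = 0.005
    coalesced_volume_factor: float = 2.0

    def __post_init__(self) -> None:
        if min(self.green_log_sd, self.red_noise_sd, self.green_noise_sd) < 0:
            raise ValueError("noise SDs must be nonnegative")
        if not 0.0 <= self.spontaneous_lysis_prob <= 1.0:
            raise ValueError("spontaneous_lysis_prob must lie in [0, 1]")
        if not 0.0 <= self.coalescence_prob <= 1.0:
            raise ValueError("coalescence_prob must lie in [0, 1]")

    def red_peak_of_alpha(self, alpha: float) -> float:
        """Noise-free red peak for a given mixing fraction (calibration aid)."""
        return self.red_offset + self.red_gain * alpha


def _draw_alpha(spec: EmulsionSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_droplets
    if spec.alpha_mode == "fixed":
        return np.full(n, float(spec.alpha_values))
    if spec.alpha_mode == "discrete_set":
        pairs = list(spec.alpha_values)
        vals = np.asarray([a for a, _ in pairs], dtype=float)
        wts = np.asarray([w for _, w in pairs], dtype=float)
        wts = wts / wts.sum()
        return vals[rng.choice(len(vals), size=n, p=wts)]
    lo, hi = spec.alpha_values
    return rng.uniform(lo, hi, size=n)


def _mult_noise(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    # mean-1 multiplicative log-normal noise
    if sd == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(sd * sd))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=n)


def simulate_emulsion(
    spec: EmulsionSpec,
    fluor: FluorescenceModel | None = None,
    t_min: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one emulsion scanned at a single observation time.

    Returns ``(events, truth)``: the event table (droplet_id, green_peak,
    red_peak, red_width, time_min) and the matching ground-truth table.
    """
    fluor = fluor or FluorescenceModel()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    t_obs = spec.incubation_min if t_min is None else t_min
    if t_obs < 0:
        raise ValueError("observation time must be nonnegative")
    n = spec.n_droplets

    alpha = _draw_alpha(spec, rng)
    vols = np.asarray([v for v, _ in spec.volume_modes], dtype=float)
    wts = np.asarray([w for _, w in spec.volume_modes], dtype=float)
    volume = vols[rng.choice(len(vols), size=n, p=wts / wts.sum())]
    coalesced = rng.random(n) < fluor.coalescence_prob
    volume = np.where(coalesced, volume * fluor.coalesced_volume_factor, volume)

    v_ml = volume * PL_TO_ML
    b = rng.poisson((1.0 - alpha) * spec.c_b_eff * v_ml)
    p = rng.poisson(alpha * spec.c_p * v_ml)

    # per-phage adsorption probability by t_obs
    kin = spec.kinetics
    if kin is None:
        a_t = np.ones(n)
        rate = np.full(n, np.inf)
        dt = np.full(n, np.inf)
    else:
        dt = np.maximum(t_obs - kin.tau_min, 0.0)
        if kin.per_droplet:
            # mass action with the droplet's own bacterial concentration b/V;
            # k recovered from the effective first-order constant
            k_ml = kin.k_cb_per_min / spec.c_b_eff if spec.c_b_eff > 0 else 0.0
            rate = k_ml * (b / v_ml)
        else:
            rate = (1.0 - alpha) * kin.k_cb_per_min
        a_t = -np.expm1(-rate * dt)
        a_t = np.broadcast_to(a_t, (n,)).copy() if np.ndim(a_t) == 0 else a_t
        rate = np.broadcast_to(rate, (n,)).copy() if np.ndim(rate) == 0 else rate
        dt = np.full(n, dt) if np.ndim(dt) == 0 else dt

    n_ads = rng.binomial(p, a_t)
    n_primary = np.minimum(b, n_ads)
    is_positive = (b >= 1) & (n_ads >= 1)

    n_spont = rng.binomial(b - n_primary, fluor.spontaneous_lysis_prob)
    spontaneous = (n_spont >= 1) & ~is_positive
    n_lysed = n_primary + n_spont
    tier = np.minimum(n_lysed, fluor.tier_cap)

    # secondary, progeny-driven lysis: first adsorption happened long enough
    # before observation for a burst to release progeny, and hosts remain
    secondary = np.zeros(n, dtype=bool)
    if kin is not None and fluor.multicycle_log_shift > 0:
        m = n_ads >= 1
        if np.any(m):
            u = rng.random(m.sum())
            lam = rate[m] * n_ads[m]
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = -np.log1p(-u * -np.expm1(-lam * dt[m])) / lam
            t_first = kin.tau_min + np.where(np.isfinite(frac), frac, 0.0)
            secondary[m] = (
                (t_obs - t_first > fluor.burst_period_min) & (b[m] > n_primary[m])
            )
    elif kin is None and fluor.multicycle_log_shift > 0:
        # equilibrium readout: every positive droplet with spare hosts has
        # had time for at least one further cycle
        secondary = is_positive & (b > n_primary)

    log_mu = (
        fluor.green_log_mean_neg
        + fluor.green_log_shift * tier
        + fluor.multicycle_log_shift * secondary
    )
    green = np.exp(rng.normal(log_mu, fluor.green_log_sd)) * _mult_noise(
        rng, fluor.green_noise_sd, n
    )
    red_peak = (fluor.red_offset + fluor.red_gain * alpha) * _mult_noise(
        rng, fluor.red_noise_sd, n
    )
    diameter = np.cbrt(6.0 * volume / math.pi)
    red_width = fluor.red_width_coeff * diameter * _mult_noise(
        rng, fluor.red_noise_sd, n
    )

    ids = np.arange(n, dtype=np.int64)
    events = pd.DataFrame(
        {
            "droplet_id": ids,
            "green_peak": green,
            "red_peak": red_peak,
            "red_width": red_width,
            "time_min": np.full(n, t_obs if math.isfinite(t_obs) else np.nan),
        }
    )
    truth = pd.DataFrame(
        {
            "droplet_id": ids,
            "alpha": alpha,
            "volume_pl": volume,
            "n_bacteria": b,
            "n_phages": p,
            "n_adsorbed": n_ads,
            "n_lysed": n_lysed,
            "tier": tier,
            "is_positive": is_positive,
            "spontaneous": spontaneous,
            "secondary": secondary,
            "coalesced": coalesced,
        }
    )
    return events, truth


def simulate_timecourse(
    spec: EmulsionSpec,
    fluor: FluorescenceModel | None = None,
    times_min: list[float] | None = None,
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Simulate one emulsion aliquot per observation time (destructive readout).

    Each time point is an independent draw sharing ``spec``; the returned list
    holds ``(events, truth)`` per time, with ``time_min`` stamped on events.
    """
    if not times_min:
        raise ValueError("times_min must be a nonempty sorted list")
    if any(t < 0 for t in times_min) or sorted(times_min) != list(times_min):
        raise ValueError("times_min must be sorted and nonnegative")
    rng = np.random.default_rng(spec.seed)
    return [simulate_emulsion(spec, fluor, t_min=t, rng=rng) for t in times_min]


@dataclass(frozen=True)
class Trace:
    """Synthetic two-channel photodetector trace with acquisition metadata."""

    red: np.ndarray
    green: np.ndarray
    sampling_rate_hz: float
    width_scale_s: float

    @property
    def n_samples(self) -> int:
        return self.red.size


def simulate_trace(
    events: pd.DataFrame,
    sampling_rate_hz: float = 100_000.0,
    spacing_s: float = 5e-3,
    width_scale_s: float = 2e-5,
) -> Trace:
    """Render an event table as a sequential two-channel pulse train.

    One rectangular pulse per droplet on each channel; pulse height is the
    channel peak and pulse duration is ``red_width * width_scale_s``.  Raises
    if any pulse would overlap its neighbour's slot.
    """
    if sampling_rate_hz <= 0 or spacing_s <= 0 or width_scale_s <= 0:
        raise ValueError("sampling rate, spacing and width scale must be positive")
    n = len(events)
    durations = events["red_width"].to_numpy() * width_scale_s if n else np.array([])
    if n and durations.max() >= spacing_s:
        raise ValueError(
            f"pulse duration {durations.max():.3g}s exceeds droplet spacing "
            f"{spacing_s:.3g}s; increase spacing_s"
        )
    total_s = spacing_s * (n + 1)
    n_samples = int(round(total_s * sampling_rate_hz))
    red = np.zeros(n_samples)
    green = np.zeros(n_samples)
    for i in range(n):
        start = int(round((spacing_s * (i + 0.5)) * sampling_rate_hz))
        stop = start + max(int(round(durations[i] * sampling_rate_hz)), 1)
        red[start:stop] = events["red_peak"].iat[i]
        green[start:stop] = events["green_peak"].iat[i]
    return Trace(red=red, green=green, sampling_rate_hz=sampling_rate_hz,
                 width_scale_s=width_scale_s)
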