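"""Reference study protocols: canonical end-to-end simulation + analysis runs.

Two workhorse designs exercised throughout the test suite and the
reproduction script:

* ``continuous_alpha_study`` — a single emulsion whose mixing fraction was
  swept continuously during production; binning the red signal and fitting
  the co-encapsulation curve recovers the phage titer and the effective
  (infection-competent) bacterial density jointly, with no bulk reference.
* ``kinetics_study`` — aliquots of one emulsion scanned after increasing
  incubation times; fitting the delayed mass-action model recovers the
  titer, the maturation lag tau and the effective adsorption rate k*c_b.

Generative parameter defaults follow the regimes the method was designed
for: titers around 1e8 PFU/mL, OD-derived nominal densities around 2e9
cells/mL of which ~29% are infection-competent, lags of ~25 min and
effective rates of ~6e-3/min.  Droplet volumes are chosen so the expected
phage occupancy stays within the assay's informative band (lambda_p <~ 2).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import core
from .digitize import fit_mixture, positive_fraction, timecourse_positive_fractions
from .estimation import AlphaFit, KineticFit, fit_alpha_curve, fit_kinetics
from .populations import AlphaCalibration, bin_continuous_alpha
from .simulate import EmulsionSpec, FluorescenceModel, KineticTruth, simulate_timecourse, simulate_emulsion

__all__ = [
    "ContinuousAlphaStudy",
    "KineticsStudy",
    "continuous_alpha_study",
    "kinetics_study",
    "run_continuous_alpha",
    "run_kinetics",
]


@dataclass(frozen=True)
class ContinuousAlphaStudy:
    spec: EmulsionSpec
    fluor: FluorescenceModel
    calibration: AlphaCalibration
    volume_pl: float
    n_bins: int
    min_bin_count: int
    c_p_true: float
    c_b_nominal: float
    effective_fraction_true: float


@dataclass(frozen=True)
class KineticsStudy:
    spec: EmulsionSpec
    fluor: FluorescenceModel
    times_min: tuple
    alpha: float
    volume_pl: float
    c_p_true: float
    tau_true_min: float
    k_cb_true_per_min: float
    lambda_b: float


def continuous_alpha_study(
    seed: int,
    n_droplets: int = 720_000,
    c_p: float = 1.205e8,
    od_effective: float = 0.773,
    effective_fraction: float = 0.286,
    volume_pl: float = 15.0,
    alpha_range: tuple[float, float] = (0.02, 0.98),
    n_bins: int = 300,
    min_bin_count: int = 50,
    rho_cells_per_od: float = core.RHO_CELLS_PER_OD_DEFAULT,
) -> ContinuousAlphaStudy:
    """Continuous mixing-fraction sweep at full production scale."""
    c_b_eff = od_effective * rho_cells_per_od
    c_b_nom = c_b_eff / effective_fraction
    fluor = FluorescenceModel()
    spec = EmulsionSpec(
        n_droplets=n_droplets,
        alpha_mode="continuous_uniform",
        alpha_values=alpha_range,
        volume_modes=((volume_pl, 1.0),),
        c_p=c_p,
        c_b_nominal=c_b_nom,
        c_b_effective=c_b_eff,
        seed=seed,
    )
    cal = AlphaCalibration(
        red_low=fluor.red_peak_of_alpha(alpha_range[0]), alpha_min=alpha_range[0],
        red_high=fluor.red_peak_of_alpha(alpha_range[1]), alpha_max=alpha_range[1],
    )
    return ContinuousAlphaStudy(
        spec=spec, fluor=fluor, calibration=cal, volume_pl=volume_pl,
        n_bins=n_bins, min_bin_count=min_bin_count, c_p_true=c_p,
        c_b_nominal=c_b_nom, effective_fraction_true=effective_fraction,
    )


def run_continuous_alpha(study: ContinuousAlphaStudy, seed: int) -> AlphaFit:
    """Simulate, bin, digitize per bin, and fit the co-encapsulation curve."""
    events, _truth = simulate_emulsion(study.spec, study.fluor)
    asg = bin_continuous_alpha(
        events["red_peak"], study.n_bins, study.min_bin_count, study.calibration
    )
    bins = []
    for _, row in asg.groups.iterrows():
        mask = asg.labels == row["group"]
        fit = fit_mixture(events.loc[mask, "green_peak"], seed=seed + int(row["group"]))
        p, _ci = positive_fraction(fit)
        bins.append((row["alpha"], p, int(row["n"])))
    return fit_alpha_curve(
        bins, study.volume_pl, c_b_nominal=study.c_b_nominal
    )


def kinetics_study(
    seed: int,
    n_per_time: int = 100_000,
    c_p: float = 8.30e7,
    tau_min: float = 24.6,
    k_cb_per_min: float = 0.0061,
    alpha: float = 0.5,
    volume_pl: float = 40.0,
    c_b_nominal: float = 1.83e9,
    effective_fraction: float = 0.286,
    times_min: tuple = (10.0, 30.0, 60.0, 100.0, 150.0, 220.0, 350.0, 600.0),
) -> KineticsStudy:
    """Single-size lysis time course in the delayed mass-action regime."""
    c_b_eff = effective_fraction * c_b_nominal
    spec = EmulsionSpec(
        n_droplets=n_per_time,
        alpha_mode="fixed",
        alpha_values=alpha,
        volume_modes=((volume_pl, 1.0),),
        c_p=c_p,
        c_b_nominal=c_b_nominal,
        c_b_effective=c_b_eff,
        kinetics=KineticTruth(k_cb_per_min=k_cb_per_min, tau_min=tau_min),
        seed=seed,
    )
    lambda_b = (1.0 - alpha) * c_b_eff * volume_pl * core.PL_TO_ML
    return KineticsStudy(
        spec=spec, fluor=FluorescenceModel(), times_min=tuple(times_min),
        alpha=alpha, volume_pl=volume_pl, c_p_true=c_p, tau_true_min=tau_min,
        k_cb_true_per_min=k_cb_per_min, lambda_b=lambda_b,
    )


def run_kinetics(study: KineticsStudy, seed: int) -> KineticFit:
    """Simulate aliquots, digitize each, and fit the lysis time course."""
    course = simulate_timecourse(study.spec, study.fluor, list(study.times_min))
    fracs = timecourse_positive_fractions(
        [events["green_peak"] for events, _truth in course], seed=seed
    )
    points = [(t, p, n) for t, (p, _ci, n) in zip(study.times_min, fracs)]
    return fit_kinetics(
        points, study.alpha, study.volume_pl, lambda_b=study.lambda_b
    )
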