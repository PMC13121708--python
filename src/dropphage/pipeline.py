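"""End-to-end pipeline: simulate/load -> populations -> digitize -> estimate.

``run_pipeline`` executes the stages a droplet phage assay needs, driven by a
validated :class:`~dropphage.config.RunConfig`, and assembles a single
JSON-serializable report keyed by stage.  Every stage logs its parameters and
counts; per-stage tables can be written alongside the report.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import fields as _dc_fields
from pathlib import Path

import numpy as np

from . import core, digitize, estimation, io as evio, populations as pops
from .config import RunConfig
from .simulate import EmulsionSpec, FluorescenceModel, KineticTruth, simulate_emulsion, simulate_timecourse

__all__ = ["run_pipeline", "report_to_json", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = "1"
log = logging.getLogger("dropphage")


def _round12(x):
    if isinstance(x, float):
        if math.isfinite(x):
            return float(f"{x:.12g}")
        return None if math.isnan(x) else ("inf" if x > 0 else "-inf")
    if isinstance(x, dict):
        return {k: _round12(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round12(v) for v in x]
    if isinstance(x, (np.floating,)):
        return _round12(float(x))
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    return x


def report_to_json(report: dict) -> str:
    """Serialize a report deterministically (sorted keys, 12 sig digits)."""
    return json.dumps(_round12(report), indent=2, sort_keys=True)


def _fluor_from_config(sim) -> FluorescenceModel:
    overrides = {}
    for f in _dc_fields(FluorescenceModel):
        v = getattr(sim, f.name, None)
        if v is not None:
            overrides[f.name] = v
    return FluorescenceModel(**overrides)


def _spec_from_config(cfg: RunConfig) -> EmulsionSpec:
    sim = cfg.simulation
    alpha_values = {
        "fixed": sim.alpha,
        "discrete_set": sim.alpha_set,
        "continuous_uniform": sim.alpha_range,
    }[sim.alpha_mode]
    kinetics = None
    if sim.k_cb_per_min is not None:
        kinetics = KineticTruth(
            k_cb_per_min=sim.k_cb_per_min,
            tau_min=sim.tau_min or 0.0,
            per_droplet=sim.per_droplet_kinetics,
        )
    return EmulsionSpec(
        n_droplets=sim.n_droplets,
        alpha_mode=sim.alpha_mode,
        alpha_values=alpha_values,
        volume_modes=tuple(sim.volume_modes),
        c_p=sim.c_p,
        c_b_nominal=sim.c_b_nominal,
        c_b_effective=sim.c_b_effective,
        kinetics=kinetics,
        incubation_min=sim.incubation_min,
        seed=cfg.seed,
    )


def _digitize_population(green, cfg: RunConfig, seed: int):
    fit = digitize.fit_mixture(
        green, k_max=cfg.digitization.k_max, seed=seed,
        compute_silhouette=cfg.digitization.compute_silhouette,
    )
    p, ci = digitize.positive_fraction(fit, method=cfg.digitization.method)
    return fit, p, ci


def _mean_volume(cfg: RunConfig) -> float:
    vm = cfg.simulation.volume_modes
    return sum(v * w for v, w in vm)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all configured stages; return the assembled report."""
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "seed": cfg.seed,
                    "stages": {}}
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # ---- source stage -----------------------------------------------------
    timecourse = None
    if cfg.simulation is not None:
        spec = _spec_from_config(cfg)
        fluor = _fluor_from_config(cfg.simulation)
        if cfg.simulation.times_min:
            timecourse = simulate_timecourse(spec, fluor, cfg.simulation.times_min)
            events = timecourse[-1][0]
            log.info("simulated %d time points x %d droplets",
                     len(timecourse), spec.n_droplets)
        else:
            events, _truth = simulate_emulsion(spec, fluor)
            log.info("simulated %d droplets", len(events))
        report["stages"]["simulate"] = {
            "n_droplets": int(spec.n_droplets),
            "alpha_mode": spec.alpha_mode,
            "c_p_true": spec.c_p,
            "c_b_nominal": spec.c_b_nominal,
            "c_b_effective": spec.c_b_eff,
        }
    else:
        events = evio.read_events(cfg.events_path)
        log.info("read %d events from %s", len(events), cfg.events_path)
        report["stages"]["read"] = {"path": str(cfg.events_path),
                                    "n_droplets": int(len(events))}
    if out_dir is not None:
        evio.write_events(events, out_dir / "events.csv", {"seed": cfg.seed})

    sim = cfg.simulation
    rho = cfg.estimation.rho_cells_per_od
    c_b_for_lambda = (sim.c_b_effective or sim.c_b_nominal) if sim else None
    volume_pl = _mean_volume(cfg) if sim else None

    # ---- populations + digitization + estimation --------------------------
    mode = cfg.populations.mode
    if mode == "none":
        est: dict = {}
        try:
            fit, p, ci = _digitize_population(events["green_peak"], cfg, cfg.seed)
            digi = {"whole": _mixture_record(fit, p, ci)}
        except digitize.AmbiguousDigitizationError as exc:
            digi = {"whole": {"ambiguous": True, "detail": str(exc)}}
            p = ci = None
        if p is not None and sim and sim.alpha_mode == "fixed":
            _lp, lb = core.expected_lambdas(sim.alpha, 0.0, c_b_for_lambda, volume_pl)
            try:
                t = estimation.digital_titer(p, ci, sim.alpha, volume_pl, lb)
                est["titer"] = _titer_record(t)
            except core.InfeasiblePositiveFraction as exc:
                est["titer"] = {"infeasible": True, "detail": str(exc)}
        elif p is None:
            est["titer"] = {"infeasible": True,
                            "detail": "digitization ambiguous (single mode)"}
        report["stages"]["digitize"] = digi
        if est:
            report["stages"]["estimate"] = est

    elif mode == "discrete":
        asg = pops.find_discrete_groups(
            events["red_peak"], cfg.populations.n_groups, seed=cfg.seed,
            red_widths=events["red_width"],
            posterior_floor=cfg.populations.posterior_floor,
        )
        digi = {}
        for g in asg.groups["group"]:
            mask = asg.labels == g
            fit, p, ci = _digitize_population(
                events.loc[mask, "green_peak"], cfg, cfg.seed + int(g))
            digi[f"group_{g}"] = _mixture_record(fit, p, ci)
        report["stages"]["populations"] = _assignment_record(asg)
        report["stages"]["digitize"] = digi

    elif mode == "continuous":
        cal = pops.AlphaCalibration(**cfg.calibration.model_dump())
        asg = pops.bin_continuous_alpha(
            events["red_peak"], cfg.populations.n_bins,
            cfg.populations.min_bin_count, cal)
        bins = []
        for _, row in asg.groups.iterrows():
            mask = asg.labels == row["group"]
            fit, p, ci = _digitize_population(
                events.loc[mask, "green_peak"], cfg, cfg.seed + int(row["group"]))
            bins.append((row["alpha"], p, int(row["n"])))
        report["stages"]["populations"] = _assignment_record(asg)
        report["stages"]["digitize"] = {"n_bins_used": len(bins)}
        if cfg.estimation.fit_alpha_curve:
            af = estimation.fit_alpha_curve(
                bins, volume_pl, rho_cells_per_od=rho,
                c_b_nominal=sim.c_b_nominal if sim else None)
            report["stages"]["estimate"] = {"alpha_fit": _alpha_fit_record(af)}

    elif mode == "size":
        asg = pops.find_size_modes(
            events["red_width"], events["red_peak"],
            n_modes=cfg.populations.n_size_modes,
            coalescence_z=cfg.populations.coalescence_z, seed=cfg.seed)
        digi = {}
        for g in asg.groups["group"]:
            mask = asg.labels == g
            fit, p, ci = _digitize_population(
                events.loc[mask, "green_peak"], cfg, cfg.seed + int(g))
            digi[f"mode_{g}"] = _mixture_record(fit, p, ci)
        report["stages"]["populations"] = _assignment_record(asg)
        report["stages"]["digitize"] = digi

    # ---- kinetics over a simulated time course -----------------------------
    if timecourse is not None and cfg.estimation.fit_kinetics and sim:
        fracs = digitize.timecourse_positive_fractions(
            [ev["green_peak"] for ev, _tr in timecourse],
            k_max=cfg.digitization.k_max, seed=cfg.seed + 1000,
            method=cfg.digitization.method,
        )
        pts = [(t, p, n) for t, (p, _ci, n) in
               zip(cfg.simulation.times_min, fracs)]
        lb = (1.0 - sim.alpha) * c_b_for_lambda * volume_pl * core.PL_TO_ML
        kf = estimation.fit_kinetics(pts, sim.alpha, volume_pl, lambda_b=lb)
        if cfg.estimation.effective_fraction_for_k:
            kf = kf.with_adsorption_constant(
                sim.c_b_nominal, cfg.estimation.effective_fraction_for_k)
        report["stages"]["estimate_kinetics"] = _kinetic_record(kf)

    if out_dir is not None:
        (out_dir / "report.json").write_text(report_to_json(report))
    return report


def _mixture_record(fit, p, ci) -> dict:
    return {
        "n_components": fit.n_components,
        "weights": fit.weights.tolist(),
        "means": fit.means.tolist(),
        "sds": fit.sds.tolist(),
        "P_L": p,
        "ci": list(ci),
        "n_droplets": fit.n_droplets,
        "silhouette": fit.silhouette,
    }


def _assignment_record(asg) -> dict:
    return {
        "n_groups": int(len(asg.groups)),
        "discarded_fraction": asg.discarded_fraction,
        "coalesced_fraction": float(np.mean(asg.coalesced)),
        "groups": asg.groups.to_dict(orient="records"),
    }


def _titer_record(t) -> dict:
    return {"lambda_p": t.lambda_p, "c_p": t.c_p,
            "ci": [t.ci_low, t.ci_high], "P_L": t.P_L,
            "alpha": t.alpha, "volume_pl": t.volume_pl, "lambda_b": t.lambda_b}


def _alpha_fit_record(af) -> dict:
    return {"c_p": af.c_p, "c_b_effective": af.c_b_effective,
            "od_effective": af.od_effective,
            "effective_fraction": af.effective_fraction,
            "r_squared": af.r_squared, "n_bins": int(len(af.bins))}


def _kinetic_record(kf) -> dict:
    return {"c_p": kf.c_p, "tau_min": kf.tau_min,
            "k_cb_per_min": kf.k_cb_per_min, "k_ml_per_min": kf.k_ml_per_min,
            "r_squared": kf.r_squared, "plateau": kf.plateau,
            "points": kf.points.to_dict(orient="records")}
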