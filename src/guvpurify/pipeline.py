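"""End-to-end orchestration: simulate -> detect -> measure -> report.

Mirrors the experimental sequence: vesicle production feeds the pinched-flow
purification device; outlet fractions are imaged; the free-dye background of
outlet I (unpurified mixture) and outlet III (purified GUVs) gives the
separation efficiency; optionally a FRET fusion assay is simulated and its
transferred-acceptor fraction recovered and converted to stoichiometry.

A single global seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence`` spawn keys, so any stage can be re-run alone
and reproduce its exact output.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import device, fret, imaging, mechanics, synthetic
from .config import RunConfig

__version__ = "0.1.0"

_STAGE_KEYS = {"scene": 0, "outlet_I": 1, "outlet_III": 2, "fusion": 3, "calibration": 4}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic child seed (< 2**31) for a named pipeline stage."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_KEYS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunReport:
    """Self-contained record of one pipeline run (config + seed reproduce it)."""

    config: dict
    version: str
    flow: dict
    assignments: dict
    mechanics: dict
    f_values: dict
    efficiency: dict
    size_distribution: dict
    detections: pd.DataFrame
    fusion: dict | None
    timings_s: dict

    def to_dict(self, include_timings: bool = False) -> dict:
        out = {
            "config": self.config,
            "version": self.version,
            "flow": self.flow,
            "assignments": self.assignments,
            "mechanics": self.mechanics,
            "f_values": self.f_values,
            "efficiency": self.efficiency,
            "size_distribution": self.size_distribution,
            "fusion": self.fusion,
        }
        if include_timings:
            out["timings_s"] = self.timings_s
        return out

    def to_json(self, include_timings: bool = False) -> str:
        return json.dumps(self.to_dict(include_timings), sort_keys=True, indent=2)


def _atomic_write(path: str, text: str) -> None:
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def _component_assignments(config: RunConfig, state, net) -> dict:
    syn = config.synthetic
    components = {
        "solute_hpts": device.ComponentSpec(device.ComponentKind.SOLUTE),
        "suv": device.ComponentSpec(device.ComponentKind.SUV, diameter_um=0.13),
        "guv": device.ComponentSpec(
            device.ComponentKind.GUV,
            diameter_um=syn.guv_diameter_mean_um,
            stretch_modulus_n_per_m=config.physics.stretch_modulus_n_per_m,
        ),
        "droplet_large": device.ComponentSpec(
            device.ComponentKind.DROPLET,
            diameter_um=syn.droplet_diameter_large_um,
            viscosity_ratio=syn.viscosity_ratio,
            surfactant_stabilized=True,
        ),
    }
    out = {}
    for name, comp in components.items():
        a = device.assign_outlet(comp, state, net)
        out[name] = {
            "outlets": list(a.outlets),
            "principal": a.principal,
            "flux_fraction": a.flux_fraction,
            "ruptured": a.ruptured,
            "follows_mixture": a.follows_mixture,
        }
    return out


def _render_outlet_images(config: RunConfig) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render the dye-channel micrographs of outlet I and outlet III.

    Outlet I carries the unpurified external solution: its background is the
    camera baseline plus the free-dye level.  Outlet III carries purified
    dye-loaded GUVs (bright lumen disks) over a clean background.
    """
    syn = config.synthetic
    optics = syn.optics()
    pop = syn.guv_population()
    diam = synthetic.sample_population(pop, stage_seed(config.seed, "scene"))
    objects = synthetic.place_objects(
        diam["diameter_um"].to_numpy(),
        optics,
        intensities={"dye": syn.lumen_intensity},
        appearance={"dye": "disk"},
        seed=stage_seed(config.seed, "scene") + 1,
    )
    img_iii, truth = synthetic.render_micrograph(
        objects, optics, ["dye"], stage_seed(config.seed, "outlet_III")
    )
    optics_i = dataclasses.replace(
        optics, background_mean=optics.background_mean + syn.free_dye_level
    )
    img_i, _ = synthetic.render_micrograph(
        [], optics_i, ["dye"], stage_seed(config.seed, "outlet_I")
    )
    return img_i[0], img_iii[0], truth


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in dependency order and assemble a RunReport."""
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    net = config.device.to_network()
    Q_guv = config.Q_guv_ul_per_h
    Q_ws = config.ratio * Q_guv
    state = device.solve_flow_split(net, Q_ws, Q_guv)
    assignments = _component_assignments(config, state, net)
    flow = {
        "Q_ws_ul_per_h": Q_ws,
        "Q_guv_ul_per_h": Q_guv,
        "ratio": config.ratio,
        "outlet_fractions": list(state.outlet_fractions),
        "pinched_fraction": state.pinched_fraction,
        "theta_deg": state.theta_deg,
    }
    timings["device"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fluid = mechanics.FluidSpec(
        config.physics.eta_continuous_pa_s, config.physics.eta_droplet_pa_s
    )
    v = mechanics.mean_velocity(
        Q_ws + Q_guv,
        config.device.pinch_width_um,
        config.device.pinch_height_um,
        config.physics.profile_factor,
    )
    stab = mechanics.stability_report(
        fluid,
        v,
        config.synthetic.guv_diameter_mean_um / 2.0,
        config.physics.stretch_modulus_n_per_m,
        config.device.pinch_width_um,
        config.physics.ca_critical,
    )
    mech = {
        "pinch_velocity_m_per_s": v,
        "capillary_number": stab.capillary_number,
        "rupture_velocity_m_per_s": stab.rupture_velocity_m_per_s,
        "stable": stab.stable,
    }
    timings["mechanics"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    img_i, img_iii, _truth = _render_outlet_images(config)
    timings["synthetic"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    imcfg = config.imaging
    detections = imaging.detect_vesicles(
        img_iii,
        imcfg.radius_range,
        canny_sigma=imcfg.canny_sigma,
        accumulator_threshold=imcfg.accumulator_threshold,
        pixel_size_um=config.synthetic.pixel_size_um,
        refine=imcfg.refine_mode,
    )
    hist_iii = imaging.background_distribution(
        img_iii,
        detections,
        margin_px=imcfg.background_margin_px,
        blur_quantile=imcfg.blur_quantile,
        bins=imcfg.histogram_bins,
    )
    hist_i = imaging.background_distribution(
        img_i,
        [],
        bins=imcfg.histogram_bins,
        max_pixels=hist_iii.n_pixels,
    )
    eff = imaging.purification_efficiency(hist_i.fit_mean, hist_iii.fit_mean)
    if detections:
        sizes = imaging.size_distribution(detections, config.synthetic.pixel_size_um)
        size_summary = {"mean_um": sizes.mean_um, "sd_um": sizes.sd_um, "n": sizes.n}
    else:
        size_summary = {"mean_um": None, "sd_um": None, "n": 0}
    f_values = {
        "f_I": hist_i.fit_mean,
        "f_I_sd": hist_i.fit_sd,
        "f_III": hist_iii.fit_mean,
        "f_III_sd": hist_iii.fit_sd,
        "background_pixels_I": hist_i.n_pixels,
        "background_pixels_III": hist_iii.n_pixels,
    }
    efficiency = {
        "e": eff.value,
        "e_rounded": eff.rounded,
        "outlet_iii_brighter": eff.outlet_iii_brighter,
    }
    timings["imaging"] = time.perf_counter() - t0

    fusion = None
    if config.fret.enabled:
        t0 = time.perf_counter()
        fusion = _fusion_stage(config)
        timings["fret"] = time.perf_counter() - t0

    return RunReport(
        config=config.model_dump(),
        version=__version__,
        flow=flow,
        assignments=assignments,
        mechanics=mech,
        f_values=f_values,
        efficiency=efficiency,
        size_distribution=size_summary,
        detections=imaging.detections_to_frame(detections),
        fusion=fusion,
        timings_s=timings,
    )


def _fusion_stage(config: RunConfig) -> dict:
    fc = config.fret
    relation = synthetic.LinearFretRelation(fc.calibration_baseline, fc.calibration_slope)
    table = synthetic.make_calibration_table(
        fc.calibration_levels,
        relation,
        noise_sd=fc.calibration_noise_sd,
        seed=stage_seed(config.seed, "calibration"),
    )
    cal = fret.fit_calibration(
        table.rename(columns={"mol_percent": "mol_percent", "E_mean": "E_mean"})
    )
    optics = config.synthetic.optics()
    guv_spec = synthetic.VesiclePopulationSpec(
        count=fc.guv_count_per_image,
        diameter_mean_um=config.synthetic.guv_diameter_mean_um,
        diameter_sd_um=config.synthetic.guv_diameter_sd_um,
    )
    experiment = synthetic.simulate_fusion_experiment(
        fc.x_transfer_true_mol_percent,
        guv_spec,
        optics,
        stage_seed(config.seed, "fusion"),
        relation=relation,
        suv_label_mol_percent=fc.suv_label_mol_percent,
        n_images=fc.n_images,
    )
    x_rec, table_after = fret.recover_transfer(
        experiment.images_after,
        experiment.channels,
        cal,
        config.imaging.radius_range,
        canny_sigma=config.imaging.canny_sigma,
        accumulator_threshold=config.imaging.accumulator_threshold,
        annulus_halfwidth=config.imaging.annulus_halfwidth_px,
    )
    table_before = pd.concat(
        [
            fret.efficiency_from_images(
                stack,
                experiment.channels,
                config.imaging.radius_range,
                canny_sigma=config.imaging.canny_sigma,
                accumulator_threshold=config.imaging.accumulator_threshold,
                annulus_halfwidth=config.imaging.annulus_halfwidth_px,
            )
            for stack in experiment.images_before
        ],
        ignore_index=True,
    )
    stoich = fret.fusion_stoichiometry(
        x_rec, R_guv_um=fc.R_guv_um, r_suv_um=fc.r_suv_um
    )
    return {
        "x_transfer_true_mol_percent": experiment.x_transfer_true,
        "x_transfer_recovered_mol_percent": x_rec,
        "E_before_mean": float(table_before["E_fret"].mean()) if len(table_before) else None,
        "E_before_sd": float(table_before["E_fret"].std(ddof=1)) if len(table_before) > 1 else None,
        "E_after_mean": float(table_after["E_fret"].mean()),
        "E_after_sd": float(table_after["E_fret"].std(ddof=1)) if len(table_after) > 1 else None,
        "n_before": int(len(table_before)),
        "n_after": int(len(table_after)),
        "n_suvs": stoich.n_suvs,
        "n_dotap": stoich.n_dotap,
        "n_dopg": stoich.n_dopg,
    }


def write_report(report: RunReport, out_dir: str) -> None:
    """Write report.json (sorted keys) and detections.csv under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    _atomic_write(os.path.join(out_dir, "report.json"), report.to_json())
    report.detections.to_csv(os.path.join(out_dir, "detections.csv"), index=False)


def sweep(
    config: RunConfig,
    parameter: str,
    values,
    *,
    stages: tuple[str, ...] = ("device", "mechanics"),
) -> pd.DataFrame:
    """Re-run the (cheap) device/mechanics stages across parameter values.

    ``parameter`` is a dotted path into the run config (e.g. ``ratio`` or
    ``device.pinch_width_um``).  Returns one row per value with the flow
    state and, when requested via ``stages``, the full pipeline outputs.
    """
    rows = []
    for value in values:
        data = config.model_dump()
        target, key = data, parameter
        while "." in key:
            head, key = key.split(".", 1)
            if head not in target:
                raise KeyError(f"unknown config path {parameter!r}")
            target = target[head]
        if key not in target:
            raise KeyError(f"unknown config path {parameter!r}")
        target[key] = value
        cfg = RunConfig.model_validate(data)
        if "imaging" in stages or "fret" in stages:
            report = run_pipeline(cfg)
            flow, mech = report.flow, report.mechanics
            extra = {"e": report.efficiency["e"]}
        else:
            net = cfg.device.to_network()
            state = device.solve_flow_split(net, cfg.ratio * cfg.Q_guv_ul_per_h, cfg.Q_guv_ul_per_h)
            flow = {
                "ratio": cfg.ratio,
                "outlet_fractions": list(state.outlet_fractions),
                "pinched_fraction": state.pinched_fraction,
                "theta_deg": state.theta_deg,
            }
            extra = {}
        row = {parameter: value, "theta_deg": flow["theta_deg"],
               "pinched_fraction": flow["pinched_fraction"]}
        for i, lab in enumerate(device.OUTLET_LABELS):
            row[f"fraction_{lab}"] = flow["outlet_fractions"][i]
        row.update(extra)
        rows.append(row)
    return pd.DataFrame(rows)
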