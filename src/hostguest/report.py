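"""End-to-end study orchestration and report rendering.

A study config (YAML or an in-memory :class:`StudyConfig`) names the input
files and analysis parameters; :func:`run_study` executes every stage whose
inputs are present (phase solubility, trajectory descriptors, energetics,
hydrogen-bond typing), skipping and logging the rest, and returns a
JSON-serializable :class:`StudyReport` that can also be rendered as
Markdown. Reports are deterministic for a given config and inputs; the
wall-clock timestamp lives in a separate provenance field.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import atom_class_table_from_frame
from .descriptors import (
    HBondCriteria,
    classify_interaction,
    estimate_diffusion,
    hbond_concentration,
    hbond_count_over_frames,
    mean_square_displacement,
)
from .energetics import (
    binding_energy_from_table,
    compatibility,
    enumerate_hbond_types,
)
from .errors import InvalidInputError
from .solubility import (
    AbsorbanceSeries,
    build_isotherm,
    fit_calibration,
    rank_by_ks,
)
from .trajectory import read_energy_table, read_trajectory

log = logging.getLogger("hostguest")

__all__ = ["StudyConfig", "StudyReport", "run_study", "render_report"]

CONFIG_SCHEMA_VERSION = 1


@dataclass
class StudyConfig:
    """Paths and parameters for a full study run.

    Any stage whose inputs are ``None`` is skipped. Paths are resolved
    relative to the config file's directory when loaded from YAML.
    """

    calibration: str | None = None  # CSV: concentration_mM, absorbance
    isotherms: str | None = None  # CSV: system, host_conc_mM, absorbance
    dilution_factor: float = 1.0
    trajectory: str | None = None  # XYZ or native CSV
    timestep: float = 1.0  # ps, when the file has no time metadata
    msd_origins: str = "multiple"
    msd_fit_window: tuple[float, float] | None = None
    rdf_dr: float = 0.1
    rdf_r_max: float | None = None
    hbond_max_distance: float = 3.0
    hbond_min_angle: float = 120.0
    energies: str | None = None  # CSV: frame, component, value_kcal_mol
    energy_window: int = 5
    solubility_parameters: dict[str, float] | None = None
    compatibility_reference: str | None = None
    class_table: str | None = None  # CSV: label, role, charge, kind
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict) or not raw:
            raise InvalidInputError(
                "empty study config; supply at least one stage input "
                "(calibration+isotherms, trajectory, energies, "
                "solubility_parameters, or class_table)"
            )
        raw.pop("schema_version", None)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidInputError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        for attr in ("calibration", "isotherms", "trajectory", "energies", "class_table"):
            value = getattr(cfg, attr)
            if value is not None:
                getattr(cfg, attr)
                setattr(cfg, attr, str((path.parent / value).resolve()))
        if cfg.msd_fit_window is not None:
            cfg.msd_fit_window = tuple(cfg.msd_fit_window)
        return cfg

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    sections: dict[str, Any]
    provenance: dict[str, Any]

    def to_dict(self) -> dict:
        return {"sections": self.sections, "provenance": self.provenance}


def _solubility_stage(cfg: StudyConfig) -> dict:
    cal_df = pd.read_csv(cfg.calibration)
    series = AbsorbanceSeries(
        concentrations=cal_df.iloc[:, 0].to_numpy(),
        absorbances=cal_df.iloc[:, 1].to_numpy(),
    )
    curve = fit_calibration(series)
    iso_df = pd.read_csv(cfg.isotherms)
    systems = {}
    named = []
    for name, group in iso_df.groupby("system", sort=False):
        iso = build_isotherm(
            group["host_conc_mM"].to_numpy(),
            group["absorbance"].to_numpy(),
            curve,
            dilution_factor=cfg.dilution_factor,
        )
        systems[str(name)] = {
            "slope_K": iso.slope_K,
            "intercept_S0_mM": iso.intercept_S0,
            "r_squared": iso.r_squared,
            "isotherm_class": iso.isotherm_class,
            "Ks_per_M": iso.Ks,
        }
        named.append((str(name), iso))
    return {
        "calibration": {
            "slope_AU_per_mM": curve.slope,
            "intercept_AU": curve.intercept,
            "r_squared": curve.r_squared,
            "n_points": curve.n_points,
        },
        "systems": systems,
        "ranking_by_Ks": rank_by_ks(named),
    }


def _descriptor_stage(cfg: StudyConfig) -> dict:
    traj = read_trajectory(cfg.trajectory, timestep=cfg.timestep)
    out: dict[str, Any] = {"n_frames": traj.n_frames, "n_atoms": traj.frames[0].n_atoms}
    if traj.n_frames >= 2:
        msd = mean_square_displacement(traj, origin_scheme=cfg.msd_origins)
        out["msd"] = {
            "final_lag_ps": float(msd.lag_times[-1]),
            "final_msd_A2": float(msd.msd[-1]),
            "origin_scheme": cfg.msd_origins,
        }
        window = cfg.msd_fit_window
        if window is None:
            span = msd.lag_times[-1]
            window = (0.1 * span, 0.5 * span)
        try:
            out["msd"]["diffusion_A2_per_ps"] = estimate_diffusion(msd, window)
            out["msd"]["fit_window_ps"] = list(window)
        except InvalidInputError:
            log.info("MSD fit window too narrow; diffusion estimate skipped")
    criteria = HBondCriteria(
        max_h_acceptor_distance=cfg.hbond_max_distance,
        min_dha_angle=cfg.hbond_min_angle,
    )
    counts, mean, sd = hbond_count_over_frames(traj, criteria)
    out["hbonds"] = {"mean_per_frame": mean, "sd_per_frame": sd}
    cell = traj.frames[0].cell
    if cell.periodic:
        conc = hbond_concentration(round(mean), cell)
        out["hbonds"]["concentration_mol_per_cm3"] = conc.c_hbs
        out["hbonds"]["cell_volume_cm3"] = conc.volume_cm3
    return out


def _typing_stage(cfg: StudyConfig, traj_section: dict | None) -> dict:
    table = atom_class_table_from_frame(pd.read_csv(cfg.class_table))
    catalogue = enumerate_hbond_types(table)
    out: dict[str, Any] = {
        "types": [
            {"label": label, "acceptor": acc, "donor_h": don}
            for label, acc, don in catalogue.entries
        ]
    }
    if cfg.trajectory is not None:
        from .energetics import rdf_per_type

        traj = read_trajectory(cfg.trajectory, timestep=cfg.timestep)
        if traj.frames[0].cell.periodic:
            curves = rdf_per_type(traj, catalogue, dr=cfg.rdf_dr, r_max=cfg.rdf_r_max)
            peaks = {}
            for label, rdf in curves.items():
                if np.all(rdf.pair_counts == 0):
                    continue
                peak_r = float(rdf.bin_centers[int(np.argmax(rdf.g_of_r))])
                peaks[label] = {
                    "first_peak_A": peak_r,
                    "interaction": classify_interaction(peak_r),
                }
            out["rdf_peaks"] = peaks
    return out


def _energetics_stage(cfg: StudyConfig) -> dict:
    out: dict[str, Any] = {}
    if cfg.energies is not None:
        table = read_energy_table(cfg.energies)
        comp = binding_energy_from_table(table, window=cfg.energy_window)
        out["binding"] = {
            "e_total": comp.e_total,
            "e_guest": comp.e_guest,
            "e_host": comp.e_host,
            "e_binding_kcal_mol": comp.e_binding,
            "window_frames": cfg.energy_window,
        }
    if cfg.solubility_parameters:
        deltas = dict(cfg.solubility_parameters)
        ref = cfg.compatibility_reference or next(iter(deltas))
        verdicts = []
        for name, delta in deltas.items():
            if name == ref:
                continue
            v = compatibility(deltas[ref], delta)
            verdicts.append({
                "pair": f"{ref}/{name}",
                "difference": v.difference,
                "category": v.category,
            })
        out["compatibility"] = {"reference": ref, "verdicts": verdicts}
    return out


def run_study(config: StudyConfig) -> StudyReport:
    """Run every stage whose inputs the config provides.

    Raises :class:`InvalidInputError` when no stage has inputs. Stage errors
    propagate annotated with the stage name.
    """
    sections: dict[str, Any] = {}
    skipped: list[str] = []
    stages = [
        ("phase_solubility", cfg_has_solubility := config.calibration and config.isotherms,
         lambda: _solubility_stage(config)),
        ("trajectory_descriptors", config.trajectory, lambda: _descriptor_stage(config)),
        ("hbond_typing", config.class_table,
         lambda: _typing_stage(config, sections.get("trajectory_descriptors"))),
        ("energetics", config.energies or config.solubility_parameters,
         lambda: _energetics_stage(config)),
    ]
    ran = 0
    for name, available, runner in stages:
        if not available:
            skipped.append(name)
            log.info("stage %s skipped (no inputs)", name)
            continue
        log.info("running stage %s", name)
        try:
            sections[name] = runner()
        except Exception as exc:
            raise type(exc)(f"stage {name}: {exc}") from exc
        ran += 1
    if ran == 0:
        raise InvalidInputError(
            "config provides no stage inputs; required: calibration+isotherms "
            "and/or trajectory and/or energies/solubility_parameters/class_table"
        )
    provenance = {
        "package_version": __version__,
        "schema_version": CONFIG_SCHEMA_VERSION,
        "seed": config.seed,
        "config_digest": config.digest(),
        "skipped_stages": skipped,
    }
    return StudyReport(sections=sections, provenance=provenance)


def render_report(report: StudyReport, format: str = "json") -> str:
    """Render a report as JSON (lossless round trip) or Markdown."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True, default=float)
    if format != "markdown":
        raise InvalidInputError(f"unknown report format {format!r}")
    lines = ["# Host-guest study report", ""]
    sol = report.sections.get("phase_solubility")
    if sol:
        cal = sol["calibration"]
        lines += [
            "## Phase solubility", "",
            f"Calibration: A = {cal['slope_AU_per_mM']:.5f} C + "
            f"{cal['intercept_AU']:.5f} (r² = {cal['r_squared']:.4f}, "
            f"n = {cal['n_points']})", "",
            "| system | K | S0 (mM) | r² | class | Ks (M⁻¹) |",
            "|---|---|---|---|---|---|",
        ]
        for name, row in sol["systems"].items():
            lines.append(
                f"| {name} | {row['slope_K']:.4e} | {row['intercept_S0_mM']:.4e} "
                f"| {row['r_squared']:.4f} | {row['isotherm_class']} "
                f"| {row['Ks_per_M']:.1f} |"
            )
        lines += ["", f"Ranking by Ks: {' > '.join(sol['ranking_by_Ks'])}", ""]
    desc = report.sections.get("trajectory_descriptors")
    if desc:
        lines += ["## Trajectory descriptors", ""]
        if "msd" in desc and "diffusion_A2_per_ps" in desc["msd"]:
            lines.append(f"Diffusion coefficient: "
                         f"{desc['msd']['diffusion_A2_per_ps']:.4g} Å²/ps")
        hb = desc.get("hbonds", {})
        lines.append(f"Hydrogen bonds per frame: {hb.get('mean_per_frame', 0):.2f} "
                     f"± {hb.get('sd_per_frame', 0):.2f}")
        if "concentration_mol_per_cm3" in hb:
            lines.append(f"H-bond concentration: "
                         f"{hb['concentration_mol_per_cm3']:.4g} mol/cm³")
        lines.append("")
    typing_sec = report.sections.get("hbond_typing")
    if typing_sec:
        lines += ["## Hydrogen-bond types", ""]
        for t in typing_sec["types"]:
            lines.append(f"- type {t['label']}: {t['acceptor']}–{t['donor_h']}")
        for label, peak in (typing_sec.get("rdf_peaks") or {}).items():
            lines.append(f"- type {label} RDF peak at {peak['first_peak_A']:.2f} Å "
                         f"({peak['interaction']})")
        lines.append("")
    ener = report.sections.get("energetics")
    if ener:
        lines += ["## Energetics", ""]
        if "binding" in ener:
            lines.append(f"Binding energy: "
                         f"{ener['binding']['e_binding_kcal_mol']:.4g} kcal/mol")
        for v in ener.get("compatibility", {}).get("verdicts", []):
            lines.append(f"- {v['pair']}: |Δδ| = {v['difference']:.3f} → {v['category']}")
        lines.append("")
    lines.append(f"_seed {report.provenance['seed']}, config "
                 f"{report.provenance['config_digest']}, hostguest "
                 f"{report.provenance['package_version']}_")
    return "\n".join(lines) + "\n"
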