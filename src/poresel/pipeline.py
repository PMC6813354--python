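"""End-to-end orchestration: generators → WHAM → binding → ephys → maps.

One flat YAML config drives every stage. All randomness flows from one
master seed through documented per-stage derivations, outputs land in a
directory named by a hash of the config (timestamp-free, so identical
configs collide into identical paths), and each stage reads its inputs
from the files the previous stage wrote — re-running a single stage
from saved intermediates reproduces the full-pipeline outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binding as binding_mod
from . import ephys as ephys_mod
from . import io as io_mod
from . import maps as maps_mod
from . import synth as synth_mod
from . import wham as wham_mod
from .constants import SIM_TEMPERATURE_K, THERMAL_MV_ROOM
from .potentials import GaussianComponent, ModelPMF

logger = logging.getLogger(__name__)

#: Stage indices used when deriving per-stage seeds from the master seed.
STAGE_IDS = {"synth": 1, "ephys": 2, "maps": 3, "dihedrals": 4}


def default_config(seed: int = 1) -> dict:
    """The bundled two-species demonstration configuration.

    Species "Na" carries the two-well landscape (main binding well near
    +3 Å, entrance barrier at −4 Å); species "X" binds more strongly
    (deeper well), so its K_D is smaller and — by construction of its
    I-V truth — its permeability lower, mimicking a blocker-like ion.
    """
    voltages = [float(v) for v in range(-80, 61, 10)]
    return {
        "seed": seed,
        "temperature_K": SIM_TEMPERATURE_K,
        "thermal_mV": THERMAL_MV_ROOM,
        "ladder": {"z_start": 12.5, "z_end": -10.0, "spacing": 0.5,
                   "force_constant": 10.0},
        "langevin": {"n_steps": 70_000, "equilibration_steps": 10_000,
                     "timestep_ns": 2e-5, "diffusion_A2_per_ns": 100.0},
        "wham": {"bin_width": 0.1, "tolerance": 1e-7},
        "cylinder": {"radius": 10.0, "z_min": -10.0, "z_max": 12.5},
        "reference_species": "Na",
        "species": [
            {"name": "Na",
             "potential": {"domain": [-12.0, 15.0], "components": [
                 {"center": 3.0, "amplitude": -3.0, "width": 1.0},
                 {"center": 7.5, "amplitude": -1.0, "width": 1.5},
                 {"center": -4.0, "amplitude": 2.0, "width": 1.2}]},
             "iv": {"V_rev": 10.0, "G_max": 1.0, "V_half": -25.0,
                    "V_slope": 8.0, "noise_sd": 0.01, "n_cells": 5,
                    "voltages": voltages, "junction_offset_mV": 0.0}},
            {"name": "X",
             "potential": {"domain": [-12.0, 15.0], "components": [
                 {"center": 3.0, "amplitude": -5.0, "width": 1.0},
                 {"center": -4.0, "amplitude": 2.5, "width": 1.2}]},
             "iv": {"V_rev": -30.0, "G_max": 0.6, "V_half": -25.0,
                    "V_slope": 8.0, "noise_sd": 0.01, "n_cells": 5,
                    "voltages": voltages, "junction_offset_mV": 2.0}},
        ],
        "maps": {"n_frames": 3000, "voxel_size": 1.0,
                 "box_lo": [-10.0, -10.0, -10.0], "box_hi": [10.0, 10.0, 14.0],
                 "mean_particles_per_frame": 3.0,
                 "hotspots": [{"center": [0.0, 0.0, 3.0], "sigma": 1.2,
                               "weight": 0.35}],
                 "bulk_weight": 0.65,
                 "sf_region": {"z_lo": 0.0, "z_hi": 8.0, "radial_cutoff": 5.0}},
        "dihedrals": {"n_steps": 50_000, "emission_sd": 8.0,
                      "p_up_to_dunked": 0.02, "p_dunked_to_up": 0.08},
    }


def config_hash(config: dict) -> str:
    """Stable short hash of a config (canonical YAML serialization)."""
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage, per-item seed below 2³¹."""
    ss = np.random.SeedSequence([int(master_seed), STAGE_IDS[stage], int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _potential_from_spec(spec: dict, temperature: float) -> ModelPMF:
    comps = tuple(GaussianComponent(center=c["center"], amplitude=c["amplitude"],
                                    width=c["width"])
                  for c in spec.get("components", []))
    return ModelPMF(components=comps, domain=tuple(spec["domain"]),
                    temperature=temperature)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and partial-output manifest."""

    def __init__(self, stage: str, run_dir: Path, cause: Exception):
        outputs = sorted(str(p.relative_to(run_dir))
                         for p in run_dir.rglob("*") if p.is_file())
        super().__init__(
            f"pipeline stage '{stage}' failed: {cause}\n"
            f"partial outputs in {run_dir}: {outputs}")
        self.stage = stage
        self.partial_outputs = outputs


# ------------------------------------------------------------------ stages

def stage_synth(config: dict, run_dir: Path) -> None:
    """Generate window trajectories, I-V records, particles and dihedrals."""
    temp = config["temperature_K"]
    lad = config["ladder"]
    ladder = wham_mod.place_windows(lad["z_start"], lad["z_end"],
                                    lad["spacing"], lad["force_constant"])
    lv = config["langevin"]
    for si, sp in enumerate(config["species"]):
        pmf = _potential_from_spec(sp["potential"], temp)
        cfg = synth_mod.LangevinConfig(
            n_steps=lv["n_steps"], equilibration_steps=lv["equilibration_steps"],
            timestep=lv["timestep_ns"], diffusion_coefficient=lv["diffusion_A2_per_ns"],
            seed=stage_seed(config["seed"], "synth", si))
        series = synth_mod.sample_ladder(pmf, ladder.centers,
                                         ladder.force_constant, cfg)
        io_mod.write_window_series(series, run_dir / "windows" / sp["name"])
        # ground truth for reference/debugging plots
        z = np.linspace(*pmf.domain, 541)
        pd.DataFrame({"z_angstrom": z, "w_true_kcal_mol": np.asarray(pmf(z))}
                     ).to_csv(run_dir / "windows" / sp["name"] / "truth.tsv",
                              sep="\t", index=False)

    records, cells = [], []
    for si, sp in enumerate(config["species"]):
        iv = sp["iv"]
        for cell in range(iv.get("n_cells", 1)):
            truth = synth_mod.SyntheticIVTruth(
                V_rev=iv["V_rev"], G_max=iv["G_max"], V_half=iv["V_half"],
                V_slope=iv["V_slope"], voltages=tuple(iv["voltages"]),
                noise_sd=iv.get("noise_sd", 0.0),
                seed=stage_seed(config["seed"], "ephys", si * 1000 + cell),
                condition=sp["name"])
            rec = synth_mod.generate_iv(truth)
            rec.junction_offset = iv.get("junction_offset_mV", 0.0)
            records.append(rec)
            cells.append(cell)
    rows = []
    for rec, cell in zip(records, cells):
        for j, v in enumerate(rec.voltages):
            rows.append({"condition": rec.condition, "cell_id": cell,
                         "voltage_mV": v, "peak_current": rec.peak_currents[j],
                         "tail_current": rec.tail_currents[j],
                         "junction_mV": rec.junction_offset})
    pd.DataFrame(rows).to_csv(run_dir / "iv.tsv", sep="\t", index=False)

    mp = config["maps"]
    spec = synth_mod.DensityFieldSpec(
        box_lo=tuple(mp["box_lo"]), box_hi=tuple(mp["box_hi"]),
        hotspots=tuple(synth_mod.Hotspot(center=tuple(h["center"]),
                                         sigma=h["sigma"], weight=h["weight"])
                       for h in mp.get("hotspots", [])),
        bulk_weight=mp.get("bulk_weight", 1.0),
        mean_particles_per_frame=mp["mean_particles_per_frame"])
    cloud = synth_mod.generate_particles(spec, mp["n_frames"],
                                         seed=stage_seed(config["seed"], "maps"))
    io_mod.write_particle_cloud(cloud, run_dir / "particles.tsv")

    dh = config["dihedrals"]
    chain = synth_mod.DihedralChainSpec(
        emission_sd=dh["emission_sd"], p_up_to_dunked=dh["p_up_to_dunked"],
        p_dunked_to_up=dh["p_dunked_to_up"])
    trace = synth_mod.generate_dihedrals(chain, dh["n_steps"],
                                         seed=stage_seed(config["seed"], "dihedrals"))
    io_mod.write_dihedral_trace(trace, run_dir / "dihedrals.tsv")


def stage_wham(config: dict, run_dir: Path) -> None:
    """Rebuild each species' PMF from its saved window trajectories."""
    temp = config["temperature_K"]
    lad = config["ladder"]
    ladder = wham_mod.place_windows(lad["z_start"], lad["z_end"],
                                    lad["spacing"], lad["force_constant"])
    wh = config["wham"]
    for sp in config["species"]:
        series = io_mod.read_window_series(run_dir / "windows" / sp["name"])
        lo = min(ladder.centers) - 2.0
        hi = max(ladder.centers) + 2.0
        hists = wham_mod.build_histograms(series, wh["bin_width"], (lo, hi))
        profile, report = wham_mod.solve_wham(
            hists, ladder, temperature=temp, tolerance=wh["tolerance"])
        profile = wham_mod.pmf_variance_profile(profile, series, ladder)
        io_mod.write_pmf(profile, run_dir / f"pmf_{sp['name']}.tsv")
        io_mod.write_convergence(report, ladder, hists.n_samples,
                                 run_dir / f"convergence_{sp['name']}.tsv")


def stage_binding(config: dict, run_dir: Path) -> list[binding_mod.BindingResult]:
    """Integrate each species' PMF into K_D and ΔG, write binding.tsv."""
    temp = config["temperature_K"]
    cy = config["cylinder"]
    cyl = binding_mod.CylinderSpec(radius=cy["radius"], z_min=cy["z_min"],
                                  z_max=cy["z_max"])
    results = []
    for sp in config["species"]:
        profile = io_mod.read_pmf(run_dir / f"pmf_{sp['name']}.tsv", temp)
        results.append(binding_mod.binding_result(profile, sp["name"], cyl))
    pd.DataFrame([{
        "species": r.species, "K_D_molar": r.K_D,
        "delta_G_kcal_mol": r.delta_G, "R": r.cylinder.radius,
        "z_min": r.cylinder.z_min, "z_max": r.cylinder.z_max,
        "temperature": r.temperature,
    } for r in results]).to_csv(run_dir / "binding.tsv", sep="\t", index=False)
    return results


def stage_ephys(config: dict, run_dir: Path) -> list[ephys_mod.PermeabilityResult]:
    """Fit I-V records, extract reversal potentials, compute P_X/P_Na."""
    df = pd.read_csv(run_dir / "iv.tsv", sep="\t", comment="#")
    thermal = config["thermal_mV"]
    reference = config["reference_species"]

    reversals: dict[str, list[float]] = {}
    fits = []
    for (cond, cell), grp in df.groupby(["condition", "cell_id"], sort=False):
        grp = grp.sort_values("voltage_mV")
        rec = ephys_mod.IVRecord(
            condition=str(cond), voltages=grp["voltage_mV"].to_numpy(),
            peak_currents=grp["peak_current"].to_numpy(),
            tail_currents=grp["tail_current"].to_numpy(),
            junction_offset=float(grp["junction_mV"].iloc[0]))
        try:
            fit = ephys_mod.fit_iv(rec)
            e_meas = fit.V_rev
            fits.append({"condition": cond, "cell_id": cell, "method": "peak_fit",
                         "V_rev": fit.V_rev, "G_max": fit.G_max,
                         "V_half": fit.V_half, "V_slope": fit.V_slope,
                         "rms_residual": fit.rms_residual})
        except ValueError:
            e_meas, se = ephys_mod.reversal_from_tails(rec)
            fits.append({"condition": cond, "cell_id": cell, "method": "tail_fit",
                         "V_rev": e_meas, "G_max": np.nan, "V_half": np.nan,
                         "V_slope": np.nan, "rms_residual": se})
        e_corr = ephys_mod.apply_junction_correction(e_meas, rec.junction_offset)
        reversals.setdefault(str(cond), []).append(e_corr)
    pd.DataFrame(fits).to_csv(run_dir / "fits.tsv", sep="\t", index=False)

    if reference not in reversals:
        raise ValueError(f"reference species {reference!r} missing from iv.tsv")
    e_na = float(np.mean(reversals[reference]))
    results = [
        ephys_mod.permeability_result(cond, np.asarray(e_cells), e_na, thermal)
        for cond, e_cells in reversals.items() if cond != reference
    ]
    # the reference itself: ratio 1 by definition, kept for the table
    results.insert(0, ephys_mod.permeability_result(
        reference, np.asarray(reversals[reference]), e_na, thermal))
    io_mod.write_permeabilities(results, run_dir / "permeability.tsv")
    return results


def stage_maps(config: dict, run_dir: Path) -> dict:
    """Density grid, iso classification, occupancy and dihedral states."""
    mp = config["maps"]
    cloud = io_mod.read_particle_cloud(run_dir / "particles.tsv",
                                       n_frames=mp["n_frames"])
    bounds = tuple(zip(mp["box_lo"], mp["box_hi"]))
    grid = maps_mod.build_density(cloud, mp["voxel_size"], bounds)
    io_mod.write_density_dx(grid, run_dir / "density.dx")
    io_mod.write_density_summary(grid, run_dir / "density_summary.tsv")
    iso = maps_mod.classify_iso(grid)

    sf = mp["sf_region"]
    region = maps_mod.SFRegion(z_lo=sf["z_lo"], z_hi=sf["z_hi"],
                               radial_cutoff=sf["radial_cutoff"])
    occ = maps_mod.occupancy(cloud, region)

    trace = io_mod.read_dihedral_trace(run_dir / "dihedrals.tsv")
    dclass = maps_mod.classify_dihedrals(trace)

    summary = {
        "n_weak_voxels": int(iso.weak_mask.sum()),
        "n_strong_voxels": int(iso.strong_mask.sum()),
        "bulk_density_per_A3": grid.bulk_density,
        "sf_occupancy_mean": occ.mean,
        "sf_occupancy_sd": occ.sd,
        "dunked_fraction": dclass.dunked_fraction,
        "upward_fraction": dclass.upward_fraction,
    }
    io_mod.write_json(summary, run_dir / "maps_summary.json")
    return summary


def stage_report(config: dict, run_dir: Path) -> dict:
    """Join binding and permeability outputs into the selectivity report."""
    bind_df = pd.read_csv(run_dir / "binding.tsv", sep="\t", comment="#")
    perm_df = pd.read_csv(run_dir / "permeability.tsv", sep="\t", comment="#")
    cy = config["cylinder"]
    results = [binding_mod.BindingResult(
        species=row.species, K_D=row.K_D_molar, delta_G=row.delta_G_kcal_mol,
        temperature=row.temperature,
        cylinder=binding_mod.CylinderSpec(radius=cy["radius"], z_min=cy["z_min"],
                                          z_max=cy["z_max"]))
        for row in bind_df.itertuples(index=False)]
    perms = [ephys_mod.PermeabilityResult(
        species=row.species, P_ratio=row.P_ratio, sem=max(row.sem, 0.0),
        n=int(row.n), E_X=row.E_X_mV, E_Na=row.E_Na_mV)
        for row in perm_df.itertuples(index=False)]
    table = binding_mod.species_table(results, perms)
    table.to_csv(run_dir / "species_table.tsv", sep="\t")
    rho = table.attrs["spearman_kd_vs_permeability"]
    report = {
        "config_hash": config_hash(config),
        "seed": config["seed"],
        "species": {s: {k: (None if pd.isna(v) else float(v))
                        for k, v in row.items()}
                    for s, row in table.to_dict(orient="index").items()},
        "spearman_kd_vs_permeability": None if np.isnan(rho) else float(rho),
    }
    io_mod.write_json(report, run_dir / "report.json")
    return report


def _stamp_outputs(run_dir: Path, config: dict) -> None:
    """Prepend a provenance comment (config hash + seed) to every TSV."""
    stamp = f"# config_hash={config_hash(config)} seed={config['seed']}\n"
    for path in sorted(run_dir.rglob("*.tsv")):
        text = path.read_text()
        if not text.startswith("# config_hash="):
            path.write_text(stamp + text)


def run_pipeline(config: dict, out_root: str | Path = "runs") -> Path:
    """Execute all stages in dependency order under one run directory.

    The directory is named by the config hash; a failed stage aborts
    with the stage name and a manifest of the partial outputs.
    """
    run_dir = Path(out_root) / config_hash(config)
    run_dir.mkdir(parents=True, exist_ok=True)
    io_mod.dump_config(config, run_dir / "config.yaml")
    stages = [
        ("synth", stage_synth), ("wham", stage_wham), ("binding", stage_binding),
        ("ephys", stage_ephys), ("maps", stage_maps), ("report", stage_report),
    ]
    for name, fn in stages:
        logger.info("pipeline stage: %s", name)
        try:
            fn(config, run_dir)
        except Exception as err:  # noqa: BLE001 - re-raised with context
            raise PipelineStageError(name, run_dir, err) from err
    _stamp_outputs(run_dir, config)
    return run_dir
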