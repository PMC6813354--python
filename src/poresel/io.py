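"""Plain-text I/O for every artifact the pipeline reads or writes.

Window trajectories, histogrammed PMFs, I-V records, particle clouds
and dihedral traces travel as TSV; 3D density grids are additionally
written in the OpenDX scalar-field format so standard molecular viewers
can render the iso-surfaces.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ephys import IVRecord, PermeabilityResult
from .maps import DensityGrid, DihedralTrace, ParticleCloud
from .synth import WindowSeries
from .wham import ConvergenceReport, PMFProfile, WindowLadder


# ---------------------------------------------------------------- windows

def write_window_series(series: list[WindowSeries], out_dir: str | Path) -> None:
    """One TSV per window (step, z_angstrom) plus a windows.tsv manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = []
    for s in series:
        df = pd.DataFrame({"step": np.arange(len(s.samples)),
                           "z_angstrom": s.samples})
        df.to_csv(out_dir / f"window_{s.window_id:03d}.tsv", sep="\t", index=False)
        meta.append({"window_id": s.window_id, "center": s.center,
                     "force_constant": s.force_constant,
                     "timestep_ns": s.timestep, "seed": s.seed})
    pd.DataFrame(meta).to_csv(out_dir / "windows.tsv", sep="\t", index=False)


def read_window_series(in_dir: str | Path) -> list[WindowSeries]:
    """Load a directory written by :func:`write_window_series`."""
    in_dir = Path(in_dir)
    meta = pd.read_csv(in_dir / "windows.tsv", sep="\t", comment="#")
    series = []
    for row in meta.itertuples(index=False):
        df = pd.read_csv(in_dir / f"window_{int(row.window_id):03d}.tsv", sep="\t", comment="#")
        series.append(WindowSeries(
            window_id=int(row.window_id), center=float(row.center),
            force_constant=float(row.force_constant),
            samples=df["z_angstrom"].to_numpy(),
            timestep=float(getattr(row, "timestep_ns", 0.0)),
            seed=int(getattr(row, "seed", 0))))
    return series


# ---------------------------------------------------------------- PMF

def write_pmf(profile: PMFProfile, path: str | Path) -> None:
    stderr = np.sqrt(np.where(np.isfinite(profile.var_w), profile.var_w, np.nan))
    pd.DataFrame({"z_angstrom": profile.z, "w_kcal_mol": profile.w,
                  "stderr_kcal_mol": stderr}).to_csv(path, sep="\t", index=False)


def read_pmf(path: str | Path, temperature: float) -> PMFProfile:
    df = pd.read_csv(path, sep="\t", comment="#")
    stderr = df.get("stderr_kcal_mol")
    var = (stderr.to_numpy() ** 2 if stderr is not None
           else np.zeros(len(df)))
    return PMFProfile(z=df["z_angstrom"].to_numpy(),
                      w=df["w_kcal_mol"].to_numpy(), var_w=var,
                      offset_convention="as stored", temperature=temperature)


def write_convergence(report: ConvergenceReport, ladder: WindowLadder,
                      n_samples: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({
        "window_id": np.arange(len(ladder)),
        "center": ladder.centers,
        "eta": report.eta,
        "eta_infinite": report.eta_infinite,
        "n_samples": n_samples,
    }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- ephys

def write_iv_records(records: list[IVRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        for j, v in enumerate(r.voltages):
            rows.append({
                "condition": r.condition, "voltage_mV": v,
                "peak_current": r.peak_currents[j],
                "tail_current": (r.tail_currents[j]
                                 if r.tail_currents is not None else np.nan),
                "junction_mV": r.junction_offset,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_iv_records(path: str | Path) -> list[IVRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for cond, grp in df.groupby("condition", sort=False):
        grp = grp.sort_values("voltage_mV")
        tails = grp["tail_current"].to_numpy()
        records.append(IVRecord(
            condition=str(cond), voltages=grp["voltage_mV"].to_numpy(),
            peak_currents=grp["peak_current"].to_numpy(),
            tail_currents=None if np.all(np.isnan(tails)) else tails,
            junction_offset=float(grp["junction_mV"].iloc[0])
            if "junction_mV" in grp else 0.0))
    return records


def write_permeabilities(results: list[PermeabilityResult], path: str | Path) -> None:
    pd.DataFrame([{
        "species": r.species, "P_ratio": r.P_ratio, "sem": r.sem, "n": r.n,
        "E_X_mV": r.E_X, "E_Na_mV": r.E_Na,
    } for r in results]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- maps

def write_particle_cloud(cloud: ParticleCloud, path: str | Path) -> None:
    pd.DataFrame({"frame": cloud.frame_index,
                  "x": cloud.positions[:, 0],
                  "y": cloud.positions[:, 1],
                  "z": cloud.positions[:, 2]}).to_csv(path, sep="\t", index=False)


def read_particle_cloud(path: str | Path, n_frames: int | None = None) -> ParticleCloud:
    df = pd.read_csv(path, sep="\t", comment="#")
    frames = df["frame"].to_numpy(dtype=int)
    if n_frames is None:
        n_frames = int(frames.max()) + 1 if len(frames) else 0
    return ParticleCloud(positions=df[["x", "y", "z"]].to_numpy(),
                         frame_index=frames, n_frames=n_frames)


def write_dihedral_trace(trace: DihedralTrace, path: str | Path) -> None:
    df = pd.DataFrame({"frame": np.arange(len(trace)),
                       "chi1_deg": trace.chi1, "chi2_deg": trace.chi2})
    if trace.true_states is not None:
        df["true_state"] = trace.true_states
    df.to_csv(path, sep="\t", index=False)


def read_dihedral_trace(path: str | Path) -> DihedralTrace:
    df = pd.read_csv(path, sep="\t", comment="#")
    states = (df["true_state"].to_numpy(dtype=object)
              if "true_state" in df else None)
    return DihedralTrace(chi1=df["chi1_deg"].to_numpy(),
                         chi2=df["chi2_deg"].to_numpy(), true_states=states)


def write_density_dx(grid: DensityGrid, path: str | Path) -> None:
    """Write a density grid as an OpenDX regular scalar field.

    The DX text format stores the grid origin, the three axis deltas,
    and the voxel values in x-fastest-last (C) order; viewers such as
    VMD and PyMOL read it directly for iso-surface rendering.
    """
    nx, ny, nz = grid.density.shape
    ox, oy, oz = grid.origin + 0.5 * grid.voxel_size  # voxel centers
    dx, dy, dz = grid.voxel_size
    lines = [
        "# particle number density (particles/Angstrom^3)",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6g} {oy:.6g} {oz:.6g}",
        f"delta {dx:.6g} 0 0",
        f"delta 0 {dy:.6g} 0",
        f"delta 0 0 {dz:.6g}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.density.ravel(order="C")
    for start in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[start:start + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    Path(path).write_text("\n".join(lines) + "\n")


def write_density_summary(grid: DensityGrid, path: str | Path) -> None:
    """TSV summary: per-voxel center coordinates, density and bulk ratio."""
    xs, ys, zs = (grid.centers(0), grid.centers(1), grid.centers(2))
    xx, yy, zz = np.meshgrid(xs, ys, zs, indexing="ij")
    pd.DataFrame({
        "x": xx.ravel(), "y": yy.ravel(), "z": zz.ravel(),
        "density_per_A3": grid.density.ravel(),
        "ratio_over_bulk": (grid.density / grid.bulk_density).ravel(),
    }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- config

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
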