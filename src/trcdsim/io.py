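"""File formats: trajectory tables, spectra, TRCD matrices, XYZ geometry.

All formats are plain text.  Trajectory tables are TSV with the header

    time_fs  state  phi1_deg  phi2_deg  ring_open  E1_eV  R1  [E2_eV  R2 ...]

(one ``E{k}_eV``/``R{k}`` pair per transition, energies ascending), one
file per trajectory, plus a JSON manifest per ensemble recording ids,
files, the master seed and a configuration hash.  Spectra are CSV
``wavelength_nm,delta_epsilon``; TRCD matrices are CSV with a
``delay_fs`` column followed by one column per wavelength.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .conformers import OccupancyTable
from .errors import TrajectoryParseError, XYZParseError
from .spectra import CDSpectrum, SpectralGrid, Transition
from .trcd import TRCDMatrix, Trajectory

__all__ = [
    "write_transitions",
    "read_transitions",
    "write_spectrum",
    "read_spectrum",
    "write_trajectory",
    "read_trajectory_table",
    "write_ensemble",
    "read_ensemble",
    "read_xyz_with_dihedrals",
    "write_trcd_matrix",
    "read_trcd_matrix",
    "write_trace",
    "write_occupancy",
]


# -- transition tables --------------------------------------------------
def write_transitions(transitions, path):
    df = pd.DataFrame(
        {
            "energy_eV": [t.energy_ev for t in transitions],
            "rotatory_1e-40cgs": [t.rotatory for t in transitions],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_transitions(path) -> list[Transition]:
    df = pd.read_csv(path, sep="\t")
    for col in ("energy_eV", "rotatory_1e-40cgs"):
        if col not in df.columns:
            raise TrajectoryParseError(f"transition table missing column {col!r}")
    return [
        Transition(float(r["energy_eV"]), float(r["rotatory_1e-40cgs"]))
        for _, r in df.iterrows()
    ]


# -- spectra ------------------------------------------------------------
def write_spectrum(spectrum: CDSpectrum, path):
    pd.DataFrame(
        {
            "wavelength_nm": spectrum.grid.wavelengths_nm,
            "delta_epsilon": spectrum.delta_epsilon,
        }
    ).to_csv(path, index=False, float_format="%.10g")


def read_spectrum(path) -> CDSpectrum:
    df = pd.read_csv(path)
    grid = SpectralGrid(df["wavelength_nm"].to_numpy(float))
    return CDSpectrum(grid, df["delta_epsilon"].to_numpy(float))


# -- trajectories -------------------------------------------------------
def _transition_columns(k: int) -> list[str]:
    cols = []
    for i in range(1, k + 1):
        cols += [f"E{i}_eV", f"R{i}"]
    return cols


def write_trajectory(traj: Trajectory, path):
    k = traj.energies_ev.shape[1]
    data = {
        "time_fs": traj.time_fs,
        "state": traj.state,
        "phi1_deg": traj.phi1,
        "phi2_deg": traj.phi2,
        "ring_open": traj.ring_open.astype(int),
    }
    for i in range(k):
        data[f"E{i+1}_eV"] = traj.energies_ev[:, i]
        data[f"R{i+1}"] = traj.rotatory[:, i]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_trajectory_table(path, traj_id: str | None = None) -> Trajectory:
    """Read and validate one trajectory TSV.

    Raises :class:`TrajectoryParseError` with a 1-based line number for a
    missing column, non-uniform time spacing, or a state regression
    (0 followed by 1).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["time_fs", "state", "phi1_deg", "phi2_deg", "ring_open"]
    for col in required:
        if col not in df.columns:
            raise TrajectoryParseError(f"missing column {col!r} in {path.name}")
    k = 0
    while f"E{k+1}_eV" in df.columns:
        if f"R{k+1}" not in df.columns:
            raise TrajectoryParseError(f"column E{k+1}_eV without matching R{k+1}")
        k += 1
    if k == 0:
        raise TrajectoryParseError("no transition columns (E1_eV/R1) found")

    times = df["time_fs"].to_numpy(float)
    if times.size >= 3:
        dts = np.diff(times)
        bad = np.nonzero(np.abs(dts - dts[0]) > 1e-6)[0]
        if bad.size:
            raise TrajectoryParseError(
                "non-uniform time spacing", line=int(bad[0]) + 3
            )  # header + 1-based + offset of diff
    state = df["state"].to_numpy(int)
    reg = np.nonzero(np.diff(state) > 0)[0]
    if reg.size:
        raise TrajectoryParseError(
            "state regression (ground state followed by excited)",
            line=int(reg[0]) + 3,
        )
    energies = np.stack([df[f"E{i+1}_eV"].to_numpy(float) for i in range(k)], axis=1)
    rotatory = np.stack([df[f"R{i+1}"].to_numpy(float) for i in range(k)], axis=1)
    return Trajectory(
        id=traj_id if traj_id is not None else path.stem,
        time_fs=times,
        state=state,
        phi1=df["phi1_deg"].to_numpy(float),
        phi2=df["phi2_deg"].to_numpy(float),
        ring_open=df["ring_open"].to_numpy(float).astype(bool),
        energies_ev=energies,
        rotatory=rotatory,
    )


def write_ensemble(ensemble, outdir, seed=None, config_hash=None) -> Path:
    """Write one TSV per trajectory plus a JSON manifest; returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for traj in ensemble:
        fname = f"{traj.id}.tsv"
        write_trajectory(traj, outdir / fname)
        files.append(fname)
    manifest = {
        "n_trajectories": len(list(ensemble)),
        "ids": [t.id for t in ensemble],
        "files": files,
        "seed": seed,
        "config_hash": config_hash,
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return mpath


def read_ensemble(manifest_path) -> list[Trajectory]:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    out = []
    for traj_id, fname in zip(manifest["ids"], manifest["files"]):
        out.append(read_trajectory_table(manifest_path.parent / fname, traj_id=traj_id))
    return out


# -- geometry -----------------------------------------------------------
def read_xyz_with_dihedrals(path, quadruples) -> np.ndarray:
    """Per-frame torsions from a multi-frame XYZ file.

    ``quadruples`` is a sequence of 1-based atom-index 4-tuples (e.g. the
    C10-C5-C6-C7 and C6-C7-C8-C9 quadruples of the triene).  Returns an
    (n_frames, n_quadruples) array of torsions in degrees.
    """
    import MDAnalysis as mda

    from .conformers import dihedral

    path = Path(path)
    if not path.exists():
        raise XYZParseError(f"no such XYZ file: {path}")
    try:
        universe = mda.Universe(str(path), format="XYZ")
    except Exception as exc:  # malformed header / truncated frame
        raise XYZParseError(f"malformed XYZ file {path.name}: {exc}") from exc
    n_atoms = universe.atoms.n_atoms
    quads = []
    for q in quadruples:
        q = tuple(int(i) for i in q)
        if len(q) != 4:
            raise XYZParseError(f"quadruple {q} must have 4 indices")
        if any(i < 1 or i > n_atoms for i in q):
            raise XYZParseError(
                f"atom index out of range in quadruple {q} (1..{n_atoms})"
            )
        quads.append(tuple(i - 1 for i in q))
    rows = []
    for _ in universe.trajectory:
        pos = universe.atoms.positions
        rows.append([dihedral(pos[a], pos[b], pos[c], pos[d]) for a, b, c, d in quads])
    return np.asarray(rows, dtype=float)


# -- TRCD ---------------------------------------------------------------
def write_trcd_matrix(matrix: TRCDMatrix, path):
    cols = ["delay_fs"] + [f"{w:.6g}" for w in matrix.grid.wavelengths_nm]
    df = pd.DataFrame(
        np.column_stack([matrix.delays_fs, matrix.values]), columns=cols
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_trcd_matrix(path, combine_mode: str = "add",
                     reference: CDSpectrum | None = None) -> TRCDMatrix:
    df = pd.read_csv(path)
    if df.columns[0] != "delay_fs":
        raise TrajectoryParseError("TRCD matrix must start with a delay_fs column")
    grid = SpectralGrid(np.array([float(c) for c in df.columns[1:]]))
    if reference is None:
        reference = CDSpectrum(grid, np.zeros(len(grid)))
    return TRCDMatrix(
        delays_fs=df["delay_fs"].to_numpy(float),
        grid=grid,
        values=df.iloc[:, 1:].to_numpy(float),
        combine_mode=combine_mode,
        reference=reference,
    )


def write_trace(delays_fs, values, path):
    pd.DataFrame({"delay_fs": delays_fs, "delta_cd": values}).to_csv(
        path, index=False, float_format="%.10g"
    )


def write_occupancy(table: OccupancyTable, path):
    rows = []
    for window in table.fractions:
        for label, frac in sorted(
            table.fractions[window].items(), key=lambda kv: -kv[1]
        ):
            rows.append({"window": window, "label": label, "fraction": frac})
    pd.DataFrame(rows, columns=["window", "label", "fraction"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
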