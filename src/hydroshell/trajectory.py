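"""Trajectory containers and plain-text trajectory I/O.

A :class:`Trajectory` is a topology (:class:`~hydroshell.core.StructureModel`
giving atom identities) plus a dense per-frame coordinate array. Two text
formats are supported: multi-model PDB (topology embedded) and multi-frame
XYZ alongside a single-frame PDB topology. Atom identity must be constant
across frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (AtomRecord, FormatError, ModelError, StructureModel, kabsch,
                   read_structure)


class TrajectoryError(ModelError):
    pass


@dataclass
class Trajectory:
    """Atom identities plus (n_frames, n_atoms, 3) coordinates in Å."""
    topology: StructureModel
    coords: np.ndarray
    frame_interval_ps: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.topology):
            raise TrajectoryError(
                f"coordinate atoms ({self.coords.shape[1]}) != topology atoms "
                f"({len(self.topology)})")
        if self.coords.shape[0] < 1:
            raise TrajectoryError("trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def duration_ns(self) -> float:
        return self.n_frames * self.frame_interval_ps / 1000.0

    @property
    def protein_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.topology.atoms)
                         if a.is_protein and not a.is_hydrogen], dtype=int)

    @property
    def water_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.topology.atoms)
                         if a.is_water and a.element == "O"], dtype=int)


@dataclass
class TrajectoryWindow:
    """A contiguous slice of frames used as one sampling window."""
    topology: StructureModel
    coords: np.ndarray
    frame_interval_ps: float
    start_time_ns: float
    aligned: bool = False

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def protein_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.topology.atoms)
                         if a.is_protein and not a.is_hydrogen], dtype=int)

    @property
    def water_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.topology.atoms)
                         if a.is_water and a.element == "O"], dtype=int)

    def protein_coords(self, frame: int = 0) -> np.ndarray:
        return self.coords[frame][self.protein_indices]

    def water_coords(self) -> np.ndarray:
        """(n_frames, n_waters, 3) water-oxygen coordinates."""
        return self.coords[:, self.water_indices, :]


def sample_windows(trajectory: Trajectory, window_frames: int,
                   interval_ns: float) -> list[TrajectoryWindow]:
    """Cut non-overlapping sampling windows ending at each interval multiple.

    With a 100-ns trajectory, 1-ns (500-frame) windows and a 10-ns interval
    this yields the ten windows ending at 10, 20, …, 100 ns.
    """
    if window_frames < 1:
        raise ValueError("window_frames must be ≥ 1")
    n = trajectory.n_frames
    if n < window_frames:
        raise TrajectoryError(
            f"trajectory has {n} frames but one window needs {window_frames} "
            f"({window_frames * trajectory.frame_interval_ps / 1000:.3g} ns)")
    frames_per_interval = interval_ns * 1000.0 / trajectory.frame_interval_ps
    windows = []
    k = 1
    while True:
        end = int(round(k * frames_per_interval))
        if end > n:
            break
        start = end - window_frames
        if start >= 0:
            windows.append(TrajectoryWindow(
                topology=trajectory.topology,
                coords=trajectory.coords[start:end],
                frame_interval_ps=trajectory.frame_interval_ps,
                start_time_ns=start * trajectory.frame_interval_ps / 1000.0))
        k += 1
    if not windows:
        raise TrajectoryError(
            f"no window of {window_frames} frames fits before the first "
            f"{interval_ns}-ns anchor")
    return windows


def align_window(window: TrajectoryWindow,
                 reference_coords: np.ndarray | None = None) -> TrajectoryWindow:
    """Rigid-body superpose every frame's protein atoms onto the reference
    (default: the window's first frame), co-transforming waters."""
    prot = window.protein_indices
    if len(prot) < 3:
        raise TrajectoryError("alignment needs ≥3 protein heavy atoms")
    ref = (np.asarray(reference_coords, float) if reference_coords is not None
           else window.coords[0][prot])
    if ref.shape != (len(prot), 3):
        raise TrajectoryError("reference does not match protein atom count")
    out = np.empty_like(window.coords)
    for f in range(window.n_frames):
        fit = kabsch(window.coords[f][prot], ref)
        out[f] = window.coords[f] @ fit.rotation.T + fit.translation
    return TrajectoryWindow(topology=window.topology, coords=out,
                            frame_interval_ps=window.frame_interval_ps,
                            start_time_ns=window.start_time_ns, aligned=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_xyz(trajectory: Trajectory, path: str | Path) -> None:
    """Write a multi-frame XYZ file (element + coordinates, 3 decimals)."""
    elements = [a.element.capitalize() for a in trajectory.topology.atoms]
    n = len(elements)
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            fh.write(f"{n}\n")
            fh.write(f"frame {f} t={f * trajectory.frame_interval_ps:.3f} ps\n")
            frame = trajectory.coords[f]
            lines = [f"{el} {x:.3f} {y:.3f} {z:.3f}"
                     for el, (x, y, z) in zip(elements, frame)]
            fh.write("\n".join(lines) + "\n")


def read_xyz_coords(path: str | Path, n_atoms: int | None = None) -> np.ndarray:
    """Read all frames of a multi-frame XYZ file into (n_frames, n_atoms, 3)."""
    frames = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"bad XYZ atom count at line {i + 1}: {lines[i]!r}") from exc
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise FormatError(f"truncated XYZ frame starting at line {i + 1}")
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise FormatError(f"{path}: no XYZ frames found")
    arr = np.array(frames)
    if n_atoms is not None and arr.shape[1] != n_atoms:
        raise TrajectoryError(
            f"XYZ has {arr.shape[1]} atoms per frame, expected {n_atoms}")
    return arr


def load_trajectory(topology_path: str | Path, traj_path: str | Path | None = None,
                    frame_interval_ps: float = 2.0) -> Trajectory:
    """Load a trajectory from text files.

    ``topology_path`` is a PDB giving atom identities (and, for a multi-model
    PDB with no separate ``traj_path``, all frames). ``traj_path``, if given,
    is a multi-frame XYZ whose atom order matches the topology.
    """
    topology = read_structure(topology_path)
    if traj_path is None:
        coords = _read_multimodel_pdb_coords(topology_path)
        if coords.shape[1] != len(topology):
            raise TrajectoryError("inconsistent atom counts across PDB models")
        return Trajectory(topology=topology, coords=coords,
                          frame_interval_ps=frame_interval_ps)
    coords = read_xyz_coords(traj_path, n_atoms=len(topology))
    return Trajectory(topology=topology, coords=coords,
                      frame_interval_ps=frame_interval_ps)


def _read_multimodel_pdb_coords(path: str | Path) -> np.ndarray:
    import gemmi
    st = gemmi.read_pdb(str(path))
    frames = []
    for model in st:
        pos = []
        for chain in model:
            for res in chain:
                for atom in res:
                    pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
        frames.append(pos)
    if not frames:
        raise FormatError(f"{path}: no models found")
    return np.array(frames, dtype=float)


def write_multimodel_pdb(trajectory: Trajectory, path: str | Path,
                         max_frames: int | None = None) -> None:
    """Write frames as a multi-MODEL PDB (mainly for small fixtures)."""
    atoms = trajectory.topology.atoms
    nf = trajectory.n_frames if max_frames is None else min(max_frames,
                                                            trajectory.n_frames)
    with open(path, "w") as fh:
        for f in range(nf):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i, a in enumerate(atoms):
                x, y, z = trajectory.coords[f, i]
                record = "ATOM  " if a.is_protein else "HETATM"
                fh.write(
                    f"{record}{i + 1:5d} {a.atom_name:<4.4s}{a.residue_name:>4.3s} "
                    f"{a.chain_id:1.1s}{a.residue_id:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
                    f"          {a.element:>2.2s}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")
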