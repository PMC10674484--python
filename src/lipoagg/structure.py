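"""Shape descriptors for peptide aggregates: Rg, Kirkwood Rh, volumes, RMSF.

Works on plain coordinate arrays (Angstrom) or on a :class:`Trajectory`
built from a multi-MODEL PDB file.  The radius of gyration is the
mass-weighted RMS distance from the centre of mass; the Kirkwood
approximation estimates the hydrodynamic radius of a rigid particle as
the inverse of the mean inverse pair distance over its (by default
carbon) atoms::

    Rh = < r_ij^-1 >^-1 ,  i < j

Sphere volumes derived from either radius use the same (4/3) pi R^3
relation as the anisotropy chain, so hydrodynamic volumes from
spectroscopy and from coordinates are directly comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from biotite.structure.info import mass as element_mass

from .hydrodynamics import volume_from_radius

__all__ = [
    "Trajectory",
    "StructureMetrics",
    "read_structure",
    "write_pdb",
    "radius_of_gyration",
    "kirkwood_rh",
    "gyration_volume",
    "rmsf",
    "trajectory_summary",
]


@dataclass(frozen=True)
class Trajectory:
    """Ordered coordinate frames with per-atom labels.

    ``frames`` has shape (n_frames, n_atoms, 3) in Angstrom; all frames
    share the same atoms in the same order.
    """

    frames: np.ndarray
    elements: Tuple[str, ...]
    masses: np.ndarray
    atom_names: Optional[Tuple[str, ...]] = None
    residue_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        fr = np.asarray(self.frames, dtype=float)
        if fr.ndim == 2:
            fr = fr[None]
        if fr.ndim != 3 or fr.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(fr)):
            raise ValueError("coordinates must be finite")
        m = np.asarray(self.masses, dtype=float)
        if m.shape != (fr.shape[1],) or np.any(m <= 0):
            raise ValueError("masses must be positive, one per atom")
        if len(self.elements) != fr.shape[1]:
            raise ValueError("one element symbol per atom required")
        object.__setattr__(self, "frames", fr)
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "elements", tuple(self.elements))
        if self.residue_ids is not None:
            object.__setattr__(self, "residue_ids",
                               np.asarray(self.residue_ids, dtype=int))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class StructureMetrics:
    """Per-frame and aggregate shape descriptors of a trajectory."""

    rg_per_frame_A: np.ndarray
    rh_per_frame_A: np.ndarray
    rg_mean_A: float
    rg_sd_A: float
    rh_mean_A: float
    rh_sd_A: float
    Vg_nm3: float
    Vh_nm3: float
    rmsf_A: Optional[np.ndarray] = None
    rmsf_atom_index: Optional[np.ndarray] = None
    rmsf_residue_ids: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        d = {
            "rg_mean_A": self.rg_mean_A, "rg_sd_A": self.rg_sd_A,
            "rh_mean_A": self.rh_mean_A, "rh_sd_A": self.rh_sd_A,
            "Vg_nm3": self.Vg_nm3, "Vh_nm3": self.Vh_nm3,
            "rg_per_frame_A": self.rg_per_frame_A.tolist(),
            "rh_per_frame_A": self.rh_per_frame_A.tolist(),
        }
        if self.rmsf_A is not None:
            d["rmsf_A"] = self.rmsf_A.tolist()
            if self.rmsf_residue_ids is not None:
                d["rmsf_residue_ids"] = self.rmsf_residue_ids.tolist()
        return d


# ---------------------------------------------------------------------------
# PDB I/O

_TWO_LETTER = {"CL", "BR", "NA", "MG", "ZN", "FE", "CA", "MN", "CU", "SE"}


def _element_from_name(name: str) -> str:
    stripped = "".join(ch for ch in name.strip() if ch.isalpha()).upper()
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    # PDB atom names like CA/CB are carbons; a genuine calcium carries an
    # explicit element column, so the single-letter reading wins here.
    return stripped[0]


def read_structure(path) -> Trajectory:
    """Read a PDB file; multiple MODEL records become trajectory frames."""
    pdb_file = pdbio.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)
    coords = np.asarray(stack.coord, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError(f"{path}: missing or non-finite coordinates")
    elements = []
    for elem, name in zip(stack.element, stack.atom_name):
        e = str(elem).strip().capitalize()
        if not e:
            e = _element_from_name(str(name)).capitalize()
        elements.append(e)
    masses = np.array([_mass_of(e) for e in elements])
    return Trajectory(
        frames=coords,
        elements=tuple(elements),
        masses=masses,
        atom_names=tuple(str(n) for n in stack.atom_name),
        residue_ids=np.asarray(stack.res_id, dtype=int),
    )


def _mass_of(element: str) -> float:
    m = element_mass(element)
    if m is None or m <= 0:
        raise ValueError(f"no standard mass for element {element!r}")
    return float(m)


def write_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as a (multi-MODEL) PDB file."""
    n = traj.n_atoms
    array = struc.AtomArrayStack(traj.n_frames, n)
    array.coord = traj.frames.astype(np.float32)
    array.element = np.array([e.upper() for e in traj.elements])
    array.atom_name = np.array(
        traj.atom_names if traj.atom_names is not None
        else [e.upper() for e in traj.elements]
    )
    array.res_id = (traj.residue_ids if traj.residue_ids is not None
                    else np.arange(1, n + 1))
    array.res_name = np.full(n, "GLY")
    array.chain_id = np.full(n, "A")
    array.hetero = np.full(n, False)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(array)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# descriptors

def radius_of_gyration(
    frame: np.ndarray,
    masses: Optional[np.ndarray] = None,
    mass_weighted: bool = True,
) -> float:
    """Rg = sqrt( sum_i m_i |r_i - r_com|^2 / sum_i m_i ), in Angstrom."""
    xyz = np.atleast_2d(np.asarray(frame, dtype=float))
    if masses is None or not mass_weighted:
        w = np.ones(len(xyz))
    else:
        w = np.asarray(masses, dtype=float)
    com = np.average(xyz, axis=0, weights=w)
    d2 = np.sum((xyz - com) ** 2, axis=1)
    return float(np.sqrt(np.average(d2, weights=w)))


def kirkwood_rh(
    frame: np.ndarray,
    elements: Optional[Sequence[str]] = None,
    selection: Optional[str] = "C",
) -> float:
    """Kirkwood hydrodynamic radius over the selected atoms, in Angstrom.

    ``selection`` filters by element symbol (default carbon, the
    convention for coarse hydrodynamic estimates of peptides); pass
    ``None`` to use every atom.  Unordered pairs i<j enter the mean;
    coincident atoms make the statistic singular and are rejected.
    """
    xyz = np.atleast_2d(np.asarray(frame, dtype=float))
    if selection is not None and elements is not None:
        mask = np.array([e.upper() == selection.upper() for e in elements])
        xyz = xyz[mask]
    if len(xyz) < 2:
        raise ValueError("need at least 2 selected atoms for the Kirkwood radius")
    dists = pdist(xyz)
    if np.any(dists == 0):
        dm = squareform(dists)
        i, j = np.argwhere(np.triu(dm == 0, k=1))[0]
        raise ValueError(f"coincident selected atoms at indices {i} and {j}")
    return float(1.0 / np.mean(1.0 / dists))


def gyration_volume(Rg_A: float) -> float:
    """Volume (nm^3) of the sphere with the given gyration radius (Angstrom)."""
    return volume_from_radius(Rg_A)


def _superpose(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``ref``."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mobile - mc)
    return rot.apply(mobile - mc) + rc


def rmsf(
    traj: Trajectory,
    selection: Optional[str] = "CA",
    superpose: bool = True,
) -> np.ndarray:
    """Per-atom root mean square fluctuation over frames, in Angstrom.

    ``selection`` filters by atom name (default Calpha).  With
    ``superpose`` each frame is rigidly fitted onto the selection's mean
    structure before averaging (mean -> fit -> recompute mean), removing
    overall translation and rotation.
    """
    if traj.n_frames < 2:
        raise ValueError("rmsf needs at least 2 frames")
    if selection is not None and traj.atom_names is not None:
        mask = np.array([n.upper() == selection.upper() for n in traj.atom_names])
    else:
        mask = np.ones(traj.n_atoms, dtype=bool)
    sel = traj.frames[:, mask, :]
    if superpose:
        if sel.shape[1] < 3:
            raise ValueError("superposition needs at least 3 selected atoms")
        mean0 = sel.mean(axis=0)
        sel = np.stack([_superpose(f, mean0) for f in sel])
    mean = sel.mean(axis=0)
    return np.sqrt(np.mean(np.sum((sel - mean) ** 2, axis=2), axis=0))


def trajectory_summary(
    traj: Trajectory,
    rh_selection: Optional[str] = "C",
    rmsf_selection: Optional[str] = "CA",
    mass_weighted: bool = True,
    superpose: bool = True,
) -> StructureMetrics:
    """Per-frame Rg and Kirkwood Rh, their means +- sd, sphere volumes from
    the mean radii, and (for multi-frame input) the Calpha RMSF profile."""
    rg = np.array([
        radius_of_gyration(f, traj.masses, mass_weighted) for f in traj.frames
    ])
    rh = np.array([
        kirkwood_rh(f, traj.elements, rh_selection) for f in traj.frames
    ])
    fluct = idx = res = None
    if traj.n_frames >= 2:
        if rmsf_selection is not None and traj.atom_names is not None:
            mask = np.array([n.upper() == rmsf_selection.upper()
                             for n in traj.atom_names])
        else:
            mask = np.ones(traj.n_atoms, dtype=bool)
        if mask.sum() >= (3 if superpose else 1):
            fluct = rmsf(traj, rmsf_selection, superpose)
            idx = np.flatnonzero(mask)
            if traj.residue_ids is not None:
                res = traj.residue_ids[idx]
    return StructureMetrics(
        rg_per_frame_A=rg,
        rh_per_frame_A=rh,
        rg_mean_A=float(rg.mean()), rg_sd_A=float(rg.std(ddof=0)),
        rh_mean_A=float(rh.mean()), rh_sd_A=float(rh.std(ddof=0)),
        Vg_nm3=gyration_volume(float(rg.mean())),
        Vh_nm3=volume_from_radius(float(rh.mean())),
        rmsf_A=fluct, rmsf_atom_index=idx, rmsf_residue_ids=res,
    )


def write_metrics_report(metrics: StructureMetrics, json_path,
                         per_frame_path=None, rmsf_path=None) -> None:
    """Write the summary as JSON plus optional per-frame / RMSF tables."""
    Path(json_path).write_text(
        json.dumps(metrics.to_dict(), indent=2, sort_keys=True)
    )
    if per_frame_path is not None:
        rows = np.column_stack([
            np.arange(len(metrics.rg_per_frame_A)),
            metrics.rg_per_frame_A, metrics.rh_per_frame_A,
        ])
        np.savetxt(per_frame_path, rows, header="frame\tRg_A\tRh_A",
                   fmt=["%d", "%.6g", "%.6g"], delimiter="\t")
    if rmsf_path is not None and metrics.rmsf_A is not None:
        res = (metrics.rmsf_residue_ids if metrics.rmsf_residue_ids is not None
               else np.arange(1, len(metrics.rmsf_A) + 1))
        np.savetxt(rmsf_path, np.column_stack([res, metrics.rmsf_A]),
                   header="residue\trmsf_A", fmt=["%d", "%.6g"], delimiter="\t")
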