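"""Structure and trajectory containers with PDB/XYZ input-output.

Crystal structures are read through gemmi into a flat per-atom table
(pandas DataFrame) carrying serial, atom name, residue, chain, element,
coordinates in Å, B-factor and the ATOM/HETATM record kind.  Trajectories
are the same atom table plus a ``(n_frames, n_atoms, 3)`` coordinate
array; multi-model PDB round-trips through gemmi, and the plain XYZ
format is supported for coordinate-only data.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "WATER_RESNAMES",
    "StructureModel",
    "Trajectory",
    "read_structure",
    "read_trajectory",
    "write_trajectory",
    "fetch_pdb",
]

#: Residue names recognised as solvent water (extensible by callers).
WATER_RESNAMES = frozenset({"HOH", "WAT", "H2O", "SOL"})

_ATOM_COLUMNS = ["serial", "name", "resname", "resnum", "chain",
                 "element", "x", "y", "z", "bfactor", "record"]


@dataclass(frozen=True)
class StructureModel:
    """A single structural model as a per-atom table."""

    atoms: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_ATOM_COLUMNS) - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns: {sorted(missing)}")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("atom coordinates must be finite")

    @property
    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(dtype=float)

    def water_residues(self) -> pd.DataFrame:
        """One row per water residue (chain, resnum, resname)."""
        wat = self.atoms[self.atoms["resname"].isin(WATER_RESNAMES)]
        return wat.drop_duplicates(subset=["chain", "resnum", "resname"])

    def select(self, *, chain: str | None = None, resnum: int | None = None,
               name: str | None = None, resname: str | None = None
               ) -> pd.DataFrame:
        df = self.atoms
        if chain is not None:
            df = df[df["chain"] == chain]
        if resnum is not None:
            df = df[df["resnum"] == resnum]
        if resname is not None:
            df = df[df["resname"] == resname]
        if name is not None:
            df = df[df["name"] == name]
        return df


@dataclass(frozen=True)
class Trajectory:
    """Shared atom table plus per-frame coordinates (Å).

    ``frame_dt`` is the frame spacing in picoseconds; frames are 0-based.
    """

    atoms: pd.DataFrame
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    frame_dt: float = 100.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[1] != len(self.atoms):
            raise ValueError("frame atom count does not match atom table")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame_model(self, i: int) -> StructureModel:
        """Materialise frame ``i`` as a StructureModel."""
        df = self.atoms.copy()
        df[["x", "y", "z"]] = self.coords[i]
        return StructureModel(df)


def fetch_pdb(pdb_id: str, dest: str, timeout: float = 30.0) -> str:
    """Download a PDB entry from the RCSB into ``dest`` and return the path.

    Raises ``OSError`` when the archive is unreachable (offline use).
    """
    import urllib.request

    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    req = urllib.request.urlopen(url, timeout=timeout)
    data = req.read()
    with open(dest, "wb") as fh:
        fh.write(data)
    return str(dest)


def _structure_to_frames(st: gemmi.Structure) -> tuple[pd.DataFrame,
                                                       np.ndarray]:
    rows = []
    frames = []
    for im, model in enumerate(st):
        coords = []
        for chain in model:
            for res in chain:
                het = res.het_flag == "H"
                for atom in res:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    if im == 0:
                        rows.append({
                            "serial": atom.serial,
                            "name": atom.name,
                            "resname": res.name,
                            "resnum": res.seqid.num,
                            "chain": chain.name,
                            "element": atom.element.name,
                            "x": atom.pos.x, "y": atom.pos.y, "z": atom.pos.z,
                            "bfactor": atom.b_iso,
                            "record": "HETATM" if het else "ATOM",
                        })
        frames.append(np.asarray(coords, dtype=float))
    n0 = frames[0].shape[0]
    for i, f in enumerate(frames):
        if f.shape[0] != n0:
            raise ValueError(
                f"frame {i} has {f.shape[0]} atoms, expected {n0}")
    atoms = pd.DataFrame(rows, columns=_ATOM_COLUMNS)
    return atoms, np.stack(frames)


def read_structure(path: str) -> StructureModel:
    """Read a PDB file into a StructureModel (first model only)."""
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ValueError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    atoms, _ = _structure_to_frames(st)
    if atoms.empty:
        raise ValueError(f"no atoms in {path}")
    return StructureModel(atoms)


def _read_xyz(path: str) -> tuple[pd.DataFrame, np.ndarray]:
    frames = []
    elements0: list[str] | None = None
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header.strip():
                break
            try:
                n = int(header.split()[0])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed XYZ atom count") from exc
            fh.readline()  # comment
            lineno += 1
            elems, xyz = [], []
            for _ in range(n):
                parts = fh.readline().split()
                lineno += 1
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: short XYZ atom line")
                elems.append(parts[0])
                xyz.append([float(v) for v in parts[1:4]])
            if elements0 is None:
                elements0 = elems
            elif len(elems) != len(elements0):
                raise ValueError(
                    f"frame {len(frames)} has {len(elems)} atoms, "
                    f"expected {len(elements0)}")
            frames.append(np.asarray(xyz, dtype=float))
    if not frames:
        raise ValueError(f"no frames in {path}")
    atoms = pd.DataFrame({
        "serial": np.arange(1, len(elements0) + 1),
        "name": elements0, "resname": "UNK", "resnum": 1, "chain": "A",
        "element": elements0,
        "x": frames[0][:, 0], "y": frames[0][:, 1], "z": frames[0][:, 2],
        "bfactor": 0.0, "record": "ATOM"})[_ATOM_COLUMNS]
    return atoms, np.stack(frames)


def read_trajectory(path: str, frame_dt: float = 100.0) -> Trajectory:
    """Read a multi-model PDB or XYZ trajectory.

    The format is chosen by file extension (.xyz vs anything else, which
    is treated as PDB).
    """
    if str(path).lower().endswith(".xyz"):
        atoms, coords = _read_xyz(str(path))
    else:
        try:
            st = gemmi.read_pdb(str(path))
        except (RuntimeError, ValueError, OSError) as exc:
            raise ValueError(f"cannot read PDB file {path}: {exc}") from exc
        if len(st) == 0:
            raise ValueError(f"no models in {path}")
        atoms, coords = _structure_to_frames(st)
    return Trajectory(atoms=atoms, coords=coords, frame_dt=frame_dt)


def write_trajectory(traj: Trajectory, path: str) -> None:
    """Write a trajectory as multi-model PDB or XYZ (by extension)."""
    if str(path).lower().endswith(".xyz"):
        with open(path, "w") as fh:
            elems = traj.atoms["element"].tolist()
            for i in range(traj.n_frames):
                fh.write(f"{traj.n_atoms}\nframe {i}\n")
                for e, (x, y, z) in zip(elems, traj.coords[i]):
                    fh.write(f"{e} {x:.6f} {y:.6f} {z:.6f}\n")
        return
    st = gemmi.Structure()
    st.name = "trajectory"
    for i in range(traj.n_frames):
        model = gemmi.Model(i + 1)
        for chain_name, chain_df in traj.atoms.groupby("chain", sort=False):
            chain = gemmi.Chain(str(chain_name))
            for (resnum, resname), res_df in chain_df.groupby(
                    ["resnum", "resname"], sort=False):
                res = gemmi.Residue()
                res.name = str(resname)
                res.seqid = gemmi.SeqId(int(resnum), " ")
                res.het_flag = "H" if res_df["record"].iloc[0] == "HETATM" \
                    else "A"
                for idx, row in res_df.iterrows():
                    atom = gemmi.Atom()
                    atom.name = str(row["name"])
                    atom.element = gemmi.Element(str(row["element"]))
                    atom.serial = int(row["serial"])
                    atom.b_iso = float(row["bfactor"])
                    x, y, z = traj.coords[i, traj.atoms.index.get_loc(idx)]
                    atom.pos = gemmi.Position(float(x), float(y), float(z))
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)
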