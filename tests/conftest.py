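import numpy as np
import pandas as pd
import pytest

from hmgclamp.eedd import FretPair
from hmgclamp.structures import StructureModel, Trajectory, write_trajectory


@pytest.fixture
def pair() -> FretPair:
    return FretPair(R0=55.0, tau_D=4.0)


def make_atoms(rows: list[dict]) -> pd.DataFrame:
    """Atom table from terse row dicts, filling IO-only columns."""
    defaults = dict(bfactor=0.0, record="ATOM", element="O", serial=0)
    full = []
    for i, row in enumerate(rows):
        r = {**defaults, **row}
        r.setdefault("serial", i + 1)
        full.append(r)
    df = pd.DataFrame(full)
    df["serial"] = range(1, len(df) + 1)
    return df[["serial", "name", "resname", "resnum", "chain", "element",
               "x", "y", "z", "bfactor", "record"]]


def make_model(rows: list[dict]) -> StructureModel:
    return StructureModel(make_atoms(rows))


@pytest.fixture
def synthetic_crystal(tmp_path):
    """Small synthetic crystal-style PDB: protein + DNA + 3 waters.

    Synthetic stand-in for a deposited co-crystal structure; B-factors
    chosen so DNA > protein and the water mean is 20.
    """
    rows = [
        dict(name="CA", resname="GLY", resnum=1, chain="A", element="C",
             x=0.0, y=0.0, z=0.0, bfactor=10.0),
        dict(name="CA", resname="ALA", resnum=2, chain="A", element="C",
             x=3.8, y=0.0, z=0.0, bfactor=14.0),
        dict(name="P", resname="DA", resnum=1, chain="B", element="P",
             x=0.0, y=8.0, z=0.0, bfactor=20.0),
        dict(name="P", resname="DT", resnum=2, chain="B", element="P",
             x=3.8, y=8.0, z=0.0, bfactor=24.0),
        dict(name="O", resname="HOH", resnum=101, chain="S", element="O",
             x=1.0, y=4.0, z=0.0, bfactor=10.0, record="HETATM"),
        dict(name="O", resname="HOH", resnum=102, chain="S", element="O",
             x=2.0, y=4.0, z=0.0, bfactor=20.0, record="HETATM"),
        # far-away water, outside the 5 A shell of the complex
        dict(name="O", resname="HOH", resnum=103, chain="S", element="O",
             x=50.0, y=50.0, z=50.0, bfactor=30.0, record="HETATM"),
    ]
    atoms = make_atoms(rows)
    coords = atoms[["x", "y", "z"]].to_numpy()[None, :, :]
    path = tmp_path / "synthetic_crystal.pdb"
    write_trajectory(Trajectory(atoms=atoms, coords=coords), str(path))
    return path
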