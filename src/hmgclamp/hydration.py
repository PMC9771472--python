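"""Water-mediated bridges at a protein-DNA interface.

A *bridge site* is defined by partner heavy atoms on the protein side
(e.g. the Tyr72 para-hydroxyl oxygen and the residue-5 carbonyl oxygen)
and on the DNA side (phosphate backbone oxygens).  A water occupies the
site when it hydrogen-bonds simultaneously to enough partners, covering
both macromolecules ("1-water motif"); alternatively a mutually
hydrogen-bonded pair of waters may span the same partners ("2-water
motif").  Tracking the identity of the occupying water frame-by-frame
over an MD trajectory yields a residency *barcode*, from which dwell
times, occupancy and exchange statistics follow.

Hydrogen bonds use a heavy-atom donor-acceptor distance cutoff plus a
D-H...A angle window when hydrogens are present (heavy-atom-only
otherwise); cutoffs are explicit and results are criterion-dependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import WATER_RESNAMES, StructureModel, Trajectory

__all__ = [
    "HBondCriteria",
    "AtomSelector",
    "SiteDefinition",
    "WaterBarcode",
    "ResidencyStats",
    "SolventSummary",
    "is_hbond",
    "assign_bridge",
    "build_barcode",
    "residency_stats",
    "distance_trace",
    "crystal_solvent_summary",
    "box_to_full_numbering",
]

_AMINO_ACIDS = frozenset("""
ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP
TYR VAL MSE
""".split())
_NUCLEOTIDES = frozenset("""
DA DT DG DC DU A T G C U DI I
""".split())

#: Default offset between consensus HMG-box numbering and full-length
#: human SRY numbering (box position 72 = residue 127).
BOX_NUMBERING_OFFSET = 55


def box_to_full_numbering(box_position: int,
                          offset: int = BOX_NUMBERING_OFFSET) -> int:
    """Map a consensus HMG-box position to full-length residue numbering."""
    return box_position + offset


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria (bounds inclusive)."""

    max_DA_dist: float = 3.5     # heavy-atom donor-acceptor distance, Å
    min_DHA_angle: float = 130.0  # D-H...A angle, degrees
    use_hydrogens: bool = True    # fall back to heavy-atom-only if absent

    def __post_init__(self) -> None:
        if self.max_DA_dist <= 0:
            raise ValueError("max_DA_dist must be positive")
        if not 0.0 < self.min_DHA_angle <= 180.0:
            raise ValueError("min_DHA_angle must lie in (0, 180]")


@dataclass(frozen=True)
class AtomSelector:
    """Selects atoms by any combination of chain, residue and atom name."""

    chain: str | None = None
    resnum: int | None = None
    resname: str | None = None
    name: str | None = None

    def resolve(self, atoms: pd.DataFrame) -> pd.DataFrame:
        df = atoms
        if self.chain is not None:
            df = df[df["chain"] == self.chain]
        if self.resnum is not None:
            df = df[df["resnum"] == self.resnum]
        if self.resname is not None:
            df = df[df["resname"] == self.resname]
        if self.name is not None:
            df = df[df["name"] == self.name]
        return df


@dataclass(frozen=True)
class SiteDefinition:
    """Bridge-site partners plus hydrogen-bond criteria.

    ``min_partners`` is the number of simultaneous partner hydrogen bonds
    a single water needs (always including at least one protein and one
    DNA partner).
    """

    protein_side_chain: tuple[AtomSelector, ...]
    protein_backbone: tuple[AtomSelector, ...]
    dna_backbone: tuple[AtomSelector, ...]
    criteria: HBondCriteria = field(default_factory=HBondCriteria)
    min_partners: int = 2

    def resolve(self, atoms: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Return (partner row positions, is_protein mask)."""
        prot_idx: list[int] = []
        dna_idx: list[int] = []
        for sel in tuple(self.protein_side_chain) + tuple(self.protein_backbone):
            rows = sel.resolve(atoms)
            if rows.empty:
                raise ValueError(f"protein partner selector matched no atoms: "
                                 f"{sel}")
            prot_idx.extend(atoms.index.get_indexer(rows.index))
        for sel in self.dna_backbone:
            rows = sel.resolve(atoms)
            if rows.empty:
                raise ValueError(f"DNA partner selector matched no atoms: "
                                 f"{sel}")
            dna_idx.extend(atoms.index.get_indexer(rows.index))
        if len(prot_idx) < 1 or len(dna_idx) < 1:
            raise ValueError("site needs >=1 protein and >=1 DNA partner")
        idx = np.array(prot_idx + dna_idx, dtype=int)
        is_protein = np.array([True] * len(prot_idx) + [False] * len(dna_idx))
        return idx, is_protein


@dataclass(frozen=True)
class WaterBarcode:
    """Per-frame bridge occupant plus gap-merged residency segments.

    ``occupants`` holds the water id per frame (``None`` when the site is
    empty).  ``segments`` are (start_frame, end_frame, water_id) with
    inclusive ends, merged across unoccupied gaps of at most
    ``gap_tolerance`` frames when the same water returns.
    """

    occupants: tuple
    segments: tuple
    gap_tolerance: int = 0
    frame_dt: float = 100.0  # ps
    motifs: tuple = ()       # per-frame motif labels, optional

    @property
    def n_frames(self) -> int:
        return len(self.occupants)

    def to_records(self) -> list[dict]:
        return [{"start_frame": s, "end_frame": e, "water_id": w}
                for s, e, w in self.segments]


@dataclass(frozen=True)
class ResidencyStats:
    """Summary of site residency derived from a barcode."""

    n_distinct_occupants: int
    occupancy_fraction: float
    first_occupancy_time_ns: float | None
    dwell_times_ns: tuple
    mean_dwell_ns: float
    max_dwell_ns: float

    def to_dict(self) -> dict:
        return {
            "n_distinct_occupants": self.n_distinct_occupants,
            "occupancy_fraction": self.occupancy_fraction,
            "first_occupancy_time_ns": self.first_occupancy_time_ns,
            "dwell_times_ns": list(self.dwell_times_ns),
            "mean_dwell_ns": self.mean_dwell_ns,
            "max_dwell_ns": self.max_dwell_ns,
        }


@dataclass(frozen=True)
class SolventSummary:
    """Ordered-water counts and per-component B-factor statistics."""

    n_waters: int
    n_waters_near_complex: int
    mean_b_protein: float
    mean_b_dna: float
    mean_b_water: float
    dna_b_higher_than_protein: bool
    chain_atom_counts: dict

    def to_dict(self) -> dict:
        return {
            "n_waters": self.n_waters,
            "n_waters_near_complex": self.n_waters_near_complex,
            "mean_b_protein": self.mean_b_protein,
            "mean_b_dna": self.mean_b_dna,
            "mean_b_water": self.mean_b_water,
            "dna_b_higher_than_protein": self.dna_b_higher_than_protein,
            "chain_atom_counts": dict(self.chain_atom_counts),
        }


def is_hbond(donor_heavy, acceptor, criteria: HBondCriteria,
             hydrogen=None) -> bool:
    """Geometric hydrogen-bond test between heavy atoms.

    True iff the donor-acceptor distance is <= ``max_DA_dist`` and, when
    a hydrogen position is supplied and ``use_hydrogens`` is set, the
    D-H...A angle is >= ``min_DHA_angle``.  Bounds are inclusive.
    """
    d = np.asarray(donor_heavy, dtype=float)
    a = np.asarray(acceptor, dtype=float)
    dist = float(np.linalg.norm(d - a))
    # inclusive bounds, with a small float cushion for exact criteria
    if dist > criteria.max_DA_dist + 1e-9:
        return False
    if hydrogen is None or not criteria.use_hydrogens:
        return True
    h = np.asarray(hydrogen, dtype=float)
    v1 = d - h
    v2 = a - h
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return False
    cosang = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return math.degrees(math.acos(cosang)) >= criteria.min_DHA_angle - 1e-9


def _water_oxygens(atoms: pd.DataFrame) -> pd.DataFrame:
    wat = atoms[atoms["resname"].isin(WATER_RESNAMES)]
    return wat[wat["element"].str.upper().str.startswith("O")]


def _water_id(row) -> str:
    return f"{row['chain']}:{row['resnum']}"


def _bridge_from_coords(wpos: np.ndarray, ppos: np.ndarray,
                        is_protein: np.ndarray, criteria: HBondCriteria,
                        min_partners: int):
    """Classify the bridge motif from water/partner coordinates.

    Returns (motif, water row positions).  Heavy-atom criterion only
    (the toy generators and barcodes operate on oxygen positions).
    """
    if wpos.size == 0:
        return "none", []
    # (n_waters, n_partners) distance matrix
    dm = np.linalg.norm(wpos[:, None, :] - ppos[None, :, :], axis=2)
    bonded = dm <= criteria.max_DA_dist
    n_prot = bonded[:, is_protein].sum(axis=1)
    n_dna = bonded[:, ~is_protein].sum(axis=1)
    n_tot = n_prot + n_dna

    # 1-water motif takes precedence
    single = np.flatnonzero((n_tot >= min_partners) & (n_prot >= 1)
                            & (n_dna >= 1))
    if single.size:
        best = single[np.lexsort((dm[single].min(axis=1), -n_tot[single]))][0]
        return "one_water", [int(best)]

    # 2-water motif: mutually bonded pair, each bonded to >=1 partner,
    # union spanning protein and DNA
    cand = np.flatnonzero(n_tot >= 1)
    if cand.size >= 2:
        ww = np.linalg.norm(wpos[cand][:, None, :] - wpos[cand][None, :, :],
                            axis=2)
        best_pair = None
        best_score = -1.0
        for ii in range(cand.size):
            for jj in range(ii + 1, cand.size):
                if ww[ii, jj] > criteria.max_DA_dist:
                    continue
                i, j = cand[ii], cand[jj]
                if (n_prot[i] + n_prot[j]) >= 1 and (n_dna[i] + n_dna[j]) >= 1:
                    score = float(n_tot[i] + n_tot[j]) - 1e-3 * ww[ii, jj]
                    if score > best_score:
                        best_score = score
                        best_pair = (int(i), int(j))
        if best_pair is not None:
            return "two_water", list(best_pair)
    return "none", []


def assign_bridge(model: StructureModel, site: SiteDefinition):
    """Classify the bridge motif in a single structural model.

    Returns ``(motif, water_ids)`` where motif is one of ``none``,
    ``one_water``, ``two_water`` and water ids are "chain:resnum"
    strings (one id for the 1-water motif, two for the 2-water motif).
    """
    idx, is_protein = site.resolve(model.atoms)
    waters = _water_oxygens(model.atoms)
    wpos = waters[["x", "y", "z"]].to_numpy(dtype=float)
    ppos = model.atoms.iloc[idx][["x", "y", "z"]].to_numpy(dtype=float)
    motif, rows = _bridge_from_coords(wpos, ppos, is_protein, site.criteria,
                                      site.min_partners)
    ids = [_water_id(waters.iloc[r]) for r in rows]
    return motif, ids


def _merge_segments(occupants: list, gap_tolerance: int) -> list[tuple]:
    runs: list[list] = []
    for i, occ in enumerate(occupants):
        if occ is not None and runs and runs[-1][2] == occ \
                and i - runs[-1][1] - 1 <= gap_tolerance \
                and all(occupants[j] is None
                        for j in range(runs[-1][1] + 1, i)):
            runs[-1][1] = i
        elif occ is not None:
            runs.append([i, i, occ])
    return [tuple(r) for r in runs]


def build_barcode(traj: Trajectory, site: SiteDefinition,
                  gap_tolerance: int = 2) -> WaterBarcode:
    """Per-frame bridge occupancy barcode over a trajectory.

    The occupant of a frame is the bridging water id (for the 2-water
    motif, the protein-proximal water of the pair, matching a
    site-centred view of residency).  Segments with the same occupant
    are merged across unoccupied gaps of at most ``gap_tolerance``
    frames.
    """
    idx, is_protein = site.resolve(traj.atoms)
    waters = _water_oxygens(traj.atoms)
    w_rows = np.asarray(traj.atoms.index.get_indexer(waters.index))
    water_ids = [_water_id(waters.iloc[i]) for i in range(len(waters))]
    occupants: list = []
    motifs: list = []
    for f in range(traj.n_frames):
        coords = traj.coords[f]
        motif, rows = _bridge_from_coords(
            coords[w_rows], coords[idx], is_protein, site.criteria,
            site.min_partners)
        motifs.append(motif)
        if motif == "none":
            occupants.append(None)
        elif motif == "one_water":
            occupants.append(water_ids[rows[0]])
        else:  # protein-proximal water of the pair
            prot_pos = coords[idx][is_protein]
            dmin = [np.min(np.linalg.norm(prot_pos - coords[w_rows[r]],
                                          axis=1)) for r in rows]
            occupants.append(water_ids[rows[int(np.argmin(dmin))]])
    segments = _merge_segments(occupants, gap_tolerance)
    return WaterBarcode(occupants=tuple(occupants), segments=tuple(segments),
                        gap_tolerance=gap_tolerance, frame_dt=traj.frame_dt,
                        motifs=tuple(motifs))


def residency_stats(barcode: WaterBarcode,
                    frame_dt: float | None = None) -> ResidencyStats:
    """Dwell-time and occupancy statistics from a barcode.

    ``frame_dt`` (ps per frame) defaults to the barcode's own value.
    Times are reported in ns.
    """
    dt_ns = (frame_dt if frame_dt is not None else barcode.frame_dt) / 1000.0
    occ = [o for o in barcode.occupants if o is not None]
    n_frames = barcode.n_frames
    frac = len(occ) / n_frames if n_frames else 0.0
    first = None
    for i, o in enumerate(barcode.occupants):
        if o is not None:
            first = i * dt_ns
            break
    dwells = tuple((e - s + 1) * dt_ns for s, e, _ in barcode.segments)
    distinct = len({w for _, _, w in barcode.segments})
    return ResidencyStats(
        n_distinct_occupants=distinct,
        occupancy_fraction=frac,
        first_occupancy_time_ns=first,
        dwell_times_ns=dwells,
        mean_dwell_ns=float(np.mean(dwells)) if dwells else 0.0,
        max_dwell_ns=float(np.max(dwells)) if dwells else 0.0,
    )


def _resolve_unique(atoms: pd.DataFrame, sel: AtomSelector) -> int:
    rows = sel.resolve(atoms)
    if rows.empty:
        raise ValueError(f"atom selector matched nothing: {sel}")
    if len(rows) > 1:
        listing = rows[["chain", "resnum", "resname", "name"]].to_dict("records")
        raise ValueError(f"ambiguous atom selector {sel}: matches {listing}")
    return int(atoms.index.get_indexer(rows.index)[0])


def distance_trace(traj: Trajectory, atom_a: AtomSelector,
                   atom_b: AtomSelector) -> np.ndarray:
    """Per-frame Euclidean distance (Å) between two uniquely selected atoms."""
    ia = _resolve_unique(traj.atoms, atom_a)
    ib = _resolve_unique(traj.atoms, atom_b)
    return np.linalg.norm(traj.coords[:, ia, :] - traj.coords[:, ib, :],
                          axis=1)


def crystal_solvent_summary(model: StructureModel,
                            near_cutoff: float = 5.0) -> SolventSummary:
    """Solvent content and B-factor statistics of a crystal structure.

    Counts water residues (by residue name), reports both the full
    solvent count and the subset within ``near_cutoff`` Å of any
    non-water atom, and mean B-factors for the protein, DNA and water
    components (NaN for absent components).
    """
    atoms = model.atoms
    is_water = atoms["resname"].isin(WATER_RESNAMES)
    is_protein = (atoms["record"] == "ATOM") & \
        atoms["resname"].isin(_AMINO_ACIDS)
    is_dna = (atoms["record"] == "ATOM") & atoms["resname"].isin(_NUCLEOTIDES)

    def mean_b(mask) -> float:
        vals = atoms.loc[mask, "bfactor"]
        return float(vals.mean()) if len(vals) else math.nan

    b_prot, b_dna, b_wat = mean_b(is_protein), mean_b(is_dna), mean_b(is_water)
    waters = atoms[is_water]
    water_res = waters.drop_duplicates(subset=["chain", "resnum", "resname"])
    n_waters = len(water_res)

    macro = atoms[~is_water][["x", "y", "z"]].to_numpy(dtype=float)
    n_near = 0
    if macro.size and len(waters):
        for _, res in water_res.iterrows():
            sel = waters[(waters["chain"] == res["chain"])
                         & (waters["resnum"] == res["resnum"])]
            pos = sel[["x", "y", "z"]].to_numpy(dtype=float)
            dmin = np.min(np.linalg.norm(
                macro[None, :, :] - pos[:, None, :], axis=2))
            if dmin <= near_cutoff:
                n_near += 1
    counts = atoms.groupby("chain")["name"].count().to_dict()
    higher = bool(np.isfinite(b_prot) and np.isfinite(b_dna)
                  and b_dna > b_prot)
    return SolventSummary(
        n_waters=n_waters, n_waters_near_complex=n_near,
        mean_b_protein=b_prot, mean_b_dna=b_dna, mean_b_water=b_wat,
        dna_b_higher_than_protein=higher, chain_atom_counts=counts)
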