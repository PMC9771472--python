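"""Seeded synthetic-data generators with exact ground truth.

Every pipeline stage has a matching generator here so recovery can be
scored against known truth without any external data.  Defaults follow
the study conditions the analyses target: 25 nM DNA in titrations, a
15-bp duplex (5'-TCGGTGATTGTTCAG-3') labelled at the 5' ends,
stopped-flow chase traces at 10/15/25/37 °C, the six circular-permutation
probe positions (120/95/79/51/47/27 bp within a 150-bp fragment), and a
toy water-diffusion trajectory standing in for a 200-ns MD run sampled
every 100 ps.

The toy trajectory is a kinetic caricature, not physics: bulk waters
take Gaussian random-walk steps inside a reflecting box, a defined triad
site (protein hydroxyl + backbone carbonyl + DNA phosphate oxygen)
captures any water entering its capture sphere, and the occupant escapes
each frame with a fixed probability.  Waters other than the occupant are
kept out of the capture sphere, which makes the emitted occupancy record
exact ground truth for barcode construction whenever the hydrogen-bond
cutoff matches the capture geometry.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .binding import KineticTrace, TitrationSeries, predict_delta_f
from .bend import PermutationLane, end_to_end, flexure_position
from .eedd import DecayCurve, FretPair, PointMass, donor_decay
from .hydration import AtomSelector, HBondCriteria, SiteDefinition
from .structures import Trajectory

__all__ = [
    "GroundTruth",
    "ToyTrajectoryConfig",
    "gen_titration",
    "gen_decay",
    "gen_donor_only_decay",
    "gen_kinetic_trace",
    "gen_permutation_lanes",
    "gen_toy_trajectory",
    "gen_step_trace",
    "DEFAULT_DNA_CONC",
    "DEFAULT_DUPLEX",
    "DEFAULT_TEMPERATURES_C",
    "DEFAULT_PERMUTATION_POSITIONS",
]

#: Fixed DNA concentration in titrations (M).
DEFAULT_DNA_CONC = 25e-9
#: The 15-bp duplex carrying the ATTGTT target site.
DEFAULT_DUPLEX = "TCGGTGATTGTTCAG"
#: Stopped-flow temperature series (deg C).
DEFAULT_TEMPERATURES_C = (10.0, 15.0, 25.0, 37.0)
#: Probe distances (bp) within the 150-bp permutation fragment.
DEFAULT_PERMUTATION_POSITIONS = (120, 95, 79, 51, 47, 27)
DEFAULT_FRAGMENT_BP = 150


@dataclass(frozen=True)
class GroundTruth:
    """True parameters of a generated dataset, serialisable as JSON."""

    params: dict

    def to_dict(self) -> dict:
        return dict(self.params)


def gen_titration(Kd: float = 20e-9, dF0: float = 1.0,
                  D0: float = DEFAULT_DNA_CONC,
                  S_grid=None, noise_sigma: float = 0.01,
                  seed: int = 0) -> tuple[TitrationSeries, GroundTruth]:
    """Titration series from the depletion isotherm plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    if S_grid is None:
        S_grid = np.concatenate([[0.0],
                                 np.geomspace(0.1 * D0, 40.0 * D0, 11)])
    S_grid = np.asarray(S_grid, dtype=float)
    clean = predict_delta_f(S_grid, D0, Kd, dF0)
    noisy = clean + rng.normal(0.0, noise_sigma, size=S_grid.shape)
    series = TitrationSeries(protein_conc=S_grid, delta_f=noisy, dna_conc=D0)
    return series, GroundTruth({"Kd": Kd, "dF0": dF0, "D0": D0,
                                "noise_sigma": noise_sigma, "seed": seed})


def gen_decay(dist, pair: FretPair, n_photons: int = 10**6,
              t_max: float | None = None, n_bins: int = 256,
              seed: int = 0) -> tuple[DecayCurve, GroundTruth]:
    """Photon-counting donor decay through the Förster kernel.

    Per-bin counts are Poisson with expectation proportional to the
    model intensity at the bin centre; the expected total is n_photons.
    """
    if n_photons < 10**3:
        raise ValueError("need at least 1e3 photons")
    rng = np.random.default_rng(seed)
    if t_max is None:
        t_max = 6.0 * pair.tau_D
    edges = np.linspace(0.0, t_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    inten = donor_decay(dist, pair, centers)
    mu = n_photons * inten / inten.sum()
    counts = rng.poisson(mu).astype(float)
    curve = DecayCurve(time=centers, counts=counts)
    truth = {"pair": {"R0": pair.R0, "tau_D": pair.tau_D},
             "n_photons": n_photons, "seed": seed}
    for attr in ("r0", "sigma", "a", "r_max", "r"):
        if hasattr(dist, attr):
            truth[attr] = getattr(dist, attr)
    return curve, GroundTruth(truth)


def gen_donor_only_decay(pair: FretPair, n_photons: int = 10**6,
                         t_max: float | None = None, n_bins: int = 256,
                         seed: int = 0) -> tuple[DecayCurve, GroundTruth]:
    """Donor-only control decay (no acceptor: mono-exponential in tau_D)."""
    # a point mass far beyond R0 makes the transfer term negligible
    return gen_decay(PointMass(1e6 * pair.R0), pair, n_photons,
                     t_max=t_max, n_bins=n_bins, seed=seed)


def gen_kinetic_trace(koff: float = 1.0, amplitude: float = 1.0,
                      baseline: float = 0.1, noise_sigma: float = 0.02,
                      t_max: float | None = None, n_points: int = 500,
                      temperature: float = 298.15,
                      seed: int = 0) -> tuple[KineticTrace, GroundTruth]:
    """Single-exponential dissociation trace plus Gaussian noise."""
    if koff <= 0:
        raise ValueError("koff must be positive")
    rng = np.random.default_rng(seed)
    if t_max is None:
        t_max = 6.0 / koff
    t = np.linspace(0.0, t_max, n_points)
    clean = baseline + amplitude * np.exp(-koff * t)
    noisy = clean + rng.normal(0.0, noise_sigma, size=t.shape)
    trace = KineticTrace(time=t, signal=noisy, temperature=temperature)
    return trace, GroundTruth({"koff": koff, "amplitude": amplitude,
                               "baseline": baseline,
                               "noise_sigma": noise_sigma,
                               "temperature": temperature, "seed": seed})


def gen_permutation_lanes(alpha: float = 80.0,
                          positions_bp=DEFAULT_PERMUTATION_POSITIONS,
                          L: float = DEFAULT_FRAGMENT_BP,
                          c0: float = 0.2, c1: float = 0.8,
                          noise_sigma: float = 0.005, seed: int = 0,
                          replicate: int = 0
                          ) -> tuple[list[PermutationLane], GroundTruth]:
    """Circular-permutation lanes from the two-arm bent-rod model."""
    rng = np.random.default_rng(seed)
    lanes = []
    for d in positions_bp:
        x = flexure_position(d, L)
        m = c0 + c1 * end_to_end(x, alpha, 1.0) \
            + rng.normal(0.0, noise_sigma)
        lanes.append(PermutationLane(fragment_length=L, bend_locus=x,
                                     rel_mobility=float(m),
                                     replicate=replicate))
    return lanes, GroundTruth({"alpha": alpha, "c0": c0, "c1": c1,
                               "noise_sigma": noise_sigma,
                               "positions_bp": list(positions_bp), "L": L,
                               "seed": seed})


@dataclass(frozen=True)
class ToyTrajectoryConfig:
    """Parameters of the toy water-diffusion trajectory.

    ``capture_radius`` is both the snap zone of the triad site and the
    exclusion zone for non-occupant waters; it must exceed the partner
    offset (2.8 Å) plus the hydrogen-bond cutoff so that no free water
    can reach a partner, making the emitted barcode exact.
    """

    n_waters: int = 10
    box_edge: float = 30.0
    diffusion_step: float = 1.0      # Å per frame (per axis sigma)
    capture_radius: float = 6.5      # Å
    escape_probability: float = 0.05  # per frame
    n_frames: int = 200
    frame_dt: float = 100.0          # ps
    start_occupied: bool = True
    partner_offset: float = 2.8      # Å, partner distance from site centre
    tail_levels: tuple = (3.0, 5.0, 8.0)
    tail_changepoints: tuple | None = None  # default: thirds of the run
    tail_noise_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_waters < 1:
            raise ValueError("need at least one water")
        if not 0.0 <= self.escape_probability <= 1.0:
            raise ValueError("escape_probability must lie in [0, 1]")
        if self.box_edge <= 2 * self.capture_radius:
            raise ValueError("box_edge must exceed 2 * capture_radius")

    @property
    def site_center(self) -> np.ndarray:
        return np.full(3, self.box_edge / 2.0)

    def site_definition(self, max_DA_dist: float = 3.5) -> SiteDefinition:
        """Site definition matching the generated partner atoms."""
        return SiteDefinition(
            protein_side_chain=(AtomSelector(chain="A", resnum=72,
                                             name="OH"),),
            protein_backbone=(AtomSelector(chain="A", resnum=5, name="O"),),
            dna_backbone=(AtomSelector(chain="B", resnum=7, name="OP1"),),
            criteria=HBondCriteria(max_DA_dist=max_DA_dist,
                                   use_hydrogens=False),
            min_partners=2)


def _toy_atom_table(cfg: ToyTrajectoryConfig) -> pd.DataFrame:
    c = cfg.site_center
    off = cfg.partner_offset
    rows = [
        # static triad partners around the site centre
        dict(serial=1, name="OH", resname="TYR", resnum=72, chain="A",
             element="O", x=c[0] + off, y=c[1], z=c[2], bfactor=0.0,
             record="ATOM"),
        dict(serial=2, name="O", resname="ILE", resnum=5, chain="A",
             element="O", x=c[0], y=c[1] + off, z=c[2], bfactor=0.0,
             record="ATOM"),
        # mobile tail amide for the plateau trace (chain A kept contiguous
        # so PDB round-trips preserve atom order)
        dict(serial=3, name="N", resname="ARG", resnum=77, chain="A",
             element="N", x=c[0] + 12.0, y=c[1] + cfg.tail_levels[0],
             z=c[2], bfactor=0.0, record="ATOM"),
        dict(serial=4, name="OP1", resname="DC", resnum=7, chain="B",
             element="O", x=c[0] - off, y=c[1], z=c[2], bfactor=0.0,
             record="ATOM"),
        # static anchor the tail walks away from
        dict(serial=5, name="OP1", resname="DG", resnum=14, chain="B",
             element="O", x=c[0] + 12.0, y=c[1], z=c[2], bfactor=0.0,
             record="ATOM"),
    ]
    for i in range(cfg.n_waters):
        rows.append(dict(serial=6 + i, name="O", resname="HOH",
                         resnum=1 + i, chain="W", element="O",
                         x=0.0, y=0.0, z=0.0, bfactor=0.0, record="HETATM"))
    return pd.DataFrame(rows)


def _reflect(pos: np.ndarray, edge: float) -> np.ndarray:
    pos = np.abs(pos)
    pos = edge - np.abs(edge - (pos % (2 * edge)))
    return pos


def gen_toy_trajectory(cfg: ToyTrajectoryConfig
                       ) -> tuple[Trajectory, GroundTruth]:
    """Toy trajectory of diffusing waters with a sticky triad site.

    Returns the trajectory plus ground truth containing the exact
    per-frame occupant record and its residency segments (gap merging
    not applied: the generator produces no flicker).
    """
    rng = np.random.default_rng(cfg.seed)
    atoms = _toy_atom_table(cfg)
    c = cfg.site_center
    rcap = cfg.capture_radius
    n = cfg.n_waters

    # initial positions: uniform in the box, outside the capture sphere
    wpos = np.empty((n, 3))
    for i in range(n):
        while True:
            p = rng.uniform(0.0, cfg.box_edge, size=3)
            if np.linalg.norm(p - c) > rcap:
                wpos[i] = p
                break
    occupant: int | None = None
    if cfg.start_occupied:
        occupant = 0
        wpos[0] = c

    if cfg.tail_changepoints is None:
        k = len(cfg.tail_levels)
        tail_cps = tuple(cfg.n_frames * j // k for j in range(1, k))
    else:
        tail_cps = tuple(cfg.tail_changepoints)
    level_of_frame = np.empty(cfg.n_frames)
    bounds = [0, *tail_cps, cfg.n_frames]
    for lvl, (a, b) in zip(cfg.tail_levels, zip(bounds, bounds[1:])):
        level_of_frame[a:b] = lvl

    anchor = np.array([c[0] + 12.0, c[1], c[2]])
    tail_row = 2
    water_rows = np.arange(5, 5 + n)

    frames = np.empty((cfg.n_frames, len(atoms), 3))
    static = atoms[["x", "y", "z"]].to_numpy(dtype=float)
    occupants: list = []
    for f in range(cfg.n_frames):
        # occupant escape; the leaving water cannot be recaptured within
        # the same frame, so instant escape yields single-frame dwells
        just_escaped: int | None = None
        if occupant is not None and rng.random() < cfg.escape_probability:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            wpos[occupant] = _reflect(c + (rcap + 0.5) * u, cfg.box_edge)
            just_escaped = occupant
            occupant = None
        # free-water diffusion with capture/exclusion
        for i in rng.permutation(n):
            if i == occupant:
                continue
            prop = _reflect(wpos[i] + rng.normal(0.0, cfg.diffusion_step,
                                                 size=3), cfg.box_edge)
            dvec = prop - c
            dist = float(np.linalg.norm(dvec))
            if dist <= rcap:
                if occupant is None and i != just_escaped:
                    occupant = int(i)
                    prop = c.copy()
                else:  # site blocked: keep the water outside the sphere
                    if dist == 0.0:
                        dvec = rng.normal(size=3)
                        dist = float(np.linalg.norm(dvec))
                    prop = _reflect(c + dvec * (rcap + 0.2) / dist,
                                    cfg.box_edge)
            wpos[i] = prop
        frame = static.copy()
        frame[water_rows] = wpos
        jitter = rng.normal(0.0, cfg.tail_noise_sigma)
        frame[tail_row] = anchor + np.array(
            [0.0, level_of_frame[f] + jitter, 0.0])
        frames[f] = frame
        occupants.append(f"W:{occupant + 1}" if occupant is not None else None)

    segments = []
    for i, occ in enumerate(occupants):
        if occ is not None and segments and segments[-1][2] == occ \
                and segments[-1][1] == i - 1:
            segments[-1][1] = i
        elif occ is not None:
            segments.append([i, i, occ])
    traj = Trajectory(atoms=atoms, coords=frames, frame_dt=cfg.frame_dt)
    truth = GroundTruth({
        "occupants": occupants,
        "segments": [tuple(s) for s in segments],
        "tail_levels": list(cfg.tail_levels),
        "tail_changepoints": list(tail_cps),
        "config": asdict(cfg),
    })
    return traj, truth


def gen_step_trace(levels=(3.0, 5.0, 8.0), changepoints=None,
                   noise_sigma: float = 0.15, n_frames: int = 300,
                   seed: int = 0) -> tuple[np.ndarray, GroundTruth]:
    """Piecewise-constant series plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    levels = tuple(levels)
    if changepoints is None:
        k = len(levels)
        changepoints = tuple(n_frames * j // k for j in range(1, k))
    changepoints = tuple(changepoints)
    if len(changepoints) != len(levels) - 1:
        raise ValueError("need len(levels) - 1 changepoints")
    if list(changepoints) != sorted(set(changepoints)) or \
            (changepoints and (changepoints[0] <= 0
                               or changepoints[-1] >= n_frames)):
        raise ValueError("changepoints must be strictly increasing and "
                         "inside (0, n_frames)")
    y = np.empty(n_frames)
    bounds = [0, *changepoints, n_frames]
    for lvl, (a, b) in zip(levels, zip(bounds, bounds[1:])):
        y[a:b] = lvl
    y += rng.normal(0.0, noise_sigma, size=n_frames)
    return y, GroundTruth({"levels": list(levels),
                           "changepoints": list(changepoints),
                           "noise_sigma": noise_sigma, "seed": seed})
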