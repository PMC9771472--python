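"""CSV/TSV/JSON input-output for the analysis stages."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bend import PermutationLane, flexure_position
from .binding import KineticTrace, TitrationSeries
from .eedd import DecayCurve
from .hydration import WaterBarcode

__all__ = [
    "read_titration_csv", "write_titration_csv",
    "read_kinetic_csv", "write_kinetic_csv",
    "read_decay_csv", "write_decay_csv",
    "read_lanes_csv", "write_lanes_csv",
    "write_json", "barcode_to_tsv",
]


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_titration_csv(path, dna_conc: float,
                       temperature: float = 298.15) -> TitrationSeries:
    df = pd.read_csv(path)
    _require(df, ["conc_M", "delta_F"], path)
    return TitrationSeries(protein_conc=df["conc_M"].to_numpy(),
                           delta_f=df["delta_F"].to_numpy(),
                           dna_conc=dna_conc, temperature=temperature)


def write_titration_csv(series: TitrationSeries, path) -> None:
    pd.DataFrame({"conc_M": series.protein_conc,
                  "delta_F": series.delta_f}).to_csv(path, index=False)


def read_kinetic_csv(path, temperature: float = 298.15) -> KineticTrace:
    df = pd.read_csv(path)
    _require(df, ["time_s", "signal"], path)
    return KineticTrace(time=df["time_s"].to_numpy(),
                        signal=df["signal"].to_numpy(),
                        temperature=temperature)


def write_kinetic_csv(trace: KineticTrace, path) -> None:
    pd.DataFrame({"time_s": trace.time,
                  "signal": trace.signal}).to_csv(path, index=False)


def read_decay_csv(path) -> DecayCurve:
    df = pd.read_csv(path)
    _require(df, ["time_ns", "counts"], path)
    return DecayCurve(time=df["time_ns"].to_numpy(),
                      counts=df["counts"].to_numpy())


def write_decay_csv(curve: DecayCurve, path) -> None:
    pd.DataFrame({"time_ns": curve.time,
                  "counts": curve.counts}).to_csv(path, index=False)


def read_lanes_csv(path) -> list[PermutationLane]:
    df = pd.read_csv(path)
    _require(df, ["distance_bp", "fragment_bp", "rel_mobility"], path)
    if "replicate" not in df.columns:
        df["replicate"] = 0
    return [PermutationLane(
                fragment_length=float(r.fragment_bp),
                bend_locus=flexure_position(float(r.distance_bp),
                                            float(r.fragment_bp)),
                rel_mobility=float(r.rel_mobility),
                replicate=int(r.replicate))
            for r in df.itertuples()]


def write_lanes_csv(lanes: list[PermutationLane], path) -> None:
    pd.DataFrame({
        "distance_bp": [ln.bend_locus * ln.fragment_length for ln in lanes],
        "fragment_bp": [ln.fragment_length for ln in lanes],
        "rel_mobility": [ln.rel_mobility for ln in lanes],
        "replicate": [ln.replicate for ln in lanes],
    }).to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")


def barcode_to_tsv(barcode: WaterBarcode, path) -> None:
    """Per-frame (frame, occupant_id, motif) record as TSV."""
    with open(path, "w") as fh:
        fh.write("frame\toccupant_id\tmotif\n")
        motifs = barcode.motifs or tuple(
            "none" if occ is None else "occupied"
            for occ in barcode.occupants)
        for i, (occ, motif) in enumerate(zip(barcode.occupants, motifs)):
            fh.write(f"{i}\t{occ if occ is not None else '.'}\t{motif}\n")
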