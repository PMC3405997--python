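"""Readers and writers for the plain-text formats the pipeline exchanges.

Tables travel as pandas DataFrames.  Genomic intervals use the BED
convention (0-based, half-open) throughout; plate readouts use the screen
CSV schema; read positions are two-column TSV (chrom, 5' position); binned
log2(IP/input) tracks are written as bedGraph.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

PLATE_COLUMNS = ["plate_id", "replicate", "well", "amplicon_id", "role", "firefly", "renilla"]
BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

_FLOAT_FMT = "%.6g"


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Read a plate-readout CSV (schema: plate_id, replicate, well, amplicon_id, role, firefly, renilla)."""
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "amplicon_id": str, "role": str})
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate CSV missing columns: {missing}")
    df["replicate"] = df["replicate"].astype(int)
    return df[PLATE_COLUMNS]


def write_plate_csv(wells: pd.DataFrame, path: str | Path) -> None:
    wells[PLATE_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3-BED6 into a frame with columns chrom/start/end[/name/score/strand]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = BED_COLUMNS[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ValueError("invalid BED intervals: require 0 <= start < end")
    return df


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED_COLUMNS if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False, float_format=_FLOAT_FMT)


def read_positions(path: str | Path) -> pd.DataFrame:
    """Read a two-column TSV of read 5' positions (chrom, pos)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos"], dtype={"chrom": str})
    df["pos"] = df["pos"].astype(int)
    return df


def write_positions(positions: pd.DataFrame, path: str | Path) -> None:
    positions[["chrom", "pos"]].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(tracks: Mapping[str, "CoverageTrack"], path: str | Path) -> None:  # noqa: F821
    """Write per-chromosome binned tracks as bedGraph (chrom, start, end, value)."""
    with open(path, "w") as fh:
        for chrom in tracks:
            t = tracks[chrom]
            b = t.bin_size
            for i, v in enumerate(t.values):
                end = min((i + 1) * b, t.chrom_length)
                fh.write(f"{chrom}\t{i * b}\t{end}\t{v:.6g}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"], dtype={"chrom": str})
    return df


def read_pwm(path: str | Path) -> pd.DataFrame:
    """Read a position x {A,C,G,T} log-odds matrix from tab-delimited text."""
    pwm = pd.read_csv(path, sep="\t")
    missing = [b for b in "ACGT" if b not in pwm.columns]
    if missing:
        raise ValueError(f"PWM file missing base columns: {missing}")
    return pwm[list("ACGT")]


def write_pwm(pwm: pd.DataFrame, path: str | Path) -> None:
    pwm[list("ACGT")].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_ground_truth(truth, path: str | Path) -> None:
    """Serialize a GroundTruth manifest to JSON."""
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_ground_truth(path: str | Path):
    from .simulate import GroundTruth

    with open(path) as fh:
        return GroundTruth.from_dict(json.load(fh))
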