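"""ChIP enrichment: qPCR-style normalized fold enrichment and binned
log2(IP/input) coverage tracks from read 5'-end positions.

qPCR enrichment is doubly normalized — to input DNA and to a non-transcribed
control locus — and H4K16ac enrichment can additionally be normalized to
histone H3 occupancy.  Coverage tracks count read 5' positions in
non-overlapping bins (default 200 bp), add a pseudocount, scale by library
size, and report log2(IP/input); reads are single positions with no
fragment extension or shifting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


class NonpositiveQuantityError(ValueError):
    """nonpositive_quantity: qPCR quantities must be positive."""


class PositionOutOfBoundsError(ValueError):
    """A read position lies outside its chromosome bounds."""


@dataclass(frozen=True)
class QpcrQuant:
    locus_id: str
    sample: str  # ip | input
    antibody: str
    quantity: float

    def __post_init__(self):
        if self.quantity <= 0:
            raise NonpositiveQuantityError("nonpositive_quantity")


@dataclass
class CoverageTrack:
    """Binned log2(IP/input) values for one chromosome."""

    chrom: str
    chrom_length: int
    bin_size: int
    values: np.ndarray  # one value per bin, len = ceil(length / bin_size)
    ip_library_size: int
    input_library_size: int

    @property
    def n_bins(self) -> int:
        return len(self.values)


def qpcr_enrichment(ip_target: float, input_target: float,
                    ip_control: float, input_control: float) -> float:
    """Fold enrichment of a target locus over a non-transcribed control.

    (IP_target/Input_target) / (IP_control/Input_control); all four
    quantities must be positive.
    """
    vals = (ip_target, input_target, ip_control, input_control)
    if any(v <= 0 for v in vals):
        raise NonpositiveQuantityError("nonpositive_quantity")
    return (ip_target / input_target) / (ip_control / input_control)


def h3_normalized_enrichment(h4k16_fold: float, h3_fold: float) -> float:
    """H4K16ac fold enrichment normalized to histone H3 occupancy."""
    if h3_fold <= 0:
        raise NonpositiveQuantityError("nonpositive_quantity")
    if h4k16_fold < 0:
        raise ValueError("fold enrichment cannot be negative")
    return h4k16_fold / h3_fold


def qpcr_enrichment_table(quants: pd.DataFrame, control_locus: str,
                          antibody: str | None = None) -> pd.DataFrame:
    """Control-locus-normalized fold enrichment for every assayed locus.

    ``quants`` columns: locus_id, sample (ip|input), antibody, quantity.
    """
    q = quants if antibody is None else quants[quants["antibody"] == antibody]
    rows = []
    for ab, grp in q.groupby("antibody", sort=True):
        pivot = grp.pivot_table(index="locus_id", columns="sample",
                                values="quantity", aggfunc="mean")
        if control_locus not in pivot.index:
            raise ValueError(f"control locus {control_locus!r} missing for {ab}")
        ctrl = pivot.loc[control_locus]
        for locus, row in pivot.iterrows():
            if locus == control_locus:
                continue
            rows.append({
                "antibody": ab, "locus_id": locus,
                "fold_enrichment": qpcr_enrichment(row["ip"], row["input"],
                                                   ctrl["ip"], ctrl["input"]),
            })
    return pd.DataFrame(rows, columns=["antibody", "locus_id", "fold_enrichment"])


def _positions_by_chrom(positions, chrom_lengths: Mapping[str, int],
                        label: str) -> dict[str, np.ndarray]:
    if isinstance(positions, pd.DataFrame):
        grouped = {c: g["pos"].to_numpy(dtype=np.int64)
                   for c, g in positions.groupby("chrom", sort=True)}
    else:
        grouped = {c: np.asarray(p, dtype=np.int64) for c, p in positions.items()}
    bad = []
    for chrom, pos in grouped.items():
        if chrom not in chrom_lengths:
            bad.extend((chrom, int(p)) for p in pos[:5])
            continue
        L = chrom_lengths[chrom]
        out = pos[(pos < 0) | (pos >= L)]
        bad.extend((chrom, int(p)) for p in out[:5])
    if bad:
        raise PositionOutOfBoundsError(
            f"{label}: positions outside chromosome bounds (first offenders: {bad[:10]})")
    return grouped


def binned_log2_track(ip_positions, input_positions,
                      chrom_lengths: Mapping[str, int], bin_size: int = 200,
                      pseudocount: float = 1.0) -> dict[str, CoverageTrack]:
    """Binned log2(IP/input) per chromosome from read 5' positions.

    Per bin: log2( ((ip+p)/IP_total) / ((in+p)/Input_total) ) with
    pseudocount p added before library scaling; totals are the in-bounds
    read counts of each sample.  Bins are 0-based half-open
    [i*b, (i+1)*b); the final partial bin is kept.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    ip = _positions_by_chrom(ip_positions, chrom_lengths, "IP")
    inp = _positions_by_chrom(input_positions, chrom_lengths, "input")
    ip_total = sum(len(v) for v in ip.values())
    in_total = sum(len(v) for v in inp.values())
    if ip_total == 0 or in_total == 0:
        raise ValueError("both samples need at least one read")
    tracks: dict[str, CoverageTrack] = {}
    for chrom, L in chrom_lengths.items():
        n_bins = -(-int(L) // bin_size)
        ipc = np.bincount(ip.get(chrom, np.empty(0, np.int64)) // bin_size,
                          minlength=n_bins).astype(float)
        inc = np.bincount(inp.get(chrom, np.empty(0, np.int64)) // bin_size,
                          minlength=n_bins).astype(float)
        with np.errstate(divide="ignore"):
            vals = (np.log2((ipc + pseudocount) / ip_total)
                    - np.log2((inc + pseudocount) / in_total))
        tracks[chrom] = CoverageTrack(chrom=chrom, chrom_length=int(L),
                                      bin_size=bin_size, values=vals,
                                      ip_library_size=ip_total,
                                      input_library_size=in_total)
    return tracks


def binned_counts(positions, chrom_lengths: Mapping[str, int],
                  bin_size: int = 200) -> dict[str, np.ndarray]:
    """Raw per-bin read counts (conservation: sums to the in-bounds total)."""
    grouped = _positions_by_chrom(positions, chrom_lengths, "reads")
    out = {}
    for chrom, L in chrom_lengths.items():
        n_bins = -(-int(L) // bin_size)
        out[chrom] = np.bincount(grouped.get(chrom, np.empty(0, np.int64)) // bin_size,
                                 minlength=n_bins)
    return out


def tracks_from_bedgraph(df: pd.DataFrame,
                         chrom_lengths: Mapping[str, int] | None = None
                         ) -> dict[str, CoverageTrack]:
    """Rebuild CoverageTracks from a bedGraph frame (uniform bins assumed)."""
    tracks = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        widths = (grp["end"] - grp["start"]).to_numpy()
        bin_size = int(widths[0]) if len(widths) == 1 else int(widths[:-1].max())
        length = (int(chrom_lengths[chrom]) if chrom_lengths is not None
                  else int(grp["end"].max()))
        tracks[chrom] = CoverageTrack(chrom=chrom, chrom_length=length,
                                      bin_size=bin_size,
                                      values=grp["value"].to_numpy(float),
                                      ip_library_size=0, input_library_size=0)
    return tracks
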