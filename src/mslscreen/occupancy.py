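"""MRE motif scanning, site classes, peak occupancy, and enrichment matrices.

This module carries the chromatin-occupancy analyses: scan a genome for
GA-rich MRE motif matches with a log-odds PWM; split MREs into five site
classes (MREs in chromatin entry sites, best- and randomly-chosen MREs on
the X and an autosome, 150 sites each); compute the fraction of motif
sites covered by binding-site peaks; and build sites x bins log2(IP/input)
matrices over midpoint +/-5 kb in 200-bp bins for heatmaps and average
profiles.

All coordinates are BED-style 0-based half-open; occupancy means >=1 bp
overlap with a peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._util import percent
from .chip import CoverageTrack

CLASS_NAMES = ("mre_in_ces", "best_x", "random_x", "best_aut", "random_aut")

_BASE_INDEX = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i


class PwmWidthError(ValueError):
    """PWM width does not match the expected motif length."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class SiteClassSet:
    """One of the five MRE site classes (n sites, short classes warned)."""

    class_name: str
    sites: pd.DataFrame
    n_requested: int
    seed: int | None = None


@dataclass
class EnrichmentMatrix:
    """sites x bins matrix of log2(IP/input); NaN marks missing bins."""

    site_names: list[str]
    values: np.ndarray  # shape (n_sites, n_bins), NaN = missing
    flank: int
    bin_size: int
    class_name: str | None = None

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        offsets = [-self.flank + j * self.bin_size for j in range(self.n_bins)]
        return pd.DataFrame(self.values, index=self.site_names,
                            columns=[f"bin_{o}" for o in offsets])


# --------------------------------------------------------------------------
# PWM scanning
# --------------------------------------------------------------------------

def garich_pwm(length: int = 21) -> pd.DataFrame:
    """A toy log-odds PWM for a GA-rich motif (configurable width).

    Alternating G/A preference against a uniform background; a stand-in
    for the experimentally derived MRE consensus matrix, which is supplied
    as input when available.
    """
    probs = np.empty((length, 4))
    for i in range(length):
        p = {"A": 0.2, "C": 0.05, "G": 0.2, "T": 0.05}
        p["G" if i % 2 == 0 else "A"] = 0.7
        probs[i] = [p[b] for b in "ACGT"]
    return pd.DataFrame(np.log2(probs / 0.25), columns=list("ACGT"))


def pwm_consensus(pwm) -> str:
    """Highest-scoring sequence of a log-odds PWM."""
    arr = _as_pwm_array(pwm)
    return "".join("ACGT"[i] for i in arr.argmax(axis=1))

def _as_pwm_array(pwm) -> np.ndarray:
    if isinstance(pwm, pd.DataFrame):
        pwm = pwm[list("ACGT")].to_numpy(float)
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[1] != 4:
        raise PwmWidthError("PWM must be a (width x 4) log-odds matrix over ACGT")
    return pwm


def pwm_scores(sequence: str, pwm) -> tuple[np.ndarray, np.ndarray]:
    """Log-odds scores of every window on the forward and reverse strand.

    Windows containing non-ACGT characters score -inf and are skipped by
    scan_mres.  The reverse-strand score at position i is the score of the
    reverse complement of sequence[i:i+w].
    """
    pwm = _as_pwm_array(pwm)
    w = pwm.shape[0]
    enc = _BASE_INDEX[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n = len(enc) - w + 1
    if n <= 0:
        return np.empty(0), np.empty(0)
    ext = np.hstack([pwm, np.full((w, 1), -np.inf)])  # column 4 = N
    rc = ext[::-1, [3, 2, 1, 0, 4]]                   # reverse-complement PWM
    fwd = np.zeros(n)
    rev = np.zeros(n)
    for j in range(w):
        col = enc[j:j + n]
        fwd += ext[j, col]
        rev += rc[j, col]
    return fwd, rev


def scan_mres(sequences: Mapping[str, str], pwm, threshold: float,
              motif_length: int | None = None,
              dedupe_positions: bool = False) -> pd.DataFrame:
    """All windows (both strands) scoring >= threshold, as a BED-like frame.

    Returns columns chrom/start/end/name/score/strand sorted by
    (chrom, start, strand).  Opposite-strand matches at the same position
    are kept unless ``dedupe_positions`` (then the better-scoring strand
    wins, forward on ties).
    """
    pwm_arr = _as_pwm_array(pwm)
    if motif_length is not None and pwm_arr.shape[0] != motif_length:
        raise PwmWidthError(
            f"PWM width {pwm_arr.shape[0]} != motif length {motif_length}")
    w = pwm_arr.shape[0]
    rows = []
    for chrom in sequences:
        fwd, rev = pwm_scores(sequences[chrom], pwm_arr)
        for strand, scores in (("+", fwd), ("-", rev)):
            for i in np.flatnonzero(scores >= threshold):
                rows.append({"chrom": chrom, "start": int(i), "end": int(i) + w,
                             "score": float(scores[i]), "strand": strand})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "strand"])
    df = df.sort_values(["chrom", "start", "strand"], kind="mergesort").reset_index(drop=True)
    if dedupe_positions and len(df):
        df = (df.sort_values(["chrom", "start", "score", "strand"],
                             ascending=[True, True, False, True], kind="mergesort")
                .drop_duplicates(["chrom", "start"]).reset_index(drop=True))
    df["name"] = [f"MRE_{c}_{i:05d}" for i, c in enumerate(df["chrom"])]
    return df[["chrom", "start", "end", "name", "score", "strand"]]


# --------------------------------------------------------------------------
# interval overlap
# --------------------------------------------------------------------------

def _trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in intervals.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(grp["start"], grp["end"]))
    return trees


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame,
                 max_gap: int = 0) -> pd.Series:
    """Boolean per query row: overlaps >=1 subject interval by >=1 bp.

    ``max_gap`` > 0 relaxes the rule to proximity within that many bp.
    """
    trees = _trees(subject)
    out = np.zeros(len(query), dtype=bool)
    for k, (chrom, s, e) in enumerate(zip(query["chrom"], query["start"], query["end"])):
        tree = trees.get(chrom)
        if tree is not None:
            out[k] = bool(tree.overlap(int(s) - max_gap, int(e) + max_gap))
    return pd.Series(out, index=query.index, name="occupied")


def occupancy_fraction(mres: pd.DataFrame, peaks: pd.DataFrame,
                       by: str = "chrom", max_gap: int = 0) -> pd.DataFrame:
    """Fraction of motif sites overlapped by >=1 peak, per group.

    ``by`` names a column of ``mres`` (e.g. "chrom" or a site-class
    label); percent is on the 0-100 scale, one decimal.
    """
    occ = overlaps_any(mres, peaks, max_gap=max_gap) if len(peaks) else \
        pd.Series(False, index=mres.index)
    rows = []
    for group, idx in mres.groupby(by, sort=True).groups.items():
        total = len(idx)
        occupied = int(occ.loc[idx].sum())
        rows.append({by: group, "occupied": occupied, "total": total,
                     "percent": percent(occupied, total)})
    return pd.DataFrame(rows)


def ces_coverage(regions: pd.DataFrame, peaks: pd.DataFrame,
                 max_gap: int = 0) -> tuple[int, int, float]:
    """(covered count, total, percent) of regions overlapping >=1 peak."""
    total = len(regions)
    if total == 0:
        return 0, 0, 0.0
    covered = 0 if not len(peaks) else int(overlaps_any(regions, peaks, max_gap).sum())
    return covered, total, percent(covered, total)


# --------------------------------------------------------------------------
# site classes
# --------------------------------------------------------------------------

def build_site_classes(mres: pd.DataFrame, ces: pd.DataFrame, x_chrom: str,
                       aut_chrom: str, n: int = 150,
                       seed: int = 0) -> dict[str, SiteClassSet]:
    """The five MRE site classes used for occupancy heatmaps.

    mre_in_ces: every MRE overlapping a CES interval.  best_x/best_aut:
    the top-n non-CES MREs by motif score on the named chromosome (ties
    broken by ascending coordinate).  random_x/random_aut: a seeded
    uniform sample (without replacement) of n non-CES MREs.  Classes with
    fewer than n available sites are returned short with a warning.
    """
    in_ces = overlaps_any(mres, ces) if len(ces) else pd.Series(False, index=mres.index)
    rng = np.random.default_rng(seed)
    out: dict[str, SiteClassSet] = {}
    out["mre_in_ces"] = SiteClassSet("mre_in_ces", mres[in_ces].copy(), n_requested=n)

    for label, chrom in (("x", x_chrom), ("aut", aut_chrom)):
        pool = mres[(mres["chrom"] == chrom) & ~in_ces]
        if len(pool) < n:
            warnings.warn(f"only {len(pool)} non-CES MREs on {chrom} "
                          f"(requested {n})", stacklevel=2)
        best = (pool.sort_values(["score", "start"], ascending=[False, True],
                                 kind="mergesort").head(n)
                    .sort_values("start").copy())
        take = min(n, len(pool))
        ridx = rng.choice(len(pool), size=take, replace=False) if take else []
        rand = pool.iloc[np.sort(np.asarray(ridx, dtype=int))].copy()
        out[f"best_{label}"] = SiteClassSet(f"best_{label}", best, n_requested=n)
        out[f"random_{label}"] = SiteClassSet(f"random_{label}", rand,
                                              n_requested=n, seed=seed)
    return out


# --------------------------------------------------------------------------
# enrichment matrices and profiles
# --------------------------------------------------------------------------

def _bin_mean(track: CoverageTrack, cum: np.ndarray, qs: int, qe: int) -> float:
    """Mean track value over [qs, qe): length-weighted over track bins.

    ``cum`` is the precomputed integral of the piecewise-constant track at
    bin boundaries (cum[i] = sum(values[:i]) * bin_size).
    """
    if qs < 0 or qe > track.chrom_length:
        return np.nan
    tb = track.bin_size

    def integral(x: int) -> float:
        i = x // tb
        if i >= len(track.values):
            return cum[-1]
        return cum[i] + track.values[i] * (x - i * tb)

    return (integral(qe) - integral(qs)) / (qe - qs)


def site_matrix(tracks: Mapping[str, CoverageTrack],
                sites: pd.DataFrame | SiteClassSet, flank: int = 5000,
                bin_size: int = 200) -> EnrichmentMatrix:
    """Per-site binned enrichment around motif midpoints.

    Each row covers midpoint +/-flank in ``2*flank/bin_size`` bins; the
    value of a bin is the mean track value within it.  Bins extending past
    a chromosome end, and sites on chromosomes absent from the tracks, are
    NaN (missing), never zero.
    """
    class_name = None
    if isinstance(sites, SiteClassSet):
        class_name = sites.class_name
        sites = sites.sites
    if (2 * flank) % bin_size != 0:
        raise ValueError("2*flank must be a multiple of bin_size")
    n_bins = 2 * flank // bin_size
    values = np.full((len(sites), n_bins), np.nan)
    cums = {c: np.concatenate([[0.0], np.cumsum(t.values) * t.bin_size])
            for c, t in tracks.items()}
    names = []
    for r, (_, row) in enumerate(sites.iterrows()):
        names.append(str(row.get("name", r)))
        track = tracks.get(row["chrom"])
        if track is None:
            warnings.warn(f"site {names[-1]}: chromosome {row['chrom']} absent "
                          "from tracks; row is missing", stacklevel=2)
            continue
        cum = cums[row["chrom"]]
        mid = (int(row["start"]) + int(row["end"])) // 2
        for j in range(n_bins):
            qs = mid - flank + j * bin_size
            values[r, j] = _bin_mean(track, cum, qs, qs + bin_size)
    return EnrichmentMatrix(site_names=names, values=values, flank=flank,
                            bin_size=bin_size, class_name=class_name)


def average_profile(matrix: EnrichmentMatrix) -> pd.DataFrame:
    """Missing-aware column means with per-bin n (all-missing bins stay NaN)."""
    if matrix.n_sites == 0:
        raise ValueError("matrix is empty")
    finite = np.isfinite(matrix.values)
    n = finite.sum(axis=0)
    sums = np.where(finite, matrix.values, 0.0).sum(axis=0)
    mean = np.divide(sums, n, out=np.full(matrix.n_bins, np.nan), where=n > 0)
    offsets = [-matrix.flank + j * matrix.bin_size for j in range(matrix.n_bins)]
    return pd.DataFrame({"bin_start_offset": offsets, "mean": mean, "n": n})
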