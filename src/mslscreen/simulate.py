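"""Synthetic screening plates and a toy genome with known ground truth.

The screen simulator emulates a duplicate 384-well dual-luciferase RNAi
screen: per-plate multiplicative scaling, log-normal measurement noise on
both reporters, fixed positive (msl2-like, Firefly strongly suppressed) and
negative (GFP-like) control wells, spiked activator/repressor effects on
chosen amplicons, and lethality that depresses Firefly and Renilla together.

The genome simulator builds a toy genome with non-overlapping GA-rich-motif
sites (MREs) on an X chromosome and autosomes, designates a subset of X
MREs as chromatin entry sites (CES), plants binding-site peaks over MREs
with class-dependent probabilities, and draws IP reads enriched inside
peaks against a uniform input.  Every emitted file is reproducible
byte-for-byte from the seed, and a GroundTruth manifest records what was
planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as msio


class SimulationConfigError(ValueError):
    """A simulation config violates its invariants."""


class MrePlacementError(ValueError):
    """Requested MREs cannot be placed without overlap in the given lengths."""


# --------------------------------------------------------------------------
# configs and ground truth
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSimConfig:
    """Generative parameters for a duplicate dual-luciferase plate screen.

    Baseline RLU levels are arbitrary (the assay scale is instrument
    dependent); every downstream statistic is ratio- or rank-based, so only
    relative effects matter.
    """

    n_plates: int = 10
    wells_per_plate: int = 384
    n_control_pos: int = 2
    n_control_neg: int = 2
    spiked_hits: tuple[tuple[str, float], ...] = ()
    lethal_fraction: float = 0.0
    noise_cv: float = 0.15
    plate_scale_sd: float = 0.1
    pos_control_effect: float = 0.1
    baseline_firefly: float = 2000.0
    baseline_renilla: float = 1000.0
    lethal_factor_range: tuple[float, float] = (0.02, 1.0 / 3.0)
    seed: int = 0

    def validate(self) -> None:
        if self.wells_per_plate < self.n_control_pos + self.n_control_neg:
            raise SimulationConfigError("wells_per_plate must cover the control wells")
        if self.n_plates < 1 or self.n_control_pos < 1 or self.n_control_neg < 1:
            raise SimulationConfigError("need >=1 plate and >=1 control of each role")
        if not 0.0 <= self.lethal_fraction < 1.0:
            raise SimulationConfigError("lethal_fraction must be in [0, 1)")
        if self.noise_cv < 0 or self.plate_scale_sd < 0:
            raise SimulationConfigError("noise_cv and plate_scale_sd must be >= 0")
        if not 0 < self.pos_control_effect:
            raise SimulationConfigError("pos_control_effect must be > 0")
        lo, hi = self.lethal_factor_range
        if not (0 < lo < hi <= 1.0 / 3.0):
            raise SimulationConfigError("lethal_factor_range must lie in (0, 1/3]")
        known = set(screen_amplicon_ids(self))
        for amp, effect in self.spiked_hits:
            if effect <= 0:
                raise SimulationConfigError(f"effect_fold must be > 0 (amplicon {amp})")
            if amp not in known:
                raise SimulationConfigError(f"spiked amplicon {amp!r} not present in layout")


@dataclass(frozen=True)
class GenomeSimConfig:
    """Generative parameters for the toy genome.

    Defaults mirror the study's setting at reduced scale: 137 CES on the X,
    a CES occupancy probability of 0.985, and background occupancy of
    roughly 48% for non-CES X MREs and 33% for autosomal MREs.  MREs keep a
    minimum gap wider than a planted peak so ground-truth occupancy labels
    stay exact; motif scores are drawn independently of CES membership
    (sequence alone does not predict utilization).
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"X": 400_000, "2L": 400_000}
    )
    x_chrom: str = "X"
    n_mres_per_chrom: int = 500
    mre_length: int = 21
    n_ces: int = 137
    p_peak_given_ces: float = 0.985
    p_peak_given_bg: Mapping[str, float] | float = field(
        default_factory=lambda: {"X": 0.479, "2L": 0.325}
    )
    reads_per_sample: int = 200_000
    peak_read_enrichment: float = 8.0
    peak_halfwidth: int = 150
    mre_min_gap: int = 400
    ces_flank: int = 90
    score_mean: float = 8.0
    score_sd: float = 2.0
    seed: int = 0

    def bg_prob(self, chrom: str) -> float:
        if isinstance(self.p_peak_given_bg, Mapping):
            try:
                return float(self.p_peak_given_bg[chrom])
            except KeyError as exc:
                raise SimulationConfigError(f"no background peak probability for {chrom}") from exc
        return float(self.p_peak_given_bg)

    def validate(self) -> None:
        if len(self.chrom_lengths) < 2 or self.x_chrom not in self.chrom_lengths:
            raise SimulationConfigError("need the X chromosome plus >=1 autosome")
        if self.n_ces > self.n_mres_per_chrom:
            raise SimulationConfigError("n_ces cannot exceed MREs on the X")
        probs = [self.p_peak_given_ces] + [self.bg_prob(c) for c in self.chrom_lengths]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise SimulationConfigError("peak probabilities must lie in [0, 1]")
        if self.peak_read_enrichment < 1.0:
            raise SimulationConfigError("peak_read_enrichment must be >= 1")
        if self.mre_length < 1 or self.mre_min_gap < 0 or self.peak_halfwidth < 1:
            raise SimulationConfigError("invalid geometry parameters")
        for chrom, length in self.chrom_lengths.items():
            span = self.n_mres_per_chrom * (self.mre_length + self.mre_min_gap)
            if span - self.mre_min_gap > length:
                raise MrePlacementError(
                    f"cannot place {self.n_mres_per_chrom} MREs of {self.mre_length} bp "
                    f"with gap {self.mre_min_gap} on {chrom} ({length} bp)"
                )


@dataclass
class GroundTruth:
    """What the simulator planted, for downstream recovery checks."""

    true_hit_amplicons: dict[str, str] = field(default_factory=dict)
    lethal_amplicons: list[str] = field(default_factory=list)
    lethal_wells: list[list] = field(default_factory=list)  # [plate_id, replicate, well]
    ces_sites: list[list] = field(default_factory=list)      # [chrom, start, end, name]
    planted_peaks: list[list] = field(default_factory=list)  # [chrom, start, end, name]
    occupied_mres: list[str] = field(default_factory=list)
    ces_mres: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


# --------------------------------------------------------------------------
# plate layout helpers
# --------------------------------------------------------------------------

_ROWS = "ABCDEFGHIJKLMNOPQRSTUVWX"
_N_COLS = 24


def well_labels(wells_per_plate: int) -> list[str]:
    """Row-major well labels (A01..A24, B01..) for a plate of the given size."""
    n_rows = math.ceil(wells_per_plate / _N_COLS)
    if n_rows > len(_ROWS):
        raise SimulationConfigError("plate too large for row labels")
    labels = [f"{_ROWS[r]}{c + 1:02d}" for r in range(n_rows) for c in range(_N_COLS)]
    return labels[:wells_per_plate]


def plate_ids(cfg: ScreenSimConfig) -> list[str]:
    return [f"P{i + 1:03d}" for i in range(cfg.n_plates)]


def _layout(cfg: ScreenSimConfig) -> tuple[list[str], list[str], list[str]]:
    """(pos control wells, neg control wells, sample wells) for one plate.

    Positive controls occupy the first wells, negative controls the last
    (A01/A02 and P23/P24 on a standard 384-well plate).
    """
    labels = well_labels(cfg.wells_per_plate)
    pos = labels[: cfg.n_control_pos]
    neg = labels[len(labels) - cfg.n_control_neg:]
    sample = labels[cfg.n_control_pos: len(labels) - cfg.n_control_neg]
    return pos, neg, sample


def screen_amplicon_ids(cfg: ScreenSimConfig) -> list[str]:
    """Deterministic sample-well amplicon ids, plate-major then well-major."""
    _, _, sample = _layout(cfg)
    return [f"A{p + 1:03d}_{w}" for p in range(cfg.n_plates) for w in sample]


# --------------------------------------------------------------------------
# screen simulation
# --------------------------------------------------------------------------

def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_screen(cfg: ScreenSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a duplicate plate screen.

    Returns a long well table (plate CSV schema) and the GroundTruth of
    spiked and lethal amplicons.  Each amplicon occupies the same well on
    both replicate plates, as in an arrayed library screened in duplicate.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pos_wells, neg_wells, sample_wells = _layout(cfg)
    pids = plate_ids(cfg)
    effects = dict(cfg.spiked_hits)

    n_sample = len(sample_wells)
    amp_ids = screen_amplicon_ids(cfg)  # plate-major

    # lethal amplicons drawn among non-spiked sample amplicons
    lethal_mask = rng.random(len(amp_ids)) < cfg.lethal_fraction
    lethal = [a for a, m in zip(amp_ids, lethal_mask) if m and a not in effects]

    truth = GroundTruth(
        true_hit_amplicons={
            a: ("decreased" if e < 1 else "increased") for a, e in effects.items() if e != 1
        },
        lethal_amplicons=list(lethal),
    )
    lethal_set = set(lethal)

    rows: list[dict] = []
    for p, pid in enumerate(pids):
        plate_amp = amp_ids[p * n_sample: (p + 1) * n_sample]
        for rep in (1, 2):
            s_f = rng.lognormal(0.0, cfg.plate_scale_sd) if cfg.plate_scale_sd else 1.0
            s_r = rng.lognormal(0.0, cfg.plate_scale_sd) if cfg.plate_scale_sd else 1.0
            wells = pos_wells + sample_wells + neg_wells
            roles = (["pos_ctrl"] * len(pos_wells) + ["sample"] * n_sample
                     + ["neg_ctrl"] * len(neg_wells))
            amps = (["msl2_ctrl"] * len(pos_wells) + plate_amp
                    + ["gfp_ctrl"] * len(neg_wells))
            eff = np.ones(len(wells))
            eff[: len(pos_wells)] = cfg.pos_control_effect
            shared = np.ones(len(wells))
            for i, a in enumerate(plate_amp):
                j = len(pos_wells) + i
                if a in effects:
                    eff[j] = effects[a]
                if a in lethal_set:
                    shared[j] = rng.uniform(*cfg.lethal_factor_range)
                    truth.lethal_wells.append([pid, rep, sample_wells[i]])
            noise_f = _lognormal_noise(rng, cfg.noise_cv, len(wells))
            noise_r = _lognormal_noise(rng, cfg.noise_cv, len(wells))
            firefly = cfg.baseline_firefly * s_f * eff * shared * noise_f
            renilla = cfg.baseline_renilla * s_r * shared * noise_r
            for i, w in enumerate(wells):
                rows.append({
                    "plate_id": pid, "replicate": rep, "well": w,
                    "amplicon_id": amps[i], "role": roles[i],
                    "firefly": firefly[i], "renilla": renilla[i],
                })
    table = pd.DataFrame(rows, columns=msio.PLATE_COLUMNS)
    # deterministic row order: plate, replicate, plate position
    return table, truth


def simulate_screen_to_dir(cfg: ScreenSimConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wells, truth = simulate_screen(cfg)
    msio.write_plate_csv(wells, outdir / "plates.csv")
    msio.write_ground_truth(truth, outdir / "truth.json")


# --------------------------------------------------------------------------
# genome simulation
# --------------------------------------------------------------------------

@dataclass
class GenomeSimResult:
    mres: pd.DataFrame
    ces: pd.DataFrame
    peaks: pd.DataFrame
    ip_positions: pd.DataFrame
    input_positions: pd.DataFrame
    truth: GroundTruth


def _place_nonoverlapping(rng: np.random.Generator, length: int, n: int,
                          width: int, gap: int) -> np.ndarray:
    """n uniform non-overlapping starts with >=gap bp between site ends."""
    pitch = width + gap
    avail = length - n * pitch + gap
    if avail < 0:
        raise MrePlacementError(
            f"cannot place {n} sites of {width} bp (gap {gap}) in {length} bp"
        )
    u = np.sort(rng.integers(0, avail + 1, size=n))
    return u + np.arange(n) * pitch


def _scatter_in_intervals(rng: np.random.Generator, intervals: np.ndarray,
                          n: int) -> np.ndarray:
    """n uniform global positions within disjoint [start, end) intervals.

    ``intervals`` is an (m, 2) array of global (concatenated-genome)
    coordinates; returns global positions.
    """
    lengths = intervals[:, 1] - intervals[:, 0]
    cum = np.concatenate([[0], np.cumsum(lengths)])
    offs = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, offs, side="right") - 1
    return intervals[idx, 0] + (offs - cum[idx])


def simulate_genome(cfg: GenomeSimConfig) -> GenomeSimResult:
    """Simulate MREs, CES, planted peaks, and IP/input read positions."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chroms = list(cfg.chrom_lengths)

    mre_rows = []
    for chrom in chroms:
        L = int(cfg.chrom_lengths[chrom])
        starts = _place_nonoverlapping(rng, L, cfg.n_mres_per_chrom,
                                       cfg.mre_length, cfg.mre_min_gap)
        scores = rng.normal(cfg.score_mean, cfg.score_sd, size=len(starts))
        for i, (s, sc) in enumerate(zip(starts, scores)):
            mre_rows.append({
                "chrom": chrom, "start": int(s), "end": int(s) + cfg.mre_length,
                "name": f"MRE_{chrom}_{i:05d}", "score": round(float(sc), 4),
                "strand": "+",
            })
    mres = pd.DataFrame(mre_rows)

    # CES: a random subset of X MREs, flanked
    x_idx = mres.index[mres["chrom"] == cfg.x_chrom].to_numpy()
    ces_pick = np.sort(rng.choice(x_idx, size=cfg.n_ces, replace=False))
    mres["in_ces"] = False
    mres.loc[ces_pick, "in_ces"] = True
    ces_rows = []
    for j, i in enumerate(ces_pick):
        r = mres.loc[i]
        L = int(cfg.chrom_lengths[r["chrom"]])
        ces_rows.append({
            "chrom": r["chrom"],
            "start": max(0, int(r["start"]) - cfg.ces_flank),
            "end": min(L, int(r["end"]) + cfg.ces_flank),
            "name": f"CES_{j:04d}", "score": 0.0, "strand": "+",
        })
    ces = pd.DataFrame(ces_rows)

    # plant peaks over MREs with class-dependent probabilities
    p = np.where(mres["in_ces"],
                 cfg.p_peak_given_ces,
                 [cfg.bg_prob(c) for c in mres["chrom"]])
    occupied = rng.random(len(mres)) < p
    peak_rows = []
    for k, i in enumerate(mres.index[occupied]):
        r = mres.loc[i]
        mid = (int(r["start"]) + int(r["end"])) // 2
        L = int(cfg.chrom_lengths[r["chrom"]])
        peak_rows.append({
            "chrom": r["chrom"],
            "start": max(0, mid - cfg.peak_halfwidth),
            "end": min(L, mid + cfg.peak_halfwidth),
            "name": f"PEAK_{k:05d}", "score": 0.0, "strand": "+",
        })
    peaks = pd.DataFrame(peak_rows, columns=msio.BED_COLUMNS)

    # reads on the concatenated genome
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    genome_len = int(offsets[-1])
    chrom_off = dict(zip(chroms, offsets[:-1]))

    if len(peaks):
        gpeaks = np.array([
            [chrom_off[c] + s, chrom_off[c] + e]
            for c, s, e in zip(peaks["chrom"], peaks["start"], peaks["end"])
        ], dtype=np.int64)
        gpeaks = gpeaks[np.argsort(gpeaks[:, 0])]
        peak_len = int((gpeaks[:, 1] - gpeaks[:, 0]).sum())
        # complement intervals (peaks are disjoint by construction)
        bounds = np.concatenate([[0], gpeaks.ravel(), [genome_len]])
        comp = bounds.reshape(-1, 2)
        comp = comp[comp[:, 1] > comp[:, 0]]
    else:
        gpeaks = np.empty((0, 2), dtype=np.int64)
        peak_len = 0
        comp = np.array([[0, genome_len]], dtype=np.int64)

    e = cfg.peak_read_enrichment
    w_peak = (e * peak_len) / (e * peak_len + (genome_len - peak_len)) if peak_len else 0.0
    n_in = rng.binomial(cfg.reads_per_sample, w_peak)
    ip_g = np.concatenate([
        _scatter_in_intervals(rng, gpeaks, n_in) if n_in else np.empty(0, dtype=np.int64),
        _scatter_in_intervals(rng, comp, cfg.reads_per_sample - n_in),
    ])
    input_g = rng.integers(0, genome_len, size=cfg.reads_per_sample)

    def to_frame(g: np.ndarray) -> pd.DataFrame:
        g = np.sort(g)
        ci = np.searchsorted(offsets, g, side="right") - 1
        return pd.DataFrame({
            "chrom": [chroms[i] for i in ci],
            "pos": g - offsets[ci],
        })

    truth = GroundTruth(
        ces_sites=[[r["chrom"], int(r["start"]), int(r["end"]), r["name"]]
                   for _, r in ces.iterrows()],
        planted_peaks=[[r["chrom"], int(r["start"]), int(r["end"]), r["name"]]
                       for _, r in peaks.iterrows()],
        occupied_mres=list(mres.loc[occupied, "name"]),
        ces_mres=list(mres.loc[mres["in_ces"], "name"]),
    )
    return GenomeSimResult(
        mres=mres, ces=ces, peaks=peaks,
        ip_positions=to_frame(ip_g), input_positions=to_frame(input_g),
        truth=truth,
    )


def simulate_genome_to_dir(cfg: GenomeSimConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = simulate_genome(cfg)
    msio.write_bed(res.mres, outdir / "mres.bed")
    msio.write_bed(res.ces, outdir / "ces.bed")
    msio.write_bed(res.peaks, outdir / "peaks.bed")
    msio.write_positions(res.ip_positions, outdir / "ip.tsv")
    msio.write_positions(res.input_positions, outdir / "input.tsv")
    msio.write_ground_truth(res.truth, outdir / "truth.json")
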