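"""Dual-luciferase plate statistics and duplicate-concordant hit calling.

The screening statistic: every well's Firefly/Renilla ratio is compared to
the median ratio of its plate; an amplicon is a hit when its ratio deviates
by more than ``k_sd`` plate standard deviations from the plate median, in
the same direction, on both replicate plates.  Plates must show at least a
5-fold dynamic range between negative (GFP) and positive (msl2) controls,
and wells whose Renilla signal falls more than 3-fold below the plate's
Renilla median are excluded as lethality/transfection artifacts.

Plate medians and SDs are computed over sample wells only — control wells
are extreme by design and would inflate the SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

RENILLA_NONPOSITIVE = "renilla_nonpositive"


class ControlsAbsentError(ValueError):
    """controls_absent: a plate lacks usable positive or negative controls."""


class DegeneratePlateSDError(ValueError):
    """degenerate_plate_sd: plate SD is zero but deviations are nonzero."""


class PlateQCFailedError(ValueError):
    """A replicate plate failed the control dynamic-range QC."""


@dataclass
class PlateStats:
    """Per plate+replicate summary used for hit calling and QC."""

    plate_id: str
    replicate: int
    median_ratio: float
    sd_ratio: float
    renilla_median: float
    dynamic_range: float
    n_sample_wells: int
    qc_pass: bool


@dataclass
class ScreenSummary:
    n_hits: int
    n_decreased: int
    n_increased: int
    genes: pd.DataFrame  # gene_id, direction, amplicons (tuple)
    n_unannotated: int


def compute_ratios(wells: pd.DataFrame) -> pd.DataFrame:
    """Attach the Firefly/Renilla ratio to each well.

    Wells with nonpositive Renilla are flagged unusable with reason
    ``renilla_nonpositive`` (ratio NaN), never silently dropped.
    """
    if (wells["firefly"] < 0).any():
        raise ValueError("negative Firefly readout")
    out = wells.copy()
    usable = out["renilla"] > 0
    out["ratio"] = np.where(usable, out["firefly"] / out["renilla"].where(usable, 1.0), np.nan)
    out["usable"] = usable
    out["reason"] = np.where(usable, "", RENILLA_NONPOSITIVE)
    return out


def _sd(values: np.ndarray, robust: bool) -> float:
    if len(values) < 2:
        return 0.0
    if robust:
        return float(sps.median_abs_deviation(values, scale="normal"))
    return float(np.std(values, ddof=1))


def plate_qc(wells: pd.DataFrame, dynamic_range_min: float = 5.0,
             robust_sd: bool = False) -> PlateStats:
    """QC and summary statistics for one plate+replicate of wells.

    dynamic_range = mean(neg-control ratios) / mean(pos-control ratios);
    the plate passes QC iff this is at least ``dynamic_range_min`` (default
    5-fold).  Median/SD are over usable sample wells only.
    """
    if wells["plate_id"].nunique() != 1 or wells["replicate"].nunique() != 1:
        raise ValueError("plate_qc expects wells of a single plate+replicate")
    if "ratio" not in wells.columns:
        wells = compute_ratios(wells)
    wells = wells[wells["usable"]]
    pos = wells.loc[wells["role"] == "pos_ctrl", "ratio"]
    neg = wells.loc[wells["role"] == "neg_ctrl", "ratio"]
    if pos.empty or neg.empty:
        raise ControlsAbsentError("controls_absent")
    sample = wells[wells["role"] == "sample"]
    pos_mean = float(pos.mean())
    dr = float(neg.mean()) / pos_mean if pos_mean > 0 else float("inf")
    return PlateStats(
        plate_id=str(wells["plate_id"].iloc[0]),
        replicate=int(wells["replicate"].iloc[0]),
        median_ratio=float(sample["ratio"].median()),
        sd_ratio=_sd(sample["ratio"].to_numpy(), robust_sd),
        renilla_median=float(sample["renilla"].median()),
        dynamic_range=dr,
        n_sample_wells=int(len(sample)),
        qc_pass=dr >= dynamic_range_min,
    )


def call_hits_plate(rep1: pd.DataFrame, rep2: pd.DataFrame, k_sd: float = 2.0,
                    renilla_fold: float = 3.0, require_matching_sign: bool = True,
                    robust_sd: bool = False, enforce_qc: bool = True) -> pd.DataFrame:
    """Duplicate-concordant hit calls for one plate screened twice.

    Per amplicon, deviation_rX = (ratio - plate median) / plate SD on that
    replicate.  A hit must exceed ``k_sd`` strictly in magnitude on both
    replicates (same sign by default) and must not be viability-excluded:
    a well whose Renilla is more than ``renilla_fold`` below the plate's
    sample-well Renilla median on either replicate is excluded.
    """
    frames = []
    for rep_df in (rep1, rep2):
        rep_df = rep_df if "ratio" in rep_df.columns else compute_ratios(rep_df)
        st = plate_qc(rep_df, robust_sd=robust_sd)
        if enforce_qc and not st.qc_pass:
            raise PlateQCFailedError(
                f"plate {st.plate_id} rep {st.replicate}: dynamic range "
                f"{st.dynamic_range:.2f} < 5")
        s = rep_df[rep_df["role"] == "sample"].copy()
        if st.sd_ratio == 0:
            dev = s["ratio"] - st.median_ratio
            if (dev.dropna() != 0).any():
                raise DegeneratePlateSDError("degenerate_plate_sd")
            s["deviation"] = np.where(s["ratio"].isna(), np.nan, 0.0)
        else:
            s["deviation"] = (s["ratio"] - st.median_ratio) / st.sd_ratio
        s["renilla_low"] = s["renilla"] < st.renilla_median / renilla_fold
        frames.append(s[["amplicon_id", "plate_id", "deviation", "renilla_low", "usable"]])

    m = frames[0].merge(frames[1], on="amplicon_id", how="outer",
                        suffixes=("_r1", "_r2"), indicator=True)
    m["unpaired"] = m["_merge"] != "both"
    m["plate_id"] = m["plate_id_r1"].fillna(m["plate_id_r2"])
    m["viability_excluded"] = m["renilla_low_r1"].eq(True) | m["renilla_low_r2"].eq(True)
    d1, d2 = m["deviation_r1"], m["deviation_r2"]
    exceeds = (d1.abs() > k_sd) & (d2.abs() > k_sd)
    same_sign = np.sign(d1) == np.sign(d2)
    concordant = exceeds & (same_sign if require_matching_sign else True)
    usable_both = m["usable_r1"].eq(True) & m["usable_r2"].eq(True)
    m["direction"] = np.select(
        [exceeds & same_sign & (d1 < 0), exceeds & same_sign & (d1 > 0)],
        ["decreased", "increased"], default="none")
    m["is_hit"] = (concordant.fillna(False) & ~m["viability_excluded"]
                   & ~m["unpaired"] & usable_both)
    cols = ["amplicon_id", "plate_id", "deviation_r1", "deviation_r2",
            "direction", "viability_excluded", "unpaired", "is_hit"]
    return m[cols].reset_index(drop=True)


def call_hits(wells: pd.DataFrame, k_sd: float = 2.0, renilla_fold: float = 3.0,
              require_matching_sign: bool = True, robust_sd: bool = False,
              enforce_qc: bool = True) -> pd.DataFrame:
    """Hit calls for a whole screen table containing both replicates."""
    wells = wells if "ratio" in wells.columns else compute_ratios(wells)
    out = []
    for pid, grp in wells.groupby("plate_id", sort=True):
        reps = {r: g for r, g in grp.groupby("replicate")}
        if set(reps) != {1, 2}:
            raise ValueError(f"plate {pid}: expected replicates 1 and 2")
        out.append(call_hits_plate(reps[1], reps[2], k_sd=k_sd,
                                   renilla_fold=renilla_fold,
                                   require_matching_sign=require_matching_sign,
                                   robust_sd=robust_sd, enforce_qc=enforce_qc))
    return pd.concat(out, ignore_index=True)


def screen_qc(wells: pd.DataFrame, robust_sd: bool = False) -> pd.DataFrame:
    """PlateStats for every plate+replicate, as a table."""
    wells = wells if "ratio" in wells.columns else compute_ratios(wells)
    rows = [plate_qc(g, robust_sd=robust_sd)
            for _, g in wells.groupby(["plate_id", "replicate"], sort=True)]
    return pd.DataFrame([vars(s) for s in rows])


def summarize_screen(hits: pd.DataFrame,
                     amplicon_gene_map: Mapping[str, str] | pd.DataFrame) -> ScreenSummary:
    """Directional hit counts and a gene-level roll-up of supporting amplicons."""
    if isinstance(amplicon_gene_map, pd.DataFrame):
        amplicon_gene_map = dict(zip(amplicon_gene_map["amplicon_id"],
                                     amplicon_gene_map["gene_id"]))
    called = hits.loc[hits["is_hit"].astype(bool)]
    n_dec = int((called["direction"] == "decreased").sum())
    n_inc = int((called["direction"] == "increased").sum())
    gene_rows: dict[tuple[str, str], list[str]] = {}
    n_unannotated = 0
    for _, row in called.iterrows():
        gene = amplicon_gene_map.get(row["amplicon_id"])
        if gene is None:
            n_unannotated += 1
            warnings.warn(f"amplicon {row['amplicon_id']} has no gene mapping; "
                          "counted as unannotated", stacklevel=2)
            gene = "unannotated"
        gene_rows.setdefault((gene, row["direction"]), []).append(row["amplicon_id"])
    genes = pd.DataFrame(
        [{"gene_id": g, "direction": d, "amplicons": tuple(sorted(a))}
         for (g, d), a in sorted(gene_rows.items())],
        columns=["gene_id", "direction", "amplicons"])
    return ScreenSummary(n_hits=len(called), n_decreased=n_dec, n_increased=n_inc,
                         genes=genes, n_unannotated=n_unannotated)


def null_hit_rate_bound(k_sd: float = 2.0, require_matching_sign: bool = False) -> float:
    """Analytic two-replicate tail bound on the null hit rate.

    With independent Gaussian deviations, P(|z| > k on both replicates) =
    (2*Phi_bar(k))^2; requiring matching signs halves it.
    """
    tail = 2.0 * sps.norm.sf(k_sd)
    p = tail * tail
    return p / 2.0 if require_matching_sign else p
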