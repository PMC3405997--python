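"""PWM scanning, site classes, occupancy fractions, enrichment matrices."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_intervals
from mslscreen import chip, occupancy as occ
from mslscreen._util import percent
from oracles import brute_force_column_means, brute_force_overlaps


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n, p=[0.3, 0.2, 0.3, 0.2]))


def pwm_score(pwm, window):
    return sum(pwm.iloc[j][b] for j, b in enumerate(window))


@pytest.fixture(scope="module")
def pwm():
    return occ.garich_pwm(21)


class TestScan:
    def test_planted_consensus_recovered(self, pwm):
        rng = np.random.default_rng(0)
        consensus = occ.pwm_consensus(pwm)
        seq = random_seq(rng, 500) + consensus + random_seq(rng, 500)
        max_score = pwm.max(axis=1).sum()
        sites = occ.scan_mres({"chr1": seq}, pwm, threshold=max_score - 1e-9)
        fwd = sites[sites["strand"] == "+"]
        assert len(fwd) == 1
        assert int(fwd["start"].iloc[0]) == 500
        assert int(fwd["end"].iloc[0]) == 521

    def test_threshold_above_max_empty(self, pwm):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 2000)
        sites = occ.scan_mres({"chr1": seq}, pwm,
                              threshold=pwm.max(axis=1).sum() + 1.0)
        assert sites.empty

    def test_n_windows_skipped(self, pwm):
        consensus = occ.pwm_consensus(pwm)
        seq = "N" * 30 + consensus + "N" * 30
        sites = occ.scan_mres({"chr1": seq}, pwm, threshold=0.0)
        assert (sites["start"] >= 30).all() and (sites["end"] <= 51).all()

    def test_width_mismatch_named_error(self, pwm):
        with pytest.raises(occ.PwmWidthError):
            occ.scan_mres({"c": "ACGT" * 30}, pwm, threshold=0, motif_length=15)

    def test_exhaustive_window_oracle(self, pwm):
        """Permissive threshold on random sequence: the site set equals
        brute-force scoring of every window on both strands."""
        rng = np.random.default_rng(2)
        seq = random_seq(rng, 3000)
        thr = 5.0
        sites = occ.scan_mres({"chr1": seq}, pwm, threshold=thr)
        got = {(int(r["start"]), r["strand"]): r["score"]
               for _, r in sites.iterrows()}
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        expected = {}
        for i in range(len(seq) - 20):
            win = seq[i:i + 21]
            s = pwm_score(pwm, win)
            if s >= thr:
                expected[(i, "+")] = s
            rc = "".join(comp[b] for b in reversed(win))
            s = pwm_score(pwm, rc)
            if s >= thr:
                expected[(i, "-")] = s
        assert set(got) == set(expected)
        for k in got:
            assert got[k] == pytest.approx(expected[k])

    def test_agrees_with_biopython_pssm(self, pwm):
        """Independent route: Biopython's PSSM scoring gives the same
        forward-strand scores."""
        from Bio.Seq import Seq
        from Bio.motifs.matrix import PositionSpecificScoringMatrix

        rng = np.random.default_rng(3)
        seq = random_seq(rng, 1000)
        fwd, _ = occ.pwm_scores(seq, pwm)
        pssm = PositionSpecificScoringMatrix(
            "ACGT", {b: list(pwm[b]) for b in "ACGT"})
        ref = np.asarray(pssm.calculate(Seq(seq)), dtype=float)
        assert np.allclose(fwd, ref, atol=1e-3)

    def test_dedupe_keeps_best_strand(self, pwm):
        consensus = occ.pwm_consensus(pwm)
        seq = "TTTT" + consensus + "TTTT"
        both = occ.scan_mres({"c": seq}, pwm, threshold=-100.0)
        dd = occ.scan_mres({"c": seq}, pwm, threshold=-100.0,
                           dedupe_positions=True)
        assert len(dd) < len(both)
        assert not dd.duplicated(["chrom", "start"]).any()


class TestOverlap:
    def test_half_open_boundary(self):
        mre = pd.DataFrame({"chrom": ["X", "X"], "start": [100, 100],
                            "end": [121, 121], "name": ["m1", "m2"]})
        touching = pd.DataFrame({"chrom": ["X"], "start": [120], "end": [200]})
        disjoint = pd.DataFrame({"chrom": ["X"], "start": [121], "end": [200]})
        assert occ.overlaps_any(mre, touching).all()
        assert not occ.overlaps_any(mre, disjoint).any()

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            q = random_intervals(rng, rng.integers(1, 60))
            s = random_intervals(rng, rng.integers(1, 60))
            got = occ.overlaps_any(q, s).tolist()
            exp = brute_force_overlaps(
                list(zip(q["chrom"], q["start"], q["end"])),
                list(zip(s["chrom"], s["start"], s["end"])))
            assert got == exp

    def test_occupancy_fraction_by_chrom(self):
        mres = pd.DataFrame({"chrom": ["X"] * 4 + ["2L"] * 2,
                             "start": [0, 100, 200, 300, 0, 100],
                             "end": [21, 121, 221, 321, 21, 121]})
        peaks = pd.DataFrame({"chrom": ["X", "X", "2L"],
                              "start": [10, 210, 500], "end": [30, 230, 600]})
        out = occ.occupancy_fraction(mres, peaks, by="chrom").set_index("chrom")
        assert out.loc["X", "occupied"] == 2 and out.loc["X", "total"] == 4
        assert out.loc["X", "percent"] == 50.0
        assert out.loc["2L", "percent"] == 0.0

    def test_empty_peaks_all_zero(self):
        mres = pd.DataFrame({"chrom": ["X"], "start": [0], "end": [21]})
        out = occ.occupancy_fraction(mres, mres.iloc[:0], by="chrom")
        assert (out["percent"] == 0).all()

    def test_adding_peaks_monotone(self):
        rng = np.random.default_rng(5)
        mres = random_intervals(rng, 200)
        peaks = random_intervals(rng, 50)
        more = pd.concat([peaks, random_intervals(rng, 50)], ignore_index=True)
        a = occ.occupancy_fraction(mres, peaks).set_index("chrom")["percent"]
        b = occ.occupancy_fraction(mres, more).set_index("chrom")["percent"]
        assert (b >= a).all()

    def test_ces_coverage_counts(self):
        regions = pd.DataFrame({"chrom": ["X"] * 7,
                                "start": [i * 1000 for i in range(7)],
                                "end": [i * 1000 + 200 for i in range(7)]})
        peaks = pd.DataFrame({"chrom": ["X"] * 4,
                              "start": [0, 1000, 2000, 3100],
                              "end": [50, 1100, 2100, 3150]})
        covered, total, pct = occ.ces_coverage(regions, peaks)
        assert (covered, total) == (4, 7)
        assert pct == percent(4, 7) == 57.1

    def test_max_gap_relaxes_rule(self):
        mre = pd.DataFrame({"chrom": ["X"], "start": [100], "end": [121]})
        peak = pd.DataFrame({"chrom": ["X"], "start": [150], "end": [200]})
        assert not occ.overlaps_any(mre, peak).any()
        assert occ.overlaps_any(mre, peak, max_gap=40).any()


class TestSiteClasses:
    def test_sizes_and_disjointness(self, toy_genome):
        _, res = toy_genome
        classes = occ.build_site_classes(res.mres, res.ces, "X", "2L",
                                         n=150, seed=0)
        in_ces = set(classes["mre_in_ces"].sites["name"])
        assert in_ces == set(res.truth.ces_mres)
        for name in ("best_x", "random_x", "best_aut", "random_aut"):
            sites = classes[name].sites
            assert len(sites) == 150
            assert in_ces.isdisjoint(set(sites["name"]))
        assert (classes["best_x"].sites["chrom"] == "X").all()
        assert (classes["best_aut"].sites["chrom"] == "2L").all()

    def test_best_class_is_top_scoring(self, toy_genome):
        _, res = toy_genome
        classes = occ.build_site_classes(res.mres, res.ces, "X", "2L", n=150, seed=0)
        pool = res.mres[(res.mres["chrom"] == "X") & ~res.mres["in_ces"]]
        cutoff = pool["score"].sort_values(ascending=False).iloc[149]
        assert classes["best_x"].sites["score"].min() >= cutoff

    def test_random_class_seeded(self, toy_genome):
        _, res = toy_genome
        a = occ.build_site_classes(res.mres, res.ces, "X", "2L", n=150, seed=1)
        b = occ.build_site_classes(res.mres, res.ces, "X", "2L", n=150, seed=1)
        c = occ.build_site_classes(res.mres, res.ces, "X", "2L", n=150, seed=2)
        assert a["random_x"].sites["name"].tolist() == b["random_x"].sites["name"].tolist()
        assert a["random_x"].sites["name"].tolist() != c["random_x"].sites["name"].tolist()

    def test_degenerate_all_in_ces_warns(self):
        mres = pd.DataFrame({"chrom": ["X"] * 3, "start": [0, 1000, 2000],
                             "end": [21, 1021, 2021],
                             "name": ["a", "b", "c"], "score": [1.0, 2.0, 3.0]})
        ces = pd.DataFrame({"chrom": ["X"], "start": [0], "end": [3000]})
        with pytest.warns(UserWarning, match="non-CES"):
            classes = occ.build_site_classes(mres, ces, "X", "2L", n=150, seed=0)
        assert classes["best_x"].sites.empty
        assert len(classes["mre_in_ces"].sites) == 3


def _uniform_track(chrom, length, value, bin_size=200):
    n = -(-length // bin_size)
    return chip.CoverageTrack(chrom=chrom, chrom_length=length, bin_size=bin_size,
                              values=np.full(n, float(value)),
                              ip_library_size=1, input_library_size=1)


class TestSiteMatrix:
    def test_uniform_track_constant_matrix(self):
        tracks = {"X": _uniform_track("X", 100_000, 1.5)}
        sites = pd.DataFrame({"chrom": ["X"] * 3, "start": [20_000, 50_000, 70_000],
                              "end": [20_021, 50_021, 70_021],
                              "name": ["a", "b", "c"]})
        mat = occ.site_matrix(tracks, sites)
        assert mat.values.shape == (3, 50)
        assert np.allclose(mat.values, 1.5)

    def test_dimensions_regardless_of_missing(self):
        tracks = {"X": _uniform_track("X", 20_000, 1.0)}
        sites = pd.DataFrame({"chrom": ["X", "X", "chrUn"],
                              "start": [100, 10_000, 5_000],
                              "end": [121, 10_021, 5_021],
                              "name": ["edge", "mid", "lost"]})
        with pytest.warns(UserWarning, match="absent"):
            mat = occ.site_matrix(tracks, sites)
        assert mat.values.shape == (3, 50)
        assert np.isnan(mat.values[0, 0])          # bin beyond chromosome start
        assert np.isfinite(mat.values[1]).all()
        assert np.isnan(mat.values[2]).all()       # unknown chromosome row

    def test_chromosome_end_bins_missing_not_zero(self):
        tracks = {"X": _uniform_track("X", 12_000, 2.0)}
        sites = pd.DataFrame({"chrom": ["X"], "start": [1000], "end": [1021],
                              "name": ["s"]})
        mat = occ.site_matrix(tracks, sites)
        # midpoint 1010: bins below offset -1010 extend past the start
        n_missing = int(np.isnan(mat.values[0]).sum())
        assert n_missing == (5000 - 1010 + 199) // 200
        assert not (mat.values[0] == 0).any()

    def test_weighted_binning_against_track(self):
        """Matrix bins aligned with track bins reproduce track values."""
        vals = np.arange(100, dtype=float)
        track = chip.CoverageTrack("X", 20_000, 200, vals, 1, 1)
        sites = pd.DataFrame({"chrom": ["X"], "start": [9990], "end": [10011],
                              "name": ["s"]})  # midpoint 10000, bin-aligned
        mat = occ.site_matrix({"X": track}, sites)
        assert np.allclose(mat.values[0], vals[25:75])

    def test_average_profile_matches_oracle(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(20, 50))
        values[rng.random(values.shape) < 0.1] = np.nan
        values[:, 7] = np.nan
        mat = occ.EnrichmentMatrix(site_names=[str(i) for i in range(20)],
                                   values=values, flank=5000, bin_size=200)
        prof = occ.average_profile(mat)
        exp = brute_force_column_means(
            [[None if np.isnan(v) else v for v in row] for row in values])
        for got, want in zip(prof["mean"], exp):
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want)
        assert prof.loc[7, "n"] == 0

    def test_simple_profile(self):
        mat = occ.EnrichmentMatrix(site_names=["a", "b"],
                                   values=np.array([[1.0, 3.0], [3.0, 5.0]]),
                                   flank=200, bin_size=200)
        prof = occ.average_profile(mat)
        assert prof["mean"].tolist() == [2.0, 4.0]

    def test_ces_class_enriched_over_background(self, toy_genome):
        """With CES occupancy ~1 and weak background, the central-bin mean of
        the CES class exceeds the random-autosome class."""
        cfg, res = toy_genome
        tracks = chip.binned_log2_track(res.ip_positions, res.input_positions,
                                        dict(cfg.chrom_lengths))
        classes = occ.build_site_classes(res.mres, res.ces, "X", "2L",
                                         n=150, seed=0)
        center = slice(24, 26)
        ces_mat = occ.site_matrix(tracks, classes["mre_in_ces"])
        aut_mat = occ.site_matrix(tracks, classes["random_aut"])
        assert np.nanmean(ces_mat.values[:, center]) > \
            np.nanmean(aut_mat.values[:, center]) + 0.5
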