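"""Toy genome: occupancy fractions, site classes, and enrichment profiles.

Simulates a genome where CES-resident MREs are almost always covered by a
binding-site peak (p=0.985) while background MREs are covered at ~48% (X)
and ~33% (autosome), builds the binned log2(IP/input) track from simulated
reads, and compares the five MRE site classes used for occupancy heatmaps.
"""

import numpy as np

from mslscreen import chip, occupancy as occ
from mslscreen.simulate import GenomeSimConfig, simulate_genome

cfg = GenomeSimConfig(n_mres_per_chrom=300, reads_per_sample=50_000, seed=4)
res = simulate_genome(cfg)

frac = occ.occupancy_fraction(res.mres, res.peaks, by="chrom")
print("MRE occupancy by chromosome (percent of MREs overlapping >=1 peak):")
print(frac.to_string(index=False))

covered, total, pct = occ.ces_coverage(res.ces, res.peaks)
print(f"\nCES covered by a peak: {covered}/{total} = {pct}%")

tracks = chip.binned_log2_track(res.ip_positions, res.input_positions,
                                dict(cfg.chrom_lengths), bin_size=200)
classes = occ.build_site_classes(res.mres, res.ces, x_chrom="X",
                                 aut_chrom="2L", n=150, seed=0)

print("\ncentral-bin mean log2(IP/input) per site class (midpoint +/-5 kb,")
print("200-bp bins; column 25/26 of 50 are the two bins over the motif):")
for name, cs in classes.items():
    mat = occ.site_matrix(tracks, cs, flank=5000, bin_size=200)
    center = float(np.nanmean(mat.values[:, 24:26]))
    print(f"  {name:12s} n={mat.n_sites:3d}  central mean = {center:+.2f}")

print("\nCES-resident MREs show strong central enrichment while equally good")
print("(best) or random background motifs do not: motif quality alone does")
print("not predict which sites are utilized.")
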