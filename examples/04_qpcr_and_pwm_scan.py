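"""qPCR fold enrichment and PWM motif scanning on a toy sequence.

ChIP-qPCR quantities are normalized to input DNA and to a non-transcribed
control locus; an H4K16ac enrichment is further normalized to histone H3
occupancy.  A GA-rich PWM then recovers a planted motif from random
sequence.
"""

import numpy as np
import pandas as pd

from mslscreen import chip, occupancy as occ

# -- qPCR: (IP/input at target) / (IP/input at control locus) --------------
quants = pd.DataFrame([
    ("ces5c2", "ip", "MSL2", 12.0), ("ces5c2", "input", "MSL2", 3.0),
    ("CG15570", "ip", "MSL2", 5.0), ("CG15570", "input", "MSL2", 5.0),
], columns=["locus_id", "sample", "antibody", "quantity"])
enr = chip.qpcr_enrichment_table(quants, control_locus="CG15570")
print("MSL2 ChIP-qPCR enrichment over the non-transcribed control locus:")
print(enr.to_string(index=False))

h4 = chip.h3_normalized_enrichment(h4k16_fold=6.0, h3_fold=2.0)
print(f"\nH4K16ac fold 6.0 over H3 occupancy fold 2.0 -> {h4:.1f} "
      "(nucleosome-density corrected)")

# -- PWM scan: recover a planted GA-rich 21-mer ----------------------------
rng = np.random.default_rng(0)
pwm = occ.garich_pwm(21)
consensus = occ.pwm_consensus(pwm)
seq = ("".join(rng.choice(list("ACGT"), size=800)) + consensus
       + "".join(rng.choice(list("ACGT"), size=800)))
sites = occ.scan_mres({"chrX": seq}, pwm, threshold=pwm.max(axis=1).sum() - 5)
print(f"\nplanted consensus {consensus} at position 800; scan found:")
print(sites.to_string(index=False))
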