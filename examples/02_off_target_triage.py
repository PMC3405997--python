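"""Triage screen candidates: off-target prediction, filters, classification.

Builds a toy transcriptome, predicts dsRNA off-targets by exact 17-mer
sharing, removes ribosomal/ambiguous/off-target candidates, validates the
rest across three reporter configurations and two reagents per gene, and
assigns functional classes.
"""

import numpy as np
import pandas as pd

from mslscreen import triage as tr

rng = np.random.default_rng(7)
bases = np.array(list("ACGT"))


def seq(n):
    return "".join(rng.choice(bases, size=n))


genes = [f"G{i}" for i in range(6)]
transcriptome = {g: seq(600) for g in genes}
# G5's transcript shares a 20-nt stretch with G1's reagent -> off-target
amps = {}
for g in genes:
    for tag in ("a", "b"):
        amps[f"{g}_{tag}"] = tr.Amplicon(f"{g}_{tag}", target_genes=(g,),
                                         dsrna_sequence=transcriptome[g][100:350])
transcriptome["G5"] += transcriptome["G1"][150:170]
amps = dict(zip(amps, tr.annotate_off_targets(amps.values(), transcriptome)))

for name in ("G1_a", "G1_b"):
    print(f"{name}: predicted off-targets = {amps[name].off_target_genes}")

ann = {
    "G0": tr.GeneAnnotation("G0", is_ribosomal=True),
    "G1": tr.GeneAnnotation("G1", functional_role="general_transcription"),
    "G2": tr.GeneAnnotation("G2", has_sequence_specific_dna_binding=True),
    "G3": tr.GeneAnnotation("G3", functional_role="rna_metabolism"),
    "G4": tr.GeneAnnotation("G4"),
    "G5": tr.GeneAnnotation("G5", is_msl_core=True),
}
records = [tr.CandidateRecord(g, "activator", supporting_amplicons=(f"{g}_a", f"{g}_b"))
           for g in genes]
hits = pd.DataFrame([(f"{g}_{t}", g, "decreased")
                     for g in genes for t in ("a", "b")],
                    columns=["amplicon_id", "gene_id", "direction"])
reporter_hits = {rep: hits for rep in tr.REPORTERS}

out = tr.triage(records, ann, amps, reporter_hits)
print("\n" + tr.triage_table(out).to_string(index=False))
print("\nClass 1 = general transcriptional activator, 2 = DNA-binding activator,")
print("5 = RNA metabolism, 6 = unstudied/other; ribosomal and off-target-")
print("contaminated candidates are filtered before classification.")
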