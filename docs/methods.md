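# Methods notes

## Screening statistic

The screen assumes an arrayed dsRNA library in 384-well plates, assayed in
duplicate, with a dual-luciferase readout: an MSL-dependent Firefly
reporter and an MSL-independent Renilla reporter whose ratio cancels
transfection efficiency and bulk viability effects. The per-plate statistic
is deliberately simple — median and (n−1) sample standard deviation of the
sample-well ratios — because plate-to-plate scale differences are removed
by working in plate-relative units.

Decisions where the procedure was genuinely open:

* **Controls are excluded from plate statistics.** Positive controls are
  suppressed ~10-fold by design; including them would inflate the SD and
  mask hits. Only sample wells enter the median/SD and the Renilla median.
* **Duplicate concordance requires matching sign** (a knockdown cannot be
  both activator and repressor). `require_matching_sign=False` restores
  the magnitude-only rule.
* **Strict inequality** at the 2-SD boundary.
* **Robust option.** `robust_sd=True` swaps the SD for a normal-scaled
  MAD. On a mostly-constant plate the MAD can be zero while deviations are
  nonzero; this raises a named `degenerate_plate_sd` error rather than
  producing infinities.
* The **Renilla viability reference** is the median Renilla of the plate's
  sample wells; a well more than 3-fold below it on either replicate is
  excluded. Wells with nonpositive Renilla are flagged
  (`renilla_nonpositive`), excluded from plate statistics, and can never
  be hits.

The analytic null bound used in the specificity check is
P(hit | null) ≤ (2·Φ̄(k))² for |z| > k on two independent replicates; the
matching-sign rule halves this, so the bound is conservative.

## Triage

Off-target prediction is exact k-mer identity (k = 17 by default, the
arrayed-library convention), strand-aware via reverse complement, with no
mismatch tolerance. `max_off_targets` defaults to 1: any predicted
off-target disqualifies a reagent, but a gene survives while one clean
reagent supports it. Filter precedence is fixed
(ambiguous_amplicon > ribosomal > off_target) so the reported removal
reason is reproducible. Validation requires the gene to be a formal hit —
not merely a concordant trend — in all three reporter configurations, with
at least two distinct reagents; this is the stricter of the two plausible
readings and errs toward specificity. RNA-metabolism annotation takes
precedence over direction-based classes; a contradictory annotation
(general transcription + sequence-specific DNA binding) classifies by DNA
binding with a warning.

## ChIP enrichment

qPCR enrichment is (IP/input at target)/(IP/input at control locus); H4K16ac
values may additionally be divided by H3 fold occupancy to correct for
nucleosome density. Coverage tracks place each read at its 5′ position
(no fragment extension — fragment-model estimation is out of scope and a
documented limitation), count per half-open 200-bp bin, add a pseudocount
(default 1) *before* dividing by library size, and report log2(IP/input).
With pseudocount 0 the track is exactly invariant under uniform
duplication of either library; with a positive pseudocount the invariance
is asymptotic in coverage. The final partial bin of each chromosome is
kept at its true width.

## Motif occupancy

PWM scanning computes float64 log-odds sums for every window on both
strands; windows containing non-ACGT characters are skipped. This scanner
is cross-checked in the tests against Biopython's PSSM scoring on random
sequence. "Best" site classes are the top-n scores with coordinate
tie-break; "random" classes are seeded draws without replacement; both
exclude CES-overlapping MREs (only — MREs bound elsewhere are not
excluded; a caller can pre-filter if the stricter definition is wanted).
MRE profiles are not strand-flipped: sites are treated as unoriented, and
the ±5 kb window is symmetric. Occupancy is ≥1 bp overlap between
half-open intervals (a `max_gap` option supports proximity rules but
defaults to 0). Matrix bins extending past a chromosome end are missing
(NaN), never zero, and are dropped from column means; matrix dimensions
are always |sites| × 2·flank/bin.

Percentages are reported on the 0–100 scale at one decimal, which is the
precision at which occupancy fractions are quoted throughout.

## Synthetic data

The screen generator models luminescence as multiplicative log-normal —
positive, right-skewed — noise (mean-one, CV parameterized) on a baseline
of 2000 RLU Firefly / 1000 RLU Renilla. The absolute scale is arbitrary
(instrument units) and nothing downstream depends on it. Per plate and
replicate, independent log-normal scale factors multiply Firefly and
Renilla, so ratios are comparable only within a plate, as in the real
assay. Controls sit at fixed wells (first wells positive = msl2-like with
Firefly suppressed 10-fold, last wells negative = GFP-like), giving an
expected dynamic range of 10, comfortably above the 5-fold QC bar.
Lethality multiplies *both* reporters of a well by a shared factor drawn
uniformly from (0.02, 1/3) — cell death dims everything — which is
exactly the artifact class the Renilla filter removes.

The genome generator places MREs (21 bp) uniformly at random subject to a
minimum gap (default 400 bp, wider than a planted 300-bp peak) so a peak
planted on one MRE can never graze a neighbour and ground-truth occupancy
labels stay exact. A random subset of X-chromosome MREs (default 137)
becomes CES; motif scores are drawn independently of CES membership, so
CES MREs are not systematically the best-scoring — sequence alone does not
predict utilization. Peaks are planted with probability 0.985 over CES
MREs and ~0.48 / ~0.33 over background X / autosomal MREs; IP reads fall
inside peaks with density elevated by `peak_read_enrichment` (default
8-fold) and input reads are uniform. Defaults are a scaled-down genome
(2 × 400 kb, a few hundred MREs per chromosome); consequently aggregate
per-chromosome fractions differ from a full-genome setting where CES are a
small minority of X MREs — the generator preserves the class-level
*ordering* and the CES coverage probability, which is what the recovery
tests measure.

What the simulators do **not** emulate: sequencing error, mappability,
fragment-length effects, realistic transcript sequences, spatial plate
artifacts (edge effects), or correlated noise between replicates. Passing
recovery tests therefore demonstrate correctness of the statistics under
the stated generative model, not robustness to those real-data artifacts.

## Problem sizes

The test suite and acceptance script run the screen recovery on 10-plate
duplicate screens over 20 (tests) or 5 (script) seeds, genome recovery on
20–50 toy genomes, and oracle comparisons on instances of ≤10³ elements ×
100 random trials — sizes chosen to make the statistical assertions stable
while keeping a full run in the order of seconds to a few minutes on one
core.

## Interfaces

The package is primarily a Python library (`examples/` shows each
capability end-to-end). The shell-shaped steps — simulation, hit calling,
track building, qPCR enrichment, occupancy fractions and matrices — also
have a thin `mslscreen` CLI. The triage cascade is intentionally
API-only: it consumes structured objects (annotations, reagents,
multi-reporter hit tables) that do not map cleanly onto flags.
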