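"""Post-screen candidate triage and functional classification.

After hit calling, candidate genes are filtered (ribosomal genes, dsRNA
reagents with predicted off-targets, amplicons without a unique target),
validated across independent reagents and three reporter configurations,
and assigned to functional classes 1-6 (or flagged as core MSL-complex
components).

Off-target prediction follows the exact-overlap convention of arrayed
dsRNA libraries: a gene is a predicted off-target of a reagent when its
transcript shares at least one exact k-mer (default k = 17 nt) with the
dsRNA sequence on either strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd
from Bio.Seq import Seq

REPORTERS = ("original", "alt_promoter", "alt_ces")
FILTER_REASONS = ("ribosomal", "off_target", "ambiguous_amplicon", "unvalidated", "unannotated")


class NoSequenceError(ValueError):
    """no_sequence: the amplicon carries no dsRNA sequence."""


class ReporterTableMissingError(KeyError):
    """reporter_table_missing: a required per-reporter hit table is absent."""


@dataclass(frozen=True)
class Amplicon:
    """A dsRNA reagent: its declared targets and (optionally) its sequence."""

    amplicon_id: str
    target_genes: tuple[str, ...] = ()
    dsrna_sequence: str | None = None
    off_target_genes: tuple[str, ...] = ()

    @property
    def is_ambiguous(self) -> bool:
        """True when the reagent has no unique declared target gene."""
        return len(self.target_genes) != 1


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    is_ribosomal: bool = False
    functional_role: str = "unknown_or_other"  # general_transcription | rna_metabolism | unknown_or_other
    has_sequence_specific_dna_binding: bool = False
    is_msl_core: bool = False

    def __post_init__(self):
        allowed = {"general_transcription", "rna_metabolism", "unknown_or_other"}
        if self.functional_role not in allowed:
            raise ValueError(f"functional_role must be one of {sorted(allowed)}")


@dataclass
class CandidateRecord:
    """One screened gene moving through the triage cascade."""

    gene_id: str
    direction: str  # activator (RNAi decreased reporter) | repressor
    supporting_amplicons: tuple[str, ...] = ()
    reporters_regulated: frozenset[str] = frozenset()
    assigned_class: int | str | None = None
    filter_reason: str | None = None


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def predict_off_targets(amplicon: Amplicon, transcriptome: Mapping[str, str],
                        k: int = 17) -> list[str]:
    """Genes sharing an exact k-mer with the dsRNA (either strand).

    Declared target genes are excluded.  Matching is exact identity over
    {A,C,G,T,N} after uppercasing; k defaults to the 17-nt overlap cutoff.
    """
    if amplicon.dsrna_sequence is None:
        raise NoSequenceError("no_sequence")
    if k < 1:
        raise ValueError("k must be >= 1")
    ds = amplicon.dsrna_sequence.upper()
    query = _kmers(ds, k) | _kmers(str(Seq(ds).reverse_complement()), k)
    hits = []
    for gene, seq in transcriptome.items():
        if gene in amplicon.target_genes:
            continue
        seq = seq.upper()
        if any(seq[i:i + k] in query for i in range(len(seq) - k + 1)):
            hits.append(gene)
    return sorted(hits)


def annotate_off_targets(amplicons: Iterable[Amplicon],
                         transcriptome: Mapping[str, str], k: int = 17) -> list[Amplicon]:
    """predict_off_targets for every amplicon that carries a sequence."""
    out = []
    for a in amplicons:
        if a.dsrna_sequence is None:
            out.append(a)
        else:
            out.append(replace(a, off_target_genes=tuple(predict_off_targets(a, transcriptome, k))))
    return out


def apply_filters(candidates: Iterable[CandidateRecord],
                  annotations: Mapping[str, GeneAnnotation],
                  amplicons: Mapping[str, Amplicon],
                  max_off_targets: int = 1) -> list[CandidateRecord]:
    """The removal cascade: ambiguous amplicons, ribosomal genes, off-targets.

    Each removed candidate carries exactly one primary reason with fixed
    precedence ambiguous_amplicon > ribosomal > off_target.  An amplicon is
    off-target-flagged when it has >= ``max_off_targets`` predicted
    off-targets (default 1: any predicted off-target flags the reagent); a
    gene survives the off-target filter as long as one clean reagent
    supports it.
    """
    out = []
    for rec in candidates:
        amps = [amplicons[a] for a in rec.supporting_amplicons]
        ann = annotations.get(rec.gene_id)
        reason = None
        if not amps or all(a.is_ambiguous for a in amps):
            reason = "ambiguous_amplicon"
        elif ann is None:
            warnings.warn(f"gene {rec.gene_id} has no annotation row; filtered",
                          stacklevel=2)
            reason = "unannotated"
        elif ann.is_ribosomal:
            reason = "ribosomal"
        elif not any(not a.is_ambiguous and len(a.off_target_genes) < max_off_targets
                     for a in amps):
            reason = "off_target"
        out.append(replace_record(rec, filter_reason=reason))
    return out


def replace_record(rec: CandidateRecord, **kw) -> CandidateRecord:
    d = vars(rec) | kw
    return CandidateRecord(**d)


def validate_multireporter(gene_id: str,
                           reporter_hits: Mapping[str, pd.DataFrame]) -> bool:
    """Multi-reporter, multi-reagent validation.

    ``reporter_hits`` maps each reporter configuration (original,
    alt_promoter, alt_ces) to its table of gene-level hits with columns
    amplicon_id, gene_id, direction.  A gene is validated iff at least two
    distinct amplicons support it (in any reporter) and it is a hit with a
    single consistent direction in all three reporter configurations.
    """
    missing = [r for r in REPORTERS if r not in reporter_hits]
    if missing:
        raise ReporterTableMissingError(f"reporter_table_missing: {missing}")
    amplicons: set[str] = set()
    directions: list[set[str]] = []
    for rep in REPORTERS:
        tbl = reporter_hits[rep]
        rows = tbl[tbl["gene_id"] == gene_id]
        if rows.empty:
            return False
        amplicons.update(rows["amplicon_id"])
        directions.append(set(rows["direction"]))
    all_dirs = set().union(*directions)
    return len(amplicons) >= 2 and len(all_dirs) == 1


def classify_candidate(record: CandidateRecord,
                       annotation: GeneAnnotation) -> int | str:
    """Assign a validated candidate to Class 1-6 or flag it as msl_core.

    Mapping: core MSL component -> msl_core; RNA-metabolism role -> 5
    (takes precedence over direction); sequence-specific DNA binding ->
    2 (activator) / 4 (repressor); general transcriptional regulator ->
    1 (activator) / 3 (repressor); everything else -> 6.
    """
    if record.direction not in ("activator", "repressor"):
        raise ValueError("direction must be activator or repressor")
    if annotation.is_msl_core:
        return "msl_core"
    if annotation.functional_role == "rna_metabolism":
        return 5
    if annotation.has_sequence_specific_dna_binding:
        if annotation.functional_role == "general_transcription":
            warnings.warn(f"gene {annotation.gene_id}: both DNA-binding and general "
                          "transcription set; classifying by DNA binding", stacklevel=2)
        return 2 if record.direction == "activator" else 4
    if annotation.functional_role == "general_transcription":
        return 1 if record.direction == "activator" else 3
    return 6


def triage(candidates: Iterable[CandidateRecord],
           annotations: Mapping[str, GeneAnnotation],
           amplicons: Mapping[str, Amplicon],
           reporter_hits: Mapping[str, pd.DataFrame],
           max_off_targets: int = 1) -> list[CandidateRecord]:
    """Full cascade: filters, multi-reporter validation, classification.

    Every input candidate ends in exactly one state: filtered(reason) or
    class 1-6 / msl_core.
    """
    out = []
    for rec in apply_filters(candidates, annotations, amplicons, max_off_targets):
        if rec.filter_reason is not None:
            out.append(rec)
            continue
        if not validate_multireporter(rec.gene_id, reporter_hits):
            out.append(replace_record(rec, filter_reason="unvalidated"))
            continue
        cls = classify_candidate(rec, annotations[rec.gene_id])
        out.append(replace_record(rec, assigned_class=cls))
    return out


def triage_table(records: Iterable[CandidateRecord]) -> pd.DataFrame:
    """Candidates as a flat table (gene, direction, class, amplicons, reason)."""
    return pd.DataFrame([
        {"gene_id": r.gene_id, "direction": r.direction,
         "assigned_class": r.assigned_class,
         "n_supporting_amplicons": len(r.supporting_amplicons),
         "supporting_amplicons": ",".join(r.supporting_amplicons),
         "filter_reason": r.filter_reason or ""}
        for r in records
    ])
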