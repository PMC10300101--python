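"""Post-processing cascade enriching model-passing calls for tumor-derived
somatic variants.

Three successive set-selections: keep only protein-affecting consequences
(VEP-style most-severe term), keep only variants seen in at least one
breast-cancer cohort, and remove known polymorphisms whose VAF is in a
germline range.  Each step is a pure selection on variant identity plus its
annotations, so the cascade's final set is order-independent.  A matched
germline-subtraction comparator is provided for samples with white-blood-
cell DNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .mixture import GermlineIntervals, DEFAULT_GERMLINE_INTERVALS, flag_germline
from .variant_io import MembershipSet, VariantCall, VariantKey

log = logging.getLogger(__name__)

#: Ensembl consequence terms in decreasing severity (standard VEP ranking).
CONSEQUENCE_SEVERITY = (
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "transcript_amplification",
    "feature_elongation",
    "feature_truncation",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "protein_altering_variant",
    "splice_donor_5th_base_variant",
    "splice_region_variant",
    "splice_donor_region_variant",
    "splice_polypyrimidine_tract_variant",
    "incomplete_terminal_codon_variant",
    "start_retained_variant",
    "stop_retained_variant",
    "synonymous_variant",
    "coding_sequence_variant",
    "mature_miRNA_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "NMD_transcript_variant",
    "non_coding_transcript_variant",
    "coding_transcript_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "TFBS_ablation",
    "TFBS_amplification",
    "TF_binding_site_variant",
    "regulatory_region_ablation",
    "regulatory_region_amplification",
    "regulatory_region_variant",
    "intergenic_variant",
    "sequence_variant",
)
_SEVERITY_RANK = {term: i for i, term in enumerate(CONSEQUENCE_SEVERITY)}

#: Consequences retained by default: protein-sequence- or splice-altering.
DEFAULT_ALLOWED_CONSEQUENCES = frozenset({
    "missense_variant",
    "start_lost",
    "stop_lost",
    "stop_gained",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "splice_donor_5th_base_variant",
})


def most_severe(consequences: Iterable[str]) -> str:
    """Most severe term under the embedded severity ranking."""
    terms = list(consequences)
    if not terms:
        raise ValueError("empty consequence list")
    for term in terms:
        if term not in _SEVERITY_RANK:
            raise ValueError(f"unknown consequence term {term!r}")
    return min(terms, key=_SEVERITY_RANK.__getitem__)


@dataclass(frozen=True)
class ConsequenceAnnotation:
    key: VariantKey
    consequences: tuple[str, ...]

    @property
    def most_severe(self) -> str:
        return most_severe(self.consequences)


def read_consequences(path: str | Path) -> dict[VariantKey, ConsequenceAnnotation]:
    """Read a VEP-style TSV (chrom, pos, ref, alt, consequences) where the
    consequences column is a comma/&-separated term list, reduced across
    transcripts to the most severe term at use time."""
    annotations: dict[VariantKey, ConsequenceAnnotation] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for col in ("chrom", "pos", "ref", "alt", "consequences"):
            if col not in header:
                raise ValueError(f"{path}: missing required column {col!r}")
        idx = {c: header.index(c) for c in header}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            key = VariantKey(parts[idx["chrom"]], int(parts[idx["pos"]]),
                             parts[idx["ref"]], parts[idx["alt"]])
            terms = tuple(
                t for t in parts[idx["consequences"]].replace("&", ",").split(",") if t
            )
            if key in annotations:
                terms = annotations[key].consequences + terms
            annotations[key] = ConsequenceAnnotation(key=key, consequences=terms)
    return annotations


def consequence_filter(
    calls: Sequence[VariantCall],
    annotations: dict[VariantKey, ConsequenceAnnotation],
    allowed: frozenset[str] = DEFAULT_ALLOWED_CONSEQUENCES,
) -> list[VariantCall]:
    """Keep calls whose most severe transcript consequence is in ``allowed``.

    Unannotated calls are removed (and counted in the log): a variant
    without a transcript effect cannot qualify.
    """
    kept, n_unannotated = [], 0
    for call in calls:
        ann = annotations.get(call.key)
        if ann is None:
            n_unannotated += 1
            continue
        if ann.most_severe in allowed:
            kept.append(call)
    if n_unannotated:
        log.info("consequence_filter: %d unannotated calls removed", n_unannotated)
    return kept


def cohort_filter(
    calls: Sequence[VariantCall],
    cohort_sets: Sequence[MembershipSet],
) -> list[VariantCall]:
    """Keep calls seen in at least one cohort variant set."""
    if not cohort_sets:
        raise ValueError("at least one cohort set required")
    return [c for c in calls if any(c.key in s for s in cohort_sets)]


@dataclass
class CascadeConfig:
    """Configuration of the post-processing cascade; defaults reproduce the
    standard pipeline (consequence -> cohort -> dbSNP/VAF germline)."""

    allowed_consequences: frozenset[str] = DEFAULT_ALLOWED_CONSEQUENCES
    cohort_sets: Sequence[MembershipSet] = ()
    dbsnp: MembershipSet | None = None
    intervals: GermlineIntervals = DEFAULT_GERMLINE_INTERVALS
    steps: tuple[str, ...] = ("consequence", "cohort", "germline")


def run_cascade(
    calls: Sequence[VariantCall],
    annotations: dict[VariantKey, ConsequenceAnnotation],
    config: CascadeConfig,
) -> tuple[list[VariantCall], list[tuple[str, int]]]:
    """Apply the enabled filters in sequence, logging counts per step.

    Each step is a pure set-selection, so the final set equals the
    intersection of the per-step keep-sets regardless of order.
    """
    current = list(calls)
    step_log: list[tuple[str, int]] = [("input", len(current))]
    for step in config.steps:
        if step == "consequence":
            current = consequence_filter(current, annotations, config.allowed_consequences)
        elif step == "cohort":
            current = cohort_filter(current, config.cohort_sets)
        elif step == "germline":
            if config.dbsnp is None:
                raise ValueError("germline step requires a dbSNP set")
            current = [
                c for c in current
                if not flag_germline(c, config.intervals, config.dbsnp)
            ]
        else:
            raise ValueError(f"unknown cascade step {step!r}")
        step_log.append((step, len(current)))
    return current, step_log


def germline_subtraction(
    cf_calls: Sequence[VariantCall],
    germline_calls: Sequence[VariantCall],
) -> list[VariantCall]:
    """Label cfDNA calls somatic when absent from the matched germline calls.

    Both call sets must come from the same patient; matching is by full
    variant key, so distinct alt alleles at one site are distinct events.
    """
    patients_cf = {c.sample_id for c in cf_calls}
    patients_g = {c.sample_id for c in germline_calls}
    if len(patients_cf) > 1 or len(patients_g) > 1:
        raise ValueError(
            f"germline subtraction is per-patient; got cfDNA samples {sorted(patients_cf)} "
            f"and germline samples {sorted(patients_g)}"
        )
    germline_keys = {c.key for c in germline_calls}
    return [c for c in cf_calls if c.key not in germline_keys]
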