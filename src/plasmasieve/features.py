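"""22-dimensional feature representation of a variant call.

Sixteen features describe the call itself (caller quality and bias
statistics, allelic support, genotype, coverage, VAF, unique-molecule
support); six describe the sequence context in a 60 bp window around the
site (nucleotide counts, GC fraction, soft-masked repeat fraction).
Vectors are standardized to zero mean / unit variance with a standardizer
fitted on training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .variant_io import VariantCall, normalize_chrom

#: Fixed feature order. The first 16 are call features, the last 6 sequence
#: context features.
FEATURE_NAMES = (
    "qual",
    "segregation_metric",      # SGB
    "read_pos_bias_p",         # RPB
    "map_qual_bias_p",         # MQB
    "map_qual_strand_bias_p",  # MQSB
    "base_qual_bias_p",        # BQB
    "allele_count",            # AC
    "hq_ref_forward",          # DP4[0]
    "hq_ref_reverse",          # DP4[1]
    "hq_alt_forward",          # DP4[2]
    "hq_alt_reverse",          # DP4[3]
    "mapping_quality",         # MQ
    "ref_alleles_in_genotype",  # 2 for 0/0, 1 for 0/1
    "coverage",                # DP
    "vaf",
    "alt_unique_molecules",
)
SEQUENCE_FEATURE_NAMES = (
    "count_A",
    "count_C",
    "count_G",
    "count_T",
    "gc_fraction",
    "repeat_fraction",
)
ALL_FEATURE_NAMES = FEATURE_NAMES + SEQUENCE_FEATURE_NAMES
N_FEATURES = len(ALL_FEATURE_NAMES)  # 22

#: Imputation values for absent caller annotations: a missing bias p-value
#: carries no evidence of bias (1.0); a missing segregation metric is
#: neutral (0.0).
_BIAS_FEATURES = {
    "read_pos_bias_p",
    "map_qual_bias_p",
    "map_qual_strand_bias_p",
    "base_qual_bias_p",
}
_ANNOTATION_BY_FEATURE = {
    "segregation_metric": "SGB",
    "read_pos_bias_p": "RPB",
    "map_qual_bias_p": "MQB",
    "map_qual_strand_bias_p": "MQSB",
    "base_qual_bias_p": "BQB",
    "allele_count": "AC",
    "mapping_quality": "MQ",
    "coverage": "DP",
}


@dataclass
class FeatureVector:
    values: np.ndarray          # shape (22,)
    missing_mask: np.ndarray    # shape (22,), True where imputed

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != (N_FEATURES,) or self.missing_mask.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have exactly {N_FEATURES} entries")


class MaskedReference:
    """Per-chromosome sequence with soft-masking preserved as lowercase."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {normalize_chrom(c): s for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MaskedReference":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self.sequences

    def window(self, chrom: str, pos_1based: int, flank: int = 30) -> str:
        """Flanking sequence around a site, the site base itself excluded.

        The window is ``flank`` bases upstream plus ``flank`` downstream
        (60 bases by default); flanks that run off a chromosome end are
        truncated.
        """
        key = normalize_chrom(chrom)
        if key not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self.sequences[key]
        i = pos_1based - 1  # 0-based site index
        if not 0 <= i < len(seq):
            raise ValueError(f"position {pos_1based} outside {chrom} (length {len(seq)})")
        return seq[max(0, i - flank): i] + seq[i + 1: i + 1 + flank]


def extract_call_features(call: VariantCall) -> tuple[np.ndarray, np.ndarray]:
    """The 16 call features, with imputation flags for absent annotations.

    Only genotypes 0/0 and 0/1 are legal here (homozygous and multi-allelic
    calls must have been removed by the basic filter); the genotype feature
    counts reference alleles in the call: 2 for 0/0, 1 for 0/1.
    """
    if call.genotype not in {"0/0", "0/1"}:
        raise ValueError(
            f"genotype {call.genotype!r} at {call.chrom}:{call.pos} should have "
            "been removed before feature extraction"
        )
    values = np.zeros(len(FEATURE_NAMES))
    mask = np.zeros(len(FEATURE_NAMES), dtype=bool)
    ann = call.call_annotations
    for j, name in enumerate(FEATURE_NAMES):
        if name == "qual":
            values[j] = call.qual
        elif name == "ref_alleles_in_genotype":
            values[j] = 2.0 if call.genotype == "0/0" else 1.0
        elif name == "vaf":
            values[j] = call.vaf
        elif name == "alt_unique_molecules":
            values[j] = call.alt_umi
        elif name.startswith("hq_"):
            idx = ("hq_ref_forward", "hq_ref_reverse",
                   "hq_alt_forward", "hq_alt_reverse").index(name)
            if call.dp4 is not None:
                values[j] = call.dp4[idx]
            else:
                values[j] = 0.0
                mask[j] = True
        else:
            key = _ANNOTATION_BY_FEATURE[name]
            if key in ann:
                values[j] = ann[key]
            else:
                mask[j] = True
                if name in _BIAS_FEATURES:
                    values[j] = 1.0
                elif name == "coverage":
                    values[j] = call.umi_depth
                else:
                    values[j] = 0.0  # SGB/AC/MQ: neutral placeholder, flagged
    return values, mask


def extract_sequence_features(
    reference: MaskedReference, chrom: str, pos: int, flank: int = 30
) -> np.ndarray:
    """Nucleotide composition of the context window around a site.

    Returns A/C/G/T counts (case-insensitive), GC fraction and the fraction
    of soft-masked (lowercase) bases.  N bases count toward no nucleotide
    bin but stay in the fraction denominators.
    """
    window = reference.window(chrom, pos, flank=flank)
    n = len(window)
    upper = window.upper()
    counts = [upper.count(b) for b in "ACGT"]
    gc = (counts[1] + counts[2]) / n if n else 0.0
    repeat = sum(1 for b in window if b.islower()) / n if n else 0.0
    return np.array([*counts, gc, repeat], dtype=float)


def extract_features(call: VariantCall, reference: MaskedReference) -> FeatureVector:
    """Full 22-entry vector: 16 call features then 6 sequence features."""
    call_vals, call_mask = extract_call_features(call)
    seq_vals = extract_sequence_features(reference, call.chrom, call.pos)
    return FeatureVector(
        values=np.concatenate([call_vals, seq_vals]),
        missing_mask=np.concatenate([call_mask, np.zeros(6, dtype=bool)]),
    )


@dataclass
class Standardizer:
    """Per-feature zero-mean/unit-variance transform fitted on training rows.

    Constant features get divisor 1 (so they map to 0) and are flagged in
    ``degenerate``.
    """

    mean: np.ndarray
    std: np.ndarray
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape[-1] != self.mean.shape[0]:
            raise ValueError("feature dimension mismatch")
        return (matrix - self.mean) / self.std


def fit_standardizer(matrix: np.ndarray) -> Standardizer:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a standardizer")
    mean = matrix.mean(axis=0)
    std = matrix.std(axis=0)
    degenerate = std == 0.0
    std = np.where(degenerate, 1.0, std)
    return Standardizer(mean=mean, std=std, degenerate=degenerate)


def apply_standardizer(s: Standardizer, matrix: np.ndarray) -> np.ndarray:
    return s.transform(matrix)


def feature_matrix(vectors: list[FeatureVector]) -> np.ndarray:
    if not vectors:
        return np.empty((0, N_FEATURES))
    return np.vstack([v.values for v in vectors])
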