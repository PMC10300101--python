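"""Readers for the pipeline's input formats and the pre-model call filters.

Variant calls come from UMI-consensus amplicon sequencing called with
``bcftools mpileup``/``call``: each record carries the mpileup per-call
annotations (segregation metric SGB, bias p-values RPB/MQB/MQSB/BQB, allele
count AC, mean mapping quality MQ, depth DP, strand-specific high-quality
support DP4) and a unique-molecule allelic depth (FORMAT/AD).  Panel target
regions are BED3; COSMIC/dbSNP/cohort variant sets are flat TSV tables keyed
by (chrom, pos, ref, alt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from cyvcf2 import VCF

log = logging.getLogger(__name__)

#: mpileup INFO annotations consumed as call features, in canonical order.
CALL_ANNOTATION_KEYS = (
    "SGB",   # segregation-based metric
    "RPB",   # read position bias (Mann-Whitney p)
    "MQB",   # mapping quality bias
    "MQSB",  # mapping quality vs strand bias
    "BQB",   # base quality bias
    "AC",    # non-reference allele count in called genotypes
    "MQ",    # mean mapping quality
    "DP",    # raw total depth
)

_AUTOSOMES_AND_X = {str(i) for i in range(1, 23)} | {"X"}


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so GRCh38 naming styles compare equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True, order=True)
class VariantKey:
    """Site + allele identity used for all membership and join operations."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))


@dataclass(frozen=True)
class Region:
    """A BED-style 0-based half-open target interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"region start must be < end: {self.chrom}:{self.start}-{self.end}"
            )

    def contains(self, pos_1based: int) -> bool:
        return self.start <= pos_1based - 1 < self.end


@dataclass
class VariantCall:
    """One called single-site variant allele with its quality annotations.

    ``ref_umi``/``alt_umi`` are unique-molecule (UMI-consensus) allelic
    depths; ``call_annotations`` holds whatever subset of the mpileup
    annotations the caller emitted — absent keys stay absent and are imputed
    (and masked) only at feature-extraction time.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    genotype: str  # "0/0", "0/1", "1/1", "1/2" or "other"
    ref_umi: int
    alt_umi: int
    call_annotations: dict[str, float] = field(default_factory=dict)
    dp4: tuple[int, int, int, int] | None = None  # ref-fwd, ref-rev, alt-fwd, alt-rev
    allele_call: str | None = None  # hotspot-panel caller verdict
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"1-based position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if self.ref_umi < 0 or self.alt_umi < 0:
            raise ValueError("allelic depths must be non-negative")

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    @property
    def umi_depth(self) -> int:
        """Unique-molecule coverage at the site (ref + alt consensus reads)."""
        return self.ref_umi + self.alt_umi

    @property
    def vaf(self) -> float:
        """Variant allele frequency from unique molecules; 0 at zero depth."""
        d = self.umi_depth
        return self.alt_umi / d if d > 0 else 0.0

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and \
            self.ref in "ACGT" and self.alt in "ACGT"


@dataclass
class MembershipSet:
    """A named set of variant keys (COSMIC, dbSNP, a cohort's mutations...)."""

    name: str
    keys: frozenset[VariantKey]

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)


class VcfParseError(ValueError):
    pass


def _genotype_string(gt_types_entry: list[int]) -> str:
    alleles = [a for a in gt_types_entry if a >= 0]
    if len(alleles) != 2:
        return "other"
    a, b = sorted(alleles)
    s = f"{a}/{b}"
    return s if s in {"0/0", "0/1", "1/1", "1/2"} else "other"


def read_variant_vcf(path: str | Path, sample_id: str) -> list[VariantCall]:
    """Read a single-sample VCF into one :class:`VariantCall` per ALT allele.

    Multi-allelic records yield one call per ALT allele, every one carrying
    the record genotype (``1/2`` flags them for downstream exclusion).
    Records without an allelic-depth FORMAT field cannot provide
    unique-molecule counts and are dropped with a logged count.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise VcfParseError(f"cannot read VCF {path!r}: {exc}") from exc

    calls: list[VariantCall] = []
    n_no_ad = 0
    for rec in vcf:
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            n_no_ad += 1
            continue
        ad_row = [int(x) for x in ad[0]]
        gt = _genotype_string(list(rec.genotypes[0][:-1])) if rec.genotypes else "other"
        if len(rec.ALT) > 1 and gt in {"0/0", "0/1", "1/1"}:
            gt = "1/2"  # caller split disagreement: >1 ALT allele at one site
        annotations: dict[str, float] = {}
        for key in CALL_ANNOTATION_KEYS:
            value = rec.INFO.get(key)
            if value is not None:
                if isinstance(value, tuple):
                    value = value[0]
                annotations[key] = float(value)
        dp4_raw = rec.INFO.get("DP4")
        dp4 = tuple(int(x) for x in dp4_raw) if dp4_raw is not None else None
        allele_call = rec.INFO.get("ALLELE_CALL")
        for i, alt in enumerate(rec.ALT):
            alt_umi = ad_row[i + 1] if i + 1 < len(ad_row) else 0
            calls.append(
                VariantCall(
                    sample_id=sample_id,
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    qual=float(rec.QUAL) if rec.QUAL is not None else 0.0,
                    genotype=gt,
                    ref_umi=ad_row[0],
                    alt_umi=alt_umi,
                    call_annotations=dict(annotations),
                    dp4=dp4,
                    allele_call=allele_call,
                    id=rec.ID,
                )
            )
    if n_no_ad:
        log.warning("%s: %d records lacked FORMAT/AD and were excluded", path, n_no_ad)
    return calls


def read_regions(path: str | Path) -> list[Region]:
    """Read a BED3+ file into 0-based half-open regions, kept verbatim."""
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path} line {lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path} line {lineno}: start >= end")
            regions.append(Region(parts[0], start, end))
    return regions


def read_membership(path: str | Path, name: str) -> MembershipSet:
    """Read a (chrom, pos, ref, alt) TSV into a deduplicated key set."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["chrom", "pos", "ref", "alt"]
        for col in required:
            if col not in header:
                raise ValueError(f"{path}: missing required column {col!r}")
        idx = {col: header.index(col) for col in required}
        keys = set()
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            keys.add(
                VariantKey(
                    parts[idx["chrom"]],
                    int(parts[idx["pos"]]),
                    parts[idx["ref"]],
                    parts[idx["alt"]],
                )
            )
    return MembershipSet(name=name, keys=frozenset(keys))


def _in_any_region(call: VariantCall, regions_by_chrom: Mapping[str, list[Region]]) -> bool:
    for region in regions_by_chrom.get(normalize_chrom(call.chrom), ()):
        if region.contains(call.pos):
            return True
    return False


def basic_filter(
    calls: Iterable[VariantCall],
    regions: Iterable[Region],
    cosmic: MembershipSet,
) -> list[VariantCall]:
    """Pre-model filtering of raw mpileup calls.

    Keeps single-nucleotide variants on chromosomes 1-22/X that fall inside a
    panel target region, are known COSMIC variants, and are not homozygous
    (1/1) or multi-allelic (1/2) by unique-molecule genotype.  Genotype 0/0
    calls with alt support are retained: they reach the classifier, which
    encodes the genotype as a feature.
    """
    regions_by_chrom: dict[str, list[Region]] = {}
    for region in regions:
        regions_by_chrom.setdefault(normalize_chrom(region.chrom), []).append(region)

    kept = []
    n_in = 0
    for call in calls:
        n_in += 1
        if not call.is_snv:
            continue
        if normalize_chrom(call.chrom) not in _AUTOSOMES_AND_X:
            continue
        if call.genotype in {"1/1", "1/2"}:
            continue
        if not _in_any_region(call, regions_by_chrom):
            continue
        if call.key not in cosmic:
            continue
        kept.append(call)
    log.info("basic_filter: %d calls in, %d kept", n_in, len(kept))
    return kept


def hotspot_panel_filter(
    calls: Iterable[VariantCall],
    blacklist: frozenset[VariantKey] | set[VariantKey] = frozenset(),
) -> list[VariantCall]:
    """Ground-truth filtering for hotspot-panel calls.

    Keeps SNVs with a positive allele call, PHRED quality >= 20 and at least
    4 unique molecules supporting the variant, minus an explicit exclusion
    list (e.g. homopolymer artefacts).
    """
    kept = []
    n_in = 0
    for call in calls:
        n_in += 1
        if not call.is_snv:
            continue
        if call.allele_call is not None and call.allele_call.lower() in {"absent", "no call"}:
            continue
        if call.qual < 20:
            continue
        if call.alt_umi < 4:
            continue
        if call.key in blacklist:
            continue
        kept.append(call)
    log.info("hotspot_panel_filter: %d calls in, %d kept", n_in, len(kept))
    return kept
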