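"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

Emulates a multi-patient cfDNA panel experiment: a soft-masked reference
sequence, per-patient VCFs of UMI-consensus calls drawn from four
class-conditional regimes (sequencing error, true somatic, germline
heterozygous, germline homozygous), and the side tables the filters consume
(COSMIC/dbSNP/cohort membership, VEP-style consequences, BED target
regions) kept consistent with the truth labels.  Everything is a pure
function of the spec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import MaskedReference, extract_features
from .svm import LabeledVariant
from .variant_io import MembershipSet, Region, VariantCall, VariantKey

#: Class-conditional VAF laws: (alpha, beta) per truth class.
VAF_LAWS = {
    "error": (1.0, 200.0),
    "somatic": (2.0, 8.0),
    "germline_het": (45.0, 45.0),
    "germline_hom": (90.0, 2.0),
}

_BASES = np.array(list("ACGT"))


def make_reference(length: int, repeat_fraction: float, seed: int) -> MaskedReference:
    """Uniform random sequence with a seeded soft-masked (lowercase) subset.

    Exactly ``round(length * repeat_fraction)`` positions are lowercased, so
    the realized masked fraction matches the request to within 1/length.
    """
    if length < 200:
        raise ValueError("reference length must be >= 200")
    rng = np.random.default_rng(seed)
    bases = rng.choice(_BASES, size=length)
    n_masked = int(round(length * repeat_fraction))
    masked_idx = rng.choice(length, size=n_masked, replace=False)
    bases[masked_idx] = np.char.lower(bases[masked_idx])
    return MaskedReference({"1": "".join(bases)})


def make_mixture_sample(
    params: list[tuple[float, float, float]], n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral sampling from a beta mixture; returns (values, component ids).

    ``params`` is a list of (alpha, beta, weight) with weights summing to 1.
    """
    weights = np.array([w for _, _, w in params])
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    if np.any(weights < 0):
        raise ValueError("mixture weights must be non-negative")
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.array([]), np.array([], dtype=int)
    comp = rng.choice(len(params), size=n, p=weights)
    alphas = np.array([a for a, _, _ in params])
    betas = np.array([b for _, b, _ in params])
    return rng.beta(alphas[comp], betas[comp]), comp


@dataclass
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Per-patient class counts default to the scale of a large-panel cfDNA
    experiment restricted to hotspot-shared regions: a couple of true
    somatic mutations against an order of magnitude more artefactual and
    germline calls.  ``separation`` scales how far somatic-call quality and
    bias statistics sit from the error regime (3 = clearly separable,
    0 = indistinguishable up to VAF).
    """

    n_patients: int = 12
    n_somatic: int = 2
    n_germline_het: int = 6
    n_germline_hom: int = 3
    n_error: int = 15
    separation: float = 3.0
    mean_umi_coverage: float = 1500.0
    sequence_length: int = 30_000
    repeat_fraction: float = 0.15
    region_size: int = 120           # amplicon-sized targets
    synonymous_fraction: float = 0.25
    n_control_calls: int = 2         # per patient; removed by basic_filter
    n_decoy_keys: int = 20           # membership entries never called
    n_hotspot_only: int = 0          # label-only truth rows per patient
    vaf_laws: dict[str, tuple[float, float]] | None = None  # override per class
    seed: int = 0

    def vaf_law(self, cls: str) -> tuple[float, float]:
        if self.vaf_laws and cls in self.vaf_laws:
            return self.vaf_laws[cls]
        return VAF_LAWS[cls]


def high_separation_spec(seed: int = 0, n_patients: int = 10) -> CohortSpec:
    """Study conditions under which the truth classes are cleanly separable.

    Somatic VAFs are drawn from Beta(3, 40) (roughly 2-20%), clear of both
    the sequencing-error regime (<1%) and the germline regimes (>35%), and
    the separation knob places somatic call-quality statistics far from the
    error regime.  A correctly wired nested-CV pipeline should recover this
    signal almost perfectly; the configuration exists to validate the
    machinery, not to emulate realistic class overlap (the default spec
    keeps the overlapping Beta(2, 8) somatic law).
    """
    return CohortSpec(
        n_patients=n_patients,
        n_somatic=4,
        separation=5.0,
        vaf_laws={"somatic": (3.0, 40.0)},
        seed=seed,
    )


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    reference: MaskedReference
    regions: list[Region]
    calls: dict[str, list[VariantCall]]            # patient -> calls
    truth: dict[tuple[str, VariantKey], str]       # (patient, key) -> class
    cosmic: MembershipSet
    dbsnp: MembershipSet
    cohort_sets: list[MembershipSet]
    consequences: dict[VariantKey, tuple[str, ...]]
    hotspot_only: dict[str, list[VariantKey]] = field(default_factory=dict)

    def labeled_variants(self) -> list[LabeledVariant]:
        """Ground-truth-labeled rows for the classifier: label True iff the
        call is a true somatic variant (the hotspot panel's verdict in the
        emulated experiment)."""
        rows = []
        for patient, calls in self.calls.items():
            for call in calls:
                cls = self.truth.get((patient, call.key))
                if cls is None or cls == "control":
                    continue
                rows.append(
                    LabeledVariant(
                        patient_id=patient,
                        key=call.key,
                        label=(cls == "somatic"),
                        features=extract_features(call, self.reference),
                        call=call,
                    )
                )
            for key in self.hotspot_only.get(patient, ()):
                rows.append(LabeledVariant(patient_id=patient, key=key, label=True))
        return rows

    def write(self, outdir: str | Path) -> dict[str, Path]:
        return write_cohort(self, outdir)


def _draw_call(
    rng: np.random.Generator,
    spec: CohortSpec,
    patient: str,
    cls: str,
    pos: int,
    ref: str,
    alt: str,
) -> VariantCall:
    a, b = spec.vaf_law(cls)
    vaf = float(np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4))
    cov = max(20, int(rng.negative_binomial(20, 20 / (20 + spec.mean_umi_coverage))))
    alt_umi = max(1, int(round(cov * vaf)))
    ref_umi = max(0, cov - alt_umi)
    is_error = cls == "error"
    sep = spec.separation
    if is_error:
        qual = float(np.clip(rng.normal(12, 6), 0.1, None))
        bias = rng.beta(0.4, max(0.4, 0.4 + 0.6 * sep), size=4)  # low p = biased
        mq = float(np.clip(rng.normal(52 - 2 * sep, 4), 10, 60))
        sgb = float(rng.normal(-0.7, 0.5))
        strand_p = 0.5 + min(0.45, 0.13 * sep)  # strand-imbalanced artefacts
    else:
        qual = float(np.clip(rng.normal(15 + 15 * sep, 8), 0.1, None))
        bias = rng.uniform(0.05, 1.0, size=4)
        mq = float(np.clip(rng.normal(57, 2), 10, 60))
        sgb = float(rng.normal(-3.0, 1.0))
        strand_p = 0.5
    alt_fwd = int(rng.binomial(alt_umi, strand_p))
    ref_fwd = int(rng.binomial(ref_umi, 0.5))
    annotations = {
        "SGB": sgb,
        "RPB": float(bias[0]),
        "MQB": float(bias[1]),
        "MQSB": float(bias[2]),
        "BQB": float(bias[3]),
        "AC": 1.0,
        "MQ": mq,
        "DP": float(int(cov * rng.uniform(1.0, 1.3))),
    }
    return VariantCall(
        sample_id=patient,
        chrom="1",
        pos=pos,
        ref=ref,
        alt=alt,
        qual=qual,
        genotype="0/1",
        ref_umi=ref_umi,
        alt_umi=alt_umi,
        call_annotations=annotations,
        dp4=(ref_fwd, ref_umi - ref_fwd, alt_fwd, alt_umi - alt_fwd),
    )


def _alt_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[int(rng.integers(3))]


def make_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort consistent with its truth labels.

    Membership tables follow the truth construction: every non-control call
    is in COSMIC, germline calls are in dbSNP, somatic calls are in at least
    one of three cohort sets; decoy keys (in tables but never called) and
    per-patient control calls (non-COSMIC, or off the allowed chromosomes)
    exercise the membership logic.  Somatic and germline variants receive
    protein-affecting consequences except for a configurable synonymous
    fraction.
    """
    per_patient = spec.n_somatic + spec.n_germline_het + spec.n_germline_hom + spec.n_error
    if per_patient == 0 or spec.n_patients == 0:
        raise ValueError("cohort spec generates zero calls")
    rng = np.random.default_rng(spec.seed)
    reference = make_reference(spec.sequence_length, spec.repeat_fraction, spec.seed + 1)
    seq = reference.sequences["1"]

    # tile amplicon-like regions over the middle of the sequence
    regions = []
    start = 200
    while start + spec.region_size < spec.sequence_length - 200:
        regions.append(Region("1", start, start + spec.region_size))
        start += spec.region_size * 2
    in_region_pos = np.concatenate([np.arange(r.start + 1, r.end + 1) for r in regions])

    n_sites = spec.n_patients * (per_patient + spec.n_control_calls + spec.n_hotspot_only)
    if n_sites > in_region_pos.size:
        raise ValueError("sequence too short for the requested call counts")
    site_pool = rng.choice(in_region_pos, size=n_sites, replace=False)
    site_iter = iter(site_pool.tolist())

    calls: dict[str, list[VariantCall]] = {}
    truth: dict[tuple[str, VariantKey], str] = {}
    hotspot_only: dict[str, list[VariantKey]] = {}
    cosmic_keys: set[VariantKey] = set()
    dbsnp_keys: set[VariantKey] = set()
    somatic_keys: set[VariantKey] = set()
    consequences: dict[VariantKey, tuple[str, ...]] = {}

    class_plan = (
        [("somatic", spec.n_somatic), ("germline_het", spec.n_germline_het),
         ("germline_hom", spec.n_germline_hom), ("error", spec.n_error)]
    )
    for p in range(spec.n_patients):
        patient = f"P{p + 1:03d}"
        patient_calls: list[VariantCall] = []
        for cls, count in class_plan:
            for _ in range(count):
                pos = next(site_iter)
                ref = seq[pos - 1].upper()
                alt = _alt_base(rng, ref)
                call = _draw_call(rng, spec, patient, cls, pos, ref, alt)
                patient_calls.append(call)
                truth[(patient, call.key)] = cls
                cosmic_keys.add(call.key)
                if cls in {"germline_het", "germline_hom"}:
                    dbsnp_keys.add(call.key)
                if cls == "somatic":
                    somatic_keys.add(call.key)
                if call.key not in consequences:
                    if cls == "error":
                        term = "intron_variant"
                    elif rng.random() < spec.synonymous_fraction:
                        term = "synonymous_variant"
                    else:
                        term = "missense_variant"
                    consequences[call.key] = (term,)
        # control calls: well-formed but non-COSMIC, removed by basic_filter
        for _ in range(spec.n_control_calls):
            pos = next(site_iter)
            ref = seq[pos - 1].upper()
            call = _draw_call(rng, spec, patient, "error", pos, ref, _alt_base(rng, ref))
            patient_calls.append(call)
            truth[(patient, call.key)] = "control"
        for _ in range(spec.n_hotspot_only):
            pos = next(site_iter)
            ref = seq[pos - 1].upper()
            key = VariantKey("1", pos, ref, _alt_base(rng, ref))
            hotspot_only.setdefault(patient, []).append(key)
            cosmic_keys.add(key)
            somatic_keys.add(key)
            consequences.setdefault(key, ("missense_variant",))
        patient_calls.sort(key=lambda c: c.pos)
        calls[patient] = patient_calls

    # decoy membership entries at positions never called
    all_pos = {k.pos for k in cosmic_keys} | {
        k.pos for ks in hotspot_only.values() for k in ks
    }
    decoy_candidates = [p for p in in_region_pos.tolist() if p not in all_pos]
    decoys = rng.choice(decoy_candidates, size=min(spec.n_decoy_keys, len(decoy_candidates)),
                        replace=False)
    decoy_keys = []
    for pos in decoys.tolist():
        ref = seq[pos - 1].upper()
        decoy_keys.append(VariantKey("1", pos, ref, _alt_base(rng, ref)))
    half = len(decoy_keys) // 2
    cosmic_keys |= set(decoy_keys[:half])
    dbsnp_keys |= set(decoy_keys[half:])

    # split somatic keys across the three cohort sets, with overlap
    somatic_list = sorted(somatic_keys)
    sets: list[set[VariantKey]] = [set(), set(), set()]
    for i, key in enumerate(somatic_list):
        sets[i % 3].add(key)
        if rng.random() < 0.3:
            sets[(i + 1) % 3].add(key)
    cohort_sets = [
        MembershipSet(name, frozenset(s))
        for name, s in zip(("tcga_erpos_her2neg", "basis_wgs", "icgc_brca_fr"), sets)
    ]

    return SyntheticCohort(
        spec=spec,
        reference=reference,
        regions=regions,
        calls=calls,
        truth=truth,
        cosmic=MembershipSet("cosmic", frozenset(cosmic_keys)),
        dbsnp=MembershipSet("dbsnp", frozenset(dbsnp_keys)),
        cohort_sets=cohort_sets,
        consequences=consequences,
        hotspot_only=hotspot_only,
    )


_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1,length={length}>
##INFO=<ID=SGB,Number=1,Type=Float,Description="Segregation based metric">
##INFO=<ID=RPB,Number=1,Type=Float,Description="Mann-Whitney U test of Read Position Bias">
##INFO=<ID=MQB,Number=1,Type=Float,Description="Mann-Whitney U test of Mapping Quality Bias">
##INFO=<ID=MQSB,Number=1,Type=Float,Description="Mann-Whitney U test of Mapping Quality vs Strand Bias">
##INFO=<ID=BQB,Number=1,Type=Float,Description="Mann-Whitney U test of Base Quality Bias">
##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count in genotypes">
##INFO=<ID=MQ,Number=1,Type=Float,Description="Average mapping quality">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">
##INFO=<ID=DP4,Number=4,Type=Integer,Description="High-quality ref-forward, ref-reverse, alt-forward, alt-reverse bases">
##INFO=<ID=ALLELE_CALL,Number=1,Type=String,Description="Hotspot panel allele call">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Unique-molecule allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def variant_call_to_vcf_line(call: VariantCall) -> str:
    info = []
    for key in ("SGB", "RPB", "MQB", "MQSB", "BQB"):
        if key in call.call_annotations:
            info.append(f"{key}={call.call_annotations[key]:.6g}")
    if "AC" in call.call_annotations:
        info.append(f"AC={int(call.call_annotations['AC'])}")
    if "MQ" in call.call_annotations:
        info.append(f"MQ={int(round(call.call_annotations['MQ']))}")
    if "DP" in call.call_annotations:
        info.append(f"DP={int(call.call_annotations['DP'])}")
    if call.dp4 is not None:
        info.append("DP4=" + ",".join(str(x) for x in call.dp4))
    if call.allele_call is not None:
        info.append(f"ALLELE_CALL={call.allele_call.replace(' ', '_')}")
    gt = call.genotype if call.genotype != "other" else "./."
    return "\t".join([
        call.chrom, str(call.pos), call.id or ".", call.ref, call.alt,
        f"{call.qual:.4g}", ".", ";".join(info) or ".",
        "GT:AD", f"{gt}:{call.ref_umi},{call.alt_umi}",
    ])


def write_membership_tsv(path: Path, keys: frozenset[VariantKey] | set[VariantKey]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for k in sorted(keys):
            fh.write(f"{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\n")


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort to disk in the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = outdir / "reference.fa"
    seq = cohort.reference.sequences["1"]
    with open(fasta, "w") as fh:
        fh.write(">1\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
    paths["reference"] = fasta

    bed = outdir / "regions.bed"
    with open(bed, "w") as fh:
        for r in cohort.regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
    paths["regions"] = bed

    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for patient, patient_calls in sorted(cohort.calls.items()):
        vcf_path = vcf_dir / f"{patient}.vcf"
        with open(vcf_path, "w") as fh:
            fh.write(_VCF_HEADER.format(length=len(seq), sample=patient))
            for call in patient_calls:
                fh.write(variant_call_to_vcf_line(call) + "\n")
        paths[f"vcf:{patient}"] = vcf_path

    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("patient\tchrom\tpos\tref\talt\tclass\n")
        for (patient, key), cls in sorted(cohort.truth.items()):
            fh.write(f"{patient}\t{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t{cls}\n")
    paths["truth"] = truth_path

    for name, mset in [("cosmic", cohort.cosmic), ("dbsnp", cohort.dbsnp)] + [
        (s.name, s) for s in cohort.cohort_sets
    ]:
        p = outdir / f"{name}.tsv"
        write_membership_tsv(p, mset.keys)
        paths[name] = p

    cons_path = outdir / "consequences.tsv"
    with open(cons_path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tconsequences\n")
        for key in sorted(cohort.consequences):
            terms = ",".join(cohort.consequences[key])
            fh.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t{terms}\n")
    paths["consequences"] = cons_path
    return paths
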