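"""Deterministic synthetic fixtures: cohorts, trios, depth profiles, annotations.

Nothing here downloads or models real population genetics (no coalescent,
no linkage).  The generator targets the statistical structure the analyses
assume: per-gene Bernoulli carrier indicators with an odds-scale case
enrichment multiplier, Mendelian trios with planted novel genotypes, and
read-depth profiles built from homogeneous segments with geometric run
lengths so the coverage codec sees best, typical and worst cases.  Every
output is a small plain-text file and is byte-identical for a given seed.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError

CHROM = "1"
GENE_SPACING = 1000  # one gene per coverage block
GENE_OFFSET = 101
DNA = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# reference sequence
# ---------------------------------------------------------------------------


def random_reference(length: int, seed: int, run_rate: float = 0.02) -> str:
    """Random DNA with embedded homopolymer/STR runs (exercises left-alignment)."""
    rng = np.random.default_rng(seed)
    out: List[str] = []
    while len(out) < length:
        if rng.random() < run_rate:
            if rng.random() < 0.5:  # homopolymer
                out.extend(str(rng.choice(DNA)) * int(rng.integers(4, 12)))
            else:  # short tandem repeat
                unit = "".join(rng.choice(DNA, size=rng.integers(2, 4)))
                out.extend(unit * int(rng.integers(3, 6)))
        else:
            out.append(str(rng.choice(DNA)))
    return "".join(out[:length])


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Statistical recipe for a synthetic case-control cohort.

    Carrier indicators are drawn per gene per sample at
    ``baseline_carrier_rate``; for genes in ``enriched_genes`` the case
    probability is the baseline odds times the multiplier, back-transformed
    -- so a multiplier of 1 is the exact null.
    """

    n_cases: int = 25
    n_controls: int = 25
    n_genes: int = 10
    variants_per_gene: int = 3
    baseline_carrier_rate: float = 0.1
    enriched_genes: Mapping[str, float] = field(default_factory=dict)
    mean_depth: float = 60.0
    depth_run_mean: float = 150.0  # geometric mean segment length
    hom_fraction: float = 0.1  # carrier genotypes that are hom-alt
    qc_fail_gq: float = 0.05  # genotypes given a failing GQ
    common_variant_fraction: float = 0.2  # sites given a high external AF
    gene_length: int = 300
    seed: int = 0

    def __post_init__(self):
        for name in ("baseline_carrier_rate", "hom_fraction", "qc_fail_gq",
                     "common_variant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        for gene, mult in self.enriched_genes.items():
            odds = self.baseline_carrier_rate / (1 - self.baseline_carrier_rate)
            if mult < 0:
                raise ValidationError(f"negative multiplier for {gene}")
            if mult * odds / (1 + mult * odds) > 1:
                raise ValidationError(f"infeasible enrichment for {gene}")

    def case_rate(self, gene: str) -> float:
        mult = self.enriched_genes.get(gene, 1.0)
        odds = mult * self.baseline_carrier_rate / (1.0 - self.baseline_carrier_rate)
        return odds / (1.0 + odds)


def gene_name(i: int) -> str:
    return f"GENE{i + 1:04d}"


def gene_region(i: int, gene_length: int) -> Tuple[int, int]:
    start = i * GENE_SPACING + GENE_OFFSET
    return start, start + gene_length - 1


@dataclass
class CohortPaths:
    out_dir: str
    reference_fasta: str
    gene_model: str
    ped: str
    vcfs: Dict[str, str]
    depths: Dict[str, str]
    external_af_tsv: str
    intolerance_tsv: str
    manifest: str


# ---------------------------------------------------------------------------
# VCF / depth writers
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##source=atavlite-simulate
##contig=<ID={chrom},length={length}>
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
##INFO=<ID=VQSLOD,Number=1,Type=Float,Description="Variant quality score log-odds">
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: 'Allele|Effect|Gene|Transcript'">
##FILTER=<ID=LowQual,Description="Low quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


@dataclass
class VcfRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gt: str  # "0/1" | "1/1"
    gq: int
    dp: int
    ad: Tuple[int, int]
    qual: float
    qd: float
    mq: float
    vqslod: float
    effect: str
    gene: str
    transcript: str
    filter: str = "PASS"

    def line(self) -> str:
        info = (
            f"QD={self.qd:.2f};MQ={self.mq:.2f};VQSLOD={self.vqslod:.2f};"
            f"ANN={self.alt}|{self.effect}|{self.gene}|{self.transcript}"
        )
        return (
            f"{self.chrom}\t{self.pos}\t.\t{self.ref}\t{self.alt}\t{self.qual:.2f}\t"
            f"{self.filter}\t{info}\tGT:GQ:DP:AD\t"
            f"{self.gt}:{self.gq}:{self.dp}:{self.ad[0]},{self.ad[1]}"
        )


def write_vcf(path, sample_id: str, records: Sequence[VcfRecord], contig_length: int):
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=CHROM, length=contig_length, sample=sample_id))
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            fh.write(rec.line() + "\n")


def write_depth_bed(path, segments: Sequence[Tuple[str, int, int, int]]):
    """segments: (chrom, 0-based start, end, depth) homogeneous runs."""
    with open(path, "w") as fh:
        for chrom, start, end, depth in segments:
            fh.write(f"{chrom}\t{start}\t{end}\t{depth}\n")


def _depth_segments(
    rng, chrom: str, start_pos: int, end_pos: int, mean_depth: float, run_mean: float,
    floor: int = 0,
) -> List[Tuple[str, int, int, int]]:
    """Homogeneous depth segments with geometric run lengths over [start, end] (1-based)."""
    segments = []
    pos = start_pos
    while pos <= end_pos:
        run = int(rng.geometric(1.0 / run_mean))
        run = max(1, min(run, end_pos - pos + 1))
        depth = max(floor, int(round(rng.normal(mean_depth, mean_depth / 3.0))))
        segments.append((chrom, pos - 1, pos - 1 + run, depth))  # BED 0-based half-open
        pos += run
    return segments


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _pick_alt(rng, ref_base: str) -> str:
    choices = [b for b in "ACGT" if b != ref_base]
    return choices[int(rng.integers(0, 3))]


def generate_cohort(spec: CohortSpec, out_dir) -> CohortPaths:
    """Materialize a cohort: per-sample VCFs + depth BEDs + PED + truth manifest.

    The truth manifest records every planted carrier genotype and the
    enriched genes, so recovery can be scored exactly.
    """
    rng = np.random.default_rng(spec.seed)
    os.makedirs(out_dir, exist_ok=True)
    genome_length = spec.n_genes * GENE_SPACING + 2 * GENE_SPACING
    reference = random_reference(genome_length, int(rng.integers(0, 2**31)))
    genes = [gene_name(i) for i in range(spec.n_genes)]
    for g in spec.enriched_genes:
        if g not in genes:
            raise ValidationError(f"enriched gene {g!r} is outside the gene panel")

    # variant sites per gene (SNVs at distinct positions)
    sites: Dict[str, List[Tuple[int, str, str]]] = {}
    for i, gene in enumerate(genes):
        start, end = gene_region(i, spec.gene_length)
        positions = sorted(
            int(p) for p in rng.choice(
                np.arange(start, end + 1), size=spec.variants_per_gene, replace=False
            )
        )
        sites[gene] = [
            (p, reference[p - 1], _pick_alt(rng, reference[p - 1])) for p in positions
        ]

    # external annotations
    ext_af_rows, intol_rows = [], []
    for i, gene in enumerate(genes):
        intol_rows.append((gene, float(np.round(rng.uniform(-3, 3), 3))))
        for p, ref, alt in sites[gene]:
            common = rng.random() < spec.common_variant_fraction
            af = float(np.round(rng.uniform(0.05, 0.5), 4)) if common else 0.0
            ext_af_rows.append((f"{CHROM}-{p}-{ref}-{alt}", af))

    sample_ids = [f"CASE{i + 1:04d}" for i in range(spec.n_cases)] + [
        f"CTRL{i + 1:04d}" for i in range(spec.n_controls)
    ]
    is_case = [True] * spec.n_cases + [False] * spec.n_controls

    manifest = {
        "spec": {
            "n_cases": spec.n_cases, "n_controls": spec.n_controls,
            "n_genes": spec.n_genes, "baseline_carrier_rate": spec.baseline_carrier_rate,
            "enriched_genes": dict(spec.enriched_genes), "seed": spec.seed,
        },
        "genes": genes,
        "carriers": {},  # sample -> {gene: variant_id}
    }

    vcfs, depths = {}, {}
    for sid, case in zip(sample_ids, is_case):
        records: List[VcfRecord] = []
        carried: Dict[str, str] = {}
        for gene in genes:
            rate = spec.case_rate(gene) if case else spec.baseline_carrier_rate
            if rng.random() >= rate:
                continue
            p, ref, alt = sites[gene][int(rng.integers(0, len(sites[gene])))]
            hom = rng.random() < spec.hom_fraction
            dp = max(10, int(round(rng.normal(spec.mean_depth, 10))))
            alt_reads = int(rng.binomial(dp, 1.0 if hom else 0.5))
            gq = (
                int(rng.integers(2, 19))
                if rng.random() < spec.qc_fail_gq
                else int(rng.integers(60, 100))
            )
            records.append(
                VcfRecord(
                    chrom=CHROM, pos=p, ref=ref, alt=alt,
                    gt="1/1" if hom else "0/1", gq=gq, dp=dp,
                    ad=(dp - alt_reads, alt_reads),
                    qual=float(np.round(rng.uniform(100, 2000), 2)),
                    qd=float(np.round(rng.uniform(5, 35), 2)),
                    mq=float(np.round(rng.uniform(50, 60), 2)),
                    vqslod=float(np.round(rng.normal(8, 3), 2)),
                    effect="missense_variant", gene=gene, transcript=f"{gene}.t1",
                )
            )
            carried[gene] = f"{CHROM}-{p}-{ref}-{alt}"
        manifest["carriers"][sid] = carried

        vcf_path = os.path.join(out_dir, f"{sid}.vcf")
        write_vcf(vcf_path, sid, records, genome_length)
        vcfs[sid] = vcf_path

        segments = []
        for i in range(spec.n_genes):
            start, end = gene_region(i, spec.gene_length)
            segments.extend(
                _depth_segments(rng, CHROM, start - 50, end + 50, spec.mean_depth,
                                spec.depth_run_mean)
            )
        depth_path = os.path.join(out_dir, f"{sid}.depth.bed")
        write_depth_bed(depth_path, segments)
        depths[sid] = depth_path

    # support files
    fasta = os.path.join(out_dir, "reference.fa")
    write_fasta(fasta, {CHROM: reference})
    gene_model = os.path.join(out_dir, "genes.tsv")
    with open(gene_model, "w") as fh:
        fh.write("gene\tchrom\tstart\tend\ttranscript\n")
        for i, gene in enumerate(genes):
            start, end = gene_region(i, spec.gene_length)
            fh.write(f"{gene}\t{CHROM}\t{start}\t{end}\t{gene}.t1\n")
    ped = os.path.join(out_dir, "cohort.ped")
    with open(ped, "w") as fh:
        for sid, case in zip(sample_ids, is_case):
            fh.write(f"F_{sid}\t{sid}\t0\t0\t0\t{2 if case else 1}\n")
    ext_af = os.path.join(out_dir, "external_af.tsv")
    with open(ext_af, "w") as fh:
        fh.write("variant_id\texternal_af\n")
        for vid, af in ext_af_rows:
            fh.write(f"{vid}\t{af}\n")
    intol = os.path.join(out_dir, "intolerance.tsv")
    with open(intol, "w") as fh:
        fh.write("gene\tintolerance\n")
        for gene, score in intol_rows:
            fh.write(f"{gene}\t{score}\n")
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return CohortPaths(
        out_dir=str(out_dir), reference_fasta=fasta, gene_model=gene_model, ped=ped,
        vcfs=vcfs, depths=depths, external_af_tsv=ext_af, intolerance_tsv=intol,
        manifest=manifest_path,
    )


# ---------------------------------------------------------------------------
# matrix-level generation (for statistical calibration at scale)
# ---------------------------------------------------------------------------


def generate_carrier_matrix(
    n_genes: int,
    n_cases: int,
    n_controls: int,
    carrier_rate: float = 0.05,
    enriched: Optional[Mapping[int, float]] = None,
    global_case_multiplier: float = 1.0,
    seed: int = 0,
):
    """Draw a gene-by-individual carrier matrix directly from the cohort model.

    Same Bernoulli/odds-multiplier model as :func:`generate_cohort`, without
    file serialization -- used for calibration runs (e.g. null lambda at 500
    genes x 200 samples) where materializing VCFs adds nothing.
    ``global_case_multiplier`` > 1 plants a cohort-wide case excess, the
    signature of a case/control coverage artifact.  Returns
    (cells, is_case) with cells of shape (n_genes, n_cases+n_controls).
    """
    if not 0 < carrier_rate < 1:
        raise ValidationError("carrier_rate must be in (0,1)")
    rng = np.random.default_rng(seed)
    enriched = enriched or {}
    odds = carrier_rate / (1 - carrier_rate)
    case_rates = np.full(n_genes, carrier_rate)
    for gi, mult in enriched.items():
        case_rates[gi] = mult * odds / (1 + mult * odds)
    g_odds = case_rates / (1 - case_rates) * global_case_multiplier
    case_rates = g_odds / (1 + g_odds)
    if np.any(case_rates >= 1):
        raise ValidationError("infeasible enrichment (rate >= 1)")
    cases = rng.random((n_genes, n_cases)) < case_rates[:, None]
    controls = rng.random((n_genes, n_controls)) < carrier_rate
    cells = np.concatenate([cases, controls], axis=1).astype(np.int8)
    is_case = np.array([True] * n_cases + [False] * n_controls)
    return cells, is_case


# ---------------------------------------------------------------------------
# trio generation
# ---------------------------------------------------------------------------

TRIO_CATEGORIES = ("de_novo", "newly_comphet", "newly_hom", "mosaic_transmission")


def generate_trio(
    planted: Sequence[Mapping],
    out_dir,
    seed: int = 0,
    n_genes: int = 6,
    gene_length: int = 300,
    mean_depth: float = 60.0,
    low_coverage_sites: Optional[Mapping[str, Sequence[int]]] = None,
    n_background_inherited: int = 3,
) -> CohortPaths:
    """Build a trio (child CHILD, parents FATHER/MOTHER) with planted events.

    ``planted`` is a list of {"category": ..., "gene": ...} dicts, one gene
    per event.  Genotypes are Mendelian except at the planted sites; mosaic
    plants give the parent an alternate-allele fraction below the detection
    threshold.  ``low_coverage_sites`` maps a sample id to positions whose
    depth is forced under 10 (to downgrade findings to "possible").
    """
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)
    genome_length = n_genes * GENE_SPACING + 2 * GENE_SPACING
    reference = random_reference(genome_length, int(rng.integers(0, 2**31)))
    genes = [gene_name(i) for i in range(n_genes)]
    gene_of = {g: i for i, g in enumerate(genes)}
    used_genes = set()
    for event in planted:
        if event["category"] not in TRIO_CATEGORIES:
            raise ValidationError(f"unknown category {event['category']!r}")
        if event["gene"] not in gene_of:
            raise ValidationError(f"gene {event['gene']!r} outside the panel")
        if event["gene"] in used_genes:
            raise ValidationError(f"contradictory plants: gene {event['gene']} reused")
        used_genes.add(event["gene"])

    members = ("CHILD", "FATHER", "MOTHER")
    records: Dict[str, List[VcfRecord]] = {m: [] for m in members}
    manifest = {"seed": seed, "planted": []}

    def fresh_site(gene: str, taken: set) -> Tuple[int, str, str]:
        start, end = gene_region(gene_of[gene], gene_length)
        while True:
            p = int(rng.integers(start, end + 1))
            if p not in taken:
                taken.add(p)
                return p, reference[p - 1], _pick_alt(rng, reference[p - 1])

    def make_record(sample, pos, ref, alt, gene, gt, aaf=0.5) -> VcfRecord:
        dp = max(12, int(round(rng.normal(mean_depth, 8))))
        alt_reads = max(1, int(rng.binomial(dp, aaf)))
        return VcfRecord(
            chrom=CHROM, pos=pos, ref=ref, alt=alt, gt=gt,
            gq=int(rng.integers(60, 100)), dp=dp, ad=(dp - alt_reads, alt_reads),
            qual=float(np.round(rng.uniform(200, 2000), 2)),
            qd=float(np.round(rng.uniform(10, 30), 2)),
            mq=float(np.round(rng.uniform(55, 60), 2)),
            vqslod=float(np.round(rng.normal(10, 2), 2)),
            effect="missense_variant", gene=gene, transcript=f"{gene}.t1",
        )

    taken: set = set()
    for event in planted:
        gene = event["gene"]
        category = event["category"]
        if category == "de_novo":
            p, ref, alt = fresh_site(gene, taken)
            records["CHILD"].append(make_record("CHILD", p, ref, alt, gene, "0/1"))
            manifest["planted"].append(
                {"category": category, "gene": gene, "variants": [f"{CHROM}-{p}-{ref}-{alt}"]}
            )
        elif category == "newly_hom":
            p, ref, alt = fresh_site(gene, taken)
            records["CHILD"].append(make_record("CHILD", p, ref, alt, gene, "1/1", aaf=1.0))
            records["FATHER"].append(make_record("FATHER", p, ref, alt, gene, "0/1"))
            records["MOTHER"].append(make_record("MOTHER", p, ref, alt, gene, "0/1"))
            manifest["planted"].append(
                {"category": category, "gene": gene, "variants": [f"{CHROM}-{p}-{ref}-{alt}"]}
            )
        elif category == "newly_comphet":
            p1, r1, a1 = fresh_site(gene, taken)
            p2, r2, a2 = fresh_site(gene, taken)
            records["CHILD"].append(make_record("CHILD", p1, r1, a1, gene, "0/1"))
            records["CHILD"].append(make_record("CHILD", p2, r2, a2, gene, "0/1"))
            records["FATHER"].append(make_record("FATHER", p1, r1, a1, gene, "0/1"))
            records["MOTHER"].append(make_record("MOTHER", p2, r2, a2, gene, "0/1"))
            pair = sorted([f"{CHROM}-{p1}-{r1}-{a1}", f"{CHROM}-{p2}-{r2}-{a2}"])
            manifest["planted"].append({"category": category, "gene": gene, "variants": pair})
        else:  # mosaic_transmission
            p, ref, alt = fresh_site(gene, taken)
            records["CHILD"].append(make_record("CHILD", p, ref, alt, gene, "0/1"))
            parent = "FATHER" if rng.random() < 0.5 else "MOTHER"
            rec = make_record(parent, p, ref, alt, gene, "0/1", aaf=0.10)
            dp = max(20, rec.dp)
            alt_reads = max(3, min(int(round(0.10 * dp)), int(0.19 * dp)))
            rec.dp, rec.ad = dp, (dp - alt_reads, alt_reads)
            records[parent].append(rec)
            manifest["planted"].append(
                {"category": category, "gene": gene, "parent": parent,
                 "variants": [f"{CHROM}-{p}-{ref}-{alt}"]}
            )

    # background inherited hets in unused genes: child het, one parent het
    free_genes = [g for g in genes if g not in used_genes]
    for gene in free_genes[:n_background_inherited]:
        p, ref, alt = fresh_site(gene, taken)
        parent = "FATHER" if rng.random() < 0.5 else "MOTHER"
        records["CHILD"].append(make_record("CHILD", p, ref, alt, gene, "0/1"))
        records[parent].append(make_record(parent, p, ref, alt, gene, "0/1"))

    low_coverage_sites = low_coverage_sites or {}
    vcfs, depths = {}, {}
    for m in members:
        vcf_path = os.path.join(out_dir, f"{m}.vcf")
        write_vcf(vcf_path, m, records[m], genome_length)
        vcfs[m] = vcf_path
        segments = []
        for i in range(n_genes):
            start, end = gene_region(i, gene_length)
            segments.extend(
                _depth_segments(rng, CHROM, start - 50, end + 50, mean_depth, 150.0,
                                floor=15)
            )
        # force requested sites under the sufficiency threshold
        forced = set(low_coverage_sites.get(m, ()))
        if forced:
            adjusted = []
            for chrom, s, e, depth in segments:
                run_sites = [p for p in forced if s + 1 <= p <= e]
                if not run_sites:
                    adjusted.append((chrom, s, e, depth))
                    continue
                cut = sorted(run_sites)
                prev = s
                for p in cut:
                    if p - 1 > prev:
                        adjusted.append((chrom, prev, p - 1, depth))
                    adjusted.append((chrom, p - 1, p, 5))
                    prev = p
                if e > prev:
                    adjusted.append((chrom, prev, e, depth))
            segments = adjusted
        depth_path = os.path.join(out_dir, f"{m}.depth.bed")
        write_depth_bed(depth_path, segments)
        depths[m] = depth_path

    fasta = os.path.join(out_dir, "reference.fa")
    write_fasta(fasta, {CHROM: reference})
    gene_model = os.path.join(out_dir, "genes.tsv")
    with open(gene_model, "w") as fh:
        fh.write("gene\tchrom\tstart\tend\ttranscript\n")
        for i, gene in enumerate(genes):
            start, end = gene_region(i, gene_length)
            fh.write(f"{gene}\t{CHROM}\t{start}\t{end}\t{gene}.t1\n")
    ped = os.path.join(out_dir, "trio.ped")
    with open(ped, "w") as fh:
        fh.write("FAM1\tCHILD\tFATHER\tMOTHER\t1\t2\n")
        fh.write("FAM1\tFATHER\t0\t0\t1\t1\n")
        fh.write("FAM1\tMOTHER\t0\t0\t2\t1\n")
    ext_af = os.path.join(out_dir, "external_af.tsv")
    with open(ext_af, "w") as fh:
        fh.write("variant_id\texternal_af\n")
        seen = set()
        for m in members:
            for rec in records[m]:
                vid = f"{rec.chrom}-{rec.pos}-{rec.ref}-{rec.alt}"
                if vid not in seen:
                    seen.add(vid)
                    fh.write(f"{vid}\t0.0\n")
    intol = os.path.join(out_dir, "intolerance.tsv")
    with open(intol, "w") as fh:
        fh.write("gene\tintolerance\n")
        for gene in genes:
            fh.write(f"{gene}\t0.0\n")
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return CohortPaths(
        out_dir=str(out_dir), reference_fasta=fasta, gene_model=gene_model, ped=ped,
        vcfs=vcfs, depths=depths, external_af_tsv=ext_af, intolerance_tsv=intol,
        manifest=manifest_path,
    )


def sha256_of_outputs(paths: CohortPaths) -> str:
    """Single digest over every generated file (determinism checks)."""
    h = hashlib.sha256()
    files = [paths.reference_fasta, paths.gene_model, paths.ped,
             paths.external_af_tsv, paths.intolerance_tsv, paths.manifest]
    files += [paths.vcfs[k] for k in sorted(paths.vcfs)]
    files += [paths.depths[k] for k in sorted(paths.depths)]
    for f in files:
        with open(f, "rb") as fh:
            h.update(os.path.basename(f).encode())
            h.update(fh.read())
    return h.hexdigest()
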