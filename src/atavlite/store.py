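"""Embedded variant warehouse.

Single-sample VCFs are ingested into one sqlite file holding a universal
(deduplicated, normalized) variant list, per-sample genotype calls with
their quality metrics, and binned run-length coverage.  Region/gene queries
return variant objects that account for *every* cohort sample: a called
genotype, a coverage-inferred hom-ref (bin >= b, i.e. depth >= 10, at the
site), or an explicit no-data marker.  This is what lets analyses run on
cohorts that were never joint-called.
"""

from __future__ import annotations

import hashlib
import sqlite3
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import pysam

from .annotation import AnnotationTable, GeneModel
from .coverage import CoverageStore
from .errors import (
    IntegrityError,
    MultiSampleVCFError,
    ValidationError,
)
from .normalize import NormalizedVariant, normalize_variant
from .ped import SampleRecord

HOM_REF_MIN_DEPTH = 10  # bin >= b; reused by the trio "possibly" logic


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's called genotype at one normalized variant."""

    sample_id: str
    variant_id: str
    zygosity: str  # "het" | "hom_alt"
    gq: Optional[float] = None
    qual: Optional[float] = None
    qd: Optional[float] = None
    mq: Optional[float] = None
    vqslod: Optional[float] = None
    dp: Optional[int] = None
    ad_ref: Optional[int] = None
    ad_alt: Optional[int] = None
    filter: str = "PASS"

    def __post_init__(self):
        if self.zygosity not in ("het", "hom_alt"):
            raise ValidationError(f"zygosity must be het|hom_alt, got {self.zygosity!r}")
        for name in ("gq", "qual", "dp", "ad_ref", "ad_alt"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")

    @property
    def alt_allele_fraction(self) -> Optional[float]:
        if self.ad_ref is None or self.ad_alt is None or (self.ad_ref + self.ad_alt) == 0:
            return None
        return self.ad_alt / (self.ad_ref + self.ad_alt)

    @property
    def passes_filter(self) -> bool:
        return self.filter in ("PASS", ".", "")


@dataclass
class AlleleFrequency:
    """Internal cohort allele accounting at one site.

    ``af`` is None (undefined, never 0) when no sample carries genotype
    information at the site.
    """

    af: Optional[float]
    n_het: int
    n_hom_alt: int
    n_informative: int  # called + coverage-inferred hom-ref

    @property
    def allele_count(self) -> int:
        return self.n_het + 2 * self.n_hom_alt

    @property
    def maf(self) -> Optional[float]:
        return None if self.af is None else min(self.af, 1.0 - self.af)

    @property
    def genotype_frequency(self) -> Optional[float]:
        if self.n_informative == 0:
            return None
        return (self.n_het + self.n_hom_alt) / self.n_informative


def af_from_counts(n_het: int, n_hom_alt: int, n_informative: int) -> AlleleFrequency:
    """AF = (het + 2*hom_alt) / (2 * informative diploid samples)."""
    if min(n_het, n_hom_alt, n_informative) < 0:
        raise ValidationError("genotype counts must be >= 0")
    if n_het + n_hom_alt > n_informative:
        raise ValidationError("more carriers than informative samples")
    af = None
    if n_informative > 0:
        af = (n_het + 2 * n_hom_alt) / (2 * n_informative)
    return AlleleFrequency(af, n_het, n_hom_alt, n_informative)


@dataclass
class AnnotatedVariantObject:
    """Everything an analysis needs about one variant in one cohort.

    The three sample partitions (calls / inferred hom-ref / no-data) always
    cover the query cohort exactly once each.
    """

    variant: NormalizedVariant
    effect: str = ""
    gene: str = ""
    transcript: str = ""
    calls: List[GenotypeCall] = field(default_factory=list)
    inferred_hom_ref: Set[str] = field(default_factory=set)
    no_data: Set[str] = field(default_factory=set)
    external: Dict[str, object] = field(default_factory=dict)

    @property
    def frequency(self) -> AlleleFrequency:
        n_het = sum(1 for c in self.calls if c.zygosity == "het")
        n_hom = sum(1 for c in self.calls if c.zygosity == "hom_alt")
        return af_from_counts(n_het, n_hom, len(self.calls) + len(self.inferred_hom_ref))

    def call_for(self, sample_id: str) -> Optional[GenotypeCall]:
        for c in self.calls:
            if c.sample_id == sample_id:
                return c
        return None


@dataclass
class IngestSummary:
    sample_id: str
    variants_added: int = 0
    calls_added: int = 0
    duplicates_merged: int = 0  # calls whose variant already existed
    skipped_no_gt: int = 0


Region = Tuple[str, int, int]


def parse_region(region: Union[str, Region]) -> Region:
    """'chrom:start-end' (1-based inclusive) -> (chrom, start, end)."""
    if isinstance(region, tuple):
        chrom, start, end = region
    else:
        try:
            chrom, span = region.rsplit(":", 1)
            start_s, end_s = span.split("-")
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ValidationError(f"bad region {region!r}, expected chrom:start-end") from None
    if start < 1 or end < start:
        raise ValidationError(f"bad region bounds {start}-{end}")
    return chrom, start, end


class VariantStore:
    """Sqlite-backed variant + call + coverage store for one cohort."""

    SCHEMA = """
    CREATE TABLE IF NOT EXISTS variants (
        variant_id TEXT PRIMARY KEY,
        chrom TEXT NOT NULL, pos INTEGER NOT NULL,
        ref TEXT NOT NULL, alt TEXT NOT NULL,
        effect TEXT DEFAULT '', gene TEXT DEFAULT '', transcript TEXT DEFAULT ''
    );
    CREATE INDEX IF NOT EXISTS idx_variants_locus ON variants (chrom, pos);
    CREATE TABLE IF NOT EXISTS calls (
        sample_id TEXT NOT NULL, variant_id TEXT NOT NULL,
        zygosity TEXT NOT NULL,
        gq REAL, qual REAL, qd REAL, mq REAL, vqslod REAL,
        dp INTEGER, ad_ref INTEGER, ad_alt INTEGER,
        filter TEXT DEFAULT 'PASS',
        PRIMARY KEY (sample_id, variant_id)
    );
    CREATE TABLE IF NOT EXISTS ingested_samples (
        sample_id TEXT PRIMARY KEY, source TEXT, n_calls INTEGER
    );
    """

    def __init__(self, path: str = ":memory:", gene_model: Optional[GeneModel] = None):
        self.path = path
        self.conn = sqlite3.connect(path)
        self.conn.executescript(self.SCHEMA)
        self.coverage = CoverageStore(self.conn)
        self.gene_model = gene_model
        self.annotation_tables: List[AnnotationTable] = []

    def close(self):
        self.conn.close()

    # -- annotation attachment ------------------------------------------------

    def attach_annotation(self, table: AnnotationTable) -> None:
        self.annotation_tables.append(table)

    @property
    def annotation_columns(self) -> List[str]:
        cols: List[str] = []
        for t in self.annotation_tables:
            cols.extend(t.value_columns)
        return cols

    # -- ingest ---------------------------------------------------------------

    def ingest_sample_vcf(
        self,
        path,
        reference: Mapping[str, str],
        sample_id: Optional[str] = None,
    ) -> IngestSummary:
        """Load one single-sample VCF.

        ``reference`` maps chrom -> sequence (a dict or a pyfaidx.Fasta) and
        is required for indel left-alignment.  Multi-allelic rows are
        decomposed per alt before normalization.  Re-ingesting a sample id
        already in the store is rejected.
        """
        vcf = pysam.VariantFile(str(path))
        header_samples = list(vcf.header.samples)
        if len(header_samples) != 1:
            raise MultiSampleVCFError(
                f"{path} has {len(header_samples)} sample columns; the store takes "
                "one single-sample VCF per sample (split with `bcftools +split`)"
            )
        sid = sample_id or header_samples[0]
        if self.conn.execute(
            "SELECT 1 FROM ingested_samples WHERE sample_id=?", (sid,)
        ).fetchone():
            raise IntegrityError(f"sample {sid!r} is already in the store")

        summary = IngestSummary(sample_id=sid)
        ref_cache: Dict[str, str] = {}
        for rec in vcf:
            gt = rec.samples[0].get("GT")
            if gt is None or all(a is None for a in gt):
                summary.skipped_no_gt += 1
                continue
            chrom = rec.chrom
            if chrom not in ref_cache:
                seq = reference[chrom]
                ref_cache[chrom] = str(seq[:]) if not isinstance(seq, str) else seq
            window = ref_cache[chrom]
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                if set(alt.upper()) - set("ACGT"):
                    continue  # symbolic / spanning-deletion alleles
                n_alt = sum(1 for a in gt if a == alt_index)
                if n_alt == 0:
                    continue
                zygosity = "hom_alt" if n_alt == 2 else "het"
                nv = normalize_variant(chrom, rec.pos, rec.ref, alt, window)
                ann = _match_ann(rec, alt)
                added = self._upsert_variant(nv, *ann)
                summary.variants_added += added
                summary.duplicates_merged += 1 - added
                self._insert_call(sid, nv.variant_id, zygosity, rec, alt_index)
                summary.calls_added += 1
        self.conn.execute(
            "INSERT INTO ingested_samples VALUES (?,?,?)",
            (sid, str(path), summary.calls_added),
        )
        self.conn.commit()
        return summary

    def _upsert_variant(self, nv: NormalizedVariant, effect, gene, transcript) -> int:
        cur = self.conn.execute(
            "INSERT OR IGNORE INTO variants VALUES (?,?,?,?,?,?,?,?)",
            (nv.variant_id, nv.chrom, nv.pos, nv.ref, nv.alt, effect, gene, transcript),
        )
        return cur.rowcount

    def _insert_call(self, sid, variant_id, zygosity, rec, alt_index):
        sample = rec.samples[0]
        ad = sample.get("AD")
        ad_ref = ad_alt = None
        if ad is not None and len(ad) > alt_index and ad[0] is not None:
            ad_ref, ad_alt = ad[0], ad[alt_index]
        filt = ";".join(rec.filter.keys()) or "."
        self.conn.execute(
            "INSERT OR REPLACE INTO calls VALUES (?,?,?,?,?,?,?,?,?,?,?,?)",
            (
                sid, variant_id, zygosity,
                sample.get("GQ"), rec.qual,
                _info_get(rec, "QD"), _info_get(rec, "MQ"), _info_get(rec, "VQSLOD"),
                sample.get("DP"), ad_ref, ad_alt, filt,
            ),
        )

    # -- queries --------------------------------------------------------------

    @property
    def n_variants(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM variants").fetchone()[0]

    @property
    def sample_ids(self) -> List[str]:
        return [r[0] for r in self.conn.execute("SELECT sample_id FROM ingested_samples")]

    def get_variant(self, variant_id: str) -> Optional[NormalizedVariant]:
        row = self.conn.execute(
            "SELECT chrom,pos,ref,alt FROM variants WHERE variant_id=?", (variant_id,)
        ).fetchone()
        return NormalizedVariant(row[0], row[1], row[2], row[3]) if row else None

    def query_region(
        self,
        samples: Sequence[SampleRecord],
        region: Union[str, Region, None] = None,
        gene: Optional[str] = None,
        min_depth: int = HOM_REF_MIN_DEPTH,
    ) -> List[AnnotatedVariantObject]:
        """Variant objects in a region or gene, complete over the cohort.

        Samples without a call become inferred hom-ref when sufficiently
        covered (default bin >= b / depth >= 10), otherwise no-data.
        """
        if gene is not None:
            if self.gene_model is None:
                raise ValidationError("gene queries need a gene model")
            gr = self.gene_model.resolve(gene)
            chrom, start, end = gr.chrom, gr.start, gr.end
        elif region is not None:
            chrom, start, end = parse_region(region)
        else:
            raise ValidationError("query_region needs a region or a gene")

        rows = self.conn.execute(
            "SELECT variant_id, chrom, pos, ref, alt, effect, gene, transcript "
            "FROM variants WHERE chrom=? AND pos BETWEEN ? AND ? ORDER BY pos, ref, alt",
            (chrom, start, end),
        ).fetchall()
        sample_ids = [s.sample_id for s in samples]
        out = []
        for vid, vchrom, pos, ref, alt, effect, vgene, tx in rows:
            nv = NormalizedVariant(vchrom, pos, ref, alt)
            obj = AnnotatedVariantObject(nv, effect=effect, gene=vgene, transcript=tx)
            called = set()
            for crow in self.conn.execute(
                "SELECT sample_id, zygosity, gq, qual, qd, mq, vqslod, dp, ad_ref, "
                "ad_alt, filter FROM calls WHERE variant_id=?",
                (vid,),
            ):
                if crow[0] not in sample_ids:
                    continue
                obj.calls.append(GenotypeCall(crow[0], vid, *crow[1:]))
                called.add(crow[0])
            for sid in sample_ids:
                if sid in called:
                    continue
                if self.coverage.is_sufficiently_covered(sid, vchrom, pos, min_depth):
                    obj.inferred_hom_ref.add(sid)
                else:
                    obj.no_data.add(sid)
            for table in self.annotation_tables:
                obj.external.update(table.lookup(nv, gene=vgene or None))
            out.append(obj)
        return out

    def query_genes(
        self, samples: Sequence[SampleRecord], genes: Iterable[str]
    ) -> Dict[str, List[AnnotatedVariantObject]]:
        return {g: self.query_region(samples, gene=g) for g in genes}

    def internal_af(
        self, variant_id: str, samples: Sequence[SampleRecord]
    ) -> AlleleFrequency:
        """Cohort allele frequency at one stored variant site."""
        nv = self.get_variant(variant_id)
        if nv is None:
            raise ValidationError(f"unknown variant {variant_id!r}")
        objs = self.query_region(samples, (nv.chrom, nv.pos, nv.pos))
        for obj in objs:
            if obj.variant.variant_id == variant_id:
                return obj.frequency
        raise ValidationError(f"variant {variant_id!r} vanished from its own site")

    # -- exports --------------------------------------------------------------

    def export_multi_sample_vcf(self, samples, region, out_path) -> int:
        """Write query_region results as a multi-sample VCF.

        Inferred hom-ref genotypes become 0/0, no-data becomes ./. .
        Returns the number of variant rows written.
        """
        objs = self.query_region(samples, region)
        sample_ids = [s.sample_id for s in samples]
        chroms = sorted({o.variant.chrom for o in objs}) or [parse_region(region)[0]]
        with open(out_path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n##source=atavlite\n")
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(sample_ids) + "\n")
            for obj in objs:
                v = obj.variant
                gts = []
                by_sample = {c.sample_id: c for c in obj.calls}
                for sid in sample_ids:
                    if sid in by_sample:
                        gts.append("0/1" if by_sample[sid].zygosity == "het" else "1/1")
                    elif sid in obj.inferred_hom_ref:
                        gts.append("0/0")
                    else:
                        gts.append("./.")
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                    + "\t".join(gts) + "\n"
                )
        return len(objs)

    def export_ped_map(self, samples, region, out_prefix) -> Tuple[str, str]:
        """Write PLINK PED/MAP text files for a region; returns their paths."""
        objs = self.query_region(samples, region)
        map_path, ped_path = f"{out_prefix}.map", f"{out_prefix}.ped"
        with open(map_path, "w") as fh:
            for obj in objs:
                v = obj.variant
                fh.write(f"{v.chrom}\t{v.variant_id}\t0\t{v.pos}\n")
        with open(ped_path, "w") as fh:
            for s in samples:
                pairs = []
                for obj in objs:
                    v = obj.variant
                    call = obj.call_for(s.sample_id)
                    if call is not None:
                        if call.zygosity == "het":
                            pairs.append(f"{v.ref} {v.alt}")
                        else:
                            pairs.append(f"{v.alt} {v.alt}")
                    elif s.sample_id in obj.inferred_hom_ref:
                        pairs.append(f"{v.ref} {v.ref}")
                    else:
                        pairs.append("0 0")
                fh.write(
                    f"{s.family_id}\t{s.sample_id}\t{s.paternal_id}\t{s.maternal_id}"
                    f"\t{s.sex}\t{s.phenotype}\t" + "\t".join(pairs) + "\n"
                )
        return ped_path, map_path

    # -- integrity ------------------------------------------------------------

    def digest(self) -> str:
        """Deterministic content hash of the store (variants, calls, coverage)."""
        h = hashlib.sha256()
        for table, order in (
            ("variants", "variant_id"),
            ("calls", "sample_id, variant_id"),
            ("coverage", "sample_id, chrom, block_index"),
        ):
            for row in self.conn.execute(f"SELECT * FROM {table} ORDER BY {order}"):
                h.update(repr(row).encode())
        return h.hexdigest()


def _info_get(rec, key):
    """INFO accessor tolerant of fields absent from the header."""
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _match_ann(rec, alt: str) -> Tuple[str, str, str]:
    """Pull (effect, gene, transcript) for one alt from an ANN/EFF-style INFO field."""
    ann = _info_get(rec, "ANN")
    if ann is None:
        return "", "", ""
    if isinstance(ann, str):
        ann = (ann,)
    for entry in ann:
        parts = entry.split("|")
        if parts and parts[0] == alt:
            effect = parts[1] if len(parts) > 1 else ""
            gene = parts[2] if len(parts) > 2 else ""
            tx = parts[3] if len(parts) > 3 else ""
            return effect, gene, tx
    return "", "", ""
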