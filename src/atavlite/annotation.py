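"""External annotations and the KnownVar clinical aggregation.

External resources (population allele frequencies, intolerance and
pathogenicity scores, clinical assertions) are modeled as schema-declared
TSV tables at one of three key levels:

* ``gene``    -- keyed by gene symbol
* ``site``    -- keyed by (chrom, pos); applies to every alt at the site
* ``variant`` -- keyed by variant_id (chrom-pos-ref-alt)

Joins are total and side-effect free: a variant missing from a table simply
gets nulls.  KnownVar aggregates clinical variant/disease assertions and is
queried in three labeled tiers: exact variant match, same-site different-alt
match, and proximity match within a configurable window.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .errors import AnnotationError, GeneLookupError, ValidationError
from .normalize import NormalizedVariant

_LEVELS = ("gene", "site", "variant")
_KEYS = {"gene": ["gene"], "site": ["chrom", "pos"], "variant": ["variant_id"]}


class AnnotationTable:
    """One external annotation resource loaded from TSV.

    The first line is a header; key columns are implied by ``level`` (gene /
    chrom+pos / variant_id), every other column is a value column.  An
    optional ``schema`` maps value-column names to 'float' or 'str' and is
    validated against the header.
    """

    def __init__(self, name: str, level: str, df: pd.DataFrame):
        if level not in _LEVELS:
            raise ValidationError(f"level must be one of {_LEVELS}, got {level!r}")
        self.name = name
        self.level = level
        keys = _KEYS[level]
        missing = [k for k in keys if k not in df.columns]
        if missing:
            raise AnnotationError(f"{name}: missing key column(s) {missing}")
        dup = df[df.duplicated(subset=keys, keep=False)]
        if len(dup):
            offending = dup[keys].iloc[0].tolist()
            raise AnnotationError(f"{name}: duplicate key {offending}")
        self.df = df.set_index(keys)
        self.value_columns = [c for c in df.columns if c not in keys]

    @classmethod
    def load(cls, path, level: str, name: Optional[str] = None, schema=None):
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
        if schema is not None:
            declared = set(schema) | set(_KEYS[level])
            if set(df.columns) != declared:
                raise AnnotationError(
                    f"{path}: header {sorted(df.columns)} does not match "
                    f"declared schema {sorted(declared)}"
                )
            for col, kind in schema.items():
                if kind == "float":
                    df[col] = pd.to_numeric(df[col], errors="raise")
        return cls(name or str(path), level, df)

    def _key_for(self, variant: NormalizedVariant, gene: Optional[str]):
        if self.level == "gene":
            return gene
        if self.level == "site":
            return (variant.chrom, variant.pos)
        return variant.variant_id

    def lookup(self, variant: NormalizedVariant, gene: Optional[str] = None) -> dict:
        """Value dict for one variant; explicit None for unmatched keys."""
        key = self._key_for(variant, gene)
        if key is None or key not in self.df.index:
            return {c: None for c in self.value_columns}
        row = self.df.loc[key]
        return {c: (None if pd.isna(row[c]) else row[c]) for c in self.value_columns}


def load_annotation_table(path, level: str, schema=None, name=None) -> AnnotationTable:
    """Module-level convenience wrapper over :meth:`AnnotationTable.load`."""
    return AnnotationTable.load(path, level, name=name, schema=schema)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRegion:
    gene: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    transcript: str = ""


class GeneModel:
    """Plain-TSV gene model (gene, chrom, start, end, transcript)."""

    def __init__(self, regions: Sequence[GeneRegion]):
        self._by_gene: Dict[str, GeneRegion] = {}
        for r in regions:
            if r.gene in self._by_gene:
                raise AnnotationError(f"duplicate gene {r.gene!r} in gene model")
            self._by_gene[r.gene] = r

    @classmethod
    def load(cls, path) -> "GeneModel":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        needed = {"gene", "chrom", "start", "end"}
        if not needed.issubset(df.columns):
            raise AnnotationError(f"gene model needs columns {sorted(needed)}")
        return cls(
            [
                GeneRegion(
                    row.gene, row.chrom, int(row.start), int(row.end),
                    getattr(row, "transcript", "") or "",
                )
                for row in df.itertuples()
            ]
        )

    def __contains__(self, gene: str) -> bool:
        return gene in self._by_gene

    def __iter__(self):
        return iter(self._by_gene.values())

    @property
    def genes(self) -> List[str]:
        return list(self._by_gene)

    def resolve(self, gene: str) -> GeneRegion:
        try:
            return self._by_gene[gene]
        except KeyError:
            near = difflib.get_close_matches(gene, self._by_gene, n=3)
            raise GeneLookupError(gene, near) from None

    def genes_overlapping(self, chrom: str, pos: int) -> List[str]:
        return [
            r.gene for r in self._by_gene.values()
            if r.chrom == chrom and r.start <= pos <= r.end
        ]


# ---------------------------------------------------------------------------
# KnownVar
# ---------------------------------------------------------------------------


@dataclass
class KnownVarTiers:
    """Result of a KnownVar lookup, clinical assertions in three tiers.

    ``proximity`` holds every record within the window around the query
    position except exact matches, so with window 0 it reduces to the
    same-site tier.
    """

    exact: List[dict] = field(default_factory=list)
    same_site: List[dict] = field(default_factory=list)
    proximity: List[dict] = field(default_factory=list)
    gene: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "exact": self.exact,
            "same_site": self.same_site,
            "proximity": self.proximity,
            "gene": self.gene,
        }


class KnownVar:
    """Clinical variant/disease assertions aggregated from several sources.

    Variant-level TSV columns: variant_id, disease, clinical_significance,
    variant_class, pubmed_ids (comma-separated), source, inheritance.
    Gene-level TSV columns: gene, n_pathogenic_cnv, n_pathogenic_indel,
    n_pathogenic_splice, n_pathogenic_nonsense, n_pathogenic_missense,
    inheritance, dosage_sensitivity.  Conflicting sources are reported side
    by side, never merged.
    """

    def __init__(self, variant_df: pd.DataFrame, gene_df: Optional[pd.DataFrame] = None):
        if "variant_id" not in variant_df.columns:
            raise AnnotationError("KnownVar variant table needs a variant_id column")
        parts = variant_df["variant_id"].str.rsplit("-", n=3, expand=True)
        variant_df = variant_df.copy()
        variant_df["chrom"] = parts[0].astype(str)
        variant_df["pos"] = parts[1].astype(int)
        self.variant_df = variant_df
        if gene_df is not None and "gene" not in gene_df.columns:
            raise AnnotationError("KnownVar gene table needs a gene column")
        self.gene_df = gene_df.set_index("gene") if gene_df is not None else None

    @classmethod
    def load(cls, variant_tsv, gene_tsv=None) -> "KnownVar":
        vdf = pd.read_csv(variant_tsv, sep="\t", dtype=str)
        gdf = pd.read_csv(gene_tsv, sep="\t") if gene_tsv is not None else None
        return cls(vdf, gdf)

    def annotate(
        self, variant: NormalizedVariant, window_bp: int = 10, gene: Optional[str] = None
    ) -> KnownVarTiers:
        """Three-tier lookup around one variant (see :class:`KnownVarTiers`)."""
        if window_bp < 0:
            raise ValidationError("window_bp must be >= 0")
        df = self.variant_df
        near = df[
            (df["chrom"] == variant.chrom)
            & (df["pos"] - variant.pos).abs().le(window_bp)
        ]
        same_pos = df[(df["chrom"] == variant.chrom) & (df["pos"] == variant.pos)]
        tiers = KnownVarTiers()
        drop = ["chrom", "pos"]
        for rec in same_pos.drop(columns=drop).to_dict("records"):
            if rec["variant_id"] == variant.variant_id:
                tiers.exact.append(rec)
            else:
                tiers.same_site.append(rec)
        for rec in near.drop(columns=drop).to_dict("records"):
            if rec["variant_id"] != variant.variant_id:
                tiers.proximity.append(rec)
        if self.gene_df is not None and gene is not None and gene in self.gene_df.index:
            tiers.gene = self.gene_df.loc[gene].to_dict()
        return tiers


def knownvar_annotate(
    knownvar: KnownVar, variant: NormalizedVariant, window_bp: int = 10, gene=None
) -> KnownVarTiers:
    return knownvar.annotate(variant, window_bp=window_bp, gene=gene)
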