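"""Rare-variant collapsing association workflow.

A collapsing analysis asks whether cases carry an excess of *qualifying
variants* (QVs) in a gene compared to controls.  The steps implemented
here:

1. QV selection: per-genotype quality filters (QUAL, GQ, QD, MQ, VQSLOD),
   per-variant annotation filters (effect, scores) and internal/external
   minor-allele-frequency bounds.
2. Case-control coverage harmonization: drop sites where depth sufficiency
   differs systematically between cases and controls (proportion-difference
   test or exact binomial test), preventing coverage-driven associations.
3. Gene-by-individual 0/1 collapsing matrix under a dominant (>=1 QV) or
   recessive (hom-alt QV, or >=2 distinct het QVs) model.
4. Per-gene two-sided Fisher's exact test on the carrier 2x2 table, and
   optionally Firth penalized logistic regression.
5. Permutation-based genomic inflation factor and QQ data: the expected
   p-value distribution is the mean order statistic over case/control label
   permutations, and lambda is the ratio of median chi-square(1) quantiles
   of observed vs expected p.
6. "collapsing-lite": rerun any strictly tighter filter configuration from
   a previous run's QV table without touching the variant store.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import binomtest, chi2, fisher_exact, hypergeom

from .errors import ConfigOrderError, ConfigurationError, ValidationError
from .firth import FirthResult, firth_logistic
from .ped import SampleRecord
from .store import AnnotatedVariantObject, VariantStore

log = logging.getLogger(__name__)

MODELS = ("dominant", "recessive")

#: quality metrics filtered per genotype, each a (config attr, call column)
_QUALITY_MINIMA = (
    ("min_qual", "qual"),
    ("min_gq", "gq"),
    ("min_qd", "qd"),
    ("min_mq", "mq"),
    ("min_vqslod", "vqslod"),
)


@dataclass(frozen=True)
class ScoreThreshold:
    """Keep a variant iff score `direction` cutoff (min: >=, max: <=)."""

    score: str
    direction: str  # "min" | "max"
    cutoff: float

    def __post_init__(self):
        if self.direction not in ("min", "max"):
            raise ValidationError(f"direction must be min|max, got {self.direction!r}")

    def passes(self, value) -> bool:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return False  # un-scored variants fail an explicit score filter
        return value >= self.cutoff if self.direction == "min" else value <= self.cutoff


@dataclass(frozen=True)
class QVConfig:
    """The full qualifying-variant filter set.

    Unset (None) filters pass everything.  ``score_thresholds`` reference
    value columns of attached annotation tables by name; referencing an
    unknown score is a configuration error, never a silent pass.
    """

    min_qual: Optional[float] = None
    min_gq: Optional[float] = None
    min_qd: Optional[float] = None
    min_mq: Optional[float] = None
    min_vqslod: Optional[float] = None
    allowed_effects: Optional[frozenset] = None  # None = any effect
    max_internal_maf: float = 1.0
    max_external_maf: float = 1.0
    external_af_column: str = "external_af"
    score_thresholds: Tuple[ScoreThreshold, ...] = ()
    require_pass_filter: bool = True
    model: str = "dominant"

    def __post_init__(self):
        if not (0.0 <= self.max_internal_maf <= 1.0 and 0.0 <= self.max_external_maf <= 1.0):
            raise ValidationError("MAF bounds must lie in [0, 1]")
        if self.model not in MODELS:
            raise ValidationError(f"model must be one of {MODELS}")
        if self.allowed_effects is not None:
            object.__setattr__(self, "allowed_effects", frozenset(self.allowed_effects))
        object.__setattr__(
            self,
            "score_thresholds",
            tuple(
                t if isinstance(t, ScoreThreshold) else ScoreThreshold(**t)
                for t in self.score_thresholds
            ),
        )

    # -- strictness partial order (used by collapsing-lite) -------------------

    def widened_filters(self, other: "QVConfig") -> List[str]:
        """Filters along which self is LOOSER than other (empty = stricter-or-equal)."""
        issues = []
        for attr, _ in _QUALITY_MINIMA:
            mine, theirs = getattr(self, attr), getattr(other, attr)
            if theirs is not None and (mine is None or mine < theirs):
                issues.append(attr)
        if self.max_internal_maf > other.max_internal_maf:
            issues.append("max_internal_maf")
        if self.max_external_maf > other.max_external_maf:
            issues.append("max_external_maf")
        if other.allowed_effects is not None:
            if self.allowed_effects is None or not self.allowed_effects <= other.allowed_effects:
                issues.append("allowed_effects")
        theirs_by_key = {(t.score, t.direction): t for t in other.score_thresholds}
        mine_by_key = {(t.score, t.direction): t for t in self.score_thresholds}
        for key, t in theirs_by_key.items():
            mine = mine_by_key.get(key)
            if mine is None:
                issues.append(f"score_threshold:{t.score}")
            elif t.direction == "min" and mine.cutoff < t.cutoff:
                issues.append(f"score_threshold:{t.score}")
            elif t.direction == "max" and mine.cutoff > t.cutoff:
                issues.append(f"score_threshold:{t.score}")
        if other.require_pass_filter and not self.require_pass_filter:
            issues.append("require_pass_filter")
        return issues

    def is_stricter_than(self, other: "QVConfig") -> bool:
        """True iff every filter of self is within other's (partial order)."""
        return not self.widened_filters(other)

    # -- (de)serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["allowed_effects"] = (
            sorted(self.allowed_effects) if self.allowed_effects is not None else None
        )
        d["score_thresholds"] = [asdict(t) for t in self.score_thresholds]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "QVConfig":
        d = dict(d)
        if d.get("allowed_effects") is not None:
            d["allowed_effects"] = frozenset(d["allowed_effects"])
        d["score_thresholds"] = tuple(
            ScoreThreshold(**t) for t in d.get("score_thresholds", ())
        )
        return cls(**d)


# ---------------------------------------------------------------------------
# QV selection
# ---------------------------------------------------------------------------

_QV_BASE_COLUMNS = [
    "sample_id", "variant_id", "gene", "zygosity", "effect",
    "qual", "gq", "qd", "mq", "vqslod", "filter_pass", "internal_maf",
]


def _variant_passes(config: QVConfig, effect, internal_maf, external: Mapping) -> bool:
    if config.allowed_effects is not None and effect not in config.allowed_effects:
        return False
    if internal_maf is not None and internal_maf > config.max_internal_maf:
        return False
    ext_af = external.get(config.external_af_column)
    if ext_af is None or (isinstance(ext_af, float) and np.isnan(ext_af)):
        ext_af = 0.0  # absent from the reference database = novel
    if min(ext_af, 1.0 - ext_af) > config.max_external_maf:
        return False
    for t in config.score_thresholds:
        if not t.passes(external.get(t.score)):
            return False
    return True


def _genotype_passes(config: QVConfig, row: Mapping) -> bool:
    if config.require_pass_filter and not row["filter_pass"]:
        return False
    for attr, col in _QUALITY_MINIMA:
        threshold = getattr(config, attr)
        if threshold is None:
            continue
        v = row.get(col)
        if v is None or (isinstance(v, float) and np.isnan(v)) or v < threshold:
            return False
    return True


@dataclass
class QVSelection:
    """Qualifying (sample, variant) pairs plus everything needed to re-filter."""

    qv_df: pd.DataFrame  # one row per qualifying genotype, annotations attached
    config: QVConfig

    @property
    def per_sample(self) -> Dict[str, Set[str]]:
        out: Dict[str, Set[str]] = {}
        for row in self.qv_df.itertuples():
            out.setdefault(row.sample_id, set()).add(row.variant_id)
        return out


def _require_scores_available(config: QVConfig, available: Iterable[str]) -> None:
    available = set(available)
    missing = [t.score for t in config.score_thresholds if t.score not in available]
    if missing:
        raise ConfigurationError(
            f"score(s) {missing} are not provided by any attached annotation "
            f"table (available: {sorted(available)})"
        )


def select_qualifying_variants(
    config: QVConfig,
    samples: Sequence[SampleRecord],
    variant_objects: Sequence[AnnotatedVariantObject],
) -> QVSelection:
    """Evaluate every configured filter over all (sample, variant) genotypes.

    Internal MAF is computed on the analysis cohort (the ``samples`` list)
    from each variant object's sample partition, so it is identical for
    every filter configuration -- the property collapsing-lite relies on.
    """
    available_scores: Set[str] = set()
    for obj in variant_objects:
        available_scores.update(obj.external)
    _require_scores_available(config, available_scores)

    ext_columns = sorted(available_scores)
    rows = []
    for obj in variant_objects:
        freq = obj.frequency
        maf = freq.maf
        for call in obj.calls:
            row = {
                "sample_id": call.sample_id,
                "variant_id": call.variant_id,
                "gene": obj.gene,
                "zygosity": call.zygosity,
                "effect": obj.effect,
                "qual": call.qual, "gq": call.gq, "qd": call.qd,
                "mq": call.mq, "vqslod": call.vqslod,
                "filter_pass": call.passes_filter,
                "internal_maf": maf,
            }
            for c in ext_columns:
                row[c] = obj.external.get(c)
            if _variant_passes(config, obj.effect, maf, obj.external) and _genotype_passes(config, row):
                rows.append(row)
    qv_df = pd.DataFrame(rows, columns=_QV_BASE_COLUMNS + ext_columns)
    return QVSelection(qv_df=qv_df, config=config)


def refilter_qv_table(qv_df: pd.DataFrame, config: QVConfig) -> pd.DataFrame:
    """Apply a (stricter) config to an existing QV table."""
    ext_columns = [c for c in qv_df.columns if c not in _QV_BASE_COLUMNS]
    _require_scores_available(config, ext_columns)
    keep = []
    for _, row in qv_df.iterrows():
        external = {c: row[c] for c in ext_columns}
        if config.external_af_column in qv_df.columns:
            external[config.external_af_column] = row[config.external_af_column]
        ok = _variant_passes(config, row["effect"], row["internal_maf"], external)
        keep.append(ok and _genotype_passes(config, row))
    return qv_df[np.asarray(keep, dtype=bool)] if len(qv_df) else qv_df


# ---------------------------------------------------------------------------
# coverage harmonization
# ---------------------------------------------------------------------------


def proportion_decision(
    n_case_covered: int, n_cases: int, n_control_covered: int, n_controls: int,
    max_abs_diff: float = 0.07,
) -> str:
    """'keep' | 'remove' by absolute difference of covered proportions."""
    if n_cases == 0 or n_controls == 0:
        raise ValidationError("need at least one case and one control")
    diff = abs(n_case_covered / n_cases - n_control_covered / n_controls)
    return "remove" if diff > max_abs_diff else "keep"


def binomial_decision(
    n_case_covered: int, n_cases: int, n_control_covered: int, n_controls: int,
    alpha: float = 0.05,
) -> Tuple[Optional[float], str]:
    """Exact two-sided binomial test of coverage/status independence.

    Among covered individuals, the number of cases is tested against the
    cohort case fraction.  Returns (p, 'keep'|'remove'); zero covered
    individuals keep the site with an undefined p.
    """
    if n_cases == 0 or n_controls == 0:
        raise ValidationError("need at least one case and one control")
    n_covered = n_case_covered + n_control_covered
    if n_covered == 0:
        log.warning("binomial harmonization: no covered individuals; keeping site")
        return None, "keep"
    p_null = n_cases / (n_cases + n_controls)
    p = binomtest(n_case_covered, n_covered, p_null, alternative="two-sided").pvalue
    return p, ("remove" if p < alpha else "keep")


def _covered_counts(store, chrom, pos, case_ids, control_ids, min_depth):
    cc = sum(store.coverage.is_sufficiently_covered(s, chrom, pos, min_depth) for s in case_ids)
    uc = sum(store.coverage.is_sufficiently_covered(s, chrom, pos, min_depth) for s in control_ids)
    return cc, uc


def harmonize_coverage_proportion(
    store: VariantStore, site: Tuple[str, int], case_ids, control_ids,
    min_depth: int = 10, max_abs_diff: float = 0.07,
) -> str:
    cc, uc = _covered_counts(store, site[0], site[1], case_ids, control_ids, min_depth)
    return proportion_decision(cc, len(case_ids), uc, len(control_ids), max_abs_diff)


def harmonize_coverage_binomial(
    store: VariantStore, site: Tuple[str, int], case_ids, control_ids,
    min_depth: int = 10, alpha: float = 0.05,
) -> Tuple[Optional[float], str]:
    cc, uc = _covered_counts(store, site[0], site[1], case_ids, control_ids, min_depth)
    return binomial_decision(cc, len(case_ids), uc, len(control_ids), alpha)


@dataclass(frozen=True)
class HarmonizationConfig:
    method: str = "proportion"  # "proportion" | "binomial" | "none"
    min_depth: int = 10
    max_abs_diff: float = 0.07
    alpha: float = 0.05

    def __post_init__(self):
        if self.method not in ("proportion", "binomial", "none"):
            raise ValidationError(f"unknown harmonization method {self.method!r}")


# ---------------------------------------------------------------------------
# collapsing matrix
# ---------------------------------------------------------------------------


@dataclass
class CollapsingMatrix:
    """Gene-by-individual binary indicator matrix with QV provenance."""

    genes: List[str]
    samples: List[str]
    cells: np.ndarray  # (n_genes, n_samples) int8
    qv_provenance: Dict[Tuple[str, str], List[str]]
    model: str = "dominant"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.genes, columns=self.samples)

    def carrier_counts(self, is_case: np.ndarray) -> pd.DataFrame:
        cells = self.cells.astype(bool)
        return pd.DataFrame(
            {
                "case_carriers": cells[:, is_case].sum(axis=1),
                "control_carriers": cells[:, ~is_case].sum(axis=1),
            },
            index=self.genes,
        )


def build_matrix(
    selection: Union[QVSelection, pd.DataFrame],
    model: str,
    samples: Sequence[str],
    genes: Sequence[str],
) -> CollapsingMatrix:
    """Collapse QVs into a 0/1 gene-by-individual matrix.

    dominant: >=1 QV in the gene.  recessive: a hom-alt QV, or >=2 distinct
    het QVs in the gene (phase is not checked here; the trio workflow does).
    """
    if model not in MODELS:
        raise ValidationError(f"model must be one of {MODELS}")
    qv_df = selection.qv_df if isinstance(selection, QVSelection) else selection
    sample_ids = [s if isinstance(s, str) else s.sample_id for s in samples]
    gene_index = {g: i for i, g in enumerate(genes)}
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    cells = np.zeros((len(genes), len(sample_ids)), dtype=np.int8)
    provenance: Dict[Tuple[str, str], List[str]] = {}

    grouped: Dict[Tuple[str, str], List[Tuple[str, str]]] = {}
    for row in qv_df.itertuples():
        grouped.setdefault((row.gene, row.sample_id), []).append(
            (row.variant_id, row.zygosity)
        )
    for (gene, sid), hits in grouped.items():
        if gene not in gene_index or sid not in sample_index:
            continue
        variant_ids = sorted({v for v, _ in hits})
        if model == "dominant":
            qualifies = len(variant_ids) >= 1
        else:
            has_hom = any(z == "hom_alt" for _, z in hits)
            n_het = len({v for v, z in hits if z == "het"})
            qualifies = has_hom or n_het >= 2
        if qualifies:
            cells[gene_index[gene], sample_index[sid]] = 1
            provenance[(gene, sid)] = variant_ids
    return CollapsingMatrix(list(genes), sample_ids, cells, provenance, model)


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------


def phenotype_vector(sample_ids: Sequence[str], ped: Sequence[SampleRecord]) -> np.ndarray:
    """Boolean is-case vector aligned to sample_ids; missing phenotypes are errors."""
    by_id = {r.sample_id: r for r in ped}
    out = np.zeros(len(sample_ids), dtype=bool)
    for i, sid in enumerate(sample_ids):
        rec = by_id.get(sid)
        if rec is None or not (rec.is_case or rec.is_control):
            raise ValidationError(f"sample {sid!r} has no case/control phenotype")
        out[i] = rec.is_case
    return out


def fisher_gene_test(matrix: CollapsingMatrix, is_case: np.ndarray) -> pd.DataFrame:
    """Two-sided Fisher's exact test per gene on the carrier 2x2 table.

    Returns one row per gene: carrier/non-carrier counts by status, p,
    odds ratio (inf/0 at empty margins, nan for 0/0), an ``uninformative``
    flag for genes without any carrier, and a Bonferroni threshold in
    ``df.attrs["bonferroni_alpha"]``.
    """
    is_case = np.asarray(is_case, dtype=bool)
    if is_case.shape[0] != len(matrix.samples):
        raise ValidationError("phenotype vector does not match matrix samples")
    n_cases = int(is_case.sum())
    n_controls = int((~is_case).sum())
    rows = []
    for gi, gene in enumerate(matrix.genes):
        carriers = matrix.cells[gi].astype(bool)
        a = int((carriers & is_case).sum())
        b = n_cases - a
        c = int((carriers & ~is_case).sum())
        d = n_controls - c
        if a + c == 0:
            p, orat, flag = 1.0, float("nan"), True
        else:
            orat, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            with np.errstate(divide="ignore", invalid="ignore"):
                orat = np.divide(a * d, b * c) if (b * c) else (
                    float("inf") if a * d else float("nan")
                )
            flag = False
        rows.append(
            {
                "gene": gene,
                "case_carriers": a, "case_noncarriers": b,
                "control_carriers": c, "control_noncarriers": d,
                "fisher_p": float(p), "odds_ratio": float(orat),
                "uninformative": flag,
            }
        )
    df = pd.DataFrame(rows).sort_values("fisher_p", kind="stable").reset_index(drop=True)
    df.attrs["bonferroni_alpha"] = 0.05 / len(matrix.genes) if matrix.genes else None
    return df


def firth_gene_test(
    matrix: CollapsingMatrix,
    is_case: np.ndarray,
    genes: Optional[Sequence[str]] = None,
    covariates: Optional[np.ndarray] = None,
) -> Dict[str, FirthResult]:
    """Firth penalized logistic regression of status on carrier indicator."""
    is_case = np.asarray(is_case, dtype=float)
    wanted = list(genes) if genes is not None else list(matrix.genes)
    out = {}
    for gene in wanted:
        gi = matrix.genes.index(gene)
        out[gene] = firth_logistic(matrix.cells[gi], is_case, covariates=covariates)
    return out


# ---------------------------------------------------------------------------
# permutation lambda / QQ
# ---------------------------------------------------------------------------

_TIE_GAMMA = 1.0 + 1e-7  # R/scipy convention for two-sided tie handling


def _fisher_p_lookup(n_total: int, n_cases: int, K: int) -> np.ndarray:
    """p[k] of the two-sided Fisher test for k case-carriers among K carriers."""
    ks = np.arange(K + 1)
    pmf = hypergeom.pmf(ks, n_total, K, n_cases)
    p = np.ones(K + 1)
    for k in ks:
        p[k] = min(1.0, pmf[pmf <= pmf[k] * _TIE_GAMMA].sum())
    return p


@dataclass
class LambdaEstimate:
    """Permutation-calibrated genomic inflation factor."""

    lambda_: float
    n_permutations: int
    expected_p: np.ndarray  # ascending mean order statistics over permutations
    observed_p: np.ndarray  # ascending
    qq: pd.DataFrame  # columns: expected_neglog10, observed_neglog10

    def __post_init__(self):
        if not self.lambda_ > 0:
            raise ValidationError(f"lambda must be positive, got {self.lambda_}")


def permutation_lambda(
    matrix: CollapsingMatrix,
    is_case: np.ndarray,
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> LambdaEstimate:
    """Estimate lambda against a permutation-derived expected p distribution.

    Case/control labels are permuted ``n_perm`` times preserving the case
    count; the per-gene Fisher p is recomputed each round (via hypergeometric
    lookup -- carrier counts are invariant under label permutation);
    ``expected_p[i]`` is the mean of the i-th smallest p across rounds, and

        lambda = median(chi2_1 quantile of 1 - p_obs)
                 / median(chi2_1 quantile of 1 - p_exp).
    """
    if n_perm < 100:
        raise ValidationError(f"n_perm must be >= 100, got {n_perm}")
    if seed is None:
        raise ValidationError("permutations require an explicit seed (audit contract)")
    is_case = np.asarray(is_case, dtype=bool)
    rng = np.random.default_rng(seed)
    n = len(matrix.samples)
    n_cases = int(is_case.sum())
    cells = matrix.cells.astype(np.int64)
    K = cells.sum(axis=1)  # carriers per gene, fixed under permutation

    lookups = {k: _fisher_p_lookup(n, n_cases, int(k)) for k in np.unique(K)}
    observed_k = cells[:, is_case].sum(axis=1)
    observed_p = np.array([lookups[int(Kg)][int(kg)] for Kg, kg in zip(K, observed_k)])

    perm = np.zeros((n, n_perm), dtype=np.int64)
    for j in range(n_perm):
        perm[rng.permutation(n)[:n_cases], j] = 1
    perm_k = cells @ perm  # (genes, perms) case-carrier counts
    perm_p = np.empty_like(perm_k, dtype=float)
    for gi, Kg in enumerate(K):
        perm_p[gi] = lookups[int(Kg)][perm_k[gi]]
    perm_p.sort(axis=0)
    expected_p = perm_p.mean(axis=1)  # ascending by construction

    obs_sorted = np.sort(observed_p)
    obs_chi = chi2.isf(obs_sorted, df=1)
    exp_chi = chi2.isf(expected_p, df=1)
    med_obs = np.median(obs_chi)
    med_exp = np.median(exp_chi)
    if med_obs == 0 or med_exp == 0:
        # most p-values are exactly 1 (tiny panels / no carriers); the
        # median ratio is undefined, not evidence of deflation
        log.warning(
            "degenerate median chi-square (obs=%g, exp=%g); lambda undefined, reporting 1",
            med_obs, med_exp,
        )
        lam = 1.0
    else:
        lam = float(med_obs / med_exp)
    qq = pd.DataFrame(
        {
            "expected_neglog10": -np.log10(expected_p),
            "observed_neglog10": -np.log10(obs_sorted),
        }
    )
    return LambdaEstimate(lam, n_perm, expected_p, obs_sorted, qq)


# ---------------------------------------------------------------------------
# run orchestration + collapsing-lite
# ---------------------------------------------------------------------------


@dataclass
class CollapsingRunOutput:
    """Everything a collapsing run produced, sufficient to re-filter (lite)."""

    config: QVConfig
    genes: List[str]
    samples: List[SampleRecord]
    qv_df: pd.DataFrame
    matrix: CollapsingMatrix
    results: pd.DataFrame
    lambda_estimate: Optional[LambdaEstimate] = None
    removed_sites: List[str] = field(default_factory=list)

    def save(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.qv_df.to_csv(os.path.join(out_dir, "qualifying_variants.tsv"), sep="\t", index=False)
        self.results.to_csv(os.path.join(out_dir, "gene_results.tsv"), sep="\t", index=False)
        self.matrix.to_frame().to_csv(os.path.join(out_dir, "matrix.tsv"), sep="\t")
        meta = {
            "config": self.config.to_dict(),
            "genes": self.genes,
            "samples": [asdict(s) for s in self.samples],
            "removed_sites": self.removed_sites,
            "lambda": self.lambda_estimate.lambda_ if self.lambda_estimate else None,
        }
        with open(os.path.join(out_dir, "run.json"), "w") as fh:
            json.dump(meta, fh, indent=1)
        if self.lambda_estimate is not None:
            self.lambda_estimate.qq.to_csv(os.path.join(out_dir, "qq.tsv"), sep="\t", index=False)

    @classmethod
    def load(cls, out_dir) -> "CollapsingRunOutput":
        with open(os.path.join(out_dir, "run.json")) as fh:
            meta = json.load(fh)
        config = QVConfig.from_dict(meta["config"])
        samples = [SampleRecord(**{k: v for k, v in s.items()}) for s in meta["samples"]]
        qv_df = pd.read_csv(
            os.path.join(out_dir, "qualifying_variants.tsv"), sep="\t",
            dtype={"sample_id": str, "variant_id": str, "gene": str},
        )
        matrix = build_matrix(qv_df, config.model, [s.sample_id for s in samples], meta["genes"])
        results = pd.read_csv(os.path.join(out_dir, "gene_results.tsv"), sep="\t")
        return cls(
            config=config, genes=meta["genes"], samples=samples, qv_df=qv_df,
            matrix=matrix, results=results, removed_sites=meta.get("removed_sites", []),
        )


def run_collapsing(
    store: VariantStore,
    ped: Sequence[SampleRecord],
    config: QVConfig,
    genes: Optional[Sequence[str]] = None,
    harmonization: Optional[HarmonizationConfig] = None,
    n_perm: Optional[int] = None,
    seed: Optional[int] = None,
) -> CollapsingRunOutput:
    """Full pipeline: query -> harmonize -> QV selection -> matrix -> tests."""
    if genes is None:
        if store.gene_model is None:
            raise ValidationError("run_collapsing needs a gene list or a store gene model")
        genes = store.gene_model.genes
    cohort = [r for r in ped if r.is_case or r.is_control]
    case_ids = [r.sample_id for r in cohort if r.is_case]
    control_ids = [r.sample_id for r in cohort if r.is_control]

    variant_objects: List[AnnotatedVariantObject] = []
    for gene in genes:
        variant_objects.extend(store.query_region(cohort, gene=gene))

    removed: List[str] = []
    if harmonization is not None and harmonization.method != "none":
        kept_objects = []
        for obj in variant_objects:
            site = (obj.variant.chrom, obj.variant.pos)
            if harmonization.method == "proportion":
                decision = harmonize_coverage_proportion(
                    store, site, case_ids, control_ids,
                    harmonization.min_depth, harmonization.max_abs_diff,
                )
            else:
                _, decision = harmonize_coverage_binomial(
                    store, site, case_ids, control_ids,
                    harmonization.min_depth, harmonization.alpha,
                )
            if decision == "keep":
                kept_objects.append(obj)
            else:
                removed.append(obj.variant.variant_id)
        variant_objects = kept_objects

    selection = select_qualifying_variants(config, cohort, variant_objects)
    matrix = build_matrix(selection, config.model, [r.sample_id for r in cohort], genes)
    is_case = phenotype_vector(matrix.samples, cohort)
    results = fisher_gene_test(matrix, is_case)
    lam = None
    if n_perm:
        lam = permutation_lambda(matrix, is_case, n_perm=n_perm, seed=seed)
    return CollapsingRunOutput(
        config=config, genes=list(genes), samples=list(cohort),
        qv_df=selection.qv_df, matrix=matrix, results=results,
        lambda_estimate=lam, removed_sites=removed,
    )


def collapsing_lite(
    previous: CollapsingRunOutput,
    stricter_config: QVConfig,
    n_perm: Optional[int] = None,
    seed: Optional[int] = None,
) -> CollapsingRunOutput:
    """Re-run a collapsing model from a previous run's QV table.

    Valid only in the relaxed -> strict direction: every filter of the new
    config must be at least as tight as the logged one, otherwise QVs the
    first pass discarded could be missing.  Results are then identical to a
    full run under the stricter config.
    """
    widened = stricter_config.widened_filters(previous.config)
    if widened:
        raise ConfigOrderError(
            "collapsing-lite requires a stricter config; these filters are "
            f"wider than in the previous run: {', '.join(widened)}"
        )
    qv_df = refilter_qv_table(previous.qv_df, stricter_config)
    sample_ids = [s.sample_id for s in previous.samples]
    matrix = build_matrix(qv_df, stricter_config.model, sample_ids, previous.genes)
    is_case = phenotype_vector(sample_ids, previous.samples)
    results = fisher_gene_test(matrix, is_case)
    lam = None
    if n_perm:
        lam = permutation_lambda(matrix, is_case, n_perm=n_perm, seed=seed)
    return CollapsingRunOutput(
        config=stricter_config, genes=previous.genes, samples=previous.samples,
        qv_df=qv_df, matrix=matrix, results=results, lambda_estimate=lam,
        removed_sites=previous.removed_sites,
    )
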