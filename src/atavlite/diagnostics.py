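"""Trio and singleton diagnostic workflow.

For an affected child with two unaffected genotyped parents, the workflow
extracts the *novel* genotypes that standard inheritance cannot explain:

* de novo          -- child het, neither parent carries the variant;
* newly homozygous -- child hom-alt, both parents het carriers;
* newly compound-heterozygous -- two het variants in one gene inherited in
  trans, one from each parent (parental carrier status is what separates a
  true comp-het from two in-phase variants on one haplotype);
* parental mosaic transmission -- a transmitted variant whose parental
  alternate-allele read fraction is too low for a constitutional het.

Genotype absence is only trusted when the parental coverage bin guarantees
depth >= 10; below that (bin a, or no coverage data at all) the call is
kept but downgraded to a "possible" finding.  The workflow surfaces
candidates for clinical review; it does not assign ACMG classifications.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .annotation import KnownVar, KnownVarTiers
from .collapsing import QVConfig, select_qualifying_variants
from .errors import PedCycleError, ValidationError
from .ped import MISSING_PARENT, SampleRecord
from .store import AnnotatedVariantObject, GenotypeCall, VariantStore, af_from_counts

log = logging.getLogger(__name__)

CONFIRMED = "confirmed"
POSSIBLE = "possible"

# coverage evidence states for a site in one individual
COVERED = "covered"  # bin >= b, depth >= 10 guaranteed
LOW = "low"          # bin a: some data, depth could be 0..9
NO_DATA = "no_data"  # no coverage block at the site


def coverage_state(bin_letter: Optional[str], min_depth: int = 10) -> str:
    from .coverage import bin_lower_bound

    if bin_letter is None:
        return NO_DATA
    return COVERED if bin_lower_bound(bin_letter) >= min_depth else LOW


@dataclass(frozen=True)
class MosaicConfig:
    """Thresholds for calling a parental genotype mosaic rather than het."""

    mosaic_max_aaf: float = 0.20
    min_alt_reads: int = 3
    min_depth: int = 10


@dataclass
class TrioFinding:
    family_id: str
    child_id: str
    category: str  # de_novo | newly_comphet | newly_hom | mosaic_transmission
    confidence: str  # confirmed | possible
    variants: Tuple[str, ...]  # one variant_id, or an ordered pair for comphet
    supporting: Dict[str, dict] = field(default_factory=dict)  # member -> evidence
    annotations: Dict[str, dict] = field(default_factory=dict)  # variant_id -> KnownVar tiers

    def __post_init__(self):
        if self.category == "newly_comphet":
            if len(self.variants) != 2 or self.variants[0] == self.variants[1]:
                raise ValidationError("comphet findings need two distinct variants")
        if self.confidence not in (CONFIRMED, POSSIBLE):
            raise ValidationError(f"bad confidence {self.confidence!r}")


# ---------------------------------------------------------------------------
# family resolution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trio:
    family_id: str
    child_id: str
    father_id: str
    mother_id: str


@dataclass
class FamilySet:
    trios: List[Trio]
    parent_child_pairs: List[Tuple[str, str]]  # (parent_id, child_id)
    singletons: List[str]  # affected samples analyzed without parents
    excluded_controls: Set[str]  # controls removed from control frequencies


def resolve_families(ped: Sequence[SampleRecord]) -> FamilySet:
    """Split a PED into trios, parent-child pairs and singleton cases.

    Affected individuals with both parents genotyped form trios; an affected
    individual with at most one genotyped parent falls back to singleton
    mode.  Every control related to an analyzed case (same family) is
    collected for exclusion from control-frequency denominators.
    """
    by_id = {r.sample_id: r for r in ped}
    _check_no_cycles(by_id)
    trios, pairs, singletons = [], [], []
    case_families: Set[str] = set()
    for r in ped:
        for parent in (r.paternal_id, r.maternal_id):
            if parent != MISSING_PARENT and parent in by_id:
                pairs.append((parent, r.sample_id))
        if not r.is_case:
            continue
        case_families.add(r.family_id)
        if r.paternal_id in by_id and r.maternal_id in by_id:
            trios.append(Trio(r.family_id, r.sample_id, r.paternal_id, r.maternal_id))
        else:
            if r.paternal_id != MISSING_PARENT or r.maternal_id != MISSING_PARENT:
                log.info(
                    "case %s lacks a fully genotyped parent pair; singleton mode",
                    r.sample_id,
                )
            singletons.append(r.sample_id)
    excluded = {
        r.sample_id for r in ped if r.is_control and r.family_id in case_families
    }
    return FamilySet(trios, pairs, singletons, excluded)


def _check_no_cycles(by_id: Dict[str, SampleRecord]) -> None:
    for start in by_id:
        seen = {start}
        frontier = [start]
        while frontier:
            nxt = []
            for sid in frontier:
                rec = by_id.get(sid)
                if rec is None:
                    continue
                for parent in (rec.paternal_id, rec.maternal_id):
                    if parent == MISSING_PARENT or parent not in by_id:
                        continue
                    if parent in seen and parent == start:
                        raise PedCycleError(f"{start!r} is listed as its own ancestor")
                    if parent not in seen:
                        seen.add(parent)
                        nxt.append(parent)
            frontier = nxt


def unrelated_controls(ped: Sequence[SampleRecord]) -> List[SampleRecord]:
    """Controls usable for frequency denominators (related controls removed)."""
    excluded = resolve_families(ped).excluded_controls
    return [r for r in ped if r.is_control and r.sample_id not in excluded]


# ---------------------------------------------------------------------------
# site-level trio classifiers
# ---------------------------------------------------------------------------

GT_STATES = ("ref", "het", "hom_alt")  # "ref" = no call at the site
COV_STATES = (COVERED, LOW, NO_DATA)


def classify_trio_site(
    child_gt: str,
    father_gt: str,
    mother_gt: str,
    father_cov: str,
    mother_cov: str,
) -> Optional[Tuple[str, str]]:
    """Single-site trio classification -> (category, confidence) or None.

    Genotypes are "ref" (no call), "het" or "hom_alt"; coverage states are
    "covered" (depth >= 10 guaranteed), "low" (bin a) or "no_data".

    de novo: child het and neither parent called; confirmed only when both
    parental absences are backed by sufficient coverage.  newly homozygous:
    child hom-alt and both parents consistent with het carriers; a called
    het parent contributes confirmation, an uncalled parent with thin
    coverage leaves ambiguity ("possible"), and a confidently hom-ref or
    hom-alt parent rules the category out.
    """
    for gt in (child_gt, father_gt, mother_gt):
        if gt not in GT_STATES:
            raise ValidationError(f"bad genotype state {gt!r}")
    for cov in (father_cov, mother_cov):
        if cov not in COV_STATES:
            raise ValidationError(f"bad coverage state {cov!r}")

    if child_gt == "het":
        if father_gt != "ref" or mother_gt != "ref":
            return None  # inherited (mosaic transmission is a separate scan)
        if father_cov == COVERED and mother_cov == COVERED:
            return ("de_novo", CONFIRMED)
        return ("de_novo", POSSIBLE)

    if child_gt == "hom_alt":
        states = []
        for gt, cov in ((father_gt, father_cov), (mother_gt, mother_cov)):
            if gt == "hom_alt":
                return None  # that parent was already homozygous; nothing new
            if gt == "het":
                states.append(CONFIRMED if cov == COVERED else POSSIBLE)
            else:  # no call
                if cov == COVERED:
                    return None  # confident hom-ref parent: not newly-hom
                states.append(POSSIBLE)  # could be an uncalled het
        return ("newly_hom", CONFIRMED if all(s == CONFIRMED for s in states) else POSSIBLE)

    return None


def _carrier_status(called: bool, cov: str) -> Optional[bool]:
    """True/False when carrier status is known, None when coverage can hide a call."""
    if called:
        return True
    return False if cov == COVERED else None


def classify_comphet_pair(
    p1_carries_v1: bool, p1_carries_v2: bool,
    p2_carries_v1: bool, p2_carries_v2: bool,
    p1_cov_v1: str = COVERED, p1_cov_v2: str = COVERED,
    p2_cov_v1: str = COVERED, p2_cov_v2: str = COVERED,
) -> Optional[str]:
    """Classify a child's het variant pair from parental evidence.

    Returns "confirmed" (trans configuration proven: one parent carries v1
    only, the other v2 only), "possible" (a trans assignment is consistent
    once unobservable parental genotypes are allowed), or None (in-phase or
    otherwise excluded).
    """
    s = (
        _carrier_status(p1_carries_v1, p1_cov_v1),
        _carrier_status(p1_carries_v2, p1_cov_v2),
        _carrier_status(p2_carries_v1, p2_cov_v1),
        _carrier_status(p2_carries_v2, p2_cov_v2),
    )

    def assignment(va_from_p1: bool) -> Optional[str]:
        # requirements (p1 gives v1, p2 gives v2) or the mirror image
        if va_from_p1:
            need = (s[0], not_(s[1]), not_(s[2]), s[3])
        else:
            need = (not_(s[0]), s[1], s[2], not_(s[3]))
        if any(v is False for v in need):
            return None
        return CONFIRMED if all(v is True for v in need) else POSSIBLE

    def not_(v):
        return None if v is None else (not v)

    outcomes = {assignment(True), assignment(False)} - {None}
    if CONFIRMED in outcomes:
        return CONFIRMED
    if POSSIBLE in outcomes:
        return POSSIBLE
    return None


def detect_parental_mosaic(
    parent_call: GenotypeCall,
    child_call: GenotypeCall,
    config: MosaicConfig = MosaicConfig(),
) -> bool:
    """Flag a transmitted variant whose parental AAF indicates mosaicism.

    Requires allelic depths in the parent; the child's AAF is unconstrained
    (the child inherited the variant constitutionally).
    """
    if parent_call.ad_ref is None or parent_call.ad_alt is None:
        raise ValidationError("parent call lacks allelic depths (AD)")
    total = parent_call.ad_ref + parent_call.ad_alt
    if total < config.min_depth or parent_call.ad_alt < config.min_alt_reads:
        return False
    return (parent_call.ad_alt / total) < config.mosaic_max_aaf


# ---------------------------------------------------------------------------
# whole-workflow driver
# ---------------------------------------------------------------------------


def _gt_state(obj: AnnotatedVariantObject, sample_id: str) -> str:
    call = obj.call_for(sample_id)
    return call.zygosity if call is not None else "ref"


def _cov_state(store: VariantStore, sample_id: str, chrom: str, pos: int) -> str:
    return coverage_state(store.coverage.coverage_bin_at(sample_id, chrom, pos))


@dataclass
class DiagnosticReport:
    findings: List[TrioFinding]
    singleton_candidates: Dict[str, List[str]]  # sample_id -> variant_ids
    notices: List[str] = field(default_factory=list)

    def by_family(self) -> Dict[str, List[TrioFinding]]:
        out: Dict[str, List[TrioFinding]] = {}
        for f in self.findings:
            out.setdefault(f.family_id, []).append(f)
        return out

    def to_records(self) -> List[dict]:
        return [
            {
                "family_id": f.family_id,
                "child_id": f.child_id,
                "category": f.category,
                "confidence": f.confidence,
                "variants": ",".join(f.variants),
            }
            for f in self.findings
        ]


def run_diagnostic(
    store: VariantStore,
    ped: Sequence[SampleRecord],
    qv_config: QVConfig,
    knownvar: Optional[KnownVar] = None,
    mosaic_config: MosaicConfig = MosaicConfig(),
    knownvar_window_bp: int = 10,
) -> DiagnosticReport:
    """Run the full trio/singleton diagnostic workflow over a PED cohort.

    Every finding carries genotypes and coverage bins for the family
    members, plus KnownVar tiers when a KnownVar aggregation is supplied.
    Affected children without two genotyped parents are analyzed in
    singleton (filter-only) mode.
    """
    families = resolve_families(ped)
    by_id = {r.sample_id: r for r in ped}
    if store.gene_model is None:
        raise ValidationError("run_diagnostic needs a store gene model")
    genes = store.gene_model.genes

    report = DiagnosticReport(findings=[], singleton_candidates={})
    for sid in families.singletons:
        rec = by_id[sid]
        if rec.paternal_id != MISSING_PARENT or rec.maternal_id != MISSING_PARENT:
            report.notices.append(f"case {sid} analyzed as singleton (parents not genotyped)")

    for trio in families.trios:
        members = [by_id[trio.child_id], by_id[trio.father_id], by_id[trio.mother_id]]
        for gene in genes:
            objs = store.query_region(members, gene=gene)
            qv = select_qualifying_variants(qv_config, members, objs)
            child_qvs = qv.per_sample.get(trio.child_id, set())
            objs_by_id = {o.variant.variant_id: o for o in objs}

            het_qvs: List[str] = []
            for vid in sorted(child_qvs):
                obj = objs_by_id[vid]
                v = obj.variant
                f_cov = _cov_state(store, trio.father_id, v.chrom, v.pos)
                m_cov = _cov_state(store, trio.mother_id, v.chrom, v.pos)
                child_gt = _gt_state(obj, trio.child_id)
                verdict = classify_trio_site(
                    child_gt,
                    _gt_state(obj, trio.father_id),
                    _gt_state(obj, trio.mother_id),
                    f_cov,
                    m_cov,
                )
                if child_gt == "het":
                    het_qvs.append(vid)
                if verdict is not None:
                    report.findings.append(
                        _make_finding(
                            trio, verdict[0], verdict[1], (vid,), store, objs_by_id,
                            knownvar, knownvar_window_bp,
                        )
                    )
            # comp-het scan over the child's het QVs in this gene
            for v1, v2 in combinations(sorted(het_qvs), 2):
                o1, o2 = objs_by_id[v1], objs_by_id[v2]
                verdict = classify_comphet_pair(
                    o1.call_for(trio.father_id) is not None,
                    o2.call_for(trio.father_id) is not None,
                    o1.call_for(trio.mother_id) is not None,
                    o2.call_for(trio.mother_id) is not None,
                    _cov_state(store, trio.father_id, o1.variant.chrom, o1.variant.pos),
                    _cov_state(store, trio.father_id, o2.variant.chrom, o2.variant.pos),
                    _cov_state(store, trio.mother_id, o1.variant.chrom, o1.variant.pos),
                    _cov_state(store, trio.mother_id, o2.variant.chrom, o2.variant.pos),
                )
                if verdict is not None:
                    report.findings.append(
                        _make_finding(
                            trio, "newly_comphet", verdict, (v1, v2), store, objs_by_id,
                            knownvar, knownvar_window_bp,
                        )
                    )

    # parental mosaic transmissions (affected children only)
    skipped_no_ad = 0
    for parent_id, child_id in families.parent_child_pairs:
        if not by_id[child_id].is_case:
            continue
        pair = [by_id[parent_id], by_id[child_id]]
        for gene in genes:
            for obj in store.query_region(pair, gene=gene):
                p_call, c_call = obj.call_for(parent_id), obj.call_for(child_id)
                if p_call is None or c_call is None:
                    continue
                try:
                    flagged = detect_parental_mosaic(p_call, c_call, mosaic_config)
                except ValidationError:
                    skipped_no_ad += 1
                    continue
                if flagged:
                    family_id = by_id[child_id].family_id
                    trio_like = Trio(family_id, child_id, parent_id, parent_id)
                    report.findings.append(
                        _make_finding(
                            trio_like, "mosaic_transmission", CONFIRMED,
                            (obj.variant.variant_id,), store,
                            {obj.variant.variant_id: obj}, knownvar, knownvar_window_bp,
                        )
                    )
    if skipped_no_ad:
        report.notices.append(f"{skipped_no_ad} sites skipped in mosaic scan (missing AD)")
        log.info("mosaic scan skipped %d sites lacking allelic depths", skipped_no_ad)

    # singleton mode: filter-only prioritization
    for sid in families.singletons:
        rec = by_id[sid]
        hits: List[str] = []
        for gene in genes:
            objs = store.query_region([rec], gene=gene)
            qv = select_qualifying_variants(qv_config, [rec], objs)
            hits.extend(sorted(qv.per_sample.get(sid, set())))
        report.singleton_candidates[sid] = hits
    return report


def _make_finding(
    trio: Trio, category, confidence, variant_ids, store, objs_by_id,
    knownvar, window_bp,
) -> TrioFinding:
    supporting = {}
    for member, sid in (
        ("child", trio.child_id), ("father", trio.father_id), ("mother", trio.mother_id),
    ):
        evidence = {}
        for vid in variant_ids:
            obj = objs_by_id[vid]
            v = obj.variant
            call = obj.call_for(sid)
            evidence[vid] = {
                "genotype": call.zygosity if call else "ref",
                "coverage_bin": store.coverage.coverage_bin_at(sid, v.chrom, v.pos),
            }
        supporting[member] = evidence
    annotations = {}
    if knownvar is not None:
        for vid in variant_ids:
            obj = objs_by_id[vid]
            annotations[vid] = knownvar.annotate(
                obj.variant, window_bp=window_bp, gene=obj.gene or None
            ).to_dict()
    return TrioFinding(
        family_id=trio.family_id,
        child_id=trio.child_id,
        category=category,
        confidence=confidence,
        variants=tuple(variant_ids),
        supporting=supporting,
        annotations=annotations,
    )


def diagnostic_yield(n_diagnosed: int, n_total: int, decimals: int = 0) -> float:
    """Percentage of individuals receiving a diagnosis, rounded for reporting."""
    if n_total <= 0 or n_diagnosed < 0 or n_diagnosed > n_total:
        raise ValidationError("need 0 <= n_diagnosed <= n_total with n_total > 0")
    return float(round(100.0 * n_diagnosed / n_total, decimals or None))
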