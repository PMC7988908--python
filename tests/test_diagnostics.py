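"""Trio diagnostics: classifiers vs brute force, families, planted recovery."""

import json
from itertools import product

import pytest

from atavlite.collapsing import QVConfig
from atavlite.diagnostics import (
    COV_STATES,
    GT_STATES,
    MosaicConfig,
    classify_comphet_pair,
    classify_trio_site,
    detect_parental_mosaic,
    diagnostic_yield,
    resolve_families,
    run_diagnostic,
    unrelated_controls,
)
from atavlite.errors import PedCycleError, ValidationError
from atavlite.ped import SampleRecord
from atavlite.simulate import generate_trio
from atavlite.store import GenotypeCall

from conftest import TRIO_PLANTED, TRIO_SEED, build_store
from oracles import brute_comphet_classifier, brute_trio_classifier


# ---------------------------------------------------------------------------
# single-site classifier
# ---------------------------------------------------------------------------


def test_trio_site_truth_table_matches_bruteforce():
    """All 3^3 genotype combinations x 3^2 parental coverage states agree
    with the independently derived classifier."""
    for child, father, mother in product(GT_STATES, repeat=3):
        for f_cov, m_cov in product(COV_STATES, repeat=2):
            got = classify_trio_site(child, father, mother, f_cov, m_cov)
            want = brute_trio_classifier(child, father, mother, f_cov, m_cov)
            assert got == want, (child, father, mother, f_cov, m_cov)


@pytest.mark.parametrize(
    "child,father,mother,f_cov,m_cov,expected",
    [
        # child 0/1, both parents covered with no call -> confirmed de novo
        ("het", "ref", "ref", "covered", "covered", ("de_novo", "confirmed")),
        # father bin a -> possible de novo
        ("het", "ref", "ref", "low", "covered", ("de_novo", "possible")),
        # mother carries it -> inherited
        ("het", "ref", "het", "covered", "covered", None),
        # child 1/1, both parents het well covered -> confirmed newly hom
        ("hom_alt", "het", "het", "covered", "covered", ("newly_hom", "confirmed")),
        # one parent already 1/1 -> nothing new
        ("hom_alt", "hom_alt", "het", "covered", "covered", None),
        # uncalled parent at bin a could be het -> possible newly hom
        ("hom_alt", "ref", "het", "low", "covered", ("newly_hom", "possible")),
        # confidently hom-ref parent rules newly-hom out
        ("hom_alt", "ref", "het", "covered", "covered", None),
    ],
)
def test_trio_site_examples(child, father, mother, f_cov, m_cov, expected):
    assert classify_trio_site(child, father, mother, f_cov, m_cov) == expected


def test_trio_site_rejects_bad_states():
    with pytest.raises(ValidationError):
        classify_trio_site("0/1", "ref", "ref", "covered", "covered")
    with pytest.raises(ValidationError):
        classify_trio_site("het", "ref", "ref", "deep", "covered")


# ---------------------------------------------------------------------------
# comp-het pair classifier
# ---------------------------------------------------------------------------

_SLOT_STATES = ("called", "absent_covered", "absent_low", "absent_no_data")


def _slot(state):
    if state == "called":
        return True, "covered"
    return False, state.removeprefix("absent_")


def test_comphet_truth_table_matches_bruteforce():
    """All 4^4 parental (carrier x coverage) configurations agree with the
    completion-enumeration oracle."""
    for states in product(_SLOT_STATES, repeat=4):
        (c11, v11), (c12, v12), (c21, v21), (c22, v22) = map(_slot, states)
        got = classify_comphet_pair(c11, c12, c21, c22, v11, v12, v21, v22)
        assert got == brute_comphet_classifier(states), states


@pytest.mark.parametrize(
    "states,expected",
    [
        # v1 paternal only, v2 maternal only -> trans, confirmed
        (("called", "absent_covered", "absent_covered", "called"), "confirmed"),
        # both variants in one parent, absent in the other -> in phase
        (("called", "called", "absent_covered", "absent_covered"), None),
        # v1 paternal; v2 absent everywhere but mother unreadable at v2 -> possible
        (("called", "absent_covered", "absent_covered", "absent_low"), "possible"),
        # neither parent carries anything, everything readable -> two de novos
        (("absent_covered",) * 4, None),
    ],
)
def test_comphet_examples(states, expected):
    (c11, v11), (c12, v12), (c21, v21), (c22, v22) = map(_slot, states)
    assert classify_comphet_pair(c11, c12, c21, c22, v11, v12, v21, v22) == expected


# ---------------------------------------------------------------------------
# mosaic detection
# ---------------------------------------------------------------------------


def _call(sid, ad_ref, ad_alt):
    return GenotypeCall(sid, "1-100-A-T", "het", ad_ref=ad_ref, ad_alt=ad_alt)


@pytest.mark.parametrize(
    "ad,expected",
    [
        ((27, 3), True),   # AAF 0.10 with 3 alt reads at depth 30
        ((10, 10), False),  # constitutional het
        ((29, 1), False),   # below the alt-read floor
        ((5, 1), False),    # depth below 10
    ],
)
def test_mosaic_thresholds(ad, expected):
    parent = _call("P", *ad)
    child = _call("C", 12, 11)
    assert detect_parental_mosaic(parent, child) is expected


def test_mosaic_requires_allelic_depths():
    parent = GenotypeCall("P", "1-100-A-T", "het")
    with pytest.raises(ValidationError, match="AD"):
        detect_parental_mosaic(parent, _call("C", 12, 11))


def test_mosaic_config_is_tunable():
    parent = _call("P", 7, 3)  # AAF 0.30
    child = _call("C", 12, 11)
    assert detect_parental_mosaic(parent, child) is False
    assert detect_parental_mosaic(parent, child, MosaicConfig(mosaic_max_aaf=0.35)) is True


# ---------------------------------------------------------------------------
# family resolution
# ---------------------------------------------------------------------------


def _ped_row(fam, sid, pat="0", mat="0", phenotype=1):
    return SampleRecord(fam, sid, pat, mat, 0, phenotype)


def test_classic_trio_resolves():
    ped = [
        _ped_row("F1", "C", "D", "M", phenotype=2),
        _ped_row("F1", "D"), _ped_row("F1", "M"),
    ]
    fams = resolve_families(ped)
    assert len(fams.trios) == 1
    assert fams.trios[0].child_id == "C"
    assert set(fams.parent_child_pairs) == {("D", "C"), ("M", "C")}
    assert fams.singletons == []


def test_two_families_processed_independently():
    ped = [
        _ped_row("F1", "C1", "D1", "M1", 2), _ped_row("F1", "D1"), _ped_row("F1", "M1"),
        _ped_row("F2", "C2", "D2", "M2", 2), _ped_row("F2", "D2"), _ped_row("F2", "M2"),
    ]
    fams = resolve_families(ped)
    assert {t.family_id for t in fams.trios} == {"F1", "F2"}


def test_related_controls_excluded_from_frequencies():
    ped = [
        _ped_row("F1", "C", "D", "M", 2),
        _ped_row("F1", "D"), _ped_row("F1", "M"),  # parents are controls
        _ped_row("F2", "U1"), _ped_row("F3", "U2"),  # unrelated controls
    ]
    assert resolve_families(ped).excluded_controls == {"D", "M"}
    assert {r.sample_id for r in unrelated_controls(ped)} == {"U1", "U2"}


def test_ped_cycle_is_an_error():
    ped = [
        _ped_row("F1", "A", "B", "0", 2),
        _ped_row("F1", "B", "A", "0"),
    ]
    with pytest.raises(PedCycleError):
        resolve_families(ped)


def test_case_without_genotyped_parents_is_singleton():
    ped = [_ped_row("F1", "C", "D", "M", 2)]  # parents not in cohort
    fams = resolve_families(ped)
    assert fams.singletons == ["C"] and fams.trios == []


# ---------------------------------------------------------------------------
# end-to-end planted recovery
# ---------------------------------------------------------------------------


def test_planted_trio_recovered_exactly(trio_store, trio_samples, trio_paths):
    """The diagnostic run finds exactly the planted events, all confirmed."""
    report = run_diagnostic(trio_store, trio_samples, QVConfig())
    with open(trio_paths.manifest) as fh:
        manifest = json.load(fh)
    planted = {
        (e["category"], tuple(sorted(e["variants"]))) for e in manifest["planted"]
    }
    found = {
        (f.category, tuple(sorted(f.variants)))
        for f in report.findings
    }
    assert found == planted
    assert all(f.confidence == "confirmed" for f in report.findings)
    # supporting evidence is attached for all three members
    assert all(set(f.supporting) == {"child", "father", "mother"} for f in report.findings)


def test_degraded_parental_coverage_downgrades_to_possible(tmp_path):
    """Same trio, but the father's depth at the de novo site forced under
    10: the finding drops from confirmed to possible."""
    first = generate_trio(TRIO_PLANTED, tmp_path / "t0", seed=TRIO_SEED)
    with open(first.manifest) as fh:
        manifest = json.load(fh)
    (dn_variant,) = [e for e in manifest["planted"] if e["category"] == "de_novo"]
    pos = int(dn_variant["variants"][0].split("-")[1])

    degraded = generate_trio(
        TRIO_PLANTED, tmp_path / "t1", seed=TRIO_SEED,
        low_coverage_sites={"FATHER": [pos]},
    )
    store = build_store(degraded)
    from atavlite.ped import read_ped

    report = run_diagnostic(store, read_ped(degraded.ped), QVConfig())
    dn = [f for f in report.findings if f.category == "de_novo"]
    assert len(dn) == 1 and dn[0].confidence == "possible"
    assert dn[0].variants == tuple(dn_variant["variants"])


def test_unaffected_only_ped_gives_empty_report(trio_store, trio_samples):
    unaffected = [
        SampleRecord(r.family_id, r.sample_id, r.paternal_id, r.maternal_id, r.sex, 1)
        for r in trio_samples
    ]
    report = run_diagnostic(trio_store, unaffected, QVConfig())
    assert report.findings == [] and report.singleton_candidates == {}


def test_singleton_mode_lists_filtered_candidates(trio_store, trio_samples):
    child = [s for s in trio_samples if s.sample_id == "CHILD"][0]
    report = run_diagnostic(trio_store, [child], QVConfig())
    assert "CHILD" in report.singleton_candidates
    assert len(report.singleton_candidates["CHILD"]) > 0
    assert report.findings == []  # no trio categories without parents
    assert any("singleton" in n for n in report.notices)


def test_knownvar_tiers_attached_to_findings(trio_store, trio_samples, trio_paths):
    import pandas as pd
    from atavlite.annotation import KnownVar

    report0 = run_diagnostic(trio_store, trio_samples, QVConfig())
    dn = [f for f in report0.findings if f.category == "de_novo"][0]
    kv = KnownVar(
        pd.DataFrame(
            {
                "variant_id": [dn.variants[0]],
                "disease": ["synthetic disorder"],
                "clinical_significance": ["Pathogenic"],
                "variant_class": ["missense"],
                "pubmed_ids": ["1"],
                "source": ["ClinVar"],
            }
        )
    )
    report = run_diagnostic(trio_store, trio_samples, QVConfig(), knownvar=kv)
    dn2 = [f for f in report.findings if f.category == "de_novo"][0]
    assert dn2.annotations[dn.variants[0]]["exact"][0]["disease"] == "synthetic disorder"


def test_yield_percentages():
    assert diagnostic_yield(29, 119) == 24.0
    assert diagnostic_yield(15, 246, decimals=1) == 6.1
    with pytest.raises(ValidationError):
        diagnostic_yield(5, 0)
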