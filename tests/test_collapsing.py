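"""Collapsing workflow: QV filters, harmonization, matrix, tests, lite."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from atavlite.collapsing import (
    CollapsingMatrix,
    HarmonizationConfig,
    QVConfig,
    ScoreThreshold,
    binomial_decision,
    build_matrix,
    collapsing_lite,
    fisher_gene_test,
    permutation_lambda,
    phenotype_vector,
    proportion_decision,
    run_collapsing,
    select_qualifying_variants,
)
from atavlite.errors import ConfigOrderError, ConfigurationError, ValidationError
from atavlite.simulate import generate_carrier_matrix

from oracles import binomial_two_sided


# ---------------------------------------------------------------------------
# QV selection
# ---------------------------------------------------------------------------


def _variant_objects(store, samples):
    objs = []
    for gene in store.gene_model.genes:
        objs.extend(store.query_region(samples, gene=gene))
    return objs


def test_per_genotype_filter_excludes_single_sample(cohort_store, cohort_samples):
    objs = _variant_objects(cohort_store, cohort_samples)
    loose = select_qualifying_variants(QVConfig(), cohort_samples, objs)
    strict = select_qualifying_variants(QVConfig(min_gq=20), cohort_samples, objs)
    dropped = set(map(tuple, loose.qv_df[["sample_id", "variant_id"]].values)) - set(
        map(tuple, strict.qv_df[["sample_id", "variant_id"]].values)
    )
    assert dropped  # the generator plants some failing GQs
    # every dropped pair had GQ < 20; the same variant stays for other samples
    low = loose.qv_df.set_index(["sample_id", "variant_id"])
    for key in dropped:
        assert low.loc[key, "gq"] < 20


def test_internal_maf_filter_is_per_variant(cohort_store, cohort_samples):
    objs = _variant_objects(cohort_store, cohort_samples)
    sel = select_qualifying_variants(
        QVConfig(max_internal_maf=0.01), cohort_samples, objs
    )
    frequent = {
        o.variant.variant_id
        for o in objs
        if o.frequency.maf is not None and o.frequency.maf > 0.01
    }
    assert frequent  # fixture has recurrent variants
    assert not set(sel.qv_df["variant_id"]) & frequent


def test_selection_matches_bruteforce_predicate(cohort_store, cohort_samples):
    """Random config vs exhaustive per-(sample, variant) re-evaluation."""
    objs = _variant_objects(cohort_store, cohort_samples)
    config = QVConfig(
        min_gq=40, min_qd=10, max_internal_maf=0.08, max_external_maf=0.01,
        allowed_effects=frozenset({"missense_variant"}),
        score_thresholds=(ScoreThreshold("intolerance", "max", 1.0),),
    )
    sel = select_qualifying_variants(config, cohort_samples, objs)
    got = set(map(tuple, sel.qv_df[["sample_id", "variant_id"]].values))

    expected = set()
    for obj in objs:
        maf = obj.frequency.maf
        ext = obj.external.get("external_af") or 0.0
        intol = obj.external.get("intolerance")
        v_ok = (
            obj.effect == "missense_variant"
            and maf is not None and maf <= 0.08
            and min(ext, 1 - ext) <= 0.01
            and intol is not None and intol <= 1.0
        )
        for call in obj.calls:
            if (
                v_ok
                and call.passes_filter
                and call.gq is not None and call.gq >= 40
                and call.qd is not None and call.qd >= 10
            ):
                expected.add((call.sample_id, call.variant_id))
    assert got == expected


def test_unknown_score_is_configuration_error(cohort_store, cohort_samples):
    objs = _variant_objects(cohort_store, cohort_samples)
    config = QVConfig(score_thresholds=(ScoreThreshold("revel", "min", 0.5),))
    with pytest.raises(ConfigurationError, match="revel"):
        select_qualifying_variants(config, cohort_samples, objs)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


def test_proportion_decision_examples():
    assert proportion_decision(100, 100, 100, 100, 0.07) == "keep"
    assert proportion_decision(95, 100, 60, 100, 0.07) == "remove"  # 0.35 > 0.07
    with pytest.raises(ValidationError):
        proportion_decision(0, 0, 5, 10)


def test_binomial_null_exact_and_extreme_tail():
    # covered case fraction equals the cohort fraction -> p = 1
    p, decision = binomial_decision(30, 60, 30, 60)
    assert p == pytest.approx(1.0) and decision == "keep"
    # 0 covered cases of 50 covered in a balanced cohort: p = 2 * (1/2)^50
    p, decision = binomial_decision(0, 500, 50, 500, alpha=0.05)
    assert p == pytest.approx(2 * 0.5**50, rel=1e-12) and decision == "remove"


def test_binomial_matches_exact_tail_oracle():
    rng = np.random.default_rng(17)
    for _ in range(60):
        n_cases = int(rng.integers(5, 60))
        n_controls = int(rng.integers(5, 60))
        cc = int(rng.integers(0, n_cases + 1))
        uc = int(rng.integers(0, n_controls + 1))
        if cc + uc == 0:
            continue
        p, _ = binomial_decision(cc, n_cases, uc, n_controls)
        expected = binomial_two_sided(cc, cc + uc, n_cases, n_cases + n_controls)
        assert p == pytest.approx(expected, abs=1e-12)


def test_zero_covered_individuals_keeps_with_undefined_p(caplog):
    p, decision = binomial_decision(0, 10, 0, 10)
    assert p is None and decision == "keep"


# ---------------------------------------------------------------------------
# matrix
# ---------------------------------------------------------------------------


def _qv_df(rows):
    return pd.DataFrame(rows, columns=["sample_id", "variant_id", "gene", "zygosity"])


def test_matrix_models_single_het():
    df = _qv_df([("S1", "v1", "G1", "het")])
    dom = build_matrix(df, "dominant", ["S1", "S2"], ["G1"])
    rec = build_matrix(df, "recessive", ["S1", "S2"], ["G1"])
    assert dom.cells.tolist() == [[1, 0]]
    assert rec.cells.tolist() == [[0, 0]]
    assert dom.qv_provenance[("G1", "S1")] == ["v1"]


def test_matrix_recessive_rules():
    hom = _qv_df([("S1", "v1", "G1", "hom_alt")])
    two_het = _qv_df([("S1", "v1", "G1", "het"), ("S1", "v2", "G1", "het")])
    same_het_twice = _qv_df([("S1", "v1", "G1", "het"), ("S1", "v1", "G1", "het")])
    assert build_matrix(hom, "recessive", ["S1"], ["G1"]).cells.tolist() == [[1]]
    assert build_matrix(two_het, "recessive", ["S1"], ["G1"]).cells.tolist() == [[1]]
    assert build_matrix(same_het_twice, "recessive", ["S1"], ["G1"]).cells.tolist() == [[0]]


def test_matrix_matches_bruteforce_cells(cohort_store, cohort_samples):
    objs = _variant_objects(cohort_store, cohort_samples)
    sel = select_qualifying_variants(QVConfig(), cohort_samples, objs)
    genes = cohort_store.gene_model.genes
    sample_ids = [s.sample_id for s in cohort_samples]
    for model in ("dominant", "recessive"):
        matrix = build_matrix(sel, model, sample_ids, genes)
        for gi, gene in enumerate(genes):
            for si, sid in enumerate(sample_ids):
                hits = sel.qv_df[
                    (sel.qv_df.gene == gene) & (sel.qv_df.sample_id == sid)
                ]
                if model == "dominant":
                    expected = int(len(hits) > 0)
                else:
                    expected = int(
                        (hits.zygosity == "hom_alt").any()
                        or hits[hits.zygosity == "het"].variant_id.nunique() >= 2
                    )
                assert matrix.cells[gi, si] == expected
        # provenance non-empty exactly where the cell is 1
        for (gene, sid), vids in matrix.qv_provenance.items():
            assert vids and matrix.cells[genes.index(gene), sample_ids.index(sid)] == 1


# ---------------------------------------------------------------------------
# Fisher per gene
# ---------------------------------------------------------------------------


def _toy_matrix(cells, model="dominant"):
    cells = np.asarray(cells, dtype=np.int8)
    return CollapsingMatrix(
        [f"G{i}" for i in range(cells.shape[0])],
        [f"S{i}" for i in range(cells.shape[1])],
        cells, {}, model,
    )


def test_zero_carrier_gene_is_uninformative_p1():
    m = _toy_matrix(np.zeros((1, 10)))
    df = fisher_gene_test(m, np.array([True] * 5 + [False] * 5))
    assert df.loc[0, "fisher_p"] == 1.0 and bool(df.loc[0, "uninformative"])


def test_fisher_counts_sum_to_cohort_and_match_scipy():
    rng = np.random.default_rng(9)
    m = _toy_matrix(rng.integers(0, 2, size=(20, 30)))
    is_case = np.array([True] * 12 + [False] * 18)
    df = fisher_gene_test(m, is_case).set_index("gene")
    for gene in m.genes:
        row = df.loc[gene]
        assert (
            row.case_carriers + row.case_noncarriers
            + row.control_carriers + row.control_noncarriers
            == 30
        )
        _, p = fisher_exact(
            [[row.case_carriers, row.case_noncarriers],
             [row.control_carriers, row.control_noncarriers]]
        )
        assert row.fisher_p == pytest.approx(p, abs=1e-15)


def test_fisher_invariant_under_sample_permutation():
    rng = np.random.default_rng(10)
    cells = rng.integers(0, 2, size=(8, 40))
    is_case = np.array([True] * 15 + [False] * 25)
    perm = rng.permutation(40)
    a = fisher_gene_test(_toy_matrix(cells), is_case)
    b = fisher_gene_test(_toy_matrix(cells[:, perm]), is_case[perm])
    pd.testing.assert_frame_equal(a, b)


def test_phenotype_vector_requires_phenotypes(cohort_samples):
    from atavlite.ped import SampleRecord

    with pytest.raises(ValidationError, match="phenotype"):
        phenotype_vector(["X1"], [SampleRecord("F", "X1", phenotype=0)])


# ---------------------------------------------------------------------------
# permutation lambda
# ---------------------------------------------------------------------------


def _null_matrix(n_genes=300, n=160, seed=5):
    cells, is_case = generate_carrier_matrix(n_genes, n // 2, n // 2, 0.08, seed=seed)
    return _toy_matrix(cells), is_case


def test_lambda_requires_floor_and_seed():
    m, is_case = _null_matrix(50, 40)
    with pytest.raises(ValidationError):
        permutation_lambda(m, is_case, n_perm=50, seed=1)
    with pytest.raises(ValidationError):
        permutation_lambda(m, is_case, n_perm=200, seed=None)


def test_lambda_estimate_contract():
    m, is_case = _null_matrix()
    est = permutation_lambda(m, is_case, n_perm=200, seed=2)
    assert est.lambda_ > 0
    assert np.all(np.diff(est.expected_p) >= 0)
    assert np.all((est.expected_p > 0) & (est.expected_p <= 1))
    assert len(est.qq) == len(m.genes)
    # same seed -> same estimate
    est2 = permutation_lambda(m, is_case, n_perm=200, seed=2)
    assert est2.lambda_ == est.lambda_


def test_doubling_permutations_is_within_monte_carlo_error():
    m, is_case = _null_matrix()
    a = permutation_lambda(m, is_case, n_perm=400, seed=3)
    b = permutation_lambda(m, is_case, n_perm=800, seed=4)
    # order-statistic means have SE <= 0.5/sqrt(n_perm); allow 4 sigma
    bound = 4 * 0.5 / np.sqrt(400)
    assert np.max(np.abs(a.expected_p - b.expected_p)) < bound


def test_planted_case_coverage_artifact_inflates_lambda():
    cells, is_case = generate_carrier_matrix(
        300, 80, 80, 0.08, global_case_multiplier=2.5, seed=6
    )
    stressed = permutation_lambda(_toy_matrix(cells), is_case, n_perm=200, seed=7)
    null_est = permutation_lambda(*_null_matrix(300, 160, 6), n_perm=200, seed=7)
    assert stressed.lambda_ > 1.3 > null_est.lambda_ * 1.05


def test_null_type_one_error_within_binomial_bound():
    """Fraction of null genes with Fisher p < 0.05 stays under
    0.05 + 3 * binomial SE (Fisher is conservative on sparse tables)."""
    m, is_case = _null_matrix(500, 200, seed=11)
    df = fisher_gene_test(m, is_case)
    frac = (df["fisher_p"] < 0.05).mean()
    assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 500)


def test_planted_enrichment_ranks_top():
    """5x case enrichment in 10 of 100 genes puts those genes at the top of
    the ranking (median over seeds)."""
    hits = []
    for seed in range(5):
        cells, is_case = generate_carrier_matrix(
            100, 300, 300, 0.05, enriched={i: 5.0 for i in range(10)}, seed=seed
        )
        m = _toy_matrix(cells)
        df = fisher_gene_test(m, is_case)
        top10 = set(df.head(10)["gene"])
        hits.append(len(top10 & {f"G{i}" for i in range(10)}))
    assert np.median(hits) >= 9


# ---------------------------------------------------------------------------
# strictness partial order + collapsing-lite
# ---------------------------------------------------------------------------


def test_strictness_partial_order():
    relaxed = QVConfig(min_gq=20, max_external_maf=0.01)
    strict = QVConfig(min_gq=50, max_external_maf=0.001)
    assert strict.is_stricter_than(relaxed)
    assert strict.is_stricter_than(strict)  # reflexive
    assert not relaxed.is_stricter_than(strict)
    incomparable = QVConfig(min_gq=10, max_external_maf=0.0001)
    assert not incomparable.is_stricter_than(relaxed)
    assert "min_gq" in incomparable.widened_filters(relaxed)


def test_lite_identity_config_reproduces_results(cohort_store, cohort_samples):
    config = QVConfig(min_gq=20, max_external_maf=0.01)
    full = run_collapsing(cohort_store, cohort_samples, config)
    lite = collapsing_lite(full, config)
    pd.testing.assert_frame_equal(full.results, lite.results)
    assert np.array_equal(full.matrix.cells, lite.matrix.cells)


def test_lite_rejects_widened_filter(cohort_store, cohort_samples):
    full = run_collapsing(cohort_store, cohort_samples, QVConfig(min_gq=40))
    with pytest.raises(ConfigOrderError, match="min_gq"):
        collapsing_lite(full, QVConfig(min_gq=20))


def _random_config_pair(rng):
    relaxed = QVConfig(
        min_gq=int(rng.choice([0, 20])),
        max_internal_maf=float(rng.choice([0.5, 0.2])),
        max_external_maf=float(rng.choice([0.5, 0.05])),
    )
    strict = QVConfig(
        min_gq=relaxed.min_gq + int(rng.choice([0, 30, 60])),
        min_qd=float(rng.choice([0, 10])) or None,
        max_internal_maf=relaxed.max_internal_maf * float(rng.choice([1.0, 0.5, 0.1])),
        max_external_maf=relaxed.max_external_maf * float(rng.choice([1.0, 0.1, 0.0])),
        allowed_effects=None if rng.random() < 0.5 else frozenset({"missense_variant"}),
        score_thresholds=()
        if rng.random() < 0.5
        else (ScoreThreshold("intolerance", "max", float(rng.choice([0.0, 2.0]))),),
        model=str(rng.choice(["dominant", "recessive"])),
    )
    return relaxed, strict


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_lite_equals_full_run_on_random_config_pairs(
    cohort_store, cohort_samples, seed
):
    rng = np.random.default_rng(seed)
    relaxed, strict = _random_config_pair(rng)
    first_pass = run_collapsing(cohort_store, cohort_samples, relaxed)
    lite = collapsing_lite(first_pass, strict)
    full = run_collapsing(cohort_store, cohort_samples, strict)
    pd.testing.assert_frame_equal(lite.results, full.results)
    assert np.array_equal(lite.matrix.cells, full.matrix.cells)


def test_run_output_save_load_round_trip(cohort_store, cohort_samples, tmp_path):
    from atavlite.collapsing import CollapsingRunOutput

    config = QVConfig(min_gq=20)
    out = run_collapsing(cohort_store, cohort_samples, config,
                         harmonization=HarmonizationConfig("binomial"))
    out.save(tmp_path / "run")
    loaded = CollapsingRunOutput.load(tmp_path / "run")
    assert loaded.config == config
    assert np.array_equal(loaded.matrix.cells, out.matrix.cells)
    lite = collapsing_lite(loaded, QVConfig(min_gq=60))
    full = run_collapsing(cohort_store, cohort_samples, QVConfig(min_gq=60),
                          harmonization=HarmonizationConfig("binomial"))
    pd.testing.assert_frame_equal(lite.results, full.results)
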