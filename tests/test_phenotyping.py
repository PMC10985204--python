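"""Gating engine, annotation schemas, and T cell state classifier tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from micsflow import phenotyping as PH

from oracles import (
    eval_gate_scalar,
    exhaustive_schema_labels,
    phenotype_table_from_bits,
    table_from_phenotypes,
)


def _table(markers: dict[str, list[float]]) -> pd.DataFrame:
    n = len(next(iter(markers.values())))
    df = pd.DataFrame({f"{m}__cell__norm": v for m, v in markers.items()})
    df.insert(0, "cell_id", np.arange(1, n + 1))
    return df


HALF = {"CD3": 0.5, "CD4": 0.5, "CD8": 0.5, "CD25": 0.5, "FoxP3": 0.5}


# ---------------------------------------------------------------------------
# schema structure


def test_builtin_schema_cardinalities():
    assert len(PH.builtin_schema("main_populations").labels) == 16
    assert len(PH.builtin_schema("tonsil").labels) == 13
    assert len(PH.DIFFERENTIATION_STATES) == 6


def test_schema_rejects_duplicate_labels():
    with pytest.raises(PH.SchemaError, match="duplicate"):
        PH.AnnotationSchema("x", [
            {"label": "a", "priority": 1, "gate": {"marker": "M"}},
            {"label": "a", "priority": 2, "gate": {"marker": "M"}},
        ])


def test_schema_rejects_duplicate_priorities():
    with pytest.raises(PH.SchemaError, match="priorit"):
        PH.AnnotationSchema("x", [
            {"label": "a", "priority": 1, "gate": {"marker": "M"}},
            {"label": "b", "priority": 1, "gate": {"marker": "M"}},
        ])


def test_missing_marker_raises_before_labeling():
    cells = _table({"CD3": [1.0]})
    with pytest.raises(PH.SchemaError, match="missing"):
        PH.apply_schema(cells, PH.builtin_schema("tcell_subsets"))


# ---------------------------------------------------------------------------
# gate evaluation vs exhaustive oracle


@pytest.mark.parametrize("name", ["main_populations", "tonsil", "tcell_subsets"])
def test_engine_matches_exhaustive_enumeration(name):
    schema = PH.builtin_schema(name)
    markers = sorted(schema.markers())
    idx, expected = exhaustive_schema_labels(schema, markers)
    cells = phenotype_table_from_bits(idx, markers)
    out = PH.apply_schema(cells, schema, thresholds={m: 0.5 for m in markers})
    got = out[f"label_{schema.name}"].to_numpy()
    assert np.array_equal(got, expected)


def test_explicit_threshold_atoms_and_population_refs():
    schema = PH.AnnotationSchema("mini", [
        {"label": "bright", "priority": 2,
         "gate": {"marker": "A", "op": ">=", "value": 5.0}},
        {"label": "bright-B", "priority": 3,
         "gate": {"all": [{"population": "bright"}, {"marker": "B"}]}},
        {"label": "dim", "priority": 1, "gate": {"not": {"marker": "A"}}},
    ])
    cells = _table({"A": [9.0, 9.0, 1.0, 0.0], "B": [1.0, 0.0, 1.0, 0.0]})
    out = PH.apply_schema(cells, schema, thresholds={"A": 2.0, "B": 0.5})
    # row 3: A=1.0 is below the positivity threshold 2.0, so not{A} holds
    assert list(out["label_mini"]) == ["bright-B", "bright", "dim", "dim"]


def test_unknown_gate_node_rejected():
    with pytest.raises(PH.SchemaError):
        PH.gate_markers({"xor": []})
    cells = _table({"A": [1.0]})
    vals = PH.marker_matrix(cells)
    pos = PH.positivity(vals, {"A": 0.5})
    with pytest.raises(PH.SchemaError):
        PH.evaluate_gate({"xor": []}, pos, vals, {})


def test_tcell_subset_examples():
    schema = PH.builtin_schema("tcell_subsets")
    cells = _table({
        "CD3":   [1.0, 1.0, 1.0, 1.0],
        "CD4":   [0.0, 1.0, 1.0, 0.0],
        "CD8":   [1.0, 0.0, 0.0, 0.0],
        "CD25":  [0.0, 0.0, 1.0, 0.0],
        "FoxP3": [0.0, 0.0, 1.0, 0.0],
    })
    out = PH.apply_schema(cells, schema, thresholds=HALF)
    assert list(out[f"label_{schema.name}"]) == ["Tc", "Th", "Treg", "other T"]


@pytest.mark.parametrize(
    "name,phenotypes",
    [("main_populations", PH.MAIN_POPULATION_PHENOTYPES),
     ("tonsil", PH.TONSIL_PHENOTYPES)],
)
def test_defining_phenotypes_classified_perfectly(name, phenotypes):
    schema = PH.builtin_schema(name)
    markers = sorted(set().union(*phenotypes.values()) | schema.markers())
    cells = table_from_phenotypes(phenotypes, markers)
    out = PH.apply_schema(cells, schema, thresholds={m: 0.5 for m in markers})
    assert (out[f"label_{schema.name}"] == out["true_label"]).all()


def test_apply_schema_row_order_invariant():
    schema = PH.builtin_schema("tcell_subsets")
    markers = sorted(schema.markers())
    rng = np.random.default_rng(2)
    cells = _table({m: rng.uniform(0, 1, 50).tolist() for m in markers})
    out = PH.apply_schema(cells, schema, thresholds=HALF)
    shuffled = cells.sample(frac=1.0, random_state=1).reset_index(drop=True)
    out_s = PH.apply_schema(shuffled, schema, thresholds=HALF)
    merged = out.merge(out_s, on="cell_id", suffixes=("_a", "_b"))
    col = f"label_{schema.name}"
    assert (merged[f"{col}_a"] == merged[f"{col}_b"]).all()


# ---------------------------------------------------------------------------
# automatic thresholds


def test_threshold_largest_gap_bimodal():
    vals = pd.DataFrame({"M": [0.1, 0.2, 0.3, 4.0, 4.1, 4.2]})
    thr = PH.estimate_thresholds(vals)
    assert thr["M"] == pytest.approx((0.3 + 4.0) / 2)


def test_threshold_constant_marker_all_negative():
    vals = pd.DataFrame({"M": [2.0] * 10})
    thr = PH.estimate_thresholds(vals)
    pos = PH.positivity(vals, thr)
    assert not pos["M"].any()


def test_threshold_overrides_win():
    vals = pd.DataFrame({"M": [0.0, 1.0]})
    thr = PH.estimate_thresholds(vals, overrides={"M": 10.0})
    assert thr["M"] == 10.0


def test_positivity_requires_all_thresholds():
    vals = pd.DataFrame({"A": [1.0], "B": [1.0]})
    with pytest.raises(PH.SchemaError, match="B"):
        PH.positivity(vals, {"A": 0.5})


# ---------------------------------------------------------------------------
# differentiation states


def _diff_table(phenos: list[dict[str, bool]]) -> pd.DataFrame:
    markers = ["CD45RA", "CD45RO", "CD27", "CD95", "CD11a"]
    return _table({m: [1.0 if p.get(m) else 0.0 for p in phenos] for m in markers})


DIFF_THR = {m: 0.5 for m in ["CD45RA", "CD45RO", "CD27", "CD95", "CD11a"]}


def test_differentiation_examples():
    phenos = [
        {"CD45RA": True, "CD27": True},                                  # TN
        {"CD45RA": True, "CD27": True, "CD95": True, "CD11a": True},     # TSCM
        {"CD45RO": True, "CD27": True, "CD11a": True},                   # TCM
        {"CD45RO": True, "CD11a": True},                                 # TEM
        {"CD45RA": True, "CD95": True, "CD11a": True},                   # TEMRA
        {"CD45RA": True, "CD11a": True},                                 # TTE
        {"CD45RO": True},                                                # other
    ]
    out = PH.t_cell_differentiation(_diff_table(phenos), thresholds=DIFF_THR)
    assert list(out["label_diff"]) == [
        "TN", "TSCM", "TCM", "TEM", "TEMRA", "TTE", "other T"
    ]


def test_differentiation_exhaustive_first_match_oracle():
    markers = ["CD45RA", "CD45RO", "CD27", "CD95", "CD11a"]
    combos = [
        {m: bool((i >> k) & 1) for k, m in enumerate(markers)}
        for i in range(32)
    ]
    out = PH.t_cell_differentiation(_diff_table(combos), thresholds=DIFF_THR)

    def oracle(pheno):
        for label, req in PH.DEFAULT_DIFFERENTIATION_TABLE:
            if all(pheno[m] == want for m, want in req.items() if want is not None):
                return label
        return "other T"

    assert list(out["label_diff"]) == [oracle(p) for p in combos]


def test_differentiation_overlapping_table_warns():
    table = [
        ("A", {"CD45RA": True}),
        ("B", {"CD45RA": True, "CD27": True}),
    ]
    with pytest.warns(UserWarning, match="ambiguous"):
        PH.t_cell_differentiation(
            _diff_table([{"CD45RA": True}]), table=table, thresholds=DIFF_THR
        )


def test_default_differentiation_table_not_ambiguous():
    assert PH.validate_differentiation_table(PH.DEFAULT_DIFFERENTIATION_TABLE) == []


# ---------------------------------------------------------------------------
# activation / PD1 tiers / exhaustion


ACT_THR = {"CD69": 0.5, "CD25": 0.5, "HLA-DR": 0.5}


def test_activation_ladder_enumeration():
    combos = [
        {m: bool((i >> k) & 1) for k, m in enumerate(["CD69", "CD25", "HLA-DR"])}
        for i in range(8)
    ]
    cells = _table({
        m: [1.0 if c[m] else 0.0 for c in combos]
        for m in ["CD69", "CD25", "HLA-DR"]
    })
    out = PH.activation_tier(cells, thresholds=ACT_THR)

    def oracle(c):
        if c["HLA-DR"]:
            return "very_late"
        if c["CD25"]:
            return "late"
        if c["CD69"]:
            return "early"
        return "none"

    assert list(out["label_activation"]) == [oracle(c) for c in combos]


def test_exhaustion_ladder_enumeration():
    combos = [
        {m: bool((i >> k) & 1) for k, m in enumerate(["PD1", "TIM3", "LAG3"])}
        for i in range(8)
    ]
    cells = _table({
        m: [1.0 if c[m] else 0.0 for c in combos] for m in ["PD1", "TIM3", "LAG3"]
    })
    out = PH.exhaustion_class(
        cells, thresholds={"PD1": 0.5, "TIM3": 0.5, "LAG3": 0.5}
    )

    def oracle(c):
        if not c["PD1"]:
            return "none"
        n = int(c["TIM3"]) + int(c["LAG3"])
        return {0: "single", 1: "double", 2: "triple"}[n]

    assert list(out["label_exhaustion"]) == [oracle(c) for c in combos]


def test_pd1_quartile_tiers_distinct_values():
    cells = _table({"PD1": list(np.linspace(0, 5, 100))})
    out = PH.pd1_tiers(cells)
    counts = out["tier_pd1"].value_counts()
    assert counts["low"] == 25 and counts["intermediate"] == 50 and counts["high"] == 25
    # rank exactly at the 75th-percentile cut lands in the upper tier
    assert out.loc[75, "tier_pd1"] == "high"
    assert out.loc[74, "tier_pd1"] == "intermediate"


def test_pd1_tiers_all_equal_single_tier():
    cells = _table({"PD1": [2.0] * 40})
    out = PH.pd1_tiers(cells)
    assert (out["tier_pd1"] == "intermediate").all()


def test_pd1_tiers_nan_unassigned_and_empty_reference():
    cells = _table({"PD1": [1.0, np.nan, 3.0]})
    out = PH.pd1_tiers(cells)
    assert out.loc[1, "tier_pd1"] == "unassigned"
    cells_all_nan = _table({"PD1": [np.nan, np.nan]})
    with pytest.raises(PH.SchemaError, match="reference"):
        PH.pd1_tiers(cells_all_nan)


def test_pd1_tiers_reference_population_restriction():
    cells = _table({"PD1": [0.0, 1.0, 2.0, 3.0, 100.0]})
    cells["is_t"] = [True, True, True, True, False]
    out = PH.pd1_tiers(cells, PH.TierSpec(reference_column="is_t"))
    # 100.0 ranks above the whole reference -> high, despite being excluded
    assert out.loc[4, "tier_pd1"] == "high"


def test_tier_spec_validation():
    with pytest.raises(ValueError):
        PH.TierSpec(cut_percentiles=(75.0, 25.0))
    with pytest.raises(ValueError):
        PH.TierSpec(cut_percentiles=(25.0, 75.0), tier_labels=("a", "b"))


def test_percentile_rank_average_ties():
    ref = np.array([1.0, 2.0, 2.0, 3.0])
    pr = PH.percentile_rank(np.array([2.0]), ref)
    # ranks of the two 2.0s are 2 and 3 -> average 2.5 -> pr = 100*(1.5)/4
    assert pr[0] == pytest.approx(37.5)


# ---------------------------------------------------------------------------
# composition and merging


def test_composition_counts_and_fractions():
    cells = pd.DataFrame({"lab": ["A"] * 4 + ["B"] * 6 + ["unassigned"] * 2})
    comp = PH.composition(cells, "lab").set_index("label")
    assert comp.loc["A", "count"] == 4
    assert comp.loc["A", "fraction"] == pytest.approx(0.4)
    assert comp.loc["B", "fraction"] == pytest.approx(0.6)
    assert comp.loc["unassigned", "count"] == 2
    assert np.isnan(comp.loc["unassigned", "fraction"])


def test_composition_empty_table():
    comp = PH.composition(pd.DataFrame({"lab": []}), "lab")
    assert len(comp) == 0


def test_merge_populations_union():
    cells = pd.DataFrame({"lab": ["Th", "Tc", "B", "Treg"]})
    out = PH.merge_populations(cells, "lab", ["Th", "Tc", "Treg"], "T cells")
    assert list(out["lab"]) == ["T cells", "T cells", "B", "T cells"]


# ---------------------------------------------------------------------------
# scalar oracle self-check (guards the oracle itself)


def test_scalar_gate_oracle_examples():
    gate = {"all": [{"marker": "A"}, {"not": {"marker": "B"}}]}
    assert eval_gate_scalar(gate, {"A": True, "B": False}, {}, {})
    assert not eval_gate_scalar(gate, {"A": True, "B": True}, {}, {})
    assert eval_gate_scalar({"any": []}, {}, {}, {}) is False
    assert eval_gate_scalar({"all": []}, {}, {}, {}) is True
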