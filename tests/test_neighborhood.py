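"""Radius-query neighborhood analysis tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from micsflow import neighborhood as N
from micsflow import synth

from oracles import brute_force_radius_query

LABEL = "label_main"


def _cells(rows):
    """rows: list of (cell_id, label, cy_um, cx_um)."""
    return pd.DataFrame(rows, columns=["cell_id", LABEL, "cy_um", "cx_um"])


def _random_scene(seed, n, labels=("T cells", "B cells", "mDC", "unassigned")):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "cell_id": np.arange(1, n + 1),
        LABEL: rng.choice(labels, size=n),
        "cy_um": rng.uniform(0, 400, n),
        "cx_um": rng.uniform(0, 400, n),
    })


# ---------------------------------------------------------------------------
# query mechanics


def test_query_validation():
    with pytest.raises(ValueError, match="radius"):
        N.NeighborhoodQuery(anchor_population="T cells", radius_um=0)
    with pytest.raises(ValueError, match="anchor"):
        N.NeighborhoodQuery()
    with pytest.raises(NotImplementedError):
        N.NeighborhoodQuery(anchor_population="x", distance_mode="boundary")


def test_inclusion_exclusion_at_radius():
    cells = _cells([
        (1, "T cells", 0.0, 0.0),
        (2, "B cells", 0.0, 4.0),   # inside radius 5
        (3, "B cells", 0.0, 5.0),   # exactly at the radius: included
        (4, "B cells", 0.0, 6.0),   # outside
    ])
    q = N.NeighborhoodQuery(anchor_population="T cells", radius_um=5.0)
    res = N.radius_query(cells, q, LABEL)
    assert res.per_anchor == {1: [2, 3]}
    assert res.pooled == [2, 3]
    assert list(res.edges["neighbor_id"]) == [2, 3]
    assert res.edges["distance_um"].tolist() == [4.0, 5.0]


def test_anchors_excluded_unless_requested():
    cells = _cells([
        (1, "T cells", 0.0, 0.0),
        (2, "T cells", 0.0, 1.0),
        (3, "B cells", 0.0, 2.0),
    ])
    q = N.NeighborhoodQuery(anchor_population="T cells", radius_um=5.0)
    res = N.radius_query(cells, q, LABEL)
    assert res.pooled == [3]
    q_incl = N.NeighborhoodQuery(
        anchor_population="T cells", radius_um=5.0, include_anchors=True
    )
    res2 = N.radius_query(cells, q_incl, LABEL)
    assert res2.per_anchor[1] == [2, 3]


def test_no_anchors_error_names_population():
    cells = _cells([(1, "B cells", 0.0, 0.0)])
    q = N.NeighborhoodQuery(anchor_population="T cells", radius_um=5.0)
    with pytest.raises(ValueError, match="T cells"):
        N.radius_query(cells, q, LABEL)


def test_anchor_ids_select_rows():
    cells = _cells([
        (1, "T cells", 0.0, 0.0),
        (2, "B cells", 0.0, 3.0),
        (3, "B cells", 0.0, 50.0),
    ])
    q = N.NeighborhoodQuery(anchor_ids=(1,), radius_um=5.0)
    res = N.radius_query(cells, q, LABEL)
    assert res.pooled == [2]


def test_missing_coordinate_columns():
    cells = pd.DataFrame({"cell_id": [1], LABEL: ["T cells"]})
    q = N.NeighborhoodQuery(anchor_population="T cells", radius_um=5.0)
    with pytest.raises(ValueError, match="cy_um"):
        N.radius_query(cells, q, LABEL)


# ---------------------------------------------------------------------------
# oracle equivalence and monotonicity


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("radius", [5.0, 25.0])
def test_matches_brute_force(seed, radius):
    cells = _random_scene(seed, 300)
    q = N.NeighborhoodQuery(anchor_population="T cells", radius_um=radius)
    res = N.radius_query(cells, q, LABEL)
    mask = (cells[LABEL] == "T cells").to_numpy()
    per, pooled = brute_force_radius_query(cells, radius, mask)
    assert res.per_anchor == per
    assert res.pooled == pooled


def test_touch_radius_subset_of_niche_radius():
    cells = _random_scene(7, 400)
    q5 = N.NeighborhoodQuery(anchor_population="T cells", radius_um=5.0)
    q25 = N.NeighborhoodQuery(anchor_population="T cells", radius_um=25.0)
    r5 = N.radius_query(cells, q5, LABEL)
    r25 = N.radius_query(cells, q25, LABEL)
    assert set(r5.pooled) <= set(r25.pooled)
    for aid, neigh in r5.per_anchor.items():
        assert set(neigh) <= set(r25.per_anchor[aid])


def test_symmetry_between_cells():
    cells = _cells([
        (1, "T cells", 0.0, 0.0),
        (2, "T cells", 0.0, 3.0),
    ])
    q = N.NeighborhoodQuery(
        anchor_population="T cells", radius_um=5.0, include_anchors=True
    )
    res = N.radius_query(cells, q, LABEL)
    assert res.per_anchor == {1: [2], 2: [1]}


# ---------------------------------------------------------------------------
# composition intersection and profiles


def test_intersect_populations_counts():
    cells = _cells([
        (1, "T cells", 0, 0), (2, "Macrophages", 0, 1), (3, "Macrophages", 0, 2),
        (4, "mDC", 0, 3), (5, "B cells", 0, 99), (6, "unassigned", 0, 4),
    ])
    comp = N.intersect_populations(cells, [2, 3, 4, 6], LABEL).set_index("label")
    assert comp.loc["Macrophages", "count"] == 2
    assert comp.loc["Macrophages", "fraction"] == pytest.approx(2 / 3)
    assert comp.loc["mDC", "fraction"] == pytest.approx(1 / 3)
    assert comp.loc["B cells", "count"] == 0
    assert np.isnan(comp.loc["unassigned", "fraction"])


def test_intersect_empty_pool_all_nan():
    cells = _cells([(1, "T cells", 0, 0), (2, "B cells", 0, 1)])
    comp = N.intersect_populations(cells, [], LABEL)
    assert (comp["count"] == 0).all()
    assert comp["fraction"].isna().all()


def test_profile_single_neighbor_degenerate_quartiles():
    cells = _cells([(1, "T cells", 0, 0), (2, "B cells", 0, 1)])
    cells["CD73__cell__norm"] = [0.0, 2.5]
    prof = N.neighbor_expression_profile(cells, [2], LABEL, markers=("CD73",))
    row = prof.set_index("label").loc["B cells"]
    assert row["n"] == 1
    assert row["median"] == 2.5 and row["q25"] == 2.5 and row["q75"] == 2.5


def test_profile_missing_marker_errors():
    cells = _cells([(1, "T cells", 0, 0)])
    with pytest.raises(ValueError, match="missing"):
        N.neighbor_expression_profile(cells, [], LABEL, markers=("CD73",))


def test_default_checkpoint_markers():
    assert set(N.DEFAULT_CHECKPOINT_MARKERS) == {
        "CD112", "CD155", "CD276", "CD39", "CD73", "IDO", "PD-L1", "VISTA",
    }


def test_compare_identical_anchor_sets():
    cells = _random_scene(3, 200)
    cells["PD-L1__cell__norm"] = 1.0
    qa = N.NeighborhoodQuery(anchor_population="T cells", radius_um=25.0)
    out = N.compare_anchor_sets(cells, qa, qa, LABEL, markers=("PD-L1",))
    comp = out["composition"]
    assert np.allclose(
        comp["count_a"].to_numpy(), comp["count_b"].to_numpy()
    )


def test_profile_recovers_elevated_marker():
    rng = np.random.default_rng(9)
    cells = _random_scene(9, 500, labels=("T cells", "A", "B"))
    # population A carries systematically higher PD-L1 than B
    base = rng.normal(1.0, 0.1, 500)
    cells["PD-L1__cell__norm"] = np.where(
        cells[LABEL] == "A", base + 2.0, base
    )
    q = N.NeighborhoodQuery(anchor_population="T cells", radius_um=50.0)
    res = N.radius_query(cells, q, LABEL)
    prof = N.neighbor_expression_profile(
        cells, res.pooled, LABEL, markers=("PD-L1",)
    ).set_index("label")
    assert prof.loc["A", "median"] > prof.loc["B", "median"] + 1.0


# ---------------------------------------------------------------------------
# permutation enrichment


def _enriched_scene(seed=0, enrichment=5.0):
    types = (
        synth.CellType("T cells", 0.1, {}),
        synth.CellType("mDC", 0.25, {}),
        synth.CellType("B cells", 0.65, {}),
    )
    spec = synth.TissueSpec(
        width_px=1000, height_px=1000, n_cells=800, pixel_size_um=0.5,
        cell_types=types, seed=seed,
    )
    df = synth.generate_neighborhood_scene("T cells", "mDC", 25.0, enrichment, spec)
    return df.rename(columns={"type_label": LABEL})


def test_enriched_scene_rejected_by_permutation_null():
    cells = _enriched_scene(seed=5, enrichment=5.0)
    q = N.NeighborhoodQuery(anchor_population="T cells", radius_um=25.0)
    out = N.permutation_enrichment_test(
        cells, q, "mDC", LABEL, n_permutations=300, seed=1
    )
    global_frac = (cells[LABEL] == "mDC").mean()
    assert out["observed_fraction"] > global_frac
    assert out["p_value"] < 0.05


def test_uniform_scene_not_rejected():
    cells = _enriched_scene(seed=6, enrichment=1.0)
    q = N.NeighborhoodQuery(anchor_population="T cells", radius_um=25.0)
    out = N.permutation_enrichment_test(
        cells, q, "mDC", LABEL, n_permutations=300, seed=2
    )
    assert out["p_value"] > 0.05


def test_permutation_determinism():
    cells = _enriched_scene(seed=7, enrichment=3.0)
    q = N.NeighborhoodQuery(anchor_population="T cells", radius_um=25.0)
    a = N.permutation_enrichment_test(cells, q, "mDC", LABEL, 100, seed=3)
    b = N.permutation_enrichment_test(cells, q, "mDC", LABEL, 100, seed=3)
    assert a == b
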