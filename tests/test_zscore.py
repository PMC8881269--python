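import numpy as np
import pandas as pd
import pytest

from tetrascreen.design import ROLE_LIBRARY, ROLE_RLUC
from tetrascreen.profiles import SIX_CLASSES
from tetrascreen.zscore import (
    MAD_SCALE,
    call_hits,
    control_composites,
    gene_scores,
    high_confidence_genes,
    negative_control_cut,
    plate_zscores,
)


def make_profiles(abund_4cs, plate="p1", roles=None, wells=None):
    """Well-profile frame with the 4CS abundance varying and the rest fixed."""
    n = len(abund_4cs)
    wells = wells or [f"A{i+1}" for i in range(n)]
    rows = []
    for w, a in zip(wells, abund_4cs):
        rest = (1.0 - a) / 5
        row = {"plate_id": plate, "well": w, "n_other": 0, "n_excluded": 0, "qc_flag": ""}
        for c in SIX_CLASSES:
            row[f"a_{c}"] = a if c == "4CS" else rest
            row[f"n_{c}"] = 100
        rows.append(row)
    return pd.DataFrame(rows)


def make_layout(wells, roles, plate="p1", genes=None, replicate=1):
    genes = genes or [f"g{i}" for i in range(len(wells))]
    return pd.DataFrame(
        {"plate_id": plate, "well": wells, "role": roles, "gene_id": genes, "replicate": replicate}
    )


def test_hand_computed_mad_example():
    """median 0.10, raw MAD 0.02 -> z* of the 0.30 well is 6.745."""
    abund = [0.08, 0.10, 0.12, 0.10, 0.30]
    profiles = make_profiles(abund)
    layout = make_layout(profiles["well"], [ROLE_LIBRARY] * 5)
    z = plate_zscores(profiles, layout, min_wells=5)
    z4 = z[z["cls"] == "4CS"].set_index("well")["z_star"]
    assert z4["A5"] == pytest.approx((0.30 - 0.10) / (MAD_SCALE * 0.02), abs=1e-9)
    assert z4["A5"] == pytest.approx(6.745, abs=1e-3)
    assert z4["A2"] == 0.0  # equal to the plate median


def test_median_and_scaled_mad_invariants(small_screen_scored):
    design, _, _, zscores = small_screen_scored
    lib = zscores[zscores["role"] == ROLE_LIBRARY]
    for (_, _), grp in lib.groupby(["plate_id", "cls"]):
        zs = grp["z_star"].to_numpy()
        med = np.median(zs)
        mad = np.median(np.abs(zs - med)) * MAD_SCALE
        assert abs(med) < 1e-9
        assert abs(mad - 1.0) < 1e-9


def test_affine_invariance_of_one_class():
    """z* unchanged when one class's abundances are affinely transformed."""
    abund = [0.08, 0.10, 0.12, 0.09, 0.30, 0.11, 0.13, 0.07]
    profiles = make_profiles(abund)
    layout = make_layout(profiles["well"], [ROLE_LIBRARY] * 8)
    z1 = plate_zscores(profiles, layout)
    shifted = profiles.copy()
    shifted["a_4CS"] = 2.5 * shifted["a_4CS"] + 0.04
    z2 = plate_zscores(shifted, layout)
    a = z1[z1["cls"] == "4CS"]["z_star"].to_numpy()
    b = z2[z2["cls"] == "4CS"]["z_star"].to_numpy()
    np.testing.assert_allclose(a, b, atol=1e-9)


def test_location_shift_of_all_wells_leaves_z_unchanged():
    abund = np.array([0.08, 0.10, 0.12, 0.09, 0.30, 0.11, 0.13, 0.07])
    profiles = make_profiles(abund)
    layout = make_layout(profiles["well"], [ROLE_LIBRARY] * 8)
    shifted = make_profiles(abund + 0.05)
    z1 = plate_zscores(profiles, layout)[lambda d: d["cls"] == "4CS"]["z_star"]
    z2 = plate_zscores(shifted, layout)[lambda d: d["cls"] == "4CS"]["z_star"]
    np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)


def test_controls_scored_but_never_in_plate_statistics():
    abund = [0.08, 0.10, 0.12, 0.09, 0.10, 0.11, 0.13, 0.07, 0.95]
    roles = [ROLE_LIBRARY] * 8 + [ROLE_RLUC]
    profiles = make_profiles(abund)
    layout = make_layout(profiles["well"], roles)
    z_with = plate_zscores(profiles, layout)
    # removing the extreme control must not change library scores
    z_without = plate_zscores(profiles.iloc[:8], layout.iloc[:8])
    a = z_with[(z_with["role"] == ROLE_LIBRARY) & (z_with["cls"] == "4CS")]["z_star"].to_numpy()
    b = z_without[z_without["cls"] == "4CS"]["z_star"].to_numpy()
    np.testing.assert_allclose(a, b, atol=1e-12)
    assert (z_with["role"] == ROLE_RLUC).any()  # control still receives a score


def test_zero_mad_flags_undefined_not_infinite():
    profiles = make_profiles([0.1] * 8)
    layout = make_layout(profiles["well"], [ROLE_LIBRARY] * 8)
    z = plate_zscores(profiles, layout)
    assert z["z_star"].isna().all()
    assert (z["flag"] == "mad_zero").all()


def test_too_few_wells_raises():
    profiles = make_profiles([0.1, 0.2, 0.3])
    layout = make_layout(profiles["well"], [ROLE_LIBRARY] * 3)
    with pytest.raises(ValueError, match="included wells"):
        plate_zscores(profiles, layout)


def _two_replicate_ztable(z_by_gene_rep):
    """Long Z*-table with given 4CS/8CG2 scores: {gene: {rep: (z4cs, z8cg2)}}."""
    rows = []
    for gene, reps in z_by_gene_rep.items():
        for rep, (z4, z8) in reps.items():
            for cls in SIX_CLASSES:
                z = {"4CS": z4, "8CG2": z8}.get(cls, 0.0)
                rows.append({"plate_id": f"p{rep}", "well": f"{gene}w", "gene_id": gene,
                             "role": ROLE_LIBRARY, "replicate": rep, "cls": cls,
                             "z_star": z, "flag": ""})
    return pd.DataFrame(rows)


def test_gene_score_composites_and_combination():
    z = _two_replicate_ztable({
        "gA": {1: (12.0, 12.0), 2: (12.0, 12.0)},
        "gB": {1: (8.0, 8.0), 2: (12.0, 12.0)},
        "gC": {1: (6.745, 0.0), 2: (6.745, 0.0)},
    })
    scores = gene_scores(z).set_index("gene_id")
    assert scores.loc["gA", "combined"] == pytest.approx(12.0)
    assert scores.loc["gB", "combined"] == pytest.approx(10.0)  # mean of 8 and 12
    assert scores.loc["gC", "score_rep1"] == pytest.approx(3.3725)


def test_undefined_replicate_propagates_as_missing():
    z = _two_replicate_ztable({"gA": {1: (np.nan, np.nan), 2: (4.0, 4.0)}})
    scores = gene_scores(z).set_index("gene_id")
    assert np.isnan(scores.loc["gA", "score_rep1"])
    assert scores.loc["gA", "combined"] == pytest.approx(4.0)
    assert scores.loc["gA", "n_defined_replicates"] == 1


def test_call_hits_union_vs_intersection_rules():
    scores = pd.DataFrame({"gene_id": ["g1"], "score_rep1": [4.0], "score_rep2": [1.0],
                           "combined": [2.5]})
    union = call_hits(scores, primary_threshold=3.0, replicate_rule="union")
    inter = call_hits(scores, primary_threshold=3.0, replicate_rule="intersection")
    assert bool(union["is_primary"][0]) and not bool(inter["is_primary"][0])


def test_high_confidence_threshold_is_strict():
    scores = pd.DataFrame({"gene_id": ["a", "b"], "score_rep1": [12.0, 10.0],
                           "score_rep2": [12.0, 10.0], "combined": [12.0, 10.0]})
    hits = call_hits(scores, high_conf_cut=10.0).set_index("gene_id")
    assert bool(hits.loc["a", "is_high_confidence"])
    assert not bool(hits.loc["b", "is_high_confidence"])  # exactly 10 is not > 10


def test_high_confidence_filter_counts():
    summary = pd.DataFrame({"gene_id": [f"g{i}" for i in range(20)],
                            "combined": np.linspace(0, 19, 20)})
    sel = high_confidence_genes(summary, z_cut=10.0, score_col="combined")
    assert len(sel) == 9  # 11..19


def test_negative_control_cut_and_positive_control_window(small_screen_scored):
    design, truth, profiles, zscores = small_screen_scored
    cut = negative_control_cut(zscores)
    ctrl = control_composites(zscores)
    neg = ctrl[ctrl["role"] == ROLE_RLUC]["composite"]
    pos = ctrl[ctrl["role"] != ROLE_RLUC]["composite"]
    assert cut > neg.max() * 0.9
    # screen window: every positive-control well outscores every negative control
    assert pos.min() > neg.max()
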