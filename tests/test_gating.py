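import numpy as np
import pandas as pd
import pytest

import tetrascreen as ts
from tetrascreen.gating import (
    EXCLUDED,
    GatingConfig,
    OTHER,
    classify_cells,
    classify_wells,
    estimate_2c_anchor,
    fucci_state,
    summarize_well,
)
from tetrascreen.profiles import SIX_CLASSES
from tetrascreen.simulate import IntensityModel, simulate_well


def records(dapi, g1, g2):
    n = len(dapi)
    return pd.DataFrame({"dapi_int": dapi, "g1_int": g1, "g2_int": g2,
                         "n_nuclei": np.ones(n, dtype=int), "cell_id": np.arange(n)})


def test_fucci_state_rules():
    states = fucci_state([500, 25, 500, 25], [25, 500, 500, 25], 100.0, 100.0)
    assert states.tolist() == ["G1only", "G2only", "both", "none"]


@pytest.mark.parametrize(
    "content,state,expected",
    [
        (1.0, "G1only", "2CG1"),
        (2.0, "G1only", "4CG1"),
        (1.5, "G1only", OTHER),
        (1.0, "G2only", "2CS"),
        (1.5, "G2only", "2CS"),
        (2.0, "G2only", "4CG2"),
        (2.0, "both", "4CS"),
        (3.0, "G2only", "4CS"),
        (3.0, "both", "4CS"),
        (4.0, "G2only", "8CG2"),
        (3.5, "G2only", "8CG2"),
        (5.0, "G2only", OTHER),
        (0.5, "G1only", OTHER),
        (1.0, "none", EXCLUDED),
    ],
)
def test_classification_boundary_table(content, state, expected):
    """Direct application of the gating boundary table."""
    anchor = 1000.0
    g1 = 500.0 if state in ("G1only", "both") else 25.0
    g2 = 500.0 if state in ("G2only", "both") else 25.0
    df = records([content * anchor], [g1], [g2])
    out = classify_cells(df, anchor, thresholds=(100.0, 100.0))
    assert out["cls"][0] == expected


def test_classification_invariance_to_common_rescale():
    cells = simulate_well(ts.dcd_default_profile(), 2000, IntensityModel(), seed=21)
    scaled = cells.copy()
    for col in ("dapi_int", "g1_int", "g2_int"):
        scaled[col] = scaled[col] * 3.13
    a = classify_cells(cells, estimate_2c_anchor(cells))
    b = classify_cells(scaled, estimate_2c_anchor(scaled))
    assert (a["cls"].to_numpy() == b["cls"].to_numpy()).mean() > 0.999


def test_non_finite_intensities_raise():
    df = records([1000.0, np.nan], [500.0, 500.0], [25.0, 25.0])
    with pytest.raises(ValueError, match="non-finite"):
        classify_cells(df, 1000.0, thresholds=(100.0, 100.0))
    with pytest.raises(ValueError, match="anchor"):
        classify_cells(records([1000.0], [500.0], [25.0]), 0.0, thresholds=(100.0, 100.0))


def test_anchor_exact_on_noiseless_2cg1_well():
    df = records([1000.0] * 60, [500.0] * 60, [25.0] * 60)
    assert estimate_2c_anchor(df, thresholds=(100.0, 100.0)) == pytest.approx(1000.0)


def test_anchor_within_5pct_at_default_noise():
    cells = simulate_well(ts.dcd_default_profile(), 2000, IntensityModel(anchor_2c=1000.0), seed=22)
    est = estimate_2c_anchor(cells)
    assert abs(est - 1000.0) / 1000.0 < 0.05


def test_anchor_pathological_pure_4cg1_well_returns_its_peak():
    # a well of only 4CG1 cells: the estimator can only report the peak it sees
    df = records([2000.0] * 80, [500.0] * 80, [25.0] * 80)
    assert estimate_2c_anchor(df, thresholds=(100.0, 100.0)) == pytest.approx(2000.0)


def test_anchor_too_few_fucci_cells_instructs_pooling():
    df = records([1000.0] * 30, [25.0] * 30, [25.0] * 30)
    with pytest.raises(ValueError, match="pool"):
        estimate_2c_anchor(df, thresholds=(100.0, 100.0))


def test_summarize_well_arithmetic():
    counts = {"2CG1": 10, "2CS": 10, "4CG2": 10, "4CG1": 10, "4CS": 5, "8CG2": 5}
    rows = [c for c, n in counts.items() for _ in range(n)] + [EXCLUDED] * 8
    prof = summarize_well(pd.DataFrame({"cls": rows}), "p1", "A1")
    assert prof.n_excluded == 8
    expected = {"2CG1": 0.2, "2CS": 0.2, "4CG2": 0.2, "4CG1": 0.2, "4CS": 0.1, "8CG2": 0.1}
    for c in SIX_CLASSES:
        assert prof.abundances[c] == pytest.approx(expected[c])
    assert sum(prof.abundances.values()) == pytest.approx(1.0)


def test_summarize_pure_well_and_empty_well():
    pure = summarize_well(pd.DataFrame({"cls": ["2CG1"] * 10}), "p", "A1")
    assert pure.abundances["2CG1"] == 1.0
    assert "low_cells" in pure.qc_flags  # 10 < default min_cells
    empty = summarize_well(pd.DataFrame({"cls": []}), "p", "A2")
    assert "empty" in empty.qc_flags
    assert np.isnan(empty.abundances["2CG1"])


def test_classify_wells_excluded_cells_never_in_abundances(small_screen):
    _, cells, _ = small_screen
    one_well = cells[(cells["plate_id"] == cells["plate_id"].iloc[0])]
    _, profiles = classify_wells(one_well)
    counts = profiles[[f"n_{c}" for c in SIX_CLASSES]].sum(axis=1)
    ab = profiles[[f"a_{c}" for c in SIX_CLASSES]].sum(axis=1)
    ok = counts > 0
    np.testing.assert_allclose(ab[ok], 1.0, atol=1e-12)


def test_gating_config_yaml_round_trip(tmp_path):
    cfg = GatingConfig(g1_threshold=123.0, min_cells=50)
    path = tmp_path / "gating.yaml"
    cfg.to_yaml(path)
    assert GatingConfig.from_yaml(path) == cfg


def test_gating_config_rejects_disordered_windows():
    with pytest.raises(ValueError):
        GatingConfig(g1_window_2c=(1.5, 1.0))
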