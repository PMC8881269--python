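import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk
from skimage.measure import label as sk_label

import tetrascreen as ts
from tetrascreen.quantify import LabelMap, group_binucleates, measure_regions, quantify_field, segment_nuclei
from tetrascreen.render import ImageParams, render_field
from tetrascreen.simulate import IntensityModel, simulate_well


def disc_image(centers, radius=8, value=1000.0, shape=(128, 128), background=10.0):
    img = np.full(shape, background)
    for cy, cx in centers:
        rr, cc = disk((cy, cx), radius, shape=shape)
        img[rr, cc] = value
    return img


# --- rendering ---------------------------------------------------------------

def test_render_empty_records_is_background_only():
    img, placements = render_field(pd.DataFrame(columns=["cell_id", "dapi_int", "g1_int", "g2_int", "n_nuclei"]),
                                   ImageParams(background=100.0, noise_sd=0.0))
    assert placements.empty
    assert (img == 100).all()


def test_render_channel_sums_match_record_within_quantization():
    rec = pd.DataFrame({"cell_id": [1], "dapi_int": [1234.5], "g1_int": [456.0],
                        "g2_int": [78.9], "n_nuclei": [1]})
    params = ImageParams(background=0.0, noise_sd=0.0)
    img, _ = render_field(rec, params, seed=0)
    for ch, col in enumerate(("dapi_int", "g1_int", "g2_int")):
        measured = img[ch].sum() / params.intensity_scale
        assert measured == pytest.approx(rec[col][0], rel=0.01)


def test_binucleate_tangent_discs_form_one_two_lobed_component():
    rec = pd.DataFrame({"cell_id": [1], "dapi_int": [2000.0], "g1_int": [500.0],
                        "g2_int": [25.0], "n_nuclei": [2]})
    img, _ = render_field(rec, ImageParams(background=0.0, binucleate_gap=0), seed=1)
    lab = sk_label(img[0] > 0, connectivity=2)
    assert lab.max() == 1


def test_render_too_many_cells_raises():
    rec = pd.DataFrame({"cell_id": range(100), "dapi_int": 1000.0, "g1_int": 1.0,
                        "g2_int": 1.0, "n_nuclei": 1})
    with pytest.raises(ValueError, match="too small"):
        render_field(rec, ImageParams(shape=(64, 64)), seed=0)


# --- segmentation ------------------------------------------------------------

def test_constant_image_yields_zero_objects():
    lm = segment_nuclei(np.full((64, 64), 7.0))
    assert lm.n_objects == 0


def test_two_disjoint_discs_two_objects():
    img = disc_image([(30, 30), (90, 90)])
    lm = segment_nuclei(img)
    assert lm.n_objects == 2


def test_non_2d_input_raises():
    with pytest.raises(ValueError):
        segment_nuclei(np.zeros((3, 64, 64)))


def test_min_area_filters_specks():
    img = disc_image([(30, 30)], radius=8)
    img[5:7, 5:7] = 1000.0  # 4-px speck, below min_area
    lm = segment_nuclei(img, min_area=30)
    assert lm.n_objects == 1


def test_segmentation_affine_intensity_invariance():
    img = disc_image([(30, 30), (90, 90), (30, 90)])
    a = segment_nuclei(img)
    b = segment_nuclei(3.7 * img + 55.0)
    np.testing.assert_array_equal(a.labels, b.labels)


def test_rendered_field_object_count_and_areas():
    rec = pd.DataFrame({"cell_id": np.arange(50), "dapi_int": 1000.0, "g1_int": 500.0,
                        "g2_int": 25.0, "n_nuclei": 1})
    params = ImageParams(shape=(900, 900), background=100.0)
    img, _ = render_field(rec, params, seed=2)
    lm = segment_nuclei(img[0].astype(float))
    assert lm.n_objects == 50
    disc_area = len(disk((50, 50), params.cell_radius)[0])
    assert np.all(np.abs(lm.areas - disc_area) / disc_area <= 0.10)


# --- binucleate grouping -----------------------------------------------------

def test_grouping_identity_when_gap_zero():
    img = disc_image([(30, 30), (90, 90)])
    lm = segment_nuclei(img)
    merged = group_binucleates(lm, max_gap_px=0)
    np.testing.assert_array_equal(lm.labels, merged.labels)
    assert merged.n_objects == 2


def test_one_pixel_gap_pair_merges_with_union_area():
    # radius-8 discs span centre +-7 px, so centres 16 apart leave a 1-px gap
    img = disc_image([(40, 30), (40, 46)], radius=8)
    lm = segment_nuclei(img)
    assert lm.n_objects == 2
    total_fg = (lm.labels > 0).sum()
    merged = group_binucleates(lm, max_gap_px=2)
    assert merged.n_objects == 1
    assert merged.n_nuclei.tolist() == [2]
    assert (merged.labels > 0).sum() == total_fg  # never loses foreground


def test_three_close_nuclei_merge_only_pairwise():
    img = disc_image([(40, 30), (40, 46), (55, 38)], radius=8)
    lm = segment_nuclei(img)
    assert lm.n_objects == 3
    merged = group_binucleates(lm, max_gap_px=6)
    assert merged.n_objects == 2
    assert sorted(merged.n_nuclei.tolist()) == [1, 2]


# --- measurement -------------------------------------------------------------

def test_uniform_intensity_closed_form():
    labels = np.zeros((32, 32), dtype=np.int32)
    labels[5:10, 5:10] = 1  # area 25
    lm = LabelMap(labels=labels, n_nuclei=np.ones(1, dtype=int))
    chans = np.stack([np.full((32, 32), 4.0), np.zeros((32, 32)), np.zeros((32, 32))])
    rec = measure_regions(lm, chans, background=0.0)
    assert rec["dapi_int"][0] == pytest.approx(4.0 * 25)
    assert rec["g1_int"][0] == 0.0 and rec["g2_int"][0] == 0.0


def test_measure_shape_mismatch_raises():
    lm = LabelMap(labels=np.zeros((16, 16), dtype=np.int32), n_nuclei=np.zeros(0, dtype=int))
    with pytest.raises(ValueError):
        measure_regions(lm, np.zeros((3, 8, 8)))


def test_field_round_trip_recovers_intensities_and_nuclei():
    """End-to-end: render synthetic cells, re-measure, compare to truth."""
    cells = simulate_well(ts.dcd_default_profile(), 60, IntensityModel(), seed=11)
    params = ImageParams(shape=(800, 800))
    img, _ = render_field(cells, params, seed=11)
    rec = quantify_field(img, intensity_scale=params.intensity_scale)
    assert len(rec) == len(cells)
    # >= 95% of cells recovered with the correct number of nuclei
    assert (np.sort(rec["n_nuclei"]) == np.sort(cells["n_nuclei"])).mean() >= 0.95
    measured = np.sort(rec["dapi_int"].to_numpy())
    truth = np.sort(cells["dapi_int"].to_numpy())
    assert np.max(np.abs(measured - truth) / truth) < 0.02
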