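"""Object measurement, size filter, T-cell overlap, depth bins, seeding math."""

import math

import numpy as np
import pytest

from choroidchip import (
    CellObject,
    CompartmentBins,
    ImageStack,
    LabelMap,
    SeedingSpec,
    bin_by_depth,
    classify_tcells,
    measure_objects,
    seeding_concentration,
    size_filter,
)


def _labelmap(arr, edge=1.0):
    return LabelMap(labels=np.asarray(arr, dtype=np.int32), spacing_xyz=(edge, edge, edge))


# ---- measure_objects ---------------------------------------------------


def test_single_voxel_object_measurement():
    arr = np.zeros((4, 4, 4), dtype=np.int32)
    arr[1, 2, 3] = 1
    objs = measure_objects(_labelmap(arr, edge=1.66))
    assert len(objs) == 1
    o = objs[0]
    assert o.volume_vox == 1
    assert o.volume_um3 == pytest.approx(1.66**3)
    assert o.centroid_um == pytest.approx((3 * 1.66, 2 * 1.66, 1 * 1.66))
    assert o.is_tcell is False


def test_cube_centroid_and_volume():
    arr = np.zeros((5, 5, 5), dtype=np.int32)
    arr[1:4, 1:4, 1:4] = 1
    objs = measure_objects(_labelmap(arr))
    assert objs[0].volume_vox == 27
    assert objs[0].centroid_um == pytest.approx((2.0, 2.0, 2.0))


def test_empty_labelmap_gives_empty_list():
    assert measure_objects(_labelmap(np.zeros((3, 3, 3)))) == []


def test_non_cubic_spacing_warns_but_computes():
    arr = np.zeros((3, 3, 3), dtype=np.int32)
    arr[1, 1, 1] = 1
    lm = LabelMap(labels=arr, spacing_xyz=(1.0, 1.0, 3.0))
    with pytest.warns(UserWarning):
        objs = measure_objects(lm)
    assert objs[0].volume_um3 == pytest.approx(3.0)


# ---- size_filter -------------------------------------------------------


def _obj(volume_vox, z_um=10.0, is_tcell=False, label=1):
    return CellObject(
        label=label,
        centroid_um=(5.0, 5.0, z_um),
        volume_vox=volume_vox,
        volume_um3=volume_vox * 1.66**3,
        is_tcell=is_tcell,
    )


def test_size_filter_thirty_voxel_boundary():
    kept = size_filter([_obj(29), _obj(30, label=2), _obj(31, label=3)], min_vox=30)
    assert [o.label for o in kept] == [2, 3]


def test_size_filter_zero_is_identity_and_monotone():
    objs = [_obj(v, label=i) for i, v in enumerate([1, 10, 40, 100], start=1)]
    assert size_filter(objs, 0) == objs
    counts = [len(size_filter(objs, m)) for m in (0, 5, 30, 50, 200)]
    assert counts == sorted(counts, reverse=True)


def test_cutoff_volume_at_cubic_edge_matches_printed_value():
    # 30 voxels at 1.66 µm cubic edge correspond to the printed 137.22 µm³
    # at its 0.01 µm³ precision (the exact product is 137.22888).
    assert 30 * 1.66**3 == pytest.approx(137.22, abs=0.01)


# ---- classify_tcells ---------------------------------------------------


def test_no_green_means_no_tcells():
    arr = np.zeros((4, 4, 4), dtype=np.int32)
    arr[1, 1, 1:3] = 1
    lm = _labelmap(arr)
    objs = measure_objects(lm)
    green = ImageStack(np.zeros((4, 4, 4)), (1, 1, 1))
    out = classify_tcells(objs, lm, green)
    assert all(not o.is_tcell for o in out)


def test_single_shared_voxel_suffices_for_tcell():
    arr = np.zeros((4, 4, 4), dtype=np.int32)
    arr[1, 1, 0:3] = 1  # object 1: three voxels
    arr[3, 3, 0:2] = 2  # object 2: two voxels, no overlap
    lm = _labelmap(arr)
    green = np.zeros((4, 4, 4))
    green[1, 1, 2] = 255.0  # exactly one voxel of object 1
    out = classify_tcells(measure_objects(lm), lm, ImageStack(green, (1, 1, 1)))
    flags = {o.label: o.is_tcell for o in out}
    assert flags == {1: True, 2: False}
    # brute-force voxel-set intersection agrees
    overlap = int(np.sum((arr == 1) & (green > 0)))
    assert overlap == 1


def test_classify_rejects_shape_mismatch():
    lm = _labelmap(np.zeros((3, 3, 3)))
    green = ImageStack(np.zeros((4, 3, 3)), (1, 1, 1))
    with pytest.raises(ValueError):
        classify_tcells([_obj(5)], lm, green)


# ---- bin_by_depth ------------------------------------------------------


def test_bin_default_edges_match_compartment_halves():
    bins = CompartmentBins()
    assert bins.bottom_range_um == (0.0, 63.0)
    assert bins.top_range_um == (64.0, 126.0)
    assert bins.split_um == 63.0


def test_bin_endpoints_and_counts():
    objs = (
        [_obj(50, z_um=0.0, label=1), _obj(50, z_um=126.0, label=2)]
        + [_obj(50, z_um=30.0, label=i) for i in range(3, 13)]
        + [_obj(50, z_um=100.0, label=i, is_tcell=True) for i in range(13, 18)]
    )
    report = bin_by_depth(objs, CompartmentBins(), chip_id="t")
    assert report.n_pbmc_bottom == 11  # z=0 and the ten at 30 µm
    assert report.n_pbmc_top == 6  # z=126 and the five at 100 µm
    assert report.n_pbmc_total == 17
    assert report.n_tcell_total == report.n_tcell_top == 5
    assert report.n_pbmc_total == report.n_pbmc_top + report.n_pbmc_bottom


def test_report_invariants_are_enforced():
    from choroidchip import RecruitmentReport

    with pytest.raises(ValueError):
        RecruitmentReport("c", 5, 2, 2, 0, 0, 0)  # total != top + bottom
    with pytest.raises(ValueError):
        RecruitmentReport("c", 2, 1, 1, 3, 2, 1)  # T cells exceed PBMCs


# ---- seeding_concentration ---------------------------------------------


def test_zero_fraction_means_zero_cells():
    out = seeding_concentration(SeedingSpec(target_fraction=0.0))
    assert out["cells_in_channel"] == 0.0
    assert out["total_cells_in_seeding_volume"] == 0.0


def test_low_density_seeding_matches_longhand_unit_conversion():
    # Long-hand oracle: 28.5 µm diameter sphere = pi/6 * 28.5^3 µm³;
    # expanded by 3.68; channel 1.5 µL = 1.5e9 µm³; 5% fill.
    sphere = math.pi / 6 * 28.5**3  # 12121.53... µm³
    expanded = sphere * 3.68
    cells_in_channel = 0.05 * 1.5e9 / expanded
    per_ul = cells_in_channel / 1.5
    out = seeding_concentration(
        SeedingSpec(cell_diameter_um=28.5, target_fraction=0.05)
    )
    assert out["cells_in_channel"] == pytest.approx(cells_in_channel)
    assert out["cells_per_ul"] == pytest.approx(per_ul)
    assert out["total_cells_in_seeding_volume"] == pytest.approx(per_ul * 5.0)


def test_seeding_defaults_and_validation():
    spec = SeedingSpec()
    assert spec.channel_volume_ul == 1.5
    assert spec.seeding_volume_ul == 5.0
    assert spec.expansion_factor == 3.68
    with pytest.raises(ValueError):
        SeedingSpec(target_fraction=1.5)
    with pytest.raises(ValueError):
        SeedingSpec(cell_diameter_um=-1)
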