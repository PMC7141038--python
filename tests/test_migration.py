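"""Classification, distances, histograms and the full quantification pipeline."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spheromigrate import (
    MigrationClass,
    classify_migration,
    estimate_core,
    filter_small_singles,
    generate_spheroid_stack,
    migration_histogram,
    quantify_panel,
    quantify_stack,
    radial_distances,
    summarize_migration,
)
from spheromigrate.migration import MigrationLabels
from spheromigrate.segmentation import CoreEstimate

from ._oracle import classify_by_flood_fill
from .conftest import MIDPOINT, small_params


def _worked_example_mask():
    """3x3 core block at (4,4) with a 3-pixel arm and one isolated corner pixel."""
    mask = np.zeros((9, 9), dtype=bool)
    mask[3:6, 3:6] = True
    mask[4, 6:9] = True
    mask[0, 0] = True
    return mask


@pytest.fixture(scope="module")
def pipeline():
    mask = _worked_example_mask()
    core = estimate_core(mask)
    labels = classify_migration(mask, core, connectivity=8)
    distances = radial_distances(labels, core)
    return mask, core, labels, distances


class TestWorkedExample:
    """Hand-checkable grid: arm pixels are collective, the corner is single."""

    def test_matches_flood_fill_oracle(self, pipeline):
        mask, core, labels, _ = pipeline
        network, single = classify_by_flood_fill(mask, core.center, connectivity=8)
        np.testing.assert_array_equal(
            np.isin(labels.labels, (MigrationClass.CORE, MigrationClass.COLLECTIVE)), network
        )
        np.testing.assert_array_equal(labels.labels == MigrationClass.SINGLE, single)

    def test_center_and_class_counts(self, pipeline):
        _, core, labels, _ = pipeline
        assert core.center == (4, 4)
        counts = labels.class_counts()
        assert counts["core"] == 9
        assert counts["collective"] == 3
        assert counts["single"] == 1

    def test_arm_distances(self, pipeline):
        _, _, _, distances = pipeline
        assert sorted(distances["collective"]) == [2.0, 3.0, 4.0]
        assert distances["single"][0] == pytest.approx(np.sqrt(32))

    def test_summary_values(self, pipeline):
        _, _, labels, distances = pipeline
        summary = summarize_migration(labels, distances)
        assert summary.n_collective == 3
        assert summary.n_single == 1
        assert summary.max_dist_collective == 4.0
        assert summary.collective_fraction == 0.75


def test_core_only_mask_has_no_outgrowth():
    mask = np.zeros((9, 9), dtype=bool)
    mask[3:6, 3:6] = True
    core = estimate_core(mask)
    labels = classify_migration(mask, core)
    summary = summarize_migration(labels, radial_distances(labels, core))
    assert summary.n_collective == 0
    assert summary.n_single == 0
    assert summary.collective_fraction is None
    assert summary.max_dist_collective is None


def test_center_off_foreground_rejected():
    mask = _worked_example_mask()
    core = estimate_core(mask)
    bad = CoreEstimate(center=(0, 8), core_radius_est=core.core_radius_est,
                       core_mask=core.core_mask)
    with pytest.raises(ValueError, match="center"):
        classify_migration(mask, bad)


def test_connectivity_choice_changes_diagonal_attachment():
    """A diagonally touching pixel is collective at 8-connectivity, single at 4."""
    mask = np.zeros((7, 7), dtype=bool)
    mask[2:5, 2:5] = True
    mask[5, 5] = True
    core = estimate_core(mask)
    loose = classify_migration(mask, core, connectivity=8)
    strict = classify_migration(mask, core, connectivity=4)
    assert loose.labels[5, 5] == MigrationClass.COLLECTIVE
    assert strict.labels[5, 5] == MigrationClass.SINGLE


def test_invalid_connectivity_rejected():
    mask = _worked_example_mask()
    core = estimate_core(mask)
    with pytest.raises(ValueError, match="connectivity"):
        classify_migration(mask, core, connectivity=26)  # 3D flag on a 2D mask


# -- distances --------------------------------------------------------------


def _labels_with_one_collective(offset, shape=(9, 9, 9), center=(4, 4, 4)):
    arr = np.zeros(shape, dtype=np.uint8)
    arr[center] = MigrationClass.CORE
    voxel = tuple(c + o for c, o in zip(center, offset))
    arr[voxel] = MigrationClass.COLLECTIVE
    labels = MigrationLabels(labels=arr, connectivity=26)
    core = CoreEstimate(center=center, core_radius_est=1.0, core_mask=arr == MigrationClass.CORE)
    return labels, core


def test_three_four_five_distance():
    labels, core = _labels_with_one_collective((0, 3, 4))
    d = radial_distances(labels, core, spacing=(1, 1, 1))
    assert d["collective"][0] == pytest.approx(5.0)


def test_surface_reference_subtracts_core_radius():
    labels, core = _labels_with_one_collective((0, 3, 4))
    core.core_radius_est = 5.0
    d = radial_distances(labels, core, spacing=(1, 1, 1), reference="surface")
    assert d["collective"][0] == pytest.approx(0.0)


def test_anisotropic_spacing():
    labels, core = _labels_with_one_collective((1, 0, 0))
    d = radial_distances(labels, core, spacing=(2, 1, 1))
    assert d["collective"][0] == pytest.approx(2.0)


def test_unknown_reference_rejected():
    labels, core = _labels_with_one_collective((0, 1, 0))
    with pytest.raises(ValueError, match="reference"):
        radial_distances(labels, core, reference="edge")


# -- histograms -------------------------------------------------------------


def test_histogram_example_bins():
    hist = migration_histogram([12.0, 27.0], [5.0], bin_width=10.0)
    np.testing.assert_array_equal(hist.bin_edges, [0.0, 10.0, 20.0, 30.0])
    np.testing.assert_array_equal(hist.collective_counts, [0, 1, 1])
    np.testing.assert_array_equal(hist.single_counts, [1, 0, 0])


def test_histogram_empty():
    hist = migration_histogram([], [], bin_width=10.0)
    assert hist.collective_counts.size == 0
    np.testing.assert_array_equal(hist.bin_edges, [0.0])


def test_histogram_lower_inclusive_edges():
    hist = migration_histogram([10.0], [0.0], bin_width=10.0)
    np.testing.assert_array_equal(hist.collective_counts, [0, 1])
    np.testing.assert_array_equal(hist.single_counts, [1, 0])


def test_histogram_negative_surface_distances_go_to_first_bin():
    hist = migration_histogram([-3.0, 4.0], [], bin_width=5.0, reference="surface")
    np.testing.assert_array_equal(hist.collective_counts, [2])


def test_histogram_rejects_bad_bin_width():
    with pytest.raises(ValueError, match="bin_width"):
        migration_histogram([1.0], [], bin_width=0.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    collective=st.lists(st.floats(0, 100, allow_nan=False), max_size=200),
    single=st.lists(st.floats(0, 100, allow_nan=False), max_size=200),
    bin_width=st.floats(0.5, 25),
)
def test_histogram_conserves_counts(collective, single, bin_width):
    hist = migration_histogram(collective, single, bin_width=bin_width)
    assert hist.collective_counts.sum() == len(collective)
    assert hist.single_counts.sum() == len(single)
    assert (hist.collective_counts >= 0).all() and (hist.single_counts >= 0).all()


def test_histogram_max_dist_clips_overflow_into_last_bin():
    hist = migration_histogram([5.0, 95.0], [], bin_width=10.0, max_dist=50.0)
    assert len(hist.collective_counts) == 5
    assert hist.collective_counts.sum() == 2
    assert hist.collective_counts[-1] == 1


# -- small-object filter ----------------------------------------------------


def test_filter_small_singles_drops_speckles():
    arr = np.zeros((7, 7), dtype=np.uint8)
    arr[3, 3] = MigrationClass.CORE
    arr[0, 0] = MigrationClass.SINGLE          # speckle, size 1
    arr[5:7, 5:7] = MigrationClass.SINGLE      # real object, size 4
    labels = MigrationLabels(labels=arr, connectivity=8)
    filtered = filter_small_singles(labels, min_size=3)
    assert filtered.labels[0, 0] == MigrationClass.BACKGROUND
    assert (filtered.labels[5:7, 5:7] == MigrationClass.SINGLE).all()
    untouched = filter_small_singles(labels, min_size=1)
    np.testing.assert_array_equal(untouched.labels, arr)


# -- full pipeline ----------------------------------------------------------


def test_quantify_reproduces_ground_truth(clean_stack_and_truth):
    stack, truth = clean_stack_and_truth
    result = quantify_stack(stack, threshold=MIDPOINT, mode="3d")
    assert result.labels.class_counts() == truth.true_counts
    np.testing.assert_array_equal(result.labels.labels, truth.labels)
    assert max(abs(a - b) for a, b in zip(result.core.center, truth.true_center)) <= 2


def test_quantify_conservation(clean_stack_and_truth):
    stack, _ = clean_stack_and_truth
    result = quantify_stack(stack, threshold=MIDPOINT)
    counts = result.labels.class_counts()
    assert counts["core"] + counts["collective"] + counts["single"] == int(result.mask.mask.sum())


def test_mip_counts_do_not_exceed_3d(clean_stack_and_truth):
    stack, _ = clean_stack_and_truth
    full = quantify_stack(stack, threshold=MIDPOINT, mode="3d").labels.class_counts()
    mip = quantify_stack(stack, threshold=MIDPOINT, mode="mip").labels.class_counts()
    total_3d = full["core"] + full["collective"] + full["single"]
    total_mip = mip["core"] + mip["collective"] + mip["single"]
    assert total_mip <= total_3d
    assert mip["single"] <= full["single"]


def test_spacing_scales_distances_not_counts():
    params = small_params(seed=31)
    stack, _ = generate_spheroid_stack(params)
    base = quantify_stack(stack, threshold=MIDPOINT)
    import dataclasses

    scaled_params = dataclasses.replace(params, spacing=(2.0, 2.0, 2.0))
    scaled_stack, _ = generate_spheroid_stack(scaled_params)
    scaled = quantify_stack(scaled_stack, threshold=MIDPOINT)
    assert scaled.summary.n_collective == base.summary.n_collective
    assert scaled.summary.n_single == base.summary.n_single
    assert scaled.summary.max_dist_collective == pytest.approx(2 * base.summary.max_dist_collective)
    assert scaled.summary.mean_dist_single == pytest.approx(2 * base.summary.mean_dist_single)


def test_quantify_rejects_unknown_mode(clean_stack_and_truth):
    stack, _ = clean_stack_and_truth
    with pytest.raises(ValueError, match="mode"):
        quantify_stack(stack, mode="4d")


def test_classification_matches_oracle_on_random_masks(rng):
    for _ in range(15):
        shape = tuple(rng.integers(6, 20, size=3))
        mask = rng.random(shape) < rng.uniform(0.25, 0.5)
        if not mask.any():
            continue
        connectivity = int(rng.choice([6, 18, 26]))
        core = estimate_core(mask)
        labels = classify_migration(mask, core, connectivity=connectivity)
        network, single = classify_by_flood_fill(mask, core.center, connectivity)
        np.testing.assert_array_equal(
            np.isin(labels.labels, (MigrationClass.CORE, MigrationClass.COLLECTIVE)), network
        )
        np.testing.assert_array_equal(labels.labels == MigrationClass.SINGLE, single)


def test_quantify_panel_tidy_table():
    from spheromigrate import generate_condition_panel

    base = small_params(seed=13)
    panel = generate_condition_panel(
        base,
        {
            "control": {"n_sprouts": 0, "n_single": 0},
            "sprouty": {"n_sprouts": 4, "n_single": 0},
            "scattered": {"n_sprouts": 0, "n_single": 8, "single_dist_range": (14.0, 27.0)},
        },
    )
    table = quantify_panel(panel, threshold=MIDPOINT)
    assert list(table["condition"]) == ["control", "sprouty", "scattered"]
    assert len(table) == 3
    assert {"n_core", "n_collective", "n_single", "collective_fraction"} <= set(table.columns)
    sprouty = table.set_index("condition").loc["sprouty"]
    scattered = table.set_index("condition").loc["scattered"]
    assert sprouty["n_collective"] > 0 and sprouty["n_single"] == 0
    assert scattered["n_single"] > 0 and scattered["n_collective"] == 0
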