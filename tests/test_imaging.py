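"""3D spot-detection pipeline: LoG, Otsu, seeds, watershed, size filter,
per-cell assignment, density."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peroxikit.imaging import (
    DegenerateInputError,
    ImageStack3D,
    QuantConfig,
    ResolutionError,
    cytoplasmic_volume,
    detect_seeds,
    filter_labels,
    log_filter,
    match_centroids,
    normalized_signal,
    numerical_density,
    otsu_threshold,
    quantify_stack,
    spots_per_cell,
    watershed_segment,
)
from peroxikit.simulate import ImageSimParams, gen_image_stack

ISO = (0.1, 0.1, 0.1)


def _gaussian_spot_stack(center_um, sigma_um, shape=(40, 40, 40), voxel=ISO, amp=100.0, bg=0.0):
    grids = [(np.arange(n) + 0.5) * d for n, d in zip(shape, voxel)]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    q = sum(
        (g - c) ** 2 / (2 * s**2) for g, c, s in zip((zz, yy, xx), center_um, (sigma_um,) * 3)
    )
    return ImageStack3D(voxels=bg + amp * np.exp(-q), voxel_size=voxel)


# ------------------------------------------------------------------- LoG


def test_log_of_constant_stack_is_zero():
    stack = ImageStack3D(voxels=np.full((8, 10, 12), 7.0), voxel_size=(0.2, 0.1, 0.1))
    resp = log_filter(stack, (0.4, 0.2, 0.2))
    # zero up to truncated-kernel float error, relative to the intensity scale
    assert np.abs(resp.values).max() < 1e-6 * stack.voxels.max()


def test_log_scale_selection_peaks_at_spot_scale():
    # gamma-normalized (gamma = 5/4) LoG: for a 3D Gaussian blob of width
    # sigma_s the response at the center is max over scales at sigma = sigma_s
    sigma_s = 0.3
    stack = _gaussian_spot_stack((2.0, 2.0, 2.0), sigma_s)
    sigmas = np.arange(0.15, 0.61, 0.025)
    center_vox = (19, 19, 19)
    responses = [log_filter(stack, float(s)).values[center_vox] for s in sigmas]
    best = sigmas[int(np.argmax(responses))]
    assert abs(best - sigma_s) <= 0.025 + 1e-9


def test_log_two_far_spots_equal_peaks():
    a = _gaussian_spot_stack((1.0, 1.0, 1.0), 0.2)
    b = _gaussian_spot_stack((3.0, 3.0, 3.0), 0.2)
    stack = ImageStack3D(voxels=a.voxels + b.voxels, voxel_size=ISO)
    resp = log_filter(stack, 0.2).values
    p1 = resp[9, 9, 9]
    p2 = resp[29, 29, 29]
    assert p1 == pytest.approx(p2, rel=1e-6)


def test_log_rejects_subvoxel_sigma():
    stack = ImageStack3D(voxels=np.ones((5, 5, 5)), voxel_size=(0.2, 0.1, 0.1))
    with pytest.raises(ResolutionError):
        log_filter(stack, (0.1, 0.2, 0.2))


# ------------------------------------------------------------------ Otsu


def otsu_bruteforce_partition(values):
    """Exhaustive search over all cut values maximizing between-class variance."""
    v = np.asarray(values, float)
    best, best_cut = -np.inf, None
    for cut in np.unique(v)[:-1]:
        lo, hi = v[v <= cut], v[v > cut]
        w0, w1 = len(lo) / len(v), len(hi) / len(v)
        bc = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if bc > best:
            best, best_cut = bc, cut
    return v > best_cut


def test_otsu_separates_two_masses():
    v = np.array([0.0] * 50 + [200.0] * 50)
    thr = otsu_threshold(v)
    assert 0 < thr <= 200
    assert ((v >= thr) == (v == 200)).all()


def test_otsu_matches_exhaustive_search_on_8bit(rng):
    for _ in range(25):
        v = rng.integers(0, 256, size=rng.integers(50, 400)).astype(float)
        if v.max() == v.min():
            continue
        thr = otsu_threshold(v)
        assert ((v >= thr) == otsu_bruteforce_partition(v)).all()


def test_otsu_rejects_constant_input():
    with pytest.raises(DegenerateInputError):
        otsu_threshold(np.full(10, 3.0))


# ----------------------------------------------------------------- seeds


def test_no_seeds_below_threshold():
    stack = _gaussian_spot_stack((2.0, 2.0, 2.0), 0.3, amp=1.0)
    resp = log_filter(stack, 0.3)
    assert len(detect_seeds(resp, resp.values.max() + 1.0, 0.2)) == 0


def test_seeds_found_at_true_spot_centers(clean_image_params):
    stack, truth = gen_image_stack(clean_image_params)
    resp = log_filter(stack, (0.25, 0.11, 0.11))
    thr = otsu_threshold(resp.values)
    seeds = detect_seeds(resp, thr, 0.4)
    assert len(seeds) == len(truth.spot_centroids)
    d = np.array(stack.voxel_size)
    seed_um = (seeds + 0.5) * d
    _, recall, precision = match_centroids(truth.spot_centroids, seed_um, np.linalg.norm(d))
    assert recall == 1.0 and precision == 1.0


def test_close_maxima_suppressed_to_stronger_one():
    resp_vals = np.zeros((5, 21, 21))
    resp_vals[2, 10, 8] = 5.0
    resp_vals[2, 10, 12] = 4.0
    from peroxikit.imaging import ResponseVolume

    resp = ResponseVolume(values=resp_vals, sigma_um=(0.2,) * 3, voxel_size=ISO)
    seeds = detect_seeds(resp, 1.0, min_separation_um=1.0)
    assert len(seeds) == 1
    assert tuple(seeds[0]) == (2, 10, 8)


# ------------------------------------------------------------- watershed


def test_watershed_single_seed_fills_mask():
    from peroxikit.imaging import ResponseVolume

    vals = np.random.default_rng(0).random((6, 8, 8))
    resp = ResponseVolume(values=vals, sigma_um=(0.2,) * 3, voxel_size=ISO)
    mask = np.zeros((6, 8, 8), bool)
    mask[1:5, 2:6, 2:6] = True
    labels = watershed_segment(resp, mask, np.array([[2, 3, 3]]))
    assert (labels[mask] == 1).all()
    assert (labels[~mask] == 0).all()


def test_watershed_dumbbell_splits_at_midplane():
    a = _gaussian_spot_stack((2.0, 2.0, 1.7), 0.2)
    b = _gaussian_spot_stack((2.0, 2.0, 2.3), 0.2)
    stack = ImageStack3D(voxels=a.voxels + b.voxels, voxel_size=ISO)
    resp = log_filter(stack, 0.2)
    thr = otsu_threshold(resp.values)
    mask = resp.values >= thr
    seeds = np.array([[19, 19, 16], [19, 19, 22]])
    labels = watershed_segment(resp, mask, seeds)
    # boundary along x at the midplane (x index 19/20) +- 1 voxel
    xs1 = np.where(labels == 1)[2]
    xs2 = np.where(labels == 2)[2]
    assert xs1.max() <= 20
    assert xs2.min() >= 19
    assert abs(len(xs1) - len(xs2)) <= 0.1 * (len(xs1) + len(xs2))


def test_watershed_label_count_bounded_by_seeds(rng):
    from peroxikit.imaging import ResponseVolume

    vals = rng.random((6, 10, 10))
    resp = ResponseVolume(values=vals, sigma_um=(0.2,) * 3, voxel_size=ISO)
    mask = vals > 0.2
    cand = np.argwhere(mask)[:5]
    labels = watershed_segment(resp, mask, cand)
    assert labels.max() <= len(cand)


def test_watershed_seed_outside_mask_is_named():
    from peroxikit.imaging import ResponseVolume

    resp = ResponseVolume(values=np.zeros((3, 3, 3)), sigma_um=(0.2,) * 3, voxel_size=ISO)
    mask = np.zeros((3, 3, 3), bool)
    mask[1, 1, 1] = True
    with pytest.raises(ValueError, match="\\(0, 0, 0\\)"):
        watershed_segment(resp, mask, np.array([[0, 0, 0]]))


# ------------------------------------------------------------ label filter


def test_filter_labels_min1_is_identity_up_to_relabel(rng):
    labels = rng.integers(0, 5, (6, 10, 10))
    spots = filter_labels(labels, 1, ISO)
    assert (spots.labels > 0).sum() == (labels > 0).sum()
    assert spots.n_spots == len(np.unique(labels)) - 1
    # largest first
    sizes = [np.sum(spots.labels == k) for k in range(1, spots.n_spots + 1)]
    assert sizes == sorted(sizes, reverse=True)


def test_filter_labels_removes_small_component():
    labels = np.zeros((4, 6, 6), int)
    labels[0, 0, :4] = 1  # 4 voxels
    labels[2, 2:5, 2:5] = 2  # 9 voxels
    spots = filter_labels(labels, 5, ISO)
    assert spots.n_spots == 1
    assert spots.volumes_um3[0] == pytest.approx(9 * np.prod(ISO))


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(min_value=1, max_value=8), st.integers(min_value=0, max_value=10**6))
def test_filter_labels_matches_bruteforce_size_filter(min_vox, seed):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 6, (5, 8, 8))
    spots = filter_labels(labels, min_vox, ISO)
    sizes = np.bincount(labels.ravel(), minlength=7)[1:]
    expected = {k + 1 for k in range(6) if sizes[k] >= min_vox}
    survived_sizes = sorted(int(np.sum(spots.labels == j)) for j in range(1, spots.n_spots + 1))
    assert survived_sizes == sorted(int(sizes[k - 1]) for k in expected)


# ------------------------------------------------ per-cell counts, density


def test_spots_per_cell_empty_spotset():
    cells = np.zeros((4, 6, 6), int)
    cells[1:3, 1:3, 1:3] = 1
    cells[1:3, 4:6, 4:6] = 2
    spots = filter_labels(np.zeros_like(cells), 1, ISO)
    counts, bg = spots_per_cell(spots, cells)
    assert counts.to_dict() == {1: 0, 2: 0}
    assert bg == []


def test_spots_per_cell_matches_ground_truth(clean_image_params, quant_config):
    stack, truth = gen_image_stack(clean_image_params)
    res = quantify_stack(stack, truth.cell_label_volume, quant_config)
    assert res.per_cell_counts.to_dict() == truth.per_cell_counts
    assert res.background_spots == []


def test_background_spot_excluded_and_reported():
    cells = np.zeros((6, 10, 10), int)
    cells[1:5, 1:5, 1:5] = 1
    spot_labels = np.zeros_like(cells)
    spot_labels[2, 2, 2] = 1  # inside cell
    spot_labels[2, 8, 8] = 2  # background
    spots = filter_labels(spot_labels, 1, ISO)
    counts, bg = spots_per_cell(spots, cells)
    assert counts.to_dict() == {1: 1}
    assert len(bg) == 1


def test_count_conservation(clean_image_params, quant_config):
    stack, truth = gen_image_stack(clean_image_params)
    res = quantify_stack(stack, truth.cell_label_volume, quant_config)
    assert res.per_cell_counts.sum() + len(res.background_spots) == res.spots.n_spots


def test_numerical_density_arithmetic():
    r = numerical_density(10, 1000.0)
    assert r.density_per_um3 == pytest.approx(0.010)
    assert numerical_density(0, 50.0).density_per_um3 == 0.0
    with pytest.raises(ValueError):
        numerical_density(1, 0.0)


def test_cytoplasmic_volume_excludes_border_cells_and_nucleus():
    cells = np.zeros((4, 10, 10), int)
    cells[1:3, 0:3, 0:3] = 1  # touches lateral border
    cells[1:3, 5:8, 5:8] = 2
    vol, kept = cytoplasmic_volume(cells, ISO)
    assert list(kept) == [2]
    assert vol == pytest.approx(2 * 9 * np.prod(ISO))
    nucleus = np.zeros_like(cells, bool)
    nucleus[1, 6, 6] = True
    vol2, _ = cytoplasmic_volume(cells, ISO, nucleus_mask=nucleus)
    assert vol2 == pytest.approx(vol - np.prod(ISO))


def test_normalized_signal_formula():
    assert normalized_signal(2_000_000, 20) == pytest.approx(10.0)
    assert normalized_signal(0, 20) == 0.0
    assert normalized_signal(4_000_000, 40) == pytest.approx(normalized_signal(2_000_000, 20))
    with pytest.raises(ValueError):
        normalized_signal(1.0, 0.0)


# ---------------------------------------------------------------- pipeline


def test_pipeline_empty_stack_yields_no_spots():
    cells = np.zeros((8, 20, 20), int)
    cells[2:6, 5:15, 5:15] = 1
    stack = ImageStack3D(voxels=np.full((8, 20, 20), 50.0), voxel_size=(0.2, 0.1, 0.1))
    res = quantify_stack(stack, cells, QuantConfig(sigma_um=(0.4, 0.2, 0.2)))
    assert res.spots.n_spots == 0
    assert res.density.density_per_um3 == 0.0


def test_pipeline_deterministic(clean_image_params, quant_config):
    stack, truth = gen_image_stack(clean_image_params)
    r1 = quantify_stack(stack, truth.cell_label_volume, quant_config)
    r2 = quantify_stack(stack, truth.cell_label_volume, quant_config)
    assert np.array_equal(r1.spots.labels, r2.spots.labels)
    assert np.array_equal(r1.spots.centroids_um, r2.spots.centroids_um)


def test_pipeline_intensity_scale_invariant(clean_image_params, quant_config):
    stack, truth = gen_image_stack(clean_image_params)
    scaled = ImageStack3D(voxels=stack.voxels * 7.5, voxel_size=stack.voxel_size)
    r1 = quantify_stack(stack, truth.cell_label_volume, quant_config)
    r2 = quantify_stack(scaled, truth.cell_label_volume, quant_config)
    assert r1.spots.n_spots == r2.spots.n_spots
    assert np.array_equal(r1.spots.labels, r2.spots.labels)
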