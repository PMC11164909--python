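"""Core detection and metrology: DoG, peak seeding, GMM, FWHM, nnd,
orchestrated detection and per-cell aggregation."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.mixture import GaussianMixture

from stormquant.domains import (
    FWHM_FACTOR,
    Nanodomain,
    NanodomainDetector,
    dog_filter,
    find_peaks,
    fit_gmm,
    fwhm_from_cov,
    mask_on_grid,
    nearest_neighbor_distances,
    summarize_cell,
)
from stormquant.io import Mask, new_table
from stormquant.render import RenderedImage, render
from stormquant.simulate import SimConfig, simulate_cell


def _image(data, px=10.0):
    return RenderedImage(np.asarray(data, dtype=float), px)


# --- DoG -------------------------------------------------------------------


def test_dog_constant_image_maps_to_zero():
    out = dog_filter(_image(np.full((64, 64), 3.7)), 20.0, 32.0)
    np.testing.assert_allclose(out, 0.0, atol=1e-12)


def test_dog_impulse_center_closed_form():
    img = np.zeros((101, 101))
    img[50, 50] = 1.0
    s1, s2 = 30.0, 48.0  # 3 and 4.8 px
    out = dog_filter(_image(img), s1, s2)
    expected = 1 / (2 * np.pi * 3.0**2) - 1 / (2 * np.pi * 4.8**2)
    assert out[50, 50] == pytest.approx(expected, rel=1e-3)


def test_dog_sigma_order_enforced():
    with pytest.raises(ValueError):
        dog_filter(_image(np.zeros((8, 8))), 30.0, 20.0)


def test_dog_blob_maximum_at_center():
    # dense rendered Gaussian blob, matched sigma1: unique max within 1 px
    yy, xx = np.mgrid[0:101, 0:101]
    sigma_px = 4.0
    blob = np.exp(-((xx - 57) ** 2 + (yy - 43) ** 2) / (2 * sigma_px**2))
    out = dog_filter(_image(blob), sigma_px * 10.0, 1.6 * sigma_px * 10.0)
    r, c = np.unravel_index(np.argmax(out), out.shape)
    assert abs(r - 43) <= 1 and abs(c - 57) <= 1


# --- peaks -----------------------------------------------------------------


def _full_grid(shape):
    return np.ones(shape, dtype=bool)


def test_flat_image_has_no_peaks():
    img = _image(np.zeros((50, 50)))
    seeds = find_peaks(np.zeros((50, 50)), img, _full_grid((50, 50)), 3, 1.0, threshold_abs=0.5)
    assert len(seeds) == 0


def test_two_impulses_found_at_their_pixels():
    filt = np.zeros((50, 50))
    filt[10, 10] = 1.0
    filt[10, 30] = 1.0
    img = _image(filt)
    seeds = find_peaks(filt, img, _full_grid((50, 50)), min_distance_px=5, threshold_abs=0.5)
    got = {(x, y) for x, y in seeds}
    assert got == {(105.0, 105.0), (305.0, 105.0)}


def test_simulated_nucleus_seed_coverage():
    cfg = SimConfig(seed=31, min_domain_separation_nm=160.0, background_density_per_um2=0.5)
    table, nuc, _, truth = simulate_cell(cfg)
    det = NanodomainDetector()
    # run just the seeding stages
    sub = table[nuc.contains(table.x_nm.to_numpy(), table.y_nm.to_numpy())]
    img = render(sub, 10.0, origin_nm=(0.0, 0.0), shape=(2000, 2000))
    s1 = 80.0 / FWHM_FACTOR / np.sqrt(2)
    filt = dog_filter(img, s1, 1.6 * s1)
    grid = mask_on_grid(nuc, img)
    seeds = find_peaks(filt, img, grid, 8, 1.0)
    matched = 0
    for _, dom in truth.domains.iterrows():
        d = np.hypot(seeds[:, 0] - dom.x_nm, seeds[:, 1] - dom.y_nm).min()
        matched += d <= dom.fwhm_nm / 2
    assert matched / len(truth.domains) >= 0.90


# --- GMM -------------------------------------------------------------------


def test_single_component_em_fixed_point(rng):
    X = rng.normal(0.0, 15.0, size=(800, 2)) + [500.0, 300.0]
    comps = fit_gmm(X, seeds=[[490.0, 310.0]], covariance_floor_nm2=1e-6)
    assert len(comps) == 1
    np.testing.assert_allclose(comps[0].mean, X.mean(axis=0), atol=1e-6)
    np.testing.assert_allclose(comps[0].cov, np.cov(X.T, bias=True), atol=1e-4)
    assert comps[0].n_locs == 800


def test_two_separated_clusters_recovered(rng):
    a = rng.normal(0, 15.0, (500, 2)) + [1000.0, 1000.0]
    b = rng.normal(0, 15.0, (500, 2)) + [2000.0, 1000.0]
    X = np.vstack([a, b])
    comps = fit_gmm(X, seeds=[[1010.0, 995.0], [1990.0, 1005.0]])
    assert len(comps) == 2
    counts = sorted(c.n_locs for c in comps)
    assert abs(counts[0] - 500) <= 5 and abs(counts[1] - 500) <= 5
    for comp, truth in zip(sorted(comps, key=lambda c: c.mean[0]), (a, b)):
        np.testing.assert_allclose(comp.mean, truth.mean(axis=0), atol=2.0)


def test_min_locs_filter_drops_tiny_components(rng):
    X = rng.normal(0, 10.0, (5, 2))
    assert fit_gmm(X, seeds=[[0.0, 0.0]], min_locs=10) == []


def test_gmm_agrees_with_sklearn_on_well_separated_mixture(rng):
    """Independent cross-check of the EM against scikit-learn's."""
    a = rng.normal(0, 20.0, (600, 2)) + [0.0, 0.0]
    b = rng.normal(0, 12.0, (400, 2)) + [900.0, 500.0]
    X = np.vstack([a, b])
    seeds = np.array([[5.0, -5.0], [895.0, 505.0]])
    ours = sorted(fit_gmm(X, seeds, covariance_floor_nm2=1e-6), key=lambda c: c.mean[0])
    ref = GaussianMixture(
        n_components=2, means_init=seeds, covariance_type="full", reg_covar=1e-6, tol=1e-8
    ).fit(X)
    order = np.argsort(ref.means_[:, 0])
    for comp, mean, cov in zip(ours, ref.means_[order], ref.covariances_[order]):
        np.testing.assert_allclose(comp.mean, mean, atol=0.5)
        np.testing.assert_allclose(comp.cov, cov, rtol=0.02, atol=0.5)


def test_background_component_absorbs_uniform_noise(rng):
    cluster = rng.normal(0, 15.0, (500, 2)) + [500.0, 500.0]
    noise = rng.uniform(0, 1000.0, (300, 2))
    X = np.vstack([cluster, noise])
    with_bg = fit_gmm(X, [[500.0, 500.0]], background=True, region_area_nm2=1e6)
    without = fit_gmm(X, [[500.0, 500.0]])
    assert len(with_bg) == 1 and len(without) == 1
    # the background component keeps stray noise out of the cluster count
    assert with_bg[0].n_locs < without[0].n_locs
    assert abs(with_bg[0].n_locs - 500) < 60


# --- FWHM ------------------------------------------------------------------


def test_fwhm_isotropic_closed_form():
    assert fwhm_from_cov(np.eye(2) * 100.0) == pytest.approx(23.548, abs=1e-3)
    assert fwhm_from_cov(np.eye(2) * 100.0) == pytest.approx(FWHM_FACTOR * 10.0, abs=1e-9)


def test_fwhm_geometric_mean_convention():
    cov = np.diag([100.0, 1600.0])  # sigma 10 and 40 nm
    assert fwhm_from_cov(cov) == pytest.approx(FWHM_FACTOR * 20.0, abs=1e-9)


def test_fwhm_rejects_degenerate():
    with pytest.raises(ValueError):
        fwhm_from_cov(np.zeros((2, 2)))
    with pytest.raises(ValueError):
        fwhm_from_cov(np.array([[1.0, 2.0], [0.0, 1.0]]))


@given(st.floats(0, 2 * math.pi), st.floats(5, 50), st.floats(5, 50))
def test_fwhm_rotation_invariant(theta, s1, s2):
    base = np.diag([s1**2, s2**2])
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    rotated = R @ base @ R.T
    assert fwhm_from_cov(rotated) == pytest.approx(fwhm_from_cov(base), abs=1e-9)


# --- nnd -------------------------------------------------------------------


def _dom(x, y, fwhm):
    return Nanodomain(np.array([x, y]), np.eye(2), fwhm, 100)


def test_nnd_two_domain_definition():
    nnd = nearest_neighbor_distances([_dom(0, 0, 40.0), _dom(100, 0, 60.0)])
    np.testing.assert_allclose(nnd, [50.0, 50.0])


def test_nnd_overlapping_discs_floored_at_zero():
    nnd = nearest_neighbor_distances([_dom(0, 0, 40.0), _dom(30, 0, 40.0)])
    np.testing.assert_allclose(nnd, [0.0, 0.0])


def test_nnd_fewer_than_two_domains_warns():
    with pytest.warns(UserWarning):
        assert nearest_neighbor_distances([_dom(0, 0, 40.0)]).size == 0


def brute_force_nnd(domains):
    out = []
    for i, di in enumerate(domains):
        best = math.inf
        for j, dj in enumerate(domains):
            if i == j:
                continue
            d = math.sqrt(
                (di.center_nm[0] - dj.center_nm[0]) ** 2
                + (di.center_nm[1] - dj.center_nm[1]) ** 2
            )
            best = min(best, max(0.0, d - di.fwhm_nm / 2 - dj.fwhm_nm / 2))
        out.append(best)
    return np.array(out)


def test_nnd_matches_brute_force_oracle(rng):
    domains = [
        _dom(x, y, f)
        for x, y, f in zip(
            rng.uniform(0, 5000, 200), rng.uniform(0, 5000, 200), rng.uniform(20, 120, 200)
        )
    ]
    np.testing.assert_array_equal(nearest_neighbor_distances(domains), brute_force_nnd(domains))


# --- orchestrated detection ------------------------------------------------


def test_detection_recovers_quiescent_and_activated_scales():
    recs = {}
    for name, fwhm, sd, sep in (("quiescent", 90.0, 10.0, 180.0), ("activated", 45.0, 6.0, 90.0)):
        cfg = SimConfig(seed=41, domain_fwhm_mean_nm=fwhm, domain_fwhm_sd_nm=sd,
                        min_domain_separation_nm=sep, n_nuclear_domains=40)
        table, nuc, _, truth = simulate_cell(cfg)
        det = NanodomainDetector(expected_fwhm_nm=fwhm).fit(table, nuc)
        rec = summarize_cell(det.domains_)
        assert rec.mean_fwhm_nm == pytest.approx(truth.domains.fwhm_nm.mean(), rel=0.10)
        assert rec.mean_locs_per_domain == pytest.approx(truth.domains.n_locs.mean(), rel=0.10)
        recs[name] = rec
    assert recs["activated"].mean_fwhm_nm < recs["quiescent"].mean_fwhm_nm


def test_detected_locs_bounded_by_mask_content(default_cell):
    cfg, (table, nuc, cyto, truth) = default_cell
    det = NanodomainDetector().fit(table, [nuc, cyto])
    in_nuc = int(nuc.contains(table.x_nm.to_numpy(), table.y_nm.to_numpy()).sum())
    total_assigned = sum(d.n_locs for d in det.domains_ if d.region == "nucleus")
    assert total_assigned <= in_nuc


def test_detection_translation_equivariance(default_cell):
    cfg = dataclasses.replace(default_cell[0], n_cytosolic_clusters=0, n_nuclear_domains=15,
                              n_frames=2000, seed=43)
    table, nuc, _, _ = simulate_cell(cfg)
    det1 = NanodomainDetector().fit(table, nuc)
    shift = np.array([137.0, -61.0])
    shifted = table.copy()
    shifted["x_nm"] += shift[0]
    shifted["y_nm"] += shift[1]
    nuc2 = Mask(nuc.data, nuc.pixel_size_nm,
                (nuc.origin_nm[0] + shift[0], nuc.origin_nm[1] + shift[1]), "nucleus")
    det2 = NanodomainDetector().fit(shifted, nuc2)
    c1 = np.sort(np.array([d.center_nm for d in det1.domains_]), axis=0)
    c2 = np.sort(np.array([d.center_nm for d in det2.domains_]), axis=0)
    assert len(det1.domains_) == len(det2.domains_)
    np.testing.assert_allclose(c2 - shift, c1, atol=10.0)  # within 1 px


def test_empty_cytoplasm_gives_zero_clusters(default_cell):
    cfg = dataclasses.replace(default_cell[0], n_cytosolic_clusters=0,
                              background_density_per_um2=0.0, seed=47)
    table, nuc, cyto, _ = simulate_cell(cfg)
    det = NanodomainDetector().fit(table, [nuc, cyto])
    assert sum(d.region == "cytoplasm" for d in det.domains_) == 0


def test_labels_align_with_domains(default_cell):
    cfg, (table, nuc, cyto, truth) = default_cell
    det = NanodomainDetector().fit(table, [nuc, cyto])
    for k, dom in enumerate(det.domains_):
        assert (det.labels_ == k).sum() == dom.n_locs


# --- per-cell aggregation --------------------------------------------------


def test_summarize_simple_means():
    doms = [_dom(0, 0, 20.0), _dom(1000, 0, 40.0)]
    rec = summarize_cell(doms, "c", "q")
    assert rec.mean_fwhm_nm == 30.0
    assert rec.n_nuclear_domains == 2


def test_summarize_no_cytosolic_flags_undefined():
    rec = summarize_cell([_dom(0, 0, 20.0)], "c", "q")
    assert rec.n_cytosolic_clusters == 0
    assert np.isnan(rec.mean_cyto_fwhm_nm)
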