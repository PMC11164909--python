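"""Generator contracts: determinism, source attribution, count laws, drift
models, fiducials, and the two-arm population design."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from stormquant.drift import DriftTrace
from stormquant.io import new_table
from stormquant.simulate import (
    SimConfig,
    add_fiducials,
    apply_drift,
    simulate_cell,
    simulate_drift,
    simulate_population,
)

SIGMA = 1 / (2 * np.sqrt(2 * np.log(2)))


def test_seed_determinism_bit_identical():
    cfg = SimConfig(seed=7, n_cytosolic_clusters=5, n_fiducials=2, drift_model="linear", drift_magnitude_nm=50)
    t1, n1, c1, g1 = simulate_cell(cfg)
    t2, n2, c2, g2 = simulate_cell(cfg)
    pd.testing.assert_frame_equal(t1, t2)
    assert np.array_equal(n1.data, n2.data)
    np.testing.assert_array_equal(g1.drift, g2.drift)
    pd.testing.assert_frame_equal(g1.domains, g2.domains)


def test_no_background_means_every_row_attributed(default_cell):
    cfg = dataclasses.replace(default_cell[0], background_density_per_um2=0.0, seed=3)
    table, _, _, truth = simulate_cell(cfg)
    assert (table["source_id"] >= 0).all()
    # count conservation: rows equal the summed ground-truth counts
    assert len(table) == truth.domains["n_locs"].sum()


def test_geometry_every_domain_loc_within_4_sigma():
    cfg = SimConfig(seed=5, background_density_per_um2=0.0, localization_precision_nm=0.0)
    table, _, _, truth = simulate_cell(cfg)
    for i, dom in truth.domains.iterrows():
        sel = table["source_id"] == i
        r = np.hypot(table.loc[sel, "x_nm"] - dom.x_nm, table.loc[sel, "y_nm"] - dom.y_nm)
        assert (r <= 4 * dom.fwhm_nm * SIGMA + 1e-9).all()


def test_total_locs_match_negative_binomial_moments():
    # 50 domains x NB(mean 200, dispersion 20): total mean 10000,
    # SD = sqrt(50 * (200 + 200^2/20)) = 331.7; demand within 3 SD
    cfg = SimConfig(seed=17, background_density_per_um2=0.0, n_nuclear_domains=50,
                    locs_per_domain_mean=200.0, locs_per_domain_dispersion=20.0)
    table, _, _, _ = simulate_cell(cfg)
    sd = np.sqrt(50 * (200 + 200**2 / 20))
    assert abs(len(table) - 10_000) <= 3 * sd


def test_nucleus_larger_than_field_rejected():
    with pytest.raises(ValueError, match="larger than field"):
        SimConfig(field_size_nm=(5000, 5000), nucleus_semiaxes_nm=(3500, 3000)).validate()


def test_counts_validation():
    with pytest.raises(ValueError):
        SimConfig(n_nuclear_domains=-1).validate()
    with pytest.raises(ValueError):
        SimConfig(locs_per_domain_mean=0).validate()


# --- drift -----------------------------------------------------------------


def test_drift_none_is_zero():
    trace = simulate_drift(20000, "none", 0.0)
    assert not trace.dxy.any()


def test_linear_drift_endpoints():
    trace = simulate_drift(20000, "linear", 200.0, seed=4)
    assert np.hypot(*trace.dxy[0]) == 0.0
    assert np.hypot(*trace.dxy[-1]) == pytest.approx(200.0)


def test_random_walk_step_sd():
    trace = simulate_drift(1000, "random_walk", 0.5, seed=3)
    steps = np.diff(trace.dxy, axis=0)
    assert np.std(steps) == pytest.approx(0.5, rel=0.10)


def test_unknown_drift_model():
    with pytest.raises(ValueError, match="unknown drift model"):
        simulate_drift(100, "sinusoidal", 1.0)


def _single_loc_table(x, y, frame):
    return new_table(np.array([x]), np.array([y]), np.array([frame]))


def test_apply_drift_is_additive():
    trace = DriftTrace(np.zeros((20, 2)))
    trace.dxy[10] = (5.0, -3.0)
    out = apply_drift(_single_loc_table(100.0, 100.0, 10), trace)
    assert (out["x_nm"].iloc[0], out["y_nm"].iloc[0]) == (105.0, 97.0)


def test_apply_drift_zero_trace_identity(default_cell):
    table = default_cell[1][0]
    out = apply_drift(table, DriftTrace(np.zeros((20000, 2))))
    pd.testing.assert_frame_equal(out, table)


def test_apply_drift_rejects_uncovered_frames():
    with pytest.raises(ValueError, match="out of drift-trace range"):
        apply_drift(_single_loc_table(0, 0, 30), DriftTrace(np.zeros((20, 2))))


# --- fiducials -------------------------------------------------------------


def test_fiducial_row_count_and_exact_position():
    base = new_table(np.empty(0), np.empty(0), np.empty(0, dtype=int))
    out = add_fiducials(base, [(500.0, 700.0)], n_frames=100, precision_nm=0.0)
    assert len(out) == 100
    assert (out["x_nm"] == 500.0).all() and (out["y_nm"] == 700.0).all()
    assert (out["source_flag"] == "fiducial").all()


def test_fiducial_noise_sample_sd():
    base = new_table(np.empty(0), np.empty(0), np.empty(0, dtype=int))
    out = add_fiducials(base, [(500.0, 700.0)], n_frames=20000, precision_nm=10.0, seed=9)
    assert np.std(out["x_nm"]) == pytest.approx(10.0, rel=0.02)
    assert np.std(out["y_nm"]) == pytest.approx(10.0, rel=0.02)


def test_fiducial_outside_field_rejected():
    base = new_table(np.empty(0), np.empty(0), np.empty(0, dtype=int))
    with pytest.raises(ValueError, match="outside field"):
        add_fiducials(base, [(-5.0, 0.0)], 10, 0.0, field_size_nm=(1000, 1000))


# --- population ------------------------------------------------------------


def _fast(cfg=None, **kw):
    base = dict(n_nuclear_domains=20, n_frames=2000, background_density_per_um2=0.0)
    base.update(kw)
    return SimConfig(**base)


def test_population_size_and_determinism():
    cells1 = simulate_population(_fast(), _fast(), n_cells_per_arm=1, seed=5)
    cells2 = simulate_population(_fast(), _fast(), n_cells_per_arm=1, seed=5)
    assert len(cells1) == 2
    pd.testing.assert_frame_equal(cells1[0].table, cells2[0].table)
    assert cells1[0].condition != cells1[1].condition


def test_population_arm_means_recover_configured_sizes():
    a = _fast(domain_fwhm_mean_nm=90.0)
    b = _fast(domain_fwhm_mean_nm=45.0)
    cells = simulate_population(a, b, n_cells_per_arm=30, seed=8)
    means = {}
    for cond in ("quiescent", "activated"):
        vals = [c.truth.domains.fwhm_nm.mean() for c in cells if c.condition == cond]
        means[cond] = np.mean(vals)
    assert means["quiescent"] - means["activated"] == pytest.approx(45.0, rel=0.10)
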