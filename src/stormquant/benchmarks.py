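"""Seeded end-to-end recovery and calibration experiments.

Each function simulates data under the package's study conditions, runs the
analysis pipeline on it, and measures how well known ground truth is
recovered.  They back both the validation test suite and the
``scripts/acceptance.py`` report, and double as worked examples of the API.

Problem sizes are chosen so the whole battery runs in minutes on one CPU:
30 cells per arm for the two-condition recovery, 100 cells for the
correlation designs, 1000 replicates for the type-I error rate.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np

from .coloc import coloc_degree
from .domains import (
    Nanodomain,
    NanodomainDetector,
    fwhm_from_cov,
    nearest_neighbor_distances,
    records_to_frame,
    summarize_cell,
)
from .drift import DriftCorrector
from .pipeline import run_pipeline
from .render import render
from .simulate import SimConfig, simulate_cell, simulate_population, simulate_two_channel_cell
from .stats import compare_conditions, mann_whitney_u, pearson_r


def _spawn(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# exact-arithmetic checks


def nnd_vs_brute_force(seed: int, n: int = 200) -> dict:
    """Max |vectorized nnd - O(n^2) pure-Python scan| over random domains."""
    rng = np.random.default_rng(seed)
    domains = [
        Nanodomain(np.array([x, y]), np.eye(2), f, 100)
        for x, y, f in zip(rng.uniform(0, 5000, n), rng.uniform(0, 5000, n), rng.uniform(20, 120, n))
    ]
    fast = nearest_neighbor_distances(domains)
    slow = np.empty(n)
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
        slow[i] = best
    return {"max_abs_diff_nm": float(np.abs(fast - slow).max()), "n": n}


def _enumeration_mwu_p(x, y) -> float:
    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    center = n * m / 2
    hits = total = 0
    for idx in itertools.combinations(range(n + m), n):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in chosen]
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        total += 1
        hits += abs(u - center) >= abs(u_obs - center) - 1e-12
    return hits / total


def mwu_exactness(seed: int) -> dict:
    """Exact-path p-values vs full enumeration for all tie-free n+m <= 10."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    cases = 0
    for n in range(1, 10):
        for m in range(1, 11 - n):
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            res = mann_whitney_u(x, y)
            worst = max(worst, abs(res.p_value - _enumeration_mwu_p(x, y)))
            cases += 1
    textbook = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    return {
        "max_abs_p_error": worst,
        "n_cases": cases,
        "textbook_u": float(textbook.u_statistic),
        "textbook_p": float(textbook.p_value),
    }


def fwhm_closed_form(seed: int, n_rotations: int = 100) -> dict:
    """Isotropic closed form and rotation invariance of the FWHM reduction."""
    iso = fwhm_from_cov(np.eye(2) * 100.0)
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_rotations):
        s1, s2 = rng.uniform(5, 50, 2)
        base = np.diag([s1**2, s2**2])
        th = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        worst = max(worst, abs(fwhm_from_cov(R @ base @ R.T) - fwhm_from_cov(base)))
    return {"isotropic_sigma10_nm": float(iso), "max_rotation_dev_nm": float(worst)}


# ---------------------------------------------------------------------------
# drift recovery


def drift_recovery(seed: int) -> dict:
    """RMSE reduction of injected drift: linear 200 nm / 20,000 frames and a
    0.5 nm-step random walk, 3 fiducials at 10 nm precision, 200-frame
    windows."""
    out = {}
    seeds = _spawn(seed, 2)
    for model, mag, s in (("linear", 200.0, seeds[0]), ("random_walk", 0.5, seeds[1])):
        cfg = SimConfig(
            seed=s,
            n_fiducials=3,
            localization_precision_nm=10.0,
            drift_model=model,
            drift_magnitude_nm=mag,
            n_nuclear_domains=30,
        )
        table, _, _, truth = simulate_cell(cfg)
        corr = DriftCorrector(window=200).fit(table)
        residual = corr.trace_.dxy - truth.drift
        residual -= residual.mean(axis=0)  # registration offset is irrelevant
        rmse_before = float(np.sqrt((truth.drift**2).sum(axis=1).mean()))
        rmse_after = float(np.sqrt((residual**2).sum(axis=1).mean()))
        out[model] = {
            "rmse_reduction_pct": 100.0 * (1.0 - rmse_after / rmse_before),
            "rmse_before_nm": rmse_before,
            "rmse_after_nm": rmse_after,
        }
    return out


# ---------------------------------------------------------------------------
# two-arm parameter recovery


ARM_QUIESCENT = dict(
    domain_fwhm_mean_nm=90.0,
    domain_fwhm_sd_nm=10.0,
    min_domain_separation_nm=180.0,
    n_nuclear_domains=40,
    locs_per_domain_mean=200.0,
)
ARM_ACTIVATED = dict(
    domain_fwhm_mean_nm=45.0,
    domain_fwhm_sd_nm=6.0,
    min_domain_separation_nm=90.0,
    n_nuclear_domains=40,
    locs_per_domain_mean=200.0,
)


def two_arm_recovery(seed: int, n_cells_per_arm: int = 30) -> dict:
    """Recovery of per-arm mean FWHM (90 vs 45 nm) and localizations per
    domain (200), plus the between-arm Mann-Whitney comparison."""
    cells = simulate_population(
        SimConfig(**ARM_QUIESCENT), SimConfig(**ARM_ACTIVATED), n_cells_per_arm, seed=seed
    )
    det_params = dict(expected_fwhm_nm=65.0)
    records = []
    for cell in cells:
        det = NanodomainDetector(cell_id=cell.cell_id, **det_params)
        det.fit(cell.table, cell.nucleus_mask)
        records.append(summarize_cell(det.domains_, cell.cell_id, cell.condition))
    df = records_to_frame(records)
    result, _ = compare_conditions(df, "mean_fwhm_nm")
    arms = {}
    for cond, true_fwhm in (("quiescent", 90.0), ("activated", 45.0)):
        sub = df[df.condition == cond]
        arms[cond] = {
            "mean_fwhm_nm": float(sub.mean_fwhm_nm.mean()),
            "true_fwhm_nm": true_fwhm,
            "fwhm_err_pct": 100.0 * abs(sub.mean_fwhm_nm.mean() / true_fwhm - 1.0),
            "mean_locs": float(sub.mean_locs_per_domain.mean()),
            "locs_err_pct": 100.0 * abs(sub.mean_locs_per_domain.mean() / 200.0 - 1.0),
            "n_cells": int(len(sub)),
        }
    activated_smaller = (
        df[df.condition == "activated"].mean_fwhm_nm.median()
        < df[df.condition == "quiescent"].mean_fwhm_nm.median()
    )
    return {
        "arms": arms,
        "mwu_p": float(result.p_value),
        "direction_correct": bool(activated_smaller),
    }


# ---------------------------------------------------------------------------
# nuclear-cytosolic correlation recovery


def _coupled_arm(coupling: float) -> SimConfig:
    return SimConfig(
        domain_fwhm_mean_nm=45.0,
        domain_fwhm_sd_nm=6.0,
        min_domain_separation_nm=90.0,
        n_nuclear_domains=30,
        n_cytosolic_clusters=12,
        cell_fwhm_sd_nm=8.0,
        cyto_count_coupling=coupling,
        cyto_count_cv=0.35,
    )


def correlation_recovery(seed: int, n_cells: int = 100, coupling: float = -0.5) -> dict:
    """Pearson r between recovered per-cell nuclear domain size and cytosolic
    cluster count, under a configured latent coupling and under the null."""
    seeds = _spawn(seed, 2)
    out = {}
    for name, rho, s in (("coupled", coupling, seeds[0]), ("null", 0.0, seeds[1])):
        cfg = _coupled_arm(rho)
        cells = simulate_population(cfg, cfg, n_cells // 2, seed=s)
        records = []
        for cell in cells:
            det = NanodomainDetector(cell_id=cell.cell_id, expected_fwhm_nm=45.0)
            det.fit(cell.table, [cell.nucleus_mask, cell.cytoplasm_mask])
            records.append(summarize_cell(det.domains_, cell.cell_id, cell.condition))
        df = records_to_frame(records)
        res = pearson_r(df.mean_fwhm_nm, df.n_cytosolic_clusters)
        out[name] = {"r": float(res.r), "configured": rho, "n_cells": int(len(df))}
    out["null_bound_95"] = 2.0 / np.sqrt(n_cells)
    return out


# ---------------------------------------------------------------------------
# colocalization calibration


def coloc_calibration(seed: int, fractions=(0.0, 0.5, 1.0)) -> dict:
    """Planting a fraction f of second-channel domains at reference-domain
    centers and recovering percent_coloc = 100 f through full detection."""
    cfg = SimConfig(
        seed=seed,
        n_nuclear_domains=30,
        domain_fwhm_mean_nm=80.0,
        min_domain_separation_nm=400.0,
        background_density_per_um2=1.0,
    )
    out = {}
    for f in fractions:
        table, nuc, _, _, _ = simulate_two_channel_cell(
            dataclasses.replace(cfg, seed=cfg.seed + int(10 * f)), planted_fraction=f
        )
        det = NanodomainDetector().fit(table, nuc)
        dna = [d for d in det.domains_ if d.channel == "ch0"]
        protein = [d for d in det.domains_ if d.channel == "ch1"]
        out[f"planted_{int(100 * f)}"] = {
            "percent_coloc": float(coloc_degree(protein, dna).percent_coloc),
            "expected": 100.0 * f,
            "n_a": len(protein),
            "n_b": len(dna),
        }
    identity = coloc_degree(
        [Nanodomain(np.array([0.0, 0.0]), np.eye(2), 50.0, 10)],
        [Nanodomain(np.array([0.0, 0.0]), np.eye(2), 50.0, 10)],
    ).percent_coloc
    out["self_coloc_percent"] = float(identity)
    return out


# ---------------------------------------------------------------------------
# conservation / determinism / type-I error


def conservation_and_determinism(seed: int, tmp_dir=None) -> dict:
    """Histogram count conservation, drift round trip, and bit-identical
    pipeline outputs under a fixed seed."""
    import tempfile
    from pathlib import Path

    from .simulate import apply_drift
    from .drift import DriftTrace, correct_drift

    cfg = SimConfig(seed=_spawn(seed, 1)[0], n_nuclear_domains=20, n_frames=2000)
    table, nuc, _, _ = simulate_cell(cfg)
    img = render(table, 10.0, shape=(2000, 2000))
    infield = (
        (table.x_nm >= 0) & (table.x_nm < 20000) & (table.y_nm >= 0) & (table.y_nm < 20000)
    ).sum()
    conserved = int(img.data.sum()) == int(infield)

    rng = np.random.default_rng(seed)
    trace = DriftTrace(np.cumsum(rng.normal(0, 0.5, (2000, 2)), axis=0))
    back = correct_drift(apply_drift(table, trace), trace)
    round_trip_err = float(
        max(np.abs(back.x_nm - table.x_nm).max(), np.abs(back.y_nm - table.y_nm).max())
    )

    demo = {
        "n_cells_per_arm": 1,
        "seed": seed,
        "arms": {
            "quiescent": {"n_nuclear_domains": 10, "n_frames": 1000},
            "activated": {"n_nuclear_domains": 10, "n_frames": 1000,
                          "domain_fwhm_mean_nm": 45.0, "min_domain_separation_nm": 90.0},
        },
    }
    base = Path(tmp_dir) if tmp_dir else Path(tempfile.mkdtemp(prefix="sq_accept_"))
    m1 = run_pipeline(demo, out_dir=base / "run1")
    m2 = run_pipeline(demo, out_dir=base / "run2")
    identical = m1.input_hashes["records"] == m2.input_hashes["records"]
    return {
        "histogram_conserves_counts": bool(conserved),
        "drift_round_trip_max_err_nm": round_trip_err,
        "pipeline_bit_identical": bool(identical),
    }


def type_one_error(seed: int, n_reps: int = 1000, n_per_arm: int = 20, alpha: float = 0.05) -> dict:
    """Rejection rate of the Mann-Whitney pipeline on null two-arm data."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        x = rng.normal(size=n_per_arm)
        y = rng.normal(size=n_per_arm)
        rejections += mann_whitney_u(x, y).p_value < alpha
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps, "n_per_arm": n_per_arm}
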