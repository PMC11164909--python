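"""End-to-end orchestration: simulate -> drift-correct -> detect -> summarize
-> compare, with a reproducibility manifest.

Every run is driven by one configuration mapping (see
:data:`stormquant.io.CONFIG_DEFAULTS`) and a master seed.  The master seed is
fanned out to per-cell child seeds through ``numpy.random.SeedSequence``, so
any single cell can be regenerated without rerunning the population.  The
manifest records the configuration snapshot, seed, package versions,
per-stage wall times, output paths and output-file hashes; deterministic
stages are bit-reproducible under a fixed manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .domains import (
    CellRecord,
    NanodomainDetector,
    domains_to_frame,
    records_to_frame,
    summarize_cell,
)
from .drift import DriftCorrector
from .io import CONFIG_DEFAULTS, Mask, load_config, read_localizations, read_mask
from .simulate import SimConfig, simulate_population
from .stats import compare_conditions, correlate_nuclear_cytosolic, pearson_r

logger = logging.getLogger(__name__)

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}


@dataclass
class RunManifest:
    config: dict
    seed: int
    versions: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _arm_config(overrides: dict, base_seed: int) -> SimConfig:
    unknown = set(overrides) - _SIM_FIELDS
    if unknown:
        raise ValueError(f"unknown simulation parameters: {sorted(unknown)}")
    ov = {
        k: tuple(v) if isinstance(v, list) else v for k, v in overrides.items()
    }
    return SimConfig(**ov, seed=base_seed) if "seed" not in ov else SimConfig(**ov)


def run_pipeline(
    config: dict | str | Path | None = None,
    out_dir: str | Path = "stormquant_run",
    seed: int | None = None,
) -> RunManifest:
    """Run the full analysis and write records, domains, comparisons and a
    manifest under ``out_dir``.  ``config`` may be a mapping or a YAML path;
    ``seed`` overrides the configured master seed.

    When the configuration carries a ``cells`` list (paths to real
    localization tables and masks), the simulation stage is skipped and those
    inputs are analyzed instead.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = load_config(None, overrides=config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=cfg["seed"])
    manifest.versions = {"stormquant": __version__, "numpy": np.__version__}

    t0 = time.perf_counter()
    cells = _gather_cells(cfg, manifest)
    manifest.timings_s["simulate_or_load"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    detector_params = dict(cfg.get("detection") or {})
    all_domains, records = [], []
    for cell in cells:
        table = cell["table"]
        if cell.get("drifted"):
            try:
                table = DriftCorrector(window=cfg["drift_window"]).fit_transform(table)
            except ValueError as exc:
                raise RuntimeError(
                    f"drift correction failed for cell {cell['cell_id']}: {exc}"
                ) from exc
        det = NanodomainDetector(cell_id=cell["cell_id"], **detector_params)
        masks = [m for m in (cell["nucleus_mask"], cell.get("cytoplasm_mask")) if m is not None]
        det.fit(table, masks)
        all_domains.extend(det.domains_)
        records.append(
            summarize_cell(det.domains_, cell_id=cell["cell_id"], condition=cell["condition"])
        )
    manifest.timings_s["detect"] = round(time.perf_counter() - t0, 3)

    records_df = records_to_frame(records)
    domains_df = domains_to_frame(all_domains)
    records_path = out / "cell_records.csv"
    domains_path = out / "domains.csv"
    records_df.to_csv(records_path, index=False)
    domains_df.to_csv(domains_path, index=False)

    t0 = time.perf_counter()
    comparisons = []
    if records_df["condition"].nunique() == 2:
        for metric in cfg["metrics"]:
            try:
                result, summary = compare_conditions(records_df, metric)
            except ValueError as exc:
                logger.warning("comparison for %s skipped: %s", metric, exc)
                continue
            comparisons.append(
                {
                    "metric": metric,
                    "u_statistic": result.u_statistic,
                    "p_value": result.p_value,
                    "n_x": result.n_x,
                    "n_y": result.n_y,
                    "median_x": result.median_x,
                    "median_y": result.median_y,
                    "method": result.method,
                }
            )
    comparisons_df = pd.DataFrame(comparisons)
    comparisons_path = out / "comparisons.csv"
    comparisons_df.to_csv(comparisons_path, index=False)
    manifest.timings_s["stats"] = round(time.perf_counter() - t0, 3)

    for name, path in (
        ("records", records_path),
        ("domains", domains_path),
        ("comparisons", comparisons_path),
    ):
        manifest.outputs[name] = str(path)
        manifest.input_hashes[name] = _sha256(path)
    manifest_path = out / "manifest.json"
    manifest.outputs["manifest"] = str(manifest_path)
    manifest.to_json(manifest_path)
    return manifest


def _gather_cells(cfg: dict, manifest: RunManifest) -> list[dict]:
    if cfg.get("cells"):
        cells = []
        for spec in cfg["cells"]:
            cid = spec.get("cell_id", Path(spec["table"]).stem)
            if "nucleus_mask" not in spec:
                raise ValueError(f"missing mask for cell {cid!r}")
            table = read_localizations(spec["table"])
            manifest.input_hashes[f"table:{cid}"] = _sha256(Path(spec["table"]))
            px = cfg["mask_pixel_size_nm"]
            nuc = read_mask(spec["nucleus_mask"], px, label="nucleus")
            cyto = (
                read_mask(spec["cytoplasm_mask"], px, label="cytoplasm")
                if spec.get("cytoplasm_mask")
                else None
            )
            cells.append(
                {
                    "cell_id": cid,
                    "condition": spec.get("condition", "unknown"),
                    "table": table,
                    "nucleus_mask": nuc,
                    "cytoplasm_mask": cyto,
                    "drifted": spec.get("drift_correct", False),
                }
            )
        return cells
    arms = cfg["arms"]
    if len(arms) != 2:
        raise ValueError("simulated runs need exactly two arms")
    (name_a, ov_a), (name_b, ov_b) = sorted(arms.items())
    sims = simulate_population(
        _arm_config(ov_a, cfg["seed"]),
        _arm_config(ov_b, cfg["seed"]),
        cfg["n_cells_per_arm"],
        seed=cfg["seed"],
        conditions=(name_a, name_b),
    )
    return [
        {
            "cell_id": s.cell_id,
            "condition": s.condition,
            "table": s.table,
            "nucleus_mask": s.nucleus_mask,
            "cytoplasm_mask": s.cytoplasm_mask,
            "drifted": s.config.drift_model != "none",
        }
        for s in sims
    ]


# ---------------------------------------------------------------------------
# figures (presentation only; statistics come from stormquant.stats)


def make_figures(
    records: pd.DataFrame,
    domains: pd.DataFrame,
    out_dir: str | Path,
    metrics: tuple[str, ...] = ("mean_fwhm_nm", "mean_locs_per_domain"),
) -> list[Path]:
    """Per-cell comparison panels and the nuclear-vs-cytosolic scatter.

    Returns the list of written files; warns (and writes nothing) on empty
    input.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if records.empty:
        warnings.warn("make_figures: empty records, nothing to plot", stacklevel=2)
        return written
    conditions = sorted(records["condition"].unique())
    for metric in metrics:
        if metric not in records.columns:
            continue
        groups = [records.loc[records.condition == c, metric].dropna() for c in conditions]
        if any(g.empty for g in groups):
            warnings.warn(f"make_figures: no data for {metric}", stacklevel=2)
            continue
        fig, ax = plt.subplots(figsize=(4, 3.5))
        ax.boxplot([g.to_numpy() for g in groups], tick_labels=conditions, showmeans=True)
        for i, g in enumerate(groups, start=1):
            jitter = (np.arange(len(g)) % 7 - 3) * 0.02
            ax.plot(i + jitter, g, ".", alpha=0.5, ms=3)
        ax.set_ylabel(metric)
        fig.tight_layout()
        path = out / f"compare_{metric}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)

    sc = records[["mean_fwhm_nm", "n_cytosolic_clusters"]].dropna()
    sc = sc[records.loc[sc.index, "n_cytosolic_clusters"] > 0]
    if len(sc) >= 3 and sc["mean_fwhm_nm"].std() > 0 and sc["n_cytosolic_clusters"].std() > 0:
        res = pearson_r(sc["mean_fwhm_nm"], sc["n_cytosolic_clusters"])
        fig, ax = plt.subplots(figsize=(4, 3.5))
        ax.plot(sc["mean_fwhm_nm"], sc["n_cytosolic_clusters"], "o", alpha=0.6, ms=4)
        ax.set_xlabel("mean nuclear nanodomain FWHM (nm)")
        ax.set_ylabel("cytosolic nanocluster count")
        ax.annotate(f"Pearson r = {res.r:.2f}", xy=(0.05, 0.92), xycoords="axes fraction")
        fig.tight_layout()
        path = out / "scatter_nuclear_vs_cytosolic.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written


def plot_domain_overlay(image, domains: pd.DataFrame, path: str | Path) -> list[tuple]:
    """Rendered image with FWHM/2 circles over every detected domain.

    Returns the (x_nm, y_nm, radius_nm) triple actually drawn for each
    domain, in row order of ``domains`` — a parse-back hook for checking the
    overlay against the domains table.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    fig, ax = plt.subplots(figsize=(5, 5))
    h, w = image.data.shape
    extent = (
        image.origin_nm[0],
        image.origin_nm[0] + w * image.pixel_size_nm,
        image.origin_nm[1] + h * image.pixel_size_nm,
        image.origin_nm[1],
    )
    ax.imshow(np.sqrt(image.data), cmap="inferno", extent=extent)
    drawn = []
    for _, row in domains.iterrows():
        c = Circle(
            (row["x_nm"], row["y_nm"]), row["fwhm_nm"] / 2.0,
            fill=False, color="cyan", lw=0.8,
        )
        ax.add_patch(c)
        drawn.append((float(row["x_nm"]), float(row["y_nm"]), float(row["fwhm_nm"]) / 2.0))
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return drawn
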