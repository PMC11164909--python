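"""Nanodomain detection and metrology.

The detection chain mirrors standard SMLM cluster analysis of chromatin:
a rendered localization histogram is band-pass filtered with a difference of
Gaussians (DoG), local maxima inside the region mask seed a Gaussian mixture
model fitted to the localization *coordinates* (point data, not raster
intensities), and each surviving mixture component becomes one nanodomain
with a center, full covariance, localization count and a scalar size.

Size convention: FWHM = 2 sqrt(2 ln 2) * (lambda1 * lambda2)^(1/4), the
geometric mean of the two covariance eigen-axes, which preserves the area of
the anisotropic Gaussian.  Fitted covariances are optionally deconvolved for
localization precision (the observed spread of a domain is the true spread
convolved with the localization error) by subtracting the mean squared
precision from the eigenvalues before the FWHM reduction.

Nearest-neighbor distance (nnd) is measured between domain *boundaries*,
each domain modelled as a disc of radius FWHM/2; overlapping discs give 0.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import logsumexp
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from sklearn.base import BaseEstimator

from .io import Mask
from .render import RenderedImage, render

logger = logging.getLogger(__name__)

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass
class Nanodomain:
    """One fitted cluster of localizations."""

    center_nm: np.ndarray  # (2,)
    cov_nm2: np.ndarray  # (2, 2) symmetric positive-definite
    fwhm_nm: float
    n_locs: int
    region: str = "nucleus"
    cell_id: str = ""
    channel: str = "ch0"


@dataclass
class CellRecord:
    """Per-cell aggregate metrics; means are NaN when no domain qualifies."""

    cell_id: str
    condition: str
    n_nuclear_domains: int = 0
    mean_fwhm_nm: float = np.nan
    mean_locs_per_domain: float = np.nan
    mean_nnd_nm: float = np.nan
    n_cytosolic_clusters: int = 0
    mean_cyto_fwhm_nm: float = np.nan
    coloc_percent: float = np.nan
    marker_intensity: float = np.nan


def domains_to_frame(domains: list[Nanodomain]) -> pd.DataFrame:
    """Flatten domains to the documented stable table layout."""
    return pd.DataFrame(
        {
            "cell_id": [d.cell_id for d in domains],
            "channel": [d.channel for d in domains],
            "region": [d.region for d in domains],
            "x_nm": [d.center_nm[0] for d in domains],
            "y_nm": [d.center_nm[1] for d in domains],
            "fwhm_nm": [d.fwhm_nm for d in domains],
            "n_locs": [d.n_locs for d in domains],
            "cov_xx": [d.cov_nm2[0, 0] for d in domains],
            "cov_xy": [d.cov_nm2[0, 1] for d in domains],
            "cov_yy": [d.cov_nm2[1, 1] for d in domains],
        }
    )


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


# ---------------------------------------------------------------------------
# filtering and seeding


def dog_filter(image: RenderedImage, sigma1_nm: float, sigma2_nm: float) -> np.ndarray:
    """Difference-of-Gaussians band-pass, sigmas in nm, reflective borders.

    Both kernels are unit-normalized, so a constant image maps to zero.
    """
    if not (0 < sigma1_nm < sigma2_nm):
        raise ValueError("need 0 < sigma1 < sigma2")
    s1 = sigma1_nm / image.pixel_size_nm
    s2 = sigma2_nm / image.pixel_size_nm
    return ndimage.gaussian_filter(image.data, s1, mode="reflect") - ndimage.gaussian_filter(
        image.data, s2, mode="reflect"
    )


def mask_on_grid(mask: Mask, image: RenderedImage) -> np.ndarray:
    """Sample a mask (possibly at another pixel size) at the image's pixel
    centers."""
    h, w = image.data.shape
    xs = image.origin_nm[0] + (np.arange(w) + 0.5) * image.pixel_size_nm
    ys = image.origin_nm[1] + (np.arange(h) + 0.5) * image.pixel_size_nm
    X, Y = np.meshgrid(xs, ys)
    return mask.contains(X.ravel(), Y.ravel()).reshape(h, w)


def find_peaks(
    filtered: np.ndarray,
    image: RenderedImage,
    grid_mask: np.ndarray,
    min_distance_px: int = 3,
    threshold_k: float = 1.0,
    threshold_abs: float | None = None,
) -> np.ndarray:
    """Local maxima of the DoG raster inside the mask, as (x, y) nm seeds.

    The default threshold is mean + k*SD of the filtered values inside the
    mask.  Returns an (n, 2) array (possibly empty); peak_local_max orders
    candidates by decreasing value, which fixes tie-breaking.
    """
    if not grid_mask.any():
        raise ValueError("empty region: peak search mask has no foreground")
    if threshold_abs is None:
        vals = filtered[grid_mask]
        threshold_abs = float(vals.mean() + threshold_k * vals.std())
    coords = peak_local_max(
        filtered,
        min_distance=min_distance_px,
        threshold_abs=threshold_abs,
        labels=grid_mask.astype(np.int32),
        exclude_border=False,
    )
    if len(coords) == 0:
        return np.empty((0, 2))
    px = image.pixel_size_nm
    x = image.origin_nm[0] + (coords[:, 1] + 0.5) * px
    y = image.origin_nm[1] + (coords[:, 0] + 0.5) * px
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# Gaussian mixture on localization coordinates


@dataclass
class GmmComponent:
    mean: np.ndarray
    cov: np.ndarray
    n_locs: int
    indices: np.ndarray  # indices into the fitted X of hard-assigned rows


def _floor_cov(cov: np.ndarray, floor: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X - mean
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
    inv = np.array([[cov[1, 1], -cov[0, 1]], [-cov[0, 1], cov[0, 0]]]) / det
    maha = inv[0, 0] * d[:, 0] ** 2 + 2 * inv[0, 1] * d[:, 0] * d[:, 1] + inv[1, 1] * d[:, 1] ** 2
    return -0.5 * (maha + np.log((2 * np.pi) ** 2 * det))


def fit_gmm(
    X: np.ndarray,
    seeds: np.ndarray,
    min_locs: int = 10,
    max_iter: int = 200,
    tol: float = 1e-6,
    covariance_floor_nm2: float = 1.0,
    background: bool = False,
    region_area_nm2: float | None = None,
) -> list[GmmComponent]:
    """EM fit of a Gaussian mixture to localization coordinates.

    One full-covariance component per seed (means initialized at the seeds),
    plus an optional uniform background component over ``region_area_nm2``.
    Covariance eigenvalues are floored at ``covariance_floor_nm2`` (set it to
    the squared localization precision).  After convergence each localization
    is hard-assigned to its maximal-responsibility component; components with
    fewer than ``min_locs`` assigned localizations are dropped.
    """
    X = np.asarray(X, dtype=float).reshape(-1, 2)
    seeds = np.asarray(seeds, dtype=float).reshape(-1, 2)
    K = len(seeds)
    if K == 0:
        raise ValueError("need at least one seed")
    if background and not region_area_nm2:
        raise ValueError("background component requires region_area_nm2")
    n = len(X)
    if n == 0:
        return []

    # init: nearest-seed partition
    d2 = ((X[:, None, :] - seeds[None, :, :]) ** 2).sum(-1)
    assign0 = np.argmin(d2, axis=1)
    means = seeds.copy()
    covs = np.empty((K, 2, 2))
    for k in range(K):
        pts = X[assign0 == k]
        if len(pts) >= 3:
            covs[k] = _floor_cov(np.cov(pts.T, bias=True), covariance_floor_nm2)
        else:
            covs[k] = np.eye(2) * max(covariance_floor_nm2, 100.0)
    weights = np.bincount(assign0, minlength=K).astype(float)
    if background:
        weights = np.append(weights * 0.95, 0.05 * weights.sum())
    weights = weights / weights.sum()
    log_bg = -np.log(region_area_nm2) if background else None

    alive = np.ones(K, dtype=bool)
    ll_prev = -np.inf
    for _ in range(max_iter):
        comps = np.flatnonzero(alive)
        logp = np.full((n, len(comps) + (1 if background else 0)), -np.inf)
        for j, k in enumerate(comps):
            logp[:, j] = np.log(max(weights[j], 1e-300)) + _log_gauss(X, means[k], covs[k])
        if background:
            logp[:, -1] = np.log(max(weights[-1], 1e-300)) + log_bg
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        resp = np.exp(logp - norm[:, None])
        # M-step
        Nk = resp.sum(axis=0)
        new_alive = alive.copy()
        for j, k in enumerate(comps):
            if Nk[j] < 1e-6:
                new_alive[k] = False
                continue
            mu = resp[:, j] @ X / Nk[j]
            d = X - mu
            cov = (resp[:, j, None] * d).T @ d / Nk[j]
            cov = _floor_cov(0.5 * (cov + cov.T), covariance_floor_nm2)
            if not np.all(np.isfinite(cov)):
                logger.info("dropping singular mixture component %d", k)
                new_alive[k] = False
                continue
            means[k] = mu
            covs[k] = cov
        if new_alive.sum() == 0:
            return []
        if not np.array_equal(new_alive, alive):
            alive = new_alive
            comps = np.flatnonzero(alive)
            weights = np.append(
                np.ones(len(comps)) / (len(comps) + (1 if background else 0)),
                [1.0 / (len(comps) + 1)] if background else [],
            )
            ll_prev = -np.inf
            continue
        weights = Nk / Nk.sum()
        if abs(ll - ll_prev) < tol * max(1.0, abs(ll)):
            break
        ll_prev = ll

    comps = np.flatnonzero(alive)
    hard = np.argmax(logp, axis=1)
    out: list[GmmComponent] = []
    for j, k in enumerate(comps):
        idx = np.flatnonzero(hard == j)
        if len(idx) < min_locs:
            continue
        out.append(GmmComponent(means[k].copy(), covs[k].copy(), len(idx), idx))
    return out


# ---------------------------------------------------------------------------
# metrology


def fwhm_from_cov(cov: np.ndarray) -> float:
    """Scalar FWHM of an anisotropic Gaussian: geometric-mean axis convention,
    2 sqrt(2 ln 2) (lambda1 lambda2)^(1/4).  Rotation-invariant."""
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2) or not np.allclose(cov, cov.T, atol=1e-9 * max(1.0, abs(cov).max())):
        raise ValueError("covariance must be a symmetric 2x2 matrix")
    vals = np.linalg.eigvalsh(cov)
    if vals.min() <= 0:
        raise ValueError("covariance must be positive-definite")
    return float(FWHM_FACTOR * (vals[0] * vals[1]) ** 0.25)


def nearest_neighbor_distances(domains: list[Nanodomain]) -> np.ndarray:
    """Boundary-to-boundary nearest-neighbor distance per domain.

    For domain i: min over j != i of max(0, ||c_i - c_j|| - fwhm_i/2 -
    fwhm_j/2), the gap between FWHM/2 discs (0 when overlapping).
    """
    if len(domains) < 2:
        warnings.warn("nearest_neighbor_distances needs >= 2 domains", stacklevel=2)
        return np.empty(0)
    centers = np.array([d.center_nm for d in domains], dtype=float)
    radii = np.array([d.fwhm_nm for d in domains], dtype=float) / 2.0
    diff = centers[:, None, :] - centers[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    gap = np.maximum(0.0, dist - radii[:, None] - radii[None, :])
    np.fill_diagonal(gap, np.inf)
    return gap.min(axis=1)


# ---------------------------------------------------------------------------
# orchestration


class NanodomainDetector(BaseEstimator):
    """Clustering-style estimator: render -> DoG -> peak seeding -> per-region
    Gaussian mixture -> nanodomains.

    Fit regions are connected components of the thresholded DoG raster
    (dilated to capture Gaussian tails), which keeps each mixture small and
    the fit stable.  Nucleus and cytoplasm masks are processed independently;
    cytoplasm uses its own expected size scale (cytosolic nanoclusters are
    ~30-50 nm versus ~50-100 nm chromatin nanodomains).

    Parameters
    ----------
    pixel_size_nm : float
        Rendering pixel (default 10 nm, common SMLM convention).
    expected_fwhm_nm, cyto_expected_fwhm_nm : float
        Size prior per region; sets the DoG scales
        sigma1 = fwhm / (2 sqrt(2 ln 2)) / sqrt(2), sigma2 = ratio * sigma1.
    sigma_ratio : float
        DoG scale ratio (default 1.6).
    peak_threshold_k : float
        Peak threshold = mean + k*SD of DoG values inside the mask.
    region_threshold_k : float
        Same policy for the binary fit-region raster.
    min_locs : int
        Noise filter: components with fewer assigned localizations dropped.
    background_component : bool
        Add a uniform background component to each mixture.
    deconvolve_precision : bool
        Subtract mean(precision^2) from covariance eigenvalues before FWHM.

    Attributes
    ----------
    domains_ : list of Nanodomain
    labels_ : (n_rows,) int array, index into ``domains_`` or -1
    """

    def __init__(
        self,
        pixel_size_nm: float = 10.0,
        expected_fwhm_nm: float = 80.0,
        cyto_expected_fwhm_nm: float = 40.0,
        sigma_ratio: float = 1.6,
        peak_threshold_k: float = 1.0,
        region_threshold_k: float = 0.5,
        min_distance_px: int | None = None,
        min_locs: int = 10,
        max_iter: int = 200,
        tol: float = 1e-6,
        background_component: bool = False,
        deconvolve_precision: bool = True,
        dilation_sigma_mult: float = 3.0,
        cell_id: str = "",
    ):
        self.pixel_size_nm = pixel_size_nm
        self.expected_fwhm_nm = expected_fwhm_nm
        self.cyto_expected_fwhm_nm = cyto_expected_fwhm_nm
        self.sigma_ratio = sigma_ratio
        self.peak_threshold_k = peak_threshold_k
        self.region_threshold_k = region_threshold_k
        self.min_distance_px = min_distance_px
        self.min_locs = min_locs
        self.max_iter = max_iter
        self.tol = tol
        self.background_component = background_component
        self.deconvolve_precision = deconvolve_precision
        self.dilation_sigma_mult = dilation_sigma_mult
        self.cell_id = cell_id

    # -- internals ---------------------------------------------------------

    def _region_expected_fwhm(self, label: str) -> float:
        return self.cyto_expected_fwhm_nm if label == "cytoplasm" else self.expected_fwhm_nm

    def _detect_region(self, table: pd.DataFrame, mask: Mask, channel: str):
        sel = mask.contains(table["x_nm"].to_numpy(float), table["y_nm"].to_numpy(float))
        if "source_flag" in table.columns:
            sel &= table["source_flag"].to_numpy() != "fiducial"
        sub = table.loc[sel]
        found: list[tuple[Nanodomain, np.ndarray]] = []
        if len(sub) == 0:
            return found
        # render only the mask's foreground bounding box (plus margin)
        fg_rows = np.flatnonzero(mask.data.any(axis=1))
        fg_cols = np.flatnonzero(mask.data.any(axis=0))
        mpx = mask.pixel_size_nm
        margin = 2 * self.pixel_size_nm
        x0 = mask.origin_nm[0] + fg_cols[0] * mpx - margin
        y0 = mask.origin_nm[1] + fg_rows[0] * mpx - margin
        w_nm = (fg_cols[-1] + 1 - fg_cols[0]) * mpx + 2 * margin
        h_nm = (fg_rows[-1] + 1 - fg_rows[0]) * mpx + 2 * margin
        shape = (
            int(np.ceil(h_nm / self.pixel_size_nm)),
            int(np.ceil(w_nm / self.pixel_size_nm)),
        )
        img = render(sub, self.pixel_size_nm, "histogram", origin_nm=(x0, y0), shape=shape)
        expected = self._region_expected_fwhm(mask.label)
        sigma1_nm = expected / FWHM_FACTOR / np.sqrt(2.0)
        filt = dog_filter(img, sigma1_nm, self.sigma_ratio * sigma1_nm)
        grid = mask_on_grid(mask, img)
        if not grid.any():
            return found
        min_dist = self.min_distance_px
        if min_dist is None:
            # one expected FWHM: seeds closer than a domain width are splits
            min_dist = max(2, int(round(expected / self.pixel_size_nm)))
        seeds = find_peaks(filt, img, grid, min_dist, self.peak_threshold_k)
        if len(seeds) == 0:
            return found

        vals = filt[grid]
        thr = float(vals.mean() + self.region_threshold_k * vals.std())
        s1_px = sigma1_nm / self.pixel_size_nm
        rad = max(1, int(np.ceil(self.dilation_sigma_mult * s1_px)))
        core = (filt >= thr) & grid
        binary = ndimage.distance_transform_edt(~core) <= rad  # disc dilation
        labels = cc_label(binary)

        px = self.pixel_size_nm
        seed_cols = np.floor((seeds[:, 0] - img.origin_nm[0]) / px).astype(int)
        seed_rows = np.floor((seeds[:, 1] - img.origin_nm[1]) / px).astype(int)
        seed_lab = labels[seed_rows, seed_cols]

        x = sub["x_nm"].to_numpy(float)
        y = sub["y_nm"].to_numpy(float)
        col = np.floor((x - img.origin_nm[0]) / px).astype(int)
        row = np.floor((y - img.origin_nm[1]) / px).astype(int)
        h, w = labels.shape
        infield = (col >= 0) & (col < w) & (row >= 0) & (row < h)
        loc_lab = np.zeros(len(sub), dtype=int)
        loc_lab[infield] = labels[row[infield], col[infield]]

        prec = sub["precision_nm"].to_numpy(float)
        orig_idx = sub.index.to_numpy()
        for lab in np.unique(seed_lab):
            if lab == 0:
                continue
            in_region = loc_lab == lab
            if in_region.sum() < self.min_locs:
                continue
            X = np.column_stack([x[in_region], y[in_region]])
            region_seeds = seeds[seed_lab == lab]
            mean_prec2 = float(np.mean(prec[in_region] ** 2))
            floor = max(1.0, mean_prec2)
            area = float((labels == lab).sum()) * px**2
            comps = fit_gmm(
                X,
                region_seeds,
                min_locs=self.min_locs,
                max_iter=self.max_iter,
                tol=self.tol,
                covariance_floor_nm2=floor,
                background=self.background_component,
                region_area_nm2=area if self.background_component else None,
            )
            for comp in comps:
                cov = comp.cov
                if self.deconvolve_precision:
                    vals_, vecs_ = np.linalg.eigh(cov)
                    vals_ = np.maximum(vals_ - mean_prec2, 1.0)
                    cov = (vecs_ * vals_) @ vecs_.T
                dom = Nanodomain(
                    center_nm=comp.mean,
                    cov_nm2=cov,
                    fwhm_nm=fwhm_from_cov(cov),
                    n_locs=comp.n_locs,
                    region=mask.label,
                    cell_id=self.cell_id,
                    channel=channel,
                )
                found.append((dom, orig_idx[np.flatnonzero(in_region)[comp.indices]]))
        return found

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X: pd.DataFrame, masks: list[Mask] | Mask | None = None) -> "NanodomainDetector":
        """Detect nanodomains in localization table ``X`` within ``masks``.

        Each mask region (nucleus, cytoplasm, ...) is processed independently;
        each channel in the table is processed separately.
        """
        if masks is None:
            raise ValueError("at least one region mask is required")
        if isinstance(masks, Mask):
            masks = [masks]
        for m in masks:
            if m.label in ("nucleus",):
                m.require_nonempty()
        self.domains_ = []
        self.labels_ = np.full(len(X), -1, dtype=np.int64)
        pos_of = pd.Series(np.arange(len(X)), index=X.index)
        for channel, chan_table in X.groupby("channel", sort=True):
            for mask in masks:
                if mask.n_foreground == 0:
                    continue
                for dom, rows in self._detect_region(chan_table, mask, str(channel)):
                    self.labels_[pos_of[rows].to_numpy()] = len(self.domains_)
                    self.domains_.append(dom)
        return self

    def fit_predict(self, X: pd.DataFrame, masks=None) -> np.ndarray:
        return self.fit(X, masks).labels_


def detect_nanodomains(
    table: pd.DataFrame, masks: list[Mask] | Mask, **params
) -> list[Nanodomain]:
    """Functional wrapper around :class:`NanodomainDetector`."""
    return NanodomainDetector(**params).fit(table, masks).domains_


def summarize_cell(
    domains: list[Nanodomain],
    cell_id: str = "",
    condition: str = "",
    marker_intensity: float = np.nan,
) -> CellRecord:
    """Aggregate detected domains into per-cell metrics.

    Nuclear metrics are means over nucleus-region domains; the cytosolic
    nanocluster count is the number of cytoplasm-region domains.  Means are
    NaN when the corresponding region has no domain.
    """
    nuc = [d for d in domains if d.region == "nucleus"]
    cyto = [d for d in domains if d.region == "cytoplasm"]
    nnd = nearest_neighbor_distances(nuc) if len(nuc) >= 2 else np.empty(0)
    return CellRecord(
        cell_id=cell_id,
        condition=condition,
        n_nuclear_domains=len(nuc),
        mean_fwhm_nm=float(np.mean([d.fwhm_nm for d in nuc])) if nuc else np.nan,
        mean_locs_per_domain=float(np.mean([d.n_locs for d in nuc])) if nuc else np.nan,
        mean_nnd_nm=float(nnd.mean()) if nnd.size else np.nan,
        n_cytosolic_clusters=len(cyto),
        mean_cyto_fwhm_nm=float(np.mean([d.fwhm_nm for d in cyto])) if cyto else np.nan,
        marker_intensity=marker_intensity,
    )
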