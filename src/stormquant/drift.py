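"""Fiducial-based stage-drift estimation and correction.

Bright fluorescent beads deposited on the coverslip are present in (nearly)
every acquisition frame, unlike blinking sample emitters.  Their apparent
motion is the stage drift.  The estimator here follows the windowed scheme
used in STORM practice: positions of each fiducial track are averaged in
fixed windows of 200 frames (4 s at 20 ms exposure), displacements are taken
relative to each track's first-window mean, averaged across tracks, assigned
to window centers and linearly interpolated to per-frame values (constant
extrapolation at the ends).  The trace is anchored so that frame 0 has zero
displacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


@dataclass
class DriftTrace:
    """Per-frame stage displacement (dx, dy) in nm, anchored at frame 0."""

    dxy: np.ndarray  # (n_frames, 2) float
    window: int | None = None

    def __post_init__(self) -> None:
        self.dxy = np.asarray(self.dxy, dtype=float)
        if self.dxy.ndim != 2 or self.dxy.shape[1] != 2:
            raise ValueError("drift trace must be (n_frames, 2)")

    def __len__(self) -> int:
        return self.dxy.shape[0]

    def at(self, frames: np.ndarray) -> np.ndarray:
        frames = np.asarray(frames, dtype=np.int64)
        if frames.size and (frames.min() < 0 or frames.max() >= len(self)):
            raise ValueError(
                f"frame index out of drift-trace range [0, {len(self)})"
            )
        return self.dxy[frames]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self)), "dx_nm": self.dxy[:, 0], "dy_nm": self.dxy[:, 1]}
        )


@dataclass
class FiducialTrack:
    """One linked bead track: per-frame observed positions with NaN gaps."""

    track_id: int
    positions: np.ndarray  # (n_frames, 2), NaN where absent
    presence: float

    @property
    def mean_position(self) -> np.ndarray:
        return np.nanmean(self.positions, axis=0)


def detect_fiducials(
    table: pd.DataFrame,
    min_presence: float = 0.9,
    photon_quantile: float = 0.99,
    link_radius_nm: float = 500.0,
    n_frames: int | None = None,
) -> list[FiducialTrack]:
    """Find persistent bright emitters (beads) in a localization table.

    Candidate rows are those whose photon count exceeds the
    ``photon_quantile`` quantile of all rows.  Candidates are linked across
    frames to the nearest existing track whose running-mean position is
    within ``link_radius_nm``; unmatched candidates seed new tracks.  Tracks
    present in at least ``min_presence`` of the frame range are returned.

    Raises ``ValueError`` when no track qualifies — supply an external trace
    or explicit bead positions in that case.
    """
    frames = table["frame"].to_numpy(np.int64)
    if n_frames is None:
        n_frames = int(frames.max()) + 1 if len(frames) else 0
    if n_frames < 2:
        raise ValueError("need at least 2 frames to detect fiducials")
    cutoff = float(np.quantile(table["photons"].to_numpy(float), photon_quantile))
    cand = table[table["photons"].to_numpy(float) >= cutoff]
    order = np.argsort(cand["frame"].to_numpy(np.int64), kind="stable")
    cx = cand["x_nm"].to_numpy(float)[order]
    cy = cand["y_nm"].to_numpy(float)[order]
    cf = cand["frame"].to_numpy(np.int64)[order]

    means: list[np.ndarray] = []  # running means
    counts: list[int] = []
    members: list[list[tuple[int, float, float]]] = []
    for x, y, f in zip(cx, cy, cf):
        if means:
            m = np.asarray(means)
            d2 = (m[:, 0] - x) ** 2 + (m[:, 1] - y) ** 2
            j = int(np.argmin(d2))
            if d2[j] <= link_radius_nm**2:
                k = counts[j]
                means[j] = (means[j] * k + np.array([x, y])) / (k + 1)
                counts[j] = k + 1
                members[j].append((f, x, y))
                continue
        means.append(np.array([x, y], dtype=float))
        counts.append(1)
        members.append([(f, x, y)])

    tracks: list[FiducialTrack] = []
    for tid, rows in enumerate(members):
        fr = np.array([r[0] for r in rows])
        present = len(np.unique(fr)) / n_frames
        if present < min_presence:
            continue
        pos = np.full((n_frames, 2), np.nan)
        pos[fr, 0] = [r[1] for r in rows]
        pos[fr, 1] = [r[2] for r in rows]
        tracks.append(FiducialTrack(tid, pos, present))
    if not tracks:
        raise ValueError(
            "no fiducial track found; supply a drift trace or bead positions"
        )
    logger.info("detected %d fiducial track(s)", len(tracks))
    return tracks


def estimate_drift(
    tracks: list[FiducialTrack],
    window: int = 200,
    statistic: str = "mean",
) -> DriftTrace:
    """Windowed drift estimate from fiducial tracks.

    Within each window of ``window`` frames the chosen statistic (mean, or
    median for blink-contaminated tracks) of each track's positions is taken;
    displacements relative to the track's first-window statistic are averaged
    across tracks (unweighted), placed at window centers and linearly
    interpolated to every frame.
    """
    if not tracks:
        raise ValueError("need at least one fiducial track")
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown window statistic {statistic!r}")
    n_frames = tracks[0].positions.shape[0]
    if window > n_frames:
        logger.warning(
            "window (%d) exceeds n_frames (%d); falling back to a single window",
            window,
            n_frames,
        )
        window = n_frames
    n_windows = int(np.ceil(n_frames / window))
    stat = np.nanmean if statistic == "mean" else np.nanmedian

    per_track = np.full((len(tracks), n_windows, 2), np.nan)
    for i, tr in enumerate(tracks):
        for w in range(n_windows):
            chunk = tr.positions[w * window : (w + 1) * window]
            if np.isfinite(chunk[:, 0]).any():
                per_track[i, w] = stat(chunk, axis=0)
        per_track[i] -= per_track[i, 0]
    with np.errstate(invalid="ignore"):
        disp = np.nanmean(per_track, axis=0)  # (n_windows, 2)
    # window centers in frame coordinates (last window may be short)
    centers = np.array(
        [(w * window + min((w + 1) * window, n_frames) - 1) / 2.0 for w in range(n_windows)]
    )
    frames = np.arange(n_frames, dtype=float)
    ok = np.isfinite(disp[:, 0])
    ctr, val = centers[ok], disp[ok]
    dxy = np.column_stack([np.interp(frames, ctr, val[:, c]) for c in (0, 1)])
    if len(ctr) >= 2:
        # linear extrapolation beyond the first/last window centers, so the
        # anchored trace tracks a steady drift without a half-window offset
        head = frames < ctr[0]
        tail = frames > ctr[-1]
        slope0 = (val[1] - val[0]) / (ctr[1] - ctr[0])
        slope1 = (val[-1] - val[-2]) / (ctr[-1] - ctr[-2])
        dxy[head] = val[0] + (frames[head, None] - ctr[0]) * slope0
        dxy[tail] = val[-1] + (frames[tail, None] - ctr[-1]) * slope1
    dxy -= dxy[0]
    return DriftTrace(dxy, window=window)


def correct_drift(table: pd.DataFrame, trace: DriftTrace) -> pd.DataFrame:
    """Subtract the per-frame drift from every localization; exact inverse of
    :func:`stormquant.simulate.apply_drift` for the true trace."""
    shift = trace.at(table["frame"].to_numpy(np.int64))
    out = table.copy()
    out["x_nm"] = out["x_nm"].to_numpy(float) - shift[:, 0]
    out["y_nm"] = out["y_nm"].to_numpy(float) - shift[:, 1]
    return out


class DriftCorrector(BaseEstimator, TransformerMixin):
    """Estimator-style drift correction: fit detects fiducials and estimates
    the trace; transform subtracts it.

    Parameters
    ----------
    window : int
        Frames per estimation window (default 200, i.e. 4 s at 20 ms).
    min_presence, photon_quantile, link_radius_nm
        Fiducial-detection thresholds (see :func:`detect_fiducials`).
    statistic : {"mean", "median"}
        Within-window position statistic.

    Attributes
    ----------
    tracks_ : list of FiducialTrack
    trace_ : DriftTrace
    n_frames_ : int
    """

    def __init__(
        self,
        window: int = 200,
        min_presence: float = 0.9,
        photon_quantile: float = 0.99,
        link_radius_nm: float = 500.0,
        statistic: str = "mean",
    ):
        self.window = window
        self.min_presence = min_presence
        self.photon_quantile = photon_quantile
        self.link_radius_nm = link_radius_nm
        self.statistic = statistic

    def fit(self, X: pd.DataFrame, y=None) -> "DriftCorrector":
        self.n_frames_ = int(X["frame"].max()) + 1
        self.tracks_ = detect_fiducials(
            X,
            min_presence=self.min_presence,
            photon_quantile=self.photon_quantile,
            link_radius_nm=self.link_radius_nm,
            n_frames=self.n_frames_,
        )
        self.trace_ = estimate_drift(self.tracks_, window=self.window, statistic=self.statistic)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "trace_"):
            raise RuntimeError("DriftCorrector must be fitted before transform")
        return correct_drift(X, self.trace_)
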