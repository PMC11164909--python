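"""Two-channel degree of colocalization between nanodomain sets.

A domain from channel A counts as colocalized when the gap between its
FWHM/2 disc and the nearest channel-B disc is at most ``gap_tolerance_nm``
(touching or overlapping discs at the default tolerance 0).  The reported
percentage is over channel A, so call with A = the protein channel and B =
the DNA channel to get "protein in DNA" colocalization.  The metric is a
domain-level contact criterion (not pixel-overlap Manders nor CBC) and sits
behind this single function so it can be swapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .domains import Nanodomain


@dataclass
class ColocResult:
    percent_coloc: float  # 0-100, NaN when A is empty
    direction: str = "A-in-B"
    flags: np.ndarray | None = None  # per-A-domain colocalization flags


def coloc_degree(
    domains_a: list[Nanodomain],
    domains_b: list[Nanodomain],
    gap_tolerance_nm: float = 0.0,
) -> ColocResult:
    """Fraction (as a percentage) of A-domains touching a B-domain.

    Empty A is undefined (NaN, flagged); empty B gives 0%.
    ``coloc_degree(A, A)`` is exactly 100.
    """
    if len(domains_a) == 0:
        return ColocResult(np.nan, flags=np.empty(0, dtype=bool))
    if len(domains_b) == 0:
        return ColocResult(0.0, flags=np.zeros(len(domains_a), dtype=bool))
    ca = np.array([d.center_nm for d in domains_a], dtype=float)
    cb = np.array([d.center_nm for d in domains_b], dtype=float)
    ra = np.array([d.fwhm_nm for d in domains_a], dtype=float) / 2.0
    rb = np.array([d.fwhm_nm for d in domains_b], dtype=float) / 2.0
    dist = np.sqrt(((ca[:, None, :] - cb[None, :, :]) ** 2).sum(-1))
    gap = dist - ra[:, None] - rb[None, :]
    flags = gap.min(axis=1) <= gap_tolerance_nm
    return ColocResult(100.0 * float(flags.mean()), flags=flags)
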