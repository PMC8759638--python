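"""Relating short-fragment peaks to domains: border classification, heatmap
matrices and midpoint-vs-length (V-plot) matrices.

A regulatory element sitting at the edge of a repressive domain sees
asymmetric nucleosomal coverage: high on the domain side, low outside.  The
flank log2-ratio captures that asymmetry, the classifier assigns each peak a
border/internal/outside label against a segmented domain list, and the two
matrix builders reproduce the standard displays: per-peak coverage heatmaps
around summits, and the 2D histogram of fragment midpoint offset versus
fragment length whose "V" separates TF footprints from flanking nucleosomes.

5' and 3' are genome-coordinate orientations (lower/higher coordinate), not
transcript strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fragio import AnalysisConfig, CoverageTrack, Fragment
from .domains import Domain
from .peaks import Peak

__all__ = [
    "PeakClassification",
    "ProfileMatrix",
    "VPlotMatrix",
    "flank_ratio",
    "classify_peaks",
    "profile_matrix",
    "vplot",
    "BORDER_SLACK_BP",
]

BORDER_SLACK_BP = 500


def chrom_end(track: CoverageTrack, chrom: str) -> int:
    return len(track.values[chrom]) * track.bin_size

LABELS = ("five_prime_border", "three_prime_border", "internal", "outside")


@dataclass(frozen=True)
class PeakClassification:
    peak: Peak
    label: str
    flank_log2_ratio: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class ProfileMatrix:
    """Per-peak coverage rows over position bins around summits."""

    matrix: np.ndarray  # peaks x bins
    positions: np.ndarray  # bin-center offsets from summit
    order: np.ndarray  # row -> index into the input peak list
    ratios: np.ndarray  # flank_log2_ratio per row

    @property
    def column_means(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


@dataclass
class VPlotMatrix:
    """2D histogram: x = midpoint - summit (10bp bins), y = length (5bp bins)."""

    counts: np.ndarray  # y-bins x x-bins
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def mass(self, x_range: tuple[float, float], y_range: tuple[float, float]) -> int:
        """Total count with x-bin center in x_range and y-bin center in y_range."""
        xc = (self.x_edges[:-1] + self.x_edges[1:]) / 2
        yc = (self.y_edges[:-1] + self.y_edges[1:]) / 2
        xm = (xc >= x_range[0]) & (xc <= x_range[1])
        ym = (yc >= y_range[0]) & (yc <= y_range[1])
        return int(self.counts[np.ix_(ym, xm)].sum())


def flank_ratio(peak: Peak, track: CoverageTrack, flank_bp: int) -> float:
    """log2((3' flank sum + 1) / (5' flank sum + 1)) of track values around the summit.

    The 3' flank is (summit, summit + flank_bp], the 5' flank
    [summit - flank_bp, summit); sums are per-base track values (a fully
    covered bin contributes value x bin_size).
    """
    chrom_len = len(track.values[peak.chrom]) * track.bin_size
    if peak.summit - flank_bp < 0 or peak.summit + flank_bp + 1 > chrom_len:
        raise ValueError(
            f"flank of {flank_bp}bp around summit {peak.summit} exceeds "
            f"chromosome bounds"
        )
    three = track.region_sum(peak.chrom, peak.summit + 1, peak.summit + flank_bp + 1)
    five = track.region_sum(peak.chrom, peak.summit - flank_bp, peak.summit)
    return float(np.log2((three + 1.0) / (five + 1.0)))


def classify_peaks(
    peaks: Sequence[Peak],
    domains: Sequence[Domain],
    border_slack_bp: int = BORDER_SLACK_BP,
    track: CoverageTrack | None = None,
    flank_bp: int = 1000,
) -> list[PeakClassification]:
    """Label each peak five_prime_border / three_prime_border / internal / outside.

    A summit within ``border_slack_bp`` of a domain's lower edge (either side
    of it) is a 5' border; within slack of the upper edge, a 3' border; the
    lower edge wins when a very narrow domain puts a summit within slack of
    both.  Strictly inside beyond the slack is internal; anything else is
    outside.  Domains must be disjoint and sorted.  When ``track`` is given
    the flank log2-ratio is computed (0.0 otherwise).
    """
    doms = sorted(domains, key=lambda d: (d.chrom, d.start))
    for a, b in zip(doms, doms[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"overlapping domains at {a.chrom}:{b.start}")

    out: list[PeakClassification] = []
    for p in peaks:
        label = "outside"
        for d in doms:
            if d.chrom != p.chrom:
                continue
            near_lo = abs(p.summit - d.start) <= border_slack_bp
            near_hi = abs(p.summit - d.end) <= border_slack_bp
            if near_lo:  # lower edge wins ties
                label = "five_prime_border"
                break
            if near_hi:
                label = "three_prime_border"
                break
            if d.start < p.summit < d.end:
                label = "internal"
                break
        ratio = 0.0
        if track is not None:
            ratio = flank_ratio(p, track, flank_bp)
        out.append(PeakClassification(p, label, ratio))
    return out


def profile_matrix(
    peaks: Sequence[Peak],
    track: CoverageTrack,
    cfg: AnalysisConfig,
    sort_by: str = "flank_ratio",
) -> ProfileMatrix:
    """Coverage heatmap matrix at +/- cfg.flank_bp around each summit.

    Columns are track-resolution bins (2 * flank_bp / bin_size of them); cell
    values are mean per-base track values in the column window.  With
    ``sort_by="flank_ratio"`` rows are ordered by descending 3'/5' ratio.
    """
    if len(peaks) == 0:
        raise ValueError("profile matrix needs >= 1 peak")
    if sort_by not in ("flank_ratio", "none"):
        raise ValueError(f"unknown sort_by {sort_by!r}")
    b = track.bin_size
    flank = cfg.flank_bp
    ncols = 2 * flank // b
    rows = np.empty((len(peaks), ncols))
    ratios = np.empty(len(peaks))
    for k, p in enumerate(peaks):
        per_base = track.per_base(p.chrom, p.summit - flank, p.summit + flank)
        rows[k] = per_base.reshape(ncols, b).mean(axis=1)
        # clipped flank sums so edge-of-chromosome peaks stay usable here
        three = track.region_sum(
            p.chrom, p.summit + 1, min(p.summit + flank + 1, chrom_end(track, p.chrom))
        )
        five = track.region_sum(p.chrom, max(p.summit - flank, 0), p.summit)
        ratios[k] = float(np.log2((three + 1.0) / (five + 1.0)))
    order = np.arange(len(peaks))
    if sort_by == "flank_ratio":
        order = np.argsort(-ratios, kind="stable")
    positions = np.arange(-flank, flank, b) + b / 2
    return ProfileMatrix(
        matrix=rows[order], positions=positions, order=order, ratios=ratios[order]
    )


def vplot(
    frags: Sequence[Fragment],
    summits: Sequence[int],
    cfg: AnalysisConfig,
    x_bin_bp: int = 10,
    y_bin_bp: int = 5,
    max_length: int = 300,
) -> VPlotMatrix:
    """Midpoint-vs-length 2D histogram around the nearest summit.

    A fragment contributes one count at (midpoint - nearest summit, length)
    when |midpoint - nearest summit| <= cfg.flank_bp.  Even-length fragment
    midpoints are start + length // 2.
    """
    flank = cfg.flank_bp
    x_edges = np.arange(-flank, flank + x_bin_bp, x_bin_bp, dtype=float)
    y_edges = np.arange(0, max_length + y_bin_bp, y_bin_bp, dtype=float)
    counts = np.zeros((len(y_edges) - 1, len(x_edges) - 1))
    if len(summits) == 0 or len(frags) == 0:
        return VPlotMatrix(counts, x_edges, y_edges)

    s = np.sort(np.asarray(summits))
    mids = np.array([f.midpoint for f in frags])
    lens = np.array([f.length for f in frags])
    idx = np.clip(np.searchsorted(s, mids), 0, len(s) - 1)
    left = np.clip(idx - 1, 0, len(s) - 1)
    nearest = np.where(
        np.abs(mids - s[left]) <= np.abs(mids - s[idx]), s[left], s[idx]
    )
    dx = mids - nearest
    keep = (np.abs(dx) <= flank) & (lens <= max_length)
    h, _, _ = np.histogram2d(
        lens[keep].astype(float), dx[keep].astype(float), bins=(y_edges, x_edges)
    )
    counts += h
    return VPlotMatrix(counts, x_edges, y_edges)
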