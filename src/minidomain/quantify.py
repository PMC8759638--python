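"""Region-level quantification, condition contrasts, meta-domain profiles and
Cut&Run-qPCR fold enrichment.

Knockdown effects are read out as percent change of normalized in-region
fragment counts against a designated control sample.  Counting is
midpoint-in-region (additive across adjacent regions) and normalization is
per million fragments, applied after libraries have been downsampled to a
common depth by the caller when that is the chosen strategy.  The
meta-domain profile rescales every domain body to 100 bins and keeps the
flanks at native 100bp resolution, so domains of very different widths
average coherently.  qPCR fold enrichment applies the double normalization
used for antibody-targeted MNase assays: relative to a whole-MNase control
digestion and relative to a reference locus depleted in the targeted marks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fragio import AnalysisConfig, CoverageTrack, Fragment
from .domains import Domain

__all__ = [
    "Region",
    "RegionQuant",
    "MetaDomainProfile",
    "QPCRTable",
    "quantify_regions",
    "meta_domain_profile",
    "qpcr_fold_enrichment",
]

META_BODY_BINS = 100
META_FLANK_BIN_BP = 100


@dataclass(frozen=True)
class Region:
    """A named interval (primer target, domain span, border element...)."""

    name: str
    chrom: str
    start: int
    end: int


@dataclass
class RegionQuant:
    """Normalized per-sample counts in one region plus percent change vs control."""

    region: Region
    counts: dict[str, float]  # sample -> per-million normalized midpoint count
    raw_counts: dict[str, int]
    control: str
    percent_change: dict[str, float | None] = field(default_factory=dict)
    flagged: bool = False  # control count of zero: percent change undefined


@dataclass
class MetaDomainProfile:
    """Mean normalized coverage over rescaled domain bodies plus native flanks."""

    values: np.ndarray
    flank_bins: int
    n_domains: int

    @property
    def body(self) -> np.ndarray:
        return self.values[self.flank_bins : self.flank_bins + META_BODY_BINS]

    @property
    def five_prime_flank(self) -> np.ndarray:
        return self.values[: self.flank_bins]

    @property
    def three_prime_flank(self) -> np.ndarray:
        return self.values[self.flank_bins + META_BODY_BINS :]


def quantify_regions(
    frag_sets: Mapping[str, Sequence[Fragment]],
    regions: Sequence[Region],
    control: str,
) -> list[RegionQuant]:
    """Midpoint-in-region counts per sample, per-million normalized, with
    percent change = 100 * (sample - control) / control for each non-control
    sample.  A region with zero control count is flagged and its percent
    changes are None.
    """
    if control not in frag_sets:
        raise ValueError(f"control sample {control!r} not present")
    totals = {name: len(frags) for name, frags in frag_sets.items()}

    # sorted midpoint arrays per (sample, chrom): counting is then two binary
    # searches per region, invariant under fragment order permutation
    mids: dict[str, dict[str, np.ndarray]] = {}
    for name, frags in frag_sets.items():
        per_chrom: dict[str, list[int]] = {}
        for f in frags:
            per_chrom.setdefault(f.chrom, []).append(f.midpoint)
        mids[name] = {c: np.sort(np.asarray(v)) for c, v in per_chrom.items()}

    out: list[RegionQuant] = []
    for region in regions:
        raw: dict[str, int] = {}
        norm: dict[str, float] = {}
        for name in frag_sets:
            m = mids[name].get(region.chrom)
            n = 0
            if m is not None:
                n = int(
                    np.searchsorted(m, region.end, "left")
                    - np.searchsorted(m, region.start, "left")
                )
            raw[name] = n
            norm[name] = n * 1e6 / totals[name] if totals[name] else 0.0
        rq = RegionQuant(region=region, counts=norm, raw_counts=raw, control=control)
        c = norm[control]
        rq.flagged = c == 0.0
        for name in frag_sets:
            if name == control:
                continue
            rq.percent_change[name] = (
                None if rq.flagged else 100.0 * (norm[name] - c) / c
            )
        out.append(rq)
    return out


def quant_table(quants: Sequence[RegionQuant]) -> pd.DataFrame:
    rows = []
    for q in quants:
        for sample, count in q.counts.items():
            rows.append(
                {
                    "region": q.region.name,
                    "sample": sample,
                    "norm_count_per_million": count,
                    "raw_count": q.raw_counts[sample],
                    "percent_change_vs_control": q.percent_change.get(sample),
                }
            )
    return pd.DataFrame(rows)


def meta_domain_profile(
    track: CoverageTrack,
    domains: Sequence[Domain],
    cfg: AnalysisConfig,
) -> MetaDomainProfile:
    """Average domains as meta-domains: 100 body bins + +/-meta_flank_bp flanks.

    Body values come from linear interpolation of per-base coverage onto 100
    evenly spaced bin centers; flanks are averaged in native 100bp bins.
    Domains too narrow to rescale (< 100bp) are skipped with a warning.
    """
    if len(domains) == 0:
        raise ValueError("meta-domain profile needs >= 1 domain")
    if cfg.meta_flank_bp % META_FLANK_BIN_BP:
        raise ValueError(f"meta_flank_bp must be a multiple of {META_FLANK_BIN_BP}")
    flank_bins = cfg.meta_flank_bp // META_FLANK_BIN_BP
    rows = []
    for d in domains:
        if d.width < META_BODY_BINS:
            warnings.warn(
                f"domain {d.chrom}:{d.start}-{d.end} narrower than "
                f"{META_BODY_BINS}bp; skipped in meta-domain profile"
            )
            continue
        per_base = track.per_base(
            d.chrom, d.start - cfg.meta_flank_bp, d.end + cfg.meta_flank_bp
        )
        flank = cfg.meta_flank_bp
        body = per_base[flank : flank + d.width]
        centers = (np.arange(META_BODY_BINS) + 0.5) * d.width / META_BODY_BINS
        body_vals = np.interp(centers, np.arange(d.width) + 0.5, body)
        five = per_base[:flank].reshape(flank_bins, META_FLANK_BIN_BP).mean(axis=1)
        three = per_base[flank + d.width :].reshape(
            flank_bins, META_FLANK_BIN_BP
        ).mean(axis=1)
        rows.append(np.concatenate([five, body_vals, three]))
    if not rows:
        raise ValueError("no domain wide enough for the meta-domain profile")
    return MetaDomainProfile(
        values=np.mean(rows, axis=0), flank_bins=flank_bins, n_domains=len(rows)
    )


# ---------------------------------------------------------------------------
# Cut&Run-qPCR


class QPCRTable:
    """Ct values per (locus, assay) with technical duplicates averaged on the Ct scale.

    ``assay`` is "cutrun" (antibody-targeted) or "mnase" (whole-MNase control
    digestion without antibody).  The reference locus (default Sas10) is a
    locus depleted in the targeted marks.
    """

    ASSAYS = ("cutrun", "mnase")

    def __init__(
        self,
        ct: Mapping[tuple[str, str], Sequence[float] | float],
        reference: str = "Sas10",
    ):
        self._ct: dict[tuple[str, str], float] = {}
        for (locus, assay), vals in ct.items():
            if assay not in self.ASSAYS:
                raise ValueError(f"unknown assay {assay!r}")
            vals = [vals] if isinstance(vals, (int, float)) else list(vals)
            if any(v <= 0 for v in vals):
                raise ValueError(f"Ct values must be > 0 at ({locus}, {assay})")
            self._ct[(locus, assay)] = float(np.mean(vals))
        self.reference = reference

    def ct(self, locus: str, assay: str) -> float:
        try:
            return self._ct[(locus, assay)]
        except KeyError:
            raise KeyError(f"missing Ct for ({locus!r}, {assay!r})") from None

    @classmethod
    def from_tsv(cls, path: str | Path, reference: str = "Sas10") -> "QPCRTable":
        """TSV columns: locus, assay, ct (one row per technical replicate)."""
        df = pd.read_csv(path, sep="\t")
        ct: dict[tuple[str, str], list[float]] = {}
        for _, row in df.iterrows():
            ct.setdefault((str(row["locus"]), str(row["assay"])), []).append(
                float(row["ct"])
            )
        return cls(ct, reference=reference)


def qpcr_fold_enrichment(table: QPCRTable, locus: str) -> float:
    """Fold enrichment doubly normalized to the whole-MNase control and the
    reference locus:

        fold = 2**(Ct_mnase(locus) - Ct_cutrun(locus))
             / 2**(Ct_mnase(ref)   - Ct_cutrun(ref))

    The reference locus itself scores exactly 1.
    """
    ref = table.reference
    num = table.ct(locus, "mnase") - table.ct(locus, "cutrun")
    den = table.ct(ref, "mnase") - table.ct(ref, "cutrun")
    return float(2.0 ** (num - den))
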