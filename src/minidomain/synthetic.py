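"""Synthetic Cut&Run fragment libraries with planted ground truth.

The generator emulates the fragment-release geometry of an antibody-targeted
MNase experiment: broad histone-mark domains shed nucleosome-sized fragments
(truncated normal lengths, mean 185 sd 25, clipped to [147, 250]) at a
configurable per-kb rate, while DNA regulatory elements shed clustered
sub-nucleosomal fragments (mean 90 sd 20, clipped to [50, 130]) whose
midpoints fall within the element footprint, optionally flanked by two phased
nucleosome hotspots at center +/- 120bp.  A low uniform background of both
fragment classes covers the rest of the chromosome.  Knockdown conditions
scale these rates multiplicatively, which reproduces percent-change readouts
directly.

Everything is Poisson-sampled around the configured rates and fully
reproducible from the spec seed; each (condition, replicate) pair draws from
an independently derived child stream so libraries can be regenerated in any
order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import special, stats

from .fragio import Fragment, GenomeTable

__all__ = [
    "PlantedDomain",
    "PlantedElement",
    "EffectProfile",
    "SyntheticGenomeSpec",
    "generate",
    "dhd_fixture",
    "write_manifest",
]

# Fragment-length models for the two release classes.
NUC_LEN_MEAN, NUC_LEN_SD, NUC_LEN_LO, NUC_LEN_HI = 185.0, 25.0, 147, 250
ELT_LEN_MEAN, ELT_LEN_SD, ELT_LEN_LO, ELT_LEN_HI = 90.0, 20.0, 50, 130

PHASED_OFFSET_BP = 120  # phased nucleosome hotspots at center +/- this
PHASED_JITTER_BP = 30


@dataclass(frozen=True)
class PlantedDomain:
    """A broad enriched interval shedding nucleosomal fragments at a set rate."""

    chrom: str
    start: int
    end: int
    nucleosomal_rate: float  # fragments per kb, per library
    mark: str = "H3K27me3"
    name: str = ""

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PlantedElement:
    """A TF-occupied element shedding clustered short fragments.

    ``position`` records ground truth relative to its owning domain
    (five_prime_border / three_prime_border / internal / none).
    """

    chrom: str
    center: int
    footprint_bp: int
    short_fragment_rate: float  # expected fragment count, per library
    position: str = "none"
    domain: str = ""
    name: str = ""
    phased_nucleosomes: bool = True

    def __post_init__(self) -> None:
        if self.footprint_bp < 1:
            raise ValueError("element footprint must be >= 1bp")


@dataclass(frozen=True)
class EffectProfile:
    """Multiplicative knockdown effect on planted rates.

    ``global_domain_scale`` multiplies every domain's nucleosomal rate;
    ``domain_scales`` (by domain name) override it.  ``element_scale`` and
    ``element_scales`` act likewise on element short-fragment rates.  Phased
    nucleosome hotspots flanking an element follow the scale of the element's
    owning domain: they are mark-carrying nucleosomes, released through the
    antibody like any other domain nucleosome, not TF footprints.
    """

    global_domain_scale: float = 1.0
    domain_scales: Mapping[str, float] = field(default_factory=dict)
    element_scale: float = 1.0
    element_scales: Mapping[str, float] = field(default_factory=dict)

    def domain_factor(self, name: str) -> float:
        return float(self.domain_scales.get(name, self.global_domain_scale))

    def element_factor(self, name: str) -> float:
        return float(self.element_scales.get(name, self.element_scale))


@dataclass
class SyntheticGenomeSpec:
    """Full description of a planted synthetic experiment."""

    genome: GenomeTable
    domains: list[PlantedDomain]
    elements: list[PlantedElement]
    background_rate: float = 20.0  # nucleosomal fragments per kb outside domains
    background_short_rate: float = 0.5  # sub-nucleosomal background per kb
    conditions: Mapping[str, EffectProfile] = field(default_factory=dict)
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate < 0 or self.background_short_rate < 0:
            raise ValueError("background rates must be >= 0")
        for d in self.domains:
            if d.chrom not in self.genome:
                raise ValueError(f"domain on unknown chromosome {d.chrom!r}")
            if not (0 <= d.start < d.end <= self.genome[d.chrom]):
                raise ValueError(f"domain {d.name or d.start} outside chromosome")
            if d.nucleosomal_rate < self.background_rate:
                raise ValueError(
                    f"domain rate {d.nucleosomal_rate} below background "
                    f"{self.background_rate}"
                )
        for e in self.elements:
            if e.chrom not in self.genome:
                raise ValueError(f"element on unknown chromosome {e.chrom!r}")
            if e.short_fragment_rate < 0:
                raise ValueError("element rate must be >= 0")
        if not self.conditions:
            self.conditions = {"control": EffectProfile()}


def _trunc_lengths(rng, n: int, mean: float, sd: float, lo: int, hi: int) -> np.ndarray:
    # inverse-CDF sampling of the truncated normal; identical in law to
    # scipy.stats.truncnorm and much cheaper per call
    a, b = (lo - mean) / sd, (hi - mean) / sd
    fa, fb = stats.norm.cdf(a), stats.norm.cdf(b)
    u = rng.random(n)
    raw = mean + sd * special.ndtri(fa + u * (fb - fa))
    return np.clip(np.rint(raw).astype(int), lo, hi)


def _place(chrom, mids, lengths, length, sample, replicate) -> list[Fragment]:
    starts = np.clip(mids - lengths // 2, 0, length - lengths)
    return [
        Fragment(chrom, int(s), int(s + l), sample, replicate)
        for s, l in zip(starts, lengths)
    ]


def _child_rng(seed: int, condition: str, replicate: int, stream: str):
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(condition.encode()), replicate,
         zlib.crc32(stream.encode())]
    )


def generate(
    spec: SyntheticGenomeSpec,
    conditions: list[str] | None = None,
) -> dict[tuple[str, str], list[Fragment]]:
    """Generate one fragment library per (condition, replicate).

    Background nucleosomal fragments are laid down uniformly outside planted
    domains; inside a domain the domain rate replaces the background.  Returns
    a dict keyed by (condition, replicate_name) with replicate names "rep1"..
    ``conditions`` restricts generation to a subset; because every
    (condition, replicate) pair draws from its own derived stream, a subset
    library is byte-identical to the same library in a full run.
    """
    out: dict[tuple[str, str], list[Fragment]] = {}
    for condition in conditions if conditions is not None else spec.conditions:
        profile = spec.conditions[condition]
        for rep_idx in range(1, spec.replicates + 1):
            rep = f"rep{rep_idx}"
            frags: list[Fragment] = []
            for chrom, length in spec.genome.items():
                chrom_domains = [d for d in spec.domains if d.chrom == chrom]
                chrom_elements = [e for e in spec.elements if e.chrom == chrom]

                # background nucleosomal, masked out of domains
                rng = _child_rng(spec.seed, condition, rep_idx, f"bg:{chrom}")
                n_bg = rng.poisson(spec.background_rate * length / 1000.0)
                mids = rng.integers(0, length, size=n_bg)
                if chrom_domains:
                    mask = np.zeros(n_bg, dtype=bool)
                    for d in chrom_domains:
                        mask |= (mids >= d.start) & (mids < d.end)
                    mids = mids[~mask]
                lens = _trunc_lengths(
                    rng, len(mids), NUC_LEN_MEAN, NUC_LEN_SD, NUC_LEN_LO, NUC_LEN_HI
                )
                frags += _place(chrom, mids, lens, length, condition, rep)

                # background short fragments, genome-wide
                n_bgs = rng.poisson(spec.background_short_rate * length / 1000.0)
                mids = rng.integers(0, length, size=n_bgs)
                lens = _trunc_lengths(
                    rng, n_bgs, ELT_LEN_MEAN, ELT_LEN_SD, ELT_LEN_LO, ELT_LEN_HI
                )
                frags += _place(chrom, mids, lens, length, condition, rep)

                # planted domains
                for d in chrom_domains:
                    rng = _child_rng(
                        spec.seed, condition, rep_idx, f"dom:{d.name or d.start}"
                    )
                    rate = d.nucleosomal_rate * profile.domain_factor(d.name)
                    n = rng.poisson(rate * d.width / 1000.0)
                    mids = rng.integers(d.start, d.end, size=n)
                    lens = _trunc_lengths(
                        rng, n, NUC_LEN_MEAN, NUC_LEN_SD, NUC_LEN_LO, NUC_LEN_HI
                    )
                    frags += _place(chrom, mids, lens, length, condition, rep)

                # planted elements (+ optional phased nucleosome hotspots)
                for e in chrom_elements:
                    rng = _child_rng(
                        spec.seed, condition, rep_idx, f"elt:{e.name or e.center}"
                    )
                    factor = profile.element_factor(e.name)
                    n = rng.poisson(e.short_fragment_rate * factor)
                    half = e.footprint_bp // 2
                    mids = e.center + rng.integers(
                        -half, e.footprint_bp - half, size=n
                    )
                    lens = _trunc_lengths(
                        rng, n, ELT_LEN_MEAN, ELT_LEN_SD, ELT_LEN_LO, ELT_LEN_HI
                    )
                    frags += _place(chrom, mids, lens, length, condition, rep)
                    if e.phased_nucleosomes:
                        dom_factor = profile.domain_factor(e.domain)
                        for sign in (-1, +1):
                            m = rng.poisson(e.short_fragment_rate * dom_factor / 2.0)
                            mids = (
                                e.center
                                + sign * PHASED_OFFSET_BP
                                + rng.integers(
                                    -PHASED_JITTER_BP, PHASED_JITTER_BP + 1, size=m
                                )
                            )
                            mids = np.clip(mids, 0, length - 1)
                            lens = _trunc_lengths(
                                rng, m, NUC_LEN_MEAN, NUC_LEN_SD,
                                NUC_LEN_LO, NUC_LEN_HI,
                            )
                            frags += _place(chrom, mids, lens, length, condition, rep)
            out[(condition, rep)] = frags
    return out


# ---------------------------------------------------------------------------
# The dhd-like fixture

# Coordinates follow the published mini-domain: 3' end 5,317,465, width 5450bp
# (the 5' end is derived as end - width because the printed 5' coordinate is
# internally inconsistent; see the manifest note), border elements spanning
# 5,312,120-5,312,212 (92bp) and 5,317,300-5,317,448 (148bp).
DHD_CHROM = "X"
DHD_CHROM_LEN = 5_400_000
DHD_DOMAIN_END = 5_317_465
DHD_DOMAIN_WIDTH = 5_450
DHD_DOMAIN_START = DHD_DOMAIN_END - DHD_DOMAIN_WIDTH  # 5,312,015
DHD_5P_ELEMENT = (5_312_120, 5_312_212)  # 92bp footprint
DHD_3P_ELEMENT = (5_317_300, 5_317_448)  # 148bp footprint


def dhd_fixture(seed: int = 0, replicates: int = 3) -> SyntheticGenomeSpec:
    """Single-chromosome spec with the dhd-like mini-domain architecture.

    One 5450bp H3K27me3/H3K9me3-like mini-domain carrying exactly two border
    elements and no internal elements, plus a large (40kb) control domain with
    both border and internal elements for contrast.  Rates encode the
    mini-domain's standout density (outlier in the size-vs-density scatter)
    and the knockdown conditions encode the reported effect regimes:
    -35% / -20% / -5% on domain signal and ~63% loss of element signal, plus a
    mini-domain-specific increase for the lid-like condition.
    """
    genome = GenomeTable({DHD_CHROM: DHD_CHROM_LEN})
    mini = PlantedDomain(
        DHD_CHROM, DHD_DOMAIN_START, DHD_DOMAIN_END,
        nucleosomal_rate=300.0, mark="H3K27me3/H3K9me3", name="dhd_mini_domain",
    )
    ctrl = PlantedDomain(
        DHD_CHROM, 5_100_000, 5_140_000,
        nucleosomal_rate=60.0, mark="H3K27me3", name="control_domain",
    )

    def elt(name, span, position, domain):
        lo, hi = span
        return PlantedElement(
            DHD_CHROM,
            center=(lo + hi) // 2,
            footprint_bp=hi - lo,
            short_fragment_rate=120.0,
            position=position,
            domain=domain,
            name=name,
        )

    elements = [
        elt("dhd_5p_border", DHD_5P_ELEMENT, "five_prime_border", "dhd_mini_domain"),
        elt("dhd_3p_border", DHD_3P_ELEMENT, "three_prime_border", "dhd_mini_domain"),
        elt("ctrl_5p_border", (5_100_100, 5_100_250), "five_prime_border",
            "control_domain"),
        elt("ctrl_3p_border", (5_139_750, 5_139_900), "three_prime_border",
            "control_domain"),
        elt("ctrl_internal_1", (5_114_925, 5_115_075), "internal", "control_domain"),
        elt("ctrl_internal_2", (5_124_925, 5_125_075), "internal", "control_domain"),
    ]

    conditions = {
        "control": EffectProfile(),
        "ez_kd": EffectProfile(global_domain_scale=0.65, element_scale=0.37),
        "snr1_kd": EffectProfile(global_domain_scale=0.80, element_scale=0.37),
        "sin3a_kd": EffectProfile(global_domain_scale=0.95, element_scale=0.37),
        "modmdg4_kd": EffectProfile(
            global_domain_scale=0.95,
            element_scales={"dhd_5p_border": 0.4, "dhd_3p_border": 0.4},
        ),
        "lid_kd": EffectProfile(
            global_domain_scale=0.95, domain_scales={"dhd_mini_domain": 1.30}
        ),
    }
    return SyntheticGenomeSpec(
        genome=genome,
        domains=[ctrl, mini],
        elements=elements,
        background_rate=20.0,
        background_short_rate=0.5,
        conditions=conditions,
        replicates=replicates,
        seed=seed,
    )


def write_manifest(spec: SyntheticGenomeSpec, path: str | Path) -> None:
    """Write the planted ground truth (intervals, rates, effects) as JSON."""
    doc = {
        "genome": dict(spec.genome.items()),
        "background_rate_per_kb": spec.background_rate,
        "background_short_rate_per_kb": spec.background_short_rate,
        "replicates": spec.replicates,
        "seed": spec.seed,
        "domains": [asdict(d) for d in spec.domains],
        "elements": [asdict(e) for e in spec.elements],
        "conditions": {
            name: {
                "global_domain_scale": p.global_domain_scale,
                "domain_scales": dict(p.domain_scales),
                "element_scale": p.element_scale,
                "element_scales": dict(p.element_scales),
            }
            for name, p in spec.conditions.items()
        },
        "notes": [
            "mini-domain 5' end derived as (3' end - 5450bp); the printed 5' "
            "coordinate is internally inconsistent with the stated width",
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
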