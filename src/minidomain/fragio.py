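"""Paired-end fragment I/O, size partitioning, depth normalization and binned coverage.

Cut&Run releases DNA fragments whose exact spans are recovered by paired-end
sequencing.  Everything downstream works on those spans: nucleosome-sized
fragments (~150-250bp) report the targeted histone modification, while
sub-nucleosomal fragments (<120bp) report transcription-factor footprints in
its immediate vicinity.  This module holds the fragment container, the genome
table, the binned coverage track, the global analysis configuration, and the
handful of deterministic transformations (size partition, downsampling,
coverage binning) that every later stage builds on.

Coordinates are 0-based half-open everywhere in memory and BED-style on disk.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Fragment",
    "GenomeTable",
    "CoverageTrack",
    "AnalysisConfig",
    "read_fragments",
    "read_genome_table",
    "write_fragments",
    "partition_by_size",
    "downsample",
    "coverage",
    "write_bedgraph",
    "read_bedgraph",
]


@dataclass(slots=True)
class Fragment:
    """A sequenced paired-end fragment as a genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    sample: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"fragment end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError(f"negative start: {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Integer midpoint; for even lengths, start + length // 2."""
        return self.start + self.length // 2


class GenomeTable:
    """Ordered chromosome name -> length (bp) map."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, Mapping) else list(sizes)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome table")
        for name, length in items:
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._sizes: dict[str, int] = dict(items)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def items(self):
        return self._sizes.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeTable) and self._sizes == other._sizes

    def __repr__(self) -> str:
        return f"GenomeTable({self._sizes!r})"


@dataclass
class CoverageTrack:
    """Binned mean per-base depth per chromosome.

    ``values[chrom][i]`` is (bases of fragment overlap in bin i) / bin_size,
    multiplied by ``norm_factor``.  Vector length is ceil(len / bin_size).
    """

    bin_size: int
    values: dict[str, np.ndarray]
    norm_factor: float = 1.0

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            bin_size=self.bin_size,
            values={c: v * factor for c, v in self.values.items()},
            norm_factor=self.norm_factor * factor,
        )

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base track values over [start, end).

        Each bin contributes value x (bases of overlap with the region), so a
        fully covered bin contributes value x bin_size.
        """
        if end <= start:
            return 0.0
        v = self.values[chrom]
        b = self.bin_size
        lo, hi = start // b, (end - 1) // b
        total = 0.0
        for i in range(lo, min(hi, len(v) - 1) + 1):
            o = min(end, (i + 1) * b) - max(start, i * b)
            if o > 0:
                total += float(v[i]) * o
        return total

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); positions outside the chromosome are 0."""
        v = self.values[chrom]
        out = np.zeros(end - start, dtype=float)
        pos = np.arange(max(start, 0), min(end, len(v) * self.bin_size))
        out[pos - start] = v[pos // self.bin_size]
        return out


@dataclass(frozen=True)
class AnalysisConfig:
    """Global knobs of the fragment-size-resolved analysis.

    Defaults mirror the published procedure: a strict <120bp cutoff separating
    sub-nucleosomal from nucleosomal fragments, 25bp bins for all-fragment
    coverage, 10bp bins for short-fragment coverage, a 1e-4 Poisson p-value for
    peak calling, 1kb heatmap flanks, 3kb meta-domain flanks and a 3kb domain
    width floor.  ``domain_bin_bp`` is the coarser binning used for domain
    segmentation (must be <= 1000).
    """

    short_threshold_bp: int = 120
    all_bin_bp: int = 25
    short_bin_bp: int = 10
    peak_pvalue: float = 1e-4
    flank_bp: int = 1000
    meta_flank_bp: int = 3000
    domain_min_bp: int = 3000
    domain_bin_bp: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "short_threshold_bp",
            "all_bin_bp",
            "short_bin_bp",
            "flank_bp",
            "meta_flank_bp",
            "domain_min_bp",
            "domain_bin_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (0.0 < self.peak_pvalue < 1.0):
            raise ValueError(f"peak_pvalue must lie in (0, 1), got {self.peak_pvalue}")

    def with_(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Reading / writing


class FragmentParseError(ValueError):
    pass


def read_genome_table(path: str | Path) -> GenomeTable:
    """Read a tab-separated chrom.sizes file (name <TAB> length)."""
    items: list[tuple[str, int]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FragmentParseError(f"{path}:{lineno}: expected 'name<TAB>length'")
        items.append((parts[0], int(parts[1])))
    return GenomeTable(items)


def _parse_bed_line(parts: list[str], lineno: int, path) -> tuple[str, int, int]:
    if len(parts) < 3:
        raise FragmentParseError(f"{path}:{lineno}: BED line needs >= 3 fields")
    try:
        return parts[0], int(parts[1]), int(parts[2])
    except ValueError as exc:
        raise FragmentParseError(f"{path}:{lineno}: non-integer coordinate") from exc


def read_fragments(
    path: str | Path,
    format: str = "BED",
    genome: GenomeTable | None = None,
    sample: str = "",
    replicate: str = "",
) -> list[Fragment]:
    """Read fragments from BED, BEDPE or SAM-lite into 0-based half-open intervals.

    BEDPE mate pairs are collapsed to one fragment spanning the outermost
    coordinates.  SAM-lite uses pysam: each properly paired read-1 record
    yields one fragment of span [pos, pos + abs(tlen)).  Input order is
    preserved.  ``genome``, when given, is used to reject unknown chromosomes.
    """
    fmt = format.upper()
    path = Path(path)
    frags: list[Fragment] = []

    def check_chrom(chrom: str, lineno) -> None:
        if genome is not None and chrom not in genome:
            raise FragmentParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")

    if fmt in ("BED", "BED3", "BED6"):
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = _parse_bed_line(line.split("\t"), lineno, path)
            check_chrom(chrom, lineno)
            frags.append(Fragment(chrom, start, end, sample, replicate))
    elif fmt == "BEDPE":
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FragmentParseError(f"{path}:{lineno}: BEDPE line needs >= 6 fields")
            c1, s1, e1 = _parse_bed_line(parts[0:3], lineno, path)
            c2, s2, e2 = _parse_bed_line(parts[3:6], lineno, path)
            if c1 != c2:
                raise FragmentParseError(
                    f"{path}:{lineno}: inter-chromosomal mate pair {c1}/{c2}"
                )
            check_chrom(c1, lineno)
            frags.append(Fragment(c1, min(s1, s2), max(e1, e2), sample, replicate))
    elif fmt in ("SAM", "SAM-LITE"):
        import pysam

        with pysam.AlignmentFile(str(path), "r", check_sq=False) as handle:
            for rec in handle:
                if rec.is_unmapped or rec.is_read2 or rec.template_length == 0:
                    continue
                span = abs(rec.template_length)
                start = rec.reference_start
                chrom = rec.reference_name
                check_chrom(chrom, rec.query_name)
                frags.append(Fragment(chrom, start, start + span, sample, replicate))
    else:
        raise ValueError(f"unknown fragment format {format!r}")
    return frags


def write_fragments(frags: Sequence[Fragment], path: str | Path) -> None:
    """Write fragments as BED3 (one line per fragment, input order)."""
    with open(path, "w") as fh:
        for f in frags:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")


# ---------------------------------------------------------------------------
# Transformations


def partition_by_size(
    frags: Sequence[Fragment], threshold: int
) -> tuple[list[Fragment], list[Fragment]]:
    """Split into (short, all): short = strictly shorter than ``threshold``.

    The "all fragments" view is the input unchanged -- the nucleosomal track
    keeps its sub-nucleosomal minority, as in the published all-fragment
    coverage.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    short = [f for f in frags if f.length < threshold]
    return short, list(frags)


def nucleosomal_only(frags: Sequence[Fragment], threshold: int) -> list[Fragment]:
    """Non-default view: fragments of length >= threshold only."""
    return [f for f in frags if f.length >= threshold]


def downsample(
    frag_sets: Mapping[str, Sequence[Fragment]],
    target: int | str = "min",
    seed: int = 0,
) -> dict[str, list[Fragment]]:
    """Downsample every set to a common depth, uniformly without replacement.

    ``target="min"`` uses the smallest set size.  Selection preserves input
    order and is a deterministic function of (seed, input).
    """
    if target == "min":
        if not frag_sets:
            return {}
        n = min(len(v) for v in frag_sets.values())
    else:
        n = int(target)
        for name, frags in frag_sets.items():
            if n > len(frags):
                raise ValueError(
                    f"target {n} exceeds size {len(frags)} of set {name!r}"
                )
    out: dict[str, list[Fragment]] = {}
    for key, frags in sorted(frag_sets.items()):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(key.encode())])
        idx = np.sort(rng.choice(len(frags), size=n, replace=False))
        out[key] = [frags[i] for i in idx]
    return {k: out[k] for k in frag_sets}  # original key order


def coverage(
    frags: Sequence[Fragment],
    genome: GenomeTable,
    bin_size: int,
    norm: str = "raw",
) -> CoverageTrack:
    """Binned mean per-base depth with full-fragment (paired-end) extension.

    Every base from start to end of each fragment counts.  ``norm`` is "raw"
    or "per-million-fragments" (scales by 1e6 / n_fragments).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if norm not in ("raw", "per-million-fragments"):
        raise ValueError(f"unknown norm {norm!r}")

    diffs = {c: np.zeros(length + 1, dtype=np.float64) for c, length in genome.items()}
    for f in frags:
        if f.chrom not in genome:
            raise ValueError(f"fragment on unknown chromosome {f.chrom!r}")
        if f.end > genome[f.chrom]:
            raise ValueError(
                f"fragment {f.chrom}:{f.start}-{f.end} beyond chromosome end "
                f"({genome[f.chrom]})"
            )
        diffs[f.chrom][f.start] += 1.0
        diffs[f.chrom][f.end] -= 1.0

    factor = 1.0
    if norm == "per-million-fragments" and len(frags) > 0:
        factor = 1e6 / len(frags)

    values: dict[str, np.ndarray] = {}
    for chrom, length in genome.items():
        depth = np.cumsum(diffs[chrom][:-1])
        nbins = math.ceil(length / bin_size)
        padded = np.zeros(nbins * bin_size)
        padded[:length] = depth
        values[chrom] = padded.reshape(nbins, bin_size).sum(axis=1) / bin_size * factor
    return CoverageTrack(bin_size=bin_size, values=values, norm_factor=factor)


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a bedGraph (0-based half-open); runs of equal value merged, zeros omitted."""
    with open(path, "w") as fh:
        for chrom, vals in track.values.items():
            if len(vals) == 0:
                continue
            run_start = 0
            run_val = vals[0]
            for i in range(1, len(vals) + 1):
                if i == len(vals) or vals[i] != run_val:
                    if run_val != 0.0:
                        fh.write(
                            f"{chrom}\t{run_start * track.bin_size}\t"
                            f"{i * track.bin_size}\t{run_val:g}\n"
                        )
                    if i < len(vals):
                        run_start, run_val = i, vals[i]


def read_bedgraph(path: str | Path, genome: GenomeTable, bin_size: int) -> CoverageTrack:
    """Read a bedGraph written at ``bin_size`` resolution back into a track."""
    values = {
        c: np.zeros(math.ceil(length / bin_size)) for c, length in genome.items()
    }
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track")):
            continue
        chrom, start, end, *rest = line.split("\t")
        if chrom not in genome:
            raise FragmentParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        start, end, val = int(start), int(end), float(rest[0])
        values[chrom][start // bin_size : -(-end // bin_size)] = val
    return CoverageTrack(bin_size=bin_size, values=values)
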