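"""Windowed read-depth profiles, region depth ratios and rough copy numbers.

The estimation model: reads from every copy of a >98%-identical gene family
mis-map freely among the copies, so the pooled depth over the reference
footprint of the family scales with the *total* copy number. The reference
footprint is worth ``copy_equivalents_reference`` copies (active genes plus
a pseudogene allowance), so a depth ratio of 1.0 against a nearby
single-copy region corresponds to the reference gene count and each
1/copy_equivalents change in the ratio to one gene copy.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._util import round_cn
from .regions import Interval, RegionSet


class DepthError(ValueError):
    """Raised for malformed or uninformative depth input."""


@dataclass(frozen=True)
class CopyModelConfig:
    """Mapping between pooled depth ratios and gene copy numbers."""

    copy_equivalents_reference: int = 7
    pseudogene_equivalents: int = 1

    def __post_init__(self) -> None:
        if self.copy_equivalents_reference < 1:
            raise ValueError("copy_equivalents_reference must be >= 1")
        if self.pseudogene_equivalents < 0:
            raise ValueError("pseudogene_equivalents must be >= 0")

    @property
    def reference_gene_copies(self) -> int:
        return self.copy_equivalents_reference - self.pseudogene_equivalents


@dataclass
class DepthProfile:
    """Mean read depth in consecutive fixed-width windows for one sample.

    ``starts`` are 1-based window start positions; windows are
    ``window_size`` bp wide except possibly the last, which is truncated at
    ``span.end``.
    """

    sample_id: str
    window_size: int
    starts: np.ndarray
    depths: np.ndarray
    span: Interval

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.starts.shape != self.depths.shape or self.starts.ndim != 1:
            raise ValueError("starts/depths must be 1-D and equal length")
        if len(self.starts) == 0:
            raise DepthError("empty depth profile")
        if np.any(np.diff(self.starts) != self.window_size):
            raise ValueError("windows must be consecutive and constant width")
        if not np.all(np.isfinite(self.depths)) or np.any(self.depths < 0):
            raise ValueError("window depths must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.starts)

    def window_interval(self, i: int) -> Interval:
        end = min(int(self.starts[i]) + self.window_size - 1, self.span.end)
        return Interval(int(self.starts[i]), end)

    def window_widths(self) -> np.ndarray:
        ends = np.minimum(self.starts + self.window_size - 1, self.span.end)
        return (ends - self.starts + 1).astype(np.int64)

    def overlap_weights(self, interval: Interval) -> np.ndarray:
        """Per-window bp of overlap with *interval*."""
        ends = np.minimum(self.starts + self.window_size - 1, self.span.end)
        lo = np.maximum(self.starts, interval.start)
        hi = np.minimum(ends, interval.end)
        return np.maximum(0, hi - lo + 1).astype(float)

    def mean_depth(self, interval: Interval) -> float:
        """Overlap-length-weighted mean window depth over *interval*."""
        w = self.overlap_weights(interval)
        total = w.sum()
        if total == 0:
            raise DepthError(
                f"interval [{interval.start}, {interval.end}] has no "
                f"overlap with profile span of sample {self.sample_id!r}"
            )
        return float(np.dot(w, self.depths) / total)

    def scaled(self, factor: float) -> "DepthProfile":
        return DepthProfile(
            self.sample_id, self.window_size, self.starts.copy(),
            self.depths * factor, self.span,
        )


@dataclass(frozen=True)
class DepthRatioSet:
    """Depth ratios of gene regions against the single-copy reference."""

    sample_id: str
    per_region_ratio: Mapping[str, float]
    combined_ratio: float
    reference_mean_depth: float


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def load_depth_windows(
    source,
    survey: Interval,
    window_size: int = 5000,
    sample_id: str | None = None,
) -> DepthProfile:
    """Read a depth table and average it into fixed windows over *survey*.

    Two tab-separated layouts are accepted (gzip allowed, ``#`` comments
    skipped):

    * windowed: ``chrom  start(0-based)  end  mean_depth``
    * per-base: ``chrom  pos(1-based)  depth``

    Bases of the survey absent from the table count as depth 0. Windows are
    consecutive ``window_size``-bp blocks from the survey start; the last
    window may be shorter.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    n_bases = survey.length
    per_base = np.zeros(n_bases, dtype=float)
    n_rows = 0
    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) >= 4:
                    s0, e0, d = int(fields[1]), int(fields[2]), float(fields[3])
                    lo = max(s0 + 1, survey.start)
                    hi = min(e0, survey.end)
                elif len(fields) == 3:
                    pos, d = int(fields[1]), float(fields[2])
                    lo = hi = pos
                    if pos < survey.start or pos > survey.end:
                        continue
                else:
                    raise ValueError(f"expected 3 or 4 columns, got {len(fields)}")
                if d < 0 or not np.isfinite(d):
                    raise ValueError(f"bad depth value {fields[-1]!r}")
            except ValueError as exc:
                raise DepthError(f"{source}:{lineno}: {exc}") from exc
            if lo > hi:
                continue
            per_base[lo - survey.start : hi - survey.start + 1] = d
            n_rows += 1
    if n_rows == 0:
        raise DepthError(f"{source}: no depth records")

    starts = np.arange(survey.start, survey.end + 1, window_size, dtype=np.int64)
    depths = np.empty(len(starts), dtype=float)
    for i, s in enumerate(starts):
        block = per_base[s - survey.start : min(s + window_size, survey.end + 1) - survey.start]
        depths[i] = block.mean()
    return DepthProfile(
        sample_id=sample_id or str(source),
        window_size=window_size,
        starts=starts,
        depths=depths,
        span=survey,
    )


def load_depth_from_alignment(
    path,
    survey: Interval,
    window_size: int = 5000,
    min_mapq: int = 0,
    chrom: str | None = None,
    sample_id: str | None = None,
) -> DepthProfile:
    """Compute a windowed profile from a SAM/BAM/CRAM alignment.

    Streams all reads (no index needed), accumulating aligned-block
    coverage over the survey interval; reads below *min_mapq* are skipped.
    Requires :mod:`pysam`.
    """
    import pysam  # optional dependency

    per_base = np.zeros(survey.length, dtype=np.int64)
    with pysam.AlignmentFile(str(path)) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.mapping_quality < min_mapq:
                continue
            if chrom is not None and read.reference_name != chrom:
                continue
            for b0, e0 in read.get_blocks():  # 0-based half-open
                lo = max(b0 + 1, survey.start)
                hi = min(e0, survey.end)
                if lo <= hi:
                    per_base[lo - survey.start : hi - survey.start + 1] += 1

    starts = np.arange(survey.start, survey.end + 1, window_size, dtype=np.int64)
    depths = np.empty(len(starts), dtype=float)
    for i, s in enumerate(starts):
        block = per_base[s - survey.start : min(s + window_size, survey.end + 1) - survey.start]
        depths[i] = block.mean()
    return DepthProfile(
        sample_id=sample_id or str(path),
        window_size=window_size,
        starts=starts,
        depths=depths,
        span=survey,
    )


def region_depth_ratio(profile: DepthProfile, regions: RegionSet) -> DepthRatioSet:
    """Depth of each gene region and of the pooled regions, relative to the
    single-copy reference interval.

    Windows contribute with overlap-length weighting, so a window
    straddling a region boundary counts only the overlapping bases. The
    combined ratio is the length-weighted mean of per-region mean depths
    divided by the reference mean.
    """
    ref_mean = profile.mean_depth(regions.reference_interval)
    if ref_mean == 0:
        raise DepthError(
            f"uninformative sample {profile.sample_id!r}: "
            "reference interval mean depth is 0"
        )
    per_region: dict[str, float] = {}
    pooled_num = 0.0
    pooled_len = 0.0
    for name in regions.region_names:
        iv = regions.regions[name]
        if profile.overlap_weights(iv).sum() == 0:
            raise DepthError(
                f"region {name!r} lies outside the profile span of "
                f"sample {profile.sample_id!r}"
            )
        m = profile.mean_depth(iv)
        per_region[name] = m / ref_mean
        pooled_num += m * iv.length
        pooled_len += iv.length
    combined = pooled_num / pooled_len / ref_mean
    return DepthRatioSet(
        sample_id=profile.sample_id,
        per_region_ratio=per_region,
        combined_ratio=combined,
        reference_mean_depth=ref_mean,
    )


def rough_copy_number(ratio: DepthRatioSet, model: CopyModelConfig = CopyModelConfig()) -> int:
    """First-pass integer copy number from the combined depth ratio.

    ``ratio * copy_equivalents - pseudogene_equivalents``, rounded half
    away from zero and floored at 0.
    """
    if ratio.combined_ratio < 0:
        raise ValueError("combined_ratio must be >= 0")
    value = (
        ratio.combined_ratio * model.copy_equivalents_reference
        - model.pseudogene_equivalents
    )
    return round_cn(value)


@dataclass(frozen=True)
class CurationResult:
    """Outcome of the flanking-depth constancy check."""

    passed: bool
    median_flank_depth: float
    offending_windows: Sequence[tuple[int, float, float]] = field(default_factory=tuple)
    #: (window_start, mean_depth, relative deviation from the flank median)


def flag_curated(
    profile: DepthProfile,
    regions: RegionSet,
    flank_bp: int = 100_000,
    max_rel_dev: float = 0.25,
) -> CurationResult:
    """Check that depth is constant in the flanks of the gene-region block.

    Samples with depth steps next to the gene clusters (e.g. larger
    encompassing duplications or deletions) make the pooled ratio
    uninterpretable; this automates the constancy judgement with an
    explicit tolerance. A window fails when its mean depth deviates from
    the median flank depth by more than ``max_rel_dev`` relative.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    block = regions.block
    flanks = []
    if block.start > profile.span.start:
        flanks.append(
            Interval(max(profile.span.start, block.start - flank_bp), block.start - 1)
        )
    if block.end < profile.span.end:
        flanks.append(
            Interval(block.end + 1, min(profile.span.end, block.end + flank_bp))
        )

    mask = np.zeros(len(profile), dtype=bool)
    for flank in flanks:
        mask |= profile.overlap_weights(flank) > 0
    # exclude windows touching the gene regions themselves
    for iv in regions.regions.values():
        mask &= profile.overlap_weights(iv) == 0
    if not mask.any():
        raise DepthError("no flank windows on either side of the region block")

    flank_depths = profile.depths[mask]
    flank_starts = profile.starts[mask]
    med = float(np.median(flank_depths))
    scale = med if med > 0 else 1.0
    rel = np.abs(flank_depths - med) / scale
    bad = rel > max_rel_dev
    offending = tuple(
        (int(s), float(d), float(r))
        for s, d, r in zip(flank_starts[bad], flank_depths[bad], rel[bad])
    )
    return CurationResult(
        passed=not bad.any(),
        median_flank_depth=med,
        offending_windows=offending,
    )
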