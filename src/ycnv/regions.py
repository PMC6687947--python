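"""Genomic interval bookkeeping for the multi-copy gene survey.

Internally every interval is 1-based and inclusive at both ends, matching
the coordinate style of genome browsers and of the region definitions this
package ships as defaults (GRCh37 chrY). BED input/output converts to and
from 0-based half-open coordinates exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based, inclusive genomic interval on a single chromosome."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "Interval") -> int:
        """Number of bases shared with *other* (0 if disjoint)."""
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return max(0, hi - lo + 1)

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    @classmethod
    def from_bed(cls, start0: int, end0: int) -> "Interval":
        """Convert a 0-based half-open BED interval."""
        return cls(start0 + 1, end0)

    def to_bed(self) -> tuple[int, int]:
        """Convert to a 0-based half-open (start, end) pair."""
        return self.start - 1, self.end


# GRCh37 chrY defaults: four gene-cluster regions, one single-copy
# normalizer, and the survey window used for depth plotting.
DEFAULT_REGIONS: dict[str, Interval] = {
    "1": Interval(23_673_224, 23_711_212),
    "2": Interval(24_026_223, 24_064_214),
    "3": Interval(24_314_689, 24_329_129),
    "4": Interval(24_549_583, 24_564_028),
}
DEFAULT_REFERENCE = Interval(23_255_000, 23_555_000)
DEFAULT_SURVEY = Interval(22_000_000, 29_000_000)

#: reserved BED name marking the single-copy reference interval
REFERENCE_NAME = "REF"


@dataclass(frozen=True)
class RegionSet:
    """Named gene-cluster regions plus the single-copy reference interval.

    All intervals must lie within ``survey_interval``; the regions must be
    mutually non-overlapping and disjoint from the reference interval.
    """

    regions: Mapping[str, Interval] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )
    reference_interval: Interval = DEFAULT_REFERENCE
    survey_interval: Interval = DEFAULT_SURVEY

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("RegionSet needs at least one region")
        ivs = sorted(self.regions.items(), key=lambda kv: kv[1].start)
        for (na, a), (nb, b) in zip(ivs, ivs[1:]):
            if a.overlap(b):
                raise ValueError(f"regions {na!r} and {nb!r} overlap")
        for name, iv in self.regions.items():
            if iv.overlap(self.reference_interval):
                raise ValueError(
                    f"region {name!r} overlaps the reference interval"
                )
            if not self.survey_interval.contains(iv):
                raise ValueError(f"region {name!r} outside survey interval")
        if not self.survey_interval.contains(self.reference_interval):
            raise ValueError("reference interval outside survey interval")

    @property
    def region_names(self) -> list[str]:
        return sorted(self.regions, key=lambda n: self.regions[n].start)

    @property
    def block(self) -> Interval:
        """Smallest interval spanning all gene-cluster regions."""
        return Interval(
            min(iv.start for iv in self.regions.values()),
            max(iv.end for iv in self.regions.values()),
        )

    @classmethod
    def from_bed(cls, path, survey: Interval | None = None) -> "RegionSet":
        """Read a BED4 file; the reserved name ``REF`` marks the reference.

        Coordinates are converted from BED's 0-based half-open convention.
        """
        regions: dict[str, Interval] = {}
        reference: Interval | None = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(
                        f"{path}:{lineno}: expected BED4, got {len(fields)} fields"
                    )
                try:
                    iv = Interval.from_bed(int(fields[1]), int(fields[2]))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
                name = fields[3]
                if name == REFERENCE_NAME:
                    reference = iv
                else:
                    regions[name] = iv
        if reference is None:
            raise ValueError(f"{path}: no interval named {REFERENCE_NAME!r}")
        lo = min([iv.start for iv in regions.values()] + [reference.start])
        hi = max([iv.end for iv in regions.values()] + [reference.end])
        if survey is None:
            survey = Interval(lo, hi)
        return cls(regions=regions, reference_interval=reference, survey_interval=survey)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for name in self.region_names:
                s, e = self.regions[name].to_bed()
                fh.write(f"chrY\t{s}\t{e}\t{name}\n")
            s, e = self.reference_interval.to_bed()
            fh.write(f"chrY\t{s}\t{e}\t{REFERENCE_NAME}\n")


def merge_span(intervals: Iterable[Interval]) -> Interval:
    ivs = list(intervals)
    return Interval(min(i.start for i in ivs), max(i.end for i in ivs))
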