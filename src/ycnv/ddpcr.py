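"""Droplet digital PCR copy-number quantification.

Droplets partition the reaction; the fraction of positive droplets gives
the template concentration by Poisson inversion, and the ratio of target
to single-copy reference concentration gives the copy number. Two
allele-specific assays (T and C channels of a paralogous sequence variant)
are quantified separately and summed for the total copy number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from ._util import round_cn

DEFAULT_DROPLET_VOLUME_NL = 0.85
DEFAULT_DISCREPANCY_THRESHOLD = 0.8

ASSAYS = ("T", "C")


class SaturatedWellError(ValueError):
    """Every droplet positive: concentration is unbounded."""


@dataclass(frozen=True)
class DropletWell:
    """Two-channel droplet counts for one well."""

    sample_id: str
    assay: str
    target_positive: int
    target_total: int
    reference_positive: int
    reference_total: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL

    def __post_init__(self) -> None:
        for pos, tot, name in (
            (self.target_positive, self.target_total, "target"),
            (self.reference_positive, self.reference_total, "reference"),
        ):
            if tot <= 0:
                raise ValueError(f"{name} droplet total must be > 0")
            if not (0 <= pos <= tot):
                raise ValueError(f"{name} positives outside [0, total]")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet volume must be > 0")


def concentration(positive: int, total: int, volume_nl: float = DEFAULT_DROPLET_VOLUME_NL) -> float:
    """Copies per nL by Poisson inversion of the positive-droplet fraction.

    lambda = -ln(1 - positive/total); concentration = lambda / volume.
    """
    if total <= 0:
        raise ValueError("total droplets must be > 0")
    if not (0 <= positive <= total):
        raise ValueError("positives outside [0, total]")
    if positive == total:
        raise SaturatedWellError("all droplets positive; well is saturated")
    if volume_nl <= 0:
        raise ValueError("droplet volume must be > 0")
    lam = -math.log(1.0 - positive / total)
    return lam / volume_nl


def assay_copy_number(well: DropletWell, reference_copies: int = 1) -> float:
    """Copies of the target per genome, against a single-copy reference.

    The droplet volume cancels in the concentration ratio.
    """
    target = concentration(well.target_positive, well.target_total, well.droplet_volume_nl)
    reference = concentration(
        well.reference_positive, well.reference_total, well.droplet_volume_nl
    )
    if reference == 0:
        raise ValueError(
            f"reference concentration is 0 for sample {well.sample_id!r}"
        )
    return target / reference * reference_copies


@dataclass(frozen=True)
class ReplicateSummary:
    """Replicate agreement for one sample/assay."""

    values: tuple[float, ...]
    consensus: float | None
    needs_third_replicate: bool


def combine_replicates(
    values: Sequence[float],
    discrepancy_threshold: float = DEFAULT_DISCREPANCY_THRESHOLD,
) -> ReplicateSummary:
    """Consensus copy number across replicates.

    Exactly two replicates differing by the threshold or more leave no
    consensus and request a third; otherwise the consensus is the mean of
    all replicate values.
    """
    values = tuple(float(v) for v in values)
    if not values:
        raise ValueError("need at least one replicate value")
    if len(values) == 2 and abs(values[0] - values[1]) >= discrepancy_threshold:
        return ReplicateSummary(values=values, consensus=None, needs_third_replicate=True)
    return ReplicateSummary(
        values=values,
        consensus=sum(values) / len(values),
        needs_third_replicate=False,
    )


def total_copy_number(t_assay: float, c_assay: float) -> tuple[float, int]:
    """Total = T-assay + C-assay copies; (real, rounded integer)."""
    if t_assay < 0 or c_assay < 0:
        raise ValueError("assay copy numbers must be >= 0")
    total = t_assay + c_assay
    return total, round_cn(total)


@dataclass(frozen=True)
class AssayResult:
    sample_id: str
    assay: str
    copy_number: float | None
    replicate_values: tuple[float, ...]
    needs_third_replicate: bool


def quantify_wells(
    wells: pd.DataFrame,
    discrepancy_threshold: float = DEFAULT_DISCREPANCY_THRESHOLD,
    reference_copies: int = 1,
) -> pd.DataFrame:
    """Quantify a table of wells into per-sample assay and total copy numbers.

    Input columns: ``sample_id, assay, replicate, target_positive,
    target_total, ref_positive, ref_total``. Output: one row per sample
    with per-assay copy numbers, the re-test flag and, when both assays
    have a consensus, the real and integer total.
    """
    required = {
        "sample_id", "assay", "replicate",
        "target_positive", "target_total", "ref_positive", "ref_total",
    }
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"missing well columns: {sorted(missing)}")

    per_assay: dict[tuple[str, str], ReplicateSummary] = {}
    for (sid, assay), grp in wells.groupby(["sample_id", "assay"], sort=False):
        values = []
        for row in grp.sort_values("replicate").itertuples(index=False):
            well = DropletWell(
                sample_id=str(sid),
                assay=str(assay),
                target_positive=int(row.target_positive),
                target_total=int(row.target_total),
                reference_positive=int(row.ref_positive),
                reference_total=int(row.ref_total),
            )
            values.append(assay_copy_number(well, reference_copies))
        per_assay[(str(sid), str(assay))] = combine_replicates(
            values, discrepancy_threshold
        )

    rows = []
    for sid in wells["sample_id"].astype(str).unique():
        row: dict = {"sample_id": sid}
        consensuses = {}
        for assay in ASSAYS:
            summary = per_assay.get((sid, assay))
            if summary is None:
                row[f"cn_{assay}"] = None
                row[f"needs_third_{assay}"] = False
                continue
            row[f"cn_{assay}"] = summary.consensus
            row[f"needs_third_{assay}"] = summary.needs_third_replicate
            if summary.consensus is not None:
                consensuses[assay] = summary.consensus
        if len(consensuses) == len(ASSAYS):
            total, integer = total_copy_number(consensuses["T"], consensuses["C"])
            row["total_cn"] = total
            row["total_cn_int"] = integer
        else:
            row["total_cn"] = None
            row["total_cn_int"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def read_wells(path) -> pd.DataFrame:
    return pd.read_csv(path)
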