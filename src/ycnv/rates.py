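"""Copy-number mutation rates from SNV-calibrated branch lengths.

Branch lengths measured in SNV counts are converted to generations through
a per-bp per-year SNV mutation rate, the callable sequence length and a
generation time; event counts divided by total branch generations give a
per-father-to-son-transmission mutation rate. The confidence interval of
the tree-based rate propagates only the SNV-rate uncertainty (the rate is
linear in it); direct transmission (trio) rates get exact Clopper-Pearson
binomial intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import NamedTuple

from scipy import stats


@dataclass(frozen=True)
class ClockConstants:
    """Molecular-clock constants for SNV-to-generation conversion."""

    snv_rate_per_bp_year: float = 0.76e-9
    snv_rate_ci: tuple[float, float] = (0.67e-9, 0.86e-9)
    callable_bp: float = 10_300_000
    generation_years: float = 30.0

    def __post_init__(self) -> None:
        lo, hi = self.snv_rate_ci
        if min(self.snv_rate_per_bp_year, lo, hi, self.callable_bp, self.generation_years) <= 0:
            raise ValueError("clock constants must be positive")
        if not (lo <= self.snv_rate_per_bp_year <= hi):
            raise ValueError("snv_rate_ci must bracket the point rate")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "snv_rate_per_bp_year": self.snv_rate_per_bp_year,
                "snv_rate_ci": list(self.snv_rate_ci),
                "callable_bp": self.callable_bp,
                "generation_years": self.generation_years,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, path) -> "ClockConstants":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            snv_rate_per_bp_year=d["snv_rate_per_bp_year"],
            snv_rate_ci=tuple(d["snv_rate_ci"]),
            callable_bp=d["callable_bp"],
            generation_years=d["generation_years"],
        )


class GenerationScale(NamedTuple):
    years_per_snv: float
    generations_per_snv: float
    total_generations: float


def snv_to_generations(
    snv_count: float, clock: ClockConstants = ClockConstants()
) -> GenerationScale:
    """Convert an SNV count into branch time.

    years/SNV = 1 / (rate x callable length); generations/SNV divides by
    the generation time; total generations multiplies by the SNV count.
    """
    if snv_count < 0:
        raise ValueError("snv_count must be >= 0")
    years_per_snv = 1.0 / (clock.snv_rate_per_bp_year * clock.callable_bp)
    generations_per_snv = years_per_snv / clock.generation_years
    return GenerationScale(
        years_per_snv=years_per_snv,
        generations_per_snv=generations_per_snv,
        total_generations=snv_count * generations_per_snv,
    )


@dataclass(frozen=True)
class RateEstimate:
    """A per-transmission copy-number mutation rate with its CI."""

    events: float
    snv_count: float
    years_per_snv: float
    generations_per_snv: float
    total_generations: float
    rate: float
    rate_ci: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "events": self.events,
            "snv_count": self.snv_count,
            "years_per_snv": self.years_per_snv,
            "generations_per_snv": self.generations_per_snv,
            "total_generations": self.total_generations,
            "rate": self.rate,
            "rate_ci": list(self.rate_ci),
        }


def cn_mutation_rate(
    event_count: float,
    snv_count: float,
    clock: ClockConstants = ClockConstants(),
) -> RateEstimate:
    """Events per father-to-son transmission over an SNV-scaled tree.

    rate = K / G where G is the total branch length in generations. The
    rate is proportional to the SNV rate (r = K.mu.L.g / S), so the CI
    substitutes the SNV-rate CI bounds.
    """
    if snv_count <= 0:
        raise ValueError("snv_count must be > 0")
    if event_count < 0:
        raise ValueError("event_count must be >= 0")
    scale = snv_to_generations(snv_count, clock)
    rate = event_count / scale.total_generations
    lo_mu, hi_mu = clock.snv_rate_ci
    ci = (
        rate * lo_mu / clock.snv_rate_per_bp_year,
        rate * hi_mu / clock.snv_rate_per_bp_year,
    )
    return RateEstimate(
        events=event_count,
        snv_count=snv_count,
        years_per_snv=scale.years_per_snv,
        generations_per_snv=scale.generations_per_snv,
        total_generations=scale.total_generations,
        rate=rate,
        rate_ci=ci,
    )


class TransmissionRate(NamedTuple):
    point: float
    ci_low: float
    ci_high: float


def transmission_rate_ci(
    mutations: int, transmissions: int, confidence: float = 0.95
) -> TransmissionRate:
    """Exact Clopper-Pearson interval for a direct transmission rate.

    Beta-quantile form: lower = B(a/2; k, n-k+1), upper = B(1-a/2; k+1,
    n-k), with the conventional 0 lower bound at k=0 and 1 upper bound at
    k=n.
    """
    if transmissions <= 0:
        raise ValueError("transmissions must be > 0")
    if not (0 <= mutations <= transmissions):
        raise ValueError("mutations must lie in [0, transmissions]")
    if not (0 < confidence < 1):
        raise ValueError("confidence must be in (0, 1)")
    alpha = 1.0 - confidence
    k, n = mutations, transmissions
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return TransmissionRate(point=k / n, ci_low=lo, ci_high=hi)
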