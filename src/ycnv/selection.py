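"""Selection tests on copy-number evolution.

Two tests: an exact binomial test for a bias between increase and decrease
events (directional selection), and a neutral Monte-Carlo null in which a
fixed set of signed events is scattered over the phylogeny in proportion
to branch length; tip-copy-number variance far below the simulated null
indicates stabilizing selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .events import Phylogeny, _node_label

# default signed event-size histogram: magnitude -> count, decreases
# negative. Derived by scaling a confident-event histogram up to the full
# event count (see events.scale_confident_histogram).
DEFAULT_EVENT_SIZES: dict[int, int] = {
    -1: 227, -2: 54, -3: 16, -4: 13, -5: 3,
    1: 185, 2: 42, 3: 19, 4: 4,
}


class DirectionBias(NamedTuple):
    p_value: float
    decrease_proportion: float
    ci_low: float
    ci_high: float


def direction_bias_test(increases: int, decreases: int, confidence: float = 0.95) -> DirectionBias:
    """Two-sided exact binomial test of decreases against p = 0.5.

    Also reports the decrease proportion with its exact Clopper-Pearson
    interval.
    """
    if increases < 0 or decreases < 0:
        raise ValueError("counts must be >= 0")
    n = increases + decreases
    if n == 0:
        raise ValueError("need at least one event")
    test = stats.binomtest(decreases, n, 0.5, alternative="two-sided")
    ci = test.proportion_ci(confidence_level=confidence, method="exact")
    return DirectionBias(
        p_value=float(test.pvalue),
        decrease_proportion=decreases / n,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )


@dataclass(frozen=True)
class NeutralSimConfig:
    """Configuration of the branch-length-proportional neutral null."""

    event_sizes: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_SIZES)
    )
    root_cn: int = 8
    replicates: int = 1000
    seed: int | None = None
    floor_at_zero: bool = True
    sample_variance: bool = False  # population variance by default

    def __post_init__(self) -> None:
        if self.root_cn < 0:
            raise ValueError("root_cn must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(v < 0 for v in self.event_sizes.values()):
            raise ValueError("event counts must be >= 0")
        if 0 in self.event_sizes:
            raise ValueError("event size 0 is not a change")


@dataclass(frozen=True)
class NeutralSimResult:
    variances: np.ndarray
    tip_cn: np.ndarray | None  # (replicates, n_tips) when kept
    tip_labels: tuple[str, ...]

    def tip_map(self, replicate: int) -> dict[str, int]:
        if self.tip_cn is None:
            raise ValueError("tip states were not retained")
        return dict(zip(self.tip_labels, (int(v) for v in self.tip_cn[replicate])))


def _edge_arrays(phylo: Phylogeny):
    """Edges (non-root nodes) in preorder with lengths and parent indexing."""
    nodes = [n for n in phylo.tree.preorder_node_iter()]
    node_index = {id(n): i for i, n in enumerate(nodes)}
    lengths = np.array(
        [0.0 if n.parent_node is None else float(n.edge.length or 0.0) for n in nodes]
    )
    parents = np.array(
        [-1 if n.parent_node is None else node_index[id(n.parent_node)] for n in nodes],
        dtype=np.int64,
    )
    tip_idx = np.array([i for i, n in enumerate(nodes) if n.is_leaf()], dtype=np.int64)
    tip_labels = tuple(_node_label(nodes[i]) for i in tip_idx)
    return nodes, lengths, parents, tip_idx, tip_labels


def simulate_neutral(
    phylo: Phylogeny,
    config: NeutralSimConfig,
    keep_tips: bool = False,
) -> NeutralSimResult:
    """Scatter the configured events over the tree, replicate by replicate.

    Each event lands on an edge with probability proportional to the
    edge's branch length (independent multinomial placement). A tip's copy
    number is the root state plus the signed sizes of all events on its
    root-to-tip path, floored at zero when configured. Per-replicate
    variance across tips is returned (population variance unless
    ``sample_variance``).
    """
    nodes, lengths, parents, tip_idx, tip_labels = _edge_arrays(phylo)
    total_len = lengths.sum()
    if total_len <= 0:
        raise ValueError("tree has zero total branch length")
    probs = lengths / total_len
    rng = np.random.default_rng(config.seed)
    n_nodes = len(nodes)
    reps = config.replicates

    variances = np.empty(reps, dtype=float)
    kept = np.empty((reps, len(tip_idx)), dtype=np.int64) if keep_tips else None
    ddof = 1 if config.sample_variance else 0

    sizes = [(int(s), int(c)) for s, c in config.event_sizes.items() if c > 0]
    for r in range(reps):
        delta = np.zeros(n_nodes, dtype=np.int64)
        for size, count in sizes:
            delta += size * rng.multinomial(count, probs)
        # accumulate root-to-tip sums down the preorder
        cum = np.empty(n_nodes, dtype=np.int64)
        cum[0] = config.root_cn
        for i in range(1, n_nodes):
            cum[i] = cum[parents[i]] + delta[i]
        tips = cum[tip_idx]
        if config.floor_at_zero:
            tips = np.maximum(tips, 0)
        variances[r] = np.var(tips, ddof=ddof)
        if keep_tips:
            kept[r] = tips
    return NeutralSimResult(variances=variances, tip_cn=kept, tip_labels=tip_labels)


@dataclass(frozen=True)
class VarianceTestResult:
    empirical_variance: float
    simulated_variances: np.ndarray
    percentile_of_empirical: float
    null_ci: tuple[float, float]
    threshold_percentile: float
    verdict: str  # below_null | within_null | above_null


def variance_percentile_test(
    empirical_variance: float,
    simulated: Sequence[float] | np.ndarray,
    threshold_percentile: float = 0.5,
) -> VarianceTestResult:
    """Rank the observed variance within the simulated neutral null.

    The percentile rank uses midranks for ties; the verdict is below_null
    when the rank falls under *threshold_percentile* (and symmetrically
    above_null over ``100 - threshold``). The 2.5th/97.5th percentiles of
    the null (linear interpolation) are reported as the null interval.
    """
    sim = np.asarray(simulated, dtype=float)
    if sim.size == 0:
        raise ValueError("simulated variance list is empty")
    less = float(np.sum(sim < empirical_variance))
    equal = float(np.sum(sim == empirical_variance))
    percentile = 100.0 * (less + 0.5 * equal) / sim.size
    lo, hi = np.percentile(sim, [2.5, 97.5])
    if percentile < threshold_percentile:
        verdict = "below_null"
    elif percentile > 100.0 - threshold_percentile:
        verdict = "above_null"
    else:
        verdict = "within_null"
    return VarianceTestResult(
        empirical_variance=float(empirical_variance),
        simulated_variances=sim,
        percentile_of_empirical=percentile,
        null_ci=(float(lo), float(hi)),
        threshold_percentile=threshold_percentile,
        verdict=verdict,
    )
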