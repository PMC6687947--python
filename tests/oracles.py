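"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: parsimony by
exhaustive enumeration of internal labelings, interval means by per-base
summation, and Beta quantiles via direct incomplete-beta inversion.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_parsimony(topology, tip_states: dict[str, int]) -> int:
    """Minimum unit-cost changes by enumerating every internal labeling.

    *topology* is a nested tuple tree whose leaves are tip names, e.g.
    ``(("A", "B"), ("C", "D"))``. The label alphabet is every integer
    between the observed min and max.
    """
    internals: list = []

    def collect(node):
        if isinstance(node, tuple):
            internals.append(node)
            for child in node:
                collect(child)

    collect(topology)
    states = sorted(set(tip_states.values()))
    alphabet = list(range(min(states), max(states) + 1))

    def cost(node, labeling) -> tuple[int, int]:
        """(state of node, cost of subtree below and including its edge)."""
        if not isinstance(node, tuple):
            return tip_states[node], 0
        own = labeling[id(node)]
        total = 0
        for child in node:
            child_state, child_cost = cost(child, labeling)
            total += child_cost + (1 if child_state != own else 0)
        return own, total

    best = None
    for combo in itertools.product(alphabet, repeat=len(internals)):
        labeling = {id(n): s for n, s in zip(internals, combo)}
        _, total = cost(topology, labeling)
        if best is None or total < best:
            best = total
    return best


def random_topology(n_tips: int, rng: np.random.Generator):
    """Random binary nested-tuple topology over tips t1..tn."""
    nodes: list = [f"t{i + 1}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append((a, b))
    return nodes[0]


def topology_to_newick(node) -> str:
    def fmt(n):
        if isinstance(n, tuple):
            return "(" + ",".join(fmt(c) for c in n) + "):1"
        return f"{n}:1"

    return fmt(node).rsplit(":", 1)[0] + ";"


def per_base_interval_mean(starts, depths, window_size, span_end, interval) -> float:
    """Overlap-weighted interval mean recomputed base by base."""
    total = 0.0
    weight = 0
    for start, depth in zip(starts, depths):
        end = min(start + window_size - 1, span_end)
        for pos in range(int(start), int(end) + 1):
            if interval.start <= pos <= interval.end:
                total += depth
                weight += 1
    if weight == 0:
        raise ValueError("no overlap")
    return total / weight


def beta_quantile_bisect(q: float, a: float, b: float, tol: float = 1e-12) -> float:
    """Beta quantile by bisection on the regularized incomplete beta."""
    from scipy.special import betainc

    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if betainc(a, b, mid) < q:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def binom_two_sided_pvalue(k: int, n: int, p: float = 0.5) -> float:
    """Two-sided exact binomial p-value by PMF summation (small-n oracle)."""
    from math import comb

    pmf = [comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    obs = pmf[k]
    return float(sum(v for v in pmf if v <= obs * (1 + 1e-12)))
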