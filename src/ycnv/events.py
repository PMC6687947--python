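"""Copy-number change events on a haploid phylogeny.

Tip copy-number states are placed on a rooted tree (branch lengths in SNV
counts) and the minimum number of state-change events explaining them is
computed by unit-cost parsimony: any change on an edge costs 1 regardless
of how many copies it gains or loses. A clade-modal heuristic labeling is
provided for comparison. Events are classified by direction, magnitude and
confidence (whether both endpoint states are fixed across every optimal
labeling).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

INF = 10**9

INCREASE = "increase"
DECREASE = "decrease"
AMBIGUOUS = "ambiguous"


class TreeError(ValueError):
    pass


@dataclass
class Phylogeny:
    """A rooted tree with optional per-tip copy-number states.

    Edge lengths carry SNV counts. Internal nodes get stable synthetic
    labels on construction so events can be addressed by the label of the
    edge's child node. ``edge_generations`` optionally carries branch
    lengths in generations (used by synthetic data with known clocks).
    """

    tree: dendropy.Tree
    tip_states: dict[str, int] | None = None
    edge_generations: dict[str, float] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        counter = 0
        for node in self.tree.preorder_node_iter():
            label = _node_label(node)
            if label is None:
                while f"in{counter}" in seen:
                    counter += 1
                label = f"in{counter}"
                node.label = label
            if label in seen:
                raise TreeError(f"duplicate node label {label!r}")
            seen.add(label)
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeError("negative edge length")

    # -- structure ---------------------------------------------------------
    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def tip_labels(self) -> list[str]:
        return [_node_label(n) for n in self.tree.leaf_node_iter()]

    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def total_branch_length(self) -> float:
        return float(
            sum(e.length or 0.0 for e in self.tree.preorder_edge_iter())
        )

    def total_generations(self) -> float:
        if self.edge_generations is None:
            raise TreeError("tree carries no generation-scaled branch lengths")
        return float(sum(self.edge_generations.values()))

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- states ------------------------------------------------------------
    def with_states(self, states: Mapping[str, int], prune_missing: bool = False) -> "Phylogeny":
        return attach_tip_states(self, states, prune_missing=prune_missing)

    def states_complete(self) -> bool:
        if self.tip_states is None:
            return False
        return all(t in self.tip_states for t in self.tip_labels())


def _node_label(node: dendropy.Node) -> str | None:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or None


def read_tree(source) -> Phylogeny:
    """Parse a rooted Newick tree from a string or file path."""
    text = str(source)
    if "(" not in text:  # path, not newick text
        with open(text) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise TreeError(f"duplicate tip labels: {exc}") from exc
    labels = [
        _node_label(n) for n in tree.leaf_node_iter() if _node_label(n) is not None
    ]
    dupes = [l for l, c in Counter(labels).items() if c > 1]
    if dupes:
        raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
    return Phylogeny(tree=tree)


def attach_tip_states(
    phylo: Phylogeny,
    states: Mapping[str, int] | pd.DataFrame,
    prune_missing: bool = False,
) -> Phylogeny:
    """Attach integer copy-number states to tips by label.

    *states* may be a mapping or a two-column table
    (``sample_id  copy_number``). Ids absent from the tree raise; tips
    without a state are pruned when *prune_missing* is set, otherwise left
    unlabeled (and rejected later by operations that need complete states).
    """
    if isinstance(states, pd.DataFrame):
        cols = list(states.columns[:2])
        states = dict(
            zip(states[cols[0]].astype(str), states[cols[1]].astype(int))
        )
    states = {str(k): int(v) for k, v in states.items()}
    for sid, cn in states.items():
        if cn < 0:
            raise ValueError(f"negative copy number for {sid!r}")
    tips = set(phylo.tip_labels())
    unknown = sorted(set(states) - tips)
    if unknown:
        raise TreeError(f"state table ids not in tree: {unknown}")

    tree = phylo.tree.clone(depth=1)
    result = Phylogeny(tree=tree, edge_generations=phylo.edge_generations)
    if prune_missing:
        missing = tips - set(states)
        if missing:
            keep = [
                n.taxon for n in tree.leaf_node_iter()
                if _node_label(n) in states and n.taxon is not None
            ]
            tree.retain_taxa(keep)
            result = Phylogeny(tree=tree, edge_generations=phylo.edge_generations)
    result.tip_states = states
    return result


def read_tip_states(path) -> dict[str, int]:
    """Read a ``sample_id<TAB>copy_number`` table (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 1] is not None and not df.iloc[0, 1].lstrip("-").isdigit():
        df = df.iloc[1:]
    return {str(r[0]): int(r[1]) for r in df.itertuples(index=False)}


# ---------------------------------------------------------------------------
# ancestral state reconstruction


@dataclass(frozen=True)
class AncestralAssignment:
    """One labeling of every node, plus per-node ambiguity flags.

    ``ambiguous[label]`` is True when the node's state is not unique among
    the optimal labelings (parsimony) or when the clade mode was tied
    (heuristic).
    """

    states: Mapping[str, int]
    ambiguous: Mapping[str, bool]
    method: str


def _alphabet(phylo: Phylogeny) -> np.ndarray:
    observed = [phylo.tip_states[t] for t in phylo.tip_labels()]
    # include pass-through intermediate states between the observed extremes
    return np.arange(min(observed), max(observed) + 1)


def min_event_labeling(phylo: Phylogeny) -> tuple[AncestralAssignment, int]:
    """Unit-cost parsimony over the integer state alphabet.

    Dynamic programming up the tree gives the minimum number of change
    events; a re-rooting pass computes, for every node, the full set of
    states it takes in *any* minimum-event labeling (the ambiguity flag).
    One concrete optimal labeling is returned, chosen deterministically
    (parent state preferred, then the smallest state). Multifurcations are
    handled natively.

    Returns ``(assignment, minimum_event_count)``.
    """
    if phylo.tip_states is None or not phylo.states_complete():
        raise TreeError("all tips must carry copy-number states")
    if phylo.n_tips() < 2:
        raise TreeError("need at least 2 tips")

    alphabet = _alphabet(phylo)
    index = {int(s): i for i, s in enumerate(alphabet)}
    A = len(alphabet)

    up: dict[dendropy.Node, np.ndarray] = {}
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            cost = np.full(A, INF, dtype=np.int64)
            cost[index[phylo.tip_states[_node_label(node)]]] = 0
        else:
            cost = np.zeros(A, dtype=np.int64)
            for child in node.child_nodes():
                c = up[child]
                cost += np.minimum(c, c.min() + 1)
        up[node] = cost

    root = phylo.root
    opt = int(up[root].min())

    # downward pass: cost of the rest of the tree given this node's state
    down: dict[dendropy.Node, np.ndarray] = {root: np.zeros(A, dtype=np.int64)}
    for node in phylo.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        contribs = {c: np.minimum(up[c], up[c].min() + 1) for c in node.child_nodes()}
        total = sum(contribs.values()) + down[node]
        for child in node.child_nodes():
            above = total - contribs[child]
            down[child] = np.minimum(above, above.min() + 1)

    mpr_sets: dict[str, np.ndarray] = {}
    for node in phylo.tree.preorder_node_iter():
        combined = up[node] + down[node]
        mpr_sets[_node_label(node)] = alphabet[combined == opt]

    # one deterministic optimal labeling
    states: dict[str, int] = {}
    for node in phylo.tree.preorder_node_iter():
        label = _node_label(node)
        if node.parent_node is None:
            choices = alphabet[up[node] == opt]
            states[label] = int(choices.min())
        else:
            parent_state = states[_node_label(node.parent_node)]
            score = up[node] + 1
            score[index[parent_state]] -= 1
            best = score.min()
            if score[index[parent_state]] == best:
                states[label] = parent_state
            else:
                states[label] = int(alphabet[score == best].min())

    n_changes = sum(
        1
        for node in phylo.tree.preorder_node_iter()
        if node.parent_node is not None
        and states[_node_label(node)] != states[_node_label(node.parent_node)]
    )
    assert n_changes == opt, "chosen labeling does not achieve the optimum"

    ambiguous = {label: len(s) > 1 for label, s in mpr_sets.items()}
    assignment = AncestralAssignment(
        states=states, ambiguous=ambiguous, method="min-event"
    )
    return assignment, opt


def clade_mode_labeling(phylo: Phylogeny) -> AncestralAssignment:
    """Heuristic labeling: each internal node takes the modal copy number
    of its subtree's tips.

    Ties resolve toward the parent's (already resolved) state; a root tie
    resolves to the global modal state, then to the smaller copy number.
    """
    if phylo.tip_states is None or not phylo.states_complete():
        raise TreeError("all tips must carry copy-number states")

    counts: dict[dendropy.Node, Counter] = {}
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            counts[node] = Counter({phylo.tip_states[_node_label(node)]: 1})
        else:
            acc: Counter = Counter()
            for child in node.child_nodes():
                acc.update(counts[child])
            counts[node] = acc

    global_counts = counts[phylo.root]
    gmax = max(global_counts.values())
    global_modes = sorted(s for s, c in global_counts.items() if c == gmax)

    states: dict[str, int] = {}
    ambiguous: dict[str, bool] = {}
    for node in phylo.tree.preorder_node_iter():
        label = _node_label(node)
        if node.is_leaf():
            states[label] = phylo.tip_states[label]
            ambiguous[label] = False
            continue
        cnt = counts[node]
        m = max(cnt.values())
        modes = sorted(s for s, c in cnt.items() if c == m)
        ambiguous[label] = len(modes) > 1
        if len(modes) == 1:
            states[label] = modes[0]
        elif node.parent_node is not None and states[_node_label(node.parent_node)] in modes:
            states[label] = states[_node_label(node.parent_node)]
        elif node.parent_node is None:
            in_modes = [s for s in global_modes if s in modes]
            states[label] = in_modes[0] if in_modes else modes[0]
        else:
            states[label] = modes[0]
    return AncestralAssignment(states=states, ambiguous=ambiguous, method="clade-mode")


# ---------------------------------------------------------------------------
# events


@dataclass(frozen=True)
class Event:
    """A copy-number change on the edge above ``child``."""

    child: str
    parent_state: int
    child_state: int
    magnitude: int
    direction: str
    confident: bool


@dataclass(frozen=True)
class EventSet:
    events: tuple[Event, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def total(self) -> int:
        return len(self.events)

    def direction_counts(self) -> dict[str, int]:
        out = {INCREASE: 0, DECREASE: 0, AMBIGUOUS: 0}
        for e in self.events:
            out[e.direction] += 1
        return out

    def magnitude_histogram(self, confident_only: bool = False, signed: bool = False) -> dict[int, int]:
        hist: Counter = Counter()
        for e in self.events:
            if confident_only and not e.confident:
                continue
            if signed:
                sign = 1 if e.direction == INCREASE else -1
                if e.direction == AMBIGUOUS:
                    continue
                hist[sign * e.magnitude] += 1
            else:
                hist[e.magnitude] += 1
        return dict(hist)

    def confident(self) -> "EventSet":
        return EventSet(tuple(e for e in self.events if e.confident))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "edge_child_id": e.child,
                    "parent_state": e.parent_state,
                    "child_state": e.child_state,
                    "magnitude": e.magnitude,
                    "direction": e.direction,
                    "confident": e.confident,
                }
                for e in self.events
            ],
            columns=[
                "edge_child_id", "parent_state", "child_state",
                "magnitude", "direction", "confident",
            ],
        )


def classify_events(assignment: AncestralAssignment, phylo: Phylogeny) -> EventSet:
    """One event per edge whose endpoint states differ.

    Direction is the sign of (child - parent); when either endpoint state
    is ambiguous across optimal labelings the direction is reported as
    ambiguous and the event is not confident.
    """
    events = []
    for node in phylo.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        child = _node_label(node)
        parent = _node_label(node.parent_node)
        ps, cs = assignment.states[parent], assignment.states[child]
        if ps == cs:
            continue
        uncertain = assignment.ambiguous[parent] or assignment.ambiguous[child]
        if uncertain:
            direction = AMBIGUOUS
        else:
            direction = INCREASE if cs > ps else DECREASE
        events.append(
            Event(
                child=child,
                parent_state=ps,
                child_state=cs,
                magnitude=abs(cs - ps),
                direction=direction,
                confident=not uncertain,
            )
        )
    return EventSet(tuple(events))


def filter_events(
    events: EventSet,
    min_magnitude: int = 1,
    cn_range: tuple[int, int] | None = None,
) -> EventSet:
    """Conservative subset: magnitude >= *min_magnitude* and both endpoint
    states inside *cn_range* (inclusive)."""
    if cn_range is not None and cn_range[0] > cn_range[1]:
        raise ValueError("cn_range low > high")
    kept = []
    for e in events.events:
        if e.magnitude < min_magnitude:
            continue
        if cn_range is not None:
            lo, hi = cn_range
            if not (lo <= e.parent_state <= hi and lo <= e.child_state <= hi):
                continue
        kept.append(e)
    return EventSet(tuple(kept))


def scale_confident_histogram(
    confident: Mapping[int, int], total_events: int
) -> dict[int, int]:
    """Scale a size histogram of confident events up to the total count.

    Each class is multiplied by ``total / sum(confident)`` and rounded by
    the largest-remainder method so the result sums exactly to
    *total_events*. Keys may be signed (direction-carrying) magnitudes.
    """
    if not confident or sum(confident.values()) <= 0:
        raise ValueError("empty confident histogram")
    s = sum(confident.values())
    if total_events < s:
        raise ValueError("total_events smaller than the confident count")
    factor = total_events / s
    raw = {k: v * factor for k, v in confident.items()}
    floored = {k: int(np.floor(v)) for k, v in raw.items()}
    shortfall = total_events - sum(floored.values())
    remainders = sorted(
        raw, key=lambda k: (raw[k] - floored[k], -abs(k)), reverse=True
    )
    out = dict(floored)
    for k in remainders[:shortfall]:
        out[k] += 1
    return out


def count_events(
    phylo: Phylogeny,
    method: str = "parsimony",
) -> tuple[AncestralAssignment, EventSet]:
    """Convenience wrapper: label ancestral states and classify events."""
    if method == "parsimony":
        assignment, _ = min_event_labeling(phylo)
    elif method == "clade-mode":
        assignment = clade_mode_labeling(phylo)
    else:
        raise ValueError(f"unknown method {method!r}")
    return assignment, classify_events(assignment, phylo)
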