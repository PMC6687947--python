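"""Synthetic-data generators with recorded ground truth.

Everything the pipeline consumes can be generated here with the
statistical structure the analysis assumes: rooted trees whose branch
lengths carry both generations and Poisson-sampled SNV counts, tip copy
numbers evolved under a known signed-event process, windowed depth
profiles under the read-pooling model, two-channel droplet counts and
father-son transmission pairs. All generators are seed-deterministic and
return enough truth to score every downstream operation.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .ddpcr import DropletWell
from .depth import CopyModelConfig, DepthProfile
from .events import Phylogeny, _node_label
from .rates import ClockConstants, snv_to_generations
from .regions import RegionSet
from .selection import DEFAULT_EVENT_SIZES


def _default_generations_per_snv(clock: ClockConstants | None = None) -> float:
    return snv_to_generations(1, clock or ClockConstants()).generations_per_snv


def simulate_tree(
    n_tips: int,
    model: str = "yule",
    total_generations_target: float = 250_000.0,
    seed: int | None = None,
    generations_per_snv: float | None = None,
) -> Phylogeny:
    """A random rooted binary tree scaled to a target total branch length.

    ``model`` is ``kingman`` (neutral coalescent) or ``yule`` (pure
    birth). Branch lengths are rescaled so the tree's total length in
    generations matches the target; per-edge SNV counts are then drawn
    Poisson(generations / generations_per_snv) and stored as the edge
    lengths, with the generation-scale lengths kept alongside.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if total_generations_target <= 0:
        raise ValueError("total_generations_target must be > 0")
    rng = np.random.default_rng(seed)
    if model == "kingman":
        root, gen_lengths = _kingman_topology(n_tips, rng)
    elif model == "yule":
        root, gen_lengths = _yule_topology(n_tips, rng)
    else:
        raise ValueError(f"unknown tree model {model!r}")

    total = sum(gen_lengths.values())
    factor = total_generations_target / total
    gps = generations_per_snv or _default_generations_per_snv()

    tree = dendropy.Tree(seed_node=root)
    tree.is_rooted = True
    for leaf in tree.leaf_node_iter():
        taxon = dendropy.Taxon(label=leaf.label)
        tree.taxon_namespace.add_taxon(taxon)
        leaf.taxon = taxon
        leaf.label = None
    phylo = Phylogeny(tree=tree)  # assigns internal labels
    edge_generations: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        label = _node_label(node)
        gens = gen_lengths[id(node)] * factor
        edge_generations[label] = gens
        node.edge.length = float(rng.poisson(gens / gps))
    phylo.edge_generations = edge_generations
    return phylo


def _new_leaf(i: int) -> dendropy.Node:
    node = dendropy.Node()
    node.label = f"t{i + 1}"
    return node


def _kingman_topology(n: int, rng: np.random.Generator):
    """Backward-in-time pairwise coalescence; returns (root, lengths-by-id)."""
    lineages = [_new_leaf(i) for i in range(n)]
    heights = {id(node): 0.0 for node in lineages}
    lengths: dict[int, float] = {}
    h = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        h += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        parent = dendropy.Node()
        for child in (a, b):
            parent.add_child(child)
            lengths[id(child)] = h - heights[id(child)]
        heights[id(parent)] = h
        lineages.append(parent)
    return lineages[0], lengths


def _yule_topology(n: int, rng: np.random.Generator):
    """Forward-in-time pure-birth process; returns (root, lengths-by-id)."""
    root = dendropy.Node()
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    t = 0.0
    lengths: dict[int, float] = {}
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / k)
        idx = int(rng.integers(k))
        node, birth = active.pop(idx)
        lengths[id(node)] = t - birth
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t += rng.exponential(1.0 / n)
    for i, (node, birth) in enumerate(active):
        lengths[id(node)] = t - birth
        node.label = f"t{i + 1}"
    return root, lengths


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one copy-number evolution realization."""

    phylo: Phylogeny
    events: tuple[tuple[str, int], ...]  # (edge child label, signed size)
    true_tip_cn: Mapping[str, int]
    total_events: int
    true_rate: float  # events per generation-transmission
    seed: int | None

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "events": [list(e) for e in self.events],
                "true_tip_cn": dict(self.true_tip_cn),
                "total_events": self.total_events,
                "true_rate": self.true_rate,
                "seed": self.seed,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def _signed_size_sampler(size_distribution: Mapping[int, float]):
    sizes = np.array(sorted(size_distribution), dtype=np.int64)
    weights = np.array([size_distribution[int(s)] for s in sizes], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("size distribution needs non-negative weights, positive total")
    if 0 in sizes:
        raise ValueError("size 0 is not a change")
    probs = weights / weights.sum()
    return sizes, probs


def _reflect(value: int, lo: int, hi: int) -> int:
    """Fold *value* back into [lo, hi] by reflection at the bounds."""
    span = hi - lo
    if span == 0:
        return lo
    while not (lo <= value <= hi):
        if value > hi:
            value = hi - (value - hi)
        elif value < lo:
            value = lo + (lo - value)
    return value


def evolve_cn(
    phylo: Phylogeny,
    rate: float,
    size_distribution: Mapping[int, float] | None = None,
    root_cn: int = 8,
    floor_at_zero: bool = True,
    seed: int | None = None,
    bounds: tuple[int, int] | None = None,
) -> SyntheticTruth:
    """Evolve copy numbers along the tree under a Poisson event process.

    Events per edge are Poisson(rate x edge generations); each event's
    signed size is drawn from *size_distribution* (default: the built-in
    signed histogram). Tip states are the root state plus the path sum of
    signed sizes, floored at zero when configured. With *bounds* set the
    running state reflects at the bounds after every event (a stabilizing
    constraint), overriding the floor.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if phylo.edge_generations is None:
        raise ValueError("tree must carry generation-scaled branch lengths")
    if bounds is not None:
        lo, hi = bounds
        if not (0 <= lo <= hi):
            raise ValueError("bounds must satisfy 0 <= low <= high")
        if not (lo <= root_cn <= hi):
            raise ValueError("root_cn outside bounds")
    sizes, probs = _signed_size_sampler(size_distribution or DEFAULT_EVENT_SIZES)
    rng = np.random.default_rng(seed)

    events: list[tuple[str, int]] = []
    state: dict[int, int] = {id(phylo.root): root_cn}
    tip_cn: dict[str, int] = {}
    for node in phylo.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        label = _node_label(node)
        gens = phylo.edge_generations[label]
        k = int(rng.poisson(rate * gens))
        cn = state[id(node.parent_node)]
        for size in rng.choice(sizes, size=k, p=probs):
            events.append((label, int(size)))
            cn += int(size)
            if bounds is not None:
                cn = _reflect(cn, *bounds)
        state[id(node)] = cn
        if node.is_leaf():
            tip_cn[label] = max(0, cn) if (floor_at_zero and bounds is None) else cn

    labeled = phylo.with_states(tip_cn)
    total_gens = phylo.total_generations()
    return SyntheticTruth(
        phylo=labeled,
        events=tuple(events),
        true_tip_cn=tip_cn,
        total_events=len(events),
        true_rate=len(events) / total_gens,
        seed=seed,
    )


def emulate_depth(
    cn_by_region: Mapping[str, int] | int,
    base_depth: float = 8.0,
    noise: str = "none",
    regions: RegionSet | None = None,
    seed: int | None = None,
    window_size: int = 5000,
    sample_id: str = "synthetic",
    model: CopyModelConfig = CopyModelConfig(),
) -> DepthProfile:
    """A windowed depth profile under the read-pooling model.

    Reads from every gene copy pool over the fixed reference footprint, so
    every window overlapping a gene region gets depth
    ``base_depth x (gene copies + pseudogene equivalents) / copy
    equivalents``; all other windows (including the single-copy reference
    interval) get ``base_depth``. ``noise='poisson'`` resamples each
    window mean as a Poisson read count over the window.
    """
    if base_depth <= 0:
        raise ValueError("base_depth must be > 0")
    if noise not in ("none", "poisson"):
        raise ValueError(f"unknown noise model {noise!r}")
    regions = regions or RegionSet()
    if isinstance(cn_by_region, (int, np.integer)):
        total_copies = int(cn_by_region)
    else:
        unknown = set(cn_by_region) - set(regions.regions)
        if unknown:
            raise ValueError(f"unknown regions: {sorted(unknown)}")
        total_copies = int(sum(cn_by_region.values()))
    if total_copies < 0:
        raise ValueError("copy numbers must be >= 0")

    survey = regions.survey_interval
    starts = np.arange(survey.start, survey.end + 1, window_size, dtype=np.int64)
    depths = np.full(len(starts), base_depth, dtype=float)
    pooled = (
        base_depth
        * (total_copies + model.pseudogene_equivalents)
        / model.copy_equivalents_reference
    )
    profile = DepthProfile(
        sample_id=sample_id, window_size=window_size,
        starts=starts, depths=depths, span=survey,
    )
    in_region = np.zeros(len(starts), dtype=bool)
    for iv in regions.regions.values():
        in_region |= profile.overlap_weights(iv) > 0
    depths[in_region] = pooled

    if noise == "poisson":
        rng = np.random.default_rng(seed)
        widths = profile.window_widths()
        depths = rng.poisson(depths * widths) / widths
    return DepthProfile(
        sample_id=sample_id, window_size=window_size,
        starts=starts, depths=depths, span=survey,
    )


class DropletTruth(dict):
    """Truth record for one emulated well (lambdas and the target CN)."""


def emulate_droplets(
    true_cn: float,
    droplets: int = 12_000,
    mean_ref_lambda: float = 0.2,
    seed: int | None = None,
    sample_id: str = "synthetic",
    assay: str = "T",
) -> tuple[DropletWell, DropletTruth]:
    """Two-channel droplet counts for a known target copy number.

    Positive counts are binomial draws with success probability
    ``1 - exp(-lambda)`` per channel; the target channel's lambda is the
    reference lambda times the copy number.
    """
    if droplets <= 0:
        raise ValueError("droplets must be > 0")
    if not (0 < mean_ref_lambda < 5):
        raise ValueError("mean_ref_lambda must be in (0, 5)")
    if true_cn < 0:
        raise ValueError("true_cn must be >= 0")
    target_lambda = mean_ref_lambda * true_cn
    if target_lambda > 5:
        warnings.warn(
            f"target lambda {target_lambda:.2f} > 5: saturation risk",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    ref_pos = int(rng.binomial(droplets, 1.0 - np.exp(-mean_ref_lambda)))
    tgt_pos = int(rng.binomial(droplets, 1.0 - np.exp(-target_lambda)))
    well = DropletWell(
        sample_id=sample_id,
        assay=assay,
        target_positive=tgt_pos,
        target_total=droplets,
        reference_positive=ref_pos,
        reference_total=droplets,
    )
    truth = DropletTruth(
        true_cn=float(true_cn),
        ref_lambda=mean_ref_lambda,
        target_lambda=target_lambda,
        droplets=droplets,
    )
    return well, truth


def make_father_son(
    n_pairs: int,
    rate: float,
    size_distribution: Mapping[int, float] | None = None,
    seed: int | None = None,
    father_cn: int = 8,
) -> tuple[pd.DataFrame, dict]:
    """Father-son copy-number pairs with a known per-transmission rate.

    Each son mutates with probability ``min(rate, 1)``; mutated sons shift
    by one signed size drawn from the distribution (floored at zero).
    Returns the pair table and a truth record with the mutation flags.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    sizes, probs = _signed_size_sampler(size_distribution or DEFAULT_EVENT_SIZES)
    rng = np.random.default_rng(seed)
    mutated = rng.random(n_pairs) < min(rate, 1.0)
    rows = []
    for i in range(n_pairs):
        son = father_cn
        if mutated[i]:
            son = max(0, father_cn + int(rng.choice(sizes, p=probs)))
        rows.append(
            {"pair_id": f"pair{i + 1}", "father_cn": father_cn, "son_cn": son}
        )
    table = pd.DataFrame(rows)
    truth = {
        "n_pairs": n_pairs,
        "rate": rate,
        "mutated": [bool(m) for m in mutated],
        "n_mutations": int(mutated.sum()),
        "seed": seed,
    }
    return table, truth


def simulate_all(
    out_dir,
    seed: int,
    n_tips: int = 100,
    total_generations_target: float = 250_000.0,
    rate: float = 2.2e-3,
    n_depth_samples: int = 8,
    n_trio_pairs: int = 77,
    base_depth: float = 8.0,
) -> dict:
    """Emit a full synthetic input set: tree, tip states, depth tables,
    droplet wells, trio pairs and a truth record.

    Files written under *out_dir*: ``tree.nwk``, ``cn.tsv``,
    ``depth/<sample>.tsv``, ``wells.csv``, ``trios.tsv``, ``truth.json``.
    Returns the truth record as a dict.
    """
    os.makedirs(out_dir, exist_ok=True)
    depth_dir = os.path.join(out_dir, "depth")
    os.makedirs(depth_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=5)]

    phylo = simulate_tree(
        n_tips, total_generations_target=total_generations_target, seed=sub[0]
    )
    truth = evolve_cn(phylo, rate=rate, seed=sub[1])
    truth.phylo.write(os.path.join(out_dir, "tree.nwk"))
    with open(os.path.join(out_dir, "cn.tsv"), "w") as fh:
        for sid, cn in sorted(truth.true_tip_cn.items()):
            fh.write(f"{sid}\t{cn}\n")

    regions = RegionSet()
    depth_samples = sorted(truth.true_tip_cn)[:n_depth_samples]
    for i, sid in enumerate(depth_samples):
        profile = emulate_depth(
            truth.true_tip_cn[sid], base_depth=base_depth, noise="poisson",
            regions=regions, seed=sub[2] + i, sample_id=sid,
        )
        widths = profile.window_widths()
        with open(os.path.join(depth_dir, f"{sid}.tsv"), "w") as fh:
            for s, w, d in zip(profile.starts, widths, profile.depths):
                fh.write(f"chrY\t{s - 1}\t{s - 1 + w}\t{d:.6g}\n")

    well_rows = []
    ddpcr_truth = {}
    for i, sid in enumerate(depth_samples):
        total_cn = truth.true_tip_cn[sid]
        t_cn = max(0, total_cn - 2)  # distal clusters usually hold 2 copies
        c_cn = total_cn - t_cn
        ddpcr_truth[sid] = {"T": t_cn, "C": c_cn}
        for assay, cn in (("T", t_cn), ("C", c_cn)):
            for replicate in (1, 2):
                well, _ = emulate_droplets(
                    cn, seed=sub[3] + 10 * i + replicate + (0 if assay == "T" else 5),
                    sample_id=sid, assay=assay,
                )
                well_rows.append(
                    {
                        "sample_id": sid, "assay": assay, "replicate": replicate,
                        "target_positive": well.target_positive,
                        "target_total": well.target_total,
                        "ref_positive": well.reference_positive,
                        "ref_total": well.reference_total,
                    }
                )
    pd.DataFrame(well_rows).to_csv(os.path.join(out_dir, "wells.csv"), index=False)

    trios, trio_truth = make_father_son(n_trio_pairs, rate=0.013, seed=sub[4])
    trios.to_csv(os.path.join(out_dir, "trios.tsv"), sep="\t", index=False)

    record = {
        "seed": seed,
        "subseeds": sub,
        "n_tips": n_tips,
        "rate": rate,
        "total_generations": truth.phylo.total_generations(),
        "total_events": truth.total_events,
        "true_rate": truth.true_rate,
        "true_tip_cn": dict(truth.true_tip_cn),
        "ddpcr_truth": ddpcr_truth,
        "trio_truth": trio_truth,
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(record, fh, indent=2)
    return record
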