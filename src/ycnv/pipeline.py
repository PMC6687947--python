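"""Config-driven end-to-end pipeline.

Wires the stages together over a synthetic (or user-supplied) input set:
depth -> ratios/rough CN -> calibration -> phylogenetic events -> mutation
rate -> selection tests; ddPCR wells -> per-sample totals. Produces a JSON
run report with per-stage summaries. Deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import os
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .calibrate import fit_ols, load_gold_standard
from .ddpcr import quantify_wells, read_wells
from .depth import (
    CopyModelConfig,
    flag_curated,
    load_depth_windows,
    region_depth_ratio,
    rough_copy_number,
)
from .events import count_events, filter_events, read_tip_states, read_tree
from .rates import ClockConstants, cn_mutation_rate, transmission_rate_ci
from .regions import RegionSet
from .selection import (
    NeutralSimConfig,
    direction_bias_test,
    simulate_neutral,
    variance_percentile_test,
)
from .simulate import simulate_all


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration; defaults match the shipped constants."""

    out_dir: str = "ycnv_run"
    seed: int = 0
    input_dir: str | None = None  # None -> generate synthetic inputs
    n_tips: int = 100
    total_generations_target: float = 250_000.0
    true_rate: float = 2.2e-3
    window_size: int = 5000
    flank_bp: int = 100_000
    max_rel_dev: float = 0.25
    replicate_threshold: float = 0.8
    min_magnitude: int = 2
    cn_range: tuple[int, int] = (5, 12)
    sim_replicates: int = 200
    root_cn: int = 8
    clock: ClockConstants = field(default_factory=ClockConstants)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "clock" in kwargs and isinstance(kwargs["clock"], dict):
            clock_known = {f.name for f in dataclasses.fields(ClockConstants)}
            bad = set(kwargs["clock"]) - clock_known
            if bad:
                raise ConfigError(f"unknown clock keys: {sorted(bad)}")
            if "snv_rate_ci" in kwargs["clock"]:
                kwargs["clock"]["snv_rate_ci"] = tuple(kwargs["clock"]["snv_rate_ci"])
            kwargs["clock"] = ClockConstants(**kwargs["clock"])
        if "cn_range" in kwargs:
            kwargs["cn_range"] = tuple(kwargs["cn_range"])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cn_range"] = list(self.cn_range)
        d["clock"]["snv_rate_ci"] = list(self.clock.snv_rate_ci)
        return d


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig, log=sys.stderr) -> dict:
    """Execute all stages in dependency order and write the run report.

    Returns the report dict; also written to ``<out_dir>/report.json``.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    if config.input_dir is None:
        input_dir = os.path.join(config.out_dir, "inputs")
        print(f"[ycnv] generating synthetic inputs in {input_dir}", file=log)
        truth = simulate_all(
            input_dir,
            seed=config.seed,
            n_tips=config.n_tips,
            total_generations_target=config.total_generations_target,
            rate=config.true_rate,
        )
        report["stages"]["simulate"] = {
            "n_tips": config.n_tips,
            "total_events_truth": truth["total_events"],
            "true_rate": truth["true_rate"],
        }
    else:
        input_dir = config.input_dir

    for required in ("tree.nwk", "cn.tsv"):
        if not os.path.exists(os.path.join(input_dir, required)):
            raise ConfigError(f"missing input file: {os.path.join(input_dir, required)}")
    report["input_checksums"] = {
        os.path.basename(p): _checksum(p)
        for p in sorted(glob.glob(os.path.join(input_dir, "*.*")))
    }

    # --- depth stage -------------------------------------------------------
    regions = RegionSet()
    model = CopyModelConfig()
    depth_rows = []
    depth_files = sorted(glob.glob(os.path.join(input_dir, "depth", "*.tsv")))
    skipped = []
    for path in depth_files:
        sid = os.path.splitext(os.path.basename(path))[0]
        profile = load_depth_windows(
            path, regions.survey_interval, config.window_size, sample_id=sid
        )
        try:
            ratios = region_depth_ratio(profile, regions)
        except Exception as exc:  # uninformative sample: report and skip
            skipped.append({"sample_id": sid, "reason": str(exc)})
            continue
        curation = flag_curated(profile, regions, config.flank_bp, config.max_rel_dev)
        row = {"sample_id": sid}
        for name in regions.region_names:
            row[f"ratio_r{name}"] = ratios.per_region_ratio[name]
        row["combined_ratio"] = ratios.combined_ratio
        row["rough_cn"] = rough_copy_number(ratios, model)
        row["curated_flag"] = curation.passed
        depth_rows.append(row)
    if depth_rows:
        depth_table = pd.DataFrame(depth_rows)
        depth_table.to_csv(
            os.path.join(config.out_dir, "depth_cn.tsv"), sep="\t", index=False
        )
        report["stages"]["depth"] = {
            "n_samples": len(depth_rows),
            "n_skipped": len(skipped),
            "skipped": skipped,
            "rough_cn_counts": depth_table["rough_cn"].value_counts().to_dict(),
        }

    # --- calibration stage (packaged gold standard) ------------------------
    gold = load_gold_standard()
    depth_model = fit_ols(
        gold["total_fibre_fish"].to_numpy(), gold["cn_read_depth"].to_numpy()
    )
    ddpcr_model = fit_ols(
        gold["total_fibre_fish"].to_numpy(), gold["cn_ddpcr"].to_numpy()
    )
    report["stages"]["calibrate"] = {
        "read_depth_vs_gold": {
            "slope": depth_model.slope,
            "intercept": depth_model.intercept,
            "r2": depth_model.r_squared,
        },
        "ddpcr_vs_gold": {
            "slope": ddpcr_model.slope,
            "intercept": ddpcr_model.intercept,
            "r2": ddpcr_model.r_squared,
        },
    }

    # --- events + rate stage ----------------------------------------------
    phylo = read_tree(os.path.join(input_dir, "tree.nwk"))
    states = read_tip_states(os.path.join(input_dir, "cn.tsv"))
    phylo = phylo.with_states(states)
    assignment, eventset = count_events(phylo, method="parsimony")
    filtered = filter_events(eventset, config.min_magnitude, config.cn_range)
    eventset.to_frame().to_csv(
        os.path.join(config.out_dir, "events.tsv"), sep="\t", index=False
    )
    snv_total = phylo.total_branch_length()
    rate = cn_mutation_rate(eventset.total, snv_total, config.clock)
    report["stages"]["events"] = {
        "n_events": eventset.total,
        "direction_counts": eventset.direction_counts(),
        "n_filtered": filtered.total,
    }
    report["stages"]["rate"] = rate.to_dict()

    trios_path = os.path.join(input_dir, "trios.tsv")
    if os.path.exists(trios_path):
        trios = pd.read_csv(trios_path, sep="\t")
        k = int((trios["father_cn"] != trios["son_cn"]).sum())
        tr = transmission_rate_ci(k, len(trios))
        report["stages"]["trio_rate"] = {
            "mutations": k,
            "transmissions": len(trios),
            "rate": tr.point,
            "ci": [tr.ci_low, tr.ci_high],
        }

    # --- selection stage ---------------------------------------------------
    directions = eventset.direction_counts()
    if directions["increase"] + directions["decrease"] > 0:
        bias = direction_bias_test(directions["increase"], directions["decrease"])
        report["stages"]["selection_direction"] = {
            "increase": directions["increase"],
            "decrease": directions["decrease"],
            "p_value": bias.p_value,
            "decrease_proportion": bias.decrease_proportion,
        }
    sizes = eventset.magnitude_histogram(signed=True)
    if sizes:
        sim_cfg = NeutralSimConfig(
            event_sizes=sizes,
            root_cn=config.root_cn,
            replicates=config.sim_replicates,
            seed=config.seed,
        )
        sims = simulate_neutral(phylo, sim_cfg)
        empirical = float(np.var(list(states.values())))
        var_test = variance_percentile_test(empirical, sims.variances)
        report["stages"]["selection_variance"] = {
            "empirical_variance": empirical,
            "percentile": var_test.percentile_of_empirical,
            "null_ci": list(var_test.null_ci),
            "verdict": var_test.verdict,
        }

    # --- ddPCR stage -------------------------------------------------------
    wells_path = os.path.join(input_dir, "wells.csv")
    if os.path.exists(wells_path):
        quant = quantify_wells(read_wells(wells_path), config.replicate_threshold)
        quant.to_csv(os.path.join(config.out_dir, "ddpcr_cn.tsv"), sep="\t", index=False)
        report["stages"]["ddpcr"] = {
            "n_samples": len(quant),
            "n_needs_third": int(
                (quant["needs_third_T"] | quant["needs_third_C"]).sum()
            ),
        }

    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
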