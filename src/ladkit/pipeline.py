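"""End-to-end orchestration of the synthetic LAD-dynamics analysis.

``run_all`` drives simulate -> tracks -> call -> classify -> fate ->
expression -> radial -> FISH on a single seeded configuration and writes
a machine-readable summary. Every stage writes its artifacts before the
next starts, so a failing stage leaves partial outputs behind and is
named in the raised error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import algebra, caller, expression, io, radial, synthetic, tracks
from .genome import Genome, default_genome
from .partition import CLASSES

log = logging.getLogger("ladkit")

SUMMARY_SCHEMA_VERSION = 1

CONDITIONS = ("control", "treated")
LAMINS = ("A", "B")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full synthetic run."""

    seed: int = 0
    n_models: int = 40
    n_genes: int = 2000
    n_nuclei: int = 100
    n_runs: int = 10  # stability-protocol repeats
    jitter: float = 0.1  # GP jitter fraction in the stability protocol
    alpha: float = 0.01
    stable_fpkm_threshold: float = 0.05
    nucleus_radius_um: float = radial.DEFAULT_NUCLEUS_RADIUS_UM
    plan: synthetic.TransitionPlan = field(default_factory=synthetic.default_plan)
    sim: synthetic.SimulationConfig = field(default_factory=synthetic.SimulationConfig)

    def __post_init__(self) -> None:
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        plan = (
            synthetic.TransitionPlan.from_dict(raw.pop("plan"))
            if "plan" in raw
            else synthetic.default_plan()
        )
        sim_raw = raw.pop("sim", {})
        if "expr_effect" in sim_raw:
            sim_raw["expr_effect"] = {
                (k.split("->")[0], k.split("->")[1]): v
                for k, v in sim_raw["expr_effect"].items()
            }
        sim = synthetic.SimulationConfig(**sim_raw)
        return cls(plan=plan, sim=sim, **raw)

    def to_yaml_dict(self) -> dict:
        d = asdict(self)
        d["plan"] = self.plan.to_dict()
        d["sim"]["expr_effect"] = {
            f"{ci}->{cj}": v for (ci, cj), v in self.sim.expr_effect.items()
        }
        return d


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            log.info("stage %s: done", name)
            return out

        return wrapped

    return deco


def run_all(config: RunConfig, out_dir, genome: Genome | None = None) -> dict:
    """Run every stage on synthetic data and write the report bundle.

    Returns the summary dictionary (also written to ``summary.json``).
    Re-running with an identical config reproduces identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = genome or default_genome()
    cfg = config.sim

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_yaml_dict(), fh, sort_keys=True)

    # default planted expression effects mirror the planned transitions if unset
    if not cfg.expr_effect:
        cfg.expr_effect = {("A-only", "B-only"): -1.0, ("iLAD", "B-only"): -1.0}

    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "genome": {"chromosomes": list(genome.chromosomes), "bin_size": genome.bin_size},
    }

    # ---- simulate --------------------------------------------------------
    @_stage("simulate")
    def stage_simulate():
        sim_dir = out / "simulate"
        sim_dir.mkdir(exist_ok=True)
        truth_ctrl, truth_trt = synthetic.plant_architecture(genome, config.plan, seed=config.seed)
        truth = {"control": truth_ctrl, "treated": truth_trt}
        with open(sim_dir / "plan.yaml", "w") as fh:
            yaml.safe_dump(config.plan.to_dict(), fh, sort_keys=True)
        counts = {}
        for ci, cond in enumerate(CONDITIONS):
            for lamin in LAMINS:
                chip, inp = synthetic.simulate_chip_counts(
                    genome, truth[cond], lamin, cfg, stream=ci
                )
                counts[(cond, lamin)] = (chip, inp)
                io.write_count_bedgraph(chip, sim_dir / f"chip_{lamin}_{cond}.bedGraph")
                io.write_count_bedgraph(inp, sim_dir / f"input_{lamin}_{cond}.bedGraph")
            for lamin in LAMINS:
                io.write_bed(
                    truth[cond].lamin_set(lamin),
                    sim_dir / f"truth_lads_{lamin}_{cond}.bed",
                )
        genes = synthetic.make_genes(genome, config.n_genes, seed=config.seed)
        genes = synthetic.simulate_expression(genes, truth_ctrl, truth_trt, cfg)
        io.write_expression_tsv(genes, sim_dir / "expression.tsv")
        structures = synthetic.simulate_structures(
            genome, truth, config.n_models, cfg, radius_um=config.nucleus_radius_um
        )
        for cond, models in structures.items():
            io.write_structures_tsv(models, sim_dir / f"structures_{cond}.tsv")
        io.write_genome_tsv(genome, sim_dir / "genome.tsv")
        return truth, counts, genes, structures

    truth, counts, genes, structures = stage_simulate()

    # ---- tracks ----------------------------------------------------------
    @_stage("tracks")
    def stage_tracks():
        trk_dir = out / "tracks"
        trk_dir.mkdir(exist_ok=True)
        ratio = {}
        for key, (chip, inp) in counts.items():
            cond, lamin = key
            chip_m, inp_m = tracks.match_depth(chip, inp, seed=config.seed)
            rt = tracks.build_ratio_track(chip_m, inp_m)
            ratio[key] = rt
            io.write_ratio_bedgraph(rt, trk_dir / f"ratio_{lamin}_{cond}.bedGraph")
        return ratio

    ratio = stage_tracks()

    # ---- call-lads -------------------------------------------------------
    @_stage("call-lads")
    def stage_call():
        lad_dir = out / "lads"
        lad_dir.mkdir(exist_ok=True)
        lads = {}
        stability = {}
        for key, rt in ratio.items():
            cond, lamin = key
            report = caller.stability_protocol(
                rt, n_runs=config.n_runs, seed=config.seed, jitter=config.jitter
            )
            lads[key] = report.final_lads
            stability[f"{lamin}_{cond}"] = report.to_json_dict()
            io.write_bed(report.final_lads, lad_dir / f"lads_{lamin}_{cond}.bed")
            with open(lad_dir / f"stability_{lamin}_{cond}.json", "w") as fh:
                json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
        return lads, stability

    lads, stability = stage_call()
    summary["stability"] = stability

    # ---- classify --------------------------------------------------------
    @_stage("classify")
    def stage_classify():
        cls_dir = out / "classes"
        cls_dir.mkdir(exist_ok=True)
        partitions = {}
        coverage = {}
        for cond in CONDITIONS:
            part = algebra.partition_classes(lads[(cond, "A")], lads[(cond, "B")], genome)
            partitions[cond] = part
            for c in CLASSES:
                safe = c.replace("-", "")
                io.write_bed(part.class_set(c), cls_dir / f"class_{safe}_{cond}.bed")
            cov = algebra.coverage_summary(part)
            cov.to_csv(cls_dir / f"coverage_{cond}.tsv", sep="\t", index=False)
            coverage[cond] = {
                r["lad_class"]: {"bp": int(r["bp"]), "fraction": r["fraction"]}
                for _, r in cov.iterrows()
            }
        return partitions, coverage

    partitions, coverage = stage_classify()
    summary["coverage"] = coverage

    # ---- jaccard ---------------------------------------------------------
    @_stage("jaccard")
    def stage_jaccard():
        import pandas as pd

        rows = []

        def add(name, s1, s2):
            try:
                ji = algebra.jaccard(s1, s2)
            except ValueError:
                ji = float("nan")
            rows.append({"comparison": name, "jaccard": ji})

        add("A_control_vs_B_control", lads[("control", "A")], lads[("control", "B")])
        add("A_treated_vs_B_treated", lads[("treated", "A")], lads[("treated", "B")])
        add("A_control_vs_A_treated", lads[("control", "A")], lads[("treated", "A")])
        add("B_control_vs_B_treated", lads[("control", "B")], lads[("treated", "B")])
        add("A_treated_vs_B_control", lads[("treated", "A")], lads[("control", "B")])
        for c in CLASSES[:3]:
            add(
                f"{c}_control_vs_treated",
                partitions["control"].class_set(c),
                partitions["treated"].class_set(c),
            )
        df = pd.DataFrame(rows)
        df.to_csv(out / "jaccard.tsv", sep="\t", index=False)
        return {r["comparison"]: r["jaccard"] for r in rows}

    summary["jaccard"] = stage_jaccard()

    # ---- fate ------------------------------------------------------------
    @_stage("fate")
    def stage_fate():
        fm = algebra.fate_matrix(partitions["control"], partitions["treated"])
        fm.to_frame().to_csv(out / "fate_matrix.tsv", sep="\t")
        fm.to_long().to_csv(out / "fate_long.tsv", sep="\t", index=False)
        return fm

    fm = stage_fate()
    summary["fate_matrix"] = {
        "classes": list(CLASSES),
        "bp": fm.counts.tolist(),
    }

    # ---- sizes -----------------------------------------------------------
    @_stage("sizes")
    def stage_sizes():
        groups = {}
        for cond in CONDITIONS:
            sizes = partitions[cond].run_sizes()
            for c in CLASSES[:3]:
                if len(sizes[c]) >= 2:
                    groups[(c, cond)] = sizes[c]
        if len(groups) < 2:
            return None
        res = algebra.compare_sizes(groups)
        res.anova.to_csv(out / "size_anova.tsv", sep="\t")
        res.tukey.to_csv(out / "size_tukey.tsv", sep="\t", index=False)
        return res

    stage_sizes()

    # ---- expression ------------------------------------------------------
    @_stage("expression")
    def stage_expression():
        rep = expression.fate_expression_report(
            genes, partitions["control"], partitions["treated"], alpha=config.alpha
        )
        rep.to_csv(out / "fate_expression.tsv", sep="\t", index=False)
        return rep

    rep = stage_expression()
    summary["expression"] = {
        "n_genes": len(genes),
        "significant_cells": [
            f"{r.control_class}->{r.treated_class}"
            for r in rep.itertuples()
            if r.significant
        ],
    }

    # ---- radial ----------------------------------------------------------
    @_stage("radial")
    def stage_radial():
        rad_dir = out / "radial"
        rad_dir.mkdir(exist_ok=True)
        class_means = {}
        for cond in CONDITIONS:
            stats_df, pairwise = radial.class_distance_stats(
                structures[cond], partitions[cond], alpha=config.alpha
            )
            stats_df.to_csv(rad_dir / f"class_distance_{cond}.tsv", sep="\t", index=False)
            pairwise.to_csv(rad_dir / f"class_pairwise_{cond}.tsv", sep="\t", index=False)
            class_means[cond] = dict(zip(stats_df["lad_class"], stats_df["mean"]))
        trans = radial.transition_distance_stats(
            structures["control"],
            structures["treated"],
            partitions["control"],
            partitions["treated"],
            alpha=config.alpha,
        )
        trans.to_csv(rad_dir / "transition_distance.tsv", sep="\t", index=False)
        shifts = {
            f"{r.control_class}->{r.treated_class}": r.direction
            for r in trans.itertuples()
            if r.direction != "none"
        }
        return class_means, shifts

    class_means, shifts = stage_radial()
    summary["radial"] = {"class_means": class_means, "significant_shifts": shifts}

    # ---- fish ------------------------------------------------------------
    @_stage("fish")
    def stage_fish():
        fish_dir = out / "fish"
        fish_dir.mkdir(exist_ok=True)
        bias = cfg.radial_bias
        probes = {
            "switch_A_to_B": {"control": bias["A-only"], "treated": bias["B-only"]},
            "stable_ilad": {"control": bias["iLAD"], "treated": bias["iLAD"]},
        }
        all_spots = []
        for k, (probe, targets) in enumerate(sorted(probes.items())):
            all_spots.extend(
                synthetic.simulate_fish_spots(
                    targets,
                    config.n_nuclei,
                    seed=config.seed + 1000 + k,
                    probe=probe,
                    spread=cfg.fish_spread,
                )
            )
        io.write_spots_tsv(all_spots, fish_dir / "spots.tsv")
        ctrl = [s for s in all_spots if s.condition == "control"]
        trt = [s for s in all_spots if s.condition == "treated"]
        comp = radial.fish_compare(ctrl, trt, alpha=config.alpha)
        comp.to_csv(fish_dir / "fish_compare.tsv", sep="\t", index=False)
        return {
            r.probe: {"pvalue": r.pvalue, "direction": r.direction}
            for r in comp.itertuples()
        }

    summary["fish"] = stage_fish()

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    log.info("summary written to %s", out / "summary.json")
    return summary
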