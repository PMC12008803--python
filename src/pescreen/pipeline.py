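"""End-to-end orchestration: simulate -> process -> score -> call -> sweep
-> endogenous, with a run manifest and a plain-text report.

Every stage reads and writes plain TSVs so any stage can be rerun standalone;
identical config + inputs + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import cassette, endogenous, io, scoring, stats
from .model import PegRNADesign, Sample, SchemaError, ScreenConfig, Variant
from .simulate import (
    SimParams,
    default_samples,
    observations_from_counts,
    simulate_counts,
    simulate_et_counts,
    simulate_library,
    simulate_screen,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

DEFAULT_SWEEP_GRID = (0.0, 5.0, 10.0, 25.0, 30.0, 50.0, 75.0, 90.0)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def simulate_stage(config: dict, outdir: str, seed: Optional[int]
                   ) -> Tuple[List[PegRNADesign], List[Variant],
                              List[Sample], Dict, Dict]:
    """Generate library, samples, FASTQ and ET counts from the config."""
    sim_cfg = dict(config.get("simulate", {}))
    if seed is not None:
        sim_cfg["seed"] = seed
    conditions = sim_cfg.pop("conditions", [{"screen_id": "screen1"}])
    write_fastq = sim_cfg.pop("write_fastq", True)
    params = SimParams(**sim_cfg)
    designs, variants, truth = simulate_library(params)
    samples: List[Sample] = []
    for cond in conditions:
        samples.extend(default_samples(**cond))
    simdir = os.path.join(outdir, "sim")
    os.makedirs(simdir, exist_ok=True)
    io.write_table(io.library_to_frame(designs, variants),
                   os.path.join(simdir, "library.tsv"))
    io.write_table(io.samples_to_frame(samples),
                   os.path.join(simdir, "samples.tsv"))
    io.write_table(truth.pegrna, os.path.join(simdir, "truth_pegrna.tsv"))
    io.write_table(truth.variant, os.path.join(simdir, "truth_variant.tsv"))
    fastq_paths: Dict = {}
    if write_fastq:
        fastq_paths, _ = simulate_screen(designs, truth, samples, params,
                                         simdir)
        counts = None
    else:
        counts = simulate_counts(truth, samples, params)
    et_counts = simulate_et_counts(designs, variants, truth, samples, params)
    for screen_id, tab in et_counts.items():
        io.write_table(tab.reset_index(),
                       os.path.join(simdir, f"et_counts_{screen_id}.tsv"))
    return designs, variants, samples, {
        "fastq": fastq_paths, "counts": counts, "et": et_counts,
        "params": params, "truth": truth,
    }, {"simdir": simdir}


def process_stage(designs: Sequence[PegRNADesign],
                  samples: Sequence[Sample],
                  screen_cfg: ScreenConfig,
                  fastq_paths: Dict[str, Tuple[str, str]],
                  counts: Optional[Dict[str, pd.DataFrame]],
                  outdir: str) -> Dict[str, pd.DataFrame]:
    """Per-sample observation tables, from FASTQ or simulated counts."""
    obs: Dict[str, pd.DataFrame] = {}
    layout = cassette.layout_from_library(designs)
    for sample in samples:
        if sample.role not in ("pre", "post", "negative_control"):
            continue
        if counts is not None and sample.sample_id in counts:
            table = observations_from_counts(counts[sample.sample_id],
                                             screen_cfg)
        elif sample.sample_id in fastq_paths:
            p1, p2 = fastq_paths[sample.sample_id]
            table, tallies = cassette.process_sample(
                io.read_fastq_pairs(p1, p2), designs, screen_cfg, layout,
                sample.sample_id)
            assert (tallies["assigned"] + tallies["recombinant"]
                    + tallies["unassigned"] + tallies["rejected"]
                    == tallies["total"])
        else:
            raise SchemaError(f"no reads or counts for sample "
                              f"{sample.sample_id!r}")
        obs[sample.sample_id] = table
        io.write_table(table,
                       os.path.join(outdir, f"obs_{sample.sample_id}.tsv"))
    return obs


def score_stage(designs: Sequence[PegRNADesign],
                samples: Sequence[Sample], screen_cfg: ScreenConfig,
                obs: Dict[str, pd.DataFrame], outdir: str
                ) -> Tuple[Dict[str, pd.DataFrame], Dict[str, str]]:
    """Per-condition score tables after replicate merging and the
    negative-control exclusion."""
    tables: Dict[str, pd.DataFrame] = {}
    condition_cell_line: Dict[str, str] = {}
    screens = sorted({s.screen_id for s in samples})
    for screen_id in screens:
        def grab(role: str) -> List[pd.DataFrame]:
            return [obs[s.sample_id] for s in samples
                    if s.screen_id == screen_id and s.role == role
                    and s.sample_id in obs]

        ctrl_tabs, pre_tabs, post_tabs = (grab(r) for r in
                                          ("negative_control", "pre", "post"))
        if not ctrl_tabs:
            raise SchemaError(f"screen {screen_id!r} has no negative-control "
                              "observations")
        if not pre_tabs or not post_tabs:
            raise SchemaError(f"screen {screen_id!r} lacks pre or post "
                              "observations")
        ctrl = cassette.merge_replicates(ctrl_tabs, screen_cfg,
                                         f"{screen_id}_ctrl")
        pre = cassette.merge_replicates(pre_tabs, screen_cfg,
                                        f"{screen_id}_pre")
        post = cassette.merge_replicates(post_tabs, screen_cfg,
                                         f"{screen_id}_post")
        excluded = cassette.negative_control_filter(ctrl, screen_cfg)
        logger.info("screen %s: %d pegRNA(s) excluded by the "
                    "negative-control editing filter", screen_id,
                    len(excluded))
        table = scoring.score_table(
            pre.set_index("pegrna_id")["read_count"],
            post.set_index("pegrna_id")["read_count"],
            pre.set_index("pegrna_id")["st_editing_pct"],
            excluded, screen_cfg)
        logger.info(
            "screen %s: %d/%d pegRNAs pass frequency filter, %d/%d pass "
            "activity filter, %d retained", screen_id,
            int(table["passed_freq_filter"].sum()), len(table),
            int(table["passed_activity_filter"].sum()), len(table),
            int(table["retained"].sum()))
        tables[screen_id] = table
        sample0 = next(s for s in samples if s.screen_id == screen_id)
        condition_cell_line[screen_id] = sample0.cell_line
        io.write_table(table, os.path.join(outdir,
                                           f"scores_{screen_id}.tsv"))
    return tables, condition_cell_line


def run_all(config: dict, outdir: str, seed: Optional[int] = None) -> str:
    """Run every stage; returns the output directory.

    The config mirrors :class:`ScreenConfig` under ``screen``, simulation
    parameters under ``simulate`` (or real input paths under ``inputs``),
    and optional ``sweep_grid`` / ``annotations`` entries.
    """
    os.makedirs(outdir, exist_ok=True)
    screen_cfg = ScreenConfig.from_dict(config.get("screen", {}))
    manifest: dict = {
        "tool": "pescreen", "version": __version__,
        "config_hash": _config_hash(config), "seed": seed,
        "inputs": {}, "stages": {},
    }

    stage = "simulate"
    try:
        if "simulate" in config:
            designs, variants, samples, generated, _ = simulate_stage(
                config, outdir, seed)
            fastq_paths = generated["fastq"]
            counts = generated["counts"]
            et_counts = generated["et"]
        else:
            inputs = config["inputs"]
            designs, variants = io.read_library(inputs["library"])
            samples = io.read_sample_sheet(inputs["sample_sheet"])
            manifest["inputs"] = {
                "library": _sha256(inputs["library"]),
                "sample_sheet": _sha256(inputs["sample_sheet"]),
            }
            fastq_dir = inputs["fastq_dir"]
            fastq_paths = {}
            for s in samples:
                for ext in (".fastq.gz", ".fastq"):
                    p1 = os.path.join(fastq_dir, f"{s.sample_id}_R1{ext}")
                    p2 = os.path.join(fastq_dir, f"{s.sample_id}_R2{ext}")
                    if os.path.exists(p1):
                        fastq_paths[s.sample_id] = (p1, p2)
                        break
            counts = None
            et_counts = {}
            for screen_id, path in inputs.get("et_counts", {}).items():
                et_counts[screen_id] = io.read_table(path).set_index(
                    "variant_id")
        manifest["stages"]["library"] = {"n_pegrnas": len(designs),
                                         "n_variants": len(variants),
                                         "n_samples": len(samples)}
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    stage = "process"
    try:
        obs = process_stage(designs, samples, screen_cfg, fastq_paths,
                            counts, outdir)
        manifest["stages"]["process"] = {
            s: int(t["read_count"].sum()) for s, t in obs.items()}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "score"
    try:
        tables, condition_cell_line = score_stage(
            designs, samples, screen_cfg, obs, outdir)
        fs = scoring.function_scores(tables, designs, variants, screen_cfg)
        manifest["stages"]["score"] = {
            "n_conditions": len(tables),
            "n_variants_scored": len(fs),
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "call"
    try:
        fs = stats.classify_variants(fs, variants, screen_cfg)
        io.write_table(fs, os.path.join(outdir, "function_scores.tsv"))
        manifest["stages"]["call"] = {
            "n_lof": int(fs["lof_call"].sum()),
            "q_cutoff": screen_cfg.q_cutoff,
        }
        if len(tables) > 1:
            cl = scoring.cellline_scores(tables, condition_cell_line,
                                         designs, variants, screen_cfg)
            io.write_table(cl, os.path.join(outdir, "cellline_scores.tsv"))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "sweep"
    try:
        grid = config.get("sweep_grid", list(DEFAULT_SWEEP_GRID))
        sweep = stats.threshold_sweep(tables, designs, variants, screen_cfg,
                                      grid)
        io.write_table(sweep, os.path.join(outdir, "threshold_sweep.tsv"))
        manifest["stages"]["sweep"] = {"n_thresholds": len(sweep)}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "endogenous"
    try:
        if et_counts:
            et_fs = endogenous.endogenous_function_scores(
                et_counts, variants, screen_cfg)
            io.write_table(et_fs, os.path.join(outdir,
                                               "endogenous_scores.tsv"))
            pre_sample = next(s for s in samples if s.role == "pre")
            st_freq = endogenous.st_variant_frequencies(
                obs[pre_sample.sample_id], designs)
            first_screen = sorted(et_counts)[0]
            et_freq = (et_counts[first_screen]["pre"]
                       / et_counts[first_screen]["pre"].sum())
            rho, paired = endogenous.st_et_concordance(st_freq, et_freq)
            io.write_table(paired.reset_index(),
                           os.path.join(outdir, "st_et_frequencies.tsv"))
            manifest["stages"]["endogenous"] = {
                "n_variants": len(et_fs), "st_et_spearman": round(rho, 4)}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "report"
    try:
        report = build_report(fs, variants, sweep, manifest,
                              annotations=config.get("annotations"))
        with open(os.path.join(outdir, "report.txt"), "w") as fh:
            fh.write(report)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise StageError(stage, exc) from exc
    return outdir


@dataclasses.dataclass
class SimulatedScreenResult:
    designs: list
    variants: list
    truth: object
    observations: Dict[str, pd.DataFrame]
    score_table: pd.DataFrame
    function_scores: pd.DataFrame


def analyze_simulated_screen(params: SimParams, screen_cfg: ScreenConfig,
                             t_pre: int = 10, t_post: int = 34
                             ) -> SimulatedScreenResult:
    """Simulate one condition at the count level and run the full scoring
    and classification chain (no FASTQ rendering).

    This is the generative model used by :func:`simulate_screen` minus read
    emission; convenient for calibration studies at large depth.
    """
    designs, variants, truth = simulate_library(params)
    samples = default_samples(t_pre=t_pre, t_post=t_post)
    counts = simulate_counts(truth, samples, params)
    obs = {sid: observations_from_counts(c, screen_cfg)
           for sid, c in counts.items()}
    excluded = cassette.negative_control_filter(obs["screen1_ctrl"],
                                                screen_cfg)
    pre = obs["screen1_pre_r1"].set_index("pegrna_id")
    post = obs["screen1_post_r1"].set_index("pegrna_id")
    table = scoring.score_table(pre["read_count"], post["read_count"],
                                pre["st_editing_pct"], excluded, screen_cfg)
    fs = scoring.function_scores({"screen1": table}, designs, variants,
                                 screen_cfg)
    fs = stats.classify_variants(fs, variants, screen_cfg)
    return SimulatedScreenResult(designs, variants, truth, obs, table, fs)


def build_report(function_table: pd.DataFrame, variants: Sequence[Variant],
                 sweep: pd.DataFrame, manifest: dict,
                 annotations: Optional[str] = None) -> str:
    """Human-readable run summary: per-consequence score medians, LoF calls
    and the threshold sweep."""
    cons = pd.Series({v.variant_id: v.consequence for v in variants})
    t = function_table.copy()
    t["consequence"] = t["variant_id"].map(cons)
    lines = ["pescreen run summary", "===================", ""]
    lines.append(f"variants scored: {len(t)}")
    lines.append(f"LoF calls (q < {manifest['stages']['call']['q_cutoff']}): "
                 f"{int(t['lof_call'].sum())}")
    lines.append("")
    lines.append("function score by consequence (median [n]):")
    med = t.groupby("consequence")["function_score"].agg(["median", "size"])
    for c, row in med.sort_values("median").iterrows():
        lines.append(f"  {c:18s} {row['median']:8.3f}  [{int(row['size'])}]")
    if annotations:
        ann = io.read_table(annotations)
        t2 = t.merge(ann, on="variant_id", how="inner")
        for col in ann.columns:
            if col == "variant_id":
                continue
            lines.append("")
            lines.append(f"function score by {col} (median [n]):")
            med = t2.groupby(col)["function_score"].agg(["median", "size"])
            for g, row in med.sort_values("median").iterrows():
                lines.append(
                    f"  {str(g):18s} {row['median']:8.3f}  [{int(row['size'])}]")
    lines.append("")
    lines.append("ST-activity threshold sweep:")
    lines.append("  threshold_pct  auc  n_pegrnas_retained  n_variants_scored")
    for row in sweep.itertuples(index=False):
        auc_str = "NA" if pd.isna(row.auc) else f"{row.auc:.3f}"
        lines.append(f"  {row.threshold_pct:10.1f}  {auc_str:>5s}  "
                     f"{row.n_pegrnas_retained:12d}  {row.n_variants_scored:12d}")
    lines.append("")
    return "\n".join(lines)
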