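"""End-to-end pipeline orchestration.

Stages run in a fixed order — simulate -> clean -> build -> metrics ->
compare -> nbs -> behavior -> report — and communicate exclusively through
plain-text files in the run directory, so each stage is idempotent and can
be re-run on its own.  One master seed deterministically derives every
stage seed (the first words of ``SeedSequence(master_seed)``'s generated
state, masked to 31 bits), making the whole run reproducible from the
configuration alone.  Result payloads carry no timestamps; wall times go to
the log only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import connectivity as conn
from . import efficiency as eff
from . import inference as inf
from . import io as cio
from . import preprocess as prep
from .synthetic import SCORE_NAMES, SyntheticSpec, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "clean", "build", "metrics", "compare", "nbs",
          "behavior", "report")

GLOBAL_METRIC_NAMES = ("density", "e_glob", "e_loc", "norm_e_glob", "norm_e_loc")


@dataclass
class PipelineConfig:
    """Validated configuration for a full run."""

    out_dir: str = "conneff_run"
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    # thresholding
    alpha: float = 0.05
    # metrics
    n_random: int = 100
    swap_factor: int = 20
    glob_tol: float = 0.1
    # inference
    n_perm: int = 10_000
    primary_alpha: float = 0.05
    positive_frac: float = 0.85
    q: float = 0.05
    directions: tuple[str, ...] = ("greater", "less")
    # behavior
    covariates: tuple[str, ...] = ("age", "sex", "education")
    master_seed: int = 0
    write_matrices: bool = True

    def __post_init__(self) -> None:
        self.directions = tuple(self.directions)
        self.covariates = tuple(self.covariates)
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticSpec(**self.synthetic)
        self.validate()

    def validate(self) -> "PipelineConfig":
        self.synthetic.validate()
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if self.swap_factor < 1:
            raise ValueError("swap_factor must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.primary_alpha < 1:
            raise ValueError("primary_alpha must be in (0, 1)")
        if not 0 <= self.positive_frac < 1:
            raise ValueError("positive_frac must be in [0, 1)")
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        for d in self.directions:
            if d not in ("greater", "less"):
                raise ValueError("directions must be 'greater'/'less'")
        return self

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            syn = dict(d["synthetic"])
            if syn.get("block_sizes") is not None:
                syn["block_sizes"] = tuple(syn["block_sizes"])
            if syn.get("effect_edges") is not None:
                syn["effect_edges"] = tuple(
                    tuple(e) for e in syn["effect_edges"])
            d["synthetic"] = SyntheticSpec(**syn)
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def stage_seed(self, stage: str) -> int:
        """31-bit stage seed derived from the master seed."""
        idx = STAGES.index(stage)
        state = np.random.SeedSequence(self.master_seed).generate_state(len(STAGES))
        return int(state[idx] & 0x7FFFFFFF)


# -- helpers ---------------------------------------------------------------

def _rundir(config: PipelineConfig) -> Path:
    path = Path(config.out_dir)
    path.mkdir(parents=True, exist_ok=True)
    return path


def _included_subjects(rundir: Path) -> list[str]:
    report = cio.read_results_json(rundir / "clean" / "cleaning_report.json")
    return [sid for sid, entry in sorted(report["subjects"].items())
            if not entry["exclude"]]


def _timed(stage: str):
    def wrap(fn):
        def inner(config: PipelineConfig, *args, **kwargs):
            start = time.perf_counter()
            logger.info("stage %s: start (seed=%d)", stage,
                        config.stage_seed(stage))
            try:
                result = fn(config, *args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"stage '{stage}' failed: {err}") from err
            logger.info("stage %s: done in %.2f s", stage,
                        time.perf_counter() - start)
            return result
        return inner
    return wrap


# -- stages ----------------------------------------------------------------

@_timed("simulate")
def stage_simulate(config: PipelineConfig) -> None:
    rundir = _rundir(config)
    out = rundir / "simulate"
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    (out / "motion").mkdir(parents=True, exist_ok=True)
    spec = dataclasses.replace(config.synthetic,
                               seed=config.stage_seed("simulate"))
    cohort = generate_cohort(spec)
    cio.write_cohort_tsv(out / "cohort.tsv", cohort.table)
    cio.write_results_json(out / "spec.json", dataclasses.asdict(spec))
    for sid, ts in cohort.timeseries.items():
        cio.write_timeseries_tsv(out / "timeseries" / f"{sid}.tsv", ts)
    for sid, mp in cohort.motion.items():
        cio.write_motion_tsv(out / "motion" / f"{sid}.tsv", mp)


@_timed("clean")
def stage_clean(config: PipelineConfig) -> None:
    rundir = _rundir(config)
    src = rundir / "simulate"
    out = rundir / "clean"
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    table = cio.read_cohort_tsv(src / "cohort.tsv")
    tr = config.synthetic.tr_seconds
    cleaner = prep.SignalCleaner()
    report: dict[str, dict] = {}
    for sid in table["subject_id"]:
        ts = cio.read_timeseries_tsv(src / "timeseries" / f"{sid}.tsv", tr,
                                     subject_id=sid)
        mp = cio.read_motion_tsv(src / "motion" / f"{sid}.tsv", subject_id=sid)
        fd = prep.framewise_displacement(mp)
        excl = prep.motion_exclusion(mp)
        report[sid] = {
            "fd_max": fd.fd_max, "fd_mean": fd.fd_mean, "fd_rms": fd.fd_rms,
            "exclude": excl.exclude, "reason": excl.reason,
        }
        if excl.exclude:
            logger.warning("subject %s excluded: %s", sid, excl.reason)
            continue
        cleaned = cleaner.fit_transform((ts, mp))
        cio.write_timeseries_tsv(out / "timeseries" / f"{sid}.tsv", cleaned)
    cio.write_results_json(out / "cleaning_report.json", {"subjects": report})


@_timed("build")
def stage_build(config: PipelineConfig) -> None:
    rundir = _rundir(config)
    out = rundir / "build"
    for sub in ("r", "p", "w"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    tr = config.synthetic.tr_seconds
    summary: dict[str, dict] = {}
    for sid in _included_subjects(rundir):
        ts = cio.read_timeseries_tsv(
            rundir / "clean" / "timeseries" / f"{sid}.tsv", tr, subject_id=sid)
        cm = conn.correlation_matrix(ts)
        g = conn.threshold_bonferroni(cm, alpha=config.alpha)
        census = conn.component_census(g)
        summary[sid] = {
            "n_nodes": g.n_nodes, "n_edges": g.n_edges,
            "density": g.density,
            "n_components": census.n_components,
            "largest_component": census.largest_size,
            "n_isolated": len(census.isolated_nodes),
        }
        if config.write_matrices:
            cio.write_matrix_tsv(out / "r" / f"{sid}.tsv", cm.r, cm.roi_labels)
            cio.write_matrix_tsv(out / "p" / f"{sid}.tsv", cm.p, cm.roi_labels)
        cio.write_matrix_tsv(out / "w" / f"{sid}.tsv", g.w, g.roi_labels)
    cio.write_results_json(out / "graph_summary.json", {"subjects": summary})


@_timed("metrics")
def stage_metrics(config: PipelineConfig) -> None:
    rundir = _rundir(config)
    out = rundir / "metrics"
    (out / "nodal").mkdir(parents=True, exist_ok=True)
    base = np.random.SeedSequence(config.stage_seed("metrics"))
    subjects = _included_subjects(rundir)
    results: dict[str, dict] = {}
    for sid, child in zip(subjects, base.spawn(len(subjects))):
        w, labels = cio.read_matrix_tsv(rundir / "build" / "w" / f"{sid}.tsv")
        g = conn.WeightedGraph(w, roi_labels=labels)
        gm = eff.global_metrics(g, n_random=config.n_random, seed=child,
                                swap_factor=config.swap_factor)
        nodal = eff.nodal_efficiency(g)
        results[sid] = {
            "density": gm.density, "e_glob": gm.e_glob, "e_loc": gm.e_loc,
            "norm_e_glob": gm.norm_e_glob, "norm_e_loc": gm.norm_e_loc,
            "n_random": gm.n_random,
            "small_world": eff.is_small_world(gm, glob_tol=config.glob_tol),
        }
        pd.DataFrame({"ROI": labels, "nodal_efficiency": nodal}).to_csv(
            out / "nodal" / f"{sid}.tsv", sep="\t", index=False,
            float_format=cio.FLOAT_FMT)
    cio.write_results_json(out / "global_metrics.json", {"subjects": results})


def _load_metric_frame(rundir: Path) -> pd.DataFrame:
    data = cio.read_results_json(rundir / "metrics" / "global_metrics.json")
    frame = pd.DataFrame.from_dict(data["subjects"], orient="index")
    frame.index.name = "subject_id"
    return frame.sort_index()


def _load_groups(rundir: Path) -> pd.DataFrame:
    table = cio.read_cohort_tsv(rundir / "simulate" / "cohort.tsv")
    return table.set_index("subject_id")


@_timed("compare")
def stage_compare(config: PipelineConfig) -> None:
    rundir = _rundir(config)
    out = rundir / "compare"
    out.mkdir(parents=True, exist_ok=True)
    metrics = _load_metric_frame(rundir)
    groups = _load_groups(rundir)
    seed = config.stage_seed("compare")
    ids_a = [s for s in metrics.index if groups.loc[s, "group"] == "A"]
    ids_b = [s for s in metrics.index if groups.loc[s, "group"] == "B"]

    global_results: dict[str, dict] = {}
    for name in GLOBAL_METRIC_NAMES:
        for direction in config.directions:
            res = inf.permutation_test_metric(
                metrics.loc[ids_a, name].to_numpy(),
                metrics.loc[ids_b, name].to_numpy(),
                n_perm=config.n_perm, direction=direction, seed=seed,
                metric_name=name)
            global_results[f"{name}_{direction}"] = {
                "metric": name, "direction": direction,
                "observed_diff": res.observed_diff, "p_value": res.p_value,
                "significant_percentile": res.significant_percentile,
                "n_perm": res.n_perm, "seed": seed,
            }
    cio.write_results_json(out / "global_comparisons.json", global_results)

    nodal_a, nodal_b, labels = [], [], None
    for sid in ids_a + ids_b:
        frame = pd.read_csv(rundir / "metrics" / "nodal" / f"{sid}.tsv",
                            sep="\t")
        labels = list(frame["ROI"])
        values = frame["nodal_efficiency"].to_numpy()
        (nodal_a if sid in ids_a else nodal_b).append(values)
    nodal_results = {}
    for direction in config.directions:
        res = inf.nodal_comparison(
            np.array(nodal_a), np.array(nodal_b), n_perm=config.n_perm,
            q=config.q, direction=direction, seed=seed)
        nodal_results[direction] = {
            "roi_labels": labels,
            "observed_diff": res.observed_diff,
            "p_values": res.p_values,
            "significant": res.significant,
            "q": res.q, "n_perm": res.n_perm, "seed": seed,
        }
    cio.write_results_json(out / "nodal_comparisons.json", nodal_results)


@_timed("nbs")
def stage_nbs(config: PipelineConfig) -> None:
    rundir = _rundir(config)
    out = rundir / "nbs"
    out.mkdir(parents=True, exist_ok=True)
    groups = _load_groups(rundir)
    seed = config.stage_seed("nbs")
    stacks: dict[str, list[np.ndarray]] = {"A": [], "B": []}
    labels: list[str] | None = None
    for sid in _included_subjects(rundir):
        r, labels = cio.read_matrix_tsv(rundir / "build" / "r" / f"{sid}.tsv")
        stacks[str(groups.loc[sid, "group"])].append(r)
    payload = {}
    for direction in config.directions:
        res = inf.nbs(
            np.array(stacks["A"]), np.array(stacks["B"]),
            primary_alpha=config.primary_alpha, n_perm=config.n_perm,
            positive_frac=config.positive_frac, direction=direction,
            seed=seed)
        rows = []
        for comp_id, comp in enumerate(res.components):
            for i, j in comp.edges:
                rows.append({
                    "roi_a": labels[i], "roi_b": labels[j],
                    "component_id": comp_id, "component_size": comp.size,
                    "corrected_p": comp.corrected_p,
                })
        pd.DataFrame(
            rows, columns=["roi_a", "roi_b", "component_id",
                           "component_size", "corrected_p"]
        ).to_csv(out / f"components_{direction}.tsv", sep="\t", index=False,
                 float_format=cio.FLOAT_FMT)
        payload[direction] = {
            "n_components": len(res.components),
            "components": [
                {"size": c.size, "corrected_p": c.corrected_p}
                for c in res.components
            ],
            "n_included_edges": int(res.included_edges.sum() // 2),
            "n_perm": res.n_perm, "seed": seed,
        }
    cio.write_results_json(out / "nbs_summary.json", payload)


@_timed("behavior")
def stage_behavior(config: PipelineConfig) -> None:
    rundir = _rundir(config)
    out = rundir / "behavior"
    out.mkdir(parents=True, exist_ok=True)
    metrics = _load_metric_frame(rundir)
    groups = _load_groups(rundir)
    ids_a = [s for s in metrics.index if groups.loc[s, "group"] == "A"]
    metric_frame = metrics.loc[ids_a, list(GLOBAL_METRIC_NAMES)]
    score_frame = groups.loc[ids_a, [s for s in SCORE_NAMES
                                     if s in groups.columns]]
    cov_frame = groups.loc[ids_a, list(config.covariates)]
    table = bhv.behavior_table(metric_frame, score_frame, cov_frame)
    table.to_csv(out / "behavior.tsv", sep="\t", index=False,
                 float_format=cio.FLOAT_FMT)


@_timed("report")
def stage_report(config: PipelineConfig) -> None:
    rundir = _rundir(config)
    out = rundir / "report"
    out.mkdir(parents=True, exist_ok=True)
    groups = _load_groups(rundir)
    metrics = _load_metric_frame(rundir)
    by_group = {}
    for g in ("A", "B"):
        ids = [s for s in metrics.index if groups.loc[s, "group"] == g]
        sub = metrics.loc[ids]
        by_group[g] = {
            "n": len(ids),
            **{f"{name}_mean": float(sub[name].mean())
               for name in GLOBAL_METRIC_NAMES},
            **{f"{name}_sd": float(sub[name].std(ddof=1))
               for name in GLOBAL_METRIC_NAMES},
            "small_world_fraction": float(sub["small_world"].mean()),
        }
    report = {
        "config": config.to_dict(),
        "groups": by_group,
        "global_comparisons": cio.read_results_json(
            rundir / "compare" / "global_comparisons.json"),
        "nbs": cio.read_results_json(rundir / "nbs" / "nbs_summary.json"),
        "note": "behavior correlations are uncorrected for multiple "
                "comparisons (see behavior/behavior.tsv)",
    }
    cio.write_results_json(out / "report.json", report)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "clean": stage_clean,
    "build": stage_build,
    "metrics": stage_metrics,
    "compare": stage_compare,
    "nbs": stage_nbs,
    "behavior": stage_behavior,
    "report": stage_report,
}


def run_stage(config: PipelineConfig, stage: str) -> None:
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    _STAGE_FUNCS[stage](config)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order; returns the run directory."""
    config.validate()
    rundir = _rundir(config)
    cio.write_results_json(rundir / "config.json", config.to_dict())
    for stage in STAGES:
        run_stage(config, stage)
    return rundir
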