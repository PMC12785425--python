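"""End-to-end orchestration: ingest or simulate, normalize, score
behavior, run association, network-comparison and hubness stages, and
write every result table plus a run manifest.

A single global seed is split into per-stage substreams
(:class:`numpy.random.SeedSequence`), so reruns of the same configuration
produce byte-identical result tables while stages stay independent.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import behavior as beh
from . import hubness as hub
from . import network as net
from .markers_io import (
    CONTROL_GROUP,
    GROUPS,
    META_COLUMNS,
    SEXES,
    MarkerPanel,
    apply_outlier_filter,
    impute_group_mean,
    read_expression_csv,
)
from .synthetic import SimConfig, simulate_cohort

logger = logging.getLogger("crsnet")

ALL_STAGES: tuple[str, ...] = (
    "ingest",
    "normalize",
    "behavior",
    "association",
    "network",
    "hubness",
)

#: Behavioral measures joined to markers in the association stage.
BEHAVIOR_MEASURES: tuple[str, ...] = (
    "coat_state",
    "weight_gain_pct",
    "sucrose_pref_pct",
    "ra_sz",
    "ra_fz",
    "z_emotionality",
)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; fully serialized for provenance."""

    outdir: str = "crsnet_out"
    expression_csv: str | None = None
    behavior_csv: str | None = None
    traces_csv: str | None = None
    sim: SimConfig | None = None
    panel_yaml: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    n_perm: int = 1000
    sexes: tuple[str, ...] = SEXES
    outlier_alpha: float = 0.05
    min_size: int = net.DEFAULT_MIN_SIZE
    cut_fraction: float = net.DEFAULT_CUT_FRACTION
    degree_threshold: float = hub.DEFAULT_DEGREE_THRESHOLD

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; valid: {ALL_STAGES}")
        has_files = self.expression_csv and self.behavior_csv and self.traces_csv
        if self.sim is None and not has_files:
            raise ValueError(
                "config needs either a simulation block or all three input CSVs"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("sim") is not None:
            sim = dict(raw["sim"])
            if "groups" in sim:
                sim["groups"] = tuple(sim["groups"])
            if "sexes" in sim:
                sim["sexes"] = tuple(sim["sexes"])
            raw["sim"] = SimConfig(**sim)
        for key in ("stages", "sexes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["stages"] = list(self.stages)
        raw["sexes"] = list(self.sexes)
        if self.sim is not None:
            raw["sim"]["groups"] = list(self.sim.groups)
            raw["sim"]["sexes"] = list(self.sim.sexes)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def validate_inputs(
    expression_csv: str | Path,
    behavior_csv: str | Path,
    traces_csv: str | Path,
    panel: MarkerPanel | None = None,
) -> list[dict[str, str]]:
    """Schema, label and cross-key checks across the three input files.

    Report-only: returns one record per violation (file, location,
    message); an empty list means the inputs are mutually consistent.
    """
    panel = panel or MarkerPanel.default()
    violations: list[dict[str, str]] = []

    expr = None
    try:
        expr = read_expression_csv(expression_csv, panel)
    except (ValueError, OSError) as exc:
        violations.append({"file": str(expression_csv), "where": "-", "message": str(exc)})

    behavior = None
    try:
        behavior = pd.read_csv(behavior_csv, dtype={"animal_id": str, "sex": str, "group": str})
        needed = {*META_COLUMNS, "week", "coat_state", "weight_g", "sucrose_ml", "water_ml"}
        missing = needed - set(behavior.columns)
        if missing:
            violations.append(
                {"file": str(behavior_csv), "where": "header",
                 "message": f"missing column(s) {sorted(missing)}"}
            )
            behavior = None
        else:
            for pos, row in enumerate(behavior.itertuples(index=False), start=2):
                if row.group not in GROUPS:
                    violations.append(
                        {"file": str(behavior_csv), "where": f"row {pos}",
                         "message": f"unknown group label {row.group!r}"}
                    )
                if row.sex not in SEXES:
                    violations.append(
                        {"file": str(behavior_csv), "where": f"row {pos}",
                         "message": f"unknown sex label {row.sex!r}"}
                    )
    except (ValueError, OSError) as exc:
        violations.append({"file": str(behavior_csv), "where": "-", "message": str(exc)})

    traces = None
    try:
        traces = pd.read_csv(traces_csv, dtype={"animal_id": str, "zone": str})
        needed = {"animal_id", "week", "bin_start_hour", "zone", "minutes"}
        missing = needed - set(traces.columns)
        if missing:
            violations.append(
                {"file": str(traces_csv), "where": "header",
                 "message": f"missing column(s) {sorted(missing)}"}
            )
            traces = None
        else:
            bad_zone = ~traces["zone"].isin(beh.ZONES)
            if bad_zone.any():
                pos = int(bad_zone.idxmax()) + 2
                violations.append(
                    {"file": str(traces_csv), "where": f"row {pos}",
                     "message": f"unknown zone label {traces['zone'][bad_zone].iloc[0]!r}"}
                )
            if ((traces["minutes"] < 0) | (traces["minutes"] > 60)).any():
                violations.append(
                    {"file": str(traces_csv), "where": "-",
                     "message": "zone minutes outside [0, 60]"}
                )
    except (ValueError, OSError) as exc:
        violations.append({"file": str(traces_csv), "where": "-", "message": str(exc)})

    if expr is not None and behavior is not None:
        expr_ids = set(expr["animal_id"])
        beh_ids = set(behavior["animal_id"])
        for animal in sorted(expr_ids - beh_ids):
            violations.append(
                {"file": str(expression_csv), "where": f"animal {animal}",
                 "message": "animal absent from behavior file"}
            )
        for animal in sorted(beh_ids - expr_ids):
            violations.append(
                {"file": str(behavior_csv), "where": f"animal {animal}",
                 "message": "animal absent from expression file"}
            )
    if traces is not None and behavior is not None:
        for animal in sorted(set(traces["animal_id"]) - set(behavior["animal_id"])):
            violations.append(
                {"file": str(traces_csv), "where": f"animal {animal}",
                 "message": "animal absent from behavior file"}
            )
    return violations


def _stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(seed).spawn(3)
    return {"sim": children[0], "network": children[1], "hubness": children[2]}


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all enabled stages; returns the run manifest.

    A stage failure is recorded in the manifest, downstream stages are
    skipped, and already-written outputs are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = MarkerPanel.from_yaml(config.panel_yaml) if config.panel_yaml else MarkerPanel.default()

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    config.to_yaml(outdir / "config.yaml")
    seeds = _stage_seeds(config.seed)
    manifest: dict[str, Any] = {
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": config.seed,
        "n_perm": config.n_perm,
        "stages": {},
        "outputs": [],
    }

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        frame.to_csv(path, index=False)
        manifest["outputs"].append(name)

    state: dict[str, Any] = {}
    failed = False
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages or failed:
                manifest["stages"][stage] = "skipped"
                continue
            t0 = time.time()
            try:
                _run_stage(stage, config, panel, seeds, state, emit, outdir, manifest)
                manifest["stages"][stage] = f"ok ({time.time() - t0:.1f}s)"
                logger.info("stage %s finished in %.1fs", stage, time.time() - t0)
            except Exception as exc:  # record and stop downstream stages
                manifest["stages"][stage] = f"failed: {exc}"
                logger.error("stage %s failed: %s", stage, exc)
                failed = True
    finally:
        manifest["ok"] = not failed
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        logger.removeHandler(handler)
        handler.close()
    return manifest


def _run_stage(stage, config, panel, seeds, state, emit, outdir, manifest) -> None:
    if stage == "ingest":
        if config.sim is not None:
            sim = dataclasses.replace(
                config.sim, seed=int(seeds["sim"].generate_state(1)[0] % (2**31))
            )
            cohort = simulate_cohort(sim, panel)
            state["expression"] = cohort.expression
            state["weekly"] = cohort.weekly
            state["traces"] = cohort.traces
            for name, frame in (
                ("expression.csv", cohort.expression),
                ("behavior.csv", cohort.weekly),
                ("traces.csv", cohort.traces),
            ):
                emit(name, frame)
        else:
            violations = validate_inputs(
                config.expression_csv, config.behavior_csv, config.traces_csv, panel
            )
            if violations:
                emit("validation_report.csv", pd.DataFrame(violations))
                raise ValueError(f"{len(violations)} input validation violation(s)")
            state["expression"] = read_expression_csv(config.expression_csv, panel)
            state["weekly"] = pd.read_csv(
                config.behavior_csv, dtype={"animal_id": str, "sex": str, "group": str}
            )
            state["traces"] = pd.read_csv(config.traces_csv, dtype={"animal_id": str, "zone": str})
    elif stage == "normalize":
        filtered, flags = apply_outlier_filter(
            state["expression"], panel, alpha=config.outlier_alpha
        )
        state["expression_clean"] = impute_group_mean(filtered, panel)
        emit("outlier_flags.csv", flags)
        emit("expression_imputed.csv", state["expression_clean"])
    elif stage == "behavior":
        scores = beh.score_behavior(state["weekly"], state["traces"])
        state["behavior_scores"] = scores
        emit("behavior_scores.csv", scores)
    elif stage == "association":
        expr = state.get("expression_clean", state["expression"])
        emit("marker_marker_correlations.csv", assoc.marker_marker_correlations(expr, panel))
        final_week = state["behavior_scores"]["week"].max()
        week5 = state["behavior_scores"][state["behavior_scores"]["week"] == final_week]
        joined = expr.merge(
            week5[["animal_id", *BEHAVIOR_MEASURES]], on="animal_id", how="inner"
        )
        emit(
            "marker_behavior_correlations.csv",
            assoc.marker_behavior_correlations(joined, panel.markers, BEHAVIOR_MEASURES),
        )
        pca = assoc.pca_markers(expr, panel)
        emit("pca_scores.csv", pca.scores.reset_index(names="animal_id"))
        emit("pca_loadings.csv", pca.loadings.reset_index(names="marker"))
        emit(
            "pca_variance.csv",
            pca.variance_explained_pct.rename_axis("component").reset_index(),
        )
        emit("pca_marker_pc_corr.csv", pca.marker_pc_corr.reset_index(names="marker"))
    elif stage == "network":
        expr = state["expression_clean"]
        pair_frames, module_frames = [], []
        net_seeds = seeds["network"].spawn(len(config.sexes))
        for sex, child in zip(config.sexes, net_seeds):
            for group in GROUPS:
                network = net.build_group_network(expr, group, sex, panel)
                partition = net.detect_modules(
                    network, min_size=config.min_size, cut_fraction=config.cut_fraction
                )
                state[f"network_{group}_{sex}"] = (network, partition)
                for fmt, suffix in (("sif", "sif"), ("graphml", "graphml")):
                    path = outdir / f"network_{group}_{sex}.{suffix}"
                    net.export_network(network, partition, path, fmt=fmt, panel=panel)
                    manifest["outputs"].append(path.name)
            summary, tests = net.compare_all_groups(
                expr, sex, panel, n_perm=config.n_perm, seed=None
                if child is None else int(child.generate_state(1)[0] % (2**31)),
                min_size=config.min_size, cut_fraction=config.cut_fraction,
            )
            pair_frames.append(summary)
            for t in tests:
                mods = t.modules.assign(group_a=t.group_a, group_b=t.group_b, sex=sex)
                module_frames.append(mods)
        emit("preservation_pairs.csv", pd.concat(pair_frames, ignore_index=True))
        emit(
            "preservation_modules.csv",
            pd.concat(module_frames, ignore_index=True)
            if module_frames
            else pd.DataFrame(
                columns=["module", "size", "best_match", "shared", "preservation",
                         "p", "group_a", "group_b", "sex"]
            ),
        )
    elif stage == "hubness":
        expr = state["expression_clean"]
        marker_frames, comp_frames = [], []
        hub_seeds = seeds["hubness"].spawn(len(config.sexes))
        for sex, child in zip(config.sexes, hub_seeds):
            results: dict[str, hub.HubChangeResult] = {}
            group_seeds = child.spawn(len(GROUPS))
            for group, gseed in zip(GROUPS, group_seeds):
                if group == CONTROL_GROUP:
                    continue
                res = hub.hub_change_test(
                    expr, sex, group, CONTROL_GROUP, panel,
                    n_perm=config.n_perm, seed=gseed,
                )
                results[group] = res
                marker_frames.append(res.to_frame())
            comp_frames.append(hub.compartment_trajectory(results, panel))
        emit("hubness_markers.csv", pd.concat(marker_frames, ignore_index=True))
        emit("hubness_compartments.csv", pd.concat(comp_frames, ignore_index=True))
    else:  # pragma: no cover
        raise AssertionError(f"unhandled stage {stage}")
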