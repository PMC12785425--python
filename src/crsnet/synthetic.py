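"""Synthetic cohorts with the study's design and statistical structure.

The generator emulates a chronic-restraint-stress (CRS) time-course
experiment: 6 stress durations (0–35 days) x 2 sexes x 8 mice, weekly
behavioral assessment over 5 weeks with staggered stress onset so every
group completes its duration at week 5, an 11-marker prefrontal-cortex
expression panel on the percent-of-control scale, and compartment-
structured residual correlation between markers (GABAergic / synaptic /
astroglial blocks).

Default effect profiles follow the study's qualitative result structure:
marker declines are graded with stress duration (VGLUT1 early, SYN1 and
PSD95 late), shelter-zone avoidance is programmed in every stressed group
from its first stressed week, and the sucrose-preference deficit appears
only at 35 days. Magnitudes are round fixture values, not estimates of
the original data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .behavior import POST_WINDOW_BINS, SESSION_BINS
from .markers_io import (
    CONTROL_GROUP,
    GROUPS,
    META_COLUMNS,
    SEXES,
    MarkerPanel,
    duration_days,
)

#: Graded mean shifts (percent-of-control units) per marker and group.
DEFAULT_MARKER_EFFECTS: dict[str, dict[str, float]] = {
    "VGLUT1": {"CRS7": -15, "CRS14": -15, "CRS21": -20, "CRS28": -20, "CRS35": -25},
    "SYN1": {"CRS21": -5, "CRS28": -10, "CRS35": -20},
    "PSD95": {"CRS14": -5, "CRS21": -10, "CRS28": -20, "CRS35": -20},
    "GAD67": {"CRS7": -5, "CRS14": -15, "CRS21": -15, "CRS28": -15, "CRS35": -10},
    "GFAP": {"CRS14": -5, "CRS21": -5, "CRS28": -10, "CRS35": -15},
}

#: Additive shift for males (females are the implicit baseline).
DEFAULT_SEX_OFFSETS: dict[str, float] = {
    "GFAP": 8.0,
    "SYN1": 8.0,
    "GPHN": 8.0,
    "PV": 8.0,
    "VIP": 6.0,
}

#: Behavioral shifts at full programmed exposure, per group:
#: shelter_min — extra shelter minutes per post-challenge hour bin;
#: sucrose_drop — percentage-point drop in sucrose preference;
#: coat — coat-state points added; weight_gain_drop — percentage points
#: of blunted weight gain at the end of the duration.
DEFAULT_BEHAVIOR_EFFECTS: dict[str, dict[str, float]] = {
    "CRS0": {"shelter_min": 0, "sucrose_drop": 0, "coat": 0, "weight_gain_drop": 0},
    "CRS7": {"shelter_min": 6, "sucrose_drop": 0, "coat": 1.0, "weight_gain_drop": 2},
    "CRS14": {"shelter_min": 8, "sucrose_drop": 0, "coat": 2.0, "weight_gain_drop": 4},
    "CRS21": {"shelter_min": 10, "sucrose_drop": 0, "coat": 3.0, "weight_gain_drop": 6},
    "CRS28": {"shelter_min": 12, "sucrose_drop": 0, "coat": 3.5, "weight_gain_drop": 8},
    "CRS35": {"shelter_min": 15, "sucrose_drop": 12, "coat": 4.0, "weight_gain_drop": 10},
}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    ``block_rho``/``cross_rho`` set the within- and between-compartment
    residual marker correlation, ``noise_sd`` the residual SD in percent
    units, and ``missing_rate`` the per-cell missingness probability.
    Identical configs (including ``seed``) yield identical cohorts.
    """

    n_per_cell: int = 8
    groups: tuple[str, ...] = GROUPS
    sexes: tuple[str, ...] = SEXES
    seed: int = 0
    marker_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(g) for m, g in DEFAULT_MARKER_EFFECTS.items()}
    )
    sex_offsets: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_OFFSETS))
    block_rho: float = 0.5
    cross_rho: float = 0.1
    noise_sd: float = 15.0
    behavior_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(e) for g, e in DEFAULT_BEHAVIOR_EFFECTS.items()}
    )
    missing_rate: float = 0.002

    def __post_init__(self) -> None:
        if self.n_per_cell < 0:
            raise ValueError("n_per_cell must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        if "sexes" in raw:
            raw["sexes"] = tuple(raw["sexes"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["groups"] = list(self.groups)
        raw["sexes"] = list(self.sexes)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class SyntheticCohort:
    """Expression table, raw weekly behavior and PhenoTyper traces,
    cross-keyed by ``animal_id``."""

    expression: pd.DataFrame
    weekly: pd.DataFrame
    traces: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / "expression.csv",
            "behavior": outdir / "behavior.csv",
            "traces": outdir / "traces.csv",
        }
        self.expression.to_csv(paths["expression"], index=False)
        self.weekly.to_csv(paths["behavior"], index=False)
        self.traces.to_csv(paths["traces"], index=False)
        return paths


def compartment_correlation(
    panel: MarkerPanel, block_rho: float, cross_rho: float
) -> np.ndarray:
    """Block correlation matrix: ``block_rho`` within a compartment,
    ``cross_rho`` between compartments, unit diagonal.

    Raises if the resulting matrix is not positive-definite, naming the
    offending parameters.
    """
    comps = np.array([panel.compartment_of[m] for m in panel.markers])
    same = comps[:, None] == comps[None, :]
    r = np.where(same, block_rho, cross_rho)
    np.fill_diagonal(r, 1.0)
    _require_pd(r, f"block_rho={block_rho}, cross_rho={cross_rho}")
    return r


def _require_pd(r: np.ndarray, what: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        raise ValueError(f"correlation matrix not positive-definite ({what})") from None


def _exposure_fraction(week: int, days: int) -> float:
    """Fraction of the programmed stress duration completed at *week*.

    Stress onset is staggered so every group finishes at week 5: a group
    stressed for d weeks starts at week 5 - d.
    """
    weeks = days / 7.0
    if weeks == 0:
        return 0.0
    return float(np.clip(week - (5.0 - weeks), 0.0, weeks) / weeks)


def _empty_cohort(panel: MarkerPanel) -> SyntheticCohort:
    return SyntheticCohort(
        expression=pd.DataFrame(columns=[*META_COLUMNS, *panel.markers]),
        weekly=pd.DataFrame(
            columns=[*META_COLUMNS, "week", "coat_state", "weight_g", "sucrose_ml", "water_ml"]
        ),
        traces=pd.DataFrame(columns=["animal_id", "week", "bin_start_hour", "zone", "minutes"]),
    )


def simulate_cohort(config: SimConfig, panel: MarkerPanel | None = None) -> SyntheticCohort:
    """Draw a full synthetic cohort under *config*.

    Expression: per-animal marker vector = 100 + group effect + male
    offset + multivariate Gaussian noise with compartment-block
    covariance, truncated at 0; after missingness is applied, each marker
    is rescaled so the mean over non-missing control animals (pooled
    across sexes) is exactly 100, mirroring percent-of-control
    normalization of real quantifications.
    """
    panel = panel or MarkerPanel.default()
    if config.n_per_cell == 0:
        return _empty_cohort(panel)
    rng_expr, rng_miss, rng_beh, rng_trace = (
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(4)
    )
    markers = list(panel.markers)
    m = len(markers)
    corr = compartment_correlation(panel, config.block_rho, config.cross_rho)
    chol = np.linalg.cholesky(corr)

    meta_rows = []
    for group in config.groups:
        for sex in config.sexes:
            for i in range(config.n_per_cell):
                meta_rows.append(
                    {"animal_id": f"{group}_{sex}{i + 1:02d}", "sex": sex, "group": group}
                )
    meta = pd.DataFrame(meta_rows)
    n = len(meta)

    mu = np.full((n, m), 100.0)
    for j, marker in enumerate(markers):
        effects = config.marker_effects.get(marker, {})
        mu[:, j] += meta["group"].map(lambda g: effects.get(g, 0.0)).to_numpy()
        mu[:, j] += np.where(meta["sex"] == "M", config.sex_offsets.get(marker, 0.0), 0.0)
    values = np.clip(mu + (rng_expr.standard_normal((n, m)) @ chol.T) * config.noise_sd, 0.0, None)
    if config.missing_rate > 0:
        values[rng_miss.random((n, m)) < config.missing_rate] = np.nan
    # percent-of-control: non-missing CRS0 mean -> exactly 100 per marker
    ctrl_rows = (meta["group"] == CONTROL_GROUP).to_numpy()
    if ctrl_rows.any():
        ctrl_means = np.nanmean(values[ctrl_rows], axis=0)
        values = 100.0 * values / ctrl_means
    expression = pd.concat([meta, pd.DataFrame(values, columns=markers)], axis=1)

    weekly_rows = []
    trace_rows = []
    for row in meta.itertuples(index=False):
        days = duration_days(row.group)
        eff = config.behavior_effects.get(row.group, {})
        w0 = rng_beh.normal(24.0, 1.5) if row.sex == "M" else rng_beh.normal(19.0, 1.2)
        for week in range(6):
            frac = _exposure_fraction(week, days)
            coat = np.clip(
                np.round(
                    (rng_beh.choice([0.0, 0.5], p=[0.7, 0.3])
                     + eff.get("coat", 0.0) * frac
                     + rng_beh.normal(0.0, 0.3)) * 2.0
                ) / 2.0,
                0.0, 7.0,
            )
            gain_pct = 1.5 * week - eff.get("weight_gain_drop", 0.0) * frac
            weight = max(10.0, w0 * (1.0 + gain_pct / 100.0 + rng_beh.normal(0.0, 0.01)))
            pref = np.clip(
                rng_beh.normal(75.0 - eff.get("sucrose_drop", 0.0) * frac, 8.0), 5.0, 95.0
            )
            total = max(0.2, rng_beh.normal(1.2, 0.2))
            weekly_rows.append(
                {
                    "animal_id": row.animal_id,
                    "sex": row.sex,
                    "group": row.group,
                    "week": week,
                    "coat_state": float(coat),
                    "weight_g": round(weight, 3),
                    "sucrose_ml": round(total * pref / 100.0, 4),
                    "water_ml": round(total * (1.0 - pref / 100.0), 4),
                }
            )
            shelter_shift = eff.get("shelter_min", 0.0) * frac
            for h in SESSION_BINS:
                p = rng_trace.dirichlet((2.0, 1.5, 2.5))
                sz, fz = 60.0 * p[0], 60.0 * p[1]
                if h in POST_WINDOW_BINS:
                    sz = min(60.0, sz + shelter_shift)
                    fz = min(fz, 60.0 - sz)
                trace_rows.append(
                    {"animal_id": row.animal_id, "week": week, "bin_start_hour": h,
                     "zone": "SZ", "minutes": round(sz, 3)}
                )
                trace_rows.append(
                    {"animal_id": row.animal_id, "week": week, "bin_start_hour": h,
                     "zone": "FZ", "minutes": round(fz, 3)}
                )
    return SyntheticCohort(
        expression=expression,
        weekly=pd.DataFrame(weekly_rows),
        traces=pd.DataFrame(trace_rows),
    )


def null_config(config: SimConfig) -> SimConfig:
    """Copy of *config* with every group effect and sex offset zeroed."""
    return dataclasses.replace(
        config,
        marker_effects={},
        sex_offsets={},
        behavior_effects={
            g: {"shelter_min": 0, "sucrose_drop": 0, "coat": 0, "weight_gain_drop": 0}
            for g in config.groups
        },
    )


def simulate_null(config: SimConfig, panel: MarkerPanel | None = None) -> SyntheticCohort:
    """Cohort with no group effects: the calibration harness for every
    permutation test in the pipeline."""
    return simulate_cohort(null_config(config), panel)


def planted_module_dataset(
    partition: Mapping[str, int],
    within_r: float,
    between_r: float,
    n: int,
    seed: int,
    noise_sd: float = 15.0,
) -> pd.DataFrame:
    """One-group expression table with a planted block-correlation structure.

    ``partition`` maps marker -> block id; the population correlation is
    ``within_r`` inside a block and ``between_r`` across blocks. Used as
    a module-recovery fixture for the clustering stage.
    """
    if within_r < between_r:
        raise ValueError("within_r must be >= between_r")
    markers = list(partition)
    blocks = np.array([partition[m] for m in markers])
    same = blocks[:, None] == blocks[None, :]
    r = np.where(same, within_r, between_r)
    np.fill_diagonal(r, 1.0)
    chol = _require_pd(r, f"within_r={within_r}, between_r={between_r}")
    rng = np.random.default_rng(seed)
    values = np.clip(
        100.0 + (rng.standard_normal((n, len(markers))) @ chol.T) * noise_sd, 0.0, None
    )
    meta = pd.DataFrame(
        {
            "animal_id": [f"S{i + 1:04d}" for i in range(n)],
            "sex": [SEXES[i % 2] for i in range(n)],
            "group": CONTROL_GROUP,
        }
    )
    return pd.concat([meta, pd.DataFrame(values, columns=markers)], axis=1)
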