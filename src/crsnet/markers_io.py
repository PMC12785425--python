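"""Marker panel model, quantification normalization, outlier flagging and
expression-table I/O.

The panel covers 11 prefrontal-cortex markers quantified either by
immunoblot (protein, normalized to total protein) or by qPCR (RNA,
normalized to the geometric mean of three reference transcripts). All
downstream analyses operate on *percent-of-control* values: for each
marker the unstressed (CRS0) group mean is scaled to 100.

An expression table is a plain :class:`pandas.DataFrame` with the metadata
columns ``animal_id``, ``sex``, ``group`` followed by one column per
marker; missing measurements are ``NaN`` (empty cells on disk).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger("crsnet")

#: Stress-duration groups, in days of chronic restraint stress.
GROUPS: tuple[str, ...] = ("CRS0", "CRS7", "CRS14", "CRS21", "CRS28", "CRS35")
CONTROL_GROUP = "CRS0"
SEXES: tuple[str, ...] = ("M", "F")
META_COLUMNS: tuple[str, ...] = ("animal_id", "sex", "group")

COMPARTMENTS: tuple[str, ...] = ("GABAergic", "synaptic", "astroglial")
ASSAYS: tuple[str, ...] = ("protein", "RNA")

_DEFAULT_PANEL: dict[str, tuple[str, str]] = {
    "GAD67": ("GABAergic", "protein"),
    "SST": ("GABAergic", "RNA"),
    "PV": ("GABAergic", "RNA"),
    "VIP": ("GABAergic", "RNA"),
    "VGLUT1": ("synaptic", "protein"),
    "PSD95": ("synaptic", "protein"),
    "SYN1": ("synaptic", "protein"),
    "GPHN": ("synaptic", "protein"),
    "GLT1": ("astroglial", "protein"),
    "GFAP": ("astroglial", "protein"),
    "GS": ("astroglial", "protein"),
}


def duration_days(group: str) -> int:
    """Days of restraint stress encoded in a group label (``CRS14`` -> 14)."""
    if group not in GROUPS:
        raise ValueError(f"unknown group label {group!r}")
    return int(group[3:])


@dataclass(frozen=True)
class MarkerPanel:
    """The marker panel: identifiers plus compartment and assay tags.

    Compartments partition the panel into GABAergic, synaptic and
    astroglial marker groups; the assay tag records whether a marker is
    quantified at the protein (immunoblot) or RNA (qPCR) level.
    """

    markers: tuple[str, ...]
    compartment_of: Mapping[str, str]
    assay_of: Mapping[str, str]

    def __post_init__(self) -> None:
        for m in self.markers:
            if m not in self.compartment_of:
                raise ValueError(f"marker {m!r} has no compartment")
            if m not in self.assay_of:
                raise ValueError(f"marker {m!r} has no assay")
            if self.compartment_of[m] not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {self.compartment_of[m]!r} for {m!r}")
            if self.assay_of[m] not in ASSAYS:
                raise ValueError(f"unknown assay {self.assay_of[m]!r} for {m!r}")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker identifiers in panel")

    @classmethod
    def default(cls) -> "MarkerPanel":
        return cls(
            markers=tuple(_DEFAULT_PANEL),
            compartment_of={m: c for m, (c, _) in _DEFAULT_PANEL.items()},
            assay_of={m: a for m, (_, a) in _DEFAULT_PANEL.items()},
        )

    def compartments(self) -> dict[str, list[str]]:
        """Map compartment -> ordered list of member markers."""
        out: dict[str, list[str]] = {c: [] for c in COMPARTMENTS}
        for m in self.markers:
            out[self.compartment_of[m]].append(m)
        return {c: ms for c, ms in out.items() if ms}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkerPanel":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        markers = tuple(spec)
        return cls(
            markers=markers,
            compartment_of={m: spec[m]["compartment"] for m in markers},
            assay_of={m: spec[m]["assay"] for m in markers},
        )

    def to_yaml(self, path: str | Path) -> None:
        spec = {
            m: {"compartment": self.compartment_of[m], "assay": self.assay_of[m]}
            for m in self.markers
        }
        with open(path, "w") as fh:
            yaml.safe_dump(spec, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Quantification normalization
# ---------------------------------------------------------------------------

def normalize_western(records: pd.DataFrame, control_group: str = CONTROL_GROUP) -> pd.Series:
    """Total-protein normalization, expressed as percent of control.

    ``records`` needs the columns ``group``, ``band_intensity`` and
    ``total_protein`` (arbitrary densitometry units). Each sample's ratio
    band/total is scaled so the control-group mean ratio maps to 100.
    """
    for col in ("group", "band_intensity", "total_protein"):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    total = records["total_protein"].to_numpy(float)
    if np.any(~np.isfinite(total)) or np.any(total <= 0):
        raise ValueError("total_protein must be finite and > 0 for every record")
    ratio = records["band_intensity"].to_numpy(float) / total
    ctrl = ratio[(records["group"] == control_group).to_numpy()]
    if ctrl.size == 0:
        raise ValueError(f"control group {control_group!r} is empty")
    return pd.Series(100.0 * ratio / ctrl.mean(), index=records.index)


def normalize_qpcr(
    records: pd.DataFrame,
    control_group: str = CONTROL_GROUP,
    ref_columns: Sequence[str] = ("ct_ref1", "ct_ref2", "ct_ref3"),
) -> pd.Series:
    """Delta-Ct normalization against the geometric mean of three references.

    Relative expression is ``2 ** -(ct_target - geomean(ct_refs))``; the
    result is scaled so the control-group mean relative expression is 100.
    """
    if len(ref_columns) != 3:
        raise ValueError("exactly 3 reference Ct columns are required")
    for col in ("group", "ct_target", *ref_columns):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    refs = records[list(ref_columns)].to_numpy(float)
    target = records["ct_target"].to_numpy(float)
    if np.any(~np.isfinite(refs)) or np.any(refs <= 0):
        raise ValueError("reference Ct values must be finite and > 0")
    if np.any(~np.isfinite(target)) or np.any(target <= 0):
        raise ValueError("target Ct values must be finite and > 0")
    geomean = np.exp(np.log(refs).mean(axis=1))
    rel = np.power(2.0, -(target - geomean))
    ctrl = rel[(records["group"] == control_group).to_numpy()]
    if ctrl.size == 0:
        raise ValueError(f"control group {control_group!r} is empty")
    return pd.Series(100.0 * rel / ctrl.mean(), index=records.index)


# ---------------------------------------------------------------------------
# Outlier flagging (two-sided Grubbs)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for a sample of size *n*."""
    if n < 3:
        raise ValueError("Grubbs test requires at least 3 values")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(values: Sequence[float], alpha: float = 0.05) -> int | None:
    """Index (positional) of the single most extreme value if it is a
    significant two-sided Grubbs outlier, else ``None``.

    A zero-variance sample has no outlier by definition.
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x)] if np.isnan(x).any() else x
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test requires at least 3 non-missing values")
    sd = x.std(ddof=1)
    if sd == 0:
        return None
    dev = np.abs(x - x.mean())
    g = dev.max() / sd
    if g > grubbs_critical(n, alpha):
        return int(dev.argmax())
    return None


def flag_outliers(
    table: pd.DataFrame, marker: str, group: str, alpha: float = 0.05
) -> list[str]:
    """Animal ids flagged as Grubbs outliers for one marker within one group.

    At most one animal is flagged per (marker, group): the test targets a
    single extreme sample. Flagged values are set missing downstream by
    :func:`apply_outlier_filter`.
    """
    sub = table.loc[table["group"] == group, ["animal_id", marker]].dropna(subset=[marker])
    if len(sub) < 3:
        raise ValueError(
            f"need >= 3 non-missing values for {marker} in {group}, have {len(sub)}"
        )
    idx = grubbs_test(sub[marker].to_numpy(float), alpha=alpha)
    if idx is None:
        return []
    return [sub["animal_id"].iloc[idx]]


def apply_outlier_filter(
    table: pd.DataFrame,
    panel: MarkerPanel | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag and blank Grubbs outliers for every (marker, group) cell.

    Returns the filtered table (flagged cells set to NaN) and a record of
    the flags (animal_id, marker, group, value).
    """
    panel = panel or MarkerPanel.default()
    out = table.copy()
    flags: list[dict] = []
    for marker in panel.markers:
        for group in GROUPS:
            sub = out.loc[out["group"] == group, ["animal_id", marker]].dropna(subset=[marker])
            if len(sub) < 3:
                continue
            idx = grubbs_test(sub[marker].to_numpy(float), alpha=alpha)
            if idx is None:
                continue
            animal = sub["animal_id"].iloc[idx]
            value = float(sub[marker].iloc[idx])
            out.loc[out["animal_id"] == animal, marker] = np.nan
            flags.append(
                {"animal_id": animal, "marker": marker, "group": group, "value": value}
            )
            logger.info("outlier removed: %s %s in %s (value %.2f)", animal, marker, group, value)
    return out, pd.DataFrame(flags, columns=["animal_id", "marker", "group", "value"])


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_group_mean(
    table: pd.DataFrame,
    panel: MarkerPanel | None = None,
    by: Sequence[str] = ("group", "sex"),
) -> pd.DataFrame:
    """Replace each missing marker value by its stratum mean.

    The stratum is group x sex by default so that imputed values cannot
    leak sex effects into sex-split network analyses. Errors if a stratum
    has no observed value to average.
    """
    panel = panel or MarkerPanel.default()
    out = table.copy()
    for marker in panel.markers:
        if marker not in out.columns:
            raise ValueError(f"table missing marker column {marker!r}")
        if not out[marker].isna().any():
            continue
        grouped = out.groupby(list(by))[marker]
        means = grouped.transform("mean")
        missing = out[marker].isna()
        if means[missing].isna().any():
            bad = out.loc[missing & means.isna(), list(by)].iloc[0].tolist()
            raise ValueError(
                f"cannot impute {marker}: stratum {tuple(bad)} has no observed value"
            )
        out.loc[missing, marker] = means[missing]
    return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_expression_csv(path: str | Path, panel: MarkerPanel | None = None) -> pd.DataFrame:
    """Read an expression table; empty cells become missing values.

    Validates the header against the panel and the metadata labels row by
    row; errors cite the offending CSV row (header = row 1).
    """
    panel = panel or MarkerPanel.default()
    table = pd.read_csv(path, dtype={"animal_id": str, "sex": str, "group": str})
    for col in META_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    value_cols = [c for c in table.columns if c not in META_COLUMNS]
    unknown = [c for c in value_cols if c not in panel.markers]
    if unknown:
        raise ValueError(f"{path}: unknown marker column(s) {unknown}")
    missing_markers = [m for m in panel.markers if m not in value_cols]
    if missing_markers:
        raise ValueError(f"{path}: missing marker column(s) {missing_markers}")
    for pos, row in enumerate(table.itertuples(index=False), start=2):
        if row.group not in GROUPS:
            raise ValueError(f"{path} row {pos}: unknown group label {row.group!r}")
        if row.sex not in SEXES:
            raise ValueError(f"{path} row {pos}: unknown sex label {row.sex!r}")
    dup = table["animal_id"].duplicated()
    if dup.any():
        pos = int(dup.idxmax()) + 2
        raise ValueError(
            f"{path} row {pos}: duplicate animal_id {table['animal_id'][dup].iloc[0]!r}"
        )
    values = table[list(panel.markers)].to_numpy(float)
    if np.nanmin(values, initial=0.0) < 0:
        raise ValueError(f"{path}: negative expression value")
    return table[[*META_COLUMNS, *panel.markers]]


def write_expression_csv(
    table: pd.DataFrame, path: str | Path, panel: MarkerPanel | None = None
) -> None:
    """Write an expression table; missing values become empty cells."""
    panel = panel or MarkerPanel.default()
    cols = [*META_COLUMNS, *panel.markers]
    table[cols].to_csv(path, index=False)
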