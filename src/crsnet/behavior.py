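"""Behavioral readouts for the chronic restraint stress paradigm.

Five weekly measures feed the integrated emotionality score:

* coat state — sum of 7 body-part grooming scores (0 / 0.5 / 1 each);
* weight gain — percent change from the animal's week-0 weight;
* sucrose preference — sucrose as percent of total fluid consumed;
* residual avoidance (RA) in the shelter zone (SZ) and food zone (FZ)
  of the PhenoTyper home-cage test, after a 1-h light challenge applied
  at 11 p.m.;
* Z-emotionality — the mean of direction-aligned z-scores of the above,
  referenced to same-sex controls, higher = greater behavioral deficit.

RA is the signed percent deviation of an animal's zone time, summed over
the 5 h following the light challenge, from the mean of same-week,
same-sex control animals. Controls therefore average to an RA of 0 by
construction; stressed animals that hide in the shelter (more SZ time,
less FZ time) score positive in both zones.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .markers_io import CONTROL_GROUP, SEXES

logger = logging.getLogger("crsnet")

#: Hour (24-h clock) at which the 1-h light challenge starts.
CHALLENGE_START_HOUR = 23
CHALLENGE_DURATION_HOURS = 1
POST_WINDOW_HOURS = 5
#: Clock-aligned, half-open hour bins of the 5-h post-challenge window.
POST_WINDOW_BINS: tuple[int, ...] = (0, 1, 2, 3, 4)
#: Overnight PhenoTyper session bins (7 p.m. through the 7 a.m. bin).
SESSION_BINS: tuple[int, ...] = (19, 20, 21, 22, 23, 0, 1, 2, 3, 4, 5, 6, 7)

ZONES: tuple[str, ...] = ("SZ", "FZ")
#: Sign convention per zone: avoidance = more shelter time, less food-zone time.
ZONE_SIGN: dict[str, float] = {"SZ": 1.0, "FZ": -1.0}

#: Emotionality measures and their deficit-aligned directions: a stressed
#: animal has a degraded coat and high RA (+1) but gains less weight and
#: prefers sucrose less (-1).
Z_DIRECTIONS: dict[str, float] = {
    "coat_state": 1.0,
    "weight_gain_pct": -1.0,
    "ra_sz": 1.0,
    "ra_fz": 1.0,
    "sucrose_pref_pct": -1.0,
}

_COAT_ALLOWED = (0.0, 0.5, 1.0)


def coat_state_score(part_scores: Sequence[float]) -> float:
    """Total coat-state score: the sum of the 7 body-part scores."""
    if len(part_scores) != 7:
        raise ValueError(f"expected 7 body-part scores, got {len(part_scores)}")
    for s in part_scores:
        if s not in _COAT_ALLOWED:
            raise ValueError(f"part score {s!r} not in {{0, 0.5, 1}}")
    return float(sum(part_scores))


def weight_gain_pct(weight_now: float, weight_week0: float) -> float:
    """Percent weight change relative to the week-0 reference weight."""
    if not weight_week0 > 0:
        raise ValueError("week-0 reference weight must be positive")
    return 100.0 * (weight_now - weight_week0) / weight_week0


def sucrose_preference(sucrose_ml: float, water_ml: float) -> float:
    """Sucrose intake as percent of total fluid; NaN when nothing was drunk."""
    if sucrose_ml < 0 or water_ml < 0:
        raise ValueError("fluid volumes must be non-negative")
    total = sucrose_ml + water_ml
    if total == 0:
        return float("nan")
    return 100.0 * sucrose_ml / total


def residual_avoidance(
    traces: pd.DataFrame,
    meta: pd.DataFrame,
    zone: str,
    control_group: str = CONTROL_GROUP,
) -> pd.DataFrame:
    """Per-animal, per-week residual avoidance for one zone.

    Parameters
    ----------
    traces
        Long table with columns ``animal_id``, ``week``, ``bin_start_hour``,
        ``zone``, ``minutes`` (minutes in zone per clock-hour bin).
    meta
        One row per animal with ``animal_id``, ``sex``, ``group``.
    zone
        ``"SZ"`` or ``"FZ"``.

    Returns a frame ``animal_id, week, ra``. An animal missing any of the
    five post-challenge bins that week gets NaN. The reference is the mean
    post-window zone time of same-week, same-sex control animals.
    """
    if zone not in ZONES:
        raise ValueError(f"zone must be one of {ZONES}, got {zone!r}")
    sub = traces[(traces["zone"] == zone) & traces["bin_start_hour"].isin(POST_WINDOW_BINS)]
    agg = sub.groupby(["animal_id", "week"])["minutes"].agg(["sum", "size"]).reset_index()
    agg["total"] = np.where(agg["size"] == len(POST_WINDOW_BINS), agg["sum"], np.nan)
    incomplete = int((agg["size"] != len(POST_WINDOW_BINS)).sum())
    if incomplete:
        logger.warning("%d animal-weeks with incomplete %s post-window traces", incomplete, zone)
    merged = agg.merge(meta[["animal_id", "sex", "group"]], on="animal_id", how="left")
    sign = ZONE_SIGN[zone]
    out = []
    for (week, sex), grp in merged.groupby(["week", "sex"]):
        ctrl = grp.loc[grp["group"] == control_group, "total"].dropna()
        if ctrl.empty:
            raise ValueError(f"no control animals for week {week}, sex {sex}")
        ref = ctrl.mean()
        if ref == 0:
            raise ValueError(f"control mean {zone} time is 0 for week {week}, sex {sex}")
        ra = sign * 100.0 * (grp["total"] - ref) / ref
        out.append(pd.DataFrame({"animal_id": grp["animal_id"], "week": week, "ra": ra}))
    return (
        pd.concat(out, ignore_index=True)
        .sort_values(["animal_id", "week"], kind="stable")
        .reset_index(drop=True)
    )


def z_emotionality(
    behavior: pd.DataFrame,
    control_group: str = CONTROL_GROUP,
    measures: Mapping[str, float] = Z_DIRECTIONS,
) -> pd.Series:
    """Integrated emotionality Z-score per animal.

    Each measure is z-scored against same-sex control mean and SD, sign
    aligned so that higher always means a greater deficit, and the
    available component z-scores are averaged. A measure whose control SD
    is zero (or undefined) is dropped for that sex with a warning.

    ``behavior`` holds one row per animal (a single week's data) with the
    measure columns plus ``sex`` and ``group``; the returned Series is
    aligned to its index.
    """
    z = pd.Series(np.nan, index=behavior.index, dtype=float)
    for sex, grp in behavior.groupby("sex"):
        ctrl = grp[grp["group"] == control_group]
        if len(ctrl) < 2:
            raise ValueError(f"need >= 2 control animals for sex {sex!r}")
        comps = []
        for measure, direction in measures.items():
            vals = ctrl[measure].dropna()
            sd = vals.std(ddof=1)
            if len(vals) < 2 or not np.isfinite(sd) or sd == 0:
                warnings.warn(
                    f"measure {measure!r} dropped for sex {sex!r}: zero/undefined control SD",
                    stacklevel=2,
                )
                logger.warning("z_emotionality: dropping %s for sex %s", measure, sex)
                continue
            comps.append(direction * (grp[measure] - vals.mean()) / sd)
        if not comps:
            raise ValueError(f"no usable measures for sex {sex!r}")
        z.loc[grp.index] = pd.concat(comps, axis=1).mean(axis=1)
    return z


def score_behavior(
    weekly: pd.DataFrame,
    traces: pd.DataFrame,
    control_group: str = CONTROL_GROUP,
) -> pd.DataFrame:
    """Compute the full behavior table from raw weekly records and traces.

    ``weekly`` has one row per animal-week with columns ``animal_id``,
    ``sex``, ``group``, ``week``, ``coat_state``, ``weight_g``,
    ``sucrose_ml``, ``water_ml``. Returns the same rows augmented with
    ``weight_gain_pct``, ``sucrose_pref_pct``, ``ra_sz``, ``ra_fz`` and
    ``z_emotionality`` (z computed within each week, per sex).
    """
    out = weekly.copy()
    ref = (
        out[out["week"] == 0]
        .set_index("animal_id")["weight_g"]
        .rename("weight_week0")
    )
    out = out.merge(ref, left_on="animal_id", right_index=True, how="left")
    if out["weight_week0"].isna().any() or (out["weight_week0"] <= 0).any():
        raise ValueError("every animal needs a positive week-0 weight")
    out["weight_gain_pct"] = 100.0 * (out["weight_g"] - out["weight_week0"]) / out["weight_week0"]
    total = out["sucrose_ml"] + out["water_ml"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["sucrose_pref_pct"] = np.where(total > 0, 100.0 * out["sucrose_ml"] / total, np.nan)

    meta = out[["animal_id", "sex", "group"]].drop_duplicates("animal_id")
    for zone, col in (("SZ", "ra_sz"), ("FZ", "ra_fz")):
        ra = residual_avoidance(traces, meta, zone, control_group)
        out = out.merge(
            ra.rename(columns={"ra": col}), on=["animal_id", "week"], how="left"
        )

    out["z_emotionality"] = np.nan
    for week, grp in out.groupby("week"):
        out.loc[grp.index, "z_emotionality"] = z_emotionality(grp, control_group)
    return out.drop(columns=["weight_week0"])
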