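"""Marker-marker and marker-behavior correlation analyses and marker PCA.

Pearson correlation is the default; coat-state scores are ordinal (0-7 in
half-point steps) so any pair involving coat state uses Spearman's rank
correlation. Multiple testing within a family is handled by
Benjamini-Hochberg FDR; the 55 unique pairs of the 11-marker panel form
one such family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .markers_io import MarkerPanel

logger = logging.getLogger("crsnet")

#: Variables treated as ordinal: these force Spearman correlation.
ORDINAL_VARIABLES = ("coat_state",)


def default_method(a: str, b: str) -> str:
    """Pearson, unless either member is ordinal (coat state) -> Spearman."""
    return "spearman" if (a in ORDINAL_VARIABLES or b in ORDINAL_VARIABLES) else "pearson"


def all_marker_pairs(panel: MarkerPanel | None = None) -> list[tuple[str, str, str]]:
    """The unique marker pairs of the panel (55 for the default 11 markers)."""
    panel = panel or MarkerPanel.default()
    return [(a, b, "pearson") for a, b in combinations(panel.markers, 2)]


def correlate_pairs(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str, str]],
) -> pd.DataFrame:
    """Correlation coefficient and two-sided p for each requested pair.

    Each pair is ``(a, b, method)`` with method ``pearson`` or
    ``spearman``; requesting Pearson for an ordinal variable is an error.
    Pairs with fewer than 3 complete cases, or with a constant member,
    yield a missing coefficient (logged / warned). Returns a frame with
    columns ``a, b, method, coefficient, p, n_used``.
    """
    rows = []
    for a, b, method in pairs:
        if method not in ("pearson", "spearman"):
            raise ValueError(f"unknown method {method!r} for pair ({a}, {b})")
        if method == "pearson" and (a in ORDINAL_VARIABLES or b in ORDINAL_VARIABLES):
            raise ValueError(
                f"pair ({a}, {b}): ordinal variable requires spearman, not pearson"
            )
        sub = table[[a, b]].dropna()
        n = len(sub)
        if n < 3:
            logger.warning("pair (%s, %s): only %d complete cases, skipped", a, b, n)
            rows.append((a, b, method, np.nan, np.nan, n))
            continue
        x = sub[a].to_numpy(float)
        y = sub[b].to_numpy(float)
        if a == b:
            rows.append((a, b, method, 1.0, 0.0, n))
            continue
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"pair ({a}, {b}): constant variable, no coefficient", stacklevel=2)
            rows.append((a, b, method, np.nan, np.nan, n))
            continue
        if method == "pearson":
            res = stats.pearsonr(x, y)
        else:
            res = stats.spearmanr(x, y)
        rows.append((a, b, method, float(res.statistic), float(res.pvalue), n))
    return pd.DataFrame(rows, columns=["a", "b", "method", "coefficient", "p", "n_used"])


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def marker_marker_correlations(
    table: pd.DataFrame, panel: MarkerPanel | None = None
) -> pd.DataFrame:
    """All-pairs marker correlations with BH q over the single 55-test family."""
    res = correlate_pairs(table, all_marker_pairs(panel))
    res["q"] = np.nan
    ok = res["p"].notna()
    if ok.any():
        res.loc[ok, "q"] = bh_fdr(res.loc[ok, "p"].to_numpy())
    return res


def marker_behavior_correlations(
    table: pd.DataFrame,
    markers: Sequence[str],
    behaviors: Sequence[str],
) -> pd.DataFrame:
    """Marker x behavioral-measure correlations on a joined table.

    Methods follow the ordinal rule (Spearman for coat state). Raw p is
    the primary readout; a BH q over the family is included for
    transparency.
    """
    pairs = [(m, b, default_method(m, b)) for m in markers for b in behaviors]
    res = correlate_pairs(table, pairs)
    res["q"] = np.nan
    ok = res["p"].notna()
    if ok.any():
        res.loc[ok, "q"] = bh_fdr(res.loc[ok, "p"].to_numpy())
    return res


@dataclass
class PCAResult:
    """Principal component analysis of the standardized marker panel.

    ``loadings`` are the orthonormal component vectors (markers x PCs),
    ``scores`` the animal projections, ``variance_explained_pct`` sums to
    100 over all components, and ``marker_pc_corr`` holds the Pearson
    correlation of each (standardized) marker with each of the first
    reported component scores.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained_pct: pd.Series
    marker_pc_corr: pd.DataFrame


def pca_markers(
    table: pd.DataFrame,
    panel: MarkerPanel | None = None,
    n_report: int = 3,
) -> PCAResult:
    """PCA of the marker panel after per-marker standardization.

    Requires a complete table (impute first). Each component is oriented
    so its largest-magnitude loading is positive, making the output
    deterministic. Errors name any zero-variance marker.
    """
    panel = panel or MarkerPanel.default()
    x = table[list(panel.markers)].to_numpy(float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 animals")
    if np.isnan(x).any():
        raise ValueError("missing values present; impute before PCA")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = [m for m, s in zip(panel.markers, sd) if s == 0]
        raise ValueError(f"zero-variance marker(s): {bad}")
    z = (x - x.mean(axis=0)) / sd

    pca = PCA()
    scores = pca.fit_transform(z)
    loadings = pca.components_.T  # markers x components, orthonormal
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    pcs = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    n_report = min(n_report, len(pcs))
    corr = np.empty((len(panel.markers), n_report))
    for j in range(n_report):
        s = scores[:, j]
        s_sd = s.std()
        for i in range(len(panel.markers)):
            corr[i, j] = (
                np.nan
                if s_sd == 0
                else np.corrcoef(z[:, i], s)[0, 1]
            )
    index = table["animal_id"] if "animal_id" in table.columns else table.index
    return PCAResult(
        scores=pd.DataFrame(scores, columns=pcs, index=index),
        loadings=pd.DataFrame(loadings, columns=pcs, index=list(panel.markers)),
        variance_explained_pct=pd.Series(
            100.0 * pca.explained_variance_ratio_, index=pcs, name="variance_explained_pct"
        ),
        marker_pc_corr=pd.DataFrame(
            corr, columns=pcs[:n_report], index=list(panel.markers)
        ),
    )
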