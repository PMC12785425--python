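"""Node centrality, permutation tests of hub-score change, and
compartment-level Stouffer meta-analysis.

Hub score is Kleinberg's centrality of the weighted co-expression graph:
for an undirected network with non-negative symmetric adjacency it is the
principal (Perron) eigenvector of the adjacency matrix, rescaled so the
most central marker scores 1. Hub and authority scores coincide for
symmetric adjacency. The score is computed on the full weighted |r|
graph over all 11 markers; no edge threshold or module restriction is
applied to centrality (degree alone uses an inclusion threshold so that
it is not trivially n - 1).

Changes versus the unstressed (CRS0) group of the same sex are tested by
the same animal-label permutation scheme as module preservation:
pool the two cells, re-split at the original sizes, rebuild both
networks and recompute per-marker hub-score differences. Two-sided
empirical p-values (add-one estimator) are combined per compartment by
unweighted Stouffer meta-analysis with signs carried from the observed
differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .markers_io import CONTROL_GROUP, MarkerPanel
from .network import GroupNetwork, _cell_matrix, _pearson_matrix, _MAX_REDRAWS

logger = logging.getLogger("crsnet")

#: |r| at or above this counts as an edge for the degree metric.
DEFAULT_DEGREE_THRESHOLD = 0.3


def kleinberg_hub_scores(
    adjacency: np.ndarray, tol: float = 1e-10, max_iter: int = 100_000
) -> np.ndarray:
    """Principal-eigenvector centrality of a non-negative symmetric matrix.

    Power iteration on the diagonally shifted adjacency (the shift leaves
    eigenvectors untouched but guarantees convergence to the Perron
    vector), run to relative tolerance *tol* and rescaled so the maximum
    score is 1. An all-zero adjacency yields all-zero scores.
    """
    a = np.asarray(adjacency, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if (a < 0).any():
        raise ValueError("adjacency must be non-negative")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    n = a.shape[0]
    if not a.any():
        logger.warning("all-zero adjacency: hub scores are 0")
        return np.zeros(n)
    shift = a.sum(axis=1).max()
    m = a + shift * np.eye(n)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = m @ x
        y /= np.linalg.norm(y)
        if np.abs(y - x).max() < tol:
            x = y
            break
        x = y
    return x / x.max()


def node_metrics(
    network: GroupNetwork, degree_threshold: float = DEFAULT_DEGREE_THRESHOLD
) -> pd.DataFrame:
    """Degree, strength and Kleinberg hub score per marker.

    Degree counts incident edges with weight >= ``degree_threshold``;
    strength sums all incident weights; hub score is max-normalized to 1.
    """
    a = network.adjacency
    return pd.DataFrame(
        {
            "marker": list(network.markers),
            "degree": (a >= degree_threshold).sum(axis=1).astype(int),
            "strength": a.sum(axis=1),
            "hubscore": kleinberg_hub_scores(a),
        }
    )


def _hub_from_x(x: np.ndarray) -> np.ndarray:
    a = np.abs(_pearson_matrix(x))
    np.fill_diagonal(a, 0.0)
    return kleinberg_hub_scores(a)


@dataclass
class HubChangeResult:
    """Per-marker hub-score change of one group versus the reference."""

    group: str
    reference_group: str
    sex: str
    markers: tuple[str, ...]
    hub_group: np.ndarray
    hub_reference: np.ndarray
    diff: np.ndarray
    p: np.ndarray
    n_perm: int
    seed: int | None
    n_redraws: int = 0
    null_draws: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": list(self.markers),
                "group": self.group,
                "reference_group": self.reference_group,
                "sex": self.sex,
                "hubscore": self.hub_group,
                "hubscore_reference": self.hub_reference,
                "observed_diff": self.diff,
                "p": self.p,
            }
        )


def hub_change_test(
    table: pd.DataFrame,
    sex: str,
    group: str,
    reference_group: str = CONTROL_GROUP,
    panel: MarkerPanel | None = None,
    n_perm: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
    keep_null: bool = False,
) -> HubChangeResult:
    """Permutation test of per-marker hub-score change versus the reference.

    The observed statistic is hubscore(group) - hubscore(reference) per
    marker; the null permutes animal labels between the two cells
    (original sizes preserved) and rebuilds both networks. Two-sided
    empirical p per marker with the add-one estimator.
    """
    panel = panel or MarkerPanel.default()
    if n_perm < 100:
        logger.warning("n_perm=%d is low; empirical p resolution is %.3g", n_perm, 1 / (n_perm + 1))
    xg = _cell_matrix(table, group, sex, panel.markers)
    xr = _cell_matrix(table, reference_group, sex, panel.markers)
    diff = _hub_from_x(xg) - _hub_from_x(xr)

    rng = np.random.default_rng(seed)
    pooled = np.vstack([xg, xr])
    n_g, n_total = xg.shape[0], pooled.shape[0]
    m = len(panel.markers)
    null = np.empty((n_perm, m))
    n_redraws = 0
    for t in range(n_perm):
        for _ in range(_MAX_REDRAWS):
            perm = rng.permutation(n_total)
            pg, pr = pooled[perm[:n_g]], pooled[perm[n_g:]]
            if (np.ptp(pg, axis=0) == 0).any() or (np.ptp(pr, axis=0) == 0).any():
                n_redraws += 1
                continue
            break
        else:
            raise RuntimeError("could not draw a non-degenerate permutation")
        null[t] = _hub_from_x(pg) - _hub_from_x(pr)
    if n_redraws:
        logger.info("hub test (%s vs %s, %s): %d degenerate draws redrawn",
                    group, reference_group, sex, n_redraws)
    p = (np.sum(np.abs(null) >= np.abs(diff)[None, :], axis=0) + 1.0) / (n_perm + 1.0)
    return HubChangeResult(
        group=group,
        reference_group=reference_group,
        sex=sex,
        markers=tuple(panel.markers),
        hub_group=_hub_from_x(xg),
        hub_reference=_hub_from_x(xr),
        diff=diff,
        p=p,
        n_perm=n_perm,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        n_redraws=n_redraws,
        null_draws=null if keep_null else None,
    )


def stouffer_meta(
    p_values: Sequence[float],
    directions: Sequence[float],
    zero_floor: float | None = None,
) -> tuple[float, int]:
    """Unweighted Stouffer combination of two-sided p-values with signs.

    Each two-sided p is converted to a signed z, ``d_i * Phi^-1(1 - p/2)``;
    the combined two-sided p is ``2 * (1 - Phi(|sum z / sqrt(k)|))`` and
    the reported direction is the sign of the summed z.
    """
    p = np.asarray(p_values, float)
    d = np.sign(np.asarray(directions, float))
    if p.size == 0:
        raise ValueError("stouffer_meta needs at least one p-value")
    if p.size != d.size:
        raise ValueError("one direction per p-value is required")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        if zero_floor is None:
            raise ValueError("p = 0 is not combinable; supply zero_floor")
        logger.warning("stouffer_meta: clamping %d zero p-values", int((p == 0).sum()))
        p = np.maximum(p, zero_floor)
    z = d * stats.norm.isf(p / 2.0)
    z_comb = z.sum() / np.sqrt(p.size)
    return float(2.0 * stats.norm.sf(abs(z_comb))), int(np.sign(z_comb))


def compartment_trajectory(
    results: Mapping[str, HubChangeResult],
    panel: MarkerPanel | None = None,
) -> pd.DataFrame:
    """Compartment-average hub scores per group and Stouffer meta p vs CRS0.

    ``results`` maps group label -> :class:`HubChangeResult` (all versus
    the same reference group and sex). The reference group's own average
    hub scores are included with no test. Compartments with no tested
    marker are skipped with a log entry.
    """
    panel = panel or MarkerPanel.default()
    if not results:
        raise ValueError("no hub-change results supplied")
    compartments = panel.compartments()
    any_result = next(iter(results.values()))
    ref = any_result.reference_group
    marker_index = {m: i for i, m in enumerate(any_result.markers)}
    rows = []
    for comp, members in compartments.items():
        idx = [marker_index[m] for m in members if m in marker_index]
        if not idx:
            logger.warning("compartment %s has no tested marker; skipped", comp)
            continue
        rows.append(
            {
                "sex": any_result.sex,
                "group": ref,
                "compartment": comp,
                "mean_hubscore": float(any_result.hub_reference[idx].mean()),
                "meta_p": np.nan,
                "direction": 0,
            }
        )
        for group, res in results.items():
            signs = np.sign(res.diff[idx])
            signs[signs == 0] = 1.0  # zero difference contributes z = 0 anyway
            meta_p, direction = stouffer_meta(res.p[idx], signs)
            rows.append(
                {
                    "sex": res.sex,
                    "group": group,
                    "compartment": comp,
                    "mean_hubscore": float(res.hub_group[idx].mean()),
                    "meta_p": meta_p,
                    "direction": direction,
                }
            )
    return pd.DataFrame(rows)
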