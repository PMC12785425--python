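"""Group-wise co-expression networks, module detection and the
Monte-Carlo module-preservation comparison.

Within each stress-duration x sex cell the 11 markers are correlated
across animals (Pearson). Markers are clustered by average linkage on
the dissimilarity 1 - r and the dendrogram is cut at a fixed fraction of
its maximum merge height; branches with at least ``min_size`` (default 3)
markers become modules, smaller branches stay unassigned.

Preservation of a module across two groups is the proportion of its
markers recovered in the best-matching module of the other group's
partition. Significance is assessed by animal-label permutation: the two
cells' animals are pooled and reassigned at random to pseudo-cells of
the original sizes, both networks and partitions are rebuilt, and
preservation is recomputed per draw. Per-module empirical p-values are
one-sided toward LOW preservation (the null hypothesis is that modules
are identical) with the add-one estimator, and are combined into one
statistic per group pair by Fisher's method; the 15 pair-level p-values
per sex are then BH-corrected.

Because pseudo-partitions need not contain the same number of modules as
the observed partition, observed and null per-module preservations are
aligned as order statistics: the k-th smallest observed preservation is
compared with the k-th smallest preservation of each draw, padding draws
with fewer modules with 1.0 (absence of a module is no evidence of low
preservation). The same functional is applied to the observed split and
to every permuted split, so each per-module p is valid under
exchangeability of animals between the two groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .association import bh_fdr
from .markers_io import GROUPS, MarkerPanel, duration_days

logger = logging.getLogger("crsnet")

#: |r| is clamped below 1 by this margin before the Fisher z-transform.
_R_CLAMP = 1.0 - 1e-12
#: Default dendrogram cut: fraction of the maximum merge height. The cut
#: must sit clearly below the top (between-module) merges, whose heights
#: scatter with sampling noise, while staying above within-module merges.
DEFAULT_CUT_FRACTION = 0.75
DEFAULT_MIN_SIZE = 3
_MAX_REDRAWS = 1000


@dataclass
class GroupNetwork:
    """One cell's marker co-expression network.

    ``r`` is the Pearson correlation matrix (unit diagonal), ``z`` its
    Fisher transform (diagonal NaN), ``adjacency`` the weighted graph
    |r| with zero diagonal.
    """

    group: str
    sex: str
    markers: tuple[str, ...]
    r: np.ndarray
    z: np.ndarray
    adjacency: np.ndarray
    n_samples: int


@dataclass
class ModulePartition:
    """Marker -> module assignment; label 0 means unassigned."""

    markers: tuple[str, ...]
    labels: np.ndarray
    min_size: int = DEFAULT_MIN_SIZE

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for m, lab in zip(self.markers, self.labels):
            if lab > 0:
                out.setdefault(int(lab), []).append(m)
        return out

    def as_dict(self) -> dict[str, int]:
        return {m: int(lab) for m, lab in zip(self.markers, self.labels)}

    @property
    def n_modules(self) -> int:
        return len(self.modules())


# ---------------------------------------------------------------------------
# Network construction and module detection
# ---------------------------------------------------------------------------

def _cell_matrix(
    table: pd.DataFrame, group: str, sex: str, markers: Sequence[str]
) -> np.ndarray:
    sub = table[(table["group"] == group) & (table["sex"] == sex)]
    x = sub[list(markers)].to_numpy(float)
    if x.shape[0] < 4:
        raise ValueError(f"cell ({group}, {sex}) has {x.shape[0]} animals; need >= 4")
    if np.isnan(x).any():
        raise ValueError(f"cell ({group}, {sex}) has missing values; impute upstream")
    const = [m for j, m in enumerate(markers) if np.ptp(x[:, j]) == 0]
    if const:
        raise ValueError(f"constant marker(s) in cell ({group}, {sex}): {const}")
    return x


def _pearson_matrix(x: np.ndarray) -> np.ndarray:
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def build_group_network(
    table: pd.DataFrame,
    group: str,
    sex: str,
    panel: MarkerPanel | None = None,
) -> GroupNetwork:
    """Pearson / Fisher-z / |r|-adjacency network for one group x sex cell."""
    panel = panel or MarkerPanel.default()
    x = _cell_matrix(table, group, sex, panel.markers)
    r = _pearson_matrix(x)
    off = ~np.eye(len(r), dtype=bool)
    n_clamped = int(np.sum(np.abs(r[off]) >= 1.0))
    if n_clamped:
        logger.warning(
            "cell (%s, %s): %d |r|=1 entries clamped for Fisher z", group, sex, n_clamped
        )
    z = np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP))
    np.fill_diagonal(z, np.nan)
    adjacency = np.abs(r)
    np.fill_diagonal(adjacency, 0.0)
    return GroupNetwork(
        group=group,
        sex=sex,
        markers=tuple(panel.markers),
        r=r,
        z=z,
        adjacency=adjacency,
        n_samples=x.shape[0],
    )


def _labels_from_r(r: np.ndarray, min_size: int, cut_fraction: float) -> np.ndarray:
    """Flat module labels (0 = unassigned) from a correlation matrix."""
    m = r.shape[0]
    if m < min_size:
        return np.zeros(m, dtype=int)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    link = hierarchy.average(squareform(d, checks=False))
    hmax = link[:, 2].max()
    if hmax <= 0:  # every marker perfectly correlated: one module of all
        flat = np.ones(m, dtype=int)
    else:
        flat = hierarchy.fcluster(link, t=cut_fraction * hmax, criterion="distance")
    labels = np.zeros(m, dtype=int)
    sizes = np.bincount(flat)
    next_label = 1
    seen: dict[int, int] = {}
    for j in range(m):
        c = flat[j]
        if sizes[c] < min_size:
            continue
        if c not in seen:
            seen[c] = next_label
            next_label += 1
        labels[j] = seen[c]
    return labels


def detect_modules(
    network: GroupNetwork,
    min_size: int = DEFAULT_MIN_SIZE,
    cut_fraction: float = DEFAULT_CUT_FRACTION,
) -> ModulePartition:
    """Average-linkage clustering of 1 - r with a static height cut.

    The dendrogram is cut at ``cut_fraction`` x (maximum merge height);
    resulting branches of at least ``min_size`` markers become modules,
    numbered 1.. in order of first marker appearance; smaller branches
    are left unassigned. Deterministic for a given correlation matrix.
    """
    return ModulePartition(
        markers=network.markers,
        labels=_labels_from_r(network.r, min_size, cut_fraction),
        min_size=min_size,
    )


# ---------------------------------------------------------------------------
# Module preservation
# ---------------------------------------------------------------------------

def _preservation_rows(
    labels_a: np.ndarray, labels_b: np.ndarray
) -> list[tuple[int, int, int, int, float]]:
    """Per module of A: (label, size, best B label, shared, proportion).

    Best match maximizes the shared proportion; ties go to the larger B
    module, then the lower label. Unassigned markers in B never count.
    """
    rows = []
    b_modules = {int(lb): np.flatnonzero(labels_b == lb) for lb in np.unique(labels_b) if lb > 0}
    for la in np.unique(labels_a):
        if la <= 0:
            continue
        members = np.flatnonzero(labels_a == la)
        best_label, best_shared, best_prop = 0, 0, 0.0
        for lb, idx_b in sorted(b_modules.items()):
            shared = int(np.isin(members, idx_b).sum())
            prop = shared / members.size
            if prop > best_prop:
                best_prop, best_label, best_shared = prop, lb, shared
            elif (
                prop == best_prop
                and best_label != 0
                and idx_b.size > b_modules[best_label].size
            ):
                best_label, best_shared = lb, shared
        rows.append((int(la), int(members.size), best_label, best_shared, best_prop))
    return rows


def module_preservation(p_a: ModulePartition, p_b: ModulePartition) -> pd.DataFrame:
    """Best-overlap preservation of each module of ``p_a`` within ``p_b``."""
    if p_a.markers != p_b.markers:
        raise ValueError("partitions must share the same marker universe")
    rows = _preservation_rows(p_a.labels, p_b.labels)
    if not rows:
        logger.warning("module_preservation: partition A has no modules")
    return pd.DataFrame(
        rows, columns=["module", "size", "best_match", "shared", "preservation"]
    )


def _sorted_preservations(labels_a: np.ndarray, labels_b: np.ndarray, k: int) -> np.ndarray:
    """Ascending per-module preservations of A in B, padded with 1.0 to length k."""
    props = sorted(row[4] for row in _preservation_rows(labels_a, labels_b))
    if len(props) < k:
        props = props + [1.0] * (k - len(props))
    return np.asarray(props[:k] if len(props) > k else props, float)


@dataclass
class PreservationTest:
    """Observed preservation, permutation null and meta-analysis for one pair."""

    group_a: str
    group_b: str
    sex: str
    modules: pd.DataFrame  # module, size, best_match, shared, preservation, p
    fisher_p: float
    n_perm: int
    seed: int | None
    n_redraws: int = 0
    null_draws: np.ndarray | None = field(default=None, repr=False)
    partition_a: ModulePartition | None = field(default=None, repr=False)
    partition_b: ModulePartition | None = field(default=None, repr=False)


def fisher_meta(p_values: Sequence[float], zero_floor: float | None = None) -> float:
    """Fisher's combined probability: X^2 = -2 sum(ln p), chi-square 2k df."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("fisher_meta needs at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        if zero_floor is None:
            raise ValueError("p = 0 is not combinable; supply zero_floor")
        logger.warning("fisher_meta: clamping %d zero p-values to %g", int((p == 0).sum()), zero_floor)
        p = np.maximum(p, zero_floor)
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, 2 * p.size))


def preservation_permutation_test(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    sex: str,
    panel: MarkerPanel | None = None,
    n_perm: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
    min_size: int = DEFAULT_MIN_SIZE,
    cut_fraction: float = DEFAULT_CUT_FRACTION,
    keep_null: bool = False,
) -> PreservationTest:
    """Animal-label permutation test of module preservation between two cells.

    Null draws pool the two cells' animals, split them at random into
    pseudo-cells of the original sizes, and rebuild both networks and
    partitions from scratch. Per-module empirical p-values use the
    add-one estimator, one-sided toward low preservation; the pair-level
    statistic is Fisher's combination of the module p-values.
    """
    panel = panel or MarkerPanel.default()
    if n_perm < 100:
        logger.warning("n_perm=%d is low; empirical p resolution is %.3g", n_perm, 1 / (n_perm + 1))
    xa = _cell_matrix(table, group_a, sex, panel.markers)
    xb = _cell_matrix(table, group_b, sex, panel.markers)
    labels_a = _labels_from_r(_pearson_matrix(xa), min_size, cut_fraction)
    labels_b = _labels_from_r(_pearson_matrix(xb), min_size, cut_fraction)
    part_a = ModulePartition(tuple(panel.markers), labels_a, min_size)
    part_b = ModulePartition(tuple(panel.markers), labels_b, min_size)
    obs = module_preservation(part_a, part_b)
    seed_int = seed if isinstance(seed, (int, np.integer)) else None

    if obs.empty:
        logger.warning(
            "pair (%s, %s, %s): no modules in %s; pair p set to 1", group_a, group_b, sex, group_a
        )
        obs["p"] = pd.Series(dtype=float)
        return PreservationTest(
            group_a, group_b, sex, obs, 1.0, n_perm, seed_int,
            partition_a=part_a, partition_b=part_b,
        )

    k = len(obs)
    order = np.lexsort((obs["module"].to_numpy(), obs["preservation"].to_numpy()))
    obs_sorted = obs["preservation"].to_numpy()[order]

    rng = np.random.default_rng(seed)
    pooled = np.vstack([xa, xb])
    n_a, n_total = xa.shape[0], pooled.shape[0]
    null = np.empty((n_perm, k))
    n_redraws = 0
    for t in range(n_perm):
        for attempt in range(_MAX_REDRAWS):
            perm = rng.permutation(n_total)
            pa, pb = pooled[perm[:n_a]], pooled[perm[n_a:]]
            if (np.ptp(pa, axis=0) == 0).any() or (np.ptp(pb, axis=0) == 0).any():
                n_redraws += 1
                continue
            break
        else:
            raise RuntimeError("could not draw a non-degenerate permutation")
        la = _labels_from_r(_pearson_matrix(pa), min_size, cut_fraction)
        lb = _labels_from_r(_pearson_matrix(pb), min_size, cut_fraction)
        null[t] = _sorted_preservations(la, lb, k)
    if n_redraws:
        logger.info("pair (%s, %s, %s): %d degenerate draws redrawn", group_a, group_b, sex, n_redraws)

    p_sorted = (np.sum(null <= obs_sorted[None, :], axis=0) + 1.0) / (n_perm + 1.0)
    p_by_module = np.empty(k)
    p_by_module[order] = p_sorted
    obs = obs.assign(p=p_by_module)
    return PreservationTest(
        group_a,
        group_b,
        sex,
        obs,
        fisher_meta(obs["p"].to_numpy()),
        n_perm,
        seed_int,
        n_redraws=n_redraws,
        null_draws=null if keep_null else None,
        partition_a=part_a,
        partition_b=part_b,
    )


def compare_all_groups(
    table: pd.DataFrame,
    sex: str,
    panel: MarkerPanel | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    min_size: int = DEFAULT_MIN_SIZE,
    cut_fraction: float = DEFAULT_CUT_FRACTION,
    groups: Sequence[str] = GROUPS,
) -> tuple[pd.DataFrame, list[PreservationTest]]:
    """All 15 pairwise preservation tests for one sex, with BH across pairs.

    Pairs are ordered by stress duration; the shorter-duration group's
    modules are scored in the longer-duration group's partition. Pairs
    with an unusable cell are skipped with a log entry.
    """
    panel = panel or MarkerPanel.default()
    pairs = list(combinations(sorted(groups, key=duration_days), 2))
    children = np.random.SeedSequence(seed).spawn(len(pairs))
    tests: list[PreservationTest] = []
    rows = []
    for (ga, gb), child in zip(pairs, children):
        try:
            t = preservation_permutation_test(
                table, ga, gb, sex, panel, n_perm=n_perm, seed=child,
                min_size=min_size, cut_fraction=cut_fraction,
            )
        except ValueError as exc:
            logger.warning("pair (%s, %s, %s) skipped: %s", ga, gb, sex, exc)
            continue
        t.seed = seed
        tests.append(t)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "sex": sex,
                "n_modules": len(t.modules),
                "fisher_p": t.fisher_p,
            }
        )
    summary = pd.DataFrame(rows, columns=["group_a", "group_b", "sex", "n_modules", "fisher_p"])
    if not summary.empty:
        summary["q"] = bh_fdr(summary["fisher_p"].to_numpy())
    else:
        summary["q"] = pd.Series(dtype=float)
    return summary, tests


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def _to_graph(
    network: GroupNetwork, partition: ModulePartition, panel: MarkerPanel
) -> nx.Graph:
    g = nx.Graph()
    labels = partition.as_dict()
    for m in network.markers:
        g.add_node(m, compartment=panel.compartment_of[m], module=labels.get(m, 0))
    idx = {m: i for i, m in enumerate(network.markers)}
    for a, b in combinations(network.markers, 2):
        la, lb = labels.get(a, 0), labels.get(b, 0)
        if la > 0 and la == lb:
            g.add_edge(a, b, weight=float(network.adjacency[idx[a], idx[b]]))
    return g


def export_network(
    network: GroupNetwork,
    partition: ModulePartition,
    path: str | Path,
    fmt: str = "sif",
    panel: MarkerPanel | None = None,
) -> Path:
    """Write the module-restricted network as SIF or GraphML.

    Edges are intra-module marker pairs weighted by |r|; markers outside
    any module appear as isolated nodes. SIF carries topology only;
    GraphML additionally carries compartment, module and weight
    attributes.
    """
    panel = panel or MarkerPanel.default()
    path = Path(path)
    g = _to_graph(network, partition, panel)
    if fmt.lower() == "sif":
        with open(path, "w") as fh:
            for a, b in sorted(g.edges()):
                fh.write(f"{a}\tcoexpression\t{b}\n")
            for node in sorted(g.nodes()):
                if g.degree(node) == 0:
                    fh.write(f"{node}\n")
    elif fmt.lower() == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'sif' or 'graphml'")
    return path
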