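"""Co-expression networks, module detection, preservation and meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import networkx as nx

from crsnet import (
    MarkerPanel,
    ModulePartition,
    build_group_network,
    compare_all_groups,
    detect_modules,
    export_network,
    fisher_meta,
    module_preservation,
    planted_module_dataset,
    preservation_permutation_test,
)
from crsnet.network import GroupNetwork, _labels_from_r


def _network_from_r(r, markers=None):
    m = r.shape[0]
    markers = tuple(markers or [f"m{i}" for i in range(m)])
    adj = np.abs(r).copy()
    np.fill_diagonal(adj, 0.0)
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    np.fill_diagonal(z, np.nan)
    return GroupNetwork("CRS0", "M", markers, r, z, adj, n_samples=10)


def _partition(labels, markers=None):
    labels = np.asarray(labels, int)
    markers = tuple(markers or [f"m{i}" for i in range(labels.size)])
    return ModulePartition(markers, labels)


class TestBuildGroupNetwork:
    def test_structure_and_fisher_z(self, expression):
        nw = build_group_network(expression, "CRS0", "M")
        assert nw.r == pytest.approx(nw.r.T)
        assert np.diag(nw.r) == pytest.approx(np.ones(11))
        off = ~np.eye(11, dtype=bool)
        assert np.all(np.abs(nw.r[off]) <= 1.0)
        assert nw.z[off] == pytest.approx(np.arctanh(nw.r[off]), abs=1e-9)
        assert np.diag(nw.adjacency) == pytest.approx(np.zeros(11))
        assert nw.adjacency == pytest.approx(np.abs(nw.r) - np.eye(11))

    def test_known_fisher_z_values(self):
        # atanh(0) = 0 and atanh(0.5) ~ 0.5493
        assert np.arctanh(0.0) == 0.0
        x = np.array([[1, 2, 3, 4, 5.0], [1, 1.8, 3.4, 3.9, 5.2]]).T
        table = pd.DataFrame(
            {"animal_id": list("abcde"), "sex": "M", "group": "CRS0", "A": x[:, 0], "B": x[:, 1]}
        )
        panel = MarkerPanel(
            ("A", "B"), {"A": "synaptic", "B": "synaptic"}, {"A": "protein", "B": "protein"}
        )
        nw = build_group_network(table, "CRS0", "M", panel)
        assert nw.z[0, 1] == pytest.approx(np.arctanh(nw.r[0, 1]))

    def test_small_cell_rejected(self, expression):
        tiny = expression[expression["animal_id"].isin(expression["animal_id"][:3])]
        with pytest.raises(ValueError, match="need >= 4"):
            build_group_network(tiny, "CRS0", "M")

    def test_constant_marker_named(self, expression):
        bad = expression.copy()
        bad.loc[(bad["group"] == "CRS0") & (bad["sex"] == "M"), "VIP"] = 7.0
        with pytest.raises(ValueError, match="VIP"):
            build_group_network(bad, "CRS0", "M")

    def test_missing_values_rejected(self, cohort):
        table = cohort.expression.copy()
        idx = table[(table["group"] == "CRS0") & (table["sex"] == "M")].index[0]
        table.loc[idx, "GS"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            build_group_network(table, "CRS0", "M")


class TestDetectModules:
    def test_no_structure_leaves_all_unassigned(self):
        nw = _network_from_r(np.eye(11))
        part = detect_modules(nw)
        assert part.n_modules == 0
        assert (part.labels == 0).all()

    def test_planted_blocks_recovered(self):
        partition = {f"m{i}": (0 if i < 4 else 1 if i < 8 else 2) for i in range(11)}
        table = planted_module_dataset(partition, 0.8, 0.0, 200, seed=0)
        x = table[list(partition)].to_numpy()
        labels = _labels_from_r(np.corrcoef(x, rowvar=False), 3, 0.75)
        got = {frozenset(np.flatnonzero(labels == l)) for l in set(labels) if l > 0}
        want = {
            frozenset(i for i, m in enumerate(partition) if partition[m] == b)
            for b in range(3)
        }
        assert got == want

    def test_pair_below_min_size_stays_unassigned(self):
        # markers 0-1 tightly correlated, everything else independent
        r = np.eye(5)
        r[0, 1] = r[1, 0] = 0.95
        part = detect_modules(_network_from_r(r), min_size=3)
        assert part.n_modules == 0

    def test_min_size_respected_and_labels_contiguous(self, expression):
        for sex in ("M", "F"):
            part = detect_modules(build_group_network(expression, "CRS21", sex))
            mods = part.modules()
            assert all(len(v) >= 3 for v in mods.values())
            assert sorted(mods) == list(range(1, len(mods) + 1))

    def test_deterministic(self, expression):
        nw = build_group_network(expression, "CRS7", "F")
        a = detect_modules(nw).labels
        b = detect_modules(nw).labels
        assert (a == b).all()


class TestModulePreservation:
    def test_identical_partitions_fully_preserved(self):
        p = _partition([1, 1, 1, 2, 2, 2, 0])
        res = module_preservation(p, p)
        assert res["preservation"].tolist() == [1.0, 1.0]

    def test_unassigned_target_gives_zero(self):
        a = _partition([1, 1, 1, 2, 2, 2])
        b = _partition([0, 0, 0, 0, 0, 0])
        assert module_preservation(a, b)["preservation"].tolist() == [0.0, 0.0]

    def test_split_overlap_enumeration(self):
        # A: {0,1,2},{3,4,5}; B: {0,1,3},{2,4,5} -> 2/3 and 2/3
        a = _partition([1, 1, 1, 2, 2, 2])
        b = _partition([1, 1, 2, 1, 2, 2])
        res = module_preservation(a, b)
        assert res["preservation"].tolist() == pytest.approx([2 / 3, 2 / 3])

    def test_tie_broken_toward_larger_target_module(self):
        # module {0,1}: one marker in each B module -> tie at 1/2; B module 2
        # is larger and must win
        a = _partition([1, 1, 0, 0, 0, 0])
        b = _partition([1, 2, 1, 2, 2, 0])
        res = module_preservation(a, b)
        assert res["best_match"].iloc[0] == 2

    def test_marker_universe_must_match(self):
        with pytest.raises(ValueError):
            module_preservation(_partition([1, 1, 1]), _partition([1, 1, 1, 1]))


class TestFisherMeta:
    def test_boundary_and_identity(self):
        assert fisher_meta([1.0, 1.0, 1.0]) == pytest.approx(1.0)
        assert fisher_meta([0.1234]) == pytest.approx(0.1234, rel=1e-12)

    def test_two_p05_matches_chi_square_oracle(self):
        x2 = -2 * (np.log(0.05) + np.log(0.05))
        assert x2 == pytest.approx(11.98, abs=0.01)
        assert fisher_meta([0.05, 0.05]) == pytest.approx(stats.chi2.sf(x2, 4))
        assert fisher_meta([0.05, 0.05]) == pytest.approx(0.0175, abs=5e-4)

    def test_zero_requires_floor(self):
        with pytest.raises(ValueError):
            fisher_meta([0.0, 0.5])
        assert fisher_meta([0.0, 0.5], zero_floor=1e-4) == pytest.approx(
            fisher_meta([1e-4, 0.5])
        )

    def test_monotone_in_inputs(self):
        assert fisher_meta([0.01, 0.2]) < fisher_meta([0.05, 0.2])


def _duplicate_cell_table(expression, src=("CRS0", "M"), dst=("CRS7", "M")):
    """Table where the dst cell is an exact copy of the src cell's values."""
    table = expression.copy()
    src_rows = table[(table["group"] == src[0]) & (table["sex"] == src[1])].copy()
    table = table[~((table["group"] == dst[0]) & (table["sex"] == dst[1]))]
    src_rows["group"] = dst[0]
    src_rows["animal_id"] = [f"dup{i}" for i in range(len(src_rows))]
    return pd.concat([table, src_rows], ignore_index=True)


class TestPreservationPermutationTest:
    def test_self_comparison_is_null(self, expression):
        table = _duplicate_cell_table(expression)
        res = preservation_permutation_test(table, "CRS0", "CRS7", "M", n_perm=200, seed=0)
        assert (res.modules["preservation"] == 1.0).all()
        assert res.fisher_p == pytest.approx(1.0)
        assert (res.modules["p"] == 1.0).all()

    def test_detects_planted_structural_difference(self, panel):
        """Two cells with different planted block partitions: low observed
        preservation relative to pooled-permutation nulls."""
        markers = list(panel.markers)
        part_a = {m: i // 4 for i, m in enumerate(markers)}
        part_b = {m: i % 3 for i, m in enumerate(markers)}
        a = planted_module_dataset(part_a, 0.8, 0.0, 40, seed=1)
        b = planted_module_dataset(part_b, 0.8, 0.0, 40, seed=2)
        a["group"], a["sex"] = "CRS0", "F"
        b["group"], b["sex"] = "CRS35", "F"
        b["animal_id"] = [f"b{i}" for i in range(len(b))]
        table = pd.concat([a, b], ignore_index=True)[["animal_id", "sex", "group", *markers]]
        res = preservation_permutation_test(table, "CRS0", "CRS35", "F", n_perm=200, seed=3)
        assert res.fisher_p < 0.05

    def test_empirical_p_bounds_and_determinism(self, expression):
        r1 = preservation_permutation_test(expression, "CRS0", "CRS35", "F", n_perm=150, seed=9)
        r2 = preservation_permutation_test(expression, "CRS0", "CRS35", "F", n_perm=150, seed=9)
        assert (r1.modules["p"] >= 1 / 151 - 1e-12).all()
        assert (r1.modules["p"] <= 1.0).all()
        assert r1.modules["p"].tolist() == r2.modules["p"].tolist()
        assert r1.fisher_p == r2.fisher_p


class TestCompareAllGroups:
    def test_fifteen_pairs_with_bh(self, expression):
        summary, tests = compare_all_groups(expression, "M", n_perm=60, seed=1)
        assert len(summary) == 15
        assert (summary["q"] >= summary["fisher_p"] - 1e-15).all()
        assert len(tests) == 15

    def test_missing_cell_skips_its_pairs(self, expression):
        table = expression[~((expression["group"] == "CRS35") & (expression["sex"] == "M"))]
        summary, _ = compare_all_groups(table, "M", n_perm=60, seed=1)
        assert len(summary) == 10
        assert "CRS35" not in set(summary["group_a"]) | set(summary["group_b"])


class TestExportNetwork:
    def test_empty_partition_emits_isolated_nodes(self, expression, tmp_path):
        nw = build_group_network(expression, "CRS0", "M")
        part = ModulePartition(nw.markers, np.zeros(11, int))
        path = export_network(nw, part, tmp_path / "net.sif", "sif")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 11
        assert all("\t" not in line for line in lines)

    def test_three_marker_module_has_three_edges(self, expression, tmp_path):
        nw = build_group_network(expression, "CRS0", "M")
        labels = np.zeros(11, int)
        labels[:3] = 1
        path = export_network(nw, ModulePartition(nw.markers, labels), tmp_path / "m.sif")
        lines = path.read_text().strip().splitlines()
        edges = [l for l in lines if "\t" in l]
        assert len(edges) == 3

    def test_graphml_roundtrip(self, expression, tmp_path):
        nw = build_group_network(expression, "CRS0", "M")
        part = detect_modules(nw)
        path = export_network(nw, part, tmp_path / "net.graphml", "graphml")
        g = nx.read_graphml(path)
        assert g.number_of_nodes() == 11
        expected_edges = sum(
            len(v) * (len(v) - 1) // 2 for v in part.modules().values()
        )
        assert g.number_of_edges() == expected_edges
        for _, _, data in g.edges(data=True):
            assert 0.0 <= data["weight"] <= 1.0
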