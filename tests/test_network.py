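import io

import numpy as np
import pandas as pd
import pytest

from apms.errors import DataError
from apms.integration import StabilityProfile
from apms.network import (
    cluster_matrix,
    enrichment_index,
    export_network,
    linkage_to_newick,
    log2_counts,
    nsaf,
    write_sif,
)


class TestNsaf:
    def test_equal_counts_equal_lengths_split_evenly(self):
        values = nsaf(pd.Series({"A": 5, "B": 5}), pd.Series({"A": 100, "B": 100}))
        assert values["A"] == pytest.approx(0.5)

    def test_length_weighting(self):
        values = nsaf(pd.Series({"A": 10, "B": 10}), pd.Series({"A": 100, "B": 200}))
        assert values["A"] == pytest.approx(2 / 3)
        assert values["B"] == pytest.approx(1 / 3)

    def test_single_prey_is_one(self):
        assert nsaf(pd.Series({"A": 7}), pd.Series({"A": 421}))["A"] == 1.0

    def test_sums_to_one(self):
        rng = np.random.default_rng(3)
        counts = pd.Series(rng.integers(0, 50, 40), index=[f"P{i}" for i in range(40)])
        counts.iloc[0] = 1  # ensure non-degenerate
        lengths = pd.Series(rng.integers(100, 2000, 40), index=counts.index)
        assert nsaf(counts, lengths).sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_counts_is_error(self):
        with pytest.raises(DataError):
            nsaf(pd.Series({"A": 0}), pd.Series({"A": 100}))

    def test_missing_length_is_error(self):
        with pytest.raises(DataError):
            nsaf(pd.Series({"A": 5}), pd.Series({"B": 100}))


class TestEnrichmentIndex:
    def setup_method(self):
        self.nsaf = pd.Series({"REF": 0.2, "HI": 0.4, "LO": 0.1, "NOPAX": 0.3})
        self.pax = pd.Series({"REF": 10.0, "HI": 10.0, "LO": 10.0})

    def test_reference_is_exactly_one(self):
        records = {r.prey: r for r in enrichment_index(self.nsaf, self.pax, "REF")}
        assert records["REF"].enrichment_index == 1.0

    def test_linearity(self):
        records = {r.prey: r for r in enrichment_index(self.nsaf, self.pax, "REF")}
        assert records["HI"].enrichment_index == pytest.approx(2.0)
        assert records["LO"].enrichment_index == pytest.approx(0.5)

    def test_missing_abundance_flagged(self):
        records = {r.prey: r for r in enrichment_index(self.nsaf, self.pax, "REF")}
        assert records["NOPAX"].enrichment_index is None
        assert records["NOPAX"].pax_abundance is None

    def test_missing_reference_is_error(self):
        with pytest.raises(DataError):
            enrichment_index(self.nsaf, self.pax, "ABSENT")


class TestClusterMatrix:
    def _matrix(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0, 8, 6)
        return pd.DataFrame(
            {
                "R1": base,
                "R2": base + rng.normal(0, 0.1, 6),
                "R3": 8 - base,
            },
            index=[f"P{i}" for i in range(6)],
        )

    def test_identical_profiles_merge_at_height_zero(self):
        m = pd.DataFrame(
            {"R1": [1.0, 1.0, 5.0], "R2": [2.0, 2.0, 1.0], "R3": [3.0, 3.0, 0.0]},
            index=["A", "B", "C"],
        )
        result = cluster_matrix(m)
        first = result.prey_linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profiles_at_distance_two(self):
        m = pd.DataFrame(
            {"R1": [0.0, 4.0], "R2": [2.0, 2.0], "R3": [4.0, 0.0]},
            index=["A", "B"],
        )
        result = cluster_matrix(m)
        assert result.prey_linkage[0][2] == pytest.approx(2.0)

    def test_row_permutation_invariance(self):
        m = self._matrix()
        perm = m.iloc[[3, 1, 5, 0, 4, 2]]
        a = cluster_matrix(m)
        b = cluster_matrix(perm)
        assert sorted(a.prey_linkage[:, 2]) == pytest.approx(
            sorted(b.prey_linkage[:, 2])
        )
        # the same groups merge, independent of input row order
        assert a.matrix.loc[a.prey_order].equals(
            b.matrix.loc[a.prey_order]
        )

    def test_zero_variance_row_warns_and_uses_unit_distance(self):
        m = self._matrix()
        m.loc["P0"] = 3.0
        with pytest.warns(UserWarning, match="zero-variance"):
            result = cluster_matrix(m)
        assert result.prey_linkage[:, 2].max() <= 2.0

    def test_too_small_matrix_rejected(self):
        with pytest.raises(DataError):
            cluster_matrix(pd.DataFrame({"R1": [1.0, 2.0]}))

    def test_replicates_of_one_bait_cluster_together(self, sim_data, scored_default):
        matrix, _ = sim_data
        passing = sorted(
            {r.prey for results in scored_default.values() for r in results if r.passes}
            - set(matrix.baits)
        )
        run_ids = [r.run_id for r in matrix.runs if not r.is_control]
        result = cluster_matrix(log2_counts(matrix.counts.loc[passing, run_ids]))
        order = [rid.split("_")[0] for rid in result.run_order]
        # replicates of each bait occupy contiguous leaves of the run tree
        blocks = [b for i, b in enumerate(order) if i == 0 or order[i - 1] != b]
        assert len(blocks) == len(set(order))


def test_newick_export_is_well_formed(sim_data):
    from Bio import Phylo  # independent parser as cross-check

    m = pd.DataFrame(
        np.random.default_rng(0).uniform(0, 8, (5, 4)),
        index=list("ABCDE"),
        columns=[f"R{i}" for i in range(4)],
    )
    result = cluster_matrix(m)
    tree = Phylo.read(io.StringIO(result.prey_newick()), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == list("ABCDE")


class TestExportNetwork:
    def _profiles(self):
        return [
            StabilityProfile("B1", "P1", 0.9, 0.9, "stable"),
            StabilityProfile("B1", "P2", 0.9, 0.5, "dynamic"),
            StabilityProfile("B2", "P1", 0.8, 0.85, "stable"),
            StabilityProfile("B1", "C1", 0.05, 1.0, "contaminant"),
            StabilityProfile("B1", "N1", 0.2, 0.3, "nonspecific"),
        ]

    def test_edges_and_shared_prey_nodes(self):
        nodes, edges = export_network(self._profiles(), {("B1", "P1"): 3.0})
        assert len(edges) == 3  # P1 twice (two baits), P2 once
        assert (nodes["gene"] == "P1").sum() == 1
        assert edges.loc[
            (edges.bait == "B1") & (edges.prey == "P1"), "weight"
        ].iloc[0] == pytest.approx(2.0)

    def test_contaminant_and_nonspecific_excluded(self):
        _, edges = export_network(self._profiles())
        assert not set(edges["prey"]) & {"C1", "N1"}

    def test_known_flag_set_from_reference_pairs(self):
        _, edges = export_network(self._profiles(), known_pairs=[("B1", "P1")])
        known = dict(zip(zip(edges.bait, edges.prey), edges.known))
        assert known[("B1", "P1")] and not known[("B1", "P2")]

    def test_sif_output(self, tmp_path):
        _, edges = export_network(self._profiles())
        path = tmp_path / "net.sif"
        write_sif(edges, path)
        lines = path.read_text().splitlines()
        assert len(lines) == len(edges)
        assert all(line.split("\t")[1] == "pp" for line in lines)
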