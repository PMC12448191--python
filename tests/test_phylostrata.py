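"""Phylostratum index construction and oldest-internode gene-age assignment."""

import numpy as np
import pandas as pd
import pytest

from sctai import (
    assign_gene_ages,
    build_phylostratum_index,
    generate_dataset,
    generate_hit_table,
    synthetic_phylostratigraphy,
)
from sctai.phylostrata import GeneAgeMap, PhylostratigraphyError
from sctai.simulate import CellTypeSpec, SimDesign


def _hits(rows):
    return pd.DataFrame(rows, columns=["query", "subject_taxon", "evalue"])


class TestBuildIndex:
    def test_focal_taxon_on_terminal_node(self, toy_index):
        assert toy_index.n_strata == 22
        assert toy_index.taxon_map["taxon_focal"] == 22

    def test_degenerate_single_node(self):
        idx = build_phylostratum_index(
            pd.DataFrame({"ps": [1], "node_name": ["root"]}),
            pd.DataFrame({"taxon_id": ["t"], "ps": [1]}),
        )
        assert idx.taxon_map["t"] == 1

    @pytest.mark.parametrize(
        "nodes, taxa",
        [
            (   # duplicate taxon assignment
                pd.DataFrame({"ps": [1, 2], "node_name": ["a", "b"]}),
                pd.DataFrame({"taxon_id": ["t", "t"], "ps": [1, 2]}),
            ),
            (   # taxon references an unlisted node
                pd.DataFrame({"ps": [1], "node_name": ["a"]}),
                pd.DataFrame({"taxon_id": ["t"], "ps": [3]}),
            ),
            (   # non-consecutive ps indices
                pd.DataFrame({"ps": [1, 3], "node_name": ["a", "b"]}),
                pd.DataFrame({"taxon_id": ["t"], "ps": [1]}),
            ),
            (   # empty node table
                pd.DataFrame({"ps": [], "node_name": []}),
                pd.DataFrame({"taxon_id": ["t"], "ps": [1]}),
            ),
        ],
    )
    def test_invalid_tables_rejected(self, nodes, taxa):
        with pytest.raises(PhylostratigraphyError):
            build_phylostratum_index(nodes, taxa)


class TestAssignAges:
    def test_oldest_matching_node_wins(self, toy_index):
        hits = _hits(
            [
                ("gene1", "taxon_focal", 1e-100),
                ("gene1", "taxon_ps11_0", 1e-20),
                ("gene1", "taxon_ps01_0", 1e-5),
            ]
        )
        ages = assign_gene_ages(hits, toy_index, 1e-3, "taxon_focal")
        assert ages["gene1"] == 1

    def test_no_self_hit_discarded(self, toy_index):
        hits = _hits(
            [
                ("kept", "taxon_focal", 1e-50),
                ("dropped", "taxon_ps05_0", 1e-50),
            ]
        )
        ages = assign_gene_ages(hits, toy_index, 1e-3, "taxon_focal")
        assert "dropped" not in ages.ages.index
        assert ages.n_discarded == 1

    def test_self_hit_only_gives_terminal_ps(self, toy_index):
        ages = assign_gene_ages(
            _hits([("orphan", "taxon_focal", 1e-80)]), toy_index, 1e-3, "taxon_focal"
        )
        assert ages["orphan"] == 22

    def test_evalue_threshold_filters_old_hit(self, toy_index):
        # ps5 hit at evalue 0.01 fails the 1e-3 threshold; hand-filtering the
        # toy table leaves the self-hit and a ps11 hit, so the age is 11
        hits = _hits(
            [
                ("g", "taxon_focal", 1e-60),
                ("g", "taxon_ps05_0", 0.01),
                ("g", "taxon_ps11_1", 1e-9),
            ]
        )
        ages = assign_gene_ages(hits, toy_index, 1e-3, "taxon_focal")
        assert ages["g"] == 11

    def test_threshold_boundary_inclusive(self, toy_index):
        hits = _hits([("g", "taxon_focal", 1e-60), ("g", "taxon_ps03_0", 1e-3)])
        ages = assign_gene_ages(hits, toy_index, 1e-3, "taxon_focal")
        assert ages["g"] == 3

    def test_unknown_taxon_is_hard_error(self, toy_index):
        with pytest.raises(PhylostratigraphyError, match="martian"):
            assign_gene_ages(
                _hits([("g", "martian", 1e-9)]), toy_index, 1e-3, "taxon_focal"
            )

    def test_empty_hit_table_warns_returns_empty(self, toy_index):
        with pytest.warns(UserWarning, match="empty"):
            ages = assign_gene_ages(_hits([]), toy_index, 1e-3, "taxon_focal")
        assert len(ages) == 0

    def test_gene_level_self_rule(self, toy_index):
        hits = pd.DataFrame(
            {
                "query": ["g1", "g2"],
                "subject_taxon": ["taxon_focal", "taxon_focal"],
                "evalue": [1e-40, 1e-40],
                "subject_gene": ["g1", "other"],
            }
        )
        ages = assign_gene_ages(hits, toy_index, 1e-3, "taxon_focal", self_rule="gene")
        assert "g1" in ages.ages.index and "g2" not in ages.ages.index

    def test_row_order_invariance(self, toy_index):
        rng = np.random.default_rng(7)
        taxa = list(toy_index.taxon_map)
        rows = [
            (f"g{i}", taxa[rng.integers(len(taxa))], float(10.0 ** -rng.uniform(0, 40)))
            for i in range(60)
            for _ in range(rng.integers(1, 6))
        ]
        rows += [(f"g{i}", "taxon_focal", 1e-99) for i in range(0, 60, 2)]
        hits = _hits(rows)
        base = assign_gene_ages(hits, toy_index, 1e-3, "taxon_focal").ages
        for seed in range(3):
            shuffled = hits.sample(frac=1.0, random_state=seed).reset_index(drop=True)
            out = assign_gene_ages(shuffled, toy_index, 1e-3, "taxon_focal").ages
            pd.testing.assert_series_equal(base.sort_index(), out.sort_index())

    def test_threshold_monotonicity(self, toy_index):
        # loosening the threshold keeps ages equal or makes them older
        rng = np.random.default_rng(3)
        taxa = list(toy_index.taxon_map)
        rows = [(f"g{i}", "taxon_focal", 1e-99) for i in range(40)]
        rows += [
            (f"g{i}", taxa[rng.integers(len(taxa))], float(10.0 ** -rng.uniform(0, 10)))
            for i in range(40)
            for _ in range(4)
        ]
        hits = _hits(rows)
        strict = assign_gene_ages(hits, toy_index, 1e-6, "taxon_focal").ages
        loose = assign_gene_ages(hits, toy_index, 1e-2, "taxon_focal").ages
        common = strict.index.intersection(loose.index)
        assert (loose.loc[common] <= strict.loc[common]).all()

    def test_tsv_round_trip(self, toy_index, tmp_path):
        ages = assign_gene_ages(
            _hits([("g", "taxon_focal", 1e-60), ("g", "taxon_ps03_0", 1e-9)]),
            toy_index, 1e-3, "taxon_focal",
        )
        ages.to_tsv(tmp_path / "ages.tsv")
        back = GeneAgeMap.from_tsv(tmp_path / "ages.tsv")
        pd.testing.assert_series_equal(ages.ages, back.ages)


class TestRoundTripWithSimulator:
    @pytest.mark.parametrize("seed", range(3))
    def test_assignment_recovers_planted_ages(self, toy_index, seed):
        design = SimDesign(
            genes_per_ps=25,
            cell_types=(CellTypeSpec("A", 5, {1: 4.0}, 5), CellTypeSpec("B", 5, {12: 4.0}, 5)),
            seed=seed,
        )
        _, truth = generate_dataset(design)
        hits = generate_hit_table(truth, toy_index, seed=seed)
        ages = assign_gene_ages(hits, toy_index, 1e-3, "taxon_focal")
        pd.testing.assert_series_equal(
            ages.ages.sort_index(), truth.gene_ages.sort_index()
        )
        assert set(truth.unaged_genes).isdisjoint(ages.ages.index)
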