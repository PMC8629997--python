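"""Incidence-matrix data model, I/O, de-duplication and summaries."""

import numpy as np
import pandas as pd
import pytest

from phagenet import (
    HostRecord,
    IncidenceMatrix,
    classify_species_tendency,
    collapse_identical_phages,
    drop_uninfected_hosts,
    ecosystem_span,
    matrix_summary,
    read_incidence,
    read_metadata,
    write_incidence,
)
from phagenet.matrix_core import align_metadata, bipartite_diameter
from phagenet.modularity import barber_Q

from conftest import as_matrix, random_binary


class TestIncidenceIO:
    def test_full_2x2(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("\tp1\tp2\nh1\t1\t1\nh2\t1\t1\n")
        m = read_incidence(path)
        assert (m.I, m.M, m.C) == (4, 4, 1.0)

    def test_single_interaction(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("\tp1\tp2\nh1\t0\t0\nh2\t1\t0\nh3\t0\t0\n")
        m = read_incidence(path)
        assert m.I == 1
        assert m.C == pytest.approx(1 / 6)

    def test_lysis_from_without_coerced_to_zero(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("\tp1\tp2\nh1\t2\t1\nh2\t0\t2\n")
        m = read_incidence(path)
        assert m.I == 1
        assert m.entries[0, 0] == 0

    def test_non_binary_cell_names_location(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("\tp1\tp2\nh1\t0\t3\nh2\t0\t0\n")
        with pytest.raises(ValueError, match="p2"):
            read_incidence(path)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            IncidenceMatrix(np.zeros((2, 1), int), ["h", "h"], ["p"])

    def test_csv_round_trip(self, toy_matrix, tmp_path):
        path = tmp_path / "m.csv"
        write_incidence(toy_matrix, path)
        assert read_incidence(path) == toy_matrix


class TestMetadataIO:
    def test_valid_hosts(self, tmp_path):
        path = tmp_path / "hosts.tsv"
        path.write_text(
            "host_id\tspecies\tspecies_group\tcoagulase\tbiome\tresistance\n"
            "a\tS. aureus\tEpidermidis-Aureus\tCoPS\thuman\tMDR\n"
            "b\tS. sciuri\tSciuri\tCoNS\tveterinary\tsusceptible\n"
            "c\tS. simulans\tSimulans\tCoNS\tenvironmental\tresistant\n"
        )
        records = read_metadata(path, "host")
        assert len(records) == 3
        assert records[0].coagulase == "CoPS"

    def test_unknown_biome_rejected(self, tmp_path):
        path = tmp_path / "hosts.tsv"
        path.write_text(
            "host_id\tspecies\tspecies_group\tcoagulase\tbiome\tresistance\n"
            "a\tS. aureus\tEpidermidis-Aureus\tCoPS\tmarine\tMDR\n"
        )
        with pytest.raises(ValueError, match="biome"):
            read_metadata(path, "host")

    def test_missing_ids_listed(self, toy_matrix, toy_hosts):
        with pytest.raises(ValueError, match="c"):
            align_metadata(toy_matrix, toy_hosts[:2], "host")


class TestCollapse:
    def test_distinct_columns_unchanged(self, toy_matrix):
        collapsed, cmap = collapse_identical_phages(toy_matrix)
        assert collapsed == toy_matrix
        assert all(len(v) == 1 for v in cmap.groups.values())

    def test_two_identical_pairs(self):
        m = as_matrix(np.array([[1, 0, 1, 0], [0, 1, 0, 1]]))
        collapsed, cmap = collapse_identical_phages(m)
        assert collapsed.n_phages == 2
        assert cmap.groups == {"p0": ["p0", "p2"], "p1": ["p1", "p3"]}

    def test_idempotent_and_reexpands(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = as_matrix(random_binary(rng))
            collapsed, cmap = collapse_identical_phages(m)
            again, cmap2 = collapse_identical_phages(collapsed)
            assert again == collapsed
            # re-expansion reproduces the original column multiset
            original = sorted(m.entries[:, j].tobytes() for j in range(m.n_phages))
            rebuilt = sorted(
                collapsed.entries[:, collapsed.phage_ids.index(rep)].tobytes()
                for rep, members in cmap.groups.items()
                for _ in members
            )
            assert original == rebuilt
            assert sorted(cmap.members()) == sorted(m.phage_ids)

    def test_all_zero_columns_retained_as_group(self):
        m = as_matrix(np.array([[1, 0, 0], [0, 0, 0]]))
        collapsed, cmap = collapse_identical_phages(m)
        assert collapsed.n_phages == 2  # one live column + one zero group
        assert cmap.groups["p1"] == ["p1", "p2"]


class TestDropUninfected:
    def test_no_zero_rows_unchanged(self, toy_matrix):
        reduced, removed = drop_uninfected_hosts(toy_matrix)
        assert reduced == toy_matrix
        assert removed == []

    def test_zero_row_removed_fill_kept(self):
        m = as_matrix(np.array([[1, 1], [0, 0], [0, 1]]))
        reduced, removed = drop_uninfected_hosts(m)
        assert removed == ["h1"]
        assert reduced.n_hosts == 2
        assert reduced.I == m.I

    def test_invariants_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = random_binary(rng, density=0.3)
            if a.sum() == 0:
                continue
            m = as_matrix(a)
            reduced, _ = drop_uninfected_hosts(m)
            assert reduced.I == m.I
            assert np.array_equal(reduced.phage_degrees(), m.phage_degrees())
            # Barber Q unchanged: zero-degree rows contribute nothing
            rl = rng.integers(0, 3, size=m.n_hosts)
            cl = rng.integers(0, 3, size=m.n_phages)
            keep = m.host_degrees() > 0
            assert barber_Q(m, rl, cl) == pytest.approx(
                barber_Q(reduced, rl[keep], cl)
            )


class TestSummary:
    def test_single_cell(self):
        m = as_matrix(np.array([[1]]))
        report = matrix_summary(m)
        assert report["host_degree"]["mean"] == 1
        assert report["diameter"] == 1

    def test_degree_sums_equal_fill(self):
        rng = np.random.default_rng(3)
        m = as_matrix(random_binary(rng, density=0.5))
        assert m.host_degrees().sum() == m.phage_degrees().sum() == m.I

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            matrix_summary(as_matrix(np.zeros((2, 2), int)))

    def test_metadata_breakdowns(self, toy_matrix, toy_hosts):
        report = matrix_summary(toy_matrix, hosts=toy_hosts)
        # 2 of 4 interactions on the CoPS host "a"
        assert report["interaction_fraction"]["CoPS"] == pytest.approx(0.5)
        assert report["permissive_fraction_by_biome"]["human"] == 1.0
        assert report["phage_species_breadth"]["max"] == 2

    def test_diameter_on_disconnected_graph(self):
        # two disjoint 1-host/1-phage pairs: diameter of the largest component
        m = as_matrix(np.array([[1, 0], [0, 1]]))
        assert bipartite_diameter(m) == 1


class TestSpeciesTendency:
    def test_single_species(self, toy_hosts):
        m = as_matrix(np.array([[1], [0], [0]]))
        m.host_ids = ["a", "b", "c"]
        labels = classify_species_tendency(m, toy_hosts)
        assert labels.loc["p0", "label"] == "single_species"

    def test_tendency_at_two_thirds(self):
        hosts = [
            HostRecord("a", "S. aureus", "Epidermidis-Aureus", "CoPS", "human", "MDR"),
            HostRecord("b", "S. aureus", "Epidermidis-Aureus", "CoPS", "human", "MDR"),
            HostRecord("c", "S. sciuri", "Sciuri", "CoNS", "human", "MDR"),
        ]
        m = IncidenceMatrix(np.array([[1], [1], [1]]), ["a", "b", "c"], ["p0"])
        labels = classify_species_tendency(m, hosts)
        assert labels.loc["p0", "label"] == "species_tendency"
        assert labels.loc["p0", "modal_species"] == "S. aureus"
        assert labels.loc["p0", "modal_share"] == pytest.approx(2 / 3)

    def test_uninfective_phage_excluded(self, toy_hosts):
        m = IncidenceMatrix(
            np.array([[1, 0], [1, 0], [0, 0]]), ["a", "b", "c"], ["p0", "p1"]
        )
        labels = classify_species_tendency(m, toy_hosts)
        assert labels.loc["p1", "label"] == "uninfective"


class TestEcosystemSpan:
    def test_spans(self, toy_matrix, toy_hosts):
        spans, agg = ecosystem_span(toy_matrix, toy_hosts)
        assert spans["p1"] == frozenset({"human", "veterinary"})
        assert spans["p2"] == frozenset({"human", "environmental"})
        assert agg["n_multi_biome"] == 2
        assert agg["n_phages_by_span"] == {2: 2}

    def test_single_biome_span(self, toy_hosts):
        m = IncidenceMatrix(np.array([[1], [0], [0]]), ["a", "b", "c"], ["p0"])
        spans, agg = ecosystem_span(m, toy_hosts)
        assert spans["p0"] == frozenset({"human"})
        assert agg["n_multi_biome"] == 0
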