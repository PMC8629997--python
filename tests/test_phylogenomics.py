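"""Hit filtering, Dice genome distances and neighbor joining.

scikit-bio serves as the independent oracle for tree construction and
newick parsing; the package's own NJ and writer are under test.
"""

import io

import numpy as np
import pandas as pd
import pytest
import skbio

from phagenet import (
    dice_distance_matrix,
    filter_hits,
    neighbor_joining,
    read_hits,
    to_newick,
    write_newick,
)
from phagenet.phylogenomics import HIT_COLUMNS, Clade, convert_outfmt6


def make_hits(rows):
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def hit(qg, sg, bit, pident=90.0, alen=100, evalue=1e-10, qp=None, sp=None):
    return (qg, sg, qp or f"{qg}_p", sp or f"{sg}_p", pident, alen, bit, evalue)


class TestFilterHits:
    def test_passing_hit_kept(self):
        hits = make_hits([hit("A", "B", 40.0, pident=35.0, alen=50, evalue=1e-5)])
        assert len(filter_hits(hits)) == 1

    def test_identity_below_threshold_dropped(self):
        hits = make_hits([hit("A", "B", 100.0, pident=29.9, alen=100, evalue=0.0)])
        assert len(filter_hits(hits)) == 0

    def test_each_threshold_applied(self):
        rows = [
            hit("A", "B", 50.0),                      # passes
            hit("A", "B", 50.0, pident=29.0),         # fails identity
            hit("A", "B", 29.0),                      # fails bitscore
            hit("A", "B", 50.0, alen=29),             # fails length
            hit("A", "B", 50.0, evalue=0.02),         # fails e-value
            hit("B", "A", 50.0),                      # passes
        ]
        kept = filter_hits(make_hits(rows))
        assert len(kept) == 2

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        rows = [
            hit("A", "B", rng.uniform(0, 100), pident=rng.uniform(0, 100),
                alen=int(rng.integers(1, 200)), evalue=10 ** rng.uniform(-30, 1))
            for _ in range(50)
        ]
        hits = make_hits(rows)
        strict = set(filter_hits(hits, 30, 30, 30, 0.01).index)
        relaxed = filter_hits(hits, 20, 10, 10, 0.1)
        assert strict <= set(relaxed.index)

    def test_malformed_row_reported(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "\t".join(HIT_COLUMNS)
            + "\nA\tB\tA_p\tB_p\tnot_a_number\t100\t50\t1e-5\n"
        )
        with pytest.raises(ValueError, match="row 0"):
            read_hits(path)


class TestDiceDistance:
    def test_self_distance_zero(self):
        hits = make_hits([hit("A", "A", 100.0), hit("B", "B", 100.0),
                          hit("A", "B", 50.0), hit("B", "A", 50.0)])
        d = dice_distance_matrix(hits)
        assert d.loc["A", "A"] == 0.0
        assert d.loc["B", "B"] == 0.0

    def test_no_cross_hits_distance_one(self):
        hits = make_hits([hit("A", "A", 100.0), hit("B", "B", 100.0)])
        d = dice_distance_matrix(hits)
        assert d.loc["A", "B"] == 1.0

    def test_half_distance(self):
        hits = make_hits([hit("A", "A", 100.0), hit("B", "B", 100.0),
                          hit("A", "B", 50.0), hit("B", "A", 50.0)])
        assert dice_distance_matrix(hits).loc["A", "B"] == pytest.approx(0.5)

    def test_multiple_hsps_summed_vs_best_hit(self):
        hits = make_hits([
            hit("A", "A", 100.0), hit("B", "B", 100.0),
            hit("A", "B", 30.0), hit("A", "B", 20.0),  # same protein pair
            hit("B", "A", 50.0),
        ])
        summed = dice_distance_matrix(hits)
        best = dice_distance_matrix(hits, best_hit_only=True)
        assert summed.loc["A", "B"] == pytest.approx(0.5)          # (50+50)/200
        assert best.loc["A", "B"] == pytest.approx(1 - 80 / 200)   # (30+50)/200

    def test_missing_self_hits_error(self):
        hits = make_hits([hit("A", "A", 100.0), hit("A", "B", 50.0)])
        with pytest.raises(ValueError, match="B"):
            dice_distance_matrix(hits)

    def test_symmetric_and_clamped(self):
        hits = make_hits([hit("A", "A", 100.0), hit("B", "B", 100.0),
                          hit("A", "B", 150.0), hit("B", "A", 150.0)])
        # symmetrized D would be negative without clamping
        with pytest.warns(UserWarning, match="clamped"):
            d = dice_distance_matrix(hits)
        assert (d.to_numpy() >= 0).all() and (d.to_numpy() <= 1).all()
        assert np.allclose(d.to_numpy(), d.to_numpy().T)


class TestConvertOutfmt6:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "hits.o6"
        path.write_text(
            "A_p1\tB_p1\t85.0\t120\t10\t1\t1\t120\t1\t120\t1e-20\t222\n"
        )
        df = convert_outfmt6(path, {"A_p1": "A", "B_p1": "B"})
        assert df.loc[0, "query_genome"] == "A"
        assert df.loc[0, "bitscore"] == 222

    def test_unmapped_protein(self, tmp_path):
        path = tmp_path / "hits.o6"
        path.write_text("A_p1\tX_p9\t85.0\t120\t10\t1\t1\t120\t1\t120\t1e-20\t222\n")
        with pytest.raises(ValueError, match="X_p9"):
            convert_outfmt6(path, {"A_p1": "A"})


def three_taxon_matrix():
    return pd.DataFrame(
        [[0, 2, 4], [2, 0, 4], [4, 4, 0]],
        index=list("ABC"), columns=list("ABC"), dtype=float,
    )


def random_additive_tree(n_taxa, rng):
    nodes = [Clade(name=f"T{i}") for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.1, 1.0))
        b.length = float(rng.uniform(0.1, 1.0))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [
            Clade(children=[b, a])
        ]
    for x in nodes:
        x.length = float(rng.uniform(0.1, 1.0))
    return Clade(children=nodes)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        tree = neighbor_joining(three_taxon_matrix())
        limbs = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert limbs == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_recovers_additive_distances(self):
        rng = np.random.default_rng(11)
        for n_taxa in range(4, 9):
            source = random_additive_tree(n_taxa, rng)
            d = source.tip_distances().sort_index().sort_index(axis=1)
            recovered = neighbor_joining(d)
            d2 = recovered.tip_distances().loc[d.index, d.columns]
            assert np.allclose(d.to_numpy(), d2.to_numpy())

    def test_agrees_with_skbio_on_additive_input(self):
        rng = np.random.default_rng(3)
        source = random_additive_tree(6, rng)
        d = source.tip_distances().sort_index().sort_index(axis=1)
        mine = neighbor_joining(d)
        dm = skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        theirs = skbio.tree.nj(dm)
        their_d = theirs.tip_tip_distances()
        for i, a in enumerate(d.index):
            for b in d.index[i + 1:]:
                mine_d = mine.tip_distances().loc[a, b]
                assert mine_d == pytest.approx(their_d[a, b], abs=1e-9)

    def test_equal_distances_star(self):
        d = pd.DataFrame(1.0, index=list("ABCD"), columns=list("ABCD"))
        np.fill_diagonal(d.to_numpy(), 0)
        d = pd.DataFrame(np.where(np.eye(4, dtype=bool), 0.0, 1.0),
                         index=list("ABCD"), columns=list("ABCD"))
        tree = neighbor_joining(d)
        lengths = [leaf.length for leaf in tree.leaves()]
        assert max(lengths) - min(lengths) == pytest.approx(0.0)

    def test_two_taxa_trivial_tree(self):
        d = pd.DataFrame([[0, 3], [3, 0]], index=["A", "B"], columns=["A", "B"],
                         dtype=float)
        with pytest.warns(UserWarning):
            tree = neighbor_joining(d)
        assert {leaf.name for leaf in tree.leaves()} == {"A", "B"}
        assert sum(leaf.length for leaf in tree.leaves()) == pytest.approx(3.0)

    def test_negative_branch_clamped(self):
        d = pd.DataFrame(
            [[0, 1, 1, 10], [1, 0, 1, 10], [1, 1, 0, 1], [10, 10, 1, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        with pytest.warns(UserWarning, match="clamped"):
            tree = neighbor_joining(d)
        assert all(leaf.length >= 0 for leaf in tree.leaves())


class TestNewick:
    def test_three_taxon_serialization(self):
        s = to_newick(neighbor_joining(three_taxon_matrix()))
        assert s == "(A:1,B:1,C:3);"

    def test_round_trip_through_skbio(self, tmp_path):
        rng = np.random.default_rng(5)
        source = random_additive_tree(7, rng)
        d = source.tip_distances().sort_index().sort_index(axis=1)
        tree = neighbor_joining(d)
        path = tmp_path / "tree.nwk"
        write_newick(tree, path)
        parsed = skbio.TreeNode.read(str(path))
        reparsed_d = parsed.tip_tip_distances()
        for i, a in enumerate(d.index):
            for b in d.index[i + 1:]:
                assert reparsed_d[a, b] == pytest.approx(
                    tree.tip_distances().loc[a, b], rel=1e-4
                )

    def test_reserved_characters_quoted(self):
        tree = Clade(children=[
            Clade(name="odd name(1)", length=1.0),
            Clade(name="plain", length=2.0),
        ])
        s = to_newick(tree)
        assert "'odd name(1)'" in s
        parsed = skbio.TreeNode.read(io.StringIO(s))
        assert {t.name for t in parsed.tips()} == {"odd name(1)", "plain"}
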