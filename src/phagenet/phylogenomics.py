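"""Dice genome distances from filtered all-vs-all protein hits, and
neighbor-joining tree construction.

The genome distance is computed from summed bitscores of valid protein
matches: with AB the bitscore sum of genome A's proteins against genome B's
and AA, BB the self-comparison sums,

    D(A, B) = 1 - 2 * AB / (AA + BB).

A hit is valid if identity >= 30%, bitscore >= 30, alignment length >= 30
amino acids and e-value <= 0.01 (all thresholds configurable). D is a
pseudo-distance: the directed values D(A,B) and D(B,A) differ only through
search asymmetries, so the matrix is symmetrized by averaging and clamped
to [0, 1] before tree building. The triangle inequality is not guaranteed.

Aligner execution is out of scope: hit tables are consumed, either in a
native 8-column dialect or converted from 12-column BLAST/DIAMOND outfmt-6
plus a protein-to-genome map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HIT_COLUMNS",
    "read_hits",
    "convert_outfmt6",
    "filter_hits",
    "dice_distance_matrix",
    "Clade",
    "neighbor_joining",
    "to_newick",
    "write_newick",
]

# native hit-table dialect
HIT_COLUMNS = [
    "query_genome",
    "subject_genome",
    "query_protein",
    "subject_protein",
    "pct_identity",
    "align_len",
    "bitscore",
    "evalue",
]

_OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits(path: str | Path) -> pd.DataFrame:
    """Read a native 8-column hit table (TSV with header)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return _validate_hits(df[HIT_COLUMNS])


def _validate_hits(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("pct_identity", "align_len", "bitscore", "evalue"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(values.isna().to_numpy())
        if bad.size:
            raise ValueError(f"malformed {col} at row {bad[0]}")
        df = df.assign(**{col: values})
    if (df["pct_identity"].lt(0) | df["pct_identity"].gt(100)).any():
        raise ValueError("pct_identity outside [0, 100]")
    if (df["bitscore"] < 0).any() or (df["evalue"] < 0).any():
        raise ValueError("negative bitscore or evalue")
    return df


def convert_outfmt6(
    path: str | Path, protein_to_genome: Mapping[str, str]
) -> pd.DataFrame:
    """Convert a headerless 12-column BLAST/DIAMOND outfmt-6 table to the
    native dialect using a protein-id -> genome-id map."""
    df = pd.read_csv(path, sep="\t", header=None, names=_OUTFMT6_COLUMNS)
    unmapped = sorted(
        set(df["qseqid"]).union(df["sseqid"]) - set(protein_to_genome)
    )
    if unmapped:
        raise ValueError(f"proteins missing from genome map: {unmapped[:5]}")
    out = pd.DataFrame(
        {
            "query_genome": df["qseqid"].map(protein_to_genome),
            "subject_genome": df["sseqid"].map(protein_to_genome),
            "query_protein": df["qseqid"],
            "subject_protein": df["sseqid"],
            "pct_identity": df["pident"],
            "align_len": df["length"],
            "bitscore": df["bitscore"],
            "evalue": df["evalue"],
        }
    )
    return _validate_hits(out)


def filter_hits(
    hits: pd.DataFrame,
    min_identity: float = 30.0,
    min_bitscore: float = 30.0,
    min_length: int = 30,
    max_evalue: float = 0.01,
) -> pd.DataFrame:
    """Keep hits passing all four validity thresholds (>=, >=, >=, <=)."""
    keep = (
        (hits["pct_identity"] >= min_identity)
        & (hits["bitscore"] >= min_bitscore)
        & (hits["align_len"] >= min_length)
        & (hits["evalue"] <= max_evalue)
    )
    return hits.loc[keep].reset_index(drop=True)


def dice_distance_matrix(
    hits: pd.DataFrame,
    genomes: Sequence[str] | None = None,
    best_hit_only: bool = False,
) -> pd.DataFrame:
    """Dice distance matrix over genomes from (already filtered) hits.

    All matches between a protein pair are summed by default ("all the valid
    protein matches"); ``best_hit_only`` keeps only the highest-bitscore HSP
    per (query protein, subject protein) pair. Every genome must have
    self-hits (AA > 0). Output is symmetrized as (D_AB + D_BA)/2 and clamped
    to [0, 1], with zeros on the diagonal.
    """
    if genomes is None:
        genomes = sorted(set(hits["query_genome"]).union(hits["subject_genome"]))
    genomes = list(genomes)
    work = hits
    if best_hit_only:
        work = (
            work.sort_values("bitscore", ascending=False)
            .drop_duplicates(
                ["query_genome", "subject_genome", "query_protein", "subject_protein"]
            )
        )
    ab = (
        work.groupby(["query_genome", "subject_genome"])["bitscore"]
        .sum()
        .unstack(fill_value=0.0)
        .reindex(index=genomes, columns=genomes, fill_value=0.0)
    )
    self_scores = pd.Series(np.diag(ab.to_numpy()), index=genomes)
    missing = self_scores.index[self_scores <= 0].tolist()
    if missing:
        raise ValueError(f"genomes with no valid self-hits: {missing}")
    aa = self_scores.to_numpy()
    denom = aa[:, None] + aa[None, :]
    directed = 1.0 - 2.0 * ab.to_numpy() / denom
    sym = (directed + directed.T) / 2.0
    clipped = np.clip(sym, 0.0, 1.0)
    if (sym < 0).any() or (sym > 1).any():
        warnings.warn("Dice distances clamped to [0, 1]", stacklevel=2)
    np.fill_diagonal(clipped, 0.0)
    return pd.DataFrame(clipped, index=genomes, columns=genomes)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class Clade:
    """A node of an (un)rooted tree: leaves have a name, internal nodes
    children; ``length`` is the branch to the parent."""

    name: str | None = None
    length: float | None = None
    children: list["Clade"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Clade"]:
        if self.is_leaf():
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def tip_distances(self) -> pd.DataFrame:
        """All pairwise leaf-to-leaf path lengths (for additivity checks)."""
        names = self.leaf_names()
        dist = pd.DataFrame(0.0, index=names, columns=names)

        def below(node: Clade) -> dict[str, float]:
            if node.is_leaf():
                return {node.name: 0.0}
            sides = []
            for child in node.children:
                d = below(child)
                sides.append({k: v + (child.length or 0.0) for k, v in d.items()})
            for i in range(len(sides)):
                for j in range(i + 1, len(sides)):
                    for a, da in sides[i].items():
                        for b, db in sides[j].items():
                            dist.loc[a, b] = dist.loc[b, a] = da + db
            merged: dict[str, float] = {}
            for s in sides:
                merged.update(s)
            return merged

        below(self)
        return dist


def _min_leaf(node: Clade) -> str:
    return min(node.leaf_names())


def neighbor_joining(d: pd.DataFrame) -> Clade:
    """Canonical Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing the Q-criterion
    Q_ij = (r - 2) d_ij - R_i - R_j, with limb lengths from the standard
    formulas; ties are broken toward the lexicographically smallest pair of
    clade keys (the smallest leaf name in each clade). Negative limb lengths
    are clamped to 0 with a warning. The final tree is unrooted, rooted for
    serialization at the trifurcation of the last three clades.
    """
    names = list(d.index)
    if list(d.columns) != names:
        raise ValueError("distance matrix must have matching index and columns")
    mat = d.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be symmetric")
    if len(names) < 3:
        warnings.warn("fewer than 3 taxa: returning a trivial tree", stacklevel=2)
        if len(names) == 1:
            return Clade(name=names[0], length=0.0)
        half = mat[0, 1] / 2.0
        return Clade(children=[
            Clade(name=names[0], length=half),
            Clade(name=names[1], length=half),
        ])

    nodes = [Clade(name=n) for n in names]
    dist = {
        (i, j): mat[i, j]
        for i in range(len(names))
        for j in range(len(names))
        if i < j
    }
    active = list(range(len(names)))
    clades = {i: nodes[i] for i in active}
    next_id = len(names)

    def get(i: int, j: int) -> float:
        return dist[(i, j)] if i < j else dist[(j, i)]

    clamped = False
    while len(active) > 3:
        r = len(active)
        row_sums = {i: sum(get(i, j) for j in active if j != i) for i in active}
        best_pair = None
        best_q = np.inf
        for ii, i in enumerate(active):
            for j in active[ii + 1:]:
                q = (r - 2) * get(i, j) - row_sums[i] - row_sums[j]
                if q < best_q - 1e-12:
                    best_q, best_pair = q, (i, j)
                elif abs(q - best_q) <= 1e-12:
                    key_new = tuple(sorted((_min_leaf(clades[i]), _min_leaf(clades[j]))))
                    key_old = tuple(
                        sorted((_min_leaf(clades[best_pair[0]]), _min_leaf(clades[best_pair[1]])))
                    )
                    if key_new < key_old:
                        best_pair = (i, j)
        i, j = best_pair
        dij = get(i, j)
        li = dij / 2.0 + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            clamped = True
        li, lj = max(li, 0.0), max(lj, 0.0)
        ci, cj = clades[i], clades[j]
        ci.length, cj.length = li, lj
        parent = Clade(children=[ci, cj])
        clades[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            dist[(k, next_id) if k < next_id else (next_id, k)] = (
                get(i, k) + get(j, k) - dij
            ) / 2.0
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    # resolve the final trifurcation with the 3-leaf closed form
    a, b, c = active
    dab, dac, dbc = get(a, b), get(a, c), get(b, c)
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    if min(la, lb, lc) < 0:
        clamped = True
    for node, length in ((clades[a], la), (clades[b], lb), (clades[c], lc)):
        node.length = max(length, 0.0)
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0", stacklevel=2)
    return Clade(children=[clades[a], clades[b], clades[c]])


_NEWICK_RESERVED = set("();:,'[] \t\n")


def _quote(name: str) -> str:
    if any(ch in _NEWICK_RESERVED for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: Clade) -> str:
    """Serialize with branch lengths at 6 significant digits."""

    def fmt(node: Clade) -> str:
        if node.is_leaf():
            body = _quote(node.name or "")
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                body += _quote(node.name)
        if node.length is not None:
            body += f":{node.length:.6g}"
        return body

    return fmt(tree) + ";"


def write_newick(tree: Clade, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")
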