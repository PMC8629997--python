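"""Data model, I/O, de-duplication and descriptive statistics for
phage-bacteria incidence matrices.

The central object is :class:`IncidenceMatrix`, a binary host x phage
biadjacency matrix (rows = bacterial hosts, columns = phages; 1 = the phage
forms single plaques on the host). Host and phage records carry the
controlled-vocabulary metadata of the study design: staphylococcal species
and multilocus species group, coagulase type, isolation biome, and
antibiotic-resistance phenotype for hosts; isolation origin, morphology and
genome length for phages.

A "lysis from without" call (cell value 2 in input files) is a bacteriolytic
halo without productive infection; it is accepted on ingest and coerced to 0.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SPECIES_GROUPS",
    "COAGULASE_TYPES",
    "BIOMES",
    "RESISTANCE_CLASSES",
    "PHAGE_ORIGINS",
    "MORPHOLOGIES",
    "PHAGE_CLUSTERS",
    "HostRecord",
    "PhageRecord",
    "IncidenceMatrix",
    "PhageClusterMap",
    "read_incidence",
    "write_incidence",
    "read_metadata",
    "align_metadata",
    "collapse_identical_phages",
    "drop_uninfected_hosts",
    "matrix_summary",
    "classify_species_tendency",
    "ecosystem_span",
]

# Six multilocus species groups of the genus Staphylococcus, plus a bucket
# for non-staphylococcal panel members (e.g. Macrococcus, Enterococcus).
SPECIES_GROUPS = (
    "Auricularis",
    "Epidermidis-Aureus",
    "Hyicus-Intermedius",
    "Saprophyticus",
    "Sciuri",
    "Simulans",
    "non_staphylococcus",
)
COAGULASE_TYPES = ("CoNS", "CoPS", "non_staphylococcal")
BIOMES = ("human", "veterinary", "environmental", "unknown")
RESISTANCE_CLASSES = ("susceptible", "resistant", "MDR")
PHAGE_ORIGINS = ("inlet", "outlet", "induced", "reference")
MORPHOLOGIES = ("myovirus", "siphovirus", "podovirus", "unknown")
PHAGE_CLUSTERS = ("A", "B", "C", "D", "unknown")


def _check_vocab(value: str, vocab: Sequence[str], fieldname: str) -> None:
    if value not in vocab:
        raise ValueError(
            f"{fieldname}={value!r} is not in the controlled vocabulary {vocab}"
        )


@dataclass(frozen=True)
class HostRecord:
    """Metadata for one bacterial host strain."""

    host_id: str
    species: str
    species_group: str
    coagulase: str
    biome: str
    resistance: str

    def __post_init__(self) -> None:
        _check_vocab(self.species_group, SPECIES_GROUPS, "species_group")
        _check_vocab(self.coagulase, COAGULASE_TYPES, "coagulase")
        _check_vocab(self.biome, BIOMES, "biome")
        _check_vocab(self.resistance, RESISTANCE_CLASSES, "resistance")


@dataclass(frozen=True)
class PhageRecord:
    """Metadata for one phage isolate."""

    phage_id: str
    origin: str
    morphology: str = "unknown"
    genome_length: int | None = None
    cluster: str = "unknown"

    def __post_init__(self) -> None:
        _check_vocab(self.origin, PHAGE_ORIGINS, "origin")
        _check_vocab(self.morphology, MORPHOLOGIES, "morphology")
        _check_vocab(self.cluster, PHAGE_CLUSTERS, "cluster")
        if self.genome_length is not None and self.genome_length <= 0:
            raise ValueError(
                f"genome_length must be positive, got {self.genome_length}"
            )


class IncidenceMatrix:
    """Binary host x phage incidence matrix with aligned identifier lists.

    Parameters
    ----------
    entries:
        2-D array-like of 0/1, shape (n_hosts, n_phages).
    host_ids, phage_ids:
        Ordered, unique identifiers for rows and columns.

    Attributes
    ----------
    I : int
        Fill -- number of positive infections.
    M : int
        Size -- n_hosts * n_phages.
    C : float
        Connectance I/M (synonym: ``density``).
    """

    def __init__(
        self,
        entries: np.ndarray,
        host_ids: Sequence[str],
        phage_ids: Sequence[str],
    ):
        entries = np.asarray(entries)
        if entries.ndim != 2:
            raise ValueError("entries must be a 2-D matrix")
        if not np.isin(entries, (0, 1)).all():
            bad = np.argwhere(~np.isin(entries, (0, 1)))[0]
            raise ValueError(
                f"non-binary cell at row {bad[0]}, column {bad[1]}: "
                f"{entries[bad[0], bad[1]]!r}"
            )
        host_ids = [str(h) for h in host_ids]
        phage_ids = [str(p) for p in phage_ids]
        if len(set(host_ids)) != len(host_ids):
            dups = [h for h, c in Counter(host_ids).items() if c > 1]
            raise ValueError(f"duplicate host ids: {dups}")
        if len(set(phage_ids)) != len(phage_ids):
            dups = [p for p, c in Counter(phage_ids).items() if c > 1]
            raise ValueError(f"duplicate phage ids: {dups}")
        if entries.shape != (len(host_ids), len(phage_ids)):
            raise ValueError(
                f"shape {entries.shape} does not match "
                f"{len(host_ids)} hosts x {len(phage_ids)} phages"
            )
        self.entries = entries.astype(np.int8)
        self.host_ids = list(host_ids)
        self.phage_ids = list(phage_ids)

    # -- derived quantities -------------------------------------------------
    @property
    def n_hosts(self) -> int:
        return self.entries.shape[0]

    @property
    def n_phages(self) -> int:
        return self.entries.shape[1]

    @property
    def I(self) -> int:  # noqa: E743 - field name from the domain
        return int(self.entries.sum())

    @property
    def M(self) -> int:
        return self.entries.size

    @property
    def C(self) -> float:
        return self.I / self.M if self.M else float("nan")

    @property
    def density(self) -> float:
        return self.C

    def host_degrees(self) -> np.ndarray:
        """Number of phages infecting each host (row sums)."""
        return self.entries.sum(axis=1)

    def phage_degrees(self) -> np.ndarray:
        """Number of hosts infected by each phage (column sums)."""
        return self.entries.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, index=self.host_ids, columns=self.phage_ids
        )

    def __repr__(self) -> str:
        return (
            f"IncidenceMatrix({self.n_hosts} hosts x {self.n_phages} phages, "
            f"I={self.I}, C={self.C:.3g})"
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, IncidenceMatrix)
            and self.host_ids == other.host_ids
            and self.phage_ids == other.phage_ids
            and np.array_equal(self.entries, other.entries)
        )


@dataclass
class PhageClusterMap:
    """Mapping from a representative phage to the identical-host-range group
    it stands for (the representative is included in its member list)."""

    groups: dict[str, list[str]]

    @property
    def multiplicity(self) -> dict[str, int]:
        return {rep: len(members) for rep, members in self.groups.items()}

    def members(self) -> list[str]:
        return [m for mem in self.groups.values() for m in mem]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if str(path).lower().endswith(".csv") else "tsv"
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_incidence(path: str | Path, dialect: str | None = None) -> IncidenceMatrix:
    """Read an incidence matrix from TSV/CSV.

    Layout: header row of phage ids, first column of host ids, cells in
    {0, 1, 2}. Value 2 marks lysis from without and is coerced to 0 (reported
    but not an infection). Row and column order is preserved.
    """
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0)
    arr = df.to_numpy()
    for (i, j) in np.argwhere(~np.isin(arr, (0, 1, 2))):
        raise ValueError(
            f"non-binary cell at host {df.index[i]!r}, phage "
            f"{df.columns[j]!r}: {arr[i, j]!r}"
        )
    arr = np.where(arr == 2, 0, arr)
    return IncidenceMatrix(arr, df.index, df.columns)


def write_incidence(m: IncidenceMatrix, path: str | Path, dialect: str | None = None) -> None:
    m.to_frame().to_csv(path, sep=_sep_for(path, dialect))


_HOST_COLUMNS = ["host_id", "species", "species_group", "coagulase", "biome", "resistance"]
_PHAGE_COLUMNS = ["phage_id", "origin", "morphology", "genome_length", "cluster"]


def read_metadata(path: str | Path, kind: str) -> list[HostRecord] | list[PhageRecord]:
    """Read host or phage metadata from a TSV with named columns.

    ``kind`` is ``"host"`` or ``"phage"``. Unknown categories are rejected
    with a :class:`ValueError` naming the offending field.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if kind == "host":
        missing = set(_HOST_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"host metadata missing columns: {sorted(missing)}")
        return [
            HostRecord(
                host_id=r.host_id,
                species=r.species,
                species_group=r.species_group,
                coagulase=r.coagulase,
                biome=r.biome,
                resistance=r.resistance,
            )
            for r in df.itertuples()
        ]
    if kind == "phage":
        required = {"phage_id", "origin"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"phage metadata missing columns: {sorted(missing)}")
        records = []
        for r in df.itertuples():
            length = getattr(r, "genome_length", None)
            if length is not None and not pd.isna(length):
                length = int(float(length))
            else:
                length = None
            records.append(
                PhageRecord(
                    phage_id=r.phage_id,
                    origin=r.origin,
                    morphology=getattr(r, "morphology", "unknown") or "unknown",
                    genome_length=length,
                    cluster=getattr(r, "cluster", "unknown") or "unknown",
                )
            )
        return records
    raise ValueError(f"kind must be 'host' or 'phage', got {kind!r}")


def write_metadata(records: Iterable[HostRecord] | Iterable[PhageRecord], path: str | Path) -> None:
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    if isinstance(records[0], HostRecord):
        cols = _HOST_COLUMNS
    else:
        cols = _PHAGE_COLUMNS
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])
    df.to_csv(path, sep="\t", index=False)


def align_metadata(
    m: IncidenceMatrix,
    records: Sequence[HostRecord] | Sequence[PhageRecord],
    kind: str,
) -> dict[str, HostRecord] | dict[str, PhageRecord]:
    """Index records by id and verify every matrix id is covered."""
    id_attr = "host_id" if kind == "host" else "phage_id"
    index = {getattr(r, id_attr): r for r in records}
    wanted = m.host_ids if kind == "host" else m.phage_ids
    missing = [i for i in wanted if i not in index]
    if missing:
        raise ValueError(f"{kind} ids in matrix but absent from metadata: {missing}")
    return index


# ---------------------------------------------------------------------------
# De-duplication and filtering
# ---------------------------------------------------------------------------

def collapse_identical_phages(
    m: IncidenceMatrix,
) -> tuple[IncidenceMatrix, PhageClusterMap]:
    """Collapse phages with bitwise-identical host-range columns.

    Phages indistinguishable on the host panel are treated as one isolate
    cluster; the representative is the first-seen column. All-zero columns
    form their own group and are retained.
    """
    seen: dict[bytes, str] = {}
    groups: dict[str, list[str]] = {}
    keep: list[int] = []
    for j, pid in enumerate(m.phage_ids):
        key = m.entries[:, j].tobytes()
        if key in seen:
            groups[seen[key]].append(pid)
        else:
            seen[key] = pid
            groups[pid] = [pid]
            keep.append(j)
    collapsed = IncidenceMatrix(
        m.entries[:, keep], m.host_ids, [m.phage_ids[j] for j in keep]
    )
    return collapsed, PhageClusterMap(groups)


def drop_uninfected_hosts(m: IncidenceMatrix) -> tuple[IncidenceMatrix, list[str]]:
    """Remove phage-resistant hosts (all-zero rows).

    Returns the reduced matrix and the removed host ids. The fill I and all
    per-phage degrees are unchanged.
    """
    degrees = m.host_degrees()
    keep = np.flatnonzero(degrees > 0)
    removed = [m.host_ids[i] for i in np.flatnonzero(degrees == 0)]
    reduced = IncidenceMatrix(
        m.entries[keep, :], [m.host_ids[i] for i in keep], m.phage_ids
    )
    return reduced, removed


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    mean = float(values.mean()) if values.size else float("nan")
    sd = float(values.std(ddof=1)) if values.size > 1 else float("nan")
    return mean, sd


def bipartite_graph(m: IncidenceMatrix) -> nx.Graph:
    """Bipartite host-phage graph (hosts and phages as nodes, infections as
    edges). Node names are prefixed ``H:`` / ``P:`` to avoid collisions."""
    g = nx.Graph()
    g.add_nodes_from((f"H:{h}" for h in m.host_ids), bipartite=0)
    g.add_nodes_from((f"P:{p}" for p in m.phage_ids), bipartite=1)
    rows, cols = np.nonzero(m.entries)
    g.add_edges_from(
        (f"H:{m.host_ids[i]}", f"P:{m.phage_ids[j]}") for i, j in zip(rows, cols)
    )
    return g


def bipartite_diameter(m: IncidenceMatrix) -> int:
    """Longest shortest path on the largest connected component of the
    host-phage bipartite graph; isolated nodes are ignored."""
    g = bipartite_graph(m)
    g.remove_nodes_from(list(nx.isolates(g)))
    if g.number_of_nodes() == 0:
        raise ValueError("empty matrix has no diameter")
    comp = max(nx.connected_components(g), key=len)
    return nx.diameter(g.subgraph(comp))


def matrix_summary(
    m: IncidenceMatrix,
    hosts: Sequence[HostRecord] | None = None,
    phages: Sequence[PhageRecord] | None = None,
) -> dict:
    """Descriptive report of the incidence matrix.

    Always reports I, M, C/density, per-host and per-phage degree mean +- sd
    (n-1 denominator) and maxima, and the bipartite diameter. With host
    metadata, adds species/species-group breadth per phage, the CoNS/CoPS
    interaction split, and permissive-host fractions per biome and
    resistance class.
    """
    if m.M == 0 or m.I == 0:
        raise ValueError("matrix summary requires a non-empty matrix")
    hd = m.host_degrees()
    pdg = m.phage_degrees()
    host_mean, host_sd = _mean_sd(hd)
    phage_mean, phage_sd = _mean_sd(pdg)
    report: dict = {
        "n_hosts": m.n_hosts,
        "n_phages": m.n_phages,
        "I": m.I,
        "M": m.M,
        "C": m.C,
        "density": m.density,
        "host_degree": {"mean": host_mean, "sd": host_sd, "max": int(hd.max())},
        "phage_degree": {"mean": phage_mean, "sd": phage_sd, "max": int(pdg.max())},
        "diameter": bipartite_diameter(m),
    }
    if hosts is not None:
        index = align_metadata(m, hosts, "host")
        recs = [index[h] for h in m.host_ids]
        species = np.array([r.species for r in recs])
        groups = np.array([r.species_group for r in recs])
        coag = np.array([r.coagulase for r in recs])
        biome = np.array([r.biome for r in recs])
        resist = np.array([r.resistance for r in recs])

        # per-phage taxonomic breadth
        n_species = []
        n_groups = []
        for j in range(m.n_phages):
            infected = m.entries[:, j] > 0
            n_species.append(len(set(species[infected])))
            n_groups.append(len(set(groups[infected])))
        sp_mean, sp_sd = _mean_sd(np.array(n_species))
        gr_mean, gr_sd = _mean_sd(np.array(n_groups))
        report["phage_species_breadth"] = {"mean": sp_mean, "sd": sp_sd, "max": int(max(n_species))}
        report["phage_group_breadth"] = {"mean": gr_mean, "sd": gr_sd, "max": int(max(n_groups))}

        # distinct phages infecting each species
        per_species = [
            int((m.entries[species == s, :].any(axis=0)).sum())
            for s in sorted(set(species))
        ]
        spi_mean, spi_sd = _mean_sd(np.array(per_species))
        report["species_infections"] = {"mean": spi_mean, "sd": spi_sd, "max": int(max(per_species))}
        report["n_infected_species"] = int(sum(1 for v in per_species if v > 0))

        # interaction split by coagulase type
        total = m.I
        report["interaction_fraction"] = {
            c: float(m.entries[coag == c, :].sum() / total)
            for c in COAGULASE_TYPES
            if (coag == c).any()
        }

        permissive = hd > 0
        report["permissive_fraction_by_biome"] = {
            b: float(permissive[biome == b].mean())
            for b in BIOMES
            if (biome == b).any()
        }
        report["permissive_fraction_by_resistance"] = {
            r: float(permissive[resist == r].mean())
            for r in RESISTANCE_CLASSES
            if (resist == r).any()
        }
        staph = groups != "non_staphylococcus"
        if staph.any():
            report["permissive_fraction_staphylococci"] = float(permissive[staph].mean())
    if phages is not None:
        align_metadata(m, phages, "phage")
    return report


def classify_species_tendency(
    m: IncidenceMatrix,
    hosts: Sequence[HostRecord],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Label each phage by the species concentration of its host range.

    ``single_species``: every infected host belongs to one species.
    ``species_tendency``: more than one species infected, but the modal
    species holds at least ``threshold`` of the infected strains.
    ``no_tendency``: otherwise. Phages with zero infections are labelled
    ``uninfective`` and excluded from aggregate counts.
    """
    index = align_metadata(m, hosts, "host")
    species = np.array([index[h].species for h in m.host_ids])
    rows = []
    for j, pid in enumerate(m.phage_ids):
        infected = m.entries[:, j] > 0
        n = int(infected.sum())
        if n == 0:
            rows.append((pid, "uninfective", None, float("nan"), 0, 0))
            continue
        counts = Counter(species[infected])
        modal, modal_n = counts.most_common(1)[0]
        share = modal_n / n
        if len(counts) == 1:
            label = "single_species"
        elif share >= threshold:
            label = "species_tendency"
        else:
            label = "no_tendency"
        rows.append((pid, label, modal, share, n, len(counts)))
    return pd.DataFrame(
        rows,
        columns=["phage_id", "label", "modal_species", "modal_share", "n_hosts", "n_species"],
    ).set_index("phage_id")


def ecosystem_span(
    m: IncidenceMatrix, hosts: Sequence[HostRecord]
) -> tuple[dict[str, frozenset[str]], dict]:
    """Biomes covered by each phage's host range.

    Returns a per-phage mapping to the set of biomes of its infected hosts,
    and aggregate counts: how many phages span 1, 2, 3 biomes and each named
    biome combination.
    """
    index = align_metadata(m, hosts, "host")
    biome = np.array([index[h].biome for h in m.host_ids])
    spans: dict[str, frozenset[str]] = {}
    for j, pid in enumerate(m.phage_ids):
        infected = m.entries[:, j] > 0
        spans[pid] = frozenset(biome[infected])
    by_count = Counter(len(s) for s in spans.values() if s)
    by_combo = Counter("+".join(sorted(s)) for s in spans.values() if s)
    aggregate = {
        "n_phages_by_span": dict(sorted(by_count.items())),
        "n_phages_by_combination": dict(sorted(by_combo.items())),
        "n_multi_biome": int(sum(1 for s in spans.values() if len(s) >= 2)),
    }
    return spans, aggregate


def summary_to_json(report: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
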