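"""Phage species delimitation: ANI graph + paraclique clustering.

Species are operational clusters at >=95% identity and >=90% coverage
(defaults; a lenient 70/70 setting is used for robustness checks). The two
asymmetric matrices are symmetrized per pair, thresholded into an
undirected graph, and the graph is partitioned by a paraclique strategy:
repeatedly take an exact maximum clique as a seed, glom on outside vertices
adjacent to at least a fraction ``g`` of the current cluster, emit, and
remove. Everything is deterministic: ties are broken by sorted id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd

from .ani import AniMatrix
from .errors import JoinError, ParameterError

SYMMETRIZATIONS = ("mean-min", "mean-both", "either")


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds and knobs of the species delimitation.

    ``symmetrization`` reconciles the two directions of each pair before
    thresholding: ``mean-min`` (default) averages the identities and takes
    the minimum coverage — conservative on coverage so that a short
    sequence embedded in a longer one cannot chain two species together;
    ``mean-both`` averages both; ``either`` accepts the pair if either
    single direction passes both thresholds. ``strict`` switches the
    comparisons from >= to >.
    """

    min_identity: float = 95.0
    min_coverage: float = 90.0
    glom: float = 0.9
    symmetrization: str = "mean-min"
    strict: bool = False
    prefix: str = "Ab_PS"

    def __post_init__(self):
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not 0.0 < v <= 100.0:
                raise ParameterError(f"{name} must be in (0, 100]")
        if not 0.0 < self.glom <= 1.0:
            raise ParameterError("glom must be in (0, 1]")
        if self.symmetrization not in SYMMETRIZATIONS:
            raise ParameterError(f"symmetrization must be one of {SYMMETRIZATIONS}")


@dataclass
class SpeciesPartition:
    """A disjoint cover of sequence ids by species clusters.

    ``species`` maps species name -> sorted member id list, in naming order.
    Before :func:`name_species` the names are positional placeholders.
    """

    species: dict[str, list[str]]
    params: Optional[ClusterParams] = None
    named: bool = False

    def __post_init__(self):
        seen: set[str] = set()
        for name, members in self.species.items():
            if not members:
                raise ParameterError(f"species {name} has no members")
            dup = seen.intersection(members)
            if dup:
                raise ParameterError(f"ids in more than one species: {sorted(dup)}")
            seen.update(members)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def all_ids(self) -> set[str]:
        return {m for members in self.species.values() for m in members}

    def sizes(self) -> list[int]:
        return [len(v) for v in self.species.values()]

    def membership(self) -> dict[str, str]:
        return {m: name for name, members in self.species.items() for m in members}

    def is_singleton(self, name: str) -> bool:
        return len(self.species[name]) == 1

    def labels(self, ids: Iterable[str]) -> list[str]:
        mm = self.membership()
        return [mm[i] for i in ids]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species": name,
                "member": m,
                "size": len(members),
                "singleton": len(members) == 1,
            }
            for name, members in self.species.items()
            for m in members
        ]
        return pd.DataFrame(rows, columns=["species", "member", "size", "singleton"])


def build_graph(matrix: AniMatrix, params: ClusterParams | None = None) -> nx.Graph:
    """Threshold the symmetrized ANI matrices into an undirected graph.

    Every sequence id becomes a node; an edge joins a pair iff its
    symmetrized identity and coverage pass the thresholds. No self-loops.
    """
    if params is None:
        params = ClusterParams()
    ids = matrix.ids
    I, C = matrix.identity, matrix.coverage
    G = nx.Graph()
    G.add_nodes_from(ids)

    def ok(ident: float, cov: float) -> bool:
        if params.strict:
            return ident > params.min_identity and cov > params.min_coverage
        return ident >= params.min_identity and cov >= params.min_coverage

    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if params.symmetrization == "mean-min":
                passed = ok((I[i, j] + I[j, i]) / 2.0, min(C[i, j], C[j, i]))
            elif params.symmetrization == "mean-both":
                passed = ok((I[i, j] + I[j, i]) / 2.0, (C[i, j] + C[j, i]) / 2.0)
            else:  # either single direction suffices
                passed = ok(I[i, j], C[i, j]) or ok(I[j, i], C[j, i])
            if passed:
                G.add_edge(ids[i], ids[j])
    return G


def _maximum_clique(G: nx.Graph) -> list[str]:
    """Exact maximum clique; ties by lexicographically smallest sorted ids."""
    best: list[str] | None = None
    for clique in nx.find_cliques(G):
        cand = sorted(clique)
        if best is None or len(cand) > len(best) or (
            len(cand) == len(best) and cand < best
        ):
            best = cand
    assert best is not None
    return best


def _glom_threshold(g: float, size: int) -> int:
    # tiny epsilon guards against binary-float artifacts (0.8*5 -> 4.0000000000000001)
    return math.ceil(g * size - 1e-9)


def paraclique_partition(graph: nx.Graph, g: float = 0.9,
                         params: ClusterParams | None = None) -> SpeciesPartition:
    """Partition a graph into paracliques plus singletons.

    While edges remain: seed with the exact maximum clique, then repeatedly
    absorb the unassigned vertex (smallest id first) adjacent to at least
    ``ceil(g * |cluster|)`` current members; emit and remove. Left-over
    vertices become singletons. Deterministic.
    """
    if not 0.0 < g <= 1.0:
        raise ParameterError("glom factor g must be in (0, 1]")
    G = graph.copy()
    clusters: list[list[str]] = []
    while G.number_of_edges() > 0:
        members = set(_maximum_clique(G))
        while True:
            need = _glom_threshold(g, len(members))
            cands = [
                v for v in G.nodes
                if v not in members
                and sum(1 for u in members if G.has_edge(u, v)) >= need
            ]
            if not cands:
                break
            members.add(min(cands))
        clusters.append(sorted(members))
        G.remove_nodes_from(members)
    clusters.extend([v] for v in sorted(G.nodes))
    species = {f"cluster_{i + 1}": c for i, c in enumerate(clusters)}
    return SpeciesPartition(species=species, params=params, named=False)


def name_species(partition: SpeciesPartition,
                 prefix: str | None = None) -> SpeciesPartition:
    """Name clusters ``<prefix>1..n`` by decreasing size, then smallest id.

    Idempotent: renaming a named partition yields identical names.
    """
    if prefix is None:
        prefix = partition.params.prefix if partition.params else "Ab_PS"
    ordered = sorted(
        partition.species.values(), key=lambda mem: (-len(mem), min(mem))
    )
    species = {f"{prefix}{i + 1}": sorted(mem) for i, mem in enumerate(ordered)}
    return SpeciesPartition(species=species, params=partition.params, named=True)


def export_network(partition: SpeciesPartition, graph: nx.Graph,
                   node_attributes: Mapping[str, Mapping[str, object]] | None = None,
                   out_prefix: str | None = None):
    """Annotate the ANI graph with species (and optional metadata) attributes.

    ``node_attributes`` maps node id -> {attribute: value} (e.g. host, ST,
    country). Returns the annotated graph; when ``out_prefix`` is given,
    writes ``<prefix>.graphml``, ``<prefix>_edges.tsv`` and
    ``<prefix>_nodes.tsv`` loadable by standard graph viewers.
    """
    mm = partition.membership()
    missing = set(graph.nodes) - set(mm)
    if missing:
        raise JoinError(missing, context="partition membership")
    H = graph.copy()
    for node in H.nodes:
        H.nodes[node]["species"] = mm[node]
        H.nodes[node]["singleton"] = partition.is_singleton(mm[node])
        if node_attributes and node in node_attributes:
            for key, val in node_attributes[node].items():
                H.nodes[node][key] = "" if val is None else val
    if out_prefix is not None:
        nx.write_graphml(H, f"{out_prefix}.graphml")
        edges = pd.DataFrame(
            [(a, b) for a, b in sorted(H.edges)], columns=["source", "target"]
        )
        edges.to_csv(f"{out_prefix}_edges.tsv", sep="\t", index=False)
        nodes = pd.DataFrame(
            [{"node": n, **H.nodes[n]} for n in sorted(H.nodes)]
        )
        nodes.to_csv(f"{out_prefix}_nodes.tsv", sep="\t", index=False)
    return H


def check_superinfection_exclusion(
    partition: SpeciesPartition,
    prophage_genomes: Mapping[str, str],
) -> list[tuple[str, str, list[str]]]:
    """List (genome, species, members) with two or more same-species prophages.

    An empty list is the expected outcome under superinfection exclusion:
    no two members of one species should reside in one bacterial genome.
    """
    mm = partition.membership()
    missing = set(mm) - set(prophage_genomes)
    if missing:
        raise JoinError(missing, context="prophage -> genome mapping")
    per: dict[tuple[str, str], list[str]] = {}
    for pid, sp in mm.items():
        per.setdefault((prophage_genomes[pid], sp), []).append(pid)
    return sorted(
        (gid, sp, sorted(members))
        for (gid, sp), members in per.items()
        if len(members) >= 2
    )
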