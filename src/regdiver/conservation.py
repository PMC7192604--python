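"""Cross-species conservation: orthogroups, hit filtering, genome dedup.

Operates on precomputed similarity-search outputs (reciprocal best-hit edge
lists, pairwise-alignment hit tables, MLST fragment hits); the searches
themselves (BLAST, phmmer, needle) run upstream. An orthogroup is a connected
component of the bidirectional-best-hit (BBH) graph; a component in which
every member identifies every other (a clique, necessarily one member per
genome) is *closed*, a closed component spanning all genomes is *strict core*,
and an *open* component is reduced to its closed part by greedy peeling.
Conservation of a gene is the fraction of genomes with an accepted ortholog.
Genome collections are deduplicated on a seven-fragment MLST signature of
whole-number identity/overlap percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

#: Classic seven-gene MLST scheme fragments.
MLST_FRAGMENTS = ("adk", "fumC", "gyrB", "icd", "mdh", "purA", "recA")

Node = tuple[str, str]  # (genome id, protein id)


@dataclass
class BBHGraph:
    """Undirected graph of reciprocal best hits between proteomes."""

    graph: nx.Graph

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, str, str]]) -> "BBHGraph":
        """Build from rows (genome_a, prot_a, genome_b, prot_b)."""
        g = nx.Graph()
        for ga, pa, gb, pb in edges:
            a, b = (str(ga), str(pa)), (str(gb), str(pb))
            if a == b:
                continue
            if ga == gb:
                raise ValueError(f"reciprocal hit within one genome: {a} - {b}")
            g.add_edge(a, b)
        return cls(g)

    @property
    def nodes(self) -> list[Node]:
        return sorted(self.graph.nodes)


@dataclass(frozen=True)
class OrthoGroup:
    members: frozenset[Node]
    label: str  # strict_core | closed | open
    retained: frozenset[Node]

    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}


def _is_clique(graph: nx.Graph, nodes: set[Node]) -> bool:
    nodes = set(nodes)
    k = len(nodes)
    if k < 2:
        return True
    sub = graph.subgraph(nodes)
    return sub.number_of_edges() == k * (k - 1) // 2


def _greedy_peel(graph: nx.Graph, nodes: set[Node]) -> frozenset[Node]:
    """Reduce a component to a clique by deleting the weakest member.

    Repeatedly removes the node with the fewest reciprocal links within the
    current set (lexicographically smallest on ties) until the remainder is a
    mutual-identification clique. Greedy rather than exact maximum clique;
    deterministic.
    """
    current = set(nodes)
    while not _is_clique(graph, current):
        sub = graph.subgraph(current)
        weakest = min(sorted(current), key=lambda n: sub.degree(n))
        current.discard(weakest)
    return frozenset(current)


def classify_orthogroups(graph: BBHGraph, n_genomes: int) -> list[OrthoGroup]:
    """Classify each BBH connected component.

    closed: clique of reciprocal edges (since edges never join proteins of the
    same genome, a clique has one member per genome); strict_core: closed and
    spanning all ``n_genomes``; open: anything else, with ``retained`` the
    greedily-peeled closed part. Components with multiple members from one
    genome (in-paralogy) can never be cliques and classify as open.
    """
    groups: list[OrthoGroup] = []
    for comp in nx.connected_components(graph.graph):
        members = frozenset(comp)
        if _is_clique(graph.graph, set(members)):
            genomes = {g for g, _ in members}
            if len(genomes) == n_genomes and len(members) == n_genomes:
                label = "strict_core"
            else:
                label = "closed"
            retained = members
        else:
            label = "open"
            retained = _greedy_peel(graph.graph, set(members))
        groups.append(OrthoGroup(members=members, label=label, retained=retained))
    return sorted(groups, key=lambda g: sorted(g.members)[0])


def conservation_fraction(
    presence: Mapping[str, set[str]], n_genomes: int
) -> dict[str, float]:
    """Fraction of genomes in which an ortholog was accepted, per gene."""
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    return {g: len(gs) / n_genomes for g, gs in presence.items()}


def gap_filter(
    hits: Mapping[str, float], max_gap: float = 0.10
) -> set[str]:
    """Reject hits whose pairwise global alignment has > ``max_gap`` gaps.

    Gap-heavy alignments indicate extra or missing domains, hence a likely
    functional difference; the boundary is inclusive (exactly 10% is kept).
    """
    for h, frac in hits.items():
        if not (0 <= frac <= 1):
            raise ValueError(f"hit {h!r}: gap fraction outside [0, 1]")
    return {h for h, frac in hits.items() if frac <= max_gap}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def mlst_dedup(
    hit_table: Mapping[str, Mapping[str, tuple]],
    min_identity: float = 70.0,
    min_overlap: float = 90.0,
    max_evalue: float = 1e-5,
    seed: int | None = None,
    fragments: tuple[str, ...] = MLST_FRAGMENTS,
) -> list[str]:
    """Deduplicate strains on their MLST identity/overlap signature.

    ``hit_table`` maps strain -> fragment -> (identity %, overlap %[, E]).
    Hits failing the identity/overlap/E thresholds are treated as missing, and
    strains missing any of the seven fragments are removed. The signature is
    the 14-tuple of round-half-up whole-number percentages; one uniformly
    random representative (seeded) is kept per distinct signature, so every
    retained pair of strains differs by at least one percent on some fragment.
    """
    if not hit_table:
        raise ValueError("empty MLST hit table")
    signatures: dict[str, tuple[int, ...]] = {}
    for strain in sorted(hit_table):
        frags = hit_table[strain]
        sig: list[int] = []
        complete = True
        for frag in fragments:
            hit = frags.get(frag)
            if hit is None:
                complete = False
                break
            identity, overlap = float(hit[0]), float(hit[1])
            evalue = float(hit[2]) if len(hit) > 2 else 0.0
            if identity < min_identity or overlap < min_overlap \
                    or evalue > max_evalue:
                complete = False
                break
            sig.extend((_round_half_up(identity), _round_half_up(overlap)))
        if complete:
            signatures[strain] = tuple(sig)

    by_sig: dict[tuple[int, ...], list[str]] = {}
    for strain, sig in signatures.items():
        by_sig.setdefault(sig, []).append(strain)
    rng = np.random.default_rng(seed)
    selected = [
        group[rng.integers(len(group))]
        for sig, group in sorted(by_sig.items())
        for group in [sorted(group)]
    ]
    return sorted(selected)
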