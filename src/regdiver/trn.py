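"""Transcriptional regulatory network (TRN) data model.

A TRN is a directed graph of transcription factors (TFs) regulating target
genes (TGs). Targets are grouped into transcription units (TUs) -- one or more
genes transcribed together from a single promoter -- and a TF's regulon size
N_TU is the number of TUs it regulates. TF-TF regulatory interactions are
excluded up front, so every retained edge points from a TF to a non-TF target;
TFs left without any non-TF target are dropped entirely. Regulators are
classified global (GR) or local (LR) by regulon size.

Coordinates are 0-based, half-open throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene on the reference.

    ``cds`` is the coding nucleotide sequence (multiple of 3, ending in a
    stop codon); ``role`` is "TF" or "TG".
    """

    id: str
    start: int
    end: int
    strand: str
    cds: str
    role: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.id}: end must exceed start")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")
        if len(self.cds) % 3 != 0:
            raise ValueError(f"gene {self.id}: CDS length not a multiple of 3")
        if self.cds and self.cds[-3:].upper() not in STOP_CODONS:
            raise ValueError(f"gene {self.id}: CDS does not end in a stop codon")
        if self.role not in {"TF", "TG"}:
            raise ValueError(f"gene {self.id}: role must be 'TF' or 'TG'")

    @property
    def n_codons(self) -> int:
        """Number of codons including the terminal stop."""
        return len(self.cds) // 3


@dataclass(frozen=True)
class TranscriptionUnit:
    id: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"TU {self.id} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"TU {self.id} contains duplicate gene ids")

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.gene_ids)


@dataclass
class RegulatoryNetwork:
    """TF -> TU regulatory network after TF-TF edge exclusion.

    ``edges`` maps each retained TF to the set of TU ids it regulates; the
    regulon size ``n_tu`` is the cardinality of that set.
    """

    tf_ids: set[str]
    tg_ids: set[str]
    edges: dict[str, set[str]]
    tus: dict[str, TranscriptionUnit]
    gene_edges: dict[str, set[str]] = field(default_factory=dict)
    regulator_class: dict[str, str] = field(default_factory=dict)

    @property
    def n_tu(self) -> dict[str, int]:
        return {tf: len(tu_ids) for tf, tu_ids in self.edges.items()}

    def validate(self) -> None:
        if self.tf_ids & self.tg_ids:
            raise AssertionError("tf_ids and tg_ids overlap")
        for tf, targets in self.gene_edges.items():
            if targets & self.tf_ids:
                raise AssertionError(f"TF {tf} still targets a TF")
        for tf in self.tf_ids:
            if len(self.edges.get(tf, ())) < 1:
                raise AssertionError(f"TF {tf} has an empty regulon")


def resolve_fully_overlapping_tus(
    tus: Sequence[TranscriptionUnit],
) -> list[TranscriptionUnit]:
    """Drop TUs whose gene set is contained in another TU's gene set.

    A single operon may carry several fully or partially overlapping TUs;
    for fully overlapping ones only the largest is kept (for TUs with equal
    gene sets, the lexicographically-smallest id survives). Partial overlaps
    are left untouched.
    """
    kept: list[TranscriptionUnit] = []
    ordered = sorted(tus, key=lambda t: t.id)
    for tu in ordered:
        subsumed = any(
            other is not tu
            and tu.gene_set <= other.gene_set
            and (tu.gene_set != other.gene_set or other.id < tu.id)
            for other in ordered
        )
        if not subsumed:
            kept.append(tu)
    return kept


def load_regulatory_network(
    edge_table: Iterable[tuple[str, str]],
    tu_table: Iterable[TranscriptionUnit] | Mapping[str, Sequence[str]],
    tf_ids: set[str] | None = None,
) -> RegulatoryNetwork:
    """Build a RegulatoryNetwork from (TF, regulated gene) edges and TUs.

    All regulatory interactions among TFs are excluded: any edge whose target
    is itself a TF is removed, and TFs left with no targets are dropped. A TF
    that is somebody's target keeps its TF role and never enters any TG set.
    By default the TF set is inferred as the regulator column of the edge
    table; pass ``tf_ids`` to declare TFs that never act as regulators.

    Regulon sizes are counted in TUs: each TF's regulon is the set of TUs
    containing at least one of its (non-TF) targets. TU overlap resolution is
    a separate step (:func:`resolve_fully_overlapping_tus`), applied to the TU
    list before the network is built when full-overlap semantics are wanted.
    """
    edges = [(str(a), str(b)) for a, b in edge_table]
    if not edges:
        raise ValueError("edge table is empty")
    if isinstance(tu_table, Mapping):
        tu_list = [TranscriptionUnit(k, tuple(v)) for k, v in tu_table.items()]
    else:
        tu_list = list(tu_table)
    tfs = set(tf_ids) if tf_ids is not None else {a for a, _ in edges}
    tfs |= {a for a, _ in edges}

    gene_to_tus: dict[str, set[str]] = {}
    for tu in tu_list:
        for g in tu.gene_ids:
            gene_to_tus.setdefault(g, set()).add(tu.id)

    gene_edges: dict[str, set[str]] = {}
    for tf, target in edges:
        if target in tfs:
            continue  # TF-TF interaction: excluded from the network
        gene_edges.setdefault(tf, set()).add(target)

    tu_edges: dict[str, set[str]] = {}
    for tf, targets in gene_edges.items():
        tu_ids: set[str] = set()
        for g in targets:
            if g not in gene_to_tus:
                raise ValueError(
                    f"regulated gene {g!r} is absent from the TU table")
            tu_ids |= gene_to_tus[g]
        tu_edges[tf] = tu_ids

    retained_tfs = {tf for tf, targets in gene_edges.items() if targets}
    tg_ids = set().union(*gene_edges.values()) if gene_edges else set()
    net = RegulatoryNetwork(
        tf_ids=retained_tfs,
        tg_ids=tg_ids,
        edges={tf: tu_edges[tf] for tf in retained_tfs},
        tus={tu.id: tu for tu in tu_list},
        gene_edges={tf: gene_edges[tf] for tf in retained_tfs},
    )
    net.validate()
    return net


def classify_regulators(
    network: RegulatoryNetwork, gr_threshold: int = 10
) -> dict[str, str]:
    """Label each TF global (GR, N_TU >= threshold) or local (LR).

    The boundary is inclusive: a regulon of exactly ``gr_threshold`` TUs is
    global.
    """
    if gr_threshold < 1:
        raise ValueError("gr_threshold must be >= 1")
    labels = {
        tf: ("GR" if n >= gr_threshold else "LR")
        for tf, n in network.n_tu.items()
    }
    network.regulator_class = labels
    return labels
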