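"""Readers and writers for the package's plain-text table dialects.

All tables are tab-separated with a header row; ``#`` lines are comments.
Dialects:

* network: ``tf_id``, ``target_id``
* transcription units: ``tu_id``, comma-joined ``gene_ids``
* SNP matrix: ``pos``, ``ref``, one column per run (``N`` = ambiguous call)
* coverage: ``run``, ``gene``, ``breadth``, ``depth``
* trajectories: ``population``, ``mutation_id``, ``gene``, ``effect``,
  ``generation``, ``frequency``
* study table: ``study``, ``type``, ``tf_mut``, ``tg_mut``, ``tf_sites``,
  ``tg_sites``
* BBH edges: ``genome_a``, ``prot_a``, ``genome_b``, ``prot_b``
* presence matrix: genes x genomes of {0, 1} (gene ids in the first column)
* diversity table: ``gene``, ``n_seq``, ``pi``, ``pi_s``, ``pi_n``, ``n_sites``

Reference CDS go through FASTA keyed by gene id (Biopython).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .conservation import BBHGraph
from .dynamics import AlleleTrajectorySet
from .pipeline import CoverageProfile, VariantMatrix
from .trn import TranscriptionUnit


def _read(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


# -- regulatory network -------------------------------------------------------

def read_network_edges(path) -> list[tuple[str, str]]:
    df = _read(path, dtype=str)
    return list(zip(df["tf_id"], df["target_id"]))


def write_network_edges(edges: Iterable[tuple[str, str]], path) -> None:
    pd.DataFrame(edges, columns=["tf_id", "target_id"]).to_csv(
        path, sep="\t", index=False)


def read_tu_table(path) -> list[TranscriptionUnit]:
    df = _read(path, dtype=str)
    return [TranscriptionUnit(row.tu_id, tuple(row.gene_ids.split(",")))
            for row in df.itertuples()]


def write_tu_table(tus: Iterable[TranscriptionUnit], path) -> None:
    pd.DataFrame(
        [(tu.id, ",".join(tu.gene_ids)) for tu in tus],
        columns=["tu_id", "gene_ids"],
    ).to_csv(path, sep="\t", index=False)


# -- SNP matrix ---------------------------------------------------------------

def read_snp_matrix(path) -> VariantMatrix:
    df = _read(path, dtype={"pos": int})
    df = df.set_index("pos")
    ref = df.pop("ref").astype(str)
    return VariantMatrix(calls=df.astype(str), ref=ref)


def write_snp_matrix(matrix: VariantMatrix, path) -> None:
    out = matrix.calls.copy()
    out.insert(0, "ref", matrix.ref)
    out.index.name = "pos"
    out.to_csv(path, sep="\t")


# -- coverage -----------------------------------------------------------------

def read_coverage(path) -> CoverageProfile:
    df = _read(path, dtype={"run": str, "gene": str,
                            "breadth": float, "depth": float})
    return CoverageProfile(df)


def write_coverage(profile: CoverageProfile, path) -> None:
    profile.table.to_csv(path, sep="\t", index=False)


# -- trajectories and study tables --------------------------------------------

def read_trajectories(path, class_map: Mapping[str, str] | None = None,
                      site_counts: Mapping[str, float] | None = None
                      ) -> AlleleTrajectorySet:
    df = _read(path, dtype={"population": str, "mutation_id": str,
                            "gene": str, "effect": str})
    return AlleleTrajectorySet(records=df, class_map=dict(class_map or {}),
                               site_counts=dict(site_counts or {}))


def write_trajectories(trajectories: AlleleTrajectorySet, path) -> None:
    trajectories.records.to_csv(path, sep="\t", index=False)


def read_study_table(path) -> pd.DataFrame:
    return _read(path, dtype={"study": str, "type": str})


def write_study_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# -- conservation inputs ------------------------------------------------------

def read_bbh_edges(path) -> BBHGraph:
    df = _read(path, dtype=str)
    return BBHGraph.from_edges(
        zip(df["genome_a"], df["prot_a"], df["genome_b"], df["prot_b"]))


def write_bbh_edges(edges: Iterable[tuple[str, str, str, str]], path) -> None:
    pd.DataFrame(edges, columns=["genome_a", "prot_a", "genome_b", "prot_b"]
                 ).to_csv(path, sep="\t", index=False)


def read_presence_matrix(path) -> dict[str, set[str]]:
    df = _read(path, index_col=0)
    return {
        str(gene): {str(c) for c in df.columns if df.at[gene, c] == 1}
        for gene in df.index
    }


def write_presence_matrix(presence: Mapping[str, set[str]],
                          genomes: Iterable[str], path) -> None:
    genomes = list(genomes)
    df = pd.DataFrame(
        {g: [int(g in presence[gene]) for gene in sorted(presence)]
         for g in genomes},
        index=sorted(presence),
    )
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


# -- diversity tables and FASTA -----------------------------------------------

def write_diversity_table(estimates: Mapping[str, "object"], path) -> None:
    rows = []
    for gene in sorted(estimates):
        e = estimates[gene]
        rows.append((gene, e.n_sequences, e.pi, e.pi_s, e.pi_n, e.n_sites))
    pd.DataFrame(rows, columns=["gene", "n_seq", "pi", "pi_s", "pi_n",
                                "n_sites"]).to_csv(path, sep="\t", index=False)


def read_diversity_table(path) -> pd.DataFrame:
    return _read(path, dtype={"gene": str})


def read_cds_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_cds_fasta(cds: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=gene, description="")
               for gene, seq in sorted(cds.items())]
    SeqIO.write(records, str(path), "fasta")


def read_codon_msa(path) -> dict[str, str]:
    """Codon MSA as FASTA; rows must share one length divisible by 3."""
    rows = read_cds_fasta(path)
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ValueError("MSA rows have unequal length")
    return rows
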