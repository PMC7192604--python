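"""Nucleotide diversity (pi, pi_S, pi_N) from codon alignments.

Diversity is the average pairwise nucleotide difference per site, with no
multiple-hit correction. Synonymous and non-synonymous components follow
Nei & Gojobori (1986) unweighted counting: each codon contributes fractional
synonymous/non-synonymous site counts (each single-base neighbour counts 1/3
of a site towards the class of its amino-acid effect, changes to stop codons
counting as non-synonymous), and codon pairs differing at k > 1 positions are
scored by averaging over the k! substitution orderings, skipping pathways that
pass through a stop codon. If every pathway is blocked, all differences count
as non-synonymous.

Two alignment sources are supported:

* pseudo-codon alignments reconstructed from read-level variant calls -- each
  row starts as the reference gene sequence and called variant codons are
  substituted in (:func:`build_pseudo_codon_alignment`);
* conventional codon multiple-sequence alignments of assembled sequences,
  with gapped codon columns removed (:func:`conventional_alignment_diversity`).

Pseudo-codon alignments are held sparsely (reference codons plus per-run
variant dictionaries); per-column codon counts make the all-pairs sums exact
without materialising rows.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
#: NCBI translation table 11 (bacterial); identical sense-codon assignments
#: to the standard code.
GENETIC_CODE_ID = 11
_TABLE = CodonTable.unambiguous_dna_by_id[GENETIC_CODE_ID]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))

MISSING_MARK = "?N-"  # characters marking a missing base inside a codon


def _aa(codon: str) -> str:
    return _TABLE.forward_table[codon]


def _validate_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    return codon


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """Nei-Gojobori (synonymous, non-synonymous) site counts of one codon.

    Each of the nine single-base neighbours contributes 1/3 of a site to the
    synonymous tally if it encodes the same amino acid, otherwise (including
    changes to stop codons) to the non-synonymous tally, so the two counts
    always sum to exactly 3.
    """
    codon = _validate_codon(codon)
    if codon in STOP_CODONS:
        raise ValueError(f"site counts undefined for stop codon {codon}")
    syn_thirds = 0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1:]
            if nb not in STOP_CODONS and _aa(nb) == _aa(codon):
                syn_thirds += 1
    return syn_thirds / 3, (9 - syn_thirds) / 3


@lru_cache(maxsize=None)
def codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, non-synonymous) differences between two codons.

    For codons differing at k positions, the k! substitution orderings are
    enumerated; orderings passing through a stop codon are skipped and the
    per-step synonymous/non-synonymous tallies are averaged over the valid
    ones. With no valid pathway, all k differences are non-synonymous.
    """
    c1 = _validate_codon(c1)
    c2 = _validate_codon(c2)
    if c1 in STOP_CODONS or c2 in STOP_CODONS:
        raise ValueError("pairwise differences undefined for stop codons")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0
    path_scores: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            path_scores.append((sd, nd))
    if not path_scores:
        return 0.0, float(k)
    sd = sum(s for s, _ in path_scores) / len(path_scores)
    nd = sum(n for _, n in path_scores) / len(path_scores)
    return sd, nd


def _hamming(c1: str, c2: str) -> int:
    return sum(a != b for a, b in zip(c1, c2))


@dataclass(frozen=True)
class DiversityEstimate:
    """Per-gene diversity summary.

    ``pi`` is per-site, ``pi_s``/``pi_n`` are per synonymous/non-synonymous
    site; site counts are Nei-Gojobori fractional counts averaged over rows.
    """

    pi: float
    pi_s: float
    pi_n: float
    n_sequences: int
    n_sites: int
    n_syn_sites: float
    n_nonsyn_sites: float


@dataclass
class PseudoCodonAlignment:
    """Codon alignment reconstructed from per-run variant calls.

    Rows are stored sparsely: every row equals ``ref_codons`` except at the
    codon indices listed in its entry of ``rows``. ``ref_codons`` excludes the
    terminal stop codon, which never enters diversity computation.
    ``removed_columns`` are codon indices dropped because some retained row
    had a variant codon with a missing base there.
    """

    gene_id: str
    ref_codons: tuple[str, ...]
    rows: dict[str, dict[int, str]]
    removed_columns: frozenset[int] = frozenset()
    dropped_rows: tuple[str, ...] = ()
    insufficient: bool = field(default=False)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def kept_columns(self) -> list[int]:
        return [i for i in range(len(self.ref_codons))
                if i not in self.removed_columns]

    def row_codons(self, run_id: str) -> list[str]:
        """Materialise one row (kept columns only)."""
        variants = self.rows[run_id]
        return [variants.get(i, self.ref_codons[i]) for i in self.kept_columns]

    def to_rows(self) -> dict[str, list[str]]:
        return {run: self.row_codons(run) for run in self.rows}

    @classmethod
    def from_rows(cls, gene_id: str,
                  rows: Mapping[str, Sequence[str]]) -> "PseudoCodonAlignment":
        """Build an alignment from explicit, equal-length codon rows."""
        items = list(rows.items())
        if not items:
            raise ValueError("no rows supplied")
        lengths = {len(r) for _, r in items}
        if len(lengths) != 1:
            raise ValueError("rows have unequal length")
        ref = tuple(str(c).upper() for c in items[0][1])
        sparse = {}
        for run, row in items:
            sparse[run] = {
                i: str(c).upper()
                for i, c in enumerate(row) if str(c).upper() != ref[i]
            }
        return cls(gene_id=gene_id, ref_codons=ref, rows=sparse)


def _is_missing(codon: str) -> bool:
    return any(b in MISSING_MARK for b in codon.upper())


def build_pseudo_codon_alignment(
    gene_id: str,
    ref_codons: Sequence[str],
    runs: Iterable[str],
    variant_sets: Mapping[str, Mapping[str, Mapping[int, str]]],
    detections: Mapping[str, set[str]],
) -> PseudoCodonAlignment:
    """Assemble the pseudo-codon alignment for one gene.

    ``ref_codons`` is the full reference CDS (terminal stop included);
    ``variant_sets`` maps run -> gene -> {codon index -> variant codon};
    ``detections`` maps run -> set of genes called present in that run.

    Rows are created only for runs where the gene is detected. Rows carrying
    an internal stop codon, or a complete non-stop variant at the terminal
    stop position, are removed. Variant codons with any missing base are
    treated as entirely missing, and every codon column missing in any
    retained row is removed from all rows. With fewer than two retained rows
    the alignment is flagged insufficient.
    """
    ref = tuple(_validate_codon(c) for c in ref_codons)
    if ref[-1] not in STOP_CODONS:
        raise ValueError(f"gene {gene_id}: reference does not end in a stop codon")
    stop_idx = len(ref) - 1

    retained: dict[str, dict[int, str]] = {}
    dropped: list[str] = []
    for run in runs:
        if gene_id not in detections.get(run, set()):
            continue
        variants = dict(variant_sets.get(run, {}).get(gene_id, {}))
        bad = False
        for idx, codon in variants.items():
            codon = codon.upper()
            if _is_missing(codon):
                continue  # handled as a missing column below
            if idx < stop_idx and codon in STOP_CODONS:
                bad = True  # premature stop: row removed
                break
            if idx == stop_idx and codon not in STOP_CODONS:
                bad = True  # lost terminal stop: row removed
                break
        if bad:
            dropped.append(run)
        else:
            retained[run] = variants

    missing_cols: set[int] = set()
    for variants in retained.values():
        for idx, codon in variants.items():
            if _is_missing(codon):
                missing_cols.add(idx)
    missing_cols.discard(stop_idx)

    rows = {
        run: {
            idx: codon.upper()
            for idx, codon in variants.items()
            if idx < stop_idx and idx not in missing_cols
            and not _is_missing(codon)
        }
        for run, variants in retained.items()
    }
    return PseudoCodonAlignment(
        gene_id=gene_id,
        ref_codons=ref[:stop_idx],
        rows=rows,
        removed_columns=frozenset(missing_cols),
        dropped_rows=tuple(sorted(dropped)),
        insufficient=len(rows) < 2,
    )


def _column_counts(alignment: PseudoCodonAlignment):
    """Yield (ref codon, Counter of non-reference codons) per kept column.

    Columns where every row carries the reference codon yield an empty
    Counter, and only columns touched by some variant are visited explicitly;
    callers reconstruct the reference multiplicity as n - sum(counts).
    """
    variant_cols: dict[int, Counter] = {}
    for variants in alignment.rows.values():
        for idx, codon in variants.items():
            variant_cols.setdefault(idx, Counter())[codon] += 1
    for idx, counts in variant_cols.items():
        if idx in alignment.removed_columns:
            continue
        yield idx, counts


def _pair_sums(counts: list[tuple[str, int]], score) -> float:
    total = 0.0
    for i in range(len(counts)):
        ci, ni = counts[i]
        for j in range(i + 1, len(counts)):
            cj, nj = counts[j]
            total += ni * nj * score(ci, cj)
    return total


def diversity_estimate(alignment: PseudoCodonAlignment) -> DiversityEstimate:
    """pi, pi_S and pi_N of an alignment (uncorrected, all unordered pairs).

    pi = (sum over pairs of mismatched sites) / #pairs / #sites. pi_S (pi_N)
    divides the mean pairwise synonymous (non-synonymous) difference count by
    the pair-averaged synonymous (non-synonymous) site count, which equals
    the row-mean site count.
    """
    if alignment.insufficient or alignment.n_rows < 2:
        raise ValueError(
            f"gene {alignment.gene_id}: fewer than 2 rows, diversity undefined")
    kept = alignment.kept_columns
    if not kept:
        raise ValueError(
            f"gene {alignment.gene_id}: no sites left after column removal")
    n = alignment.n_rows
    n_pairs = n * (n - 1) / 2

    # Site counts start from all-reference rows, then adjust variant columns.
    ref_syn = {i: codon_site_counts(alignment.ref_codons[i])[0] for i in kept}
    syn_sites_total = n * sum(ref_syn.values())

    diff_sites = 0.0
    syn_diffs = 0.0
    nonsyn_diffs = 0.0
    for idx, counts in _column_counts(alignment):
        ref_codon = alignment.ref_codons[idx]
        n_ref = n - sum(counts.values())
        col = [(c, k) for c, k in counts.items() if k > 0]
        if n_ref > 0:
            col.append((ref_codon, n_ref))
        diff_sites += _pair_sums(col, _hamming)
        sd_nd = {
            pair: codon_pair_differences(*pair)
            for pair in itertools.combinations([c for c, _ in col], 2)
        }
        syn_diffs += _pair_sums(col, lambda a, b: sd_nd[(a, b)][0])
        nonsyn_diffs += _pair_sums(col, lambda a, b: sd_nd[(a, b)][1])
        for codon, k in counts.items():
            syn_sites_total += k * (codon_site_counts(codon)[0] - ref_syn[idx])

    n_sites = 3 * len(kept)
    mean_syn_sites = syn_sites_total / n
    mean_nonsyn_sites = n_sites - mean_syn_sites
    pi = diff_sites / n_pairs / n_sites
    pi_s = (syn_diffs / n_pairs) / mean_syn_sites if mean_syn_sites > 0 else math.nan
    pi_n = (nonsyn_diffs / n_pairs) / mean_nonsyn_sites if mean_nonsyn_sites > 0 else math.nan
    return DiversityEstimate(
        pi=pi, pi_s=pi_s, pi_n=pi_n, n_sequences=n, n_sites=n_sites,
        n_syn_sites=mean_syn_sites, n_nonsyn_sites=mean_nonsyn_sites,
    )


def nucleotide_diversity(alignment: PseudoCodonAlignment) -> float:
    """Average pairwise nucleotide difference per site (uncorrected pi)."""
    return diversity_estimate(alignment).pi


def syn_nonsyn_diversity(alignment: PseudoCodonAlignment) -> tuple[float, float]:
    """(pi_S, pi_N) of an alignment via Nei-Gojobori pathway averaging."""
    est = diversity_estimate(alignment)
    return est.pi_s, est.pi_n


def conventional_alignment_diversity(
    codon_msa: Mapping[str, str] | Mapping[str, Sequence[str]],
) -> DiversityEstimate:
    """Diversity of a conventional codon MSA (assembled sequences).

    Accepts either nucleotide strings (length divisible by 3) or codon lists,
    one row per sequence. Every codon column containing a gap in any row is
    dropped; columns containing a stop codon in any row are dropped as well,
    so the Nei-Gojobori accounting stays defined. The remaining columns feed
    the same estimator as the read-based path.
    """
    if len(codon_msa) < 2:
        raise ValueError("need at least 2 sequences")
    rows: dict[str, list[str]] = {}
    length = None
    for sid, seq in codon_msa.items():
        if isinstance(seq, str):
            if len(seq) % 3 != 0:
                raise ValueError(f"sequence {sid}: length not a multiple of 3")
            codons = [seq[i:i + 3].upper() for i in range(0, len(seq), 3)]
        else:
            codons = [str(c).upper() for c in seq]
        if length is None:
            length = len(codons)
        elif len(codons) != length:
            raise ValueError("alignment rows have unequal length")
        rows[sid] = codons
    assert length is not None

    def usable(col: int) -> bool:
        for codons in rows.values():
            c = codons[col]
            if any(b not in BASES for b in c) or c in STOP_CODONS:
                return False
        return True

    kept = [i for i in range(length) if usable(i)]
    if not kept:
        raise ValueError("no ungapped codon columns left")
    clean = {sid: [codons[i] for i in kept] for sid, codons in rows.items()}
    aln = PseudoCodonAlignment.from_rows("msa", clean)
    return diversity_estimate(aln)


MAD_CONSISTENCY = 1.4826


def scale_by_tg(
    values: Mapping[str, float],
    tg_ids: Iterable[str],
    mad_constant: float = MAD_CONSISTENCY,
) -> dict[str, float]:
    """Standardise diversity by the median and MAD of the target genes.

    scaled(x) = (x - median_TG) / (mad_constant * raw MAD_TG). With the
    default consistency constant 1.4826 the scale matches a normal standard
    deviation; pass ``mad_constant=1`` for the raw MAD. Scaling by TGs places
    the TG median at zero in every dataset, so a systematic shift of TFs shows
    up as a nonzero TF median on a common scale.
    """
    tg_vals = np.array([values[g] for g in tg_ids if g in values
                        and not math.isnan(values[g])], dtype=float)
    if tg_vals.size < 2:
        raise ValueError("need at least 2 TG values to scale")
    med = float(np.median(tg_vals))
    mad = float(np.median(np.abs(tg_vals - med))) * mad_constant
    if mad == 0:
        raise ValueError("degenerate TG distribution: MAD is zero")
    return {g: (v - med) / mad for g, v in values.items()}
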