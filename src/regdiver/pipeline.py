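"""Variant-matrix cleaning, gene presence calls, and run selection.

Post-processing downstream of a variant caller: a SNP matrix (reference
positions x sequencing runs, single-base calls with ``N`` marking ambiguity)
is cleaned, gene presence is called per run from breadth/depth of coverage,
runs with too few genes are discarded, and near-clonal runs are removed by
greedy declustering on codon-distance vectors over marker genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .trn import Gene

AMBIGUOUS = "N"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class VariantMatrix:
    """Base calls at variant reference positions.

    ``calls`` is positions x runs (index: 0-based reference position, values:
    single bases, ``N`` for ambiguous); ``ref`` gives the reference base per
    position.
    """

    calls: pd.DataFrame
    ref: pd.Series

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.ref.index):
            raise ValueError("calls and ref must share the same position index")

    @property
    def run_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def positions(self) -> list[tuple[int, str]]:
        return list(zip(self.calls.index.tolist(), self.ref.tolist()))

    def is_empty(self) -> bool:
        return self.calls.shape[0] == 0


@dataclass
class CoverageProfile:
    """Per-(run, gene) sequencing coverage.

    ``breadth`` is the fraction of gene length covered by at least one read;
    ``depth`` the mean number of reads per base.
    """

    table: pd.DataFrame  # columns: run, gene, breadth, depth

    def __post_init__(self) -> None:
        required = {"run", "gene", "breadth", "depth"}
        if not required <= set(self.table.columns):
            raise ValueError(f"coverage table needs columns {sorted(required)}")
        b = self.table["breadth"]
        d = self.table["depth"]
        if ((b < 0) | (b > 1)).any():
            raise ValueError("breadth outside [0, 1]")
        if (d < 0).any():
            raise ValueError("negative depth")

    @property
    def run_ids(self) -> list[str]:
        return sorted(self.table["run"].unique())

    def for_run(self, run: str) -> dict[str, tuple[float, float]]:
        sub = self.table[self.table["run"] == run]
        return {
            g: (float(b), float(d))
            for g, b, d in zip(sub["gene"], sub["breadth"], sub["depth"])
        }


@dataclass(frozen=True)
class DepthSummary:
    """Trimmed-Gaussian depth statistics behind one run's presence calls."""

    x_bar: float   # mean depth over breadth-passing, nonzero-depth genes
    y_bar: float   # mean after trimming depths >= 2 * x_bar
    s: float       # sample standard deviation (n - 1) after trimming
    threshold: float  # y_bar - 3 s


@dataclass
class CodonVariantSet:
    """Codon-level variants of one sequencing run.

    ``variants`` maps gene id -> {0-based codon index -> variant codon};
    codons may contain a missing-base marker (``?``/``N``).
    """

    run_id: str
    variants: dict[str, dict[int, str]] = field(default_factory=dict)

    def gene_variants(self, gene_id: str) -> dict[int, str]:
        return self.variants.get(gene_id, {})

    def n_variants(self) -> int:
        return sum(len(v) for v in self.variants.values())


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    ivs = sorted(intervals)
    starts: list[int] = []
    ends: list[int] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"degenerate interval ({s}, {e})")
        if starts and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.array(starts), np.array(ends)


def clean_snp_matrix(
    matrix: VariantMatrix,
    cds_intervals: Iterable[tuple[int, int]],
    max_ambiguous_frac: float = 0.10,
) -> VariantMatrix:
    """Clean a SNP matrix (idempotent).

    Positions outside every CDS interval (0-based half-open) are removed;
    positions ambiguous in more than ``max_ambiguous_frac`` of runs are
    removed; remaining ambiguous calls are imputed with the modal unambiguous
    base at the position (ties resolve to the reference base); positions left
    invariant after imputation are removed. An empty result is returned with
    a warning, never an error.
    """
    if matrix.is_empty():
        warnings.warn("SNP matrix is empty", stacklevel=2)
        return matrix
    calls = matrix.calls
    ref = matrix.ref

    starts, ends = _merge_intervals(cds_intervals)
    pos = calls.index.to_numpy()
    idx = np.searchsorted(starts, pos, side="right") - 1
    in_cds = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
    calls, ref = calls.loc[in_cds], ref.loc[in_cds]

    amb = calls.eq(AMBIGUOUS)
    frac = amb.mean(axis=1)
    keep = frac <= max_ambiguous_frac
    calls, ref, amb = calls.loc[keep], ref.loc[keep], amb.loc[keep]

    imputed = calls.copy()
    for p in calls.index[amb.any(axis=1)]:
        row = calls.loc[p]
        counts = row[row != AMBIGUOUS].value_counts()
        top = counts[counts == counts.max()].index.tolist()
        modal = top[0] if len(top) == 1 else ref.loc[p]
        imputed.loc[p] = row.where(row != AMBIGUOUS, modal)

    variant = imputed.nunique(axis=1) > 1
    imputed, ref = imputed.loc[variant], ref.loc[variant]
    if imputed.shape[0] == 0:
        warnings.warn("all positions removed during cleaning", stacklevel=2)
    return VariantMatrix(calls=imputed, ref=ref)


def detect_genes(
    profile: Mapping[str, tuple[float, float]],
    min_breadth: float = 0.6,
) -> tuple[set[str], DepthSummary]:
    """Call gene presence in one run from coverage breadth and depth.

    Pipeline: (1) keep genes with breadth >= ``min_breadth``; (2) drop
    zero-depth genes; (3) compute the mean depth x_bar and trim depths
    >= 2 x_bar to obtain a Gaussian-like distribution; (4) compute its mean
    y_bar and sample standard deviation s; (5) present = genes from step 2
    with depth >= y_bar - 3 s, plus the well-covered genes trimmed in step 3.
    If fewer than two genes survive trimming, s is undefined and all step-2
    genes are called present with a warning.
    """
    if not profile:
        raise ValueError("coverage profile covers no gene")
    step1 = {g: d for g, (b, d) in profile.items() if b >= min_breadth}
    step2 = {g: d for g, d in step1.items() if d > 0}
    if not step2:
        return set(), DepthSummary(math.nan, math.nan, math.nan, math.nan)
    depths = np.array(list(step2.values()), dtype=float)
    x_bar = float(depths.mean())
    high = {g for g, d in step2.items() if d >= 2 * x_bar}
    trimmed = np.array([d for g, d in step2.items() if g not in high])
    if trimmed.size < 2:
        warnings.warn(
            "fewer than 2 genes after depth trimming; standard deviation "
            "undefined, all breadth/depth-passing genes called present",
            stacklevel=2,
        )
        return set(step2), DepthSummary(x_bar, math.nan, math.nan, math.nan)
    y_bar = float(trimmed.mean())
    s = float(trimmed.std(ddof=1))
    threshold = y_bar - 3 * s
    present = {g for g, d in step2.items() if d >= threshold} | high
    return present, DepthSummary(x_bar, y_bar, s, threshold)


def filter_runs(
    detections: Mapping[str, set[str]], min_genes: int = 3000
) -> list[str]:
    """Drop runs in which fewer than ``min_genes`` genes were detected."""
    return sorted(r for r, genes in detections.items() if len(genes) >= min_genes)


def select_marker_genes(
    diversity: Mapping[str, float],
    core: Mapping[str, bool],
    gapped: Mapping[str, bool],
) -> set[str]:
    """Select declustering marker genes by a diversity band.

    Restricted to core, non-gapped genes; keeps those with diversity strictly
    above the 75th percentile (Q3) and at most Q3 + IQR. Percentiles use
    linear interpolation between order statistics.
    """
    if not diversity:
        raise ValueError("diversity table is empty")
    pool = {
        g: v for g, v in diversity.items()
        if core.get(g, False) and not gapped.get(g, True)
    }
    if not pool:
        raise ValueError("no core, non-gapped genes available")
    vals = np.array(list(pool.values()), dtype=float)
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    return {g for g, v in pool.items() if q3 < v <= q3 + iqr}


def codon_distance_vector(
    variants: CodonVariantSet,
    markers: Sequence[str],
    codon_counts: Mapping[str, int],
    detected: set[str] | None = None,
) -> np.ndarray:
    """Fractions of variant codons in marker genes (the run's coordinates).

    Component g = (# distinct variant codon positions in g) / codon count of
    g. Marker genes must be detected in the run when ``detected`` is given.
    """
    out = np.zeros(len(markers), dtype=float)
    for i, g in enumerate(markers):
        if detected is not None and g not in detected:
            raise ValueError(
                f"marker gene {g!r} not detected in run {variants.run_id!r}")
        n_var = len(set(variants.gene_variants(g)))
        out[i] = n_var / codon_counts[g]
    return out


def decluster(
    vectors: Mapping[str, np.ndarray], min_dist: float = 0.1
) -> list[str]:
    """Greedy declustering of runs in codon-distance space.

    Runs are visited in lexicographic id order; a run is admitted iff its
    Euclidean distance to every already-admitted run is strictly greater than
    ``min_dist``. All pairwise distances among the output therefore exceed
    ``min_dist``.
    """
    if not vectors:
        raise ValueError("no runs to decluster")
    admitted: list[str] = []
    kept: list[np.ndarray] = []
    for run in sorted(vectors):
        v = np.asarray(vectors[run], dtype=float)
        if all(np.linalg.norm(v - u) > min_dist for u in kept):
            admitted.append(run)
            kept.append(v)
    return admitted


def codon_variants_from_matrix(
    matrix: VariantMatrix, genes: Mapping[str, Gene]
) -> dict[str, CodonVariantSet]:
    """Collapse a cleaned SNP matrix to per-run, per-gene codon variants.

    Positions are mapped into codons via each gene's coordinates (0-based
    half-open; minus-strand genes are complemented and index-reversed).
    Ambiguous calls surviving in the matrix become missing-base markers
    (``?``) inside the affected codon.
    """
    by_codon: dict[str, dict[int, list[tuple[int, int]]]] = {}
    pos_arr = matrix.calls.index.to_numpy()
    for gid, gene in genes.items():
        mask = (pos_arr >= gene.start) & (pos_arr < gene.end)
        for p in pos_arr[mask]:
            if gene.strand == "+":
                cds_i = int(p - gene.start)
            else:
                cds_i = int(gene.end - 1 - p)
            by_codon.setdefault(gid, {}).setdefault(cds_i // 3, []).append(
                (int(p), cds_i % 3))

    out = {run: CodonVariantSet(run_id=run) for run in matrix.run_ids}
    for gid, codons in by_codon.items():
        gene = genes[gid]
        for codon_idx, sites in codons.items():
            ref_codon = gene.cds[3 * codon_idx: 3 * codon_idx + 3]
            for run in matrix.run_ids:
                chars = list(ref_codon)
                changed = False
                for p, offset in sites:
                    call = str(matrix.calls.at[p, run]).upper()
                    if call == AMBIGUOUS:
                        chars[offset] = "?"
                        changed = True
                        continue
                    base = call if gene.strand == "+" else call.translate(_COMPLEMENT)
                    if base != chars[offset]:
                        chars[offset] = base
                        changed = True
                if changed:
                    out[run].variants.setdefault(gid, {})[codon_idx] = "".join(chars)
    return out
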