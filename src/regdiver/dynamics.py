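"""Derived-allele-frequency dynamics and lab-evolution mutation enrichment.

Whole-population sequencing of a long-term evolution experiment yields, per
population p and mutation m, a frequency trajectory f_{p,m}(t) sampled on a
fixed generation grid. The total derived allele frequency of a gene,
M_p(t) = sum_m f_{p,m}(t), measures mutation accumulation; class means over
TF/TG gene sets (zero for unmutated genes) compare the two classes over time.
De-novo appearance rates are counted per generation interval and normalized by
the class's non-synonymous site count, and the distribution of the maximum
frequency a variant attains inside each interval separates origination-rate
effects from frequency effects.

Mutation tables from adaptive-laboratory-evolution (ALE) and
mutation-accumulation (MA) projects are tested for TF enrichment with
one-sided Fisher's exact tests (Holm-corrected) and compared between study
types by the odds-ratio rank-sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats

NONSYN = "nonsynonymous"
TRAJECTORY_COLUMNS = ("population", "mutation_id", "gene", "effect",
                      "generation", "frequency")


@dataclass
class AlleleTrajectorySet:
    """Mutation x timepoint frequencies with gene class annotations.

    ``records`` columns: population, mutation_id, gene, effect
    (nonsynonymous / synonymous / other), generation, frequency.
    ``class_map`` labels genes (e.g. TF_GR / TF_LR / TG); ``site_counts``
    holds per-class non-synonymous site counts for rate normalization.
    """

    records: pd.DataFrame
    class_map: dict[str, str] = field(default_factory=dict)
    site_counts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(TRAJECTORY_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"trajectory table lacks columns {sorted(missing)}")
        f = self.records["frequency"]
        if len(f) and (((f < 0) | (f > 1)).any()):
            raise ValueError("frequencies outside [0, 1]")

    @property
    def populations(self) -> list[str]:
        return sorted(self.records["population"].unique())

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(self.records["generation"].unique())

    def genes_in_class(self, class_name: str) -> list[str]:
        return sorted(g for g, c in self.class_map.items() if c == class_name)

    def subset_without_gene(self, gene: str) -> "AlleleTrajectorySet":
        return AlleleTrajectorySet(
            records=self.records[self.records["gene"] != gene].reset_index(drop=True),
            class_map={g: c for g, c in self.class_map.items() if g != gene},
            site_counts=dict(self.site_counts),
        )


def gene_daf(
    trajectories: AlleleTrajectorySet,
    population: str,
    gene: str,
    t: int,
    effect: str | None = None,
) -> float:
    """M_p(t): summed frequency over the gene's mutations at time t.

    Zero when the gene carries no (matching) mutation; unknown populations or
    genes are an error. ``effect`` optionally restricts the mutation class.
    """
    df = trajectories.records
    if population not in set(df["population"]):
        raise KeyError(f"unknown population {population!r}")
    if trajectories.class_map and gene not in trajectories.class_map:
        raise KeyError(f"unknown gene {gene!r}")
    sel = (df["population"] == population) & (df["gene"] == gene) \
        & (df["generation"] == t)
    if effect is not None:
        sel &= df["effect"] == effect
    return float(df.loc[sel, "frequency"].sum())


def class_mean_daf(
    trajectories: AlleleTrajectorySet,
    class_name: str,
    population: str,
    t: int,
) -> float:
    """Mean non-synonymous DAF over every gene of a class (zeros included)."""
    genes = trajectories.genes_in_class(class_name)
    if not genes:
        raise ValueError(f"class {class_name!r} is empty")
    df = trajectories.records
    sel = (df["population"] == population) & (df["generation"] == t) \
        & (df["effect"] == NONSYN) & df["gene"].isin(genes)
    return float(df.loc[sel, "frequency"].sum()) / len(genes)


def class_mean_daf_series(
    trajectories: AlleleTrajectorySet,
    class_name: str,
    population: str | None = None,
    grid: np.ndarray | None = None,
) -> pd.Series:
    """Class-mean DAF at every sampled timepoint.

    With ``population=None`` the per-population series are averaged (thick
    curves over populations); otherwise one population's series is returned.
    ``grid`` defaults to the generations observed in the records; timepoints
    with no record in a population contribute zero.
    """
    genes = trajectories.genes_in_class(class_name)
    if not genes:
        raise ValueError(f"class {class_name!r} is empty")
    df = trajectories.records
    df = df[(df["effect"] == NONSYN) & df["gene"].isin(genes)]
    pops = [population] if population is not None else trajectories.populations
    if grid is None:
        grid = trajectories.timepoints
    per_pop = []
    for pop in pops:
        sums = df[df["population"] == pop].groupby("generation")["frequency"].sum()
        per_pop.append(sums.reindex(grid, fill_value=0.0) / len(genes))
    return pd.concat(per_pop, axis=1).mean(axis=1)


def _first_appearance(df: pd.DataFrame) -> pd.DataFrame:
    """First generation with nonzero frequency per (population, mutation)."""
    nz = df[df["frequency"] > 0]
    return (nz.groupby(["population", "mutation_id"], as_index=False)
            ["generation"].min())


def de_novo_rate(
    trajectories: AlleleTrajectorySet,
    class_name: str,
    interval: int = 10_000,
    per_population: bool = False,
):
    """Per-interval de-novo mutation counts per non-synonymous site.

    A mutation is de novo in the interval [k*interval, (k+1)*interval)
    containing its first observed nonzero frequency. Counts (pooled over
    populations unless ``per_population``) are divided by the class's
    non-synonymous site count. Returns (interval start array, rates).
    """
    if class_name not in trajectories.site_counts:
        raise ValueError(f"no site count for class {class_name!r}")
    sites = trajectories.site_counts[class_name]
    genes = set(trajectories.genes_in_class(class_name))
    df = trajectories.records
    df = df[(df["effect"] == NONSYN) & df["gene"].isin(genes)]
    horizon = int(trajectories.timepoints.max()) if len(trajectories.records) else 0
    n_bins = max(-(-max(horizon, 1) // interval), 1)
    if horizon % interval != 0:
        warnings.warn("horizon is not a multiple of the interval; the last "
                      "interval is truncated", stacklevel=2)
    starts = np.arange(n_bins) * interval
    first = _first_appearance(df)
    bins = np.clip(first["generation"] // interval, 0, n_bins - 1).astype(int)
    if per_population:
        out = {}
        for pop in trajectories.populations:
            counts = np.bincount(bins[first["population"] == pop],
                                 minlength=n_bins)
            out[pop] = counts / sites
        return starts, out
    counts = np.bincount(bins, minlength=n_bins)
    return starts, counts / sites


def max_freq_per_interval(
    trajectories: AlleleTrajectorySet,
    class_name: str,
    interval: int = 10_000,
) -> dict[int, np.ndarray]:
    """Maximum frequency attained by each variant inside each interval.

    Variants are pooled from all populations; a variant enters an interval's
    distribution only if it has nonzero frequency at some timepoint inside it.
    Keys are interval start generations.
    """
    genes = set(trajectories.genes_in_class(class_name))
    df = trajectories.records
    df = df[(df["effect"] == NONSYN) & df["gene"].isin(genes)].copy()
    out: dict[int, np.ndarray] = {}
    if df.empty:
        return out
    df["bin"] = (df["generation"] // interval).astype(int)
    df = df[df["frequency"] > 0]
    grouped = df.groupby(["bin", "population", "mutation_id"])["frequency"].max()
    for b, sub in grouped.groupby(level="bin"):
        out[int(b) * interval] = np.sort(sub.to_numpy())
    return out


def drop_outlier_gene(
    trajectories: AlleleTrajectorySet,
    class_name: str,
    fixation_threshold: float = 1.0,
) -> tuple[AlleleTrajectorySet, str]:
    """Remove the class's extreme outlier gene.

    Per mutated gene the score is (#mutations, fraction of its mutations that
    reach ``fixation_threshold`` at some timepoint); the gene maximal in
    lexicographic order (mutation count first, fixation fraction as
    tie-break) is dropped. Requires at least two mutated genes in the class.
    """
    genes = set(trajectories.genes_in_class(class_name))
    df = trajectories.records
    df = df[(df["effect"] == NONSYN) & df["gene"].isin(genes)]
    nz = df[df["frequency"] > 0]
    if nz.empty:
        raise ValueError(f"class {class_name!r} has no mutated gene")
    per_mut = nz.groupby(["gene", "population", "mutation_id"])["frequency"].max()
    scores: dict[str, tuple[int, float]] = {}
    for gene, sub in per_mut.groupby(level="gene"):
        n_mut = len(sub)
        fixed = float(np.mean(sub.to_numpy() >= fixation_threshold))
        scores[str(gene)] = (n_mut, fixed)
    if len(scores) < 2:
        raise ValueError(
            f"class {class_name!r} has fewer than 2 mutated genes")
    outlier = max(sorted(scores), key=lambda g: scores[g])
    return trajectories.subset_without_gene(outlier), outlier


@dataclass(frozen=True)
class StudyEnrichment:
    study: str
    study_type: str
    odds_ratio: float
    p_value: float
    p_adjusted: float


def ale_enrichment(
    studies: pd.DataFrame | Sequence[Mapping],
    ale_types: tuple[str, ...] = ("ALE", "AR", "LTEE"),
    ma_types: tuple[str, ...] = ("MA",),
) -> tuple[list[StudyEnrichment], stats.TestResult]:
    """TF mutation enrichment per lab-evolution study, plus ALE-vs-MA rank-sum.

    Each study provides non-synonymous mutation counts and site counts for
    TFs and TGs (columns: study, type, tf_mut, tg_mut, tf_sites, tg_sites).
    The per-study one-sided Fisher's exact test asks whether the per-site TF
    mutation rate exceeds the TG rate; p-values are Holm-adjusted across
    studies. The returned rank-sum test asks whether odds ratios of
    selection-driven studies (``ale_types``) exceed those of mutation-
    accumulation studies.
    """
    df = pd.DataFrame(studies)
    required = {"study", "type", "tf_mut", "tg_mut", "tf_sites", "tg_sites"}
    if not required <= set(df.columns):
        raise ValueError(f"study table needs columns {sorted(required)}")
    if (df[["tf_sites", "tg_sites"]] <= 0).any().any():
        raise ValueError("zero or negative site counts")
    if (df[["tf_mut", "tg_mut"]] < 0).any().any():
        raise ValueError("negative mutation counts")

    raw = []
    odds = []
    for _, row in df.iterrows():
        table = [
            [int(row.tf_mut), int(row.tf_sites) - int(row.tf_mut)],
            [int(row.tg_mut), int(row.tg_sites) - int(row.tg_mut)],
        ]
        res = stats.fisher_exact_one_sided(table, alternative="greater")
        raw.append(res.p_value)
        odds.append(res.statistic)
    adjusted = stats.holm_bonferroni(raw)
    results = [
        StudyEnrichment(study=str(r.study), study_type=str(r.type),
                        odds_ratio=float(o), p_value=float(p),
                        p_adjusted=float(q))
        for (_, r), o, p, q in zip(df.iterrows(), odds, raw, adjusted)
    ]
    ale_or = [r.odds_ratio for r in results if r.study_type in ale_types
              and np.isfinite(r.odds_ratio)]
    ma_or = [r.odds_ratio for r in results if r.study_type in ma_types
             and np.isfinite(r.odds_ratio)]
    if ale_or and ma_or:
        ranksum = stats.wilcoxon_rank_sum(ale_or, ma_or, alternative="greater")
    else:
        ranksum = stats.TestResult(float("nan"), 1.0, "greater", 0,
                                   "rank-sum-skipped")
    return results, ranksum


def mutated_protein_test(
    n_mut_tf: int,
    n_mut_total: int,
    n_tf_genome: int = 304,
    n_prot_genome: int = 4140,
) -> tuple[float, stats.TestResult]:
    """Enrichment of TFs among beneficially mutated proteins.

    Compares the observed count of mutated TFs among ``n_mut_total`` mutated
    proteins against the genome background fraction of TFs (by default
    304 known-and-predicted TFs out of 4140 proteins, ~7.3%), one-sided
    Fisher's exact test for excess.
    """
    if not (0 <= n_mut_tf <= n_mut_total):
        raise ValueError("need 0 <= n_mut_tf <= n_mut_total")
    if n_mut_total > n_prot_genome or n_tf_genome > n_prot_genome:
        raise ValueError("counts exceed the genome totals")
    table = [
        [n_mut_tf, n_tf_genome - n_mut_tf],
        [n_mut_total - n_mut_tf,
         (n_prot_genome - n_tf_genome) - (n_mut_total - n_mut_tf)],
    ]
    expected = n_tf_genome / n_prot_genome
    return expected, stats.fisher_exact_one_sided(table, alternative="greater")
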