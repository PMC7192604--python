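"""Regulon-level diversity aggregation and TF-vs-regulon inference.

The regulon diversity of a TF is the grand mean over its transcription units
(mean of per-TU means, each TU mean taken over member genes with a defined
value). The grand mean, rather than a gene-count-weighted mean, removes the
effect of operon/pathway length on the regulon estimate. Paired TF-vs-regulon
comparisons use the one-sided Wilcoxon signed-rank test, and the sampling
asymmetry between a single TF value and a many-gene regulon mean is controlled
by a regulon-size-preserving network randomization test: TFs are replaced by
randomly selected TGs, pseudo-regulons of the same TU count and TU sizes are
drawn from the TG pool, and the observed mean paired difference is referred to
the null distribution of that statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats as sps

from . import stats
from .trn import RegulatoryNetwork

logger = logging.getLogger(__name__)


def _defined(v) -> bool:
    return v is not None and not (isinstance(v, float) and math.isnan(v))


def regulon_diversity(
    network: RegulatoryNetwork, gene_values: Mapping[str, float]
) -> dict[str, float]:
    """Grand mean diversity of each TF's regulon.

    Per TU, the mean over member genes with defined values; per TF, the
    unweighted mean over its TUs' means. TUs without any valued gene are
    excluded; TFs whose every TU is empty of valued genes are dropped (and
    logged). The network's TU list is expected to have fully-overlapping TUs
    resolved already.
    """
    out: dict[str, float] = {}
    for tf in sorted(network.tf_ids):
        tu_means = []
        for tu_id in network.edges[tf]:
            tu = network.tus.get(tu_id)
            if tu is None:
                continue
            vals = [gene_values[g] for g in tu.gene_ids
                    if g in gene_values and _defined(gene_values[g])]
            if vals:
                tu_means.append(float(np.mean(vals)))
        if tu_means:
            out[tf] = float(np.mean(tu_means))
        else:
            logger.info("TF %s: no valued gene in any TU; regulon undefined", tf)
    return out


@dataclass
class PairedComparison:
    """Per-TF paired record plus the one-sided signed-rank test."""

    tf_ids: list[str]
    tf_values: np.ndarray
    regulon_values: np.ndarray
    differences: np.ndarray  # tf_value - regulon_value
    test: stats.TestResult
    direction: str


def paired_tf_comparison(
    tf_values: Mapping[str, float],
    regulon_values: Mapping[str, float],
    alternative: str = "tf_less",
) -> PairedComparison:
    """Wilcoxon signed-rank test of TF diversity against the TF's own regulon.

    ``alternative`` is "tf_less" (the paper-style hypothesis that TFs are less
    diverse than their own targets), "tf_greater" or "two_sided". Fewer than 6
    pairs is allowed but logged as underpowered.
    """
    mapping = {"tf_less": "less", "tf_greater": "greater",
               "two_sided": "two-sided", "two-sided": "two-sided"}
    if alternative not in mapping:
        raise ValueError(f"unknown alternative {alternative!r}")
    tfs = sorted(
        tf for tf in tf_values
        if tf in regulon_values and _defined(tf_values[tf])
        and _defined(regulon_values[tf])
    )
    if not tfs:
        raise ValueError("no TF with both a TF value and a regulon value")
    if len(tfs) < 6:
        logger.warning("only %d pairs: paired test is underpowered", len(tfs))
    x = np.array([tf_values[tf] for tf in tfs], dtype=float)
    y = np.array([regulon_values[tf] for tf in tfs], dtype=float)
    test = stats.wilcoxon_signed_rank(x, y, alternative=mapping[alternative])
    return PairedComparison(
        tf_ids=tfs, tf_values=x, regulon_values=y, differences=x - y,
        test=test, direction=alternative,
    )


@dataclass
class RandomizationResult:
    observed_statistic: float
    null_statistics: np.ndarray
    p_value: float
    seed: int | None
    n_trials: int

    def __post_init__(self) -> None:
        if len(self.null_statistics) != self.n_trials:
            raise ValueError("null_statistics length must equal n_trials")


def _signed_rank_statistic(diffs: np.ndarray) -> float:
    """W+ (sum of positive ranks) with zeros dropped and midranks for ties."""
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return 0.0
    ranks = sps.rankdata(np.abs(nz))
    return float(ranks[nz > 0].sum())


def randomization_test(
    network: RegulatoryNetwork,
    gene_values: Mapping[str, float],
    n_trials: int = 1000,
    seed: int | None = None,
    statistic: str = "mean_diff",
    preserve_tu_sizes: bool = True,
    replace_tfs: bool = False,
) -> RandomizationResult:
    """Regulon-size-preserving network randomization test.

    The observed statistic is the mean over TFs of (TF value - regulon grand
    mean). Each trial replaces every TF with a pseudo-TF drawn uniformly from
    the TGs (without replacement within the trial unless ``replace_tfs``) and
    draws a pseudo-regulon of random TGs, excluding the pseudo-TF, matching
    the original TU count and TU sizes (or only the total gene count when
    ``preserve_tu_sizes`` is False); the trial statistic is computed
    identically. The reported tail probability is max(k, 1) / n_trials where
    k counts trials at least as extreme (<= observed), so 1/n_trials is the
    estimator's floor.

    ``statistic`` is "mean_diff" (default) or "signed_rank" (W+ of the paired
    differences, smaller when TFs sit below their regulons).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if statistic not in {"mean_diff", "signed_rank"}:
        raise ValueError(f"unknown statistic {statistic!r}")

    reg_vals = regulon_diversity(network, gene_values)
    tfs = sorted(tf for tf in reg_vals
                 if tf in gene_values and _defined(gene_values[tf]))
    if not tfs:
        raise ValueError("no TF usable for the randomization test")
    tg_pool = sorted(g for g in network.tg_ids
                     if g in gene_values and _defined(gene_values[g]))
    if len(tg_pool) < len(tfs):
        raise ValueError("fewer valued TGs than TFs")
    pool_vals = np.array([gene_values[g] for g in tg_pool], dtype=float)
    m = pool_vals.size

    def stat_fn(diffs: np.ndarray) -> float:
        if statistic == "mean_diff":
            return float(diffs.mean())
        return _signed_rank_statistic(diffs)

    observed = stat_fn(
        np.array([gene_values[tf] - reg_vals[tf] for tf in tfs]))

    # Per TF: list of TU sizes (gene counts) of the TUs it regulates.
    tu_sizes = []
    for tf in tfs:
        sizes = [len(network.tus[t].gene_ids) for t in network.edges[tf]
                 if t in network.tus]
        tu_sizes.append(sizes if preserve_tu_sizes else [sum(sizes)])

    rng = np.random.default_rng(seed)
    null = np.empty(n_trials, dtype=float)
    for t in range(n_trials):
        if replace_tfs:
            pseudo = rng.integers(0, m, size=len(tfs))
        else:
            pseudo = rng.choice(m, size=len(tfs), replace=False)
        diffs = np.empty(len(tfs))
        for i, sizes in enumerate(tu_sizes):
            p = pseudo[i]
            tu_means = []
            for s in sizes:
                # draw s indices from the pool excluding p: sample in m - 1
                # and shift past p
                picks = rng.choice(m - 1, size=min(s, m - 1), replace=False)
                picks = picks + (picks >= p)
                tu_means.append(pool_vals[picks].mean())
            diffs[i] = pool_vals[p] - float(np.mean(tu_means))
        null[t] = stat_fn(diffs)

    k = int(np.sum(null <= observed))
    p_value = max(k, 1) / n_trials
    return RandomizationResult(
        observed_statistic=observed, null_statistics=null,
        p_value=p_value, seed=seed, n_trials=n_trials,
    )


def covariate_correlation(
    x: Mapping[str, float],
    y: Mapping[str, float],
    alternative: str = "two-sided",
) -> stats.TestResult:
    """Spearman correlation between two per-TF covariates (e.g. diversity
    against regulon size, or diversity difference against gene length)."""
    keys = sorted(k for k in x if k in y
                  and _defined(x[k]) and _defined(y[k]))
    if len(keys) < 3:
        raise ValueError("need at least 3 paired values")
    return stats.spearman(
        [x[k] for k in keys], [y[k] for k in keys], alternative=alternative)


def minmax_scale(values):
    """Map values affinely onto [0, 1] (used for display of differences)."""
    if isinstance(values, Mapping):
        keys = list(values)
        arr = np.array([values[k] for k in keys], dtype=float)
    else:
        keys = None
        arr = np.asarray(values, dtype=float)
    if arr.size < 2 or np.nanmax(arr) == np.nanmin(arr):
        raise ValueError("need at least 2 distinct values")
    scaled = (arr - np.nanmin(arr)) / (np.nanmax(arr) - np.nanmin(arr))
    if keys is None:
        return scaled
    return dict(zip(keys, scaled.tolist()))


def length_filtered_edges(
    network: RegulatoryNetwork, gene_lengths: Mapping[str, int]
) -> RegulatoryNetwork:
    """Drop regulatory edges whose target is longer than the TF.

    Pipeline recipe for the gene-length confound: after filtering, paired
    comparisons are re-run on the reduced network so that a TF is only
    compared with targets at most as long as itself.
    """
    new_gene_edges: dict[str, set[str]] = {}
    for tf, targets in network.gene_edges.items():
        kept = {g for g in targets
                if gene_lengths.get(g, 0) <= gene_lengths.get(tf, 0)}
        if kept:
            new_gene_edges[tf] = kept

    gene_to_tus: dict[str, set[str]] = {}
    for tu in network.tus.values():
        for g in tu.gene_ids:
            gene_to_tus.setdefault(g, set()).add(tu.id)
    new_edges = {
        tf: set().union(*(gene_to_tus.get(g, set()) for g in targets))
        for tf, targets in new_gene_edges.items()
    }
    new_edges = {tf: tus for tf, tus in new_edges.items() if tus}
    tf_ids = set(new_edges)
    return RegulatoryNetwork(
        tf_ids=tf_ids,
        tg_ids=set().union(*new_gene_edges.values()) if new_gene_edges else set(),
        edges=new_edges,
        tus=dict(network.tus),
        gene_edges={tf: new_gene_edges[tf] for tf in tf_ids},
    )
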