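"""Synthetic cohorts with the statistical structure the analysis assumes.

Everything downstream of external data acquisition is testable offline via
these generators:

* a regulatory network with power-law regulon sizes (TRNs are scale-free in
  out-degree: a few global regulators, many single-TU local regulators);
* a reference genome of TF/TG coding sequences;
* isolate cohorts of codon variants with a controlled non-synonymous
  diversity ratio between TF and TG classes and class-equal synonymous
  variation -- candidate codon changes are sampled uniformly over single-base
  changes and accepted into the non-synonymous or synonymous budget by
  translation, so the generated data are honest with respect to the
  Nei-Gojobori accounting used downstream;
* per-run coverage profiles (breadth/depth around a target sequencing depth,
  with gene dropout and duplication);
* longitudinal allele-frequency trajectories emulating whole-population
  sequencing of a long-term evolution experiment (Poisson mutation
  origination, logistic selective sweeps, drifting transients, 500-generation
  sampling).

All generators are pure functions of their parameters and seed.

Default magnitudes (rationale in docs/methods.md): target non-synonymous
diversity of TGs theta_tg = 0.005 and synonymous diversity 0.02 (E. coli-like
pi_N < pi_S); 50x sequencing depth; observable-mutation origination rate
2e-8 per non-synonymous site per generation with sweep fraction 0.1 over a
60 000-generation horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .diversity import BASES, STOP_CODONS, SENSE_CODONS, _aa, codon_site_counts
from .pipeline import CodonVariantSet, CoverageProfile, VariantMatrix
from .trn import Gene, RegulatoryNetwork, TranscriptionUnit
from .dynamics import AlleleTrajectorySet

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SyntheticCohort:
    """A generated network + genome + isolate variant sets, with truth."""

    network: RegulatoryNetwork
    genome: dict[str, Gene]
    isolates: dict[str, CodonVariantSet]
    truth: dict[str, float]  # gene id -> expected per-nonsyn-site diversity

    @property
    def run_ids(self) -> list[str]:
        return sorted(self.isolates)


@dataclass
class SyntheticTrajectoryStudy:
    """Generated allele-frequency trajectories plus their ground truth."""

    trajectories: AlleleTrajectorySet
    site_counts: dict[str, float]
    params: dict = field(default_factory=dict)


def generate_network(
    n_tf: int,
    n_tg: int,
    alpha: float = 2.5,
    seed: int | None = None,
    mean_tu_size: float = 2.0,
) -> RegulatoryNetwork:
    """Random TRN with power-law regulon sizes.

    Regulon sizes (numbers of TUs) are drawn from a discrete power law
    P(k) ~ k^-alpha truncated at the number of available TUs; TGs are
    partitioned into TUs of geometric size (mean ``mean_tu_size``) and each
    TF additionally regulates at least one single-gene TU.
    """
    if n_tf < 1:
        raise ValueError("n_tf must be >= 1")
    if n_tg < n_tf:
        raise ValueError("need at least as many TGs as TFs")
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    rng = np.random.default_rng(seed)

    tg_ids = [f"tg{i:04d}" for i in range(n_tg)]
    tf_ids = [f"tf{i:03d}" for i in range(n_tf)]

    # Partition TGs into TUs; keep a healthy share of singletons so each TF
    # can be anchored on a single-gene TU.
    tus: list[TranscriptionUnit] = []
    i = 0
    k = 0
    while i < n_tg:
        size = 1 + rng.geometric(1.0 / mean_tu_size) - 1 if mean_tu_size > 1 else 1
        size = int(min(max(size, 1), n_tg - i, 5))
        tus.append(TranscriptionUnit(f"tu{k:04d}", tuple(tg_ids[i:i + size])))
        i += size
        k += 1
    singles = [tu for tu in tus if len(tu.gene_ids) == 1]
    if not singles:
        raise ValueError("infeasible sizes: no single-gene TU available")
    n_tus = len(tus)
    if n_tus < 1:
        raise ValueError("infeasible sizes: no TU available")

    # Discrete truncated power law over 1..n_tus.
    ks = np.arange(1, n_tus + 1)
    pmf = ks.astype(float) ** (-alpha)
    pmf /= pmf.sum()
    sizes = rng.choice(ks, size=n_tf, p=pmf)

    edges: dict[str, set[str]] = {}
    gene_edges: dict[str, set[str]] = {}
    tu_by_id = {tu.id: tu for tu in tus}
    for tf, n_tu in zip(tf_ids, sizes):
        anchor = singles[rng.integers(len(singles))]
        chosen = {anchor.id}
        if n_tu > 1:
            others = [tu.id for tu in tus if tu.id != anchor.id]
            extra = rng.choice(len(others), size=min(n_tu - 1, len(others)),
                               replace=False)
            chosen |= {others[j] for j in extra}
        edges[tf] = chosen
        gene_edges[tf] = {g for t in chosen for g in tu_by_id[t].gene_ids}

    net = RegulatoryNetwork(
        tf_ids=set(tf_ids), tg_ids=set(tg_ids), edges=edges,
        tus=tu_by_id, gene_edges=gene_edges,
    )
    net.validate()
    return net


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random CDS: ATG start, random sense codons, one stop codon."""
    body = rng.choice(len(SENSE_CODONS), size=max(n_codons - 2, 0))
    stop = sorted(STOP_CODONS)[rng.integers(3)]
    return "ATG" + "".join(SENSE_CODONS[j] for j in body) + stop


def generate_genome(
    network: RegulatoryNetwork,
    tf_codons: int = 250,
    tg_codons: int = 300,
    length_cv: float = 0.2,
    spacer: int = 100,
    seed: int | None = None,
) -> dict[str, Gene]:
    """Random coding sequences laid head-to-tail on a reference.

    TFs default to slightly shorter genes than TGs (as in real bacterial
    annotations). Lengths are lognormal-ish around the class mean with
    coefficient of variation ``length_cv``; all genes on the plus strand at
    0-based half-open coordinates.
    """
    rng = np.random.default_rng(seed)
    genome: dict[str, Gene] = {}
    pos = 0
    for gid in sorted(network.tf_ids) + sorted(network.tg_ids):
        role = "TF" if gid in network.tf_ids else "TG"
        mean = tf_codons if role == "TF" else tg_codons
        n_codons = max(30, int(round(mean * rng.lognormal(0, length_cv))))
        cds = _random_cds(rng, n_codons)
        genome[gid] = Gene(id=gid, start=pos, end=pos + len(cds),
                           strand="+", cds=cds, role=role)
        pos += len(cds) + spacer
    return genome


def _nonsyn_neighbours(codon: str) -> list[str]:
    out = []
    for p in range(3):
        for b in BASES:
            if b == codon[p]:
                continue
            nb = codon[:p] + b + codon[p + 1:]
            if nb not in STOP_CODONS and _aa(nb) != _aa(codon):
                out.append(nb)
    return out


def _syn_neighbours(codon: str) -> list[str]:
    out = []
    for p in range(3):
        for b in BASES:
            if b == codon[p]:
                continue
            nb = codon[:p] + b + codon[p + 1:]
            if nb not in STOP_CODONS and _aa(nb) == _aa(codon):
                out.append(nb)
    return out


def generate_isolates(
    network: RegulatoryNetwork,
    genome: Mapping[str, Gene],
    n_isolates: int = 200,
    theta_tg: float = 0.005,
    delta_tf: float = 1.0,
    theta_syn: float | None = 0.02,
    seed: int | None = None,
) -> SyntheticCohort:
    """Cohort of isolates with class-controlled non-synonymous diversity.

    Per gene, segregating codon sites arise as a Poisson process calibrated so
    the expected pi_N equals ``theta_tg`` for TGs and ``delta_tf * theta_tg``
    for TFs; synonymous sites are calibrated to ``theta_syn`` identically for
    both classes (default 0.02; None disables synonymous variation). Each
    segregating site gets a single-base variant codon (accepted into the
    non-synonymous or synonymous budget by translation) carried by k isolates,
    k uniform on 1..n-1, so a site's expected pairwise-difference contribution
    is (n+1) / (3 (n-1)) per pair.
    """
    if n_isolates < 2:
        raise ValueError("diversity is undefined for fewer than 2 isolates")
    if theta_tg < 0:
        raise ValueError("theta_tg must be >= 0")
    if not (0 < delta_tf <= 1):
        raise ValueError("delta_tf must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = n_isolates
    # expected pairwise-difference fraction of one segregating site,
    # E_k[ k (n-k) / C(n,2) ] with k uniform on 1..n-1
    c = (n + 1) / (3 * (n - 1))

    run_ids = [f"iso{i:04d}" for i in range(n)]
    isolates = {r: CodonVariantSet(run_id=r) for r in run_ids}
    truth: dict[str, float] = {}

    for gid in sorted(genome):
        gene = genome[gid]
        codons = [gene.cds[i:i + 3] for i in range(0, len(gene.cds) - 3, 3)]
        s_counts = [codon_site_counts(cd) for cd in codons]
        s_n = sum(nc for _, nc in s_counts)
        s_s = sum(sc for sc, _ in s_counts)
        theta_n = theta_tg * (delta_tf if gene.role == "TF" else 1.0)
        truth[gid] = theta_n

        lam_n = theta_n * s_n / c
        lam_s = (theta_syn or 0.0) * s_s / c
        k_n = rng.poisson(lam_n)
        k_s = rng.poisson(lam_s)
        if k_n + k_s == 0:
            continue
        order = rng.permutation(len(codons))
        used = 0

        def place(count: int, neighbours) -> None:
            nonlocal used
            placed = 0
            while placed < count and used < len(order):
                idx = int(order[used])
                used += 1
                options = neighbours(codons[idx])
                if not options:
                    continue
                variant = options[rng.integers(len(options))]
                k = int(rng.integers(1, n))
                carriers = rng.choice(n, size=k, replace=False)
                for ci in carriers:
                    isolates[run_ids[ci]].variants.setdefault(
                        gid, {})[idx] = variant
                placed += 1

        place(k_n, _nonsyn_neighbours)
        place(k_s, _syn_neighbours)

    return SyntheticCohort(network=network, genome=dict(genome),
                           isolates=isolates, truth=truth)


def generate_coverage(
    genome: Mapping[str, Gene],
    present: Mapping[str, set[str]],
    mean_depth: float = 50.0,
    duplicated: set[str] | None = None,
    depth_cv: float = 0.15,
    breadth_noise: float = 0.02,
    seed: int | None = None,
) -> CoverageProfile:
    """Per-run per-gene breadth/depth around a target sequencing depth.

    Absent genes get breadth 0 and depth 0; present genes get breadth near 1
    and gamma-distributed depth around ``mean_depth`` (2x for duplicated
    genes).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    duplicated = duplicated or set()
    rng = np.random.default_rng(seed)
    shape = 1.0 / depth_cv ** 2
    rows = []
    for run in sorted(present):
        here = present[run]
        for gid in sorted(genome):
            if gid not in here:
                rows.append((run, gid, 0.0, 0.0))
                continue
            target = mean_depth * (2.0 if gid in duplicated else 1.0)
            depth = rng.gamma(shape, target / shape)
            breadth = float(np.clip(1.0 - abs(rng.normal(0, breadth_noise)), 0, 1))
            rows.append((run, gid, breadth, float(depth)))
    return CoverageProfile(pd.DataFrame(
        rows, columns=["run", "gene", "breadth", "depth"]))


def generate_trajectories(
    classes: Mapping[str, str],
    site_counts: Mapping[str, float],
    n_pops: int = 6,
    horizon: int = 60_000,
    origination_rate: float = 2e-8,
    sweep_fraction: float = 0.1,
    interval: int = 500,
    class_rate_boost: Mapping[str, tuple[float, float]] | None = None,
    sweep_s_range: tuple[float, float] = (0.001, 0.003),
    f_detect: float = 0.01,
    drift_sigma: float = 0.02,
    seed: int | None = None,
    clonal_interference: bool = False,
) -> SyntheticTrajectoryStudy:
    """Longitudinal allele-frequency trajectories (population sequencing).

    Mutations originate per gene as a Poisson process at ``origination_rate``
    per non-synonymous site per generation (the rate of mutations that reach
    observable frequency, not the raw point-mutation rate).
    ``class_rate_boost`` maps a class label to (boost, decay): the class's
    origination intensity is scaled by 1 + boost * exp(-t / decay), emulating
    an early burst of selected regulatory mutations. A fraction
    ``sweep_fraction`` of mutations sweeps deterministically (logistic curve,
    selection coefficient uniform in ``sweep_s_range``) to fixation, which is
    absorbing unless ``clonal_interference`` is set (then sweeps saturate just
    below 1); the rest drift as a small absorbing random walk from the
    detection-scale frequency ``f_detect``. Output is sampled every
    ``interval`` generations.
    """
    if horizon % interval != 0:
        raise ValueError("horizon must be a multiple of the sampling interval")
    rng = np.random.default_rng(seed)
    grid = np.arange(0, horizon + interval, interval)
    class_rate_boost = dict(class_rate_boost or {})

    genes_by_class: dict[str, list[str]] = {}
    for g, c in classes.items():
        genes_by_class.setdefault(c, []).append(g)
    for c in site_counts:
        if c not in genes_by_class:
            raise ValueError(f"site count given for unknown class {c!r}")

    records = []
    mut_counter = 0
    for p in range(n_pops):
        pop = f"pop{p:02d}"
        for cls, genes in sorted(genes_by_class.items()):
            sites_per_gene = site_counts[cls] / len(genes)
            boost, decay = class_rate_boost.get(cls, (0.0, 1.0))
            base = origination_rate * sites_per_gene
            # thinning: envelope rate base * (1 + boost)
            for g in sorted(genes):
                n_cand = rng.poisson(base * (1 + boost) * horizon)
                for _ in range(n_cand):
                    t0 = rng.uniform(0, horizon)
                    accept = (1 + boost * math.exp(-t0 / decay)) / (1 + boost)
                    if rng.random() > accept:
                        continue
                    mut_counter += 1
                    mid = f"m{mut_counter:06d}"
                    freqs = _one_trajectory(
                        rng, grid, t0, sweep_fraction, sweep_s_range,
                        f_detect, drift_sigma, clonal_interference)
                    if not np.any(freqs > 0):
                        continue
                    first = int(np.argmax(freqs > 0))
                    for ti in range(first, len(grid)):
                        records.append((pop, mid, g, "nonsynonymous",
                                        int(grid[ti]), float(freqs[ti])))

    df = pd.DataFrame(records, columns=[
        "population", "mutation_id", "gene", "effect", "generation",
        "frequency"])
    traj = AlleleTrajectorySet(records=df, class_map=dict(classes),
                               site_counts=dict(site_counts))
    params = {
        "origination_rate": origination_rate, "sweep_fraction": sweep_fraction,
        "horizon": horizon, "interval": interval, "n_pops": n_pops,
        "class_rate_boost": class_rate_boost, "seed": seed,
    }
    return SyntheticTrajectoryStudy(trajectories=traj,
                                    site_counts=dict(site_counts),
                                    params=params)


def _one_trajectory(
    rng: np.random.Generator,
    grid: np.ndarray,
    t0: float,
    sweep_fraction: float,
    s_range: tuple[float, float],
    f_detect: float,
    drift_sigma: float,
    clonal_interference: bool,
) -> np.ndarray:
    freqs = np.zeros(len(grid))
    after = grid > t0
    if rng.random() < sweep_fraction:
        s = rng.uniform(*s_range)
        ratio = (1 - f_detect) / f_detect
        f = 1.0 / (1.0 + ratio * np.exp(-s * (grid[after] - t0)))
        f[f >= 0.995] = 1.0
        if clonal_interference:
            f = np.minimum(f, 0.98)
        else:
            fixed = np.maximum.accumulate(f >= 1.0)
            f[fixed] = 1.0
        freqs[after] = f
    else:
        f = f_detect
        vals = []
        for _ in range(int(after.sum())):
            if f <= 0:
                vals.append(0.0)
                continue
            f = float(np.clip(f + rng.normal(0, drift_sigma), 0.0, 1.0))
            if f >= 1.0:
                f = 1.0
            vals.append(f)
            if f == 0.0:
                f = 0.0
        arr = np.array(vals)
        # fixation is absorbing
        if np.any(arr == 1.0):
            arr[np.argmax(arr == 1.0):] = 1.0
        freqs[after] = arr
    return freqs


def cohort_to_variant_matrix(cohort: SyntheticCohort) -> VariantMatrix:
    """Expand a cohort's codon variants into a reference-position SNP matrix.

    The inverse of the pipeline's codon collapsing: every base at which some
    isolate's variant codon differs from the reference becomes a matrix row
    with per-run calls (reference base for non-carriers).
    """
    calls: dict[int, dict[str, str]] = {}
    refs: dict[int, str] = {}
    for run, cvs in cohort.isolates.items():
        for gid, variants in cvs.variants.items():
            gene = cohort.genome[gid]
            for idx, codon in variants.items():
                ref_codon = gene.cds[3 * idx: 3 * idx + 3]
                for off, (a, b) in enumerate(zip(ref_codon, codon)):
                    if a == b:
                        continue
                    if gene.strand == "+":
                        pos = gene.start + 3 * idx + off
                        ref_base, alt = a, b
                    else:
                        pos = gene.end - 1 - (3 * idx + off)
                        ref_base = a.translate(_COMPLEMENT)
                        alt = b.translate(_COMPLEMENT)
                    refs[pos] = ref_base
                    calls.setdefault(pos, {})[run] = alt

    positions = sorted(refs)
    runs = cohort.run_ids
    data = {
        run: [calls.get(p, {}).get(run, refs[p]) for p in positions]
        for run in runs
    }
    df = pd.DataFrame(data, index=pd.Index(positions, name="pos"))
    return VariantMatrix(calls=df, ref=pd.Series(
        [refs[p] for p in positions], index=df.index, name="ref"))
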