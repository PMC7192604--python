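"""Independent brute-force oracles for cross-checking the implementation.

Everything here is written the slow, obvious way: explicit all-pairs loops,
explicit pathway recursion, full enumeration of null distributions. Nothing
imports the implementation's computational paths beyond the genetic code
constants (which both sides must share by definition).
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[11]
_STOPS = set(_TABLE.stop_codons)
_BASES = "ACGT"


def _aa(codon):
    return _TABLE.forward_table[codon]


def site_counts_oracle(codon):
    """Fractional syn/nonsyn site counts by explicit neighbour enumeration."""
    syn = Fraction(0)
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1:]
            if nb not in _STOPS and _aa(nb) == _aa(codon):
                syn += Fraction(1, 3)
    return float(syn), float(3 - syn)


def _paths(c1, c2):
    """All substitution orderings between two codons, as step lists."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    for order in itertools.permutations(diff):
        steps = []
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            steps.append((cur, nxt))
            cur = nxt
        yield steps


def pair_diffs_oracle(c1, c2):
    """Mean (syn, nonsyn) differences over stop-free substitution pathways."""
    scored = []
    for steps in _paths(c1, c2):
        if any(b in _STOPS for _, b in steps):
            continue
        sd = sum(1 for a, b in steps if _aa(a) == _aa(b))
        scored.append((sd, len(steps) - sd))
    if not scored:
        k = sum(1 for a, b in zip(c1, c2) if a != b)
        return 0.0, float(k)
    return (sum(s for s, _ in scored) / len(scored),
            sum(n for _, n in scored) / len(scored))


def diversity_oracle(rows):
    """(pi, pi_s, pi_n) of codon rows by explicit all-pairs summation.

    ``rows`` is a list of equal-length codon lists (no stops, no gaps).
    pi = mean pairwise mismatched-site count / sites; pi_S and pi_N divide
    mean pairwise syn/nonsyn differences by the row-mean Nei-Gojobori site
    counts.
    """
    n = len(rows)
    n_codons = len(rows[0])
    n_sites = 3 * n_codons
    pairs = list(itertools.combinations(range(n), 2))
    diff = syn_d = non_d = 0.0
    for i, j in pairs:
        for a, b in zip(rows[i], rows[j]):
            diff += sum(x != y for x, y in zip(a, b))
            sd, nd = pair_diffs_oracle(a, b)
            syn_d += sd
            non_d += nd
    syn_sites = sum(site_counts_oracle(c)[0] for row in rows for c in row) / n
    pi = diff / len(pairs) / n_sites
    pi_s = (syn_d / len(pairs)) / syn_sites
    pi_n = (non_d / len(pairs)) / (n_sites - syn_sites)
    return pi, pi_s, pi_n


def signed_rank_p_oracle(diffs, alternative):
    """Exact signed-rank p by enumerating all 2^n sign assignments."""
    nz = [d for d in diffs if d != 0]
    n = len(nz)
    mags = sorted(abs(d) for d in nz)
    assert len(set(mags)) == n, "oracle requires tie-free differences"
    ranks = {m: r + 1 for r, m in enumerate(mags)}
    w_obs = sum(ranks[abs(d)] for d in nz if d > 0)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(sorted(ranks.values()), signs) if s))
    if alternative == "less":
        return sum(w <= w_obs for w in ws) / len(ws)
    if alternative == "greater":
        return sum(w >= w_obs for w in ws) / len(ws)
    lo = sum(w <= w_obs for w in ws)
    hi = sum(w >= w_obs for w in ws)
    return min(1.0, 2 * min(lo, hi) / len(ws))


def rank_sum_p_oracle(x, y, alternative):
    """Exact rank-sum p by enumerating all C(m+n, m) rank assignments."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    m = len(x)
    rank_of = {v: r + 1 for r, v in enumerate(pooled)}
    w_obs = sum(rank_of[v] for v in x)
    ws = [sum(combo) for combo in
          itertools.combinations(range(1, len(pooled) + 1), m)]
    if alternative == "less":
        return sum(w <= w_obs for w in ws) / len(ws)
    if alternative == "greater":
        return sum(w >= w_obs for w in ws) / len(ws)
    lo = sum(w <= w_obs for w in ws)
    hi = sum(w >= w_obs for w in ws)
    return min(1.0, 2 * min(lo, hi) / len(ws))


def _rho(x, y):
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mid = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = mid
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                    * sum((b - my) ** 2 for b in ry))
    return num / den


def spearman_oracle(x, y, alternative):
    """(rho, p) with midranks and a full-permutation null."""
    rho = _rho(x, y)
    rhos = [_rho(x, perm) for perm in itertools.permutations(y)]
    eps = 1e-12
    if alternative == "less":
        p = sum(r <= rho + eps for r in rhos) / len(rhos)
    elif alternative == "greater":
        p = sum(r >= rho - eps for r in rhos) / len(rhos)
    else:
        p = sum(abs(r) >= abs(rho) - eps for r in rhos) / len(rhos)
    return rho, p


def fisher_p_oracle(table, alternative):
    """One-sided Fisher p by enumerating all tables with the same margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(aa):
        return (math.comb(r1, aa) * math.comb(r2, c1 - aa)
                / math.comb(n, c1))

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    if alternative == "greater":
        return sum(prob(k) for k in range(a, hi + 1))
    if alternative == "less":
        return sum(prob(k) for k in range(lo, a + 1))
    p_obs = prob(a)
    return min(1.0, sum(p for k in range(lo, hi + 1)
                        if (p := prob(k)) <= p_obs * (1 + 1e-12)))


def holm_oracle(ps):
    """Step-down Holm adjustment by hand."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * ps[i])
        adj[i] = min(1.0, running)
    return adj
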