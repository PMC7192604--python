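"""Orthogroup classification, conservation fractions, and genome dedup.

Builds a small reciprocal-best-hit graph by hand, classifies its components
(strict core / closed / open with greedy clique peeling), computes per-gene
conservation fractions, and deduplicates strains on an MLST signature.
"""

import itertools

from regdiver import conservation as cons

# 6 genomes; one gene in all of them (clique), one in 4 of them plus a
# spurious pendant hit.
genomes = [f"gen{i}" for i in range(6)]
core_nodes = [(g, "dnaA") for g in genomes]
partial = [(g, "marR") for g in genomes[:4]]
edges = [(*a, *b) for a, b in itertools.combinations(core_nodes, 2)]
edges += [(*a, *b) for a, b in itertools.combinations(partial, 2)]
edges.append((*partial[0], "gen5", "decoy"))

graph = cons.BBHGraph.from_edges(edges)
for group in cons.classify_orthogroups(graph, n_genomes=6):
    names = sorted({p for _, p in group.members})
    print(f"orthogroup {names}: {group.label}, "
          f"retained {len(group.retained)}/{len(group.members)} members")

presence = {"dnaA": set(genomes), "marR": set(genomes[:4])}
frac = cons.conservation_fraction(presence, n_genomes=6)
print(f"conservation: dnaA {frac['dnaA']:.2f}, marR {frac['marR']:.2f} "
      "(fraction of genomes with an accepted ortholog)")

hits = {"good": 0.05, "borderline": 0.10, "gappy": 0.22}
print(f"gap filter (>10% alignment gaps rejected): keep {sorted(cons.gap_filter(hits))}")

table = {
    "K12a": {f: (100.0, 100.0) for f in cons.MLST_FRAGMENTS},
    "K12b": {f: (99.7, 100.0) for f in cons.MLST_FRAGMENTS},  # rounds to K12a
    "O157": {f: (91.0, 97.0) for f in cons.MLST_FRAGMENTS},
}
kept = cons.mlst_dedup(table, seed=0)
print(f"MLST dedup keeps {kept}: identical whole-number signatures collapse "
      "to one representative")
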