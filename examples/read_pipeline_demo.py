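"""Read-level pipeline demo: SNP matrix -> presence calls -> declustering.

Materialises a small demo cohort as plain-text fixtures (SNP matrix TSV,
coverage TSV, reference CDS FASTA) under ./demo_cohort/, then runs the
cleaning, coverage-based gene detection, codon-distance and declustering
stages on those files, as one would on real variant-caller output.
"""

from pathlib import Path

import numpy as np

from regdiver import io, pipeline, synth

out = Path("demo_cohort")
out.mkdir(exist_ok=True)

net = synth.generate_network(n_tf=5, n_tg=60, seed=10)
genome = synth.generate_genome(net, seed=11)
cohort = synth.generate_isolates(net, genome, n_isolates=12,
                                 theta_tg=0.02, seed=12)
present = {r: set(genome) for r in cohort.run_ids}
coverage = synth.generate_coverage(genome, present, mean_depth=50.0, seed=13)

io.write_snp_matrix(synth.cohort_to_variant_matrix(cohort), out / "snp.tsv")
io.write_coverage(coverage, out / "coverage.tsv")
io.write_cds_fasta({g: genome[g].cds for g in genome}, out / "cds.fasta")
print(f"fixtures written to {out}/")

matrix = io.read_snp_matrix(out / "snp.tsv")
intervals = [(g.start, g.end) for g in genome.values()]
cleaned = pipeline.clean_snp_matrix(matrix, intervals)
print(f"SNP matrix: {matrix.calls.shape[0]} positions, "
      f"{cleaned.calls.shape[0]} after cleaning")

cov = io.read_coverage(out / "coverage.tsv")
detections = {}
for run in cov.run_ids:
    called, summary = pipeline.detect_genes(cov.for_run(run))
    detections[run] = called
print(f"presence calls: {np.mean([len(v) for v in detections.values()]):.0f} "
      f"genes/run of {len(genome)} (depth threshold ~ "
      f"{summary.threshold:.1f}x)")

variants = pipeline.codon_variants_from_matrix(cleaned, genome)
markers = sorted(genome)[:20]
codon_counts = {g: genome[g].n_codons - 1 for g in markers}
vectors = {
    run: pipeline.codon_distance_vector(variants[run], markers, codon_counts)
    for run in cov.run_ids
}
kept = pipeline.decluster(vectors, min_dist=0.02)
print(f"declustering at distance 0.02 keeps {len(kept)} of "
      f"{len(vectors)} runs (near-clonal isolates removed)")
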