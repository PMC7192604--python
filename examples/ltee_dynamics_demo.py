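"""Derived-allele-frequency dynamics over a 60 000-generation experiment.

Simulates whole-population allele-frequency trajectories for six populations
with an early burst of TF mutation origination, then tracks class-mean DAF,
per-interval de-novo rates, interval frequency maxima and the extreme-outlier
removal -- the quantities used to compare the tempo of TF and TG evolution.
Finally runs the enrichment tests on a small lab-evolution study table.
"""

import numpy as np
import pandas as pd

from regdiver import dynamics, synth

classes = {f"tf{i:03d}": "TF" for i in range(30)}
classes |= {f"tg{i:03d}": "TG" for i in range(300)}
sites = {"TF": 30_000.0, "TG": 300_000.0}

study = synth.generate_trajectories(
    classes, sites, n_pops=6, horizon=60_000, origination_rate=2e-8,
    sweep_fraction=0.1, class_rate_boost={"TF": (8.0, 5000.0)}, seed=1)
traj = study.trajectories

grid = np.arange(500, 60_500, 500)
tf = dynamics.class_mean_daf_series(traj, "TF", grid=grid)
tg = dynamics.class_mean_daf_series(traj, "TG", grid=grid)
for t in (10_000, 30_000, 60_000):
    print(f"t={t:>6}: class-mean DAF  TF {tf.loc[t]:.4f}  TG {tg.loc[t]:.4f}")
print("TF sits above TG throughout; the gap opens in the first ~10k "
      "generations while the TF origination boost decays.")

for cls in ("TF", "TG"):
    starts, rates = dynamics.de_novo_rate(traj, cls, interval=10_000)
    first, last = rates[0], rates[-1]
    print(f"de-novo rate per nonsyn site, {cls}: "
          f"{first:.2e} in [0,10k) -> {last:.2e} in [50k,60k)")

maxima = dynamics.max_freq_per_interval(traj, "TF", interval=10_000)
print(f"median max frequency of TF variants in [0,10k): "
      f"{np.median(maxima[0]):.2f} over {len(maxima[0])} variants")

reduced, dropped = dynamics.drop_outlier_gene(traj, "TF")
print(f"extreme-outlier removal drops TF gene {dropped!r} "
      "(most mutations, highest fixation fraction)")

studies = pd.DataFrame({
    "study": ["glucose-ALE", "antibiotic-AR", "LTEE", "MA-1", "MA-2"],
    "type": ["ALE", "AR", "LTEE", "MA", "MA"],
    "tf_mut": [14, 3, 20, 2, 3],
    "tg_mut": [40, 25, 80, 30, 28],
    "tf_sites": [60_000, 60_000, 60_000, 60_000, 60_000],
    "tg_sites": [600_000, 600_000, 600_000, 600_000, 600_000],
})
results, ranksum = dynamics.ale_enrichment(studies)
for r in results:
    print(f"{r.study:>14} ({r.study_type:>4}): OR {r.odds_ratio:5.2f}, "
          f"Holm-adjusted p {r.p_adjusted:.3g}")
print(f"ALE odds ratios exceed MA: rank-sum p = {ranksum.p_value:.3f}")

expected, res = dynamics.mutated_protein_test(n_mut_tf=8, n_mut_total=40)
print(f"beneficially mutated TFs: 8/40 observed vs {expected:.1%} genome "
      f"background, Fisher p = {res.p_value:.3g}")
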