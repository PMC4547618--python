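"""Parameter recovery on synthetic paired 16S/metagenome data.

Generates mock reference worlds (1% divergence between each genome's 16S and
its marker-database reference), simulates paired samples, predicts KO
profiles from the 16S side and rank-correlates them with the exact
shotgun-side truth, at three metagenome noise levels.
"""
import numpy as np

from amplifun import recovery_benchmark

bench = recovery_benchmark(seeds=range(1, 6), mutation_rate=0.01,
                           min_identity=0.97, n_reads=10_000,
                           noise_rates=(0.0, 0.2, 0.5))
for noise, rhos in bench.items():
    print(f"noise sigma {noise:.1f}: per-sample Spearman rho = "
          f"{[round(r, 4) for r in rhos]}  median = {np.median(rhos):.4f}")
# With no noise the prediction is limited only by multinomial read sampling,
# so the median correlation is ~0.999; multiplicative log-normal noise on the
# metagenome side perturbs the KO ranking and degrades it monotonically.
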