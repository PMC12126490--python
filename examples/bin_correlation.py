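"""Genome-wide 5 kb bin Spearman correlation between two coverage tracks.

Two ChIP-like tracks sharing the same enriched families are binned at 5 kb
and rank-correlated; a third, unrelated track shows near-zero correlation.
"""

import numpy as np

import ervscape as ev
from ervscape import synth

cfg = ev.SimulationConfig(
    seed=4, n_families=4, loci_per_family=40, genome_length=2_000_000,
    orphan_fraction=0.3,
    enrichment_factors={
        "trackA": {"fam01": 8.0, "fam02": 5.0, "fam03": 1.0, "fam04": 1.0},
        "trackB": {"fam01": 6.0, "fam02": 4.0, "fam03": 1.0, "fam04": 1.0},
    },
    library_sizes={"trackA": 10_000_000, "trackB": 10_000_000},
)
annotation = ev.generate_repeat_annotation(cfg)
cov_a = synth.simulate_coverage(annotation, cfg, "trackA")
cov_b = synth.simulate_coverage(annotation, cfg, "trackB")

bins_a = ev.bin_signal(cov_a, bin_width=5000)
bins_b = ev.bin_signal(cov_b, bin_width=5000)
rho, p = ev.spearman_correlation(
    bins_a.signal.iloc[:, 0].to_numpy(), bins_b.signal.iloc[:, 0].to_numpy()
)
print(f"trackA vs trackB over {len(bins_a)} bins of 5 kb: rho = {rho:.3f}, p = {p:.3g}")

rng = np.random.default_rng(5)
noise = {c: rng.random(v.size) for c, v in cov_a.items()}
bins_n = ev.bin_signal(noise, bin_width=5000)
rho_n, p_n = ev.spearman_correlation(
    bins_a.signal.iloc[:, 0].to_numpy(), bins_n.signal.iloc[:, 0].to_numpy()
)
print(f"trackA vs unstructured noise:          rho = {rho_n:.3f}, p = {p_n:.3g}")
print("\nco-occupancy at the same repeat families drives the high rank"
      "\ncorrelation; an unrelated track correlates at ~0.")
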