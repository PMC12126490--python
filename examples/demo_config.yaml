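# Demo configuration for `ervscape run-all`.
# Every stage runs on synthetic data: repeat annotation + ChIP/input counts
# with planted enrichment, LTR profiles and a planted 4x accessibility loss
# at fam01, genome-bin correlation, a Kd titration (3 replicates), an HSQC
# peak-list pair, and a FRAP curve with a 0.25 dip at 15 s.
seed: 7
outdir: ervscape_demo
n_families: 6
loci_per_family: 30
genome_length: 2000000
orphan_fraction: 0.3
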