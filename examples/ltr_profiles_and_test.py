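"""LTR-anchored coverage profiles and differential accessibility.

Builds a synthetic annotation with full-length (5'-LTR + internal + 3'-LTR)
and orphan-LTR integrations, deduplicates LTRs (5' kept where both flanks
exist), lays coverage over a -1.5 kb / +8 kb window around each anchor, and
tests a planted 4x accessibility loss per family with Wilcoxon rank-sum +
Benjamini-Hochberg.
"""

import ervscape as ev
from ervscape import synth

cfg = ev.SimulationConfig(
    seed=2,
    n_families=3,
    loci_per_family=30,
    genome_length=3_000_000,
    orphan_fraction=0.4,
    enrichment_factors={"atac": {"fam01": 3.0, "fam02": 3.0, "fam03": 1.0}},
    library_sizes={"atac": 10_000_000},
)
annotation = ev.generate_repeat_annotation(cfg)
anchors = ev.dedup_ltrs(annotation, synth.default_family_ltr_map(cfg))
print(f"{len(annotation)} loci -> {len(anchors)} anchors (one per integration)")

coverage = synth.simulate_coverage(annotation, cfg, "atac")
profile = ev.build_profile_matrix(coverage, anchors)
avg = ev.average_profile(profile)
print("\naverage profile, first bins (bin_start is bp relative to the LTR 5' edge):")
print(avg.head(4).round(4).to_string(index=False))
peak = avg.loc[avg["mean"].idxmax()]
print(f"peak mean coverage {peak['mean']:.3f} at {int(peak.bin_start)} bp: signal is "
      "concentrated downstream of the anchor, over the element body.")

# two-condition counts with a planted 4x loss at fam01 (e.g. a silencing mutant)
a, b = synth.simulate_atac_counts(anchors.anchors, mean=50, dispersion=10,
                                  loss_factors={"fam01": 0.25}, seed=3)
result = ev.ltr_differential_test(a, b)
print("\nper-family differential accessibility (A vs B):")
print(result.round(6).to_string(index=False))
print("\nfam01 carries the planted 4x loss, hence its tiny adjusted p-value;"
      "\nthe other families behave as null.")
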