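"""Dip depth of the non-bleached half in half-bleach FRAP.

Simulates a half-bleach FRAP experiment on a condensate whose non-bleached
half transiently loses 25% of its intensity around 15 s — the signature of
liquid-like internal mixing — and reads the dip back from the
Savitzky-Golay-smoothed trace.
"""

import ervscape as ev

curve = ev.simulate_frap_curve(
    dip_depth=0.25, dip_time=15.0, n_frames=300, frame_dt=0.1,
    noise_sd=0.01, seed=8,
)
dips = ev.frap_dip_depth(curve, sg_window=11, sg_order=3, probe_times=[1.0, 15.0])

for t, depth in dips.items():
    print(f"dip depth at {t:>4.1f} s: {depth:.3f}")
print("\na large dip (~0.25) at 15 s means unbleached molecules freely mix"
      "\ninto the bleached half — internal diffusion consistent with a"
      "\nliquid-liquid phase-separated compartment; a solid-like compartment"
      "\nwould show no dip.")
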