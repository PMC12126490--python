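"""Chemical shift perturbations between apo and peptide-bound HSQC spectra.

Simulates a 20-residue apo peak list, shifts residues 4 and 12 by
(0.1 ppm 1H, 0.5 ppm 15N), removes residue 9 (exchange-broadened beyond
detection), then matches peaks and computes both CSP metrics per residue.
"""

import ervscape as ev
from ervscape import synth

apo, bound = synth.simulate_peak_lists(
    n_residues=20,
    shifted_set={4, 12},
    disappeared_set={9},
    shift_magnitudes=(0.1, 0.5),
    seed=6,
)
records = ev.match_and_classify_peaks(apo, bound, tol_h=0.15, tol_n=1.0)

print("residue  status       sqrt(dH^2+(dN/5)^2)   |dH|+0.105|dN|")
for r in records:
    if r.status != "matched" or r.csp_euclidean > 1e-9:
        eu = f"{r.csp_euclidean:.4f}" if r.status == "matched" else "   -  "
        wa = f"{r.csp_weighted:.4f}" if r.status == "matched" else "   -  "
        print(f"{r.residue_id:>7}  {r.status:<12}       {eu}           {wa}")

print("\nresidues 4 and 12 show the planted perturbation under both metrics"
      "\n(Euclidean 0.1414 ppm; weighted absolute sum 0.1525 ppm with"
      "\nalpha = 0.105); residue 9 is called disappeared because no bound peak"
      "\nremains within tolerance of its apo position.")
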