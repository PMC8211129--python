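"""Quantifying evidence FOR left-right gait symmetry.

Classical inference can only fail to reject symmetry; the Bayesian interval
null (|delta| <= 0.2, effects too small to matter) can actively support it.
Simulates 99 gait cycles of left/right knee flexion with a negligible
0.5-degree residual asymmetry and maps P(H0 | data) along the cycle.
"""

import numpy as np

from bspm import PriorSpec, bayesian_spm, extract_clusters, make_gait_like, spm_t_test

left, right = make_gait_like(n_cycles=99, asymmetry_deg=0.5, seed=3)

classical = spm_t_test(left, right, design="paired", alpha=0.05)
print(f"classical SPM{{t}}: t* = {classical.t_star:.2f}, "
      f"{len(classical.clusters)} supra-threshold cluster(s)")

pmap = bayesian_spm(left, right, design="paired",
                    prior=PriorSpec(r="medium", c=0.2), null_type="interval")
frac_pp = np.mean(pmap.pp_h0 >= 0.95)
frac_q = np.mean(pmap.q_h0 <= 0.05)
print(f"Bayesian PPM: PP(H0) >= 0.95 over {100 * frac_pp:.0f}% of the cycle")
print(f"              q(H0) <= 0.05 over {100 * frac_q:.0f}% of the cycle")

clusters = extract_clusters(pmap, "H0", "q_005")
print("H0 clusters (q rule):",
      [f"{c.start_pct:.0f}-{c.end_pct:.0f}%" for c in clusters])
if clusters.max_admitted_pep is not None:
    print(f"largest posterior error probability admitted at q < 0.05: "
          f"{clusters.max_admitted_pep:.3f}")

print("\nA high PP(H0) fraction is positive evidence that this subject's")
print("knee motion is left-right symmetric -- a statement classical")
print("inference cannot make from a non-significant result.")
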