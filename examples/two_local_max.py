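"""Two-group trajectories with two localised bursts: classical vs Bayesian.

Simulates 2 x 6 smooth unit-variance trajectories where the second group
carries Gaussian bursts at 25% and 75% of the movement, then runs the
classical SPM{t} (RFT threshold and cluster p-values) and the Bayesian
posterior probability map (interval null, q-value FDR thresholding) side
by side.
"""

import numpy as np

from bspm import (PriorSpec, bayesian_spm, extract_clusters,
                  make_two_local_max, spm_t_test)

group1, group2 = make_two_local_max(n_per_group=6, seed=11)

classical = spm_t_test(group1, group2, design="two_sample", alpha=0.05)
print(f"classical SPM{{t}}: FWHM = {classical.fwhm:.1f} nodes, "
      f"resels = {classical.resel_count:.1f}, t* = {classical.t_star:.3f}")
for cl in classical.clusters:
    print(f"  cluster {cl.start_pct:.0f}-{cl.end_pct:.0f}% "
          f"(peak t = {cl.extremum:+.2f}), p = {cl.p_value:.3f}")

pmap = bayesian_spm(group1, group2, design="two_sample",
                    prior=PriorSpec(r="medium", c=0.2), null_type="interval")
print(f"\nBayesian PPM (medium prior, interval null |delta| <= 0.2):")
print(f"  max PP(H1) = {pmap.pp_h1.max():.3f} at {np.argmax(pmap.pp_h1)}% "
      "of movement")
for rule in ("pp_095", "q_005"):
    clusters = extract_clusters(pmap, "H1", rule)
    spans = [f"{c.start_pct:.0f}-{c.end_pct:.0f}%" for c in clusters]
    print(f"  H1 clusters by {rule}: {spans or 'none'}")

print("\nThe q-value rule admits slightly broader clusters than the")
print("conservative PP >= 0.95 rule while keeping the FDR at 5%; both")
print("should bracket the simulated burst centres at 25% and 75%.")
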