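"""Continuum power analysis: how many gait cycles to plan for.

Suppose a left-right knee-angle difference is only clinically meaningful
above 2 degrees. Model the difference curve as a 2-degree Gaussian pulse
late in the cycle, with 2.4-degree cycle-to-cycle noise of 20-node
smoothness, and estimate the omnibus power of the paired SPM{t} (the
probability of at least one supra-threshold cluster anywhere) over a grid
of sample sizes.
"""

import numpy as np

from bspm import ContinuumModel, FieldSpec, continuum_power, gaussian_pulse

Q = 101
noise = FieldSpec(J=2, Q=Q, fwhm=20.0, amplitude_sd=2.4)
null_model = ContinuumModel(baseline=np.zeros(Q), effect=np.zeros(Q),
                            noise=noise)
alt_model = ContinuumModel(baseline=np.zeros(Q),
                           effect=gaussian_pulse(Q, center=76, fwhm=12,
                                                 amplitude=2.0),
                           noise=noise)

curve = continuum_power(null_model, alt_model,
                        n_values=range(10, 101, 10),
                        alpha=0.05, iterations=500, seed=42)

print("n cycles   omnibus power")
for n, p in zip(curve.n_values, curve.power):
    marker = " <-- first n with power >= 0.80" \
        if n == curve.smallest_n_reaching(0.80) else ""
    print(f"{n:8d}   {p:.3f}{marker}")

print("\nPower rises with the number of cycles; plan at least the marked n")
print("to detect a 2-degree asymmetry with 80% probability at alpha = 0.05.")
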