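"""Simulate two-site pyruvate->lactate exchange and recover k_PL.

The closed-form model describes hyperpolarised pyruvate decaying while
converting to lactate; fitting the sampled curves recovers the apparent
conversion rate, the metabolism metric behind the k_PL habitat maps.
"""

import numpy as np

from hphabitat import fit_kpl, simulate_dynamic_curves

kpl_true, r_pyr, r_lac = 0.025, 1 / 30, 1 / 25   # s^-1
times = np.arange(0.0, 60.1, 3.0)                # s

pyr, lac = simulate_dynamic_curves(kpl_true, r_pyr, r_lac, times, p0=10.0)
print(f"peak lactate {lac.max():.3f} (a.u.) at t = {times[lac.argmax()]:.0f} s")

kpl_hat = fit_kpl(times, pyr, lac, r_pyr=r_pyr, r_lac=r_lac)
print(f"planted k_PL = {kpl_true:.4f} s^-1, recovered = {kpl_hat:.6f} s^-1, "
      f"abs error = {abs(kpl_hat - kpl_true):.2e}")
# On noiseless curves the fit recovers the planted rate to well below
# 1e-4 s^-1, i.e. the estimator itself adds no bias.
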