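"""Constructed background traces with independently controlled trigger states.

Used by the baseline-cascade tests and the acceptance suite: each of the
three noisy-background triggers (zigzag fraction, relative background RMSE,
max/quartile ratio) can be driven into its failing state without flipping
the other two.
"""

import numpy as np

from conftest import gaussian_trace, make_eic


def trigger_trace(zigzag_bad=False, rmse_bad=False, ratio_bad=False, n=400):
    """Background EIC whose trigger outcomes match the three flags.

    Base: flat 100 (tight baseline, RMSE 0) or wide uniform scatter 50-150
    (relative RMSE well above 10%). A tall Gaussian drives the max/quartile
    ratio above 3 unless ``ratio_bad``. Zigzag trains alternate between
    2.5x the lower quartile (high, but never enough to rescue the ratio
    trigger) and exactly the lower quartile (close to baseline), covering
    well over a quarter of the trace when ``zigzag_bad``.
    """
    rng = np.random.default_rng(42)
    t = np.arange(n) * 0.01
    if rmse_bad:
        y = rng.uniform(50.0, 150.0, n)
    else:
        y = np.full(n, 100.0)
    if not ratio_bad:
        y = y + gaussian_trace(t, t[n // 2], 1000.0, 0.05)
    if zigzag_bad:
        q = np.quantile(y, 0.25)
        for s in range(10, n // 2 - 30, 30):
            y[s:s + 12:2] = 2.5 * q
            y[s + 1:s + 13:2] = q
        for s in range(n // 2 + 40, n - 20, 30):
            y[s:s + 12:2] = 2.5 * q
            y[s + 1:s + 13:2] = q
    return make_eic(t, y, background=True)
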