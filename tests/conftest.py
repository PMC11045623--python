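import numpy as np
import pytest

from atscreen.eic import EIC


def make_eic(rt, intensity, background=False, analyte_id="a", sample_id="s",
             mz=100.0):
    rt = np.asarray(rt, dtype=float)
    return EIC(analyte_id, sample_id, mz, 5.0, False, rt,
               np.asarray(intensity, dtype=float), (float(rt[0]), float(rt[-1])),
               is_background=background)


def gaussian_trace(t, apex_rt, height, sigma, baseline=0.0):
    return height * np.exp(-0.5 * ((t - apex_rt) / sigma) ** 2) + baseline


@pytest.fixture
def time_axis():
    return np.arange(0.0, 4.0, 0.01)
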