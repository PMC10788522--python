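import numpy as np
import pytest

from hrvnet import tpdc

# stable bivariate VAR(2) used across DEKF/PDC tests
VAR2_A1 = np.array([[0.4, 0.3], [0.2, 0.3]])
VAR2_A2 = np.array([[-0.2, 0.1], [0.05, -0.15]])


@pytest.fixture(scope="session")
def var2_coeffs():
    return VAR2_A1, VAR2_A2


@pytest.fixture(scope="session")
def fast_tpdc():
    """Factory for a reduced-resolution TPDC pipeline function.

    Used wherever the pipeline is evaluated hundreds of times (surrogate
    nulls): a 16-point frequency grid and coefficient-trajectory stride
    of 5 leave the band/time average essentially unchanged while keeping
    each evaluation in the millisecond range.
    """

    def factory(order=2, stride=5, n_freq=16, band=(0.009, 0.08)):
        grid = tpdc.default_freq_grid(n_freq)

        def fn(ts):
            return tpdc.tpdc_matrix(
                ts, order=order, band=band, freq_grid=grid, time_stride=stride
            )

        return fn

    return factory
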