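import numpy as np

from btccea.survival import ParametricFit


def make_fit(lam: float, gam: float) -> ParametricFit:
    """Wrap known Weibull parameters as a fitted law for engine-level tests."""
    return ParametricFit("weibull", lam, gam, np.nan, np.nan, 0)
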