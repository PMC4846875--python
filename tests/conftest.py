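import numpy as np
import pytest

from phenoks.model import CompoundProfiler
from phenoks.synthetic import SyntheticPanelConfig, generate_panel


def brute_force_signed_ks(treated, control) -> float:
    """Independent ECDF-scan oracle for the signed two-sample KS statistic."""
    pts = sorted(set(treated) | set(control))
    d_plus = d_minus = 0.0
    for x in pts:
        f_t = sum(v <= x for v in treated) / len(treated)
        f_c = sum(v <= x for v in control) / len(control)
        d_plus = max(d_plus, f_c - f_t)
        d_minus = max(d_minus, f_t - f_c)
    # same documented tie rule as the implementation: ties resolve to +
    return d_plus if d_plus >= d_minus - 1e-12 else -d_minus


@pytest.fixture(scope="session")
def small_panel():
    """Reduced synthetic screen: one compound per archetype, 60 cells."""
    cfg = SyntheticPanelConfig(n_compounds=4, n_cells_per_condition=60,
                               rng_seed=7)
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def small_fit(small_panel):
    model = CompoundProfiler.from_panel(small_panel, n_boot=200, seed=7)
    return model.fit()
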