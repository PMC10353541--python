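import numpy as np
import pandas as pd
import pytest

from cytopanel.panel_model import build_panel1, build_panel2
from cytopanel.synthetic import (
    SampleMetadata,
    default_spec,
    simulate_sample,
)


@pytest.fixture(scope="session")
def panel1():
    return build_panel1()


@pytest.fixture(scope="session")
def panel2():
    return build_panel2()


@pytest.fixture(scope="session")
def spec1():
    """Down-scaled panel-1 generating conditions for fast unit tests."""
    return default_spec(1, n_events=30_000, seed=11)


@pytest.fixture(scope="session")
def spec2():
    return default_spec(2, n_events=30_000, seed=11)


@pytest.fixture(scope="session")
def unstim_pair1(spec1):
    """Matched (fully-stained, isotype) unstimulated panel-1 samples."""
    full = simulate_sample(spec1, SampleMetadata("D1", "Unstimulated", "fully-stained", 1, 1))
    iso = simulate_sample(spec1, SampleMetadata("D1", "Unstimulated", "isotype", 1, 1))
    return full, iso


@pytest.fixture(scope="session")
def unstim_pair2(spec2):
    full = simulate_sample(spec2, SampleMetadata("D1", "Unstimulated", "fully-stained", 1, 2))
    iso = simulate_sample(spec2, SampleMetadata("D1", "Unstimulated", "isotype", 1, 2))
    return full, iso


def make_flat_sample(panel, fluorescence: dict[str, np.ndarray], n: int | None = None):
    """An EventMatrix where every event passes scatter/singlet/viability.

    Unspecified detectors are constant background (50); scatter is set so
    the trunk gates are transparent, letting tests probe marker gates
    directly.
    """
    from cytopanel.synthetic import EventMatrix

    n = n or len(next(iter(fluorescence.values())))
    fsc = np.full(n, 60_000.0)
    scatter = pd.DataFrame({"FSC-A": fsc, "FSC-H": fsc * 0.98, "SSC-A": np.full(n, 30_000.0)})
    fl = pd.DataFrame({d: np.full(n, 50.0) for d in panel.detectors})
    for det, vals in fluorescence.items():
        fl[det] = np.asarray(vals, float)
    md = SampleMetadata("Dx", "Unstimulated", "fully-stained", 1, panel.panel_id)
    return EventMatrix(md, scatter, fl)
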