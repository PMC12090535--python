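import numpy as np
import pytest

from mkgp.kernels import GenotypePanel
from mkgp.simulate import SimConfig, simulate_study


@pytest.fixture
def micro_panel() -> GenotypePanel:
    """Three lines, one marker with codes 0/1/2: the worked micro-example."""
    return GenotypePanel(
        line_ids=np.array(["a", "b", "c"], dtype=object),
        codes=np.array([[0.0], [1.0], [2.0]]),
    )


@pytest.fixture(scope="session")
def small_study():
    """A small but realistic two-trait study panel shared across tests."""
    cfg = SimConfig(n_lines=60, n_markers=300, n_genes=120, seed=7, n_subpops=10)
    return simulate_study(cfg)


@pytest.fixture(autouse=True)
def _quiet_low_ess():
    """Short test chains trip the ESS diagnostic by design; keep output clean."""
    import warnings

    from mkgp._util import MkgpWarning

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=r"\[LOW_ESS\]", category=MkgpWarning)
        yield
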