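import numpy as np
import pytest

from genediv.simulate import default_config, simulate_panel, simulate_q, simulate_phenotypes
from genediv.variant_scan import call_variants


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def panel_truth(cfg):
    return simulate_panel(cfg, seed=1)


@pytest.fixture(scope="session")
def panel(panel_truth):
    return panel_truth[0]


@pytest.fixture(scope="session")
def truth(panel_truth):
    return panel_truth[1]


@pytest.fixture(scope="session")
def variants(panel, cfg):
    return call_variants(panel, cfg.model)


@pytest.fixture(scope="session")
def qmatrix(cfg, truth):
    return simulate_q(cfg, truth, seed=1)


@pytest.fixture(scope="session")
def phenotypes(cfg, truth, qmatrix):
    return simulate_phenotypes(cfg, truth, qmatrix, seed=1)


def toy_panel(rows: list[str], ids=None, reference: str | None = None, reference_id="ref"):
    """Small literal alignment helper for unit tests."""
    from genediv.io_core import AlignedPanel

    ids = ids or [f"s{i+1}" for i in range(len(rows))]
    ref = np.array(list(reference), dtype="U1") if reference is not None else None
    return AlignedPanel(ids, np.array([list(r) for r in rows], dtype="U1"),
                        reference_id if reference is not None else None, ref)
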