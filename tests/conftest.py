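import pytest

from cherry_curator.core import MarkerPanel, SSRGenotype
from cherry_curator.synthetic_collection import GeneratorConfig, generate


@pytest.fixture(scope="session")
def small_panel() -> MarkerPanel:
    return MarkerPanel(loci=("L1", "L2", "L3"), motif_bp={"L1": 2, "L2": 2, "L3": 2})


@pytest.fixture(scope="session")
def clean_collection():
    """A corruption-free collection: clones byte-identical to cultivars."""
    cfg = GeneratorConfig(
        seed=101,
        n_cultivars=12,
        clones_per_cultivar=(2, 3),
        clone_error_rate=0.0,
        missing_rate=0.0,
        sizing_jitter_rate=0.0,
    )
    return cfg, *generate(cfg)


@pytest.fixture(scope="session")
def noisy_collection():
    """Default study conditions: 10% per-reaction error, jitter, missing."""
    cfg = GeneratorConfig(seed=202, n_cultivars=30, n_trios=5)
    return cfg, *generate(cfg)


def genotype(pairs: dict) -> SSRGenotype:
    return SSRGenotype(pairs)
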