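import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import screenforge as sf

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_library() -> sf.SgRNALibrary:
    """Two genes x 2 guides plus one non-targeting control."""
    records = [
        sf.SgRNARecord("g1_sg1", "ACGTACGTACGTACGTACGT", "G1", "gene"),
        sf.SgRNARecord("g1_sg2", "TTTTACGTACGTACGTACGA", "G1", "gene"),
        sf.SgRNARecord("g2_sg1", "CCCCACGTACGTACGTACGT", "G2", "gene"),
        sf.SgRNARecord("g2_sg2", "GGGGACGTACGTACGTACGT", "G2", "gene"),
        sf.SgRNARecord("ntc_sg1", "AAAAAAAAAACCCCCCCCCC", "NTC_1", "non_targeting"),
    ]
    return sf.SgRNALibrary(records, spacer_length=20, name="toy")


@pytest.fixture(scope="session")
def small_screen() -> sf.ScreenResult:
    """A seeded 50-gene screen reused across read-only tests."""
    cfg = sf.SimConfig(
        n_genes=50, n_controls=100, coverage=100, seq_depth=300, seed=1
    )
    return sf.simulate_screen(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_counts(
    rng: np.random.Generator, n_guides: int, samples: list[str]
) -> pd.DataFrame:
    """NB-ish random count table for oracle tests."""
    mu = rng.lognormal(np.log(200), 0.7, n_guides)
    k = rng.poisson(rng.gamma(10.0, mu[:, None] / 10.0, (n_guides, len(samples))))
    return pd.DataFrame(
        k, index=pd.Index([f"g{i}" for i in range(n_guides)], name="sgrna_id"),
        columns=samples,
    )
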