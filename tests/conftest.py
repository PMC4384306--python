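import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gapmer as g

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def uniform_bg_m():
    """Uniform mononucleotide background (e_b = 0.25 for each base)."""
    return g.BackgroundModel.from_frequencies(
        g.GappedNmer("m"), {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    )


@pytest.fixture(scope="session")
def random_background():
    """A 20 kb i.i.d. uniform background sequence."""
    rng = np.random.default_rng(42)
    return "".join(rng.choice(list("ACGT"), size=20_000))


@pytest.fixture(scope="session")
def hb_like_sites():
    """101 aligned 7-mers drawn from a sharp T-rich consensus motif."""
    spec = g.SyntheticSpec(
        motif=g.consensus_motif("TTTTTTG", 0.85),
        n_sites=101,
        n_peaks=1,
        background_length=1000,
        seed=11,
    )
    sites, _, _ = g.generate_fixtures(spec)
    return sites


@pytest.fixture(scope="session")
def small_dataset():
    """Sites + 20 planted-motif peaks + background, desk scale."""
    spec = g.SyntheticSpec(
        motif=g.consensus_motif("TTTTTTG", 0.9),
        n_sites=40,
        n_peaks=20,
        sites_per_peak=2,
        background_length=20_000,
        seed=5,
    )
    return g.generate_fixtures(spec)
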