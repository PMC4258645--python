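import pytest

from swfringe.presets import cap_fixture, discocyte_fixture


@pytest.fixture(scope="session")
def cap_noiseless():
    """Default noiseless 512x512 cap fixture (514 nm, n=1, 37 antinodes)."""
    return cap_fixture(noisy=False)


@pytest.fixture(scope="session")
def cap_noisy():
    """Seeded noisy cap fixture: photon_scale 500, background 5, seed 0."""
    return cap_fixture(seed=0, photon_scale=500.0, background=5.0)


@pytest.fixture(scope="session")
def cap_moire_noisy():
    """Narrowband (580/5 nm) moire cap fixture, seeded noise."""
    return cap_fixture(
        mode="narrowband_moire", seed=0, photon_scale=500.0, background=5.0
    )


@pytest.fixture(scope="session")
def cap_1024_noiseless():
    """1024x1024 noiseless cap render for contour-based reconstruction."""
    return cap_fixture(noisy=False, size=1024)


@pytest.fixture(scope="session")
def discocyte_noiseless():
    """Noiseless biconcave red-cell membrane render (488 nm, n=1.34)."""
    return discocyte_fixture(noisy=False)
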