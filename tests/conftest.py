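import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wm3():
    """Neutral well-mixed Moran process on 3 sites, no mutation."""
    from selsym import well_mixed_moran

    return well_mixed_moran(3)


@pytest.fixture(scope="session")
def wm3_group(wm3):
    from selsym import symmetry_group

    return symmetry_group(wm3)


@pytest.fixture(scope="session")
def star5():
    from selsym import star_moran_db

    return star_moran_db(5)


@pytest.fixture(scope="session")
def star5_group(star5):
    from selsym import symmetry_group

    return symmetry_group(star5)
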