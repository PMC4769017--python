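import pytest

from mapkscan import Alignment, AnchorCatalog, MotifCatalog


@pytest.fixture(scope="session")
def anchor_catalog() -> AnchorCatalog:
    return AnchorCatalog.default()


@pytest.fixture(scope="session")
def motif_catalog() -> MotifCatalog:
    return MotifCatalog.default()


@pytest.fixture
def small_alignment() -> Alignment:
    return Alignment(
        (
            ("s1", "ACDEF"),
            ("s2", "ACDEY"),
            ("s3", "ACD-F"),
            ("s4", "ACDEF"),
        )
    )
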