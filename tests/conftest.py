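import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def quartet_tree():
    from homoplasy.io import read_newick_string

    return read_newick_string("((A,B),(C,D));")


@pytest.fixture
def quartet_alignment():
    """Nine clean sites plus one A/T/A/T homoplasy at position 4 (1-based)."""
    from homoplasy.io import Alignment

    #            123 4 567890
    return Alignment(
        [
            ("A", "AAA" "A" "CGTACG"),
            ("B", "AAA" "T" "CGTACG"),
            ("C", "ATC" "A" "CGTACG"),
            ("D", "ATC" "T" "CGTACG"),
        ]
    )
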