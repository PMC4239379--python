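import pytest

from xylptools.synthetic import SyntheticFamilySpec, generate_family


@pytest.fixture(scope="session")
def small_family():
    """A small planted family (clades A and C plus all decoy classes)."""
    return generate_family(SyntheticFamilySpec(
        n_per_clade={"A": 6, "C": 6},
        decoys={c: 2 for c in ("seven_cys", "wrong_gap",
                               "no_glycomodules", "no_signal")},
        seed=11,
    ))
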