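import pytest

from ph1kit import MsaSpec, demo_inputs, make_family_fixture, simulate_msa


@pytest.fixture(scope="session")
def family():
    return make_family_fixture()


@pytest.fixture(scope="session")
def demo():
    return demo_inputs(seed=1)


@pytest.fixture(scope="session")
def conserved_msa():
    """8-species alignment with Met49 and Asn72 fully conserved."""
    base = simulate_msa(MsaSpec(length=120, seed=7))
    seq = list(str(base[0].seq))
    seq[48] = "M"
    seq[71] = "N"
    return simulate_msa(
        MsaSpec(
            length=120,
            planted_conservation={48: 8, 71: 8},
            reference_seq="".join(seq),
            seed=7,
        )
    )
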