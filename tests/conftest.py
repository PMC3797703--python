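import pytest

from herbdcaps.reference import build_reference_fixture


@pytest.fixture(scope="session")
def ref():
    """The packaged synthetic reference fixture (seed 0)."""
    return build_reference_fixture(0)


@pytest.fixture(scope="session")
def wild_amplicon(ref):
    """Wild-allele dCAPS amplicon (127 nt, one enforced base)."""
    from herbdcaps.pcr_digest import build_amplicon

    fwd, rev = ref.design.primer_pair
    amp = build_amplicon(ref.templates[ref.snp.wild_codon], fwd, rev)
    assert amp is not None
    return amp
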