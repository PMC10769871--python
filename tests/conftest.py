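import pytest

from bilrscreen import hmm, synthetic


@pytest.fixture(scope="session")
def family():
    """Standard BilR family fixture: 5 short, 5 long, 10 decoys."""
    return synthetic.generate_bilr_family(5, 5, 10, seed=3)


@pytest.fixture(scope="session")
def calibrated_profile(family):
    """Profile built on the clade-1 core alignment, Gumbel-calibrated."""
    profile = hmm.build_profile(
        family.clade1_alignment(),
        family.reference_id,
        reference_residue_span=(1, family.core_length),
        motif_reference_positions=family.motif_positions,
    )
    return hmm.calibrate(profile, n_random=300, random_length=400, seed=17)


@pytest.fixture(scope="session")
def small_pangenome():
    """Pangenome small enough for real RBH clustering in tests."""
    return synthetic.generate_pangenome(4, 4, 25, True, 0.05, seed=5)
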