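import pytest
from hypothesis import settings

from quadstall import seqkit
from quadstall.melt_thermo import params_from_dG37_Tm

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

# reported stabilities of the folded QFP variants: (dG37 kcal/mol, Tm C)
REPORTED_FOLDED = {
    "wild-type": (-5.15, 76.4),
    "C-mutant": (-4.77, 72.6),
    "G-mutant": (-5.86, 82.4),
    "U-mutant": (-0.47, 39.9),
}


@pytest.fixture(scope="session")
def sense_windows():
    """Sense-strand QFP windows (RNA) recovered from the printed primers."""
    return seqkit.qfp_sense_windows()


@pytest.fixture(scope="session")
def reported_params():
    """Two-state parameters back-derived from each reported (dG37, Tm)."""
    return {name: params_from_dG37_Tm(dg, tm)
            for name, (dg, tm) in REPORTED_FOLDED.items()}


@pytest.fixture(scope="session")
def noiseless_bundle(tmp_path_factory):
    """Zero-noise synthetic bundle shared by end-to-end tests."""
    from quadstall import synthetic_data
    out = tmp_path_factory.mktemp("bundle_noiseless")
    config = synthetic_data.make_study_scenario(seed=7, noiseless=True)
    synthetic_data.generate_bundle(config, out)
    return out
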