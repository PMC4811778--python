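import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from xlquant import chem


@pytest.fixture(scope="session")
def linker():
    return chem.builtin_linker("bAL2")


@pytest.fixture(scope="session")
def mass_table():
    return chem.DEFAULT_MASS_TABLE


@pytest.fixture(scope="session")
def worked_species():
    """The published worked example: inter-linked peptide pair with
    carbamidomethylated cysteines, +4 charged."""
    pep_b = "LAKEYEATLEECCAK"
    mods = tuple(
        (1, i + 1, chem.CARBAMIDOMETHYL) for i, r in enumerate(pep_b) if r == "C"
    )
    return chem.LinkedSpecies(
        link_type=chem.LinkType.INTER,
        peptide_a="NYQEAKDAFLGSFLYEYSR",
        site_a=6,
        peptide_b=pep_b,
        site_b=3,
        modifications=mods,
        charge=4,
    )
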