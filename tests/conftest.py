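import warnings

import pytest

import pbkra


@pytest.fixture(scope="session")
def physiology():
    return pbkra.builtin_physiology()


@pytest.fixture(scope="session")
def estragole():
    return pbkra.builtin_chemical("estragole")


@pytest.fixture(scope="session")
def safrole():
    return pbkra.builtin_chemical("safrole")


@pytest.fixture(scope="session")
def methyleugenol():
    return pbkra.builtin_chemical("methyleugenol")


@pytest.fixture(scope="session")
def realistic_dose():
    """Realistic daily intake: 0.07 mg/kg bw over a 24 h window."""
    return pbkra.DoseRegimen(oral_dose=0.07, duration=24.0)


@pytest.fixture(scope="session")
def scenario_suite(physiology, estragole, safrole, methyleugenol, realistic_dose):
    """The full labelled scenario suite (ES/SA sources, ME target, all modes)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pbkra.run_scenarios(
            [estragole, safrole], methyleugenol,
            ["ORIGINAL", "MW_PC", "ALL"], physiology, realistic_dose,
        )


@pytest.fixture(scope="session")
def candidate_pool():
    return pbkra.builtin_candidate_pool()
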