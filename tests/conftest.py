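import pytest

from crpmeth import simulate as sim


@pytest.fixture(scope="session")
def crp4_locus():
    """1012-bp synthetic locus with the studied monomer's region geometry
    and per-region context site counts."""
    return sim.make_locus(430, 369, 213, seed=11)


@pytest.fixture(scope="session")
def wt_landscape(crp4_locus):
    return sim.simulate_landscape(crp4_locus, sim.CRP4_LIKE_RATES)


@pytest.fixture(scope="session")
def mutant_landscape(crp4_locus):
    effect = sim.GenotypeEffect("rddm_mutant", {"CHH": 0.25})
    return sim.simulate_landscape(crp4_locus, sim.CRP4_LIKE_RATES, effect)
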