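import pytest

from crossri.simulate import DirectionParams, SimulationConfig, StrainSpec


@pytest.fixture(scope="session")
def null_sim_config() -> SimulationConfig:
    """Two strains with identical parameters and no hybrid effects."""
    return SimulationConfig(
        strains={"A": StrainSpec(), "B": StrainSpec()},
        directions=[("A", "B")],
        params={("A", "B"): DirectionParams(p_mate=0.75)},
        n_rep=40, ci_penetrance=0.0, seed=11)


@pytest.fixture(scope="session")
def effect_sim_config() -> SimulationConfig:
    """Moderate barriers at every ladder stage plus unidirectional CI."""
    return SimulationConfig(
        strains={"A": StrainSpec(), "B": StrainSpec(infected=True)},
        directions=[("A", "B")],
        params={("A", "B"): DirectionParams(
            p_mate=0.4, female_viability=0.9, female_behaviour=0.7,
            female_fertility=0.8, male_viability=0.6, male_behaviour=0.7,
            male_fertility=0.5)},
        n_rep=40, ci_penetrance=0.525, seed=11)
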