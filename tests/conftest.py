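import pytest

from pathrecon import (
    PathwayDefinition,
    Reaction,
    ScenarioConfig,
    generate_scenario,
    run_pipeline,
)

SMALL_COUNTS = {
    "CAL": 3, "SUC": 2, "STA": 2, "RES": 3, "AMI": 5, "CEL": 2, "FAT": 2, "NUC": 3,
}


def make_reaction(rid, ecs=(), subs=("CAL",), rtype="enzymatic", substrates=(), products=()):
    return Reaction(
        reaction_id=rid,
        ec_numbers=frozenset(ecs),
        substrates=frozenset(substrates),
        products=frozenset(products),
        sub_metabolisms=frozenset(subs),
        rtype=rtype,
    )


def make_pathway(species, reactions, ec_to_proteins=None):
    p = PathwayDefinition(species=species)
    for r in reactions:
        p.add_reaction(r)
    for ec, prots in (ec_to_proteins or {}).items():
        p.ec_to_proteins.setdefault(ec, set()).update(prots)
    return p


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced 6-template scenario (~22 reactions) used by tests that
    exercise the full alignment pipeline."""
    cfg = ScenarioConfig(seed=13, reactions_per_sub=dict(SMALL_COUNTS), decoy_fraction=0.2)
    return generate_scenario(cfg)


@pytest.fixture(scope="session")
def small_result(small_scenario):
    return run_pipeline(small_scenario)
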