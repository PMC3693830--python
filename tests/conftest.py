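import pytest

from sideminer import (
    DrugRecord,
    GeneratorParams,
    SideEffectTerm,
    StudyNetwork,
    TargetNode,
    simulate_world,
    worked_example_fixture,
)


def make_network(target_drugs, se_drugs, modes=None):
    """Build a StudyNetwork from {protein: drugs} and {se: drugs} dicts."""
    net = StudyNetwork()
    for protein, drugs in target_drugs.items():
        node = TargetNode(protein, "binding")
        net.targets[node.key] = node
        net.target_drugs[node.key] = set(drugs)
        for d in drugs:
            net.drugs.setdefault(d, DrugRecord(d))
    for se, drugs in se_drugs.items():
        net.side_effects[se] = SideEffectTerm(se)
        net.se_drugs[se] = set(drugs)
        for d in drugs:
            net.drugs.setdefault(d, DrugRecord(d))
    for (drug, protein), mode_set in (modes or {}).items():
        net.mode_annotations[(drug, protein)] = set(mode_set)
    net.active_drug_set = set(net.drugs)
    net.validate()
    return net


@pytest.fixture
def worked_example():
    return worked_example_fixture()


@pytest.fixture(scope="session")
def default_world():
    """One synthetic world at default generator settings."""
    return simulate_world(GeneratorParams(seed=7))


@pytest.fixture(scope="session")
def default_world_result(default_world):
    """Pipeline output on the default world (KS permutations kept small)."""
    from sideminer import run_study

    return run_study(
        default_world.network,
        default_world.fingerprints,
        default_world.annotations,
        {"seed": 7, "ks_permutations": 500},
    )
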