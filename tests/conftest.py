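import sys
from dataclasses import replace
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for vertex_oracle

import efmin as ef


@pytest.fixture
def toy() -> ef.MetabolicModel:
    return ef.build_toy_network()


@pytest.fixture
def cycle_model() -> ef.MetabolicModel:
    return ef.build_cycle_fixture()


@pytest.fixture
def toy_bounded(toy) -> ef.MetabolicModel:
    """Toy network with substrate uptake capped at 1 (makes FBA bounded)."""
    rxns = [
        replace(r, upper_bound=1.0) if r.id == "r1" else replace(r) for r in toy.reactions
    ]
    return ef.MetabolicModel(list(toy.metabolites), rxns, "r9")


def toy_weights(**overrides) -> ef.WeightVector:
    w = {f"r{i}": 1.0 for i in range(1, 10)}
    w.update(overrides)
    return ef.WeightVector(w)


#: Expression-derived weights favouring P3 over P4 over (suppressed) P2.
CASE_P3 = dict(r1=0.0, r2=1.0, r3=0.9, r4=0.1, r5=0.1, r6=0.2, r7=0.2, r8=0.2, r9=0.0)
#: Highly expressed P4 genes: the longest path becomes the cheapest.
CASE_P4 = dict(r1=0.0, r2=1.0, r3=0.8, r4=0.7, r5=0.7, r6=0.05, r7=0.05, r8=0.05, r9=0.0)
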