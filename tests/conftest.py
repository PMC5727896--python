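import numpy as np
import pytest

from omvlink.model_core import (
    INF_CAP,
    MetabolicModel,
    Metabolite,
    Reaction,
)
from omvlink import synthetic_data as syn


def build_model(mets, rxns, objective=None, compartments=("c", "e", "cm", "em", "o", "lu")):
    """Compact toy-model builder: mets = [(id, comp)], rxns = [(id, stoich, lb, ub[, tag])]."""
    m = MetabolicModel("toy", compartments)
    for mid, comp in mets:
        base = mid[: -(len(comp) + 1)] if mid.endswith("_" + comp) else mid
        m.add_metabolite(Metabolite(id=mid, base_id=base, compartment=comp))
    for spec in rxns:
        rid, stoich, lb, ub = spec[:4]
        tag = spec[4] if len(spec) > 4 else "original"
        m.add_reaction(
            Reaction(id=rid, stoichiometry=stoich, lower_bound=lb,
                     upper_bound=ub, origin_tag=tag)
        )
    if objective:
        m.set_objective(objective)
    return m


@pytest.fixture
def chain_model():
    """EX_A(lb -10) -> A_c -> biomass: optimum bounded by uptake."""
    return build_model(
        [("A_lu", "lu"), ("A_c", "c")],
        [
            ("EX_A", {"A_lu": -1.0}, -10.0, INF_CAP, "exchange"),
            ("T_A", {"A_lu": -1.0, "A_c": 1.0}, 0.0, INF_CAP),
            ("R1", {"A_c": -1.0}, 0.0, INF_CAP),
        ],
        objective="R1",
    )


@pytest.fixture
def branch_model():
    """Two branches of capacity 3 and 4 feeding the objective: optimum 7."""
    return build_model(
        [("A_lu", "lu"), ("A_c", "c"), ("B_c", "c"), ("C_c", "c"), ("P_c", "c")],
        [
            ("EX_A", {"A_lu": -1.0}, -INF_CAP, INF_CAP, "exchange"),
            ("T_A", {"A_lu": -1.0, "A_c": 1.0}, 0.0, INF_CAP),
            ("B1", {"A_c": -1.0, "B_c": 1.0}, 0.0, 3.0),
            ("B2", {"A_c": -1.0, "C_c": 1.0}, 0.0, 4.0),
            ("J1", {"B_c": -1.0, "P_c": 1.0}, 0.0, INF_CAP),
            ("J2", {"C_c": -1.0, "P_c": 1.0}, 0.0, INF_CAP),
            ("OBJ", {"P_c": -1.0}, 0.0, INF_CAP),
        ],
        objective="OBJ",
    )


def random_toy_model(seed, n_internal=4):
    """Random small single-compartment network with an exchange-fed chain."""
    rng = np.random.default_rng(seed)
    mets = [("S_lu", "lu")] + [(f"m{i}_c", "c") for i in range(n_internal)]
    rxns = [
        ("EX_S", {"S_lu": -1.0}, -float(rng.integers(1, 20)), INF_CAP, "exchange"),
        ("T_S", {"S_lu": -1.0, "m0_c": 1.0}, 0.0, float(rng.integers(1, 50))),
    ]
    for i in range(n_internal - 1):
        lb = 0.0 if rng.random() < 0.7 else -float(rng.integers(1, 10))
        rxns.append(
            (f"R{i}", {f"m{i}_c": -1.0, f"m{i+1}_c": 1.0},
             lb, float(rng.integers(1, 30)))
        )
    rxns.append((f"SNK", {f"m{n_internal-1}_c": -1.0}, 0.0, INF_CAP, "sink"))
    return build_model(mets, rxns, objective="SNK")


@pytest.fixture(scope="session")
def host_microbe():
    model, truth = syn.make_host_microbe_model(seed=7, redundancy_fraction=1.0 / 3.0)
    return model, truth


@pytest.fixture(scope="session")
def gapfill_instance(host_microbe):
    model, _ = host_microbe
    return syn.make_gapfill_instance(
        model, n_gaps=2, n_decoys=5, seed=11, n_two_step=1,
        n_reversibility_conflicts=1,
    )
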