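"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity through a different route than the
implementation under test: polytope vertex enumeration for LP optima,
direct per-reaction LPs for flux variability, exhaustive subset search
for gap-fill minimality, and graph reachability for transfer routes.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

from omvlink.gap_filling import (
    UniversalReactionDB,
    find_unconnected_metabolites,
    instantiate_universal,
)


def vertex_fba_oracle(model, objective_id, tol=1e-7):
    """LP maximum by enumerating basic feasible solutions (n <= ~8)."""
    S, _mets, rxns = model.stoichiometric_matrix()
    S = np.asarray(S.todense())
    n = len(rxns)
    lb = np.array([model.reactions[r].lower_bound for r in rxns])
    ub = np.array([model.reactions[r].upper_bound for r in rxns])
    r = np.linalg.matrix_rank(S, tol=1e-9)
    obj = rxns.index(objective_id)
    best = None
    for fixed in itertools.combinations(range(n), n - r):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        if np.linalg.matrix_rank(A, tol=1e-9) < len(free):
            continue
        for sides in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            v = np.zeros(n)
            v[list(fixed)] = sides
            b = -S[:, list(fixed)] @ np.array(sides)
            sol = np.linalg.lstsq(A, b, rcond=None)[0]
            v[free] = sol
            if np.max(np.abs(S @ v)) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            if best is None or v[obj] > best:
                best = v[obj]
    return best


def fva_oracle(model, reaction_id):
    """Feasible flux range of one reaction via two direct scipy LPs."""
    S, _mets, rxns = model.stoichiometric_matrix()
    bounds = [
        (model.reactions[r].lower_bound, model.reactions[r].upper_bound)
        for r in rxns
    ]
    j = rxns.index(reaction_id)
    out = []
    for sign in (1.0, -1.0):
        c = np.zeros(len(rxns))
        c[j] = sign
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                      method="highs")
        out.append(sign * res.fun if res.status == 0 else np.nan)
    return out[0], out[1]  # (min, max)


def bruteforce_gapfill_minimum(model, db, compartment, targets, mode="consumable",
                               epsilon=1e-6):
    """Smallest db subset restoring connectivity of all targets, or None.

    Enumerates subsets by increasing cardinality (lexicographic within a
    cardinality) and returns the first sufficient subset.
    """
    ids = sorted(db.records)
    for k in range(len(ids) + 1):
        for combo in itertools.combinations(ids, k):
            sub = UniversalReactionDB()
            for rid in combo:
                sub.add(db.records[rid])
            aug, _ = instantiate_universal(model, sub, compartment)
            if any(t not in aug.metabolites for t in targets):
                continue
            bad = find_unconnected_metabolites(
                aug, compartment, mode, epsilon, targets
            )
            if not bad:
                return set(combo)
    return None


def reachability_producible(model, metabolite_id):
    """Graph oracle: can mass reach the metabolite from any supply?

    Builds a metabolite digraph with an edge substrate->product for every
    reaction direction the bounds allow, sources at exchange reactions
    open to uptake; valid on the synthetic skeletons, where every
    non-boundary reaction is a unit conversion chain.
    """
    import networkx as nx

    g = nx.DiGraph()
    supply = "__SUPPLY__"
    g.add_node(supply)
    for rxn in model.reactions.values():
        subs = [m for m, c in rxn.stoichiometry.items() if c < 0]
        prods = [m for m, c in rxn.stoichiometry.items() if c > 0]
        if rxn.origin_tag in ("exchange", "source"):
            met = next(iter(rxn.stoichiometry))
            if rxn.lower_bound < 0 or (rxn.origin_tag == "source"
                                       and rxn.upper_bound > 0):
                g.add_edge(supply, met)
            continue
        if rxn.upper_bound > 0:
            for s in subs:
                for p in prods:
                    g.add_edge(s, p)
        if rxn.lower_bound < 0:
            for s in subs:
                for p in prods:
                    g.add_edge(p, s)
    return g.has_node(metabolite_id) and nx.has_path(g, supply, metabolite_id)
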