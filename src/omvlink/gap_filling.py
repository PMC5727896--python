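"""Consistency-based gap filling against a universal reaction database.

Given a model with unconnected (non-producible or non-consumable)
metabolites, candidate reactions from a compartment-free universal
database are instantiated in the target compartment and a
minimum-cardinality subset is selected that restores connectivity of
every resolvable target.  Selection is an exact mixed-integer program
solved with HiGGS through :func:`scipy.optimize.milp`: one steady-state
flux vector per target, shared binary indicators on database reactions,
objective = number of database reactions used (with an exact
power-of-two secondary weighting for deterministic, lexicographic-style
tie-breaking).  At the instance sizes this package targets (tens of
model reactions, up to a few dozen candidates) the exact program is
fast and directly guarantees minimality.

Reversibility bookkeeping follows the two-source protocol: each
database reaction carries a thermodynamic reversibility estimate, and
optionally a curated one; after selection, curated values override the
estimates, reaction bounds are reset to the curated direction, and
target connectivity is re-checked (a target can flip back to
unconnected, which is recorded, not hidden).
"""

from __future__ import annotations

import itertools
import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import LinearConstraint, milp

from .config import AnalysisConfig, DEFAULT_CONFIG
from .model_core import (
    INF_CAP,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    add_sink,
    add_source,
    flux_variability,
    run_fba,
)

logger = logging.getLogger(__name__)

REVERSIBILITIES = ("reversible", "forward", "backward")


class GapFillError(ValueError):
    pass


@dataclass
class UniversalReaction:
    id: str
    stoichiometry: dict[str, float]  # base metabolite ids, compartment-free
    reversibility_estimate: str = "reversible"
    curated_reversibility: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise GapFillError(f"universal reaction {self.id!r} has no stoichiometry")
        for value in (self.reversibility_estimate, self.curated_reversibility):
            if value is not None and value not in REVERSIBILITIES:
                raise GapFillError(
                    f"universal reaction {self.id!r}: bad reversibility {value!r}"
                )

    def bounds(self, use_curated: bool = False) -> tuple[float, float]:
        rev = self.reversibility_estimate
        if use_curated and self.curated_reversibility is not None:
            rev = self.curated_reversibility
        if rev == "reversible":
            return -INF_CAP, INF_CAP
        if rev == "forward":
            return 0.0, INF_CAP
        return -INF_CAP, 0.0


@dataclass
class UniversalReactionDB:
    records: dict[str, UniversalReaction] = field(default_factory=dict)

    def add(self, rxn: UniversalReaction) -> None:
        if rxn.id in self.records:
            raise GapFillError(f"duplicate universal reaction id {rxn.id!r}")
        self.records[rxn.id] = rxn

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    @classmethod
    def from_tsv(cls, path) -> "UniversalReactionDB":
        df = pd.read_csv(path, sep="\t")
        db = cls()
        for _, row in df.iterrows():
            curated = row.get("curated_reversibility")
            if isinstance(curated, float) and np.isnan(curated):
                curated = None
            db.add(
                UniversalReaction(
                    id=str(row["reaction_id"]),
                    stoichiometry=parse_equation(str(row["equation"]))[0],
                    reversibility_estimate=str(row["reversibility_estimate"]),
                    curated_reversibility=curated,
                )
            )
        return db

    def to_tsv(self, path) -> None:
        rows = []
        for rxn in self.records.values():
            rows.append(
                {
                    "reaction_id": rxn.id,
                    "equation": format_equation(rxn.stoichiometry),
                    "reversibility_estimate": rxn.reversibility_estimate,
                    "curated_reversibility": rxn.curated_reversibility or "",
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_ARROWS = ("<=>", "=>", "<=")


def parse_equation(text: str) -> tuple[dict[str, float], str]:
    """Parse ``"a A + b B <=> c C"`` into stoichiometry + arrow.

    Negative coefficients are substrates.  A ``<=`` arrow is normalized
    by flipping sides so coefficients always read left-to-right.
    """
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise GapFillError(f"no reaction arrow in equation {text!r}")
    left, right = text.split(arrow, 1)
    if arrow == "<=":
        left, right = right, left
        arrow = "=>"
    stoich: dict[str, float] = {}
    for side, sign in ((left, -1.0), (right, +1.0)):
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            m = re.match(r"^(\d+(?:\.\d+)?)\s+(\S+)$", term)
            if m:
                coeff, met = float(m.group(1)), m.group(2)
            else:
                coeff, met = 1.0, term
            stoich[met] = stoich.get(met, 0.0) + sign * coeff
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    return stoich, arrow


def format_equation(stoich: Mapping[str, float]) -> str:
    def side(items):
        return " + ".join(
            (f"{abs(c):g} {m}" if abs(c) != 1.0 else m) for m, c in items
        )

    subs = sorted((m, c) for m, c in stoich.items() if c < 0)
    prods = sorted((m, c) for m, c in stoich.items() if c > 0)
    return f"{side(subs)} <=> {side(prods)}"


# ----------------------------------------------------------- connectivity


def find_blocked_reactions(
    model: MetabolicModel, epsilon: float = DEFAULT_CONFIG.consistency_epsilon
) -> set[str]:
    """Reactions unable to carry |flux| >= epsilon at steady state."""
    blocked: set[str] = set()
    ranges = flux_variability(model)
    for rid, (vmin, vmax) in ranges.items():
        if max(abs(vmin), abs(vmax)) < epsilon:
            blocked.add(rid)
    return blocked


def find_unconnected_metabolites(
    model: MetabolicModel,
    compartment: str,
    mode: str,
    epsilon: float = DEFAULT_CONFIG.flux_epsilon,
    metabolites: Optional[Iterable[str]] = None,
) -> set[str]:
    """Metabolites in a compartment that the network cannot consume/produce.

    ``consumable`` mode probes each metabolite with a temporary source
    reaction (can the network absorb it?), ``producible`` mode with a
    temporary sink.  Temporary reactions are removed afterwards.
    """
    if mode not in ("consumable", "producible"):
        raise GapFillError(f"unknown mode {mode!r}")
    if metabolites is None:
        metabolites = [
            m.id for m in model.metabolites.values() if m.compartment == compartment
        ]
    unconnected: set[str] = set()
    for mid in sorted(metabolites):
        if mid not in model.metabolites:
            raise GapFillError(f"metabolite {mid!r} not in model")
        probe = add_source(model, mid) if mode == "consumable" else add_sink(model, mid)
        try:
            res = run_fba(model, maximize=probe)
            flux = res.objective_value if res.status == "optimal" else 0.0
            if flux is None or flux < epsilon:
                unconnected.add(mid)
        finally:
            model.remove_reaction(probe)
    return unconnected


# ------------------------------------------------------------ instantiation


def instantiate_universal(
    model: MetabolicModel,
    db: UniversalReactionDB,
    compartment: str,
    use_curated: bool = False,
) -> tuple[MetabolicModel, list[str]]:
    """Copy the model and add every database reaction in one compartment.

    Metabolites absent from the model are created.  Instantiated ids are
    ``U_<reaction>__<compartment>``; returned alongside the augmented
    model in database iteration order.
    """
    out = model.copy()
    added: list[str] = []
    for urxn in db:
        stoich: dict[str, float] = {}
        for base, coeff in urxn.stoichiometry.items():
            mid = f"{base}_{compartment}"
            if mid not in out.metabolites:
                out.add_metabolite(
                    Metabolite(id=mid, base_id=base, compartment=compartment,
                               name=base)
                )
            stoich[mid] = coeff
        lb, ub = urxn.bounds(use_curated=use_curated)
        rid = f"U_{urxn.id}__{compartment}"
        out.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                origin_tag="gapfill",
            )
        )
        added.append(rid)
    return out, added


# -------------------------------------------------------------- selection


@dataclass
class GapFillResult:
    compartment: str
    mode: str
    added_reactions: list[str]  # universal db ids, sorted
    per_target: dict[str, list[str]]  # target -> enabling db reactions
    resolved: dict[str, bool]  # target -> connectivity flag after filling
    unresolved: list[str]
    reversibility_overrides: list[tuple[str, str, str, str]] = field(
        default_factory=list
    )  # (reaction, estimate, curated, final)
    model: Optional[MetabolicModel] = None  # model + selected reactions

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "compartment": self.compartment,
                    "mode": self.mode,
                    "added_reactions": self.added_reactions,
                    "per_target": self.per_target,
                    "resolved": self.resolved,
                    "unresolved": self.unresolved,
                    "reversibility_overrides": [
                        list(t) for t in self.reversibility_overrides
                    ],
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    def to_table(self) -> pd.DataFrame:
        """Per-target summary table (metabolite, reactions, flags)."""
        rows = []
        for target in sorted(self.per_target):
            rows.append(
                {
                    "metabolite": target,
                    "reactions": ";".join(self.per_target[target]),
                    "connected": self.resolved.get(target, False),
                }
            )
        for target in self.unresolved:
            rows.append({"metabolite": target, "reactions": "", "connected": False})
        return pd.DataFrame(rows, columns=["metabolite", "reactions", "connected"])


def _probe_reaction(model: MetabolicModel, target: str, mode: str) -> str:
    return (
        add_source(model, target) if mode == "consumable" else add_sink(model, target)
    )


def _milp_select(
    aug: MetabolicModel,
    candidate_ids: list[str],
    targets: list[str],
    mode: str,
    epsilon: float,
) -> Optional[list[str]]:
    """Exact minimum-cardinality selection over the candidate reactions.

    Variables: one flux vector per target (each with its own probe
    reaction already present in ``aug``) plus one binary per candidate.
    Constraints: per-target steady state, probe flux >= epsilon, and
    |v_cand| <= INF_CAP * y.  Returns the sorted db ids of the optimum or
    None when infeasible.
    """
    S, _mets, rxn_order = aug.stoichiometric_matrix()
    n = len(rxn_order)
    m_rows = S.shape[0]
    ncand = len(candidate_ids)
    ntar = len(targets)
    idx = {r: j for j, r in enumerate(rxn_order)}
    cand_idx = [idx[c] for c in candidate_ids]
    probe_ids = [
        (f"SRC_{t}" if mode == "consumable" else f"SNK_{t}") for t in targets
    ]

    nvar = ntar * n + ncand
    lb = np.empty(nvar)
    ub = np.empty(nvar)
    for t in range(ntar):
        for j, rid in enumerate(rxn_order):
            rxn = aug.reactions[rid]
            lb[t * n + j] = rxn.lower_bound
            ub[t * n + j] = rxn.upper_bound
    lb[ntar * n:] = 0.0
    ub[ntar * n:] = 1.0

    cons = []
    # steady state per target
    for t in range(ntar):
        block = sparse.hstack(
            [
                sparse.csr_matrix((m_rows, t * n)),
                S,
                sparse.csr_matrix((m_rows, (ntar - 1 - t) * n + ncand)),
            ]
        )
        cons.append(LinearConstraint(block, 0.0, 0.0))
    # probe flux >= epsilon
    probe_rows = sparse.lil_matrix((ntar, nvar))
    for t, pid in enumerate(probe_ids):
        probe_rows[t, t * n + idx[pid]] = 1.0
    cons.append(LinearConstraint(probe_rows.tocsr(), epsilon, np.inf))
    # big-M gating: v - M y <= 0 and v + M y >= 0 for every candidate/target
    gate = sparse.lil_matrix((2 * ntar * ncand, nvar))
    glb = np.empty(2 * ntar * ncand)
    gub = np.empty(2 * ntar * ncand)
    row = 0
    for t in range(ntar):
        for k, cj in enumerate(cand_idx):
            gate[row, t * n + cj] = 1.0
            gate[row, ntar * n + k] = -INF_CAP
            glb[row], gub[row] = -np.inf, 0.0
            row += 1
            gate[row, t * n + cj] = 1.0
            gate[row, ntar * n + k] = INF_CAP
            glb[row], gub[row] = 0.0, np.inf
            row += 1
    cons.append(LinearConstraint(gate.tocsr(), glb, gub))

    integrality = np.zeros(nvar)
    integrality[ntar * n:] = 1.0

    def solve(extra_cons, weights):
        c = np.zeros(nvar)
        c[ntar * n:] = weights
        res = milp(
            c=c,
            constraints=cons + extra_cons,
            integrality=integrality,
            bounds=(lb, ub),
        )
        return res

    res = solve([], np.ones(ncand))
    if not res.success:
        return None
    k = int(round(res.x[ntar * n:].sum()))
    if k == 0:
        return []
    # deterministic tie-break: fix cardinality, minimize exact binary weights
    # over lexicographically sorted candidate ids
    order = sorted(range(ncand), key=lambda i: candidate_ids[i])
    weights = np.empty(ncand)
    for rank, i in enumerate(order):
        weights[i] = float(2 ** rank)
    card_row = sparse.lil_matrix((1, nvar))
    card_row[0, ntar * n:] = 1.0
    res2 = solve([LinearConstraint(card_row.tocsr(), k, k)], weights)
    x = res2.x if res2.success else res.x
    chosen = [candidate_ids[i] for i in range(ncand) if x[ntar * n + i] > 0.5]
    return sorted(chosen)


def gap_fill(
    model: MetabolicModel,
    db: UniversalReactionDB,
    compartment: str,
    targets: Iterable[str],
    mode: str = "consumable",
    config: AnalysisConfig = DEFAULT_CONFIG,
    transporter_pool: Optional[UniversalReactionDB] = None,
) -> GapFillResult:
    """Select a minimal set of universal reactions connecting the targets.

    Targets are metabolite ids in ``compartment`` that should become
    consumable (``mode="consumable"``) or producible.  Already-connected
    targets require nothing; targets unreachable even with the full
    database are reported unresolved.  ``transporter_pool`` optionally
    supplies exporter-style reactions (instantiated as written, e.g.
    spanning compartments) that enter the same selection.
    """
    targets = sorted(set(targets))
    epsilon = config.consistency_epsilon
    missing = [t for t in targets if t not in model.metabolites]
    for t in missing:
        # target may first need creating from db metabolites
        base = t[: -len("_" + compartment)] if t.endswith("_" + compartment) else t
        if any(base in u.stoichiometry for u in db):
            continue
        raise GapFillError(f"target {t!r} absent and not creatable from the database")

    aug, _added_ids = instantiate_universal(model, db, compartment)
    candidate_ids = [f"U_{u.id}__{compartment}" for u in db]
    if transporter_pool is not None:
        for u in transporter_pool:
            stoich = {}
            for mid, coeff in u.stoichiometry.items():
                if mid not in aug.metabolites:
                    comp = mid.rsplit("_", 1)[-1]
                    if comp not in aug.compartments:
                        comp = compartment
                        mid = f"{mid}_{compartment}"
                    aug.add_metabolite(
                        Metabolite(id=mid, base_id=mid, compartment=comp, name=mid)
                    )
                stoich[mid] = coeff
            lb, ub = u.bounds()
            rid = f"U_{u.id}__transport"
            aug.add_reaction(
                Reaction(id=rid, stoichiometry=stoich, lower_bound=lb,
                         upper_bound=ub, origin_tag="gapfill")
            )
            candidate_ids.append(rid)

    still_missing = [t for t in targets if t not in aug.metabolites]
    unresolved = list(still_missing)
    targets = [t for t in targets if t in aug.metabolites]

    # which targets need filling at all / are resolvable with the full db
    need: list[str] = []
    for t in targets:
        base_ok = t in model.metabolites and not find_unconnected_metabolites(
            model, compartment, mode, config.flux_epsilon, [t]
        )
        if base_ok:
            continue
        full_ok = not find_unconnected_metabolites(
            aug, compartment, mode, config.flux_epsilon, [t]
        )
        if full_ok:
            need.append(t)
        else:
            unresolved.append(t)

    chosen: list[str] = []
    if need:
        work = aug.copy()
        for t in need:
            _probe_reaction(work, t, mode)
        chosen = _milp_select(work, sorted(candidate_ids), need, mode, epsilon)
        if chosen is None:  # pragma: no cover - guarded by per-target checks
            raise GapFillError("joint selection infeasible despite per-target checks")

    # final model: original + chosen reactions only
    final = model.copy()
    chosen_db_ids: list[str] = []
    for rid in chosen:
        rxn = aug.reactions[rid]
        for mid in rxn.stoichiometry:
            if mid not in final.metabolites:
                final.add_metabolite(aug.metabolites[mid].copy())
        final.add_reaction(rxn.copy())
        chosen_db_ids.append(_db_id(rid))

    per_target: dict[str, list[str]] = {}
    resolved: dict[str, bool] = {}
    for t in targets:
        if t in unresolved:
            continue
        if t not in final.metabolites:
            unresolved.append(t)
            continue
        ok = not find_unconnected_metabolites(
            final, compartment, mode, config.flux_epsilon, [t]
        )
        resolved[t] = ok
        per_target[t] = _enabling_reactions(final, t, mode, chosen, config)
    return GapFillResult(
        compartment=compartment,
        mode=mode,
        added_reactions=sorted(chosen_db_ids),
        per_target=per_target,
        resolved=resolved,
        unresolved=sorted(set(unresolved)),
        model=final,
    )


def _db_id(instantiated_id: str) -> str:
    body = instantiated_id[len("U_"):]
    return body.rsplit("__", 1)[0]


def _enabling_reactions(
    final: MetabolicModel,
    target: str,
    mode: str,
    chosen: list[str],
    config: AnalysisConfig,
) -> list[str]:
    """Added reactions carrying flux in the target's connectivity certificate."""
    probe = _probe_reaction(final, target, mode)
    try:
        res = run_fba(final, maximize=probe)
        if res.status != "optimal" or not res.fluxes:
            return []
        return sorted(
            _db_id(rid)
            for rid in chosen
            if abs(res.fluxes.get(rid, 0.0)) > config.flux_epsilon
        )
    finally:
        final.remove_reaction(probe)


def reconcile_reversibility(
    result: GapFillResult, db: UniversalReactionDB,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> GapFillResult:
    """Override estimated reversibilities of added reactions with curated ones.

    Bounds of every added reaction whose curated reversibility differs
    from the estimate are reset to the curated direction, overrides are
    logged, and target connectivity is recomputed -- a target whose sole
    enabling reaction flips direction is re-flagged unconnected.
    """
    if result.model is None:
        raise GapFillError("result carries no model; run gap_fill first")
    model = result.model.copy()
    overrides: list[tuple[str, str, str, str]] = []
    lookup = {u.id: u for u in db}
    for db_id in result.added_reactions:
        u = lookup.get(db_id)
        if u is None or u.curated_reversibility is None:
            continue
        if u.curated_reversibility != u.reversibility_estimate:
            rid = f"U_{u.id}__{result.compartment}"
            if rid not in model.reactions:
                continue
            lb, ub = u.bounds(use_curated=True)
            model.reactions[rid].lower_bound = lb
            model.reactions[rid].upper_bound = ub
            overrides.append(
                (u.id, u.reversibility_estimate, u.curated_reversibility,
                 u.curated_reversibility)
            )
    resolved: dict[str, bool] = {}
    per_target: dict[str, list[str]] = {}
    unresolved = list(result.unresolved)
    for t in result.resolved:
        ok = not find_unconnected_metabolites(
            model, result.compartment, result.mode, config.flux_epsilon, [t]
        )
        resolved[t] = ok
        if ok:
            per_target[t] = _enabling_reactions(
                model, t, result.mode,
                [f"U_{d}__{result.compartment}" for d in result.added_reactions
                 if f"U_{d}__{result.compartment}" in model.reactions],
                config,
            )
        else:
            per_target[t] = []
            logger.warning(
                "target %s became unconnected after reversibility reconciliation", t
            )
    return GapFillResult(
        compartment=result.compartment,
        mode=result.mode,
        added_reactions=list(result.added_reactions),
        per_target=per_target,
        resolved=resolved,
        unresolved=sorted(set(unresolved)),
        reversibility_overrides=overrides,
        model=model,
    )
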