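"""Compartmentalized stoichiometric models and flux balance analysis.

The model container is deliberately lightweight: metabolites and reactions
are plain dataclasses held in insertion-ordered dicts, and FBA is a single
LP solved with HiGHS through :func:`scipy.optimize.linprog`.  Default
compartments follow the host-microbe convention used throughout the
package: ``c``/``e`` for the microbe cell and its surroundings, ``cm``/
``em`` for the host cytosol and extracellular space, ``o`` for outer
membrane vesicles and ``lu`` for the gut lumen.

Flux bounds are kept in whatever flux units the input model uses
(g/gDW/h in the datasets this package targets) and are treated as
opaque; "unbounded" is capped at
``INF_CAP`` = 1000 flux units following common COBRA practice so every LP
stays bounded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

#: Finite stand-in for an unbounded flux bound.
INF_CAP = 1000.0

#: Default compartment ids: microbe cell/extracellular, host cytosol/
#: extracellular, OMV, lumen.
DEFAULT_COMPARTMENTS = ("c", "e", "cm", "em", "o", "lu")

ORIGIN_TAGS = frozenset(
    {"original", "omv_transport", "gapfill", "source", "sink", "exchange"}
)

SINGLETON_TAGS = frozenset({"source", "sink", "exchange"})


class ModelError(ValueError):
    """Structural problem in a metabolic model."""


@dataclass
class Metabolite:
    id: str
    base_id: str
    compartment: str
    name: str = ""
    kegg_id: Optional[str] = None
    super_pathway: Optional[str] = None
    formula: Optional[str] = None
    organism: Optional[str] = None

    def copy(self) -> "Metabolite":
        return replace(self)


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -INF_CAP
    upper_bound: float = INF_CAP
    origin_tag: str = "original"
    annotation: list[str] = field(default_factory=list)
    organism: Optional[str] = None

    def __post_init__(self) -> None:
        self.lower_bound = _cap(self.lower_bound)
        self.upper_bound = _cap(self.upper_bound)
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.origin_tag not in ORIGIN_TAGS:
            raise ModelError(
                f"reaction {self.id}: unknown origin_tag {self.origin_tag!r}"
            )
        if self.origin_tag in SINGLETON_TAGS and len(self.stoichiometry) != 1:
            raise ModelError(
                f"reaction {self.id}: {self.origin_tag} reactions must touch "
                f"exactly one metabolite"
            )

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            origin_tag=self.origin_tag,
            annotation=list(self.annotation),
            organism=self.organism,
        )


def _cap(bound: float) -> float:
    if math.isinf(bound):
        return math.copysign(INF_CAP, bound)
    return float(bound)


@dataclass
class FluxResult:
    """Outcome of one linear optimization over a model."""

    status: str  # optimal | infeasible | unbounded
    objective_value: Optional[float]
    fluxes: dict[str, float]


class MetabolicModel:
    """A compartmentalized stoichiometric network with bounds and objective."""

    def __init__(
        self,
        model_id: str = "model",
        compartments: Iterable[str] = DEFAULT_COMPARTMENTS,
    ) -> None:
        self.id = model_id
        self.compartments: set[str] = set(compartments)
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.objective_reaction_id: Optional[str] = None
        # scratch pad used by set_medium to report skipped components
        self.medium_skipped: list[str] = []

    # ---------------------------------------------------------------- build

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        if met.compartment not in self.compartments:
            raise ModelError(
                f"metabolite {met.id!r}: unknown compartment {met.compartment!r}"
            )
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ModelError(
                f"reaction {rxn.id!r} references unknown metabolites {missing}"
            )
        if not rxn.stoichiometry:
            raise ModelError(f"reaction {rxn.id!r} has empty stoichiometry")
        self.reactions[rxn.id] = rxn
        return rxn

    def remove_reaction(self, reaction_id: str) -> Reaction:
        rxn = self.reactions.pop(reaction_id)
        if self.objective_reaction_id == reaction_id:
            self.objective_reaction_id = None
        return rxn

    def set_objective(self, reaction_id: str) -> None:
        if reaction_id not in self.reactions:
            raise ModelError(f"objective reaction {reaction_id!r} not in model")
        self.objective_reaction_id = reaction_id

    # ---------------------------------------------------------------- query

    def validate(self) -> None:
        """Raise :class:`ModelError` on any violated structural invariant."""
        if self.objective_reaction_id is not None:
            if self.objective_reaction_id not in self.reactions:
                raise ModelError(
                    f"objective {self.objective_reaction_id!r} is dangling"
                )
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ModelError(
                    f"metabolite {met.id!r} in undeclared compartment "
                    f"{met.compartment!r}"
                )
        for rxn in self.reactions.values():
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelError(
                        f"reaction {rxn.id!r} references dangling {mid!r}"
                    )
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelError(f"reaction {rxn.id!r} has inverted bounds")

    def reactions_of_metabolite(self, metabolite_id: str) -> list[str]:
        return [
            r.id for r in self.reactions.values() if metabolite_id in r.stoichiometry
        ]

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.origin_tag == "exchange"]

    def stoichiometric_matrix(self):
        """Sparse S plus the row (metabolite) and column (reaction) orders."""
        met_order = list(self.metabolites)
        rxn_order = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_order)}
        rows, cols, vals = [], [], []
        for j, rid in enumerate(rxn_order):
            for mid, coeff in self.reactions[rid].stoichiometry.items():
                rows.append(met_index[mid])
                cols.append(j)
                vals.append(coeff)
        S = sparse.coo_matrix(
            (vals, (rows, cols)), shape=(len(met_order), len(rxn_order))
        ).tocsr()
        return S, met_order, rxn_order

    def copy(self) -> "MetabolicModel":
        m = MetabolicModel(self.id, self.compartments)
        for met in self.metabolites.values():
            m.metabolites[met.id] = met.copy()
        for rxn in self.reactions.values():
            m.reactions[rxn.id] = rxn.copy()
        m.objective_reaction_id = self.objective_reaction_id
        return m

    def bounds_snapshot(self) -> dict[str, tuple[float, float]]:
        return {r.id: (r.lower_bound, r.upper_bound) for r in self.reactions.values()}

    def restore_bounds(self, snapshot: Mapping[str, tuple[float, float]]) -> None:
        for rid, (lb, ub) in snapshot.items():
            rxn = self.reactions[rid]
            rxn.lower_bound = lb
            rxn.upper_bound = ub

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


# -------------------------------------------------------------------- FBA


_LP_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded"}


def _solve_lp(model: MetabolicModel, objective: dict[str, float], sense: str):
    """Optimize sum(objective[r] * v_r) s.t. S v = 0 and bounds.

    sense is "max" or "min".  Returns (status, value, flux dict).
    """
    S, _mets, rxn_order = model.stoichiometric_matrix()
    n = len(rxn_order)
    c = np.zeros(n)
    for rid, w in objective.items():
        c[rxn_order.index(rid)] = w
    if sense == "max":
        c = -c
    bounds = [
        (model.reactions[r].lower_bound, model.reactions[r].upper_bound)
        for r in rxn_order
    ]
    if n == 0:
        return "optimal", 0.0, {}
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    status = _LP_STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return status, None, {}
    value = float(res.fun if sense == "min" else -res.fun)
    fluxes = {r: float(v) for r, v in zip(rxn_order, res.x)}
    return "optimal", value, fluxes


def run_fba(
    model: MetabolicModel, maximize: Optional[str] = None
) -> FluxResult:
    """Maximize the flux of one reaction subject to steady state and bounds.

    Parameters
    ----------
    model:
        The model to optimize.
    maximize:
        Reaction id to maximize; defaults to the model's objective reaction.
    """
    target = maximize if maximize is not None else model.objective_reaction_id
    if target is None:
        raise ModelError("model has no objective and no reaction was named")
    if target not in model.reactions:
        raise ModelError(f"objective reaction {target!r} not in model")
    status, value, fluxes = _solve_lp(model, {target: 1.0}, "max")
    return FluxResult(status=status, objective_value=value, fluxes=fluxes)


def flux_variability(
    model: MetabolicModel, reaction_ids: Optional[Iterable[str]] = None
) -> dict[str, tuple[float, float]]:
    """Feasible flux range (min, max) of each reaction, no objective fixed."""
    if reaction_ids is None:
        reaction_ids = list(model.reactions)
    out: dict[str, tuple[float, float]] = {}
    for rid in reaction_ids:
        _, vmin, _ = _solve_lp(model, {rid: 1.0}, "min")
        _, vmax, _ = _solve_lp(model, {rid: 1.0}, "max")
        out[rid] = (
            vmin if vmin is not None else float("nan"),
            vmax if vmax is not None else float("nan"),
        )
    return out


# ----------------------------------------------------------- sources/sinks


def add_source(model: MetabolicModel, metabolite_id: str) -> str:
    """Add an irreversible creation pseudo-reaction for one metabolite.

    The reaction ``SRC_<metabolite>`` produces the metabolite from nothing
    with bounds [0, INF_CAP]; used to probe consumability.
    """
    return _add_boundary(model, metabolite_id, "SRC_", +1.0, "source")


def add_sink(model: MetabolicModel, metabolite_id: str) -> str:
    """Add an irreversible destruction pseudo-reaction (``SNK_<metabolite>``)."""
    return _add_boundary(model, metabolite_id, "SNK_", -1.0, "sink")


def _add_boundary(
    model: MetabolicModel,
    metabolite_id: str,
    prefix: str,
    coeff: float,
    tag: str,
) -> str:
    if metabolite_id not in model.metabolites:
        raise ModelError(f"metabolite {metabolite_id!r} not in model")
    rid = prefix + metabolite_id
    if rid in model.reactions:
        raise ModelError(f"{tag} reaction {rid!r} already exists")
    model.add_reaction(
        Reaction(
            id=rid,
            stoichiometry={metabolite_id: coeff},
            lower_bound=0.0,
            upper_bound=INF_CAP,
            origin_tag=tag,
        )
    )
    return rid


# ------------------------------------------------------------------ medium


def set_medium(
    model: MetabolicModel,
    medium: Mapping[str, float],
    mode: str = "defined",
    uptake_bound: float = 100.0,
) -> MetabolicModel:
    """Return a copy of the model with exchange uptake bounds set for a medium.

    In ``defined`` mode only exchanges of medium components get a lower
    bound of ``-uptake_bound`` and every other exchange is closed to
    uptake; in ``rich`` mode every exchange is opened (the medium mapping
    is ignored).  Medium components lacking an exchange reaction are
    skipped with a warning and listed on the returned model's
    ``medium_skipped`` attribute; concentrations are informational only.
    """
    if mode not in ("defined", "rich"):
        raise ValueError(f"unknown medium mode {mode!r}")
    out = model.copy()
    exchanges = {next(iter(r.stoichiometry)): r for r in out.exchange_reactions()}
    if not exchanges:
        raise ModelError("model has no exchange reactions")
    skipped: list[str] = []
    if mode == "rich":
        for rxn in exchanges.values():
            rxn.lower_bound = -uptake_bound
    else:
        for rxn in exchanges.values():
            rxn.lower_bound = 0.0
        for mid in medium:
            rxn = exchanges.get(mid)
            if rxn is None:
                skipped.append(mid)
                logger.warning("medium component %s has no exchange; skipped", mid)
                continue
            rxn.lower_bound = -uptake_bound
    out.medium_skipped = sorted(skipped)
    return out


def read_medium_tsv(path) -> dict[str, float]:
    """Read a medium TSV (metabolite_id, concentration[, unit])."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if "metabolite_id" not in df.columns:
        raise ValueError(f"{path}: medium table needs a metabolite_id column")
    conc = df.get("concentration", pd.Series([float("nan")] * len(df)))
    return dict(zip(df["metabolite_id"].astype(str), conc.astype(float)))
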