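"""Per-metabolite in-silico classification: essentiality, producibility,
consumability.

Protocols follow the host-microbe simulation conventions: to probe one
organism the other organism's lumen interface is closed, OMV transports
are closed so only endogenous metabolism is assessed, dietary uptake
bounds are applied at the lumen, and each metabolite is probed with a
temporary source (consumability) or sink (producibility) maximized as
the objective.  Metabolite essentiality in the microbe blocks every
reaction touching the metabolite in the cell compartment and asks
whether biomass optimization still clears the growth cutoff
(0.1 per hour by default).

All operations are transactional: they work on copies or restore bounds
afterwards, so the input model is never mutated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .config import AnalysisConfig, DEFAULT_CONFIG
from .model_core import (
    MetabolicModel,
    ModelError,
    Reaction,
    add_sink,
    add_source,
    run_fba,
    set_medium,
)

logger = logging.getLogger(__name__)


@dataclass
class DietSpec:
    """Lumen uptake bound magnitudes keyed by lumen metabolite id."""

    bounds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {m: b for m, b in self.bounds.items() if b < 0}
        if bad:
            raise ValueError(f"negative diet bounds: {bad}")

    @classmethod
    def from_tsv(cls, path) -> "DietSpec":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["metabolite_id"].astype(str),
                            df["uptake_bound"].astype(float))))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"metabolite_id": list(self.bounds),
             "uptake_bound": list(self.bounds.values())}
        ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- blocking


def block_organism(model: MetabolicModel, organism: str) -> MetabolicModel:
    """Close the lumen interface of one organism (bounds [0, 0]).

    Every reaction tagged with that organism that touches a lumen
    metabolite -- its uptake and export transports -- is closed, so no
    mass can move between the lumen and that organism.
    """
    known = {r.organism for r in model.reactions.values() if r.organism}
    if organism not in known:
        raise ModelError(f"unknown organism tag {organism!r}; model has {sorted(known)}")
    out = model.copy()
    lumen_mets = {
        m.id for m in out.metabolites.values() if m.compartment == "lu"
    }
    for rxn in out.reactions.values():
        if rxn.organism == organism and lumen_mets & set(rxn.stoichiometry):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def block_omv(model: MetabolicModel) -> MetabolicModel:
    """Close every OMV transport reaction (bounds [0, 0])."""
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.origin_tag == "omv_transport":
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def apply_diet(
    model: MetabolicModel, diet: DietSpec,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> MetabolicModel:
    """Set lumen exchange lower bounds to the diet's uptake magnitudes.

    Exchanges absent from the diet are closed to uptake; diet entries
    with no exchange reaction are skipped with a warning.
    """
    out = model.copy()
    exchanges = {
        next(iter(r.stoichiometry)): r for r in out.exchange_reactions()
    }
    for rxn in exchanges.values():
        rxn.lower_bound = 0.0
    skipped = []
    for mid, bound in diet.bounds.items():
        rxn = exchanges.get(mid)
        if rxn is None:
            skipped.append(mid)
            logger.warning("diet metabolite %s has no exchange; skipped", mid)
            continue
        rxn.lower_bound = -bound
    out.medium_skipped = sorted(skipped)
    return out


def prepare_condition(
    model: MetabolicModel,
    organism: str,
    diet: Optional[DietSpec] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> MetabolicModel:
    """Model configured to probe one organism's endogenous metabolism.

    Blocks the other organism(s) at the lumen, closes OMV transports and
    applies the diet.
    """
    out = model
    others = {
        r.organism for r in model.reactions.values() if r.organism
    } - {organism}
    for other in sorted(others):
        out = block_organism(out, other)
    out = block_omv(out)
    if diet is not None:
        out = apply_diet(out, diet, config)
    return out


# ------------------------------------------------------ classification ops


def classify_consumability(
    model: MetabolicModel,
    metabolite: str,
    organism: str,
    diet: Optional[DietSpec] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
    prepared: bool = False,
) -> tuple[bool, float]:
    """Can the organism consume the metabolite? (max source flux probe).

    Adds a temporary source on the metabolite, maximizes it, and calls
    the metabolite consumable iff the optimum exceeds
    ``config.flux_epsilon``.  Unless ``prepared``, the other organism and
    the OMV route are blocked and the diet applied first.
    """
    return _classify(model, metabolite, organism, diet, config, prepared, "source")


def classify_producibility(
    model: MetabolicModel,
    metabolite: str,
    organism: str,
    diet: Optional[DietSpec] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
    prepared: bool = False,
) -> tuple[bool, float]:
    """Can the organism produce the metabolite? (max sink flux probe)."""
    return _classify(model, metabolite, organism, diet, config, prepared, "sink")


def _classify(model, metabolite, organism, diet, config, prepared, kind):
    if metabolite not in model.metabolites:
        raise ModelError(f"metabolite {metabolite!r} not in model")
    work = model if prepared else prepare_condition(model, organism, diet, config)
    if work is model:
        work = model.copy()
    probe = add_source(work, metabolite) if kind == "source" else add_sink(
        work, metabolite
    )
    res = run_fba(work, maximize=probe)
    flux = res.objective_value if res.status == "optimal" else 0.0
    flux = flux if flux is not None else 0.0
    return flux > config.flux_epsilon, float(flux)


def apply_observed_uptake(
    model: MetabolicModel,
    imported_metabolites: Iterable[str],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> MetabolicModel:
    """Force a small minimum uptake for metabolites observed to be imported.

    Each metabolite gains a source reaction with lower bound
    ``config.forced_uptake_min`` and upper bound
    ``config.medium_uptake_bound``, restricting the solver to solutions
    consistent with the qualitative uptake profile.
    """
    out = model.copy()
    for mid in sorted(set(imported_metabolites)):
        rid = add_source(out, mid)
        out.reactions[rid].lower_bound = config.forced_uptake_min
        out.reactions[rid].upper_bound = config.medium_uptake_bound
    return out


def metabolite_essentiality(
    model: MetabolicModel,
    metabolite: str,
    medium: Optional[Mapping[str, float]] = None,
    imported_set: Iterable[str] = (),
    config: AnalysisConfig = DEFAULT_CONFIG,
    medium_mode: str = "defined",
    objective: Optional[str] = None,
    cell_compartment: str = "c",
) -> tuple[bool, float]:
    """Is a cell metabolite essential for in-silico growth?

    All reactions whose stoichiometry includes the metabolite in the
    cell compartment are closed, biomass is maximized, and the
    metabolite is essential iff growth falls below
    ``config.growth_cutoff`` (an infeasible knockout counts as zero
    growth).  The medium and the forced-uptake set are applied before
    the knockout.
    """
    if metabolite not in model.metabolites:
        raise ModelError(f"metabolite {metabolite!r} not in model")
    if model.metabolites[metabolite].compartment != cell_compartment:
        raise ModelError(
            f"metabolite {metabolite!r} is not in the {cell_compartment!r} compartment"
        )
    work = model
    if medium is not None:
        work = set_medium(work, medium, medium_mode, config.medium_uptake_bound)
    if imported_set:
        work = apply_observed_uptake(work, imported_set, config)
    if work is model:
        work = model.copy()
    for rxn in work.reactions.values():
        if metabolite in rxn.stoichiometry:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    res = run_fba(work, maximize=objective)
    growth = res.objective_value if res.status == "optimal" else 0.0
    growth = growth if growth is not None else 0.0
    return growth < config.growth_cutoff, float(growth)


# --------------------------------------------------------------- sweeps


def run_classification_sweep(
    model: MetabolicModel,
    metabolite_sets: Mapping[str, Iterable[str]],
    conditions: Mapping[str, dict],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Batch driver over (metabolite, organism, condition) combinations.

    ``metabolite_sets`` maps organism -> metabolite ids to classify;
    ``conditions`` maps condition name -> keyword dict (``diet``,
    ``essential_objective``, ``medium``, ``imported_set``).  Returns a
    tidy ClassificationTable with the supporting objective values so
    every flag is re-derivable.
    """
    rows = []
    for cond_name in sorted(conditions):
        cond = conditions[cond_name]
        diet = cond.get("diet")
        for organism in sorted(metabolite_sets):
            prepared = prepare_condition(model, organism, diet, config)
            for mid in sorted(set(metabolite_sets[organism])):
                if mid not in model.metabolites:
                    logger.warning("sweep: metabolite %s not in model; skipped", mid)
                    continue
                consumable, src_flux = classify_consumability(
                    prepared, mid, organism, config=config, prepared=True
                )
                producible, snk_flux = classify_producibility(
                    prepared, mid, organism, config=config, prepared=True
                )
                essential = None
                growth = None
                ess_obj = cond.get("essential_objective", {}).get(organism)
                if ess_obj is not None and model.metabolites[mid].compartment == "c":
                    essential, growth = metabolite_essentiality(
                        model,
                        mid,
                        medium=cond.get("medium"),
                        imported_set=cond.get("imported_set", ()),
                        config=config,
                        medium_mode=cond.get("medium_mode", "defined"),
                        objective=ess_obj,
                    )
                rows.append(
                    {
                        "metabolite": mid,
                        "organism": organism,
                        "condition": cond_name,
                        "consumable": consumable,
                        "max_source_flux": src_flux,
                        "producible": producible,
                        "max_sink_flux": snk_flux,
                        "essential": essential,
                        "growth": growth,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "metabolite",
            "organism",
            "condition",
            "consumable",
            "max_source_flux",
            "producible",
            "max_sink_flux",
            "essential",
            "growth",
        ],
    )
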