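"""Synthetic fixtures with known ground truth for every pipeline stage.

These generators stand in for the inputs a real vesicle-cargo
analysis would use but which are rarely redistributable: an integrated
microbe-host genome-scale model, a KEGG-style universal reaction set,
and a replicate-level untargeted metabolomics table.
Each generator is a pure function of its parameters and seed
(numpy PCG64 via :func:`numpy.random.default_rng`) and returns a
:class:`SyntheticTruth` recording exactly what was planted, so tests
can score recovery instead of eyeballing.

Model anatomy (per organism): lumen nutrients with exchange reactions,
uptake transports into the organism's extracellular compartment, a
transport into the cytosol, and a three-step linear pathway to a
biomass precursor; biomass consumes every precursor.  A configurable
fraction of pathways gets a redundant parallel branch, making their
intermediates non-essential by construction.  On top of this skeleton
the generator plants the special cases the analyses probe: metabolites
the microbe exports directly to the lumen (host-importable), vesicle
cargo with no direct route (host-reachable only via OMVs),
produced-but-never-consumed metabolites (the creatinine pattern), and
consumed-but-never-produced ones.

Two small curated reference tables (a gap-fill summary of vesicle
cargo metabolites and a defined-medium recipe) are shipped as TSV
package-data fixtures with loaders here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig, DEFAULT_CONFIG
from .fba_analyses import DietSpec
from .gap_filling import UniversalReaction, UniversalReactionDB
from .model_core import (
    INF_CAP,
    MetabolicModel,
    Metabolite,
    Reaction,
)
from .omv_expansion import HOST, MICROBE, IdDictionary

SUPER_PATHWAYS = (
    "Amino acid",
    "Carbohydrate",
    "Cofactors and vitamins",
    "Energy",
    "Lipid",
    "Nucleotide",
    "Peptide",
    "Xenobiotics",
)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators."""

    seed: int
    params: dict = field(default_factory=dict)
    essential: dict[str, set[str]] = field(default_factory=dict)
    nonessential: dict[str, set[str]] = field(default_factory=dict)
    consumable: dict[str, dict[str, bool]] = field(default_factory=dict)
    producible: dict[str, dict[str, bool]] = field(default_factory=dict)
    direct_export: set[str] = field(default_factory=set)  # base ids
    omv_only: set[str] = field(default_factory=set)  # base ids
    omv_cargo: set[str] = field(default_factory=set)  # base ids
    gapfill_minimal: dict[str, set[str]] = field(default_factory=dict)
    gapfill_targets: list[str] = field(default_factory=list)
    reconcile_flips: set[str] = field(default_factory=set)  # targets lost
    presence: dict[tuple, bool] = field(default_factory=dict)
    exported: dict[str, set[str]] = field(default_factory=dict)
    kegg_mapped: set[str] = field(default_factory=set)
    super_pathway: dict[str, str] = field(default_factory=dict)
    enriched_pathway: Optional[str] = None
    query_set: set[str] = field(default_factory=set)


# ------------------------------------------------------------------ model


def make_host_microbe_model(
    n_core_pathways: int = 3,
    n_shared_lumen_nutrients: int = 1,
    redundancy_fraction: float = 0.0,
    seed: int = 0,
    n_direct_export: int = 2,
    n_omv_only: int = 2,
    prerelocalized: bool = True,
) -> tuple[MetabolicModel, SyntheticTruth]:
    """Two lumen-coupled organisms with planted classification truth.

    With ``prerelocalized=False`` the host is emitted in the generic
    ``c``/``e`` compartments (organism-tagged) so the relocalization
    operation can be exercised; ids stay distinct because host and
    microbe entities carry different base names.
    """
    if n_core_pathways < 1:
        raise ValueError("n_core_pathways must be >= 1")
    if not 0.0 <= redundancy_fraction <= 1.0:
        raise ValueError("redundancy_fraction must lie in [0, 1]")
    if min(n_shared_lumen_nutrients, n_direct_export, n_omv_only) < 0:
        raise ValueError("counts must be non-negative")

    truth = SyntheticTruth(
        seed=seed,
        params=dict(
            n_core_pathways=n_core_pathways,
            n_shared_lumen_nutrients=n_shared_lumen_nutrients,
            redundancy_fraction=redundancy_fraction,
            n_direct_export=n_direct_export,
            n_omv_only=n_omv_only,
            prerelocalized=prerelocalized,
        ),
    )
    model = MetabolicModel(f"synthetic_host_microbe_{seed}")
    n_redundant = int(round(redundancy_fraction * n_core_pathways))

    def met(mid, comp, organism=None, name=""):
        if mid not in model.metabolites:
            base = mid[: -(len(comp) + 1)] if mid.endswith("_" + comp) else mid
            model.add_metabolite(
                Metabolite(id=mid, base_id=base, compartment=comp,
                           name=name or mid, organism=organism)
            )
        return mid

    def rxn(rid, stoich, lb, ub, organism=None, tag="original"):
        model.add_reaction(
            Reaction(id=rid, stoichiometry=stoich, lower_bound=lb,
                     upper_bound=ub, origin_tag=tag, organism=organism)
        )
        return rid

    organisms = {
        MICROBE: ("c", "e", "b"),
        HOST: ("cm", "em", "h") if prerelocalized else ("c", "e", "h"),
    }

    for org, (cyt, ext, sfx) in organisms.items():
        truth.essential[org] = set()
        truth.nonessential[org] = set()
        truth.consumable[org] = {}
        truth.producible[org] = {}
        precursors = []
        for p in range(n_core_pathways):
            base = f"nut{p}{sfx}"
            lu = met(f"{base}_lu", "lu")
            exl = met(f"{base}_{ext}", ext, org)
            cy = met(f"{base}_{cyt}", cyt, org)
            rxn(f"EX_{base}_lu", {lu: -1.0}, -INF_CAP, INF_CAP, tag="exchange")
            rxn(f"TU_{base}", {lu: -1.0, exl: 1.0}, -INF_CAP, INF_CAP, org)
            rxn(f"TC_{base}", {exl: -1.0, cy: 1.0}, -INF_CAP, INF_CAP, org)
            ia = met(f"i{p}a{sfx}_{cyt}", cyt, org)
            ib = met(f"i{p}b{sfx}_{cyt}", cyt, org)
            prec = met(f"prec{p}{sfx}_{cyt}", cyt, org)
            rxn(f"P{p}R1{sfx}", {cy: -1.0, ia: 1.0}, 0.0, INF_CAP, org)
            rxn(f"P{p}R2{sfx}", {ia: -1.0, ib: 1.0}, 0.0, INF_CAP, org)
            rxn(f"P{p}R3{sfx}", {ib: -1.0, prec: 1.0}, 0.0, INF_CAP, org)
            precursors.append(prec)
            redundant = p < n_redundant
            if redundant:
                ja = met(f"j{p}a{sfx}_{cyt}", cyt, org)
                rxn(f"P{p}RA{sfx}", {cy: -1.0, ja: 1.0}, 0.0, INF_CAP, org)
                rxn(f"P{p}RB{sfx}", {ja: -1.0, prec: 1.0}, 0.0, INF_CAP, org)
                truth.nonessential[org] |= {ia, ib}
            else:
                truth.essential[org] |= {ia, ib}
            for mid in (ia, ib, prec):
                truth.consumable[org][mid] = True
                truth.producible[org][mid] = True
        # waste route: cytosol -> extracellular -> lumen -> boundary
        waste_c = met(f"w{sfx}_{cyt}", cyt, org)
        waste_e = met(f"w{sfx}_{ext}", ext, org)
        waste_lu = met(f"w{sfx}_lu", "lu")
        rxn(f"TWX_{sfx}", {waste_c: -1.0, waste_e: 1.0}, 0.0, INF_CAP, org)
        rxn(f"TWL_{sfx}", {waste_e: -1.0, waste_lu: 1.0}, 0.0, INF_CAP, org)
        rxn(f"EX_w{sfx}_lu", {waste_lu: -1.0}, 0.0, INF_CAP, tag="exchange")
        # produced-but-never-consumed metabolite (creatinine pattern)
        crtn = met(f"crtnlike{sfx}_{cyt}", cyt, org)
        rxn(f"CRTN{sfx}", {f"nut0{sfx}_{cyt}": -1.0, crtn: 1.0}, 0.0, INF_CAP, org)
        truth.producible[org][crtn] = True
        truth.consumable[org][crtn] = False
        rxn(
            f"BIOMASS_{sfx.upper()}",
            {m: -1.0 for m in precursors},
            0.0,
            INF_CAP,
            org,
        )

    mic_cyt, mic_ext, _ = organisms[MICROBE]
    host_cyt, host_ext, hsfx = organisms[HOST]

    for q in range(n_shared_lumen_nutrients):
        base = f"snut{q}"
        lu = met(f"{base}_lu", "lu")
        rxn(f"EX_{base}_lu", {lu: -1.0}, -INF_CAP, INF_CAP, tag="exchange")
        for org, (cyt, ext, sfx) in organisms.items():
            exl = met(f"{base}{sfx}_{ext}", ext, org)
            cy = met(f"{base}{sfx}_{cyt}", cyt, org)
            rxn(f"TU_{base}{sfx}", {lu: -1.0, exl: 1.0}, -INF_CAP, INF_CAP, org)
            rxn(f"TC_{base}{sfx}", {exl: -1.0, cy: 1.0}, -INF_CAP, INF_CAP, org)
            rxn(f"SCONS_{base}{sfx}", {cy: -1.0, f"w{sfx}_{cyt}": 1.0},
                0.0, INF_CAP, org)

    # microbe metabolites exported directly to the lumen and host-importable;
    # their host-side species are host-specific by construction, so they sit
    # in cm/em even when the rest of the host still awaits relocalization
    for k in range(n_direct_export):
        base = f"dex{k}"
        truth.direct_export.add(base)
        truth.omv_cargo.add(base)
        c = met(f"{base}_c", "c", MICROBE)
        e = met(f"{base}_e", "e", MICROBE)
        lu = met(f"{base}_lu", "lu")
        cm = met(f"{base}_cm", "cm", HOST)
        em = met(f"{base}_em", "em", HOST)
        rxn(f"DPROD_{base}", {"nut0b_c": -1.0, c: 1.0}, 0.0, INF_CAP, MICROBE)
        rxn(f"DEXP_{base}", {c: -1.0, e: 1.0}, 0.0, INF_CAP, MICROBE)
        rxn(f"DEXL_{base}", {e: -1.0, lu: 1.0}, 0.0, INF_CAP, MICROBE)
        rxn(f"EX_{base}_lu", {lu: -1.0}, 0.0, INF_CAP, tag="exchange")
        rxn(f"DIMP_{base}", {lu: -1.0, em: 1.0}, 0.0, INF_CAP, HOST)
        rxn(f"DIMC_{base}", {em: -1.0, cm: 1.0}, 0.0, INF_CAP, HOST)
        rxn(f"DCONS_{base}", {cm: -1.0, f"w{hsfx}_{host_cyt}": 1.0},
            0.0, INF_CAP, HOST)
        truth.consumable[HOST][cm] = True
        truth.producible[HOST][cm] = False  # needs import; blocked endogenously

    # vesicle cargo with no direct export route: host-reachable only via OMVs
    for k in range(n_omv_only):
        base = f"vonly{k}"
        truth.omv_only.add(base)
        truth.omv_cargo.add(base)
        c = met(f"{base}_c", "c", MICROBE)
        cm = met(f"{base}_cm", "cm", HOST)
        rxn(f"VPROD_{base}", {"nut0b_c": -1.0, c: 1.0}, 0.0, INF_CAP, MICROBE)
        rxn(f"VCONS_{base}", {cm: -1.0, f"w{hsfx}_{host_cyt}": 1.0},
            0.0, INF_CAP, HOST)
        truth.consumable[HOST][cm] = True
        truth.producible[HOST][cm] = False

    model.set_objective("BIOMASS_B")
    model.validate()
    return model, truth


def microbe_medium(model: MetabolicModel) -> dict[str, float]:
    """Defined-medium stand-in: every lumen nutrient the skeleton declares."""
    return {
        m.id: 1.0
        for m in model.metabolites.values()
        if m.compartment == "lu" and (
            m.base_id.startswith("nut") or m.base_id.startswith("snut")
        )
    }


def western_diet(model: MetabolicModel, uptake: float = 10.0) -> DietSpec:
    """Diet stand-in: uniform uptake bound on every lumen nutrient."""
    return DietSpec({mid: uptake for mid in microbe_medium(model)})


# --------------------------------------------------------------- gap fill


def make_gapfill_instance(
    model: MetabolicModel,
    n_gaps: int = 2,
    n_decoys: int = 5,
    seed: int = 0,
    n_two_step: int = 0,
    n_reversibility_conflicts: int = 0,
    compartment: str = "cm",
) -> tuple[MetabolicModel, UniversalReactionDB, SyntheticTruth]:
    """Plant unconnected target metabolites and a database that fixes them.

    Each single-step target ``gap<k>`` is a new, reaction-less metabolite
    in ``compartment``; the database holds the unique reaction that
    degrades it into the host waste pool, plus decoys over fresh base
    metabolites (trivially mass-balanced dead ends that can never stand
    in for a planted reaction).  Two-step targets need a chain of two
    database reactions.  ``n_reversibility_conflicts`` of the planted
    single-step reactions get a curated reversibility opposing the
    estimate, so reconciliation flips their target back to unconnected.
    Planted minimal sets are verified at generation time: every planted
    reaction is necessary for its target (full database minus it fails)
    and the planted set is sufficient, so it is the unique minimum.
    """
    if n_reversibility_conflicts > n_gaps:
        raise ValueError("cannot plant more conflicts than single-step gaps")
    out = model.copy()
    db = UniversalReactionDB()
    truth = SyntheticTruth(
        seed=seed,
        params=dict(n_gaps=n_gaps, n_decoys=n_decoys, n_two_step=n_two_step,
                    n_reversibility_conflicts=n_reversibility_conflicts),
    )
    waste_base = next(
        (m.base_id for m in out.metabolites.values()
         if m.compartment == compartment and m.base_id.startswith("w")),
        None,
    )
    if waste_base is None:
        raise ValueError(f"model has no waste pool in {compartment!r}")

    for k in range(n_gaps):
        base = f"gap{k}"
        mid = f"{base}_{compartment}"
        out.add_metabolite(
            Metabolite(id=mid, base_id=base, compartment=compartment, name=base)
        )
        rid = f"TGR{k:02d}"
        conflicted = k < n_reversibility_conflicts
        db.add(
            UniversalReaction(
                id=rid,
                stoichiometry={base: -1.0, waste_base: 1.0},
                reversibility_estimate="forward",
                # curated direction opposes the estimate: reaction can then
                # only produce the target, never consume it
                curated_reversibility="backward" if conflicted else None,
            )
        )
        truth.gapfill_targets.append(mid)
        truth.gapfill_minimal[mid] = {rid}
        if conflicted:
            truth.reconcile_flips.add(mid)

    for k in range(n_two_step):
        base = f"gap2_{k}"
        inter = f"gap2i_{k}"
        mid = f"{base}_{compartment}"
        out.add_metabolite(
            Metabolite(id=mid, base_id=base, compartment=compartment, name=base)
        )
        r1, r2 = f"TGS{k:02d}a", f"TGS{k:02d}b"
        db.add(UniversalReaction(r1, {base: -1.0, inter: 1.0}, "forward"))
        db.add(UniversalReaction(r2, {inter: -1.0, waste_base: 1.0}, "forward"))
        truth.gapfill_targets.append(mid)
        truth.gapfill_minimal[mid] = {r1, r2}

    rng = np.random.default_rng(seed)
    for j in range(n_decoys):
        rev = ("reversible", "forward", "backward")[int(rng.integers(3))]
        db.add(
            UniversalReaction(
                id=f"DECOY{j:02d}",
                stoichiometry={f"dx{j}a": -1.0, f"dx{j}b": 1.0},
                reversibility_estimate=rev,
            )
        )

    if len(db) <= 12:
        _verify_gapfill_truth(out, db, truth, compartment)
    return out, db, truth


def _verify_gapfill_truth(model, db, truth, compartment) -> None:
    from .gap_filling import find_unconnected_metabolites, instantiate_universal

    planted = sorted({r for s in truth.gapfill_minimal.values() for r in s})
    # sufficiency of the planted set
    subset = UniversalReactionDB()
    for u in db:
        if u.id in planted:
            subset.add(u)
    aug, _ = instantiate_universal(model, subset, compartment)
    bad = find_unconnected_metabolites(
        aug, compartment, "consumable", metabolites=truth.gapfill_targets
    )
    if bad:
        raise AssertionError(f"planted set insufficient for {sorted(bad)}")
    # necessity of every planted reaction
    for target, needed in truth.gapfill_minimal.items():
        for rid in needed:
            reduced = UniversalReactionDB()
            for u in db:
                if u.id != rid:
                    reduced.add(u)
            aug, _ = instantiate_universal(model, reduced, compartment)
            still = find_unconnected_metabolites(
                aug, compartment, "consumable", metabolites=[target]
            )
            if target not in still:
                raise AssertionError(
                    f"planted reaction {rid} not necessary for {target}"
                )


# ------------------------------------------------------------ metabolomics


def make_metabolomics_table(
    n_metabolites: int = 60,
    media: tuple[str, ...] = ("RM", "DM"),
    compartments: tuple[str, ...] = ("cell", "medium", "OMV"),
    timepoints: tuple[str, ...] = ("TP1", "TP2"),
    detect_prob_present: float = 1.0,
    false_detect_prob: float = 0.0,
    n_replicates: int = 3,
    frac_kegg_mapped: float = 0.7,
    frac_exported: float = 0.2,
    frac_depleted: float = 0.85,
    export_effect_size: float = 5.0,
    noise_sd: float = 1.0,
    blank_mean: float = 10.0,
    seed: int = 0,
    kegg_ids: Optional[list[str]] = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Replicate-level metabolomics stand-in with planted presence/export.

    Emulates a 3-replicate untargeted panel across two media, three
    compartments and two time points (OMV preparations are pooled over
    growth, time ``NA``), with pre-inoculation blanks for the medium
    compartment.  Presence truth is drawn per (metabolite, sample) with
    OMV presence nested inside cell presence per medium; detection noise
    is Bernoulli around the truth.

    The medium compartment emulates what growth does to spent medium:
    exported products are absent from the blank, appear at a low level
    at TP1 and reach ``export_effect_size`` noise standard deviations at
    TP2; a fraction ``frac_depleted`` of the medium's own components are
    consumed (falling by the same magnitude by TP2); only the remainder
    stays flat.  Flat profiles being the minority mirrors how strongly
    batch growth reshapes medium composition.

    When ``kegg_ids`` is given (e.g. the keys of a model dictionary),
    mapped metabolites draw their KEGG ids from it in order, so presence
    sets can be joined onto a model through that dictionary.
    """
    for name, p in (
        ("detect_prob_present", detect_prob_present),
        ("false_detect_prob", false_detect_prob),
        ("frac_kegg_mapped", frac_kegg_mapped),
        ("frac_exported", frac_exported),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(
        seed=seed,
        params=dict(
            n_metabolites=n_metabolites,
            detect_prob_present=detect_prob_present,
            false_detect_prob=false_detect_prob,
            n_replicates=n_replicates,
            frac_kegg_mapped=frac_kegg_mapped,
            frac_exported=frac_exported,
            export_effect_size=export_effect_size,
            noise_sd=noise_sd,
        ),
    )
    mets = [f"met{i:04d}" for i in range(n_metabolites)]
    mapped = rng.random(n_metabolites) < frac_kegg_mapped
    pathways = rng.choice(len(SUPER_PATHWAYS), size=n_metabolites)
    exported_mask = rng.random(n_metabolites) < frac_exported
    for i, mid in enumerate(mets):
        truth.super_pathway[mid] = SUPER_PATHWAYS[pathways[i]]
        if mapped[i]:
            truth.kegg_mapped.add(mid)

    samples: list[tuple[str, str, Optional[str]]] = []
    for medium in media:
        for comp in compartments:
            if comp == "OMV":
                samples.append((medium, comp, "NA"))
            else:
                for tp in timepoints:
                    samples.append((medium, comp, tp))
        samples.append((medium, "medium", "blank"))

    # presence truth: cell presence per medium, OMV nested within cell
    cell_present = {
        medium: rng.random(n_metabolites) < (0.7 if medium == "RM" else 0.5)
        for medium in media
    }
    omv_present = {
        medium: cell_present[medium] & (rng.random(n_metabolites) < 0.6)
        for medium in media
    }
    # medium-compartment fate: component of the uninoculated medium
    # (depleted or flat during growth) or a growth product exported to it
    medium_component = {
        medium: rng.random(n_metabolites) < 0.4 for medium in media
    }
    is_exported = {
        medium: exported_mask & ~medium_component[medium] for medium in media
    }
    is_depleted = {
        medium: medium_component[medium]
        & (rng.random(n_metabolites) < frac_depleted)
        for medium in media
    }
    effect = export_effect_size * noise_sd
    for medium in media:
        truth.exported[medium] = {
            mets[i] for i in range(n_metabolites) if is_exported[medium][i]
        }

    kegg_pool = list(kegg_ids) if kegg_ids else []
    next_kegg = iter(kegg_pool)
    rows = []
    for i, mid in enumerate(mets):
        if mapped[i]:
            kegg = next(next_kegg, None) or f"C9{i:04d}"
        else:
            kegg = None
        sp = truth.super_pathway[mid]
        for medium, comp, tp in samples:
            base_level = blank_mean
            if comp == "cell":
                present = bool(cell_present[medium][i])
            elif comp == "OMV":
                present = bool(omv_present[medium][i])
            elif is_exported[medium][i]:
                # growth product: absent from the blank, accumulating
                present = tp != "blank"
                base_level = {"TP1": 2.0 * noise_sd, "TP2": effect}.get(tp, 0.0)
            elif medium_component[medium][i]:
                present = True
                if is_depleted[medium][i]:
                    base_level = blank_mean - {
                        "blank": 0.0, "TP1": 0.4 * effect, "TP2": effect,
                    }[tp]
            else:
                present = False
            if tp != "blank":
                truth.presence[(mid, medium, comp, tp)] = present
            for rep in range(1, n_replicates + 1):
                detected = (
                    rng.random() < detect_prob_present
                    if present
                    else rng.random() < false_detect_prob
                )
                if detected:
                    intensity = max(
                        float(rng.normal(base_level, noise_sd)), 1e-3
                    )
                else:
                    intensity = np.nan
                rows.append(
                    {
                        "metabolite_id": mid,
                        "name": mid,
                        "kegg_id": kegg,
                        "super_pathway": sp,
                        "medium": medium,
                        "compartment": comp,
                        "time": tp,
                        "replicate": rep,
                        "intensity": intensity,
                    }
                )
    table = pd.DataFrame(rows)
    return table, truth


# -------------------------------------------------------------- annotation


def make_annotation_bundle(
    model: MetabolicModel,
    n_pathways: int = 5,
    enrichment_factor: float = 1.0,
    seed: int = 0,
    frac_mapped: float = 1.0,
    query_size: int = 12,
    pathway_size: int = 12,
    n_extra_background: int = 60,
    diet_uptake: float = 10.0,
) -> tuple[IdDictionary, dict[str, set[str]], DietSpec, SyntheticTruth]:
    """Dictionary, pathway annotation and diet consistent with a model.

    The dictionary maps synthetic KEGG compound ids onto a fraction of
    the model's base metabolite ids.  Pathway annotations span those
    plus ``n_extra_background`` additional mapped compounds -- real
    pathway databases cover far more compounds than any one model, and
    the enrichment background must reflect that.  ``enrichment_factor``
    is the relative rate of first-pathway members among query draws:
    each query slot is a member of the planted pathway with probability
    ``factor * pathway_rate`` (capped below 1), so factor 1 reduces to
    uniform sampling and larger factors plant a genuine f-fold
    over-representation.
    """
    rng = np.random.default_rng(seed)
    bases = sorted({m.base_id for m in model.metabolites.values()})
    n_mapped = int(round(frac_mapped * len(bases)))
    order = rng.permutation(len(bases))
    mapped_bases = [bases[i] for i in sorted(order[:n_mapped])]
    mapped_bases += [f"bg{j:03d}" for j in range(n_extra_background)]
    entries = {f"C8{i:04d}": b for i, b in enumerate(mapped_bases)}
    dictionary = IdDictionary(entries, {k: "base" for k in entries})

    truth = SyntheticTruth(
        seed=seed,
        params=dict(n_pathways=n_pathways, enrichment_factor=enrichment_factor,
                    frac_mapped=frac_mapped, query_size=query_size,
                    pathway_size=pathway_size),
    )
    truth.kegg_mapped = set(mapped_bases)

    pathways: dict[str, set[str]] = {}
    universe = list(mapped_bases)
    for p in range(n_pathways):
        size = min(pathway_size, len(universe))
        members = rng.choice(len(universe), size=size, replace=False)
        pathways[f"path{p:02d}"] = {universe[i] for i in members}

    query: set[str] = set()
    if universe and query_size > 0:
        planted = sorted(pathways.get("path00", set()))
        others = sorted(set(universe) - set(planted))
        n_query = min(query_size, len(universe))
        rate = min(0.95, enrichment_factor * len(planted) / len(universe))
        k = int(rng.binomial(n_query, rate))
        k = min(k, len(planted))
        n_other = min(n_query - k, len(others))
        member_pick = rng.choice(len(planted), size=k, replace=False)
        other_pick = rng.choice(len(others), size=n_other, replace=False)
        query = {planted[i] for i in member_pick} | {
            others[i] for i in other_pick
        }
    truth.query_set = query
    if enrichment_factor > 1.0:
        truth.enriched_pathway = "path00"

    diet = western_diet(model, uptake=diet_uptake)
    return dictionary, pathways, diet, truth


# ------------------------------------------------------ printed fixtures


def load_gapfill_reference_table() -> pd.DataFrame:
    """The transcribed gap-fill reference table (17 OMV metabolites).

    Columns: bigg_id, name, reaction, reversibility (R reversible /
    I irreversible as printed), producible / consumable flags after
    reversibility reconciliation, enzyme annotation (curated input, not
    computed).  Metabolites connected by two reactions span two rows.
    """
    with resources.files("omvlink.data").joinpath(
        "gapfill_reference.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"enzyme": "string"})


def load_defined_medium_table() -> pd.DataFrame:
    """The defined-medium recipe fixture (compound, concentration, unit)."""
    with resources.files("omvlink.data").joinpath(
        "defined_medium.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
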