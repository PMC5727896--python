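"""Transforming a host-microbe model into its OMV-enabled counterpart.

The expansion mirrors the construction of the integrated
microbe-mouse-OMV model: host entities are moved out of the generic
``c``/``e`` compartments into host-specific ``cm``/``em``, a vesicle
compartment ``o`` is added, and every vesicle-cargo metabolite gains a
pair of irreversible transport reactions -- one packing it from the
microbe cell into the vesicle (``c -> o``) and one delivering it from
the vesicle to the host cytosol (``o -> cm``).  Cargo metabolites not
observed in a given growth medium can then be switched off per medium.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .model_core import (
    INF_CAP,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
)

logger = logging.getLogger(__name__)

HOST = "host"
MICROBE = "microbe"


class DictionaryError(ValueError):
    pass


@dataclass
class IdDictionary:
    """Bidirectional KEGG <-> BiGG identifier mapping with provenance.

    ``entries`` maps kegg_id -> bigg_id; each entry carries a provenance
    tag (``base`` for the bundled dictionary, ``manual`` for curated
    additions, which win on conflict during merges).
    """

    entries: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._check_invariants()

    def _check_invariants(self) -> None:
        seen_bigg: dict[str, str] = {}
        for kegg, bigg in self.entries.items():
            if bigg in seen_bigg:
                raise DictionaryError(
                    f"bigg id {bigg!r} mapped from both {seen_bigg[bigg]!r} "
                    f"and {kegg!r}"
                )
            seen_bigg[bigg] = kegg

    def has_kegg(self, kegg_id: str) -> bool:
        return kegg_id in self.entries

    def to_bigg(self, kegg_id: str) -> Optional[str]:
        return self.entries.get(kegg_id)

    def to_kegg(self, bigg_id: str) -> Optional[str]:
        for kegg, bigg in self.entries.items():
            if bigg == bigg_id:
                return kegg
        return None

    @classmethod
    def from_tsv(cls, path) -> "IdDictionary":
        df = pd.read_csv(path, sep="\t")
        for col in ("kegg_id", "bigg_id"):
            if col not in df.columns:
                raise DictionaryError(f"{path}: missing column {col}")
        prov = df["provenance"] if "provenance" in df.columns else "base"
        entries: dict[str, str] = {}
        provenance: dict[str, str] = {}
        for kegg, bigg, p in zip(
            df["kegg_id"], df["bigg_id"],
            prov if not isinstance(prov, str) else [prov] * len(df),
        ):
            kegg, bigg = str(kegg), str(bigg)
            if kegg in entries and entries[kegg] != bigg and provenance[kegg] == p:
                raise DictionaryError(
                    f"conflicting bigg targets for {kegg!r} within provenance {p!r}"
                )
            entries[kegg] = bigg
            provenance[kegg] = str(p)
        return cls(entries, provenance)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "kegg_id": list(self.entries),
                "bigg_id": [self.entries[k] for k in self.entries],
                "provenance": [self.provenance.get(k, "base") for k in self.entries],
            }
        ).to_csv(path, sep="\t", index=False)


def merge_dictionary(base: IdDictionary, manual: IdDictionary) -> IdDictionary:
    """Union of two dictionaries; manual entries override base on conflict."""
    entries = dict(base.entries)
    provenance = {k: base.provenance.get(k, "base") for k in base.entries}
    for kegg, bigg in manual.entries.items():
        entries[kegg] = bigg
        provenance[kegg] = manual.provenance.get(kegg, "manual")
    # drop base entries whose bigg target is now claimed by a manual entry
    manual_targets = {
        b for k, b in entries.items() if provenance[k] == "manual"
    }
    for kegg in list(entries):
        if provenance[kegg] != "manual" and entries[kegg] in manual_targets:
            del entries[kegg]
            del provenance[kegg]
    return IdDictionary(entries, provenance)


@dataclass
class ExpansionReport:
    metabolites_added_per_compartment: dict[str, int]
    transport_reactions_added: list[str]
    relabeled_entities: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    omv_metabolites: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.transport_reactions_added) != 2 * len(self.omv_metabolites):
            raise ModelError(
                "transport pairing violated: "
                f"{len(self.transport_reactions_added)} transports for "
                f"{len(self.omv_metabolites)} OMV metabolites"
            )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "metabolites_added_per_compartment": self.metabolites_added_per_compartment,
                    "transport_reactions_added": self.transport_reactions_added,
                    "relabeled_entities": self.relabeled_entities,
                    "skipped": self.skipped,
                    "omv_metabolites": self.omv_metabolites,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


# ------------------------------------------------------------ relabeling


def relocalize_host_compartments(
    model: MetabolicModel, host_tag: str = HOST
) -> MetabolicModel:
    """Move host entities from generic ``c``/``e`` into ``cm``/``em``.

    Metabolite ids are re-suffixed accordingly and all stoichiometries
    rewritten; microbe entities are untouched, so the network is
    isomorphic to the input and every feasible flux distribution is
    preserved.  Entities in shared compartments must carry an organism
    tag.
    """
    mapping = {"c": "cm", "e": "em"}
    untagged = [
        m.id
        for m in model.metabolites.values()
        if m.compartment in mapping and m.organism is None
    ]
    if untagged:
        raise ModelError(
            f"untagged metabolites in shared compartments: {sorted(untagged)}"
        )
    out = MetabolicModel(model.id, set(model.compartments) | {"cm", "em"})
    rename: dict[str, str] = {}
    relabeled: list[str] = []
    for met in model.metabolites.values():
        new = met.copy()
        if met.organism == host_tag and met.compartment in mapping:
            new_comp = mapping[met.compartment]
            new.compartment = new_comp
            if new.id.endswith("_" + met.compartment):
                new.id = new.id[: -len(met.compartment)] + new_comp
            else:
                new.id = new.id + "_" + new_comp
            rename[met.id] = new.id
            relabeled.append(met.id)
        out.add_metabolite(new)
    for rxn in model.reactions.values():
        new = rxn.copy()
        new.stoichiometry = {
            rename.get(mid, mid): coeff for mid, coeff in rxn.stoichiometry.items()
        }
        out.add_reaction(new)
    out.objective_reaction_id = model.objective_reaction_id
    out.relabeled_entities = relabeled  # type: ignore[attr-defined]
    return out


# ------------------------------------------------------------- expansion


def transport_ids(base_id: str) -> tuple[str, str]:
    """Deterministic ids for the packing and delivery transports of a cargo."""
    return f"TOMV_{base_id}_c_o", f"TOMV_{base_id}_o_cm"


def add_omv_compartment(
    model: MetabolicModel,
    omv_metabolites: Iterable[str],
    dictionary: Optional[IdDictionary] = None,
) -> tuple[MetabolicModel, ExpansionReport]:
    """Add an OMV compartment ``o`` and paired transports for each cargo.

    ``omv_metabolites`` are base ids (BiGG-style) or KEGG ids resolvable
    through the dictionary.  Each resolved cargo metabolite is created in
    ``c``, ``o`` and ``cm`` where absent, and gains two irreversible
    transports ``TOMV_<base>_c_o`` and ``TOMV_<base>_o_cm`` (lb = 0).
    Unresolvable ids are reported as skipped, not fatal.
    """
    out = model.copy()
    out.compartments.add("o")
    added_per_comp: dict[str, int] = {}
    transports: list[str] = []
    skipped: list[str] = []
    resolved: list[str] = []
    for raw in sorted(set(omv_metabolites)):
        base = raw
        if dictionary is not None and dictionary.has_kegg(raw):
            base = dictionary.to_bigg(raw)
        elif raw.startswith("C") and raw[1:].isdigit():
            # looks like a KEGG compound id with no dictionary entry
            skipped.append(raw)
            continue
        resolved.append(base)
        template = None
        for comp in ("c", "o", "cm"):
            mid = f"{base}_{comp}"
            if mid in out.metabolites:
                template = out.metabolites[mid]
        for comp in ("c", "o", "cm"):
            mid = f"{base}_{comp}"
            if mid not in out.metabolites:
                out.add_metabolite(
                    Metabolite(
                        id=mid,
                        base_id=base,
                        compartment=comp,
                        name=template.name if template else base,
                        kegg_id=template.kegg_id if template else None,
                        super_pathway=template.super_pathway if template else None,
                        organism=None if comp == "o" else (
                            MICROBE if comp == "c" else HOST
                        ),
                    )
                )
                added_per_comp[comp] = added_per_comp.get(comp, 0) + 1
        pack_id, deliver_id = transport_ids(base)
        for rid, src, dst in (
            (pack_id, f"{base}_c", f"{base}_o"),
            (deliver_id, f"{base}_o", f"{base}_cm"),
        ):
            if rid in out.reactions:
                raise ModelError(f"transport {rid!r} already exists")
            out.add_reaction(
                Reaction(
                    id=rid,
                    stoichiometry={src: -1.0, dst: +1.0},
                    lower_bound=0.0,
                    upper_bound=INF_CAP,
                    origin_tag="omv_transport",
                )
            )
            transports.append(rid)
    report = ExpansionReport(
        metabolites_added_per_compartment=added_per_comp,
        transport_reactions_added=transports,
        skipped=skipped,
        omv_metabolites=resolved,
    )
    return out, report


def restrict_omv_to_medium(
    model: MetabolicModel, observed_in_medium: Iterable[str]
) -> MetabolicModel:
    """Close both transports of every cargo not observed in this medium.

    ``observed_in_medium`` holds base ids of metabolites seen in OMVs
    under the medium being simulated; all other OMV transport pairs get
    bounds [0, 0].
    """
    observed = set(observed_in_medium)
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.origin_tag != "omv_transport":
            continue
        base = _transport_base(rxn.id)
        if base not in observed:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def _transport_base(transport_id: str) -> str:
    if transport_id.endswith("_c_o"):
        return transport_id[len("TOMV_"):-len("_c_o")]
    if transport_id.endswith("_o_cm"):
        return transport_id[len("TOMV_"):-len("_o_cm")]
    raise ModelError(f"not an OMV transport id: {transport_id!r}")
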