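"""End-to-end orchestration: measurements -> expansion -> gap fill ->
classification -> enrichment, from a single YAML/dict config.

Stages run in the natural analysis order: presence calls
from replicate metabolomics, KEGG mapping, vesicle-compartment
expansion restricted to the defined-medium cargo, gap filling of
unconnected cargo in the host cytosol, reversibility reconciliation,
FBA classification of cargo consumability/producibility in the host
and metabolite essentiality in the microbe, and enrichment statistics.
Every stage writes its artifact under the output directory and the
machine-readable report records counts that are re-derivable from
those artifacts.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .config import AnalysisConfig
from .enrichment_stats import (
    chi_square_enrichment,
    contingency_from_sets,
    pathway_enrichment,
)
from .fba_analyses import (
    DietSpec,
    block_omv,
    run_classification_sweep,
)
from .gap_filling import gap_fill, reconcile_reversibility
from .measurements import (
    call_presence,
    derive_sets,
    infer_export,
    map_to_kegg,
    replicate_consistency,
    summarize_superpathways,
)
from .model_core import MetabolicModel, add_sink, run_fba
from .omv_expansion import (
    HOST,
    MICROBE,
    add_omv_compartment,
    relocalize_host_compartments,
    restrict_omv_to_medium,
)
from . import synthetic_data as syn

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineReport:
    seed: int
    config: dict
    stages: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)
    complete: bool = False
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config,
            "stages": self.stages,
            "warnings": self.warnings,
            "errors": self.errors,
            "complete": self.complete,
            "version": self.version,
        }

    def write(self, out_dir: str) -> str:
        """Atomically write report.json (and a Markdown summary)."""
        os.makedirs(out_dir, exist_ok=True)
        path = os.path.join(out_dir, "report.json")
        fd, tmp = tempfile.mkstemp(dir=out_dir, suffix=".tmp")
        with os.fdopen(fd, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True, default=_json_default)
        os.replace(tmp, path)
        with open(os.path.join(out_dir, "report.md"), "w") as fh:
            fh.write(self._markdown())
        return path

    def _markdown(self) -> str:
        lines = ["# omvlink pipeline report", ""]
        lines.append(f"- complete: {self.complete}")
        lines.append(f"- seed: {self.seed}")
        for stage in self.stages:
            lines.append(f"\n## {stage}\n")
            for k, v in self.stages[stage].items():
                if isinstance(v, (int, float, str, bool)):
                    lines.append(f"- {k}: {v}")
        if self.warnings:
            lines.append("\n## warnings\n")
            lines.extend(f"- {w}" for w in self.warnings)
        if self.errors:
            lines.append("\n## errors\n")
            lines.extend(f"- {e}" for e in self.errors)
        return "\n".join(lines) + "\n"


def _json_default(obj):
    if isinstance(obj, set):
        return sorted(obj)
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return str(obj)


DEFAULT_SYNTHETIC = {
    "model": {
        "n_core_pathways": 3,
        "n_shared_lumen_nutrients": 1,
        "redundancy_fraction": 1.0 / 3.0,
        "n_direct_export": 2,
        "n_omv_only": 2,
        "prerelocalized": False,
    },
    "metabolomics": {
        "n_metabolites": 40,
        "detect_prob_present": 1.0,
        "false_detect_prob": 0.0,
        "frac_kegg_mapped": 0.7,
        "frac_exported": 0.2,
    },
    "gapfill": {"n_gaps": 2, "n_decoys": 5, "n_reversibility_conflicts": 1},
    "annotation": {"n_pathways": 4, "enrichment_factor": 1.0},
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh) or {}


def run_pipeline(config, out_dir: Optional[str] = None) -> PipelineReport:
    """Execute the full analysis described by a config mapping or YAML path.

    The config either names input files (``inputs``: model SBML,
    metabolomics TSV, dictionary TSV, universal DB TSV, diet TSV) or
    requests synthetic generation under ``synthetic`` with the run seed.
    Any stage failure produces a partial report (``complete: false``)
    carrying the error record; the report is then still written before
    the exception propagates.
    """
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    out_dir = out_dir or cfg.get("out_dir")
    analysis = AnalysisConfig.from_dict({**cfg.get("config", {}), "rng_seed": seed})
    report = PipelineReport(seed=seed, config=cfg)
    truths: dict[str, syn.SyntheticTruth] = {}
    try:
        _run_stages(cfg, seed, analysis, report, truths, out_dir)
        report.complete = True
    except Exception as exc:  # partial report, then re-raise
        report.errors.append(f"{type(exc).__name__}: {exc}")
        if out_dir:
            report.write(out_dir)
        raise
    if out_dir:
        report.write(out_dir)
    report.truths = truths  # type: ignore[attr-defined]
    return report


def _run_stages(cfg, seed, analysis, report, truths, out_dir):
    # ---------------------------------------------------------- inputs
    if "inputs" in cfg:
        from .fba_analyses import DietSpec
        from .gap_filling import UniversalReactionDB
        from .measurements import load_replicate_table
        from .omv_expansion import IdDictionary
        from .sbml_io import read_sbml

        inputs = cfg["inputs"]
        model = read_sbml(inputs["model"])
        reps = load_replicate_table(inputs["metabolomics"])
        dictionary = IdDictionary.from_tsv(inputs["dictionary"])
        db = UniversalReactionDB.from_tsv(inputs["universal_db"])
        diet = DietSpec.from_tsv(inputs["diet"])
        pathways = _load_pathways(inputs["pathways"]) if "pathways" in inputs else {}
        gap_targets = None
    else:
        s = {**DEFAULT_SYNTHETIC, **cfg.get("synthetic", {})}
        for key in DEFAULT_SYNTHETIC:
            if key in cfg.get("synthetic", {}):
                s[key] = {**DEFAULT_SYNTHETIC[key], **cfg["synthetic"][key]}
        model, model_truth = syn.make_host_microbe_model(seed=seed, **s["model"])
        truths["model"] = model_truth
        if not s["model"].get("prerelocalized", True):
            model = relocalize_host_compartments(model)
            report.stages["relocalization"] = {
                "n_relabeled": len(getattr(model, "relabeled_entities", []))
            }
        dictionary, pathways, diet, ann_truth = syn.make_annotation_bundle(
            model, seed=seed + 1, **s["annotation"]
        )
        truths["annotation"] = ann_truth
        reps, met_truth = syn.make_metabolomics_table(
            seed=seed + 2, kegg_ids=sorted(dictionary.entries), **s["metabolomics"]
        )
        truths["metabolomics"] = met_truth
        model, db, gap_truth = syn.make_gapfill_instance(
            model, seed=seed + 3, **s["gapfill"]
        )
        truths["gapfill"] = gap_truth
        gap_targets = gap_truth.gapfill_targets

    # ----------------------------------------------------- measurements
    presence = call_presence(reps, analysis)
    consistency = replicate_consistency(reps)
    sets = derive_sets(presence)
    mapped, unmapped_report = map_to_kegg(presence, dictionary)
    try:
        mapped_sets = derive_sets(mapped)
    except Exception:
        # nothing mappable: downstream model joins are simply empty
        mapped_sets = {k: set() for k in sets}
        report.warnings.append("no KEGG-mappable metabolites; model joins empty")
    summary = summarize_superpathways(presence)
    export = infer_export(reps, analysis)
    report.stages["measurements"] = {
        "n_metabolites": int(presence["metabolite_id"].nunique()),
        "replicate_consistency": float(consistency),
        "core_omv_size": len(sets["core_omv"]),
        "rm_only_omv_size": len(sets["rm_only_omv"]),
        "dm_only_omv_size": len(sets["dm_only_omv"]),
        "n_unmapped": int(len(unmapped_report)),
        "n_exported_RM": len(export.exported.get("RM", set())),
        "n_exported_DM": len(export.exported.get("DM", set())),
        "sets": {k: sorted(v) for k, v in sets.items()},
    }
    report.warnings.extend(f"export: skipped {s}" for s in export.skipped)

    # -------------------------------------------------------- expansion
    needs_relocalization = any(
        m.organism == HOST and m.compartment in ("c", "e")
        for m in model.metabolites.values()
    )
    if needs_relocalization:
        model = relocalize_host_compartments(model)

    def to_base(metabolite_ids):
        out = set()
        kegg_of = dict(
            zip(mapped["metabolite_id"], mapped["kegg_id"].astype(str))
        )
        for mid in metabolite_ids:
            kegg = kegg_of.get(mid)
            if kegg is not None and dictionary.has_kegg(kegg):
                out.add(dictionary.to_bigg(kegg))
        return out

    cargo_bases = to_base(
        set(mapped.loc[mapped["present"] & (mapped["compartment"] == "OMV"),
                       "metabolite_id"])
    )
    # cargo planted on the model side joins the observed cargo
    model_bases = {m.base_id for m in model.metabolites.values()}
    if "model" in truths:
        cargo_bases |= truths["model"].omv_cargo
    expanded, expansion = add_omv_compartment(model, cargo_bases, dictionary)
    dm_bases = to_base(
        set(mapped.loc[mapped["present"] & (mapped["compartment"] == "OMV")
                       & (mapped["medium"] == "DM"), "metabolite_id"])
    )
    if "model" in truths:
        dm_bases |= truths["model"].omv_cargo
    dm_model = restrict_omv_to_medium(expanded, dm_bases)
    report.stages["expansion"] = {
        "n_omv_metabolites": len(expansion.omv_metabolites),
        "n_transport_reactions": len(expansion.transport_reactions_added),
        "n_skipped": len(expansion.skipped),
        "relocalized": bool(needs_relocalization),
    }
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        from .sbml_io import write_sbml

        write_sbml(dm_model, os.path.join(out_dir, "expanded_model.xml"))
        expansion.to_json(os.path.join(out_dir, "expansion_report.json"))

    # --------------------------------------------------------- gap fill
    if gap_targets is None:
        from .gap_filling import find_unconnected_metabolites

        host_cargo = [
            f"{b}_cm" for b in sorted(cargo_bases)
            if f"{b}_cm" in dm_model.metabolites
        ]
        gap_targets = sorted(
            find_unconnected_metabolites(
                block_omv(dm_model), "cm", "consumable",
                analysis.flux_epsilon, host_cargo,
            )
        )
    gf = gap_fill(dm_model, db, "cm", gap_targets, "consumable", analysis)
    gf = reconcile_reversibility(gf, db, analysis)
    working_model = gf.model if gf.model is not None else dm_model
    report.stages["gap_fill"] = {
        "n_targets": len(gap_targets),
        "n_added_reactions": len(gf.added_reactions),
        "added_reactions": list(gf.added_reactions),
        "n_resolved": int(sum(gf.resolved.values())),
        "n_unresolved": len(gf.unresolved),
        "n_reversibility_overrides": len(gf.reversibility_overrides),
    }
    if out_dir:
        gf.to_json(os.path.join(out_dir, "gapfill_result.json"))
        gf.to_table().to_csv(
            os.path.join(out_dir, "gapfill_table.tsv"), sep="\t", index=False
        )

    # ---------------------------------------------------- classification
    host_targets = [
        f"{b}_cm" for b in sorted(cargo_bases)
        if f"{b}_cm" in working_model.metabolites
    ]
    microbe_targets = sorted(
        truths["model"].essential[MICROBE] | truths["model"].nonessential[MICROBE]
    ) if "model" in truths else [
        m.id for m in working_model.metabolites.values()
        if m.compartment == "c" and m.organism == MICROBE
    ]
    medium = syn.microbe_medium(working_model)
    sweep = run_classification_sweep(
        working_model,
        {HOST: host_targets, MICROBE: microbe_targets},
        {
            "western_diet": {
                "diet": diet,
                "medium": medium,
                "essential_objective": {MICROBE: "BIOMASS_B"},
            }
        },
        analysis,
    )
    report.stages["classification"] = {
        "n_rows": int(len(sweep)),
        "n_host_consumable": int(
            sweep.loc[(sweep["organism"] == HOST), "consumable"].sum()
        ),
        "n_microbe_essential": int(
            sweep.loc[sweep["organism"] == MICROBE, "essential"].eq(True).sum()
        ),
    }
    if out_dir:
        sweep.to_csv(
            os.path.join(out_dir, "classification.tsv"), sep="\t", index=False
        )

    # -------------------------------------------------------- enrichment
    host_rows = sweep[sweep["organism"] == HOST]
    consumable_bases = {
        m[: -len("_cm")] for m in host_rows.loc[host_rows["consumable"], "metabolite"]
    }
    core_bases = to_base(mapped_sets["core_omv"])
    background = set(model_bases) | cargo_bases
    enrichment = None
    if core_bases and background:
        table = contingency_from_sets(core_bases, consumable_bases, background)
        enrichment = chi_square_enrichment(table, analysis.chi2_alpha,
                                           label="core_omv_vs_consumable")
    pw_results = []
    if pathways:
        query = core_bases & set().union(*pathways.values()) if core_bases else set()
        pw_background = {b for s in pathways.values() for b in s}
        if "annotation" in truths and truths["annotation"].query_set:
            query = truths["annotation"].query_set & pw_background
            pw_background |= truths["annotation"].kegg_mapped
        if query:
            pw_results = pathway_enrichment(
                query, pathways, pw_background, analysis.bh_q
            )
    report.stages["enrichment"] = {
        "chi2_p": None if enrichment is None else enrichment.p_value,
        "chi2_significant": None if enrichment is None else enrichment.significant,
        "n_pathways_tested": len(pw_results),
        "n_pathways_significant": int(
            sum(r.significant for r in pw_results)
        ),
        "significant_pathways": sorted(
            r.label for r in pw_results if r.significant
        ),
    }

    # ------------------------------------------------------ route counts
    direct, omv_only = omv_route_counts(expanded, sorted(cargo_bases))
    report.stages["routes"] = {
        "direct_export_importable": len(direct),
        "omv_only": len(omv_only),
        "direct_bases": sorted(direct),
        "omv_only_bases": sorted(omv_only),
    }
    report.stages["routes"]["cargo_size"] = len(cargo_bases)


def omv_route_counts(
    expanded: MetabolicModel, cargo_bases, epsilon: float = 1e-6
) -> tuple[set[str], set[str]]:
    """Partition vesicle cargo by how it can reach the host cytosol.

    A cargo base is directly transferable when its host-cytosol species
    can be produced with every OMV transport closed (microbe export
    through the lumen plus host import); cargo producible in the host
    cytosol only while OMV transports are open is counted as
    OMV-only.  Cargo unreachable either way is in neither set.
    """
    no_omv = block_omv(expanded)
    direct: set[str] = set()
    omv_only: set[str] = set()
    for base in cargo_bases:
        mid = f"{base}_cm"
        if mid not in expanded.metabolites:
            continue
        if _producible(no_omv, mid, epsilon):
            direct.add(base)
        elif _producible(expanded, mid, epsilon):
            omv_only.add(base)
    return direct, omv_only


def _producible(model: MetabolicModel, metabolite: str, epsilon: float) -> bool:
    work = model.copy()
    probe = add_sink(work, metabolite)
    res = run_fba(work, maximize=probe)
    return res.status == "optimal" and (res.objective_value or 0.0) > epsilon


def report_omv_route_counts(report: PipelineReport) -> tuple[int, int]:
    """(direct export+import count, OMV-only count) from a pipeline report."""
    if "routes" not in report.stages:
        raise PipelineError("report has no classification/routes stage")
    r = report.stages["routes"]
    return int(r["direct_export_importable"]), int(r["omv_only"])


def _load_pathways(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for pid, grp in df.groupby("pathway_id"):
        out[str(pid)] = set(grp["metabolite_id"].astype(str))
    return out
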