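"""Replicate-level metabolomics: presence calls, derived sets, export.

A :class:`ReplicateTable` is a long-format pandas DataFrame with one row
per (metabolite, sample, replicate) intensity measurement.  Samples are
described by medium (RM rich / DM defined), compartment (cell, medium,
OMV) and time point (TP1 exponential, TP2 stationary, ``blank`` for
pre-inoculation medium, NA for OMV preparations pooled over growth).
A metabolite is called present in a sample when it is detected in at
least two of three replicates; the rule generalizes to k >= n-1 for n
replicates and is configurable.

The module also carries the Stokes-Einstein computation used to convert
nanoparticle-tracking diffusion coefficients into vesicle hydrodynamic
radii.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig, DEFAULT_CONFIG

logger = logging.getLogger(__name__)

#: Exact SI value of the Boltzmann constant (J/K).
BOLTZMANN = 1.380649e-23

REPLICATE_COLUMNS = [
    "metabolite_id",
    "name",
    "kegg_id",
    "super_pathway",
    "medium",
    "compartment",
    "time",
    "replicate",
    "intensity",
]

SAMPLE_KEY = ["medium", "compartment", "time"]

MEDIA = ("RM", "DM")
COMPARTMENTS = ("cell", "medium", "OMV")


class MeasurementError(ValueError):
    pass


def load_replicate_table(path) -> pd.DataFrame:
    """Read a long-format replicate TSV and validate its columns."""
    df = pd.read_csv(path, sep="\t", dtype={"kegg_id": "string"})
    missing = [c for c in REPLICATE_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementError(f"{path}: missing columns {missing}")
    return validate_replicate_table(df)


def validate_replicate_table(df: pd.DataFrame) -> pd.DataFrame:
    present = df["intensity"].dropna()
    if (present < 0).any():
        raise MeasurementError("negative intensities in replicate table")
    return df


def _detected(intensity: pd.Series) -> pd.Series:
    """A replicate detects a metabolite iff its intensity is present and > 0."""
    return intensity.notna() & (intensity > 0)


def call_presence(
    reps: pd.DataFrame, config: AnalysisConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Collapse replicates into per-sample boolean presence calls.

    Returns a DataFrame with one row per (metabolite, sample) carrying
    ``detected_count``, ``n_replicates`` and ``present`` (k >= n - offset,
    i.e. the 2-of-3 rule at triplicate sampling).
    """
    df = reps.copy()
    df["detected"] = _detected(df["intensity"])
    grouped = (
        df.groupby(["metabolite_id"] + SAMPLE_KEY, dropna=False, sort=True)
        .agg(
            detected_count=("detected", "sum"),
            n_replicates=("replicate", "nunique"),
            name=("name", "first"),
            kegg_id=("kegg_id", "first"),
            super_pathway=("super_pathway", "first"),
        )
        .reset_index()
    )
    if (grouped["n_replicates"] < 1).any():
        raise MeasurementError("sample with zero replicates")
    offset = config.presence_min_detected_offset
    grouped["present"] = grouped["detected_count"] >= (
        grouped["n_replicates"] - offset
    ).clip(lower=1)
    return grouped


def replicate_consistency(reps: pd.DataFrame) -> float:
    """Fraction of (metabolite, sample) pairs detected in all or no replicates.

    Only metabolites measured (detected at least once) anywhere in the
    table enter the denominator, matching how consistency is assessed for
    an identified-metabolite panel.
    """
    if reps.empty:
        raise MeasurementError("empty replicate table")
    df = reps.copy()
    df["detected"] = _detected(df["intensity"])
    measured_anywhere = set(
        df.loc[df["detected"], "metabolite_id"].unique()
    )
    if not measured_anywhere:
        raise MeasurementError("no metabolite detected anywhere")
    df = df[df["metabolite_id"].isin(measured_anywhere)]
    per_pair = df.groupby(["metabolite_id"] + SAMPLE_KEY, dropna=False)[
        "detected"
    ].agg(["sum", "count"])
    unanimous = (per_pair["sum"] == 0) | (per_pair["sum"] == per_pair["count"])
    return float(unanimous.mean())


# ------------------------------------------------------------- derived sets


def _sample_set(presence: pd.DataFrame, medium: str, compartment: str,
                time: Optional[str] = None) -> set[str]:
    mask = (
        (presence["medium"] == medium)
        & (presence["compartment"] == compartment)
        & presence["present"]
    )
    if time is not None:
        mask &= presence["time"] == time
    return set(presence.loc[mask, "metabolite_id"])


def derive_sets(presence: pd.DataFrame) -> dict[str, set[str]]:
    """Named metabolite sets from presence calls (union over time points).

    ``core_omv`` is the intersection of the OMV contents in rich and
    defined media; ``rm_only_omv``/``dm_only_omv`` the corresponding
    set differences.  Per-(medium, compartment) sets are included under
    keys like ``"RM_cell"``.
    """
    observed = set(zip(presence["medium"], presence["compartment"]))
    for required in (("RM", "OMV"), ("DM", "OMV")):
        if required not in observed:
            raise MeasurementError(f"presence table lacks sample {required}")
    sets: dict[str, set[str]] = {}
    for medium in MEDIA:
        for compartment in COMPARTMENTS:
            if (medium, compartment) in observed:
                sets[f"{medium}_{compartment}"] = _sample_set(
                    presence, medium, compartment
                )
    rm_omv, dm_omv = sets["RM_OMV"], sets["DM_OMV"]
    sets["core_omv"] = rm_omv & dm_omv
    sets["rm_only_omv"] = rm_omv - dm_omv
    sets["dm_only_omv"] = dm_omv - rm_omv
    sets["any_omv"] = rm_omv | dm_omv
    return sets


def map_to_kegg(
    presence: pd.DataFrame, dictionary: Optional["IdDictionary"] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split presence calls into KEGG-mappable and unmapped metabolites.

    A metabolite is mappable when it carries a KEGG id (and, if a
    KEGG<->BiGG dictionary is given, that id resolves to a model id).
    The unmapped report keeps names and super-pathways so lipid/dipeptide
    tallies remain possible downstream.
    """
    has_kegg = presence["kegg_id"].notna() & (presence["kegg_id"].astype(str) != "")
    if dictionary is not None:
        in_dict = presence["kegg_id"].map(
            lambda k: isinstance(k, str) and dictionary.has_kegg(k)
        )
        mappable = has_kegg & in_dict
    else:
        mappable = has_kegg
    mapped = presence[mappable].copy()
    report = (
        presence[~mappable][["metabolite_id", "name", "super_pathway"]]
        .drop_duplicates("metabolite_id")
        .sort_values("metabolite_id")
        .reset_index(drop=True)
    )
    return mapped, report


def summarize_superpathways(presence: pd.DataFrame) -> pd.DataFrame:
    """Count present metabolites per super-pathway in each sample.

    Returns a super_pathway x sample table with a Total row; metabolites
    without a label are counted under "unclassified".
    """
    df = presence[presence["present"]].copy()
    df["super_pathway"] = df["super_pathway"].fillna("unclassified")
    df["sample"] = df[SAMPLE_KEY].astype(str).agg("/".join, axis=1)
    counts = (
        df.pivot_table(
            index="super_pathway",
            columns="sample",
            values="metabolite_id",
            aggfunc="nunique",
            fill_value=0,
        )
        .sort_index()
    )
    counts.loc["Total"] = counts.sum(axis=0)
    return counts


# ------------------------------------------------------------------ export


@dataclass
class ExportResult:
    """Outcome of the medium-change export inference."""

    table: pd.DataFrame  # metabolite_id, medium, p, q, direction, exported
    exported: dict[str, set[str]] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)


def infer_export(
    reps: pd.DataFrame, config: AnalysisConfig = DEFAULT_CONFIG
) -> ExportResult:
    """Infer metabolites exported to the growth medium.

    For each medium, TP2 replicate intensities in the extracellular
    ("medium") compartment are tested against the pre-inoculation blank
    mean with a one-sample two-tailed t-test; Benjamini-Hochberg is
    applied across all tested metabolites at ``config.bh_q``.  A
    metabolite is called exported when it is BH-significant and its mean
    concentration rises from TP1 to TP2 (blank mean used where TP1 is
    absent), composing the significance and direction criteria.
    """
    from .enrichment_stats import benjamini_hochberg, one_sample_t

    med = reps[reps["compartment"] == "medium"]
    if med.empty:
        raise MeasurementError("no medium-compartment samples")
    rows = []
    skipped: list[str] = []
    for medium in sorted(med["medium"].dropna().unique()):
        sub = med[med["medium"] == medium]
        blanks = sub[sub["time"] == "blank"]
        if blanks.empty:
            raise MeasurementError(f"no pre-inoculation blank for medium {medium}")
        for mid, grp in sub.groupby("metabolite_id", sort=True):
            blank_vals = grp.loc[grp["time"] == "blank", "intensity"].dropna()
            tp1 = grp.loc[grp["time"] == "TP1", "intensity"].dropna()
            tp2 = grp.loc[grp["time"] == "TP2", "intensity"].dropna()
            if len(tp2) < 2:
                skipped.append(f"{medium}:{mid}")
                logger.warning(
                    "metabolite %s in %s: <2 TP2 replicates; skipped", mid, medium
                )
                continue
            blank_mean = float(blank_vals.mean()) if len(blank_vals) else 0.0
            _, p = one_sample_t(tp2.to_numpy(float), blank_mean)
            tp1_mean = float(tp1.mean()) if len(tp1) else blank_mean
            increased = float(tp2.mean()) > tp1_mean
            rows.append(
                {
                    "metabolite_id": mid,
                    "medium": medium,
                    "p": p,
                    "direction": "up" if increased else "down",
                }
            )
    table = pd.DataFrame(rows, columns=["metabolite_id", "medium", "p", "direction"])
    if len(table):
        qvals, reject = benjamini_hochberg(table["p"].to_numpy(), config.bh_q)
        table["q"] = qvals
        table["exported"] = reject & (table["direction"] == "up").to_numpy()
    else:
        table["q"] = []
        table["exported"] = []
    exported = {
        medium: set(
            table.loc[(table["medium"] == medium) & table["exported"], "metabolite_id"]
        )
        for medium in table["medium"].unique()
    }
    return ExportResult(table=table, exported=exported, skipped=skipped)


# ------------------------------------------------------ vesicle sizing


def hydrodynamic_radius(D_t: float, T: float, eta: float) -> float:
    """Hydrodynamic radius (m) from a diffusion coefficient (m^2/s).

    Stokes-Einstein: ``r_h = k_B T / (6 pi eta D_t)`` with T in kelvin
    and viscosity eta in Pa s.
    """
    _require_positive(D_t=D_t, T=T, eta=eta)
    return BOLTZMANN * T / (6.0 * math.pi * eta * D_t)


def diffusion_coefficient(r_h: float, T: float, eta: float) -> float:
    """Diffusion coefficient (m^2/s) of a sphere of hydrodynamic radius r_h (m)."""
    _require_positive(r_h=r_h, T=T, eta=eta)
    return BOLTZMANN * T / (6.0 * math.pi * eta * r_h)


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value}")
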