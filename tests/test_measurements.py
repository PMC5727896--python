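import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omvlink.config import AnalysisConfig
from omvlink.measurements import (
    BOLTZMANN,
    MeasurementError,
    call_presence,
    derive_sets,
    diffusion_coefficient,
    hydrodynamic_radius,
    infer_export,
    map_to_kegg,
    replicate_consistency,
    summarize_superpathways,
)
from omvlink import synthetic_data as syn


def make_reps(rows):
    """rows: (metabolite, medium, compartment, time, [intensities or None])."""
    data = []
    for mid, medium, comp, time, intensities in rows:
        for i, x in enumerate(intensities, start=1):
            data.append(
                {
                    "metabolite_id": mid, "name": mid, "kegg_id": None,
                    "super_pathway": "Amino acid", "medium": medium,
                    "compartment": comp, "time": time, "replicate": i,
                    "intensity": x,
                }
            )
    return pd.DataFrame(data)


NA = np.nan


class TestCallPresence:
    @pytest.mark.parametrize(
        "intensities,expected",
        [
            ((5.0, NA, 6.0), True),   # 2 of 3
            ((NA, NA, NA), False),
            ((5.0, 5.0, 5.0), True),
            ((5.0, NA, NA), False),   # 1 of 3
            ((5.0, 6.0, 7.0, NA), True),   # 3 of 4 under k >= n-1
            ((5.0, 6.0, NA, NA), False),   # 2 of 4
        ],
    )
    def test_two_of_three_rule_and_generalization(self, intensities, expected):
        reps = make_reps([("m1", "RM", "cell", "TP1", intensities)])
        out = call_presence(reps)
        assert bool(out["present"].iloc[0]) is expected

    def test_exhaustive_truth_table_n3(self):
        """All 8 detection patterns at n=3 match the at-least-two rule."""
        for pattern in range(8):
            bits = [(pattern >> b) & 1 for b in range(3)]
            intensities = [5.0 if b else NA for b in bits]
            reps = make_reps([("m", "RM", "cell", "TP1", intensities)])
            out = call_presence(reps)
            assert bool(out["present"].iloc[0]) is (sum(bits) >= 2)

    def test_permutation_invariance(self):
        a = make_reps([("m", "RM", "cell", "TP1", (5.0, NA, 6.0))])
        b = make_reps([("m", "RM", "cell", "TP1", (NA, 6.0, 5.0))])
        assert bool(call_presence(a)["present"].iloc[0]) == bool(
            call_presence(b)["present"].iloc[0]
        )

    def test_zero_intensity_is_not_a_detection(self):
        reps = make_reps([("m", "RM", "cell", "TP1", (0.0, 0.0, 5.0))])
        assert not call_presence(reps)["present"].iloc[0]


class TestReplicateConsistency:
    def test_all_unanimous(self):
        reps = make_reps(
            [
                ("m1", "RM", "cell", "TP1", (1.0, 1.0, 1.0)),
                ("m2", "RM", "cell", "TP1", (2.0, 2.0, 2.0)),
                ("m2", "DM", "cell", "TP1", (NA, NA, NA)),
            ]
        )
        assert replicate_consistency(reps) == pytest.approx(1.0)

    def test_direct_count(self):
        """10 pairs, 3 with split detection -> 0.7."""
        rows = []
        for i in range(10):
            split = i < 3
            rows.append(
                (f"m{i}", "RM", "cell", "TP1",
                 (1.0, NA, 1.0) if split else (1.0, 1.0, 1.0))
            )
        assert replicate_consistency(make_reps(rows)) == pytest.approx(0.7)

    def test_empty_errors(self):
        with pytest.raises(MeasurementError):
            replicate_consistency(make_reps([]))


class TestDeriveSets:
    def presence(self, rm_omv, dm_omv):
        rows = [(m, "RM", "OMV", "NA", (1.0, 1.0, 1.0)) for m in rm_omv]
        rows += [(m, "DM", "OMV", "NA", (1.0, 1.0, 1.0)) for m in dm_omv]
        # absent marker rows keep both samples in the table
        rows += [("__pad__", "RM", "OMV", "NA", (NA, NA, NA))]
        rows += [("__pad__", "DM", "OMV", "NA", (NA, NA, NA))]
        return call_presence(make_reps(rows))

    def test_core_is_intersection(self):
        sets = derive_sets(self.presence(["a", "b", "c"], ["b", "c", "d"]))
        assert sets["core_omv"] == {"b", "c"}
        assert sets["rm_only_omv"] == {"a"}
        assert sets["dm_only_omv"] == {"d"}

    def test_disjoint_inputs_empty_core(self):
        sets = derive_sets(self.presence(["a"], ["b"]))
        assert sets["core_omv"] == set()

    def test_identical_inputs_idempotent(self):
        sets = derive_sets(self.presence(["a", "b"], ["a", "b"]))
        assert sets["core_omv"] == {"a", "b"}

    def test_inclusion_exclusion(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            universe = [f"m{i}" for i in range(12)]
            rm = [m for m in universe if rng.random() < 0.5]
            dm = [m for m in universe if rng.random() < 0.5]
            sets = derive_sets(self.presence(rm, dm))
            assert len(sets["RM_OMV"]) + len(sets["DM_OMV"]) - len(
                sets["core_omv"]
            ) == len(sets["any_omv"])

    def test_missing_sample_errors(self):
        rows = [("a", "RM", "OMV", "NA", (1.0, 1.0, 1.0))]
        with pytest.raises(MeasurementError):
            derive_sets(call_presence(make_reps(rows)))


class TestMapToKegg:
    def test_split_counts(self):
        reps = make_reps(
            [(f"m{i}", "RM", "cell", "TP1", (1.0, 1.0, 1.0)) for i in range(5)]
        )
        reps.loc[reps["metabolite_id"].isin(["m0", "m1", "m2"]), "kegg_id"] = "C00001"
        # make the kegg ids distinct
        for i, mid in enumerate(["m0", "m1", "m2"]):
            reps.loc[reps["metabolite_id"] == mid, "kegg_id"] = f"C0000{i}"
        mapped, report = map_to_kegg(call_presence(reps))
        assert mapped["metabolite_id"].nunique() == 3
        assert len(report) == 2
        assert set(report.columns) == {"metabolite_id", "name", "super_pathway"}

    def test_all_mapped_empty_report(self):
        reps = make_reps([("m0", "RM", "cell", "TP1", (1.0, 1.0, 1.0))])
        reps["kegg_id"] = "C00001"
        _, report = map_to_kegg(call_presence(reps))
        assert report.empty

    def test_generator_truth(self):
        table, truth = syn.make_metabolomics_table(
            n_metabolites=200, frac_kegg_mapped=0.7, seed=9
        )
        mapped, report = map_to_kegg(call_presence(table))
        assert set(mapped["metabolite_id"]) == truth.kegg_mapped
        assert set(report["metabolite_id"]).isdisjoint(truth.kegg_mapped)


class TestSummarize:
    def test_one_per_pathway(self):
        rows = [(f"m{i}", "RM", "cell", "TP1", (1.0, 1.0, 1.0)) for i in range(3)]
        reps = make_reps(rows)
        reps.loc[reps["metabolite_id"] == "m1", "super_pathway"] = "Lipid"
        reps.loc[reps["metabolite_id"] == "m2", "super_pathway"] = None
        out = summarize_superpathways(call_presence(reps))
        col = out.columns[0]
        assert out.loc["Amino acid", col] == 1
        assert out.loc["Lipid", col] == 1
        assert out.loc["unclassified", col] == 1
        assert out.loc["Total", col] == 3

    def test_total_equals_column_sum_on_synthetic(self):
        table, _ = syn.make_metabolomics_table(n_metabolites=50, seed=2)
        out = summarize_superpathways(call_presence(table))
        body = out.drop(index="Total")
        assert (out.loc["Total"] == body.sum(axis=0)).all()


class TestInferExport:
    def test_zero_effect_not_exported(self):
        reps = make_reps(
            [
                ("m", "DM", "medium", "blank", (10.0, 10.0, 10.0)),
                ("m", "DM", "medium", "TP1", (10.0, 10.0, 10.0)),
                ("m", "DM", "medium", "TP2", (10.0, 10.0, 10.0)),
            ]
        )
        res = infer_export(reps)
        assert res.table["p"].iloc[0] == pytest.approx(1.0)
        assert not res.table["exported"].iloc[0]

    def test_planted_increase_exported(self):
        reps = make_reps(
            [
                ("m", "DM", "medium", "blank", (NA, NA, NA)),
                ("m", "DM", "medium", "TP1", (1.0, 1.0, 1.0)),
                ("m", "DM", "medium", "TP2", (5.0, 6.0, 7.0)),
            ]
        )
        res = infer_export(reps)
        # closed-form one-sample t against blank mean 0: t = 6/(1/sqrt(3))
        t_expect = 6.0 / (1.0 / math.sqrt(3.0))
        from scipy import stats

        p_expect = 2 * stats.t.sf(t_expect, df=2)
        assert res.table["p"].iloc[0] == pytest.approx(p_expect, rel=1e-9)
        assert res.exported["DM"] == {"m"}

    def test_decrease_never_exported(self):
        reps = make_reps(
            [
                ("m", "DM", "medium", "blank", (10.0, 10.0, 10.0)),
                ("m", "DM", "medium", "TP1", (8.0, 8.0, 8.0)),
                ("m", "DM", "medium", "TP2", (1.0, 2.0, 3.0)),
            ]
        )
        res = infer_export(reps)
        assert res.table["direction"].iloc[0] == "down"
        assert not res.table["exported"].iloc[0]

    def test_too_few_replicates_skipped(self):
        reps = make_reps(
            [
                ("m", "DM", "medium", "blank", (10.0, 10.0, 10.0)),
                ("m", "DM", "medium", "TP2", (12.0, NA, NA)),
            ]
        )
        res = infer_export(reps)
        assert res.skipped == ["DM:m"]
        assert res.table.empty

    def test_missing_blank_errors(self):
        reps = make_reps([("m", "DM", "medium", "TP2", (1.0, 2.0, 3.0))])
        with pytest.raises(MeasurementError):
            infer_export(reps)

    def test_recovery_on_simulations(self):
        """Sensitivity >= 0.9 and FDR <= 1.5q at 5-sigma effects, 200 reps."""
        tp = fp = fn = 0
        q = AnalysisConfig().bh_q
        for rep in range(200):
            table, truth = syn.make_metabolomics_table(
                n_metabolites=30, export_effect_size=5.0, seed=20_000 + rep
            )
            res = infer_export(table)
            for medium in ("RM", "DM"):
                called = res.exported.get(medium, set())
                tested = set(
                    res.table.loc[res.table["medium"] == medium, "metabolite_id"]
                )
                true = truth.exported.get(medium, set()) & tested
                tp += len(called & true)
                fp += len(called - true)
                fn += len(true - called)
        assert tp / (tp + fn) >= 0.9
        assert fp / max(tp + fp, 1) <= 1.5 * q


class TestStokesEinstein:
    def test_direct_evaluation(self):
        # r_h = k_B T / (6 pi eta D)
        r = hydrodynamic_radius(D_t=4.9e-12, T=298.0, eta=8.9e-4)
        expect = BOLTZMANN * 298.0 / (6 * math.pi * 8.9e-4 * 4.9e-12)
        assert r == pytest.approx(expect, rel=1e-12)
        assert r == pytest.approx(5.0e-8, rel=0.02)

    def test_viscosity_scaling(self):
        r1 = hydrodynamic_radius(1e-12, 298.0, 1e-3)
        r2 = hydrodynamic_radius(1e-12, 298.0, 2e-3)
        assert r1 == pytest.approx(2.0 * r2, rel=1e-12)

    @given(
        D=st.floats(1e-14, 1e-10), T=st.floats(250.0, 350.0),
        eta=st.floats(1e-4, 1e-2),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, D, T, eta):
        r = hydrodynamic_radius(D, T, eta)
        assert diffusion_coefficient(r, T, eta) == pytest.approx(D, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_non_positive_inputs_error(self, bad):
        with pytest.raises(ValueError):
            hydrodynamic_radius(bad, 298.0, 1e-3)
        with pytest.raises(ValueError):
            diffusion_coefficient(1e-8, bad, 1e-3)
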