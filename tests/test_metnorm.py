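"""Internal-standard assignment, ratio normalization and batch correction."""

import numpy as np
import pandas as pd
import pytest

from slcfuncmap import (
    MetabolomicsDesign,
    NormalizedMatrix,
    ParameterError,
    assign_internal_standards,
    batch_correct,
    gen_metabolomics_experiment,
    normalize,
    validate_peak_table,
)
from slcfuncmap.metnorm import ISAssignment, ISRecord


def _row(run, sample, analyte, role, area, cond="calibration", conc=np.nan):
    return {
        "run_id": run, "batch_id": run, "sample_id": sample, "analysis_id": "A",
        "condition": cond, "clone_id": "", "replicate": 1, "analyte_id": analyte,
        "analyte_role": role, "area": area, "expected_conc": conc,
    }


def _calib_table(met_areas_by_run, is_areas_by_run, levels=(1.0, 2.0, 4.0, 8.0)):
    """Calibration-only peak table; areas are per-run lists over the levels."""
    rows = []
    for run, met_areas in met_areas_by_run.items():
        for li, level in enumerate(levels):
            sid = f"{run}_L{li}"
            rows.append(_row(run, sid, "M", "target", met_areas[li], conc=level))
            for is_id, is_runs in is_areas_by_run.items():
                rows.append(
                    _row(run, sid, is_id, "internal_standard", is_runs[run][li], conc=level)
                )
    return pd.DataFrame(rows)


PANEL = pd.DataFrame(
    {"analyte_id": ["IS1", "IS2"], "structure_match_target": ["", ""]}
)


class TestAssignment:
    def test_structure_matched_wins(self):
        pt = _calib_table(
            {"r1": [1000, 2000, 4000, 8000]},
            {"IS1": {"r1": [100] * 4}, "IS2": {"r1": [100] * 4}},
        )
        panel = pd.DataFrame(
            {"analyte_id": ["IS1", "IS2"], "structure_match_target": ["M", ""]}
        )
        out = assign_internal_standards(pt, panel)
        rec = out.records["M"]
        assert rec.reference_is == ("IS1",) and rec.basis == "same_structure"

    def test_tie_selects_both(self):
        pt = _calib_table(
            {"r1": [1000, 2000, 4000, 8000], "r2": [500, 1000, 2000, 4000]},
            {
                "IS1": {"r1": [100] * 4, "r2": [100] * 4},
                "IS2": {"r1": [200] * 4, "r2": [200] * 4},
            },
        )
        out = assign_internal_standards(pt, PANEL)
        rec = out.records["M"]
        assert rec.reference_is == ("IS1", "IS2")
        assert rec.basis == "regression_best"
        assert rec.pct_qualifying == {"IS1": 1.0, "IS2": 1.0}

    def test_fallback_below_run_fraction(self):
        # run r2's metabolite response is scrambled: no standard can rescue
        # it, so both standards qualify in only 1 of 2 runs (50% < 75%)
        pt = _calib_table(
            {"r1": [1000, 2000, 4000, 8000], "r2": [3000, 800, 5000, 1200]},
            {
                "IS1": {"r1": [100] * 4, "r2": [100] * 4},
                "IS2": {"r1": [200] * 4, "r2": [200] * 4},
            },
        )
        out = assign_internal_standards(pt, PANEL)
        rec = out.records["M"]
        assert rec.basis == "regression_fallback"
        assert rec.pct_qualifying["IS1"] == pytest.approx(0.5)

    def test_true_is_recovered_on_synthetic_data(self):
        design = MetabolomicsDesign()
        pt, truth = gen_metabolomics_experiment(11, design, noise_sd=0.1)
        panel = pd.DataFrame(
            {
                "analyte_id": list(design.internal_standards),
                "structure_match_target": [""] * len(design.internal_standards),
            }
        )
        out = assign_internal_standards(pt, panel)
        hits = sum(
            out.records[m].reference_is == (truth.true_is_map[m],)
            for m in truth.true_is_map
        )
        assert hits >= 0.95 * len(truth.true_is_map)
        assert all(r.basis == "regression_best" for r in out.records.values())


def _one_sample_table(met_area, is_areas):
    rows = [_row("r1", "s1", "M", "target", met_area, cond="induced")]
    for is_id, area in is_areas.items():
        rows.append(_row("r1", "s1", is_id, "internal_standard", area, cond="induced"))
    return pd.DataFrame(rows)


class TestNormalize:
    @pytest.mark.parametrize(
        "met_area,is_areas,expected",
        [
            (100.0, {"IS1": 100.0}, 0.0),  # unit ratio
            (400.0, {"IS1": 100.0}, 2.0),  # log2(4)
            (200.0, {"IS1": 100.0, "IS2": 400.0}, 0.0),  # mean(log2 2, log2 0.5)
        ],
    )
    def test_hand_values(self, met_area, is_areas, expected):
        pt = _one_sample_table(met_area, is_areas)
        assign = ISAssignment(
            {"M": ISRecord(tuple(sorted(is_areas)), "regression_best")}, pd.DataFrame()
        )
        nm = normalize(pt, assign)
        assert nm.data.loc["M", "s1"] == pytest.approx(expected)

    def test_reduced_is_set_when_one_missing(self):
        pt = _one_sample_table(400.0, {"IS1": 100.0, "IS2": 0.0})
        assign = ISAssignment(
            {"M": ISRecord(("IS1", "IS2"), "regression_best")}, pd.DataFrame()
        )
        nm = normalize(pt, assign)
        assert nm.data.loc["M", "s1"] == pytest.approx(2.0)

    def test_zero_metabolite_area_missing(self):
        pt = _one_sample_table(0.0, {"IS1": 100.0})
        assign = ISAssignment({"M": ISRecord(("IS1",), "regression_best")}, pd.DataFrame())
        nm = normalize(pt, assign)
        assert np.isnan(nm.data.loc["M", "s1"])

    def test_run_effect_cancels_in_ratio(self):
        design = MetabolomicsDesign(injection_sd=0.0, matrix_sd=0.0)
        pt, truth = gen_metabolomics_experiment(
            2, design, noise_sd=0.0, batch_effects={"run1": 1.0, "run2": 10.0}
        )
        # raw areas differ 10x between runs
        sub = pt[(pt["analyte_id"] == "M00") & (pt["condition"] == "uninduced")]
        by_run = sub.groupby("run_id")["area"].mean()
        assert by_run["run2"] / by_run["run1"] == pytest.approx(10.0)
        panel = pd.DataFrame(
            {"analyte_id": list(design.internal_standards),
             "structure_match_target": [""] * 4}
        )
        nm = normalize(pt, assign_internal_standards(pt, panel))
        vals = nm.data.loc["M00", nm.sample_meta["condition"] == "uninduced"]
        assert vals.std() == pytest.approx(0.0, abs=1e-12)


def _nm(values_by_run):
    cols, runs, vals = [], [], []
    for run, v in values_by_run.items():
        for i, x in enumerate(v):
            cols.append(f"{run}_s{i}")
            runs.append(run)
            vals.append(x)
    data = pd.DataFrame([vals], index=["M"], columns=cols)
    meta = pd.DataFrame({"run_id": runs, "condition": "induced"}, index=cols)
    return NormalizedMatrix(data, meta, "normalized")


class TestBatchCorrect:
    def test_single_run_identity(self):
        nm = _nm({"r1": [1.0, 2.0, 3.0, 7.0]})
        out = batch_correct(nm)
        assert np.allclose(out.data, nm.data)
        assert out.stage == "batch_corrected"

    def test_shifted_runs_align_medians(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, 9)
        nm = _nm({"r1": base, "r2": base + 5.0})
        out = batch_correct(nm)
        runs = out.sample_meta["run_id"]
        m1 = np.median(out.data.loc["M", runs.index[runs == "r1"]])
        m2 = np.median(out.data.loc["M", runs.index[runs == "r2"]])
        pooled = np.median(out.data.loc["M"])
        assert m1 == pytest.approx(pooled) and m2 == pytest.approx(pooled)

    def test_constant_run_centered_only(self):
        nm = _nm({"r1": [0.0, 1.0, 2.0, 3.0], "r2": [10.0, 10.0, 10.0]})
        out = batch_correct(nm)
        runs = out.sample_meta["run_id"]
        r2_vals = out.data.loc["M", runs.index[runs == "r2"]]
        # centered to the overall median, spread unchanged (zero)
        assert r2_vals.nunique() == 1

    def test_idempotent_on_affine_copy_runs(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 8)
        nm = _nm({"r1": base, "r2": 2 * base + 3})
        once = batch_correct(nm)
        twice = batch_correct(
            NormalizedMatrix(once.data, once.sample_meta, "normalized")
        )
        assert np.abs(once.data - twice.data).to_numpy().max() < 1e-9

    def test_requires_normalized_stage(self):
        nm = _nm({"r1": [1.0, 2.0]})
        out = batch_correct(nm)
        with pytest.raises(ParameterError):
            batch_correct(out)


class TestValidation:
    def test_negative_area_rejected(self):
        pt = _one_sample_table(-1.0, {"IS1": 100.0})
        with pytest.raises(Exception, match="non-negative"):
            validate_peak_table(pt)

    def test_planted_effect_for_unknown_analyte(self):
        with pytest.raises(ParameterError, match="unknown analytes"):
            gen_metabolomics_experiment(1, MetabolomicsDesign(), planted={"NOPE": 1.0})
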