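"""Internal-standard assignment, ratio normalization and batch correction for
targeted MRM metabolomics.

Raw peak areas from a triple-quadrupole run carry large multiplicative
instrument and injection effects.  Each metabolite is therefore reported as the
log2 ratio of its peak area to the area of one or more reference internal
standards (isotopically labeled compounds spiked into every sample), which
cancels any factor shared between target and standard.  Reference standards are
either structure-matched or chosen by calibration-curve quality: per run, a
weighted linear regression of the expected calibration concentration on the
target/standard area ratio is scored by adjusted R², and a standard qualifies
for a metabolite when the fit reaches the threshold in a sufficient share of
runs.  Residual run-to-run location/scale differences are removed by aligning
each metabolite's per-run median and interquartile range to its pooled values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import AssignmentError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

PEAK_COLUMNS = [
    "run_id",
    "batch_id",
    "sample_id",
    "analysis_id",
    "condition",
    "clone_id",
    "replicate",
    "analyte_id",
    "analyte_role",
    "area",
    "expected_conc",
]

CONDITIONS = {"induced", "uninduced", "calibration"}


def validate_peak_table(pt: pd.DataFrame) -> pd.DataFrame:
    """Check the structural invariants of a long-format peak table."""
    missing = [c for c in PEAK_COLUMNS if c not in pt.columns]
    if missing:
        raise ValidationError(f"peak table is missing columns {missing}")
    if (pt["area"] < 0).any():
        raise ValidationError("peak areas must be non-negative")
    bad_cond = set(pt["condition"]) - CONDITIONS
    if bad_cond:
        raise ValidationError(f"unknown conditions {sorted(bad_cond)}")
    calib = pt["condition"] == "calibration"
    if pt.loc[calib, "expected_conc"].isna().any():
        raise ValidationError("calibration rows must carry an expected concentration")
    dup = pt.duplicated(subset=["run_id", "sample_id", "analyte_id"])
    if dup.any():
        raise ValidationError("(run, sample, analyte) rows must be unique")
    return pt


@dataclass
class ISRecord:
    reference_is: tuple[str, ...]
    basis: str  # same_structure | regression_best | regression_fallback
    pct_qualifying: dict[str, float] = field(default_factory=dict)


@dataclass
class ISAssignment:
    """Metabolite → reference internal standard(s) with selection provenance."""

    records: dict[str, ISRecord]
    r2_table: pd.DataFrame  # columns: metabolite, internal_standard, run_id, adj_r2

    def reference_for(self, metabolite: str) -> tuple[str, ...]:
        return self.records[metabolite].reference_is


@dataclass
class NormalizedMatrix:
    """Metabolite × sample matrix of log2 internal-standard ratios."""

    data: pd.DataFrame  # index: metabolite, columns: sample_id
    sample_meta: pd.DataFrame  # index: sample_id; run_id, analysis_id, condition, ...
    stage: str  # normalized | batch_corrected
    provenance: pd.DataFrame | None = None  # sample_id, metabolite, used_is


def _adjusted_r2(y: np.ndarray, x: np.ndarray, weights: np.ndarray) -> float:
    """Adjusted R² of the weighted simple regression y ~ x."""
    res = sm.WLS(y, sm.add_constant(x), weights=weights).fit()
    n = len(y)
    return float(1.0 - (1.0 - res.rsquared) * (n - 1) / (n - 2))


def assign_internal_standards(
    pt: pd.DataFrame,
    panel: pd.DataFrame,
    r2_threshold: float = 0.85,
    run_fraction: float = 0.75,
    weighting: str = "inv_x2",
) -> ISAssignment:
    """Pick reference internal standard(s) for every metabolite in the table.

    ``panel`` has one row per internal standard: ``analyte_id`` and
    ``structure_match_target`` (the metabolite the standard is an isotopologue
    of, empty otherwise).  Structure-matched metabolites take their matched
    standard directly.  For the rest, each (metabolite, standard, run) with at
    least 3 calibration points is fit by weighted regression of expected
    concentration on the area ratio; a standard's qualifying percentage is the
    share of eligible runs with adjusted R² at or above ``r2_threshold``.  The
    standard(s) with the highest percentage among those reaching
    ``run_fraction`` are selected (ties keep all); if none reaches it, the
    best-percentage standard is kept as a fallback.
    """
    if weighting not in {"none", "inv_x", "inv_x2"}:
        raise ParameterError(f"unknown weighting {weighting!r}")
    validate_peak_table(pt)

    is_ids = list(panel["analyte_id"])
    structure_of = {
        row.structure_match_target: row.analyte_id
        for row in panel.itertuples()
        if isinstance(row.structure_match_target, str) and row.structure_match_target
    }
    targets = sorted(pt.loc[pt["analyte_role"] == "target", "analyte_id"].unique())
    calib = pt[pt["condition"] == "calibration"]

    # area lookup per run: analyte -> sample -> (area, expected_conc)
    records: dict[str, ISRecord] = {}
    r2_rows: list[dict] = []
    failed: list[str] = []

    for met in targets:
        if met in structure_of:
            records[met] = ISRecord((structure_of[met],), "same_structure")
            continue
        pct: dict[str, float] = {}
        for is_id in is_ids:
            n_eligible = 0
            n_qualifying = 0
            for run_id, sub in calib.groupby("run_id"):
                met_rows = sub[(sub["analyte_id"] == met) & (sub["area"] > 0)]
                is_rows = sub[(sub["analyte_id"] == is_id) & (sub["area"] > 0)]
                merged = met_rows.merge(
                    is_rows[["sample_id", "area"]], on="sample_id", suffixes=("", "_is")
                )
                if merged.empty:
                    continue  # metabolite or IS not detected in this run
                if len(merged) < 3:
                    logger.debug(
                        "run %s has <3 calibration points for (%s, %s); excluded",
                        run_id, met, is_id,
                    )
                    continue
                ratio = merged["area"].to_numpy() / merged["area_is"].to_numpy()
                conc = merged["expected_conc"].to_numpy(dtype=float)
                if weighting == "none":
                    w = np.ones_like(ratio)
                elif weighting == "inv_x":
                    w = 1.0 / ratio
                else:
                    w = 1.0 / ratio**2
                adj = _adjusted_r2(conc, ratio, w)
                n_eligible += 1
                if adj >= r2_threshold:
                    n_qualifying += 1
                r2_rows.append(
                    {
                        "metabolite": met,
                        "internal_standard": is_id,
                        "run_id": run_id,
                        "adj_r2": adj,
                    }
                )
            if n_eligible > 0:
                pct[is_id] = n_qualifying / n_eligible
        if not pct:
            failed.append(met)
            continue
        best = max(pct.values())
        qualifying = {i for i, p in pct.items() if p >= run_fraction}
        if qualifying:
            best_q = max(pct[i] for i in qualifying)
            chosen = tuple(sorted(i for i in qualifying if pct[i] == best_q))
            basis = "regression_best"
        else:
            chosen = tuple(sorted(i for i, p in pct.items() if p == best))
            basis = "regression_fallback"
        records[met] = ISRecord(chosen, basis, pct)

    if failed:
        raise AssignmentError(
            f"no eligible calibration runs for metabolites: {failed}"
        )
    r2_table = pd.DataFrame(
        r2_rows, columns=["metabolite", "internal_standard", "run_id", "adj_r2"]
    )
    return ISAssignment(records, r2_table)


def normalize(pt: pd.DataFrame, assign: ISAssignment) -> NormalizedMatrix:
    """log2(metabolite area / internal-standard area), averaged over the
    reference standards detected in each sample."""
    validate_peak_table(pt)
    samples = pt[pt["condition"].isin({"induced", "uninduced"})]
    sample_meta = (
        samples[["sample_id", "run_id", "batch_id", "analysis_id", "condition",
                 "clone_id", "replicate"]]
        .drop_duplicates(subset="sample_id")
        .set_index("sample_id")
    )
    # area lookup: (sample, analyte) -> area
    area = samples.set_index(["sample_id", "analyte_id"])["area"]
    metabolites = sorted(assign.records)
    sample_ids = list(sample_meta.index)
    values = np.full((len(metabolites), len(sample_ids)), np.nan)
    prov_rows: list[dict] = []
    for i, met in enumerate(metabolites):
        refs = assign.reference_for(met)
        for j, sid in enumerate(sample_ids):
            a_met = area.get((sid, met), np.nan)
            if not np.isfinite(a_met) or a_met <= 0:
                if a_met == 0:
                    logger.debug("zero area for %s in %s; left missing", met, sid)
                continue
            ratios = []
            used = []
            for is_id in refs:
                a_is = area.get((sid, is_id), np.nan)
                if np.isfinite(a_is) and a_is > 0:
                    ratios.append(np.log2(a_met / a_is))
                    used.append(is_id)
            if not ratios:
                logger.debug("no reference IS detected for %s in %s", met, sid)
                continue
            if len(used) < len(refs):
                logger.debug(
                    "sample %s uses reduced IS set %s for %s", sid, used, met
                )
            values[i, j] = float(np.mean(ratios))
            prov_rows.append(
                {"sample_id": sid, "metabolite": met, "used_is": ";".join(used)}
            )
    data = pd.DataFrame(values, index=metabolites, columns=sample_ids)
    provenance = pd.DataFrame(prov_rows, columns=["sample_id", "metabolite", "used_is"])
    return NormalizedMatrix(data, sample_meta, "normalized", provenance)


def batch_correct(nm: NormalizedMatrix) -> NormalizedMatrix:
    """Align each metabolite's per-run median and IQR to its pooled values.

    v' = (v − median_run) / IQR_run × IQR_overall + median_overall.  Runs with
    zero IQR are centered only.  A metabolite present in a single run is left
    unchanged (its run statistics equal the pooled statistics).
    """
    if nm.stage != "normalized":
        raise ParameterError(f"batch_correct expects stage 'normalized', got {nm.stage!r}")
    data = nm.data.copy()
    runs = nm.sample_meta["run_id"]
    for met in data.index:
        row = data.loc[met]
        vals = row.dropna()
        if vals.empty:
            continue
        med_all = float(np.median(vals))
        iqr_all = float(np.subtract(*np.percentile(vals, [75, 25])))
        for run_id in runs.unique():
            cols = runs.index[runs == run_id]
            sub = row[cols].dropna()
            if sub.empty:
                continue
            med_run = float(np.median(sub))
            iqr_run = float(np.subtract(*np.percentile(sub, [75, 25])))
            if iqr_run == 0.0:
                data.loc[met, sub.index] = sub - med_run + med_all
            else:
                data.loc[met, sub.index] = (sub - med_run) / iqr_run * iqr_all + med_all
    return NormalizedMatrix(data, nm.sample_meta, "batch_corrected", nm.provenance)
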