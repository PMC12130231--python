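"""Differential metabolite abundance between induced and uninduced samples.

Each analysis (one SLC cell-line model) compares doxycycline-induced to
uninduced samples, four replicates per condition.  Wild-type overexpression
models use a one-way ANOVA on the induction factor; knock-out re-expression
models, which contribute two independent clones, use a two-way additive ANOVA
with the clone as a second factor (no interaction).  P values are corrected per
analysis with the Benjamini–Hochberg step-up procedure and differential
abundance is called at a false discovery rate of 5%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError
from .metnorm import NormalizedMatrix

logger = logging.getLogger(__name__)

PADJ_THRESHOLD = 0.05


@dataclass
class ExperimentDesign:
    """Sample layout of one differential analysis."""

    analysis_id: str
    model: str  # one_way | two_way_clone
    samples: pd.DataFrame  # sample_id, condition, clone_id, replicate

    def __post_init__(self) -> None:
        if self.model not in {"one_way", "two_way_clone"}:
            raise ParameterError(f"unknown model {self.model!r}")
        required = {"sample_id", "condition"}
        if not required.issubset(self.samples.columns):
            raise ValidationError(f"design needs columns {sorted(required)}")
        conds = set(self.samples["condition"])
        if not {"induced", "uninduced"}.issubset(conds):
            raise ValidationError("design must contain induced and uninduced samples")
        if self.model == "two_way_clone":
            if "clone_id" not in self.samples.columns:
                raise ValidationError("two_way_clone design requires clone_id")
            per_clone = self.samples.groupby("clone_id")["condition"].nunique()
            if len(per_clone) < 2 or (per_clone < 2).any():
                raise ValidationError(
                    "two_way_clone requires >=2 clones, each with both conditions"
                )
        group_cols = ["condition"] + (
            ["clone_id"] if self.model == "two_way_clone" else []
        )
        sizes = self.samples.groupby(group_cols).size()
        if sizes.nunique() > 1:
            logger.warning(
                "analysis %s is unbalanced: group sizes %s",
                self.analysis_id, sizes.to_dict(),
            )


def load_design(path, analysis_id: str, model: str) -> ExperimentDesign:
    """Read a design CSV with columns sample_id, condition, clone, replicate."""
    df = pd.read_csv(path, dtype=str)
    df = df.rename(columns={"clone": "clone_id"})
    return ExperimentDesign(analysis_id, model, df)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _f_test_induction(y: np.ndarray, induction: np.ndarray, clone: np.ndarray | None):
    """F-test of the induction term in an additive linear model.

    Returns (F, p).  Degenerate zero-residual fits are resolved explicitly:
    zero effect with zero residual gives F=0/p=1; a nonzero effect fit exactly
    gives p=0.
    """
    n = len(y)
    cols = [np.ones(n), induction.astype(float)]
    reduced_cols = [np.ones(n)]
    if clone is not None:
        levels = sorted(set(clone))
        for lev in levels[1:]:
            dummy = (clone == lev).astype(float)
            cols.append(dummy)
            reduced_cols.append(dummy)
    X_full = np.column_stack(cols)
    X_red = np.column_stack(reduced_cols)
    df_full = n - X_full.shape[1]
    if df_full <= 0:
        return np.nan, np.nan

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid)

    rss_full = rss(X_full)
    rss_red = rss(X_red)
    num = max(rss_red - rss_full, 0.0)
    # numerically-zero residuals, relative to the response scale
    tol = 1e-12 * max(1.0, float(y @ y))
    if rss_full <= tol:
        if num <= tol:
            return 0.0, 1.0
        return np.inf, 0.0
    F = num / (rss_full / df_full)
    return F, float(stats.f.sf(F, 1, df_full))


def test_differential(nm: NormalizedMatrix, design: ExperimentDesign) -> pd.DataFrame:
    """Per-feature induction test on a batch-corrected matrix.

    Returns a DiffTable with columns feature, lfc, pvalue, padj, significant;
    ``analysis_id`` and ``model`` are stored in ``DataFrame.attrs``.  Features
    entirely missing in one condition get NaN statistics and are excluded from
    the BH family.
    """
    if nm.stage != "batch_corrected":
        raise ParameterError(
            f"test_differential expects stage 'batch_corrected', got {nm.stage!r}"
        )
    sample_ids = [s for s in design.samples["sample_id"] if s in nm.data.columns]
    if len(sample_ids) < len(design.samples):
        logger.warning(
            "analysis %s: %d design samples missing from the matrix",
            design.analysis_id, len(design.samples) - len(sample_ids),
        )
    meta = design.samples.set_index("sample_id").loc[sample_ids]
    rows = []
    for feature in nm.data.index:
        vals = nm.data.loc[feature, sample_ids]
        ok = vals.notna().to_numpy()
        y = vals.to_numpy(dtype=float)[ok]
        cond = meta["condition"].to_numpy()[ok]
        induced = cond == "induced"
        if induced.sum() == 0 or (~induced).sum() == 0:
            logger.debug(
                "feature %s missing in one condition of %s; no statistics",
                feature, design.analysis_id,
            )
            rows.append({"feature": feature, "lfc": np.nan, "pvalue": np.nan})
            continue
        if design.model == "two_way_clone":
            clone = meta["clone_id"].to_numpy()[ok]
            diffs = []
            for c in sorted(set(clone)):
                m = clone == c
                if induced[m].any() and (~induced[m]).any():
                    diffs.append(y[m & induced].mean() - y[m & ~induced].mean())
            lfc = float(np.mean(diffs)) if diffs else np.nan
            F, p = _f_test_induction(y, induced, clone)
        else:
            lfc = float(y[induced].mean() - y[~induced].mean())
            F, p = _f_test_induction(y, induced, None)
        rows.append({"feature": feature, "lfc": lfc, "pvalue": p})
    table = pd.DataFrame(rows, columns=["feature", "lfc", "pvalue"])
    table["padj"] = np.nan
    tested = table["pvalue"].notna()
    if tested.any():
        table.loc[tested, "padj"] = bh_adjust(table.loc[tested, "pvalue"])
    table["significant"] = table["padj"] < PADJ_THRESHOLD
    table.attrs["analysis_id"] = design.analysis_id
    table.attrs["model"] = design.model
    return table
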