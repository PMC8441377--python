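"""Downstream expression statistics: ddCT fold change, percent change, ratios.

Implements the comparative-CT (Livak) method for RT-qPCR relative expression
with two normalization schemes — one global calibrator cell (e.g. empty
vector at permissive temperature) or a calibrator matched on growth condition
— plus percent-change quantification of staining/blot intensity tables,
per-replicate transduction-efficiency ratios, and Welch two-sample t tests.

Amplification efficiency is fixed at 2.0 (fold change = 2^-ddCt); technical
replicates of the same (sample, gene) are averaged to one Cq before dCt.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ddct_fold_change",
    "percent_change",
    "transduction_efficiency",
    "two_sample_t",
    "PercentChangeResult",
]

logger = logging.getLogger(__name__)

GLOBAL_CALIBRATOR = "global_calibrator"
CONDITION_MATCHED = "condition_matched"


def _validate_qpcr(qpcr: pd.DataFrame) -> None:
    required = {"sample_id", "group", "condition", "gene", "cq"}
    missing = required - set(qpcr.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    if not qpcr["cq"].between(0, 45, inclusive="neither").all():
        raise ValueError("Cq values must lie in (0, 45)")
    genes = set(qpcr["gene"])
    if not genes <= {"target", "housekeeping"}:
        raise ValueError(f"gene must be target/housekeeping, got {sorted(genes)}")


def ddct_fold_change(
    qpcr: pd.DataFrame,
    calibrator: tuple[str, str],
    scheme: str = GLOBAL_CALIBRATOR,
) -> pd.DataFrame:
    """Comparative-CT fold change per sample.

    dCt = Cq(target) - Cq(housekeeping) per sample (technical replicates
    averaged first). ddCt subtracts the mean dCt of the calibrator samples:
    with ``global_calibrator`` the single cell ``calibrator`` =
    (group, condition) calibrates every sample; with ``condition_matched`` the
    calibrator group is taken within each sample's own condition. Fold change
    is 2^-ddCt.
    """
    _validate_qpcr(qpcr)
    if scheme not in (GLOBAL_CALIBRATOR, CONDITION_MATCHED):
        raise ValueError(f"unknown scheme {scheme!r}")
    cal_group, cal_condition = calibrator

    # one Cq per (sample, gene): average technical replicates
    cq = (
        qpcr.groupby(["sample_id", "group", "condition", "gene"])["cq"]
        .mean()
        .unstack("gene")
    )
    if "housekeeping" not in cq.columns or cq["housekeeping"].isna().any():
        bad = (
            cq.index.get_level_values("sample_id").tolist()
            if "housekeeping" not in cq.columns
            else cq[cq["housekeeping"].isna()].index.get_level_values("sample_id").tolist()
        )
        raise ValueError(f"missing housekeeping Cq for samples: {bad}")
    if cq["target"].isna().any():
        bad = cq[cq["target"].isna()].index.get_level_values("sample_id").tolist()
        raise ValueError(f"missing target Cq for samples: {bad}")

    out = cq.reset_index()
    out["dct"] = out["target"] - out["housekeeping"]

    if scheme == GLOBAL_CALIBRATOR:
        cal = out[(out["group"] == cal_group) & (out["condition"] == cal_condition)]
        if cal.empty:
            raise ValueError(f"empty calibrator cell {calibrator}")
        out["ddct"] = out["dct"] - cal["dct"].mean()
    else:
        cal_means = (
            out[out["group"] == cal_group].groupby("condition")["dct"].mean()
        )
        if cal_means.empty:
            raise ValueError(f"empty calibrator group {cal_group!r}")
        missing = set(out["condition"]) - set(cal_means.index)
        if missing:
            raise ValueError(f"no calibrator samples for conditions: {sorted(missing)}")
        out["ddct"] = out["dct"] - out["condition"].map(cal_means)

    out["fold_change"] = np.exp2(-out["ddct"])
    return out[["sample_id", "group", "condition", "dct", "ddct", "fold_change"]]


@dataclass
class PercentChangeResult:
    percent_change: float  # positive = decrease relative to control
    mean_control: float
    mean_treated: float
    control_values: np.ndarray
    treated_values: np.ndarray


def _cell_values(
    intensity: pd.DataFrame,
    measure: str,
    cell: tuple[str, str],
    normalizer: str | None,
) -> np.ndarray:
    group, condition = cell
    sub = intensity[(intensity["group"] == group) & (intensity["condition"] == condition)]
    vals = sub[sub["measure"] == measure].set_index("replicate")["value"]
    if vals.empty:
        raise ValueError(f"no {measure!r} rows for cell {cell}")
    if normalizer is None:
        return vals.to_numpy(dtype=float)
    norm = sub[sub["measure"] == normalizer].set_index("replicate")["value"]
    missing = set(vals.index) - set(norm.index)
    if missing:
        raise ValueError(f"missing {normalizer!r} for replicates {sorted(missing)}")
    norm = norm.loc[vals.index]
    if (norm <= 0).any():
        raise ValueError(f"nonpositive {normalizer!r} value; cannot normalize")
    return (vals / norm).to_numpy(dtype=float)


def percent_change(
    intensity: pd.DataFrame,
    measure: str,
    treated: tuple[str, str],
    control: tuple[str, str],
    normalizer: str | None = None,
) -> PercentChangeResult:
    """Percent change of a measure between two (group, condition) cells.

    Values are first divided per replicate by the ``normalizer`` measure (e.g.
    blot bands by tubulin) when given. Percent change =
    100*(mean_control - mean_treated)/mean_control; positive numbers are
    decreases, matching how staining/blot reductions are reported.
    """
    required = {"group", "condition", "replicate", "measure", "value"}
    missing = required - set(intensity.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    if (intensity["value"] < 0).any():
        raise ValueError("intensity values must be >= 0")
    cv = _cell_values(intensity, measure, control, normalizer)
    tv = _cell_values(intensity, measure, treated, normalizer)
    mc, mt = float(np.mean(cv)), float(np.mean(tv))
    if mc == 0:
        raise ValueError("control mean is 0: percent change undefined")
    return PercentChangeResult(100.0 * (mc - mt) / mc, mc, mt, cv, tv)


def transduction_efficiency(intensity: pd.DataFrame) -> tuple[float, pd.Series]:
    """Mean per-replicate ratio of mCherry-positive to brightfield cell counts.

    Returns (mean ratio, per-replicate ratios). Ratios above 1 are allowed
    (counting noise) but logged.
    """
    bf = intensity[intensity["measure"] == "cells_brightfield"].set_index("replicate")["value"]
    mc = intensity[intensity["measure"] == "cells_mcherry"].set_index("replicate")["value"]
    if bf.empty or mc.empty:
        raise ValueError("need cells_brightfield and cells_mcherry rows")
    missing = set(mc.index) ^ set(bf.index)
    if missing:
        raise ValueError(f"unmatched replicates: {sorted(missing)}")
    if (bf <= 0).any():
        raise ValueError("brightfield count of 0: ratio undefined")
    ratios = (mc.loc[bf.index] / bf).rename("ratio")
    if (ratios > 1).any():
        logger.warning("transduction ratio > 1 for replicates %s",
                       sorted(ratios[ratios > 1].index))
    return float(ratios.mean()), ratios


def two_sample_t(
    a: Sequence[float], b: Sequence[float], equal_var: bool = False
) -> tuple[float, float, float]:
    """Two-sided two-sample t test; Welch by default.

    Returns (t, df, p) with Welch–Satterthwaite degrees of freedom (or n1+n2-2
    for the pooled-variance variant).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate: both groups constant; t test undefined, report the limit
        df = float(len(a) + len(b) - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), df, 0.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)
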