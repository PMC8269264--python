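"""Cohort-level clinical descriptors.

Small utilities for the clinical side of the study: the percent
excess-BMI-loss statistic used to summarize surgical success, and per-group
per-time-point covariate summaries with a paired rank test between
enrollment and the latest sampled visit.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .tables import TIMEPOINT_ORDER

logger = logging.getLogger(__name__)


def excess_bmi_loss_pct(bmi_start: float, bmi_end: float,
                        reference: float = 25.0) -> float:
    """Percent of the BMI excess above ``reference`` lost between two points.

    ``100 × (start − end) / (start − reference)``: 100% means the subject
    came all the way down to the reference BMI; 0% means no change.
    Scaling all three inputs about the reference leaves the value unchanged.
    """
    if bmi_start <= reference:
        raise ValueError(
            f"bmi_start ({bmi_start}) must exceed the reference ({reference})")
    return 100.0 * (bmi_start - bmi_end) / (bmi_start - reference)


def summarize_groups(meta: pd.DataFrame,
                     covariates=("bmi", "a1c", "age")) -> pd.DataFrame:
    """Mean ± SD per (covariate, time point) plus paired enrollment-vs-latest p.

    For each covariate, reports mean, SD and n at every time point with data
    (lean H included).  A two-sided Wilcoxon signed-rank test compares
    enrollment (A) with each subject's latest sampled obese time point,
    over subjects observed at both; its p-value is descriptive, attached to
    the latest-point rows as ``p_paired_vs_A``.
    """
    rows = []
    obese = meta[meta["timepoint"].isin(list(TIMEPOINT_ORDER))]
    for cov in covariates:
        values = pd.to_numeric(meta[cov], errors="coerce")
        for code in sorted(meta["timepoint"].unique()):
            sel = values[(meta["timepoint"] == code) & values.notna()]
            if sel.empty:
                logger.info("summarize_groups: no %s data at %s, omitted", cov, code)
                continue
            rows.append({"covariate": cov, "timepoint": code,
                         "mean": float(sel.mean()), "sd": float(sel.std(ddof=0)),
                         "n": int(len(sel)), "p_paired_vs_A": np.nan})
        # paired A vs latest sampled obese point per subject
        cov_obese = pd.to_numeric(obese[cov], errors="coerce")
        paired_a, paired_late = [], []
        for _, sub in obese.groupby("subject_id"):
            sub = sub.sort_values("timepoint", key=lambda s: s.map(TIMEPOINT_ORDER))
            vals = pd.to_numeric(sub[cov], errors="coerce")
            if len(sub) < 2 or sub.iloc[0]["timepoint"] != "A":
                continue
            if pd.notna(vals.iloc[0]) and pd.notna(vals.iloc[-1]):
                paired_a.append(float(vals.iloc[0]))
                paired_late.append(float(vals.iloc[-1]))
        if len(paired_a) >= 5 and not np.allclose(paired_a, paired_late):
            stat = stats.wilcoxon(paired_a, paired_late, alternative="two-sided")
            for row in rows:
                if row["covariate"] == cov and row["timepoint"] in ("B", "C", "D", "E"):
                    row["p_paired_vs_A"] = float(stat.pvalue)
    return pd.DataFrame(rows)
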