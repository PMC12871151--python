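"""Condition-level aggregation, rank-sum comparisons and activation index.

Readouts (rate constants, lifetimes, nucleation fractions, forces) are
summarized per condition as median and quartiles and compared pairwise by
the two-sided Mann–Whitney U test (exact null distribution for small
samples, tie-corrected normal approximation otherwise). Significance
stars follow the thresholds ** p < 1e-2, *** p < 1e-5, **** p < 1e-10;
no multiple-testing correction is applied (noted in the report footer).

Integrin activation from flow cytometry is normalized as the activation
index AI = (F − F₀) / (F_max − F₀), with F the mean PAC-1 fluorescence,
F₀ its value under the competitive inhibitor and F_max under the
activating antibody.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

STAR_THRESHOLDS = ((1e-10, "****"), (1e-5, "***"), (1e-2, "**"))
REPORT_FOOTER = ("p-values are uncorrected for multiple comparisons; "
                 "stars: ** p<1e-2, *** p<1e-5, **** p<1e-10")


@dataclass
class ActivationMeasurement:
    """PAC-1 mean fluorescence triplet for the activation index."""

    F: float      # MFI of the sample
    F0: float     # MFI under the competitive inhibitor
    Fmax: float   # MFI under the activating antibody


@dataclass
class ConditionSummary:
    """Named scalar readout samples for one experimental condition."""

    condition_label: str
    samples: dict[str, list[float]] = field(default_factory=dict)
    n_cells: int = 0

    @property
    def n_adhesions(self) -> int:
        return max((len(v) for v in self.samples.values()), default=0)


def activation_index(m: ActivationMeasurement) -> float:
    """AI = (F − F₀) / (F_max − F₀); requires F_max ≠ F₀."""
    if m.Fmax == m.F0:
        raise ValueError("activation index undefined: Fmax equals F0")
    return (m.F - m.F0) / (m.Fmax - m.F0)


def compare_conditions(a, b) -> dict[str, float]:
    """Two-sided Mann–Whitney U test between two readout samples.

    Uses the exact null distribution when both samples are small (≤ 8) and
    tie-free, otherwise the tie-corrected normal approximation. Returns
    the U statistic of the first sample and the two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if np.isnan(p):  # zero-variance tie-corrected denominator (all tied)
        p = 1.0
    return {"u_statistic": float(res.statistic), "p_value": min(p, 1.0)}


def significance_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return ""


def build_report(summaries: list[ConditionSummary]):
    """Summary and pairwise-comparison tables for a set of conditions.

    Returns ``(summary_table, comparison_table)`` DataFrames. The summary
    holds median and Tukey quartiles per (condition, readout); the
    comparison table holds all pairwise Mann–Whitney tests per readout
    with significance stars. With a single condition the comparison table
    is empty.
    """
    if not summaries:
        raise ValueError("at least one condition is required")
    labels = [s.condition_label for s in summaries]
    if len(set(labels)) != len(labels):
        raise ValueError("condition labels must be unique")
    rows = []
    for s in summaries:
        for name, values in s.samples.items():
            v = np.asarray(values, dtype=float)
            if v.size == 0:
                continue
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows.append({"condition": s.condition_label, "readout": name,
                         "median": med, "q1": q1, "q3": q3, "n": v.size,
                         "whisker_low": max(v.min(), q1 - 1.5 * (q3 - q1)),
                         "whisker_high": min(v.max(), q3 + 1.5 * (q3 - q1))})
    summary = pd.DataFrame(rows)
    comp_rows = []
    for sa, sb in combinations(summaries, 2):
        for name in sorted(set(sa.samples) & set(sb.samples)):
            va, vb = sa.samples[name], sb.samples[name]
            if len(va) < 2 or len(vb) < 2:
                continue
            res = compare_conditions(va, vb)
            comp_rows.append({
                "readout": name, "condition_a": sa.condition_label,
                "condition_b": sb.condition_label,
                "u_statistic": res["u_statistic"], "p_value": res["p_value"],
                "stars": significance_stars(res["p_value"])})
    comparisons = pd.DataFrame(
        comp_rows, columns=["readout", "condition_a", "condition_b",
                            "u_statistic", "p_value", "stars"])
    summary.attrs["footer"] = REPORT_FOOTER
    comparisons.attrs["footer"] = REPORT_FOOTER
    return summary, comparisons
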