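"""Group-comparison statistics and the end-to-end pipeline report.

Two-group comparisons use the two-sample Student's t-test (equal variance
by default, Welch by flag); three or more groups use one-way ANOVA followed
by Tukey's HSD pairwise multi-comparison. Significance stars follow the
convention * p<0.05, ** p<0.01, *** p<0.001. Group dispersions are reported
as plain mean +- SEM (no mixed-effect modelling).
"""
from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datatypes import ComparisonResult, significance_stars

__all__ = ["t_test", "anova_tukey", "build_report"]


def t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
    labels: Sequence[str] = ("A", "B"),
) -> ComparisonResult:
    """Two-sided two-sample t-test (Student by default, Welch if not)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(
        test="student_t" if equal_var else "welch_t",
        groups=list(labels),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        pairwise=None,
        stars=significance_stars(float(res.pvalue)),
    )


def anova_tukey(
    groups: Dict[str, Sequence[float]], alpha: float = 0.05
) -> ComparisonResult:
    """One-way ANOVA with Tukey HSD pairwise follow-up for >= 3 groups."""
    if len(groups) < 3:
        raise ValueError("anova_tukey needs at least three groups; use t_test")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs at least two observations")
    f_stat, p_global = sps.f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * v.size for k, v in arrays.items()])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairwise = pd.DataFrame(
        data=tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    pairwise["stars"] = [significance_stars(p) for p in tukey.pvalues]
    return ComparisonResult(
        test="anova_tukey",
        groups=list(arrays),
        statistic=float(f_stat),
        p_value=float(p_global),
        pairwise=pairwise,
        stars=significance_stars(float(p_global)),
    )


def build_report(
    out_dir: str,
    contractility: Optional[pd.DataFrame] = None,
    elasticity_groups: Optional[pd.DataFrame] = None,
    method_differences: Optional[pd.DataFrame] = None,
    imaging: Optional[pd.DataFrame] = None,
    qc_tally: Optional[Dict[str, int]] = None,
    provenance: Optional[Dict[str, str]] = None,
) -> Path:
    """Assemble the pipeline report: one CSV per section plus a markdown summary.

    Sections whose input is None are marked absent in the summary; at least
    one section must be present. Re-running with identical inputs produces
    byte-identical tables. ``provenance`` maps each section to the input it
    was computed from and is logged verbatim.
    """
    sections = {
        "contractility": contractility,
        "elasticity_groups": elasticity_groups,
        "method_differences": method_differences,
        "imaging": imaging,
    }
    if all(v is None for v in sections.values()) and qc_tally is None:
        raise ValueError("cannot build a report from no analysis outputs")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    lines = ["# Cardiomyocyte differentiation pipeline report", ""]
    for name, df in sections.items():
        if df is None:
            lines.append(f"- {name}: absent (no input provided)")
            continue
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        lines.append(f"- {name}: {len(df)} rows, written to {path.name}")
    if qc_tally is not None:
        tally_df = pd.DataFrame(
            sorted(qc_tally.items()), columns=["outcome", "count"]
        )
        tally_df.to_csv(out / "qc_tally.csv", index=False)
        lines.append(f"- qc_tally: {int(tally_df['count'].sum())} curves, written to qc_tally.csv")
    else:
        lines.append("- qc_tally: absent (no input provided)")
    if provenance:
        lines += ["", "## Provenance"]
        lines += [f"- {k}: {v}" for k, v in sorted(provenance.items())]
    summary = out / "summary.md"
    summary.write_text("\n".join(lines) + "\n")
    return summary
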