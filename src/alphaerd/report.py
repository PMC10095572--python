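"""Human-readable markdown summary of a pipeline run."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["make_report"]


def _fmt(x, digits=2) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "—"
    return f"{x:.{digits}f}"


def _fmt_p(p) -> str:
    if p is None or not np.isfinite(p):
        return "—"
    return f"{p:.3g}" if p >= 0.001 else "<0.001"


def _demographics_md(demo: pd.DataFrame) -> list[str]:
    lines = ["| group | N | Age | Gender m/f | APOE E4−/E4+ | LFT (words) |",
             "|---|---|---|---|---|---|"]
    for _, row in demo.iterrows():
        if row["row"] == "p_value":
            lines.append(
                "| *p*-values | | {} | {} | {} | {} |".format(
                    _fmt_p(row.get("age_mean")), _fmt_p(row.get("gender_m")),
                    _fmt_p(row.get("apoe_e4neg")), _fmt_p(row.get("lft_mean")),
                )
            )
        else:
            lines.append(
                "| {} | {} | {} ± {} | {}/{} | {}/{} | {} ± {} |".format(
                    row["row"], int(row["n"]),
                    _fmt(row["age_mean"], 1), _fmt(row["age_se"], 1),
                    int(row["gender_m"]), int(row["gender_f"]),
                    int(row["apoe_e4neg"]), int(row["apoe_e4pos"]),
                    _fmt(row["lft_mean"], 1), _fmt(row["lft_se"], 1),
                )
            )
    return lines


def _table_md(frame: pd.DataFrame, columns: dict[str, str], p_cols=("p",)) -> list[str]:
    lines = ["| " + " | ".join(columns.values()) + " |",
             "|" + "---|" * len(columns)]
    for _, row in frame.iterrows():
        cells = []
        for col in columns:
            val = row.get(col)
            if col in p_cols:
                cells.append(_fmt_p(val))
            elif isinstance(val, (float, np.floating)):
                cells.append(_fmt(val))
            else:
                cells.append(str(val))
        lines.append("| " + " | ".join(cells) + " |")
    return lines


def make_report(result) -> str:
    """Markdown analogue of the study's result tables for one pipeline run.

    Sign convention: negative ERD% is desynchronization (task-related
    activation), positive is synchronization.
    """
    out = ["# Task-related alpha ERD/S analysis", ""]
    out.append(f"Cohort: {result.metadata['subject_id'].nunique()} subjects; "
               f"{len(result.excluded)} excluded for insufficient artifact-free epochs.")
    out.append("Negative ERD% = desynchronization (activation); positive = synchronization.")
    out.append("")
    for label, report in result.reports.items():
        title = "Full cohort" if label == "full" else label.replace("_", " ")
        out.append(f"## {title} (N = {report.n_subjects})")
        out.append("")
        out.append("### Demographics")
        out.extend(_demographics_md(report.demographics))
        out.append("")
        if not report.one_sample.empty:
            out.append("### One-sample ERD/S tests (mean vs 0)")
            out.extend(_table_md(report.one_sample, {
                "clu_group": "group", "band": "band", "region": "region", "n": "n",
                "mean_erd": "mean ERD%", "se": "SE", "t": "t", "p": "p"}))
            out.append("")
        if not report.glm.empty:
            out.append("### Genotype GLM (covariates: APOE, sex, age)")
            out.extend(_table_md(report.glm, {
                "band": "band", "region": "region", "F": "F",
                "df_num": "df1", "df_den": "df2", "p": "p"}))
            out.append("")
        if not report.posthoc.empty:
            out.append("### Duncan post hoc")
            out.extend(_table_md(report.posthoc, {
                "band": "band", "region": "region", "comparison": "comparison",
                "mean_difference": "Δ mean", "critical_range": "critical range",
                "p": "p", "significant": "significant"}))
            out.append("")
        if not report.correlations.empty:
            out.append("### Pearson correlations with age")
            out.extend(_table_md(report.correlations, {
                "pair": "pair", "n": "n", "r": "r", "p": "p"}))
            out.append("")
        if report.warnings:
            out.append("### Warnings")
            out.extend(f"- {w}" for w in report.warnings)
            out.append("")
    return "\n".join(out)
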