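"""End-to-end pipeline: study file -> the four report tables.

Everything here is a pure, deterministic function of the study dataset and
the pipeline configuration; all randomness lives in the synthetic-study
generator.  The bundle carries both display tables (percentages rounded
half-up to one decimal) and raw unrounded values for JSON export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field

from .aggregation import (
    ConfusionCounts,
    Level,
    average_counts,
    counts_at_level,
)
from .agreement import (
    call_vector,
    change_table,
    intra_reader_changes,
    mean_pairwise_kappa,
    readers_vs_ai_kappa,
    status_accuracy,
)
from .failures import find_majority_disagreements
from .matching import OverlapConvention, match_study
from .metrics import metric_table_json, metrics_from_counts, render_metric_table
from .model import StudyDataset, summarize_dataset
from .simulate import threshold_sweep

LEVELS: tuple[Level, ...] = ("examination", "image", "fracture")


class PipelineConfig(BaseModel):
    """Analysis configuration, serialized alongside every report."""

    model_config = ConfigDict(frozen=True)

    overlap_mode: str = "gt_fraction"
    overlap_threshold: float = Field(0.40, ge=0.0, le=1.0)
    inclusive_threshold: bool = True
    ci_level: float = Field(0.95, gt=0.0, lt=1.0)
    majority_threshold: int = Field(5, ge=1)
    fracture_change_denominator: str = "gt_plus_fp_events"
    ndigits: int = 1
    sweep_thresholds: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))

    def convention(self) -> OverlapConvention:
        return OverlapConvention(
            mode=self.overlap_mode,
            threshold=self.overlap_threshold,
            inclusive=self.inclusive_threshold,
        )


@dataclass
class ReportBundle:
    """All tables of one pipeline run plus the config that produced them."""

    dataset_summary: "object"  # Table-1 analogue (DataFrame)
    metric_tables: dict  # level -> DataFrame (Table-2 analogue)
    metric_raw: dict  # level -> raw counts/metrics/CIs (JSON-able)
    change_tables: dict  # level -> DataFrame (Table-3 analogue)
    failure_table: "object"  # Table-4 analogue (DataFrame)
    kappa_table: "object"  # DataFrame: inter-reader / reader-vs-AI per level
    status_accuracy: dict  # round -> {accuracy, n_correct, n_tp}
    per_reader: "object"  # appendix DataFrame
    sweep: "object"  # threshold sweep DataFrame
    config: PipelineConfig
    counts: dict = field(default_factory=dict)  # (level, label) -> ConfusionCounts


def run_pipeline(ds: StudyDataset, config: PipelineConfig = PipelineConfig()) -> ReportBundle:
    import pandas as pd

    conv = config.convention()
    reader_ids = ds.reader_ids
    if not reader_ids:
        raise ValueError("study has no reader annotations")

    matches = {"ai": match_study(ds, ds.ai, conv)}
    anns = {"ai": ds.ai}
    for rid in reader_ids:
        for rnd in ("r1", "r2"):
            key = f"{rid}:{rnd}"
            anns[key] = ds.reader_annotations(rid, rnd)
            matches[key] = match_study(ds, anns[key], conv)

    counts: dict[tuple[str, str], ConfusionCounts] = {}
    for level in LEVELS:
        for key in anns:
            counts[(level, key)] = counts_at_level(ds, anns[key], matches[key], level, key)
        counts[(level, "avg_radiologist")] = average_counts(
            [counts[(level, f"{rid}:r1")] for rid in reader_ids], "avg_radiologist"
        )
        counts[(level, "avg_radiologist_ai")] = average_counts(
            [counts[(level, f"{rid}:r2")] for rid in reader_ids], "avg_radiologist_ai"
        )

    metric_tables = {}
    metric_raw = {}
    for level in LEVELS:
        by_source = {
            lab: counts[(level, lab)]
            for lab in ("avg_radiologist", "avg_radiologist_ai", "ai")
        }
        metric_tables[level] = render_metric_table(
            by_source, ci_level=config.ci_level, ndigits=config.ndigits
        )
        metric_raw[level] = metric_table_json(by_source, ci_level=config.ci_level)

    change_tables = {}
    for level in LEVELS:
        summaries = [
            intra_reader_changes(
                ds, rid, level, conv,
                fracture_denominator=config.fracture_change_denominator,
            )[1]
            for rid in reader_ids
        ]
        change_tables[level] = change_table(summaries)

    _, failure_table = find_majority_disagreements(
        ds, conv, majority_threshold=config.majority_threshold
    )

    kappa_rows = []
    for level in LEVELS:
        kw = dict(kappa_mode=True, convention=conv) if level == "fracture" else {}
        vecs = {
            rnd: [call_vector(ds, "reader", level, rnd, rid, **kw) for rid in reader_ids]
            for rnd in ("r1", "r2")
        }
        ai_vec = call_vector(ds, "ai", level, **kw)
        # inter-reader agreement is undefined for a single reader
        inter = (
            {rnd: mean_pairwise_kappa(vecs[rnd]).kappa for rnd in ("r1", "r2")}
            if len(reader_ids) >= 2
            else {"r1": float("nan"), "r2": float("nan")}
        )
        kappa_rows.append(
            {
                "level": level,
                "inter_reader_r1": inter["r1"],
                "inter_reader_r2": inter["r2"],
                "readers_vs_ai_r1": readers_vs_ai_kappa(vecs["r1"], ai_vec).kappa,
                "readers_vs_ai_r2": readers_vs_ai_kappa(vecs["r2"], ai_vec).kappa,
            }
        )
    kappa_df = pd.DataFrame(kappa_rows).set_index("level")

    status = {}
    for rnd in ("r1", "r2"):
        acc, n_correct, n_tp = status_accuracy(ds, rnd, convention=conv)
        status[rnd] = {"accuracy": acc, "n_correct": n_correct, "n_tp": n_tp}

    appendix_rows = []
    for level in LEVELS:
        for key in sorted(k for (lv, k) in counts if lv == level):
            c = counts[(level, key)]
            ms = metrics_from_counts(c, config.ci_level)
            appendix_rows.append(
                {
                    "level": level,
                    "source": key,
                    **c.as_dict(),
                    **{name: mv.value for name, mv in ms.as_dict().items()},
                }
            )
    per_reader = pd.DataFrame(appendix_rows)

    sweep = threshold_sweep(
        ds,
        config.sweep_thresholds,
        mode=config.overlap_mode,
        inclusive=config.inclusive_threshold,
    )

    return ReportBundle(
        dataset_summary=summarize_dataset(ds),
        metric_tables=metric_tables,
        metric_raw=metric_raw,
        change_tables=change_tables,
        failure_table=failure_table,
        kappa_table=kappa_df,
        status_accuracy=status,
        per_reader=per_reader,
        sweep=sweep,
        config=config,
        counts={f"{level}/{key}": c for (level, key), c in counts.items()},
    )


def _df_markdown(df, index=True) -> str:
    """Minimal pipe-table renderer (no external tabulate dependency)."""
    import pandas as pd

    d = df.reset_index() if index else df
    d = d.astype(object).where(pd.notna(d), "")
    cols = [str(c) for c in d.columns]
    lines = ["| " + " | ".join(cols) + " |", "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in d.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines)


def write_report(
    bundle: ReportBundle,
    outdir: str | Path,
    formats: Sequence[str] = ("csv", "json", "markdown"),
) -> None:
    """Write the report bundle under ``outdir`` as CSV, JSON and Markdown."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    tables = {"table1_dataset": (bundle.dataset_summary, False)}
    for level, df in bundle.metric_tables.items():
        tables[f"table2_metrics_{level}"] = (df, True)
    for level, df in bundle.change_tables.items():
        tables[f"table3_changes_{level}"] = (df, False)
    tables["table4_failures"] = (bundle.failure_table, True)
    tables["kappa"] = (bundle.kappa_table, True)
    tables["per_reader_appendix"] = (bundle.per_reader, False)
    tables["threshold_sweep"] = (bundle.sweep, False)

    if "csv" in formats:
        for name, (df, index) in tables.items():
            df.to_csv(outdir / f"{name}.csv", index=index)
    if "markdown" in formats:
        parts = [f"## {name}\n\n{_df_markdown(df, index)}\n" for name, (df, index) in tables.items()]
        (outdir / "report.md").write_text("\n".join(parts), encoding="utf-8")
    if "json" in formats:
        payload = {
            "config": bundle.config.model_dump(),
            "metrics": bundle.metric_raw,
            "status_accuracy": bundle.status_accuracy,
            "counts": {
                key: {**c.as_dict(), "level": c.level} for key, c in bundle.counts.items()
            },
            "kappa": bundle.kappa_table.to_dict(orient="index"),
            "failures": bundle.failure_table.to_dict(orient="index"),
            "changes": {
                level: df.to_dict(orient="records")
                for level, df in bundle.change_tables.items()
            },
        }
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, default=float)
            fh.write("\n")


def plot_metric_bars(bundle: ReportBundle, level: Level = "examination", path: Optional[str | Path] = None):
    """Bar chart of PPV/NPV/sensitivity/specificity/accuracy with CI error
    bars for the three reading conditions at one level."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    raw = bundle.metric_raw[level]
    metrics = ["ppv", "npv", "sensitivity", "specificity", "accuracy"]
    sources = ["avg_radiologist", "avg_radiologist_ai", "ai"]
    fig, ax = plt.subplots(figsize=(9, 4.5))
    x = np.arange(len(metrics))
    width = 0.26
    for k, src in enumerate(sources):
        vals, err_lo, err_hi = [], [], []
        for m in metrics:
            mv = raw[src]["metrics"][m]
            v = mv["value"] or 0.0
            vals.append(100 * v)
            ci = mv["ci"]
            err_lo.append(100 * (v - ci["lower"]) if ci else 0.0)
            err_hi.append(100 * (ci["upper"] - v) if ci else 0.0)
        ax.bar(x + (k - 1) * width, vals, width, yerr=[err_lo, err_hi], capsize=3, label=src)
    ax.set_xticks(x, [m.upper() if len(m) <= 3 else m.capitalize() for m in metrics])
    ax.set_ylabel("%")
    ax.set_ylim(0, 105)
    ax.set_title(f"Per-{level} diagnostic performance")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
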