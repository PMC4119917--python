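"""Assemble the pipeline's summary tables.

Three layouts mirror the standard presentation of this analysis: a grid of
mean structure-sequence correlations (structural measures x sequence
measures), a two-predictor comparison table (means, difference, percentage
of wins), and a variance-partition block (Total / Common / Unique rows with
dataset mean +/- spread and percentage of explained variance).
"""

from __future__ import annotations

import pandas as pd

from .io import write_report
from .stats import ComparisonResult, PartitionSummary


def correlation_grid(
    means: dict[str, dict[str, float]],
    sequence_order: list[str] | None = None,
) -> pd.DataFrame:
    """Mean correlation grid: one row per structural profile.

    ``means[structural][sequence]`` -> dataset-mean correlation.
    """
    rows = []
    for struct, by_seq in means.items():
        row = {"profile": struct}
        cols = sequence_order or list(by_seq)
        row.update({s: by_seq[s] for s in cols})
        rows.append(row)
    return pd.DataFrame(rows)


def comparison_row(result: ComparisonResult) -> dict:
    """One comparison-table row: reference, means, delta, % of wins."""
    return {
        "reference": result.reference,
        result.predictor1: round(result.mean1, 3),
        result.predictor2: round(result.mean2, 3),
        "delta": round(result.delta, 3),
        "percent": round(100.0 * result.proportion_x1_wins),
        "p_worst": result.worst_p,
        "significant": result.significant,
    }


def comparison_table(results: list[ComparisonResult]) -> str:
    return write_report([comparison_row(r) for r in results])


def partition_block(
    common: float,
    unique_x1: float,
    unique_x2: float,
    names: tuple[str, str, str] = ("y", "x1", "x2"),
    sd: dict | None = None,
) -> list[dict]:
    """Assemble the four partition rows; the total is the sum of the parts."""
    total = common + unique_x1 + unique_x2
    sd = sd or {}
    label = {
        "total": "Total",
        "common": "Common",
        "unique_x1": f"Unique {names[1]}",
        "unique_x2": f"Unique {names[2]}",
    }
    value = {
        "total": total,
        "common": common,
        "unique_x1": unique_x1,
        "unique_x2": unique_x2,
    }
    fit = f"{names[0]}~{names[1]}+{names[2]}"
    rows = []
    for key in ("total", "common", "unique_x1", "unique_x2"):
        row = {
            "fit": fit,
            "contribution": label[key],
            "R2": round(value[key], 3),
            "percent": round(100.0 * value[key] / total, 2) if total else float("nan"),
        }
        if key in sd:
            row["sd"] = round(sd[key], 3)
        rows.append(row)
    return rows


def partition_table(summary: PartitionSummary) -> str:
    rows = partition_block(
        summary.mean["common"],
        summary.mean["unique_x1"],
        summary.mean["unique_x2"],
        names=summary.names,
        sd=summary.sd,
    )
    # percentages in the block come from the summed means; replace with the
    # per-protein-averaged percentages, which is what the dataset tables show
    for row, key in zip(rows, ("total", "common", "unique_x1", "unique_x2")):
        row["percent"] = round(summary.mean_pct[key], 2)
        row["sem"] = round(summary.sem[key], 3)
    return write_report(rows)
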