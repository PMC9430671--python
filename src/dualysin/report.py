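"""Summary artifacts: genus tables, TIR distributions and screen fractions."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .itss_screen import ScreenResult
from .sequence_io import GeneRecord


@dataclass
class GenusSummary:
    """Per-genus counts and the TIR distribution of the retained calls."""

    genus: str
    n_full: int
    n_filtered: int
    tir_quantiles: dict[str, float] = field(default_factory=dict)
    outliers: list[float] = field(default_factory=list)


def percent(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-up to one decimal."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero; fraction undefined")
    frac = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def screen_fraction(screen: ScreenResult) -> float | None:
    """Retained percentage of a screen (one decimal); None on an empty cohort."""
    if screen.n_total == 0:
        return None
    return percent(screen.n_retained, screen.n_total)


def summarize_by_genus(
    screen: ScreenResult, cohort: Sequence[GeneRecord]
) -> list[GenusSummary]:
    """One row per genus: cohort size, retained count, retained-TIR box stats.

    Quantiles are computed only over retained calls; values outside the Tukey
    fences are listed separately as outliers, box-plot style.
    """
    by_genus: dict[str, list[GeneRecord]] = {}
    for rec in cohort:
        by_genus.setdefault(rec.host_genus, []).append(rec)
    out: list[GenusSummary] = []
    for genus in sorted(by_genus):
        recs = by_genus[genus]
        tirs = [
            screen.calls[r.gene_id].candidate.tir
            for r in recs
            if screen.calls.get(r.gene_id)
            and screen.calls[r.gene_id].status == "retained"
        ]
        summary = GenusSummary(genus=genus, n_full=len(recs), n_filtered=len(tirs))
        if tirs:
            arr = np.asarray(tirs, dtype=float)
            q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            summary.tir_quantiles = {
                "min": float(arr.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(arr.max()),
            }
            summary.outliers = sorted(float(x) for x in arr[(arr < lo) | (arr > hi)])
        out.append(summary)
    return out


def write_genus_summary_tsv(
    summaries: Sequence[GenusSummary], path: str | Path
) -> Path:
    """Box-plot-ready TSV of the per-genus summary."""
    path = Path(path)
    rows = []
    for s in summaries:
        row = {"genus": s.genus, "n_full": s.n_full, "n_filtered": s.n_filtered}
        for key in ("min", "q1", "median", "q3", "max"):
            row[key] = s.tir_quantiles.get(key, "")
        row["outliers"] = ";".join(f"{x:g}" for x in s.outliers)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def plot_genus_boxes(summaries: Sequence[GenusSummary], path: str | Path) -> Path:
    """Optional rendering of the per-genus TIR box plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    with_data = [s for s in summaries if s.tir_quantiles]
    fig, ax = plt.subplots(figsize=(max(4, len(with_data)), 4))
    stats = [
        {
            "label": s.genus,
            "whislo": s.tir_quantiles["min"],
            "q1": s.tir_quantiles["q1"],
            "med": s.tir_quantiles["median"],
            "q3": s.tir_quantiles["q3"],
            "whishi": s.tir_quantiles["max"],
            "fliers": s.outliers,
        }
        for s in with_data
    ]
    ax.bxp(stats, showfliers=True)
    ax.set_yscale("log")
    ax.set_ylabel("TIR (relative units)")
    fig.autofmt_xdate(rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
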