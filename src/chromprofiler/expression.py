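"""Expression stratification, significance filters and Tukey boxplot stats.

The TPM cutoffs are the published stratification: protein-coding genes are
"low" at 0 < TPM <= 2 and "high" at TPM >= 4; lncRNA genes are "low" at
0 < TPM <= 0.1 and "high" at TPM >= 0.5.  Genes at TPM = 0 or in the gap
between the cutoffs belong to neither stratum.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Gene
from .coverage import CoverageTrack

__all__ = [
    "TPM_CUTOFFS",
    "BoxplotSummary",
    "boxplot_summary",
    "stratify_by_expression",
    "gene_body_signal",
    "filter_significant",
    "splice_event_gene_sets",
    "read_expression_table",
    "read_de_table",
    "read_rmats_table",
    "AS_EVENT_TYPES",
]

# biotype -> (low_max, high_min); low is (0, low_max], high is [high_min, inf)
TPM_CUTOFFS: dict[str, tuple[float, float]] = {
    "protein_coding": (2.0, 4.0),
    "lncRNA": (0.1, 0.5),
}

AS_EVENT_TYPES = ("SE", "A5SS", "A3SS", "MXE", "RI")


@dataclass(frozen=True)
class BoxplotSummary:
    """Tukey five-number summary: whiskers at the most extreme data points
    within Q1 - 1.5*IQR and Q3 + 1.5*IQR; points beyond are outliers."""

    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def boxplot_summary(values, method: str = "linear") -> BoxplotSummary:
    """Quartiles by linear interpolation between order statistics (the common
    plotting default; *method* accepts any numpy quantile method)."""
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("boxplot_summary requires at least one value")
    q1, med, q3 = np.percentile(x, [25, 50, 75], method=method)
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = np.sort(x[(x < lo_fence) | (x > hi_fence)])
    return BoxplotSummary(
        n=int(x.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(outliers.tolist()),
    )


def stratify_by_expression(records: pd.DataFrame, biotype: str) -> dict[str, set[str]]:
    """Split genes of one biotype into low/high expression strata.

    *records* needs columns ``gene_id``, ``biotype``, ``tpm``.  Returns
    ``{"low": ids, "high": ids}``; TPM = 0 and gap genes are in neither.
    """
    if biotype not in TPM_CUTOFFS:
        raise ValueError(
            f"unknown biotype {biotype!r}; expected one of {sorted(TPM_CUTOFFS)}"
        )
    low_max, high_min = TPM_CUTOFFS[biotype]
    sub = records[records["biotype"] == biotype]
    tpm = sub["tpm"]
    low = set(sub.loc[(tpm > 0) & (tpm <= low_max), "gene_id"])
    high = set(sub.loc[tpm >= high_min, "gene_id"])
    return {"low": low, "high": high}


def gene_body_signal(track: CoverageTrack, genes: list[Gene]) -> pd.Series:
    """Mean signal over each gene's span, indexed by gene id."""
    out = {}
    for g in genes:
        out[g.id] = track.mean(g.span)
    return pd.Series(out, name="mean_signal", dtype=np.float64)


def filter_significant(
    records: pd.DataFrame, fdr_max: float = 0.05, min_fc: float = 2.0
) -> pd.DataFrame:
    """Keep significant rows and add a ``direction`` column (up/down).

    Differential-expression tables (``log2fc`` column) keep rows with
    |fold change| >= *min_fc* AND fdr <= *fdr_max*; splicing event tables
    (``delta_psi`` column) keep rows with fdr <= *fdr_max* only.  Both
    boundaries are inclusive.
    """
    if "fdr" not in records.columns:
        raise ValueError("records lack an 'fdr' column")
    if "log2fc" in records.columns:
        effect = records["log2fc"]
        keep = (effect.abs() >= np.log2(min_fc)) & (records["fdr"] <= fdr_max)
    elif "delta_psi" in records.columns:
        effect = records["delta_psi"]
        keep = records["fdr"] <= fdr_max
    else:
        raise ValueError("records need a 'log2fc' (DE) or 'delta_psi' (AS) column")
    out = records.loc[keep].copy()
    out["direction"] = np.where(effect.loc[keep] > 0, "up", "down")
    return out


def splice_event_gene_sets(events: pd.DataFrame) -> dict[str, set[str]]:
    """Genes with >=1 positive-direction significant event (Up) and with >=1
    negative-direction event (Down); genes with both appear in both sets.
    *events* should already be filtered by :func:`filter_significant`."""
    if len(events) == 0:
        return {"Up": set(), "Down": set()}
    up = set(events.loc[events["delta_psi"] > 0, "gene_id"])
    down = set(events.loc[events["delta_psi"] < 0, "gene_id"])
    return {"Up": up, "Down": down}


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "biotype", "tpm"} - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    if (df["tpm"] < 0).any():
        raise ValueError("TPM values must be >= 0")
    return df


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "log2fc", "fdr"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return df


def read_rmats_table(path: str | Path, event_type: str) -> pd.DataFrame:
    """Read one rMATS output table (e.g. ``SE.MATS.JC.txt``).

    Only ``GeneID``, ``IncLevelDifference`` and ``FDR`` are required; they map
    to gene_id, delta_psi and fdr.
    """
    if event_type not in AS_EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")
    df = pd.read_csv(path, sep="\t")
    missing = {"GeneID", "IncLevelDifference", "FDR"} - set(df.columns)
    if missing:
        raise ValueError(f"rMATS table missing columns: {sorted(missing)}")
    out = pd.DataFrame(
        {
            "gene_id": df["GeneID"].astype(str).str.strip('"'),
            "event_type": event_type,
            "delta_psi": df["IncLevelDifference"].astype(float),
            "fdr": df["FDR"].astype(float),
        }
    )
    if ((out["fdr"] < 0) | (out["fdr"] > 1)).any():
        raise ValueError("FDR values must lie in [0, 1]")
    return out
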