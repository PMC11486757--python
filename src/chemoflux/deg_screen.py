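"""Differential-expression thresholding and arCOG category tallies.

Operates on per-gene statistics tables (gene id, log2 fold change, p-value)
produced by an upstream count-based DE fit.  A gene is called differentially
expressed when its Benjamini-Hochberg adjusted p-value is below 0.05 and its
expression at least doubled (log2FC >= 1, "up") or halved (log2FC <= -1,
"down").  The p-value threshold is strict (<), the fold-change thresholds
inclusive.  Tallies aggregate the calls by archaeal cluster of orthologous
genes (arCOG) class and direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "classify_degs", "tally_arcog", "load_gene_stats"]

REQUIRED_COLUMNS = ("gene_id", "log2fc", "pvalue")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_degs(
    table: pd.DataFrame,
    *,
    lfc_up: float = 1.0,
    lfc_down: float = -1.0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Call each gene up / down / none and count the calls.

    Uses the table's ``padj`` column when present, otherwise adjusts
    ``pvalue`` with Benjamini-Hochberg first.  Returns the table with
    ``padj`` and ``deg_class`` columns added, plus the counts.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    out = table.copy()
    if "padj" not in out.columns or out["padj"].isna().all():
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    significant = out["padj"] < alpha
    up = significant & (out["log2fc"] >= lfc_up)
    down = significant & (out["log2fc"] <= lfc_down)
    out["deg_class"] = np.select([up, down], ["up", "down"], default="none")
    counts = {
        "up": int(up.sum()),
        "down": int(down.sum()),
        "none": int(len(out) - up.sum() - down.sum()),
        "total_deg": int(up.sum() + down.sum()),
    }
    return out, counts


def tally_arcog(classified: pd.DataFrame, mapping: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-arCOG-class counts of up- and downregulated genes.

    ``mapping`` supplies gene_id -> arCOG class for tables without an
    ``arcog`` column; genes without a class are tallied as ``unknown``.
    """
    if "deg_class" not in classified.columns:
        raise ValueError("table must be classified first (no 'deg_class' column)")
    df = classified.copy()
    if mapping is not None:
        df["arcog"] = df["gene_id"].map(mapping)
    if "arcog" not in df.columns:
        df["arcog"] = None
    df["arcog"] = df["arcog"].fillna("unknown").replace("", "unknown")
    degs = df[df["deg_class"].isin(["up", "down"])]
    tally = (
        degs.groupby(["arcog", "deg_class"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["up", "down"], fill_value=0)
    )
    tally.index.name = "arcog"
    return tally.astype(int)


def load_gene_stats(path) -> pd.DataFrame:
    """Read a per-gene statistics CSV/TSV (gene_id, log2fc, pvalue[, padj, arcog])."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df
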