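"""Gene-level introgression values from a windowed ancestry track and
enrichment of gene absence inside introgressed regions."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def read_ancestry_track(path) -> pd.DataFrame:
    """Read a BED3+score track: chrom, start, end (0-based half-open),
    ancestry proportion in [0, 1]."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "ancestry"])
    if ((df["ancestry"] < 0) | (df["ancestry"] > 1)).any():
        raise ValueError("ancestry proportions must lie in [0, 1]")
    return df


def gene_introgression_value(track: pd.DataFrame,
                             genes: pd.DataFrame) -> pd.DataFrame:
    """Max ancestry over all track windows overlapping each gene by >= 1 bp.

    Genes overlapping no window get value 0 and ``no_overlap=True``.
    Returns a frame with gene_id, introgression_value, no_overlap.
    """
    values = np.zeros(len(genes))
    no_overlap = np.ones(len(genes), dtype=bool)
    by_chrom = dict(tuple(track.groupby("chrom", sort=False)))
    g = genes.reset_index(drop=True)
    for chrom, gsub in g.groupby("chrom", sort=False):
        t = by_chrom.get(chrom)
        if t is None:
            continue
        ws = t["start"].to_numpy()
        we = t["end"].to_numpy()
        anc = t["ancestry"].to_numpy()
        for i, gene in gsub.iterrows():
            hit = (gene["start"] < we) & (gene["end"] > ws)
            if hit.any():
                values[i] = anc[hit].max()
                no_overlap[i] = False
    return pd.DataFrame({
        "gene_id": g["gene_id"],
        "introgression_value": values,
        "no_overlap": no_overlap,
    })


def classify_introgressed(values: np.ndarray | pd.Series,
                          threshold: float = 0.1) -> np.ndarray:
    """Introgressed iff value strictly exceeds the threshold."""
    return np.asarray(values, dtype=float) > threshold


def absence_enrichment(absent: np.ndarray, introgressed: np.ndarray,
                       correction: bool = False) -> dict:
    """2x2 Pearson chi-squared test of gene absence vs introgression.

    ``absent`` and ``introgressed`` are per-gene booleans for one focal
    sample.  Returns the contingency table (rows: absent yes/no;
    columns: introgressed yes/no), within-class absence percentages, the
    chi-squared statistic (1 df, no continuity correction unless
    requested) and its p-value.  Degenerate margins yield the table with
    NaN statistic and a note, not an exception.
    """
    absent = np.asarray(absent, dtype=bool)
    introgressed = np.asarray(introgressed, dtype=bool)
    if absent.shape != introgressed.shape:
        raise ValueError("flag arrays must align")
    table = np.array([
        [int((absent & introgressed).sum()), int((absent & ~introgressed).sum())],
        [int((~absent & introgressed).sum()), int((~absent & ~introgressed).sum())],
    ])
    n_in = table[:, 0].sum()
    n_out = table[:, 1].sum()
    pct_absent_in = 100.0 * table[0, 0] / n_in if n_in else np.nan
    pct_absent_out = 100.0 * table[0, 1] / n_out if n_out else np.nan
    result = {
        "table": table,
        "pct_absent_introgressed": pct_absent_in,
        "pct_absent_outside": pct_absent_out,
        "chi2": np.nan,
        "p_value": np.nan,
        "note": "",
    }
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        result["note"] = "degenerate margin; test not performed"
        logger.warning("absence_enrichment: %s", result["note"])
        return result
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    result["chi2"] = float(chi2)
    result["p_value"] = float(p)
    return result
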