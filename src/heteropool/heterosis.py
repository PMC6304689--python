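"""Sorting of ancestral variation (parallel vs opposite frequency shifts
in the two heterotic pools) and gene-complementation in simulated crosses.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .gene_depth import CopyStateMatrix

logger = logging.getLogger(__name__)

PARALLEL, OPPOSITE, EXCLUDED = "parallel", "opposite", "excluded"

REASON_NONE = ""
REASON_MISSING = "missing_freq"
REASON_BAND = "opv_freq_out_of_band"
REASON_SHIFT_B = "insufficient_shift_B"
REASON_SHIFT_R = "insufficient_shift_R"

CROSS_TYPES = ("BxR", "BxB", "RxR", "OPVxB", "OPVxR", "OPVxOPV")


def classify_shift(f_opv, f_b, f_r, opv_band=(0.25, 0.75),
                   min_shift: float = 0.2) -> pd.DataFrame:
    """Classify sites as parallel or opposite sorting of ancestral variation.

    A site is classifiable when the OPV alternate-allele frequency lies
    inside ``opv_band`` (inclusive) and both pools have shifted by at
    least ``min_shift`` (inclusive) from the OPV frequency.  Parallel
    means both shifts share a sign; opposite means they differ.  All
    other sites are excluded with an annotated reason (checked in order:
    missing frequency, OPV band, B shift, R shift).
    """
    f_opv = np.asarray(f_opv, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    f_r = np.asarray(f_r, dtype=float)
    d_b = f_b - f_opv
    d_r = f_r - f_opv
    n = f_opv.shape[0]
    category = np.full(n, EXCLUDED, dtype=object)
    reason = np.full(n, REASON_NONE, dtype=object)
    tol = 1e-12  # float-representation guard on the inclusive thresholds

    missing = np.isnan(f_opv) | np.isnan(f_b) | np.isnan(f_r)
    out_of_band = ~missing & ((f_opv < opv_band[0] - tol)
                              | (f_opv > opv_band[1] + tol))
    short_b = ~missing & ~out_of_band & (np.abs(d_b) < min_shift - tol)
    short_r = (~missing & ~out_of_band & ~short_b
               & (np.abs(d_r) < min_shift - tol))
    ok = ~missing & ~out_of_band & ~short_b & ~short_r

    reason[missing] = REASON_MISSING
    reason[out_of_band] = REASON_BAND
    reason[short_b] = REASON_SHIFT_B
    reason[short_r] = REASON_SHIFT_R
    same_sign = np.sign(d_b) == np.sign(d_r)
    category[ok & same_sign] = PARALLEL
    category[ok & ~same_sign] = OPPOSITE

    return pd.DataFrame({
        "f_OPV": f_opv, "f_B": f_b, "f_R": f_r,
        "delta_B": d_b, "delta_R": d_r,
        "category": category, "reason": reason,
    })


def parallel_fraction(classifications: pd.DataFrame) -> dict:
    """Fraction of classified (parallel or opposite) sites that sorted in
    parallel, plus the fraction of in-band OPV sites entering the analysis.
    """
    cat = classifications["category"]
    n_parallel = int((cat == PARALLEL).sum())
    n_opposite = int((cat == OPPOSITE).sum())
    denom = n_parallel + n_opposite
    in_band = int((classifications["reason"] != REASON_BAND).sum()
                  - (classifications["reason"] == REASON_MISSING).sum())
    result = {
        "n_parallel": n_parallel,
        "n_opposite": n_opposite,
        "n_classified": denom,
        "fraction_parallel": n_parallel / denom if denom else np.nan,
        "fraction_entering": denom / in_band if in_band else np.nan,
    }
    if denom == 0:
        result["note"] = "no classified sites; fraction undefined"
    return result


def windowed_opposite_rate(classifications: pd.DataFrame, chrom, pos,
                           window_bp: int = 500_000) -> pd.DataFrame:
    """Per-window parallel/opposite counts and opposite rate.

    ``pos`` is 1-based; windows are 0-based half-open anchored at 0.
    Windows with no classified sites carry zero counts and NaN rate.
    """
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    cat = classifications["category"].to_numpy()
    rows = []
    for ch in pd.unique(chrom):
        m = chrom == ch
        widx = (pos[m] - 1) // window_bp
        n_windows = int(widx.max()) + 1 if m.any() else 0
        n_par = np.zeros(n_windows, dtype=int)
        n_opp = np.zeros(n_windows, dtype=int)
        np.add.at(n_par, widx[cat[m] == PARALLEL], 1)
        np.add.at(n_opp, widx[cat[m] == OPPOSITE], 1)
        starts = np.arange(n_windows, dtype=np.int64) * window_bp
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(n_par + n_opp > 0, n_opp / (n_par + n_opp), np.nan)
        rows.append(pd.DataFrame({
            "chrom": ch, "start": starts, "end": starts + window_bp,
            "n_parallel": n_par, "n_opposite": n_opp, "opposite_rate": rate,
        }))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_parallel",
                                     "n_opposite", "opposite_rate"])
    return pd.concat(rows, ignore_index=True)


def shared_absent_count(absent: np.ndarray, i: int, j: int) -> int:
    """Number of genes absent in both parents of a cross."""
    return int((absent[:, i] & absent[:, j]).sum())


def _cross_groups(cross_type: str) -> tuple[str, str]:
    a, b = cross_type.split("x")
    return a, b


def simulate_crosses(states: CopyStateMatrix, groups: np.ndarray,
                     n_crosses_per_type: int = 500, seed: int | None = None,
                     cross_types=CROSS_TYPES):
    """Draw random distinct-parent pairs within/between cultivar groups and
    count genes absent in both parents of each cross.

    Pairs are unordered with distinct parents, sampled with replacement
    across draws.  Within-group types need group size >= 2 or they are
    skipped with a warning.  Returns (per-cross frame, per-type summary).
    """
    groups = np.asarray(groups)
    absent = states.absent()
    rng = np.random.default_rng(seed)
    samples = np.asarray(states.samples)
    rows = []
    for ct in cross_types:
        ga, gb = _cross_groups(ct)
        idx_a = np.flatnonzero(groups == ga)
        idx_b = np.flatnonzero(groups == gb)
        if ga == gb and idx_a.size < 2:
            logger.warning("cross type %s skipped: group %s has <2 samples",
                           ct, ga)
            continue
        if idx_a.size == 0 or idx_b.size == 0:
            logger.warning("cross type %s skipped: empty group", ct)
            continue
        for _ in range(n_crosses_per_type):
            if ga == gb:
                i, j = rng.choice(idx_a, size=2, replace=False)
            else:
                i = rng.choice(idx_a)
                j = rng.choice(idx_b)
            rows.append({
                "cross_type": ct,
                "parent_1": samples[i],
                "parent_2": samples[j],
                "shared_absent": shared_absent_count(absent, i, j),
            })
    crosses = pd.DataFrame(rows)
    if len(crosses):
        summary = (crosses.groupby("cross_type")["shared_absent"]
                   .agg(["mean", "median", "min", "max",
                         ("q25", lambda s: s.quantile(0.25)),
                         ("q75", lambda s: s.quantile(0.75)), "count"])
                   .reset_index())
    else:
        summary = pd.DataFrame(columns=["cross_type", "mean", "median", "min",
                                        "max", "q25", "q75", "count"])
    return crosses, summary


def all_pairs_cross_means(states: CopyStateMatrix, groups: np.ndarray,
                          cross_types=CROSS_TYPES) -> dict[str, float]:
    """Exhaustive per-type mean shared-absent count over all valid pairs
    (deterministic companion to :func:`simulate_crosses`)."""
    groups = np.asarray(groups)
    absent = states.absent()
    means = {}
    for ct in cross_types:
        ga, gb = _cross_groups(ct)
        idx_a = np.flatnonzero(groups == ga)
        idx_b = np.flatnonzero(groups == gb)
        if ga == gb:
            pairs = list(combinations(idx_a, 2))
        else:
            pairs = [(i, j) for i in idx_a for j in idx_b]
        if not pairs:
            continue
        means[ct] = float(np.mean(
            [shared_absent_count(absent, i, j) for i, j in pairs]))
    return means
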