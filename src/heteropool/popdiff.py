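"""Pairwise Weir & Cockerham (1984) F_ST, windowed scans, LD-pruned PCA,
and keyword candidate-gene extraction.

Windowed F_ST is the ratio of sums: numerator and denominator variance
components are summed over all markers in a window before dividing, so
window values are not the mean of per-site ratios.  Negative per-site
components are retained in the sums.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class MarkerConfig:
    """Marker requirements applied per pairwise comparison: called in
    more than ``min_called_per_group - 1`` samples per group, MAF above
    ``min_maf`` and observed heterozygosity below ``max_het``, both
    computed over the union of the two compared groups (configurable
    via ``maf_scope``: 'pair' or 'global')."""

    min_called_per_group: int = 2
    min_maf: float = 0.05
    max_het: float = 0.6
    maf_scope: str = "pair"


def weir_cockerham_components(n1, p1, h1, n2, p2, h2):
    """Two-population diploid variance components (a, b, c).

    Parameters are per-site arrays: diploid sample sizes ``n``, alt-allele
    frequencies ``p`` and observed heterozygote proportions ``h`` for the
    two populations.  Returns the among-population (a), among-individual-
    within-population (b) and within-individual (c) components; the
    per-site estimate is ``a / (a + b + c)``.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    r = 2.0
    n_sum = n1 + n2
    nbar = n_sum / r
    nc = (n_sum - (n1 ** 2 + n2 ** 2) / n_sum) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / n_sum
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / n_sum
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
    c = hbar / 2.0
    return a, b, c


def _group_site_stats(panel: GenotypePanel, group: str):
    dos = panel.dosage[:, panel.group_indices(group)]
    called = dos != MISSING
    n = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(called, dos, 0).sum(axis=1) / (2.0 * n), np.nan)
        h = np.where(n > 0, (dos == 1).sum(axis=1) / n, np.nan)
    return n, p, h


def site_fst(panel: GenotypePanel, group_a: str, group_b: str,
             marker_cfg: MarkerConfig | None = None) -> pd.DataFrame:
    """Per-site F_ST components for one pair of groups.

    Markers failing the per-comparison requirements (see
    :class:`MarkerConfig`) are excluded.  Returns a frame with columns
    chrom, pos, a, d, fst, n_a, n_b for the retained sites.
    """
    cfg = marker_cfg or MarkerConfig()
    na, pa, ha = _group_site_stats(panel, group_a)
    nb, pb, hb = _group_site_stats(panel, group_b)

    keep = (na >= cfg.min_called_per_group) & (nb >= cfg.min_called_per_group)
    keep &= panel.is_biallelic_snp
    if cfg.maf_scope == "pair":
        idx = np.concatenate([panel.group_indices(group_a),
                              panel.group_indices(group_b)])
        dos = panel.dosage[:, idx]
    elif cfg.maf_scope == "global":
        dos = panel.dosage
    else:
        raise ValueError(f"unknown maf_scope {cfg.maf_scope!r}")
    called = dos != MISSING
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0,
                        np.where(called, dos, 0).sum(axis=1) / (2.0 * n_called),
                        np.nan)
        het = np.where(n_called > 0, (dos == 1).sum(axis=1) / n_called, np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        keep &= (maf > cfg.min_maf) & (het < cfg.max_het)
    keep &= ~np.isnan(maf)

    a, b, c = weir_cockerham_components(na[keep], pa[keep], ha[keep],
                                        nb[keep], pb[keep], hb[keep])
    d = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(d != 0, a / d, np.nan)
    return pd.DataFrame({
        "chrom": panel.chrom[keep],
        "pos": panel.pos[keep],
        "a": a,
        "d": d,
        "fst": fst,
        "n_a": na[keep],
        "n_b": nb[keep],
    })


def window_fst(components: pd.DataFrame, window_bp: int = 500_000,
               chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Sum per-site (a, d) within non-overlapping windows and divide.

    Windows are 0-based half-open, anchored at position 0; a 1-based
    site position ``pos`` falls in window ``(pos - 1) // window_bp``.
    When ``chrom_sizes`` is given, empty windows up to the chromosome
    end are reported with ``n_markers=0`` and NaN fst.
    """
    comp = components
    rows = []
    chroms = (list(chrom_sizes) if chrom_sizes is not None
              else list(pd.unique(comp["chrom"])))
    by_chrom = dict(tuple(comp.groupby("chrom", sort=False))) if len(comp) else {}
    for chrom in chroms:
        sub = by_chrom.get(chrom)
        if chrom_sizes is not None:
            n_windows = int(np.ceil(chrom_sizes[chrom] / window_bp))
        elif sub is not None and len(sub):
            n_windows = int((sub["pos"].max() - 1) // window_bp) + 1
        else:
            continue
        sum_a = np.zeros(n_windows)
        sum_d = np.zeros(n_windows)
        n_markers = np.zeros(n_windows, dtype=int)
        if sub is not None and len(sub):
            widx = ((sub["pos"].to_numpy() - 1) // window_bp).astype(int)
            np.add.at(sum_a, widx, sub["a"].to_numpy())
            np.add.at(sum_d, widx, sub["d"].to_numpy())
            np.add.at(n_markers, widx, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where((sum_d != 0) & (n_markers > 0), sum_a / sum_d, np.nan)
        starts = np.arange(n_windows, dtype=np.int64) * window_bp
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": starts + window_bp,
            "n_markers": n_markers,
            "sum_a": sum_a,
            "sum_d": sum_d,
            "fst": fst,
        }))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_markers",
                                     "sum_a", "sum_d", "fst"])
    return pd.concat(rows, ignore_index=True)


def top_windows(windows: pd.DataFrame, pct: float = 5.0,
                value_col: str = "fst", flag_col: str = "top5") -> pd.DataFrame:
    """Flag windows whose value is at or above the (100 - pct) percentile
    among defined (non-NaN) windows; ties at the cutoff are all flagged."""
    out = windows.copy()
    vals = out[value_col].to_numpy(dtype=float)
    defined = ~np.isnan(vals)
    if defined.sum() == 0:
        out[flag_col] = False
        return out
    cutoff = np.percentile(vals[defined], 100.0 - pct)
    out[flag_col] = defined & (vals >= cutoff)
    return out


def ld_prune(dosage: np.ndarray, chrom: np.ndarray | None = None,
             r2_max: float = 0.2, window_sites: int = 50,
             step: int = 1) -> np.ndarray:
    """Greedy LD pruning on squared Pearson correlation of dosages.

    Scans sites left to right (genomic order); a site is dropped when its
    r^2 with any already-retained site among the previous ``window_sites``
    original positions exceeds ``r2_max``.  Missing dosages are
    mean-imputed for the correlation only.  Comparisons never cross
    chromosome boundaries.  Returns the retained site indices in order.
    """
    dos = dosage.astype(float)
    miss = dosage == MISSING
    if miss.any():
        dos[miss] = np.nan
        col_means = np.nanmean(dos, axis=1)
        inds = np.where(miss)
        dos[inds] = col_means[inds[0]]
    # center rows once; r^2 then comes from dot products
    dos = dos - dos.mean(axis=1, keepdims=True)
    norms = np.sqrt((dos ** 2).sum(axis=1))

    n = dos.shape[0]
    if chrom is None:
        chrom = np.zeros(n, dtype=int)
    retained: list[int] = []
    retained_in_chrom: list[int] = []
    cur_chrom = None
    for i in range(n):
        if chrom[i] != cur_chrom:
            cur_chrom = chrom[i]
            retained_in_chrom = []
        if norms[i] == 0:  # monomorphic: uncorrelated with everything
            retained.append(i)
            retained_in_chrom.append(i)
            continue
        window_lo = i - window_sites + 1
        drop = False
        for j in reversed(retained_in_chrom):
            if j < window_lo:
                break
            if norms[j] == 0:
                continue
            r = dos[i] @ dos[j] / (norms[i] * norms[j])
            if r * r > r2_max:
                drop = True
                break
        if not drop:
            retained.append(i)
            retained_in_chrom.append(i)
    return np.asarray(retained, dtype=int)


def pca(dosage: np.ndarray, n_components: int = 10,
        subsample_frac: float | None = None, seed: int | None = None,
        scale: str = "patterson", ld_prune_kwargs: dict | None = None):
    """PCA of a (sites x samples) dosage matrix.

    Sites are optionally random-subsampled (seeded) and LD-pruned, then
    mean-imputed, mean-centered per site and, for ``scale='patterson'``,
    divided by the binomial standard deviation sqrt(p(1-p)) of the site
    allele frequency (``scale='center'`` skips the division, which suits
    binary indicator matrices).  Zero-variance sites are dropped.

    Returns ``(scores, eigenvalues)``: scores are samples x components
    (projections onto the principal axes), eigenvalues are those of the
    sample covariance matrix, non-increasing.
    """
    n_sites, n_samples = dosage.shape
    rng = np.random.default_rng(seed)
    idx = np.arange(n_sites)
    if subsample_frac is not None and subsample_frac < 1.0:
        k = max(1, int(round(subsample_frac * n_sites)))
        idx = np.sort(rng.choice(n_sites, size=k, replace=False))
    sub = dosage[idx]
    if ld_prune_kwargs is not None:
        keep = ld_prune(sub, **ld_prune_kwargs)
        sub = sub[keep]

    x = sub.astype(float)
    miss = sub == MISSING
    if miss.any():
        x[miss] = np.nan
        means = np.nanmean(x, axis=1)
        inds = np.where(miss)
        x[inds] = means[inds[0]]
    means = x.mean(axis=1, keepdims=True)
    x = x - means
    if scale == "patterson":
        p = np.clip(means[:, 0] / 2.0, 0.0, 1.0)
        sd = np.sqrt(p * (1.0 - p))
        keep = sd > 0
        x = x[keep] / sd[keep, None]
    elif scale == "center":
        keep = (x ** 2).sum(axis=1) > 0
        x = x[keep]
    else:
        raise ValueError(f"unknown scale {scale!r}")

    if n_components > n_samples:
        logger.warning("n_components truncated to n_samples=%d", n_samples)
        n_components = n_samples
    # samples-by-samples covariance eigendecomposition via SVD of x.T
    u, s, _ = np.linalg.svd(x.T, full_matrices=False)
    eigvals = s ** 2 / max(n_samples - 1, 1)
    scores = u * s
    return scores[:, :n_components], eigvals[:n_components]


def candidate_genes(windows: pd.DataFrame, genes: pd.DataFrame,
                    fst_min: float = 0.2, keyword: str = "pentatricopeptide",
                    chrom: str | None = None) -> pd.DataFrame:
    """Genes overlapping (>= 1 bp) any window with fst > ``fst_min`` on the
    stated chromosome whose annotation contains ``keyword``
    (case-insensitive).  ``genes`` needs columns gene_id, chrom, start,
    end (0-based half-open) and annotation."""
    win = windows[windows["fst"] > fst_min]
    if chrom is not None:
        win = win[win["chrom"] == chrom]
    g = genes
    if chrom is not None:
        g = g[g["chrom"] == chrom]
    kw = keyword.lower()
    g = g[g["annotation"].astype(str).str.lower().str.contains(kw, regex=False)]
    hits = []
    for ch, wsub in win.groupby("chrom"):
        gsub = g[g["chrom"] == ch]
        if not len(gsub):
            continue
        ws = wsub["start"].to_numpy()
        we = wsub["end"].to_numpy()
        for _, gene in gsub.iterrows():
            if np.any((gene["start"] < we) & (gene["end"] > ws)):
                hits.append(gene)
    if not hits:
        return genes.iloc[0:0]
    return pd.DataFrame(hits).drop_duplicates(subset="gene_id").reset_index(drop=True)
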