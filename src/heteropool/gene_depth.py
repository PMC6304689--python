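"""Gene-level read-depth quantification and three-state copy classification.

Each gene x sample cell is classified from mean per-base depth relative
to the sample's median gene depth m_s (computed over all genes, zeros
included): absent (depth == 0), amplified (depth > 3 * m_s), otherwise
present.  Downstream summaries, a group-label permutation null, a nested
depth/group regression, gene-length bias and a PAV PCA live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import popdiff

logger = logging.getLogger(__name__)

ABSENT, PRESENT, AMPLIFIED = 0, 1, 2
STATE_NAMES = {ABSENT: "absent", PRESENT: "present", AMPLIFIED: "amplified"}


@dataclass
class GeneDepthMatrix:
    """Genes x samples mean per-base depth with gene coordinates.

    ``genes`` is a frame with columns gene_id, chrom, start, end
    (0-based half-open) and optionally annotation; row order matches
    the depth matrix."""

    genes: pd.DataFrame
    samples: list[str]
    depth: np.ndarray

    def __post_init__(self) -> None:
        if self.depth.shape != (len(self.genes), len(self.samples)):
            raise ValueError("depth matrix shape mismatch")
        if np.any(self.depth < 0):
            raise ValueError("negative depths")

    @property
    def lengths(self) -> np.ndarray:
        return (self.genes["end"] - self.genes["start"]).to_numpy()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.depth, columns=self.samples)
        df.insert(0, "gene_id", self.genes["gene_id"].to_numpy())
        return df

    @classmethod
    def from_tsv(cls, depth_path, genes: pd.DataFrame) -> "GeneDepthMatrix":
        """Load a precomputed gene x sample TSV (first column gene_id)."""
        df = pd.read_csv(depth_path, sep="\t")
        df = df.set_index("gene_id").loc[genes["gene_id"]]
        return cls(genes=genes.reset_index(drop=True),
                   samples=list(df.columns),
                   depth=df.to_numpy(dtype=float))


@dataclass
class CopyStateMatrix:
    """Genes x samples states in {ABSENT, PRESENT, AMPLIFIED} plus the
    per-sample median gene depth used for classification."""

    genes: pd.DataFrame
    samples: list[str]
    states: np.ndarray
    median_depth: np.ndarray

    def absent(self) -> np.ndarray:
        return self.states == ABSENT

    def amplified(self) -> np.ndarray:
        return self.states == AMPLIFIED

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.vectorize(STATE_NAMES.get)(self.states), columns=self.samples)
        df.insert(0, "gene_id", self.genes["gene_id"].to_numpy())
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, genes: pd.DataFrame,
                   median_depth: np.ndarray | None = None) -> "CopyStateMatrix":
        df = df.set_index("gene_id").loc[genes["gene_id"]]
        name_to_code = {v: k for k, v in STATE_NAMES.items()}
        states = np.vectorize(name_to_code.__getitem__)(
            df.to_numpy()).astype(np.int8)
        if median_depth is None:
            median_depth = np.full(df.shape[1], np.nan)
        return cls(genes=genes.reset_index(drop=True), samples=list(df.columns),
                   states=states, median_depth=median_depth)


def compute_gene_depth(depth_track: pd.DataFrame, genes: pd.DataFrame,
                       sample: str = "sample") -> GeneDepthMatrix:
    """Mean per-base depth per gene from a single-sample per-base track.

    ``depth_track`` has columns chrom, pos (0-based) and depth; positions
    absent from the track count as depth 0.  Gene intervals are 0-based
    half-open.
    """
    values = np.zeros(len(genes))
    by_chrom = dict(tuple(depth_track.groupby("chrom", sort=False)))
    for i, gene in genes.reset_index(drop=True).iterrows():
        sub = by_chrom.get(gene["chrom"])
        length = gene["end"] - gene["start"]
        if length <= 0:
            raise ValueError(f"gene {gene['gene_id']} has non-positive length")
        if sub is None:
            logger.warning("gene %s outside depth track; depth set to 0",
                           gene["gene_id"])
            continue
        pos = sub["pos"].to_numpy()
        mask = (pos >= gene["start"]) & (pos < gene["end"])
        values[i] = sub["depth"].to_numpy()[mask].sum() / length
    return GeneDepthMatrix(genes=genes.reset_index(drop=True),
                           samples=[sample], depth=values[:, None])


def classify_copy_state(depths: GeneDepthMatrix) -> CopyStateMatrix:
    """Classify every gene x sample cell into absent/present/amplified.

    The per-sample median m_s is taken over all genes including zeros;
    samples with m_s == 0 are uninterpretable and rejected.
    """
    m = np.median(depths.depth, axis=0)
    zero = m <= 0
    if zero.any():
        bad = [s for s, z in zip(depths.samples, zero) if z]
        raise ValueError(f"median gene depth is 0 for sample(s) {bad}; "
                         "coverage uninterpretable")
    states = np.full(depths.depth.shape, PRESENT, dtype=np.int8)
    states[depths.depth == 0] = ABSENT
    states[depths.depth > 3.0 * m[None, :]] = AMPLIFIED
    return CopyStateMatrix(genes=depths.genes, samples=depths.samples,
                           states=states, median_depth=m)


def pav_summaries(states: CopyStateMatrix) -> dict:
    """Per-sample and per-gene absence/amplification counts and the
    derived gene sets (absent in >=1 / >1 / all; amplified in >=1 / all)."""
    absent = states.absent()
    amp = states.amplified()
    gene_ids = states.genes["gene_id"].to_numpy()
    per_sample = pd.DataFrame({
        "sample_id": states.samples,
        "n_absent": absent.sum(axis=0),
        "n_amplified": amp.sum(axis=0),
        "median_depth": states.median_depth,
    })
    per_gene = pd.DataFrame({
        "gene_id": gene_ids,
        "n_samples_absent": absent.sum(axis=1),
        "n_samples_amplified": amp.sum(axis=1),
    })
    n_samples = len(states.samples)
    na = per_gene["n_samples_absent"].to_numpy()
    namp = per_gene["n_samples_amplified"].to_numpy()
    return {
        "per_sample": per_sample,
        "per_gene": per_gene,
        "absent_ge1": set(gene_ids[na >= 1]),
        "absent_gt1": set(gene_ids[na > 1]),
        "absent_all": set(gene_ids[na == n_samples]),
        "amplified_ge1": set(gene_ids[namp >= 1]),
        "amplified_all": set(gene_ids[namp == n_samples]),
    }


def group_pav_freq(states: CopyStateMatrix, groups: np.ndarray,
                   group_a: str = "B", group_b: str = "R") -> pd.DataFrame:
    """Per-gene absence/amplification frequency per group and the signed
    difference ``delta = freq(group_a) - freq(group_b)`` (positive means
    more often absent/amplified in group_a)."""
    groups = np.asarray(groups)
    out = {"gene_id": states.genes["gene_id"].to_numpy()}
    for kind, mat in (("absent", states.absent()), ("amplified", states.amplified())):
        freqs = {}
        for g in (group_a, group_b):
            idx = np.flatnonzero(groups == g)
            if idx.size == 0:
                raise ValueError(f"group {g!r} empty")
            freqs[g] = mat[:, idx].mean(axis=1)
            out[f"freq_{kind}_{g}"] = freqs[g]
        out[f"delta_{kind}"] = freqs[group_a] - freqs[group_b]
    return pd.DataFrame(out)


def top_differentiated(pav: pd.DataFrame, pct: float = 1.0,
                       kind: str = "absent") -> pd.DataFrame:
    """Flag genes with |delta| at or above the (100 - pct) percentile;
    ties at the cutoff are all flagged."""
    out = pav.copy()
    vals = np.abs(out[f"delta_{kind}"].to_numpy(dtype=float))
    cutoff = np.percentile(vals, 100.0 - pct)
    out[f"top_{kind}"] = vals >= cutoff
    return out


def permutation_differentiation_test(
        states: CopyStateMatrix, groups: np.ndarray, kind: str = "absent",
        diff_threshold: float = 0.2, n_perm: int = 999, seed: int | None = None,
        group_a: str = "B", group_b: str = "R"):
    """Count genes with |freq_a - freq_b| >= threshold and compare against
    a null built by permuting group labels over the pooled samples.

    Returns ``(observed, null_counts, p)`` with the add-one estimator
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if not 0 < diff_threshold <= 1:
        raise ValueError("diff_threshold must be in (0, 1]")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups = np.asarray(groups)
    idx_a = np.flatnonzero(groups == group_a)
    idx_b = np.flatnonzero(groups == group_b)
    mat = (states.absent() if kind == "absent" else states.amplified()).astype(float)
    sub = mat[:, np.concatenate([idx_a, idx_b])]
    n_a = idx_a.size

    def count(cols_a: np.ndarray, cols_b: np.ndarray) -> int:
        diff = sub[:, cols_a].mean(axis=1) - sub[:, cols_b].mean(axis=1)
        # tolerance keeps e.g. 0.5 - 0.3 >= 0.2 despite float representation
        return int((np.abs(diff) >= diff_threshold - 1e-12).sum())

    pooled = np.arange(sub.shape[1])
    observed = count(pooled[:n_a], pooled[n_a:])
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        null_counts[i] = count(perm[:n_a], perm[n_a:])
    p = (1 + int((null_counts >= observed).sum())) / (n_perm + 1)
    return observed, null_counts, p


@dataclass
class NestedRegressionReport:
    """OLS fits n_absent ~ 1, ~ depth, ~ depth + group (no interaction)
    with incremental F tests, plus per-group slopes of n_absent on depth."""

    f_depth: float
    p_depth: float
    df_depth: tuple[int, int]
    f_group: float
    p_group: float
    df_group: tuple[int, int]
    r2_depth: float
    r2_full: float
    group_slopes: dict[str, float]
    note: str = ""


def depth_absence_regression(per_sample: pd.DataFrame) -> NestedRegressionReport:
    """Nested regression of per-sample absent-gene count on median depth
    then group identity (no interaction term).

    ``per_sample`` needs columns median_depth, group, n_absent.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = per_sample.copy()
    if df["n_absent"].nunique() == 1:
        slopes = {g: 0.0 for g in df["group"].unique()}
        return NestedRegressionReport(
            f_depth=np.nan, p_depth=np.nan, df_depth=(0, 0),
            f_group=np.nan, p_group=np.nan, df_group=(0, 0),
            r2_depth=0.0, r2_full=0.0, group_slopes=slopes,
            note="response constant; F undefined")

    m1 = smf.ols("n_absent ~ median_depth", data=df).fit()
    m2 = smf.ols("n_absent ~ median_depth + C(group)", data=df).fit()
    m0 = smf.ols("n_absent ~ 1", data=df).fit()
    with np.errstate(invalid="ignore", divide="ignore"):
        anova01 = anova_lm(m0, m1)
        anova12 = anova_lm(m1, m2)

    slopes = {}
    for g, sub in df.groupby("group"):
        if sub["median_depth"].nunique() < 2:
            slopes[g] = np.nan
        else:
            fit = sm.OLS(sub["n_absent"],
                         sm.add_constant(sub["median_depth"])).fit()
            slopes[g] = float(fit.params["median_depth"])

    return NestedRegressionReport(
        f_depth=float(anova01["F"].iloc[1]),
        p_depth=float(anova01["Pr(>F)"].iloc[1]),
        df_depth=(int(anova01["df_diff"].iloc[1]), int(anova01["df_resid"].iloc[1])),
        f_group=float(anova12["F"].iloc[1]),
        p_group=float(anova12["Pr(>F)"].iloc[1]),
        df_group=(int(anova12["df_diff"].iloc[1]), int(anova12["df_resid"].iloc[1])),
        r2_depth=float(m1.rsquared),
        r2_full=float(m2.rsquared),
        group_slopes=slopes,
    )


def pav_length_bias(states: CopyStateMatrix) -> dict:
    """Compare gene-length distributions of PAV genes (absent in >= 1
    sample) vs non-PAV genes: medians, Mann-Whitney rank-sum with normal
    approximation, and length deciles per class."""
    lengths = states.genes["end"].to_numpy() - states.genes["start"].to_numpy()
    is_pav = states.absent().any(axis=1)
    pav_len = lengths[is_pav]
    other_len = lengths[~is_pav]
    report = {
        "n_pav": int(is_pav.sum()),
        "n_other": int((~is_pav).sum()),
        "median_pav": float(np.median(pav_len)) if len(pav_len) else np.nan,
        "median_other": float(np.median(other_len)) if len(other_len) else np.nan,
    }
    if len(pav_len) == 0 or len(other_len) == 0:
        logger.warning("one length class empty; rank-sum test skipped")
        report.update({"statistic": np.nan, "p_value": np.nan})
        return report
    res = stats.mannwhitneyu(pav_len, other_len, alternative="two-sided",
                             method="asymptotic")
    qs = np.linspace(0.1, 0.9, 9)
    report.update({
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "deciles_pav": np.quantile(pav_len, qs).tolist(),
        "deciles_other": np.quantile(other_len, qs).tolist(),
    })
    return report


def pav_pca(states: CopyStateMatrix, n_components: int = 10):
    """PCA of absence indicators (absent=1 else 0), mean-centered only."""
    indicators = states.absent().astype(np.int8)
    return popdiff.pca(indicators, n_components=n_components, scale="center")
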