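"""VCF input, site filtering, and per-group allele statistics.

The panel is stored as dense numpy arrays: an alt-allele dosage matrix
(sites x samples, values 0/1/2 and -1 for missing) plus per-genotype
depths and per-site metadata.  Filtering follows a fixed rule order so
that each removed site is attributed to exactly one (first-failing)
rule in the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

VALID_GROUPS = ("OPV", "B", "R")

#: fixed first-failing attribution order for apply_site_filters
FILTER_RULE_ORDER = (
    "biallelic_snp",
    "min_qual",
    "max_site_het",
    "min_site_mean_depth",
    "max_site_mean_depth",
    "strand_balance",
    "read_placement",
    "min_maf",
    "max_missing",
    "reference_sample_called",
)


@dataclass
class GenotypePanel:
    """Samples x sites genotype panel with site metadata and group labels.

    Attributes
    ----------
    samples : list of sample ids (columns of the matrices)
    groups : array of group labels, one per sample, each in {OPV, B, R}
    chrom, pos : per-site chromosome name and 1-based position
    ref, alt : per-site reference allele and comma-joined alternate alleles
    qual : per-site QUAL
    info : mapping of INFO key -> per-site float array (NaN where absent)
    is_biallelic_snp : per-site flag (single ALT, both alleles length 1)
    dosage : (n_sites, n_samples) int8 alt-allele dosage; -1 = missing
    depth : (n_sites, n_samples) int32 per-genotype DP; -1 = unknown
    """

    samples: list[str]
    groups: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    info: dict[str, np.ndarray]
    is_biallelic_snp: np.ndarray
    dosage: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        n_sites, n_samples = self.dosage.shape
        if len(self.samples) != n_samples:
            raise ValueError("sample list does not match dosage matrix width")
        for name in ("chrom", "pos", "ref", "alt", "qual", "is_biallelic_snp"):
            if len(getattr(self, name)) != n_sites:
                raise ValueError(f"site field {name!r} length mismatch")
        if self.depth.shape != self.dosage.shape:
            raise ValueError("depth matrix shape mismatch")
        bad = set(np.unique(self.groups)) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[1]

    def group_indices(self, group: str) -> np.ndarray:
        idx = np.flatnonzero(self.groups == group)
        if idx.size == 0:
            raise ValueError(f"group {group!r} has no samples")
        return idx

    def take_sites(self, mask_or_index: np.ndarray) -> "GenotypePanel":
        """Return a new panel restricted to the selected sites."""
        m = np.asarray(mask_or_index)
        return GenotypePanel(
            samples=list(self.samples),
            groups=self.groups.copy(),
            chrom=self.chrom[m],
            pos=self.pos[m],
            ref=self.ref[m],
            alt=self.alt[m],
            qual=self.qual[m],
            info={k: v[m] for k, v in self.info.items()},
            is_biallelic_snp=self.is_biallelic_snp[m],
            dosage=self.dosage[m],
            depth=self.depth[m],
        )


@dataclass
class SiteFilterConfig:
    """Thresholds of the high-confidence biallelic-SNP filter suite.

    Defaults: QUAL > 30, site observed heterozygosity < 0.3, genotype
    DP > 1 (else set missing), per-site mean DP in (1, 16), biallelic
    SNPs only, SAR & SAF > 0, RPL & RPR > 1, MAF > 0.05, missing < 0.3.
    All inequalities are strict, matching the stated thresholds.
    """

    min_qual: float = 30.0
    max_site_het: float = 0.3
    min_genotype_depth: int = 1
    min_site_mean_depth: float = 1.0
    max_site_mean_depth: float = 16.0
    require_biallelic_snp: bool = True
    min_maf: float = 0.05
    max_missing: float = 0.3
    require_strand_balance: bool = True
    require_read_placement: bool = True
    require_reference_sample_called: bool = False
    reference_sample: str | None = None


@dataclass
class FilterReport:
    """Per-rule removal counts (first-failing attribution)."""

    n_input: int
    n_passed: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    n_genotypes_set_missing: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "n_removed": self.removed_by_rule.get(r, 0)}
                for r in FILTER_RULE_ORDER]
        rows.append({"rule": "TOTAL_REMOVED", "n_removed": self.n_input - self.n_passed})
        rows.append({"rule": "PASSED", "n_removed": self.n_passed})
        return pd.DataFrame(rows)


def read_sample_table(path) -> pd.DataFrame:
    """Read a TSV with columns sample_id, group (extra columns kept)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError("sample table needs 'sample_id' and 'group' columns")
    bad = set(df["group"]) - set(VALID_GROUPS)
    if bad:
        raise ValueError(f"unknown group label(s) in sample table: {sorted(bad)}")
    return df


def read_vcf(path, sample_table: pd.DataFrame | str) -> GenotypePanel:
    """Load a VCF into a :class:`GenotypePanel`.

    Multiallelic and indel records are retained but flagged
    ``is_biallelic_snp=False`` so the filter stage can remove them.
    Samples missing from the sample table raise an error.
    """
    from cyvcf2 import VCF

    if isinstance(sample_table, (str, bytes)) or hasattr(sample_table, "__fspath__"):
        sample_table = read_sample_table(sample_table)

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    table = sample_table.set_index("sample_id")
    missing_samples = [s for s in samples if s not in table.index]
    if missing_samples:
        raise ValueError(f"samples absent from sample table: {missing_samples}")
    groups = np.asarray([table.loc[s, "group"] for s in samples], dtype=object)

    chroms, poss, refs, alts, quals, bial = [], [], [], [], [], []
    info_cols: dict[str, list] = {k: [] for k in ("SAR", "SAF", "RPL", "RPR")}
    dosages, depths = [], []

    for v in vcf:
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(",".join(v.ALT) if v.ALT else ".")
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        is_snp = (len(v.ALT) == 1 and len(v.REF) == 1
                  and all(len(a) == 1 for a in v.ALT))
        bial.append(is_snp)
        for k in info_cols:
            val = v.INFO.get(k)
            info_cols[k].append(np.nan if val is None else float(val))
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(v.gt_types, dtype=np.int8)
        dos = np.where(gt == 3, MISSING, gt).astype(np.int8)
        dosages.append(dos)
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            depths.append(np.full(len(samples), -1, dtype=np.int32))
        else:
            dp = dp.astype(np.int32).reshape(-1)
            dp[dp < 0] = -1
            depths.append(dp)
    vcf.close()

    n_sites = len(poss)
    dosage = (np.vstack(dosages) if n_sites else
              np.empty((0, len(samples)), dtype=np.int8))
    depth = (np.vstack(depths) if n_sites else
             np.empty((0, len(samples)), dtype=np.int32))
    info = {k: np.asarray(vals, dtype=float) for k, vals in info_cols.items()}
    return GenotypePanel(
        samples=samples,
        groups=groups,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        qual=np.asarray(quals, dtype=float),
        info=info,
        is_biallelic_snp=np.asarray(bial, dtype=bool),
        dosage=dosage,
        depth=depth,
    )


def _site_stats(dosage: np.ndarray):
    """Per-site (n_called, het_fraction, maf, missing_fraction) over all samples."""
    called = dosage != MISSING
    n_called = called.sum(axis=1)
    n_samples = dosage.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_called > 0, (dosage == 1).sum(axis=1) / n_called, np.nan)
        alt_count = np.where(called, dosage, 0).sum(axis=1)
        freq = np.where(n_called > 0, alt_count / (2.0 * n_called), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    missing_frac = 1.0 - n_called / n_samples
    return n_called, het, maf, missing_frac


def apply_site_filters(
    panel: GenotypePanel, cfg: SiteFilterConfig | None = None
) -> tuple[GenotypePanel, FilterReport]:
    """Apply the site-filter suite; returns the surviving panel and a report.

    Genotypes with DP <= ``min_genotype_depth`` are set to missing first,
    then site-level rules run in :data:`FILTER_RULE_ORDER`; a removed site
    is attributed to the first rule it fails.  Rules whose INFO fields are
    absent from the panel are skipped with a warning.
    """
    cfg = cfg or SiteFilterConfig()
    dosage = panel.dosage.copy()
    low_dp = (panel.depth >= 0) & (panel.depth <= cfg.min_genotype_depth)
    n_set_missing = int((low_dp & (dosage != MISSING)).sum())
    dosage[low_dp] = MISSING
    panel = replace_dosage(panel, dosage)

    n_called, het, maf, missing_frac = _site_stats(dosage)
    depth_known = panel.depth >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dp = np.where(
            depth_known.sum(axis=1) > 0,
            np.where(depth_known, panel.depth, 0).sum(axis=1) / depth_known.sum(axis=1),
            np.nan,
        )

    def info_ok(key: str) -> np.ndarray | None:
        arr = panel.info.get(key)
        if arr is None or np.all(np.isnan(arr)):
            logger.warning("INFO field %s absent; skipping the dependent rule", key)
            return None
        return arr

    fails: dict[str, np.ndarray] = {}
    n = panel.n_sites
    false_ = np.zeros(n, dtype=bool)

    fails["biallelic_snp"] = (~panel.is_biallelic_snp
                              if cfg.require_biallelic_snp else false_)
    fails["min_qual"] = ~(panel.qual > cfg.min_qual)
    fails["max_site_het"] = ~(het < cfg.max_site_het)
    fails["min_site_mean_depth"] = ~(mean_dp > cfg.min_site_mean_depth)
    fails["max_site_mean_depth"] = ~(mean_dp < cfg.max_site_mean_depth)

    if cfg.require_strand_balance:
        sar, saf = info_ok("SAR"), info_ok("SAF")
        fails["strand_balance"] = (false_ if sar is None or saf is None
                                   else ~((sar > 0) & (saf > 0)))
    else:
        fails["strand_balance"] = false_
    if cfg.require_read_placement:
        rpl, rpr = info_ok("RPL"), info_ok("RPR")
        fails["read_placement"] = (false_ if rpl is None or rpr is None
                                   else ~((rpl > 1) & (rpr > 1)))
    else:
        fails["read_placement"] = false_

    fails["min_maf"] = ~(maf > cfg.min_maf)
    fails["max_missing"] = ~(missing_frac < cfg.max_missing)

    if cfg.require_reference_sample_called:
        if cfg.reference_sample is None or cfg.reference_sample not in panel.samples:
            raise ValueError("reference_sample must name a panel sample")
        ref_col = panel.samples.index(cfg.reference_sample)
        fails["reference_sample_called"] = dosage[:, ref_col] == MISSING
    else:
        fails["reference_sample_called"] = false_

    keep = np.ones(n, dtype=bool)
    removed_by_rule: dict[str, int] = {}
    unattributed = np.ones(n, dtype=bool)
    for rule in FILTER_RULE_ORDER:
        f = np.nan_to_num(fails[rule].astype(bool), nan=True) & unattributed
        removed_by_rule[rule] = int(f.sum())
        keep &= ~f
        unattributed &= ~f

    report = FilterReport(
        n_input=n,
        n_passed=int(keep.sum()),
        removed_by_rule=removed_by_rule,
        n_genotypes_set_missing=n_set_missing,
    )
    return panel.take_sites(keep), report


def replace_dosage(panel: GenotypePanel, dosage: np.ndarray) -> GenotypePanel:
    return GenotypePanel(
        samples=list(panel.samples), groups=panel.groups, chrom=panel.chrom,
        pos=panel.pos, ref=panel.ref, alt=panel.alt, qual=panel.qual,
        info=panel.info, is_biallelic_snp=panel.is_biallelic_snp,
        dosage=dosage, depth=panel.depth,
    )


def group_allele_freq(panel: GenotypePanel, group: str, min_called: int = 1):
    """Per-site alternate-allele frequency within one group.

    Returns ``(freq, n_called, ok)`` where ``freq`` is alt alleles over
    2 x called diploid genotypes (NaN where no calls) and ``ok`` flags
    sites with at least ``min_called`` called samples in the group.
    """
    idx = panel.group_indices(group)
    dos = panel.dosage[:, idx]
    called = dos != MISSING
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0,
                        np.where(called, dos, 0).sum(axis=1) / (2.0 * n_called),
                        np.nan)
    return freq, n_called, n_called >= min_called


def observed_heterozygosity(panel: GenotypePanel):
    """(per-site het over called samples, per-sample het over called sites)."""
    dos = panel.dosage
    called = dos != MISSING
    het = dos == 1
    with np.errstate(invalid="ignore", divide="ignore"):
        site_het = np.where(called.sum(axis=1) > 0,
                            het.sum(axis=1) / called.sum(axis=1), np.nan)
        sample_het = np.where(called.sum(axis=0) > 0,
                              het.sum(axis=0) / called.sum(axis=0), np.nan)
    return site_het, sample_het


def write_vcf(panel: GenotypePanel, path) -> None:
    """Serialize a panel as an uncompressed VCF v4.2 with GT:DP genotypes."""
    info_keys = [k for k, v in panel.info.items() if not np.all(np.isnan(v))]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=heteropool\n")
        for chrom in pd.unique(panel.chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        for k in info_keys:
            fh.write(f'##INFO=<ID={k},Number=1,Type=Float,'
                     f'Description="{k} read count">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for i in range(panel.n_sites):
            info = ";".join(
                f"{k}={panel.info[k][i]:g}" for k in info_keys
                if not np.isnan(panel.info[k][i])
            ) or "."
            qual = "." if np.isnan(panel.qual[i]) else f"{panel.qual[i]:g}"
            cells = []
            for j in range(panel.n_samples):
                dp = panel.depth[i, j]
                dp_s = "." if dp < 0 else str(int(dp))
                cells.append(f"{gt_map[int(panel.dosage[i, j])]}:{dp_s}")
            fh.write(f"{panel.chrom[i]}\t{panel.pos[i]}\t.\t{panel.ref[i]}\t"
                     f"{panel.alt[i]}\t{qual}\t.\t{info}\tGT:DP\t"
                     + "\t".join(cells) + "\n")


def write_sample_table(panel: GenotypePanel, path,
                       median_depth: np.ndarray | None = None) -> None:
    df = pd.DataFrame({"sample_id": panel.samples, "group": panel.groups})
    if median_depth is not None:
        df["median_depth"] = median_depth
    df.to_csv(path, sep="\t", index=False)
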