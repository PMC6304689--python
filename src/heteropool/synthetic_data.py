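"""Synthetic three-group panel generator with a complete truth ledger.

Generates genotypes for an open-pollinated progenitor group (OPV) and two
inbred heterotic pools (B, R) in which ancestral variation is sorted with
configurable parallel/opposite shift fractions; introgression blocks
private to one pool; gene models with deletions enriched inside blocks and
copy-number amplifications; and per-gene read depths drawn from a Poisson
coverage model.  Everything is reproducible bit-for-bit from the seed, and
a :class:`SyntheticTruth` ledger records every planted signal for
parameter-recovery tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gene_depth import GeneDepthMatrix
from .variant_io import MISSING, GenotypePanel, write_sample_table, write_vcf

logger = logging.getLogger(__name__)

UNSHIFTED, PARALLEL, OPPOSITE = "unshifted", "parallel", "opposite"
KEYWORD = "pentatricopeptide"


@dataclass
class IntrogressionBlock:
    chrom: str
    start: int  # 0-based half-open
    end: int
    carrier_group: str = "R"
    ancestry_level: float = 0.8


@dataclass
class SimConfig:
    """Parameters of the synthetic panel.

    Sample counts default to the real panel shape (9 OPV, 127 B, 96 R)
    and sample median coverage is drawn log-uniform on ~[1.6, 19].
    ``introgression_blocks=None`` places one R-carried block each on
    chromosomes 8, 10 and 13 when the genome has >= 13 chromosomes.
    """

    n_opv: int = 9
    n_b: int = 127
    n_r: int = 96
    n_chrom: int = 17
    chrom_length_bp: int = 10_000_000
    n_sites: int = 20_000
    n_genes: int = 2_000
    # short-gene-heavy lognormal length distribution
    gene_length_log_mean: float = 7.6
    gene_length_log_sd: float = 0.9
    gene_min_length: int = 150
    n_keyword_genes: int = 20
    n_keyword_in_block: int = 5
    ancestral_beta: tuple[float, float] = (0.8, 0.8)
    ancestral_band: tuple[float, float] = (0.05, 0.95)
    p_shifted: float = 0.2
    p_opposite_given_shifted: float = 0.003
    shift_magnitude_min: float = 0.2
    shift_magnitude_scale: float = 0.1
    drift_shift_sd: float = 0.0
    introgression_blocks: list[IntrogressionBlock] | None = None
    del_rate_in_block: float = 0.015
    del_rate_outside: float = 0.01
    # outbred OPV lines rarely carry homozygous deletions
    opv_del_factor: float = 0.3
    group_del_fraction: float = 0.0
    group_del_freq: float = 0.7
    amp_rate: float = 0.01
    amp_copy_min: int = 4
    amp_copy_max: int = 10
    depth_min: float = 1.6
    depth_max: float = 19.0
    read_length_bp: int = 100
    inbreeding_opv: float = 0.0
    inbreeding_b: float = 0.95
    inbreeding_r: float = 0.95
    p_fail_qual: float = 0.02
    p_fail_strand: float = 0.01
    p_fail_placement: float = 0.01
    p_indel: float = 0.01
    p_multiallelic: float = 0.01
    ancestry_window_bp: int = 500_000
    ancestry_baseline_max: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_shifted", "p_opposite_given_shifted",
                     "del_rate_in_block", "del_rate_outside", "amp_rate",
                     "opv_del_factor",
                     "group_del_fraction", "group_del_freq",
                     "p_fail_qual", "p_fail_strand", "p_fail_placement",
                     "p_indel", "p_multiallelic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_sites < 1 or self.n_genes < 1:
            raise ValueError("n_sites and n_genes must be >= 1")
        if min(self.n_opv, self.n_b, self.n_r) < 1:
            raise ValueError("every group needs at least one sample")
        if self.shift_magnitude_min < 0.2:
            raise ValueError("shift magnitudes must support >= 0.2")
        for blk in self.blocks():
            if blk.start < 0 or blk.end > self.chrom_length_bp:
                raise ValueError(f"block {blk} outside chromosome bounds")

    def chrom_names(self) -> list[str]:
        return [f"chr{i:02d}" for i in range(1, self.n_chrom + 1)]

    def blocks(self) -> list[IntrogressionBlock]:
        if self.introgression_blocks is not None:
            return self.introgression_blocks
        if self.n_chrom < 13:
            return []
        L = self.chrom_length_bp
        return [
            IntrogressionBlock("chr08", int(0.30 * L), int(0.50 * L), "R", 0.8),
            IntrogressionBlock("chr10", int(0.20 * L), int(0.60 * L), "R", 0.8),
            IntrogressionBlock("chr13", int(0.40 * L), int(0.65 * L), "R", 0.8),
        ]


@dataclass
class SyntheticTruth:
    """Ledger of every planted signal.

    ``sites``: chrom, pos (1-based), category in {unshifted, parallel,
    opposite}, true group frequencies, clipped flag.  ``genes``: models
    with annotation and in_block flag.  ``copy_number``: genes x samples
    true relative copies (0 deleted, 1, or k amplified).  ``samples``:
    sample_id, group, true median coverage.  ``blocks``: planted
    introgression blocks.
    """

    sites: pd.DataFrame
    genes: pd.DataFrame
    copy_number: np.ndarray
    samples: pd.DataFrame
    blocks: list[IntrogressionBlock] = field(default_factory=list)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.sites.to_csv(outdir / "sites.tsv", sep="\t", index=False)
        self.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
        cn = pd.DataFrame(self.copy_number,
                          columns=self.samples["sample_id"].tolist())
        cn.insert(0, "gene_id", self.genes["gene_id"].to_numpy())
        cn.to_csv(outdir / "copy_number.tsv", sep="\t", index=False)
        self.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        with open(outdir / "blocks.json", "w") as fh:
            json.dump([asdict(b) for b in self.blocks], fh, indent=1)

    @classmethod
    def read(cls, outdir) -> "SyntheticTruth":
        outdir = Path(outdir)
        sites = pd.read_csv(outdir / "sites.tsv", sep="\t")
        # keep_default_na preserves the empty-string group-deletion labels
        genes = pd.read_csv(outdir / "genes.tsv", sep="\t",
                            keep_default_na=False)
        cn = pd.read_csv(outdir / "copy_number.tsv", sep="\t")
        samples = pd.read_csv(outdir / "samples.tsv", sep="\t")
        with open(outdir / "blocks.json") as fh:
            blocks = [IntrogressionBlock(**b) for b in json.load(fh)]
        return cls(sites=sites, genes=genes,
                   copy_number=cn.drop(columns="gene_id").to_numpy(),
                   samples=samples, blocks=blocks)


def _truncated_beta(rng, a, b, lo, hi, size):
    u = rng.uniform(stats.beta.cdf(lo, a, b), stats.beta.cdf(hi, a, b), size)
    return stats.beta.ppf(u, a, b)


def _draw_genotypes(rng, freq, n_samples, inbreeding):
    """Dosage draws at diploid HWE adjusted by inbreeding coefficient F."""
    f = freq[:, None]
    p_hom_alt = f ** 2 + inbreeding * f * (1.0 - f)
    p_het = 2.0 * f * (1.0 - f) * (1.0 - inbreeding)
    u = rng.random((freq.shape[0], n_samples))
    dos = np.zeros((freq.shape[0], n_samples), dtype=np.int8)
    dos[u < p_hom_alt + p_het] = 1
    dos[u < p_hom_alt] = 2
    return dos


def _in_blocks(chrom, pos_start, pos_end, blocks, carrier=None):
    """Boolean mask of intervals overlapping any block (optionally only
    blocks carried by ``carrier``).  Intervals are 0-based half-open."""
    mask = np.zeros(len(chrom), dtype=bool)
    for blk in blocks:
        if carrier is not None and blk.carrier_group != carrier:
            continue
        mask |= ((chrom == blk.chrom) & (pos_start < blk.end)
                 & (pos_end > blk.start))
    return mask


def _make_gene_models(rng, config: SimConfig) -> pd.DataFrame:
    chroms = np.asarray(config.chrom_names(), dtype=object)
    gene_chrom = rng.choice(chroms, size=config.n_genes)
    lengths = np.maximum(
        rng.lognormal(config.gene_length_log_mean,
                      config.gene_length_log_sd, config.n_genes),
        config.gene_min_length).astype(np.int64)
    lengths = np.minimum(lengths, config.chrom_length_bp // 2)
    starts = (rng.random(config.n_genes)
              * (config.chrom_length_bp - lengths)).astype(np.int64)
    annotation = np.asarray(["hypothetical protein"] * config.n_genes,
                            dtype=object)

    n_kw = min(config.n_keyword_genes, config.n_genes)
    kw_idx = rng.choice(config.n_genes, size=n_kw, replace=False)
    annotation[kw_idx] = f"{KEYWORD} repeat-containing protein"
    # plant part of the keyword genes inside R-carried blocks so that
    # candidate-gene recovery has known truth
    r_blocks = [b for b in config.blocks() if b.carrier_group == "R"]
    if r_blocks and config.n_keyword_in_block > 0:
        n_in = min(config.n_keyword_in_block, n_kw)
        for k, gi in enumerate(kw_idx[:n_in]):
            blk = r_blocks[k % len(r_blocks)]
            gene_chrom[gi] = blk.chrom
            span = max(blk.end - blk.start - lengths[gi], 1)
            starts[gi] = blk.start + int(rng.integers(span))

    order = np.lexsort((starts, gene_chrom.astype(str)))
    df = pd.DataFrame({
        "gene_id": "", "chrom": gene_chrom[order], "start": starts[order],
        "end": starts[order] + lengths[order], "annotation": annotation[order],
    })
    df["gene_id"] = [f"gene{i + 1:05d}" for i in range(len(df))]
    df["in_block"] = _in_blocks(df["chrom"].to_numpy(), df["start"].to_numpy(),
                                df["end"].to_numpy(), config.blocks())
    return df


def generate_genotypes(config: SimConfig) -> tuple[GenotypePanel, SyntheticTruth]:
    """Generate the genotype panel and its truth ledger.

    Per site, an ancestral OPV frequency is drawn from the configured
    truncated Beta; with probability ``p_shifted`` both pools shift by at
    least ``shift_magnitude_min``, in the same direction (parallel) or in
    opposite directions with probability ``p_opposite_given_shifted``.
    Sites inside introgression blocks have the carrier group's frequency
    pulled toward the allele rarer in the ancestor, elevating F_ST there.
    B/R genotypes are drawn near-fully homozygous; OPV at Hardy-Weinberg.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = config.chrom_names()

    # --- samples ------------------------------------------------------
    sample_ids = ([f"OPV{i + 1:03d}" for i in range(config.n_opv)]
                  + [f"B{i + 1:03d}" for i in range(config.n_b)]
                  + [f"R{i + 1:03d}" for i in range(config.n_r)])
    groups = np.asarray(["OPV"] * config.n_opv + ["B"] * config.n_b
                        + ["R"] * config.n_r, dtype=object)
    n_samples = len(sample_ids)
    coverage = np.exp(rng.uniform(np.log(config.depth_min),
                                  np.log(config.depth_max), n_samples))

    # --- site coordinates --------------------------------------------
    site_chrom_idx = rng.integers(0, config.n_chrom, config.n_sites)
    pos = np.empty(config.n_sites, dtype=np.int64)
    for ci in range(config.n_chrom):
        m = site_chrom_idx == ci
        k = int(m.sum())
        if k:
            pos[m] = np.sort(rng.choice(
                np.arange(1, config.chrom_length_bp + 1), size=k,
                replace=False))
    order = np.lexsort((pos, site_chrom_idx))
    site_chrom_idx = site_chrom_idx[order]
    pos = pos[order]
    site_chrom = np.asarray(chrom_names, dtype=object)[site_chrom_idx]

    # --- true frequencies --------------------------------------------
    a, b = config.ancestral_beta
    lo, hi = config.ancestral_band
    f_opv = _truncated_beta(rng, a, b, lo, hi, config.n_sites)
    shifted = rng.random(config.n_sites) < config.p_shifted
    opposite = shifted & (rng.random(config.n_sites)
                          < config.p_opposite_given_shifted)
    category = np.full(config.n_sites, UNSHIFTED, dtype=object)
    category[shifted] = PARALLEL
    category[opposite] = OPPOSITE

    mag_b = config.shift_magnitude_min + rng.exponential(
        config.shift_magnitude_scale, config.n_sites)
    mag_r = config.shift_magnitude_min + rng.exponential(
        config.shift_magnitude_scale, config.n_sites)
    sign = np.where(rng.random(config.n_sites) < 0.5, -1.0, 1.0)
    d_b = np.where(shifted, sign * mag_b, 0.0)
    d_r = np.where(shifted, np.where(opposite, -sign, sign) * mag_r, 0.0)
    f_b = f_opv + d_b
    f_r = f_opv + d_r
    if config.drift_shift_sd > 0:
        f_b = f_b + rng.normal(0.0, config.drift_shift_sd, config.n_sites)
        f_r = f_r + rng.normal(0.0, config.drift_shift_sd, config.n_sites)

    clipped = (f_b < 0) | (f_b > 1) | (f_r < 0) | (f_r > 1)
    if clipped.any():
        logger.info("clipped %d/%d shifted frequencies to [0, 1]",
                    int(clipped.sum()), config.n_sites)
    f_b = np.clip(f_b, 0.0, 1.0)
    f_r = np.clip(f_r, 0.0, 1.0)

    blocks = config.blocks()
    divergent = np.where(f_opv < 0.5, 1.0, 0.0)
    for grp, fvec in (("B", f_b), ("R", f_r)):
        in_blk = _in_blocks(site_chrom, pos - 1, pos, blocks, carrier=grp)
        if in_blk.any():
            lvl = np.zeros(config.n_sites)
            for blk in blocks:
                if blk.carrier_group != grp:
                    continue
                m = ((site_chrom == blk.chrom) & (pos - 1 >= blk.start)
                     & (pos - 1 < blk.end))
                lvl[m] = np.maximum(lvl[m], blk.ancestry_level)
            fvec[in_blk] = ((1.0 - lvl[in_blk]) * fvec[in_blk]
                            + lvl[in_blk] * divergent[in_blk])

    # --- genotypes and per-genotype depth ----------------------------
    dosage = np.empty((config.n_sites, n_samples), dtype=np.int8)
    for grp, fvec, F in (("OPV", f_opv, config.inbreeding_opv),
                         ("B", f_b, config.inbreeding_b),
                         ("R", f_r, config.inbreeding_r)):
        idx = np.flatnonzero(groups == grp)
        dosage[:, idx] = _draw_genotypes(rng, fvec, idx.size, F)
    depth = rng.poisson(coverage[None, :],
                        (config.n_sites, n_samples)).astype(np.int32)
    dosage[depth == 0] = MISSING

    # --- site QC fields, engineered failure fractions ----------------
    qual = rng.uniform(31.0, 2000.0, config.n_sites)
    fail_qual = rng.random(config.n_sites) < config.p_fail_qual
    qual[fail_qual] = rng.uniform(0.0, 30.0, int(fail_qual.sum()))
    sar = rng.poisson(10.0, config.n_sites).astype(float) + 1.0
    saf = rng.poisson(10.0, config.n_sites).astype(float) + 1.0
    fail_strand = rng.random(config.n_sites) < config.p_fail_strand
    strand_side = rng.random(config.n_sites) < 0.5
    sar[fail_strand & strand_side] = 0.0
    saf[fail_strand & ~strand_side] = 0.0
    rpl = rng.poisson(10.0, config.n_sites).astype(float) + 2.0
    rpr = rng.poisson(10.0, config.n_sites).astype(float) + 2.0
    fail_place = rng.random(config.n_sites) < config.p_fail_placement
    place_side = rng.random(config.n_sites) < 0.5
    rpl[fail_place & place_side] = rng.integers(
        0, 2, int((fail_place & place_side).sum())).astype(float)
    rpr[fail_place & ~place_side] = rng.integers(
        0, 2, int((fail_place & ~place_side).sum())).astype(float)

    bases = np.asarray(list("ACGT"), dtype=object)
    ref = bases[rng.integers(0, 4, config.n_sites)]
    alt_base = bases[(rng.integers(1, 4, config.n_sites)
                      + np.searchsorted(bases, ref)) % 4]
    alt = alt_base.copy()
    is_indel = rng.random(config.n_sites) < config.p_indel
    is_multi = (~is_indel) & (rng.random(config.n_sites) < config.p_multiallelic)
    ref = np.where(is_indel, ref + "T", ref)
    third = bases[(np.searchsorted(bases, alt_base)
                   + rng.integers(1, 4, config.n_sites)) % 4]
    same = third == ref
    third[same] = bases[(np.searchsorted(bases, third[same]) + 1) % 4]
    alt = np.where(is_multi, alt_base + "," + third, alt)

    panel = GenotypePanel(
        samples=sample_ids, groups=groups, chrom=site_chrom, pos=pos,
        ref=ref, alt=alt, qual=qual,
        info={"SAR": sar, "SAF": saf, "RPL": rpl, "RPR": rpr},
        is_biallelic_snp=~(is_indel | is_multi),
        dosage=dosage, depth=depth,
    )

    # --- gene models and copy-number truth ---------------------------
    genes = _make_gene_models(rng, config)
    copy_number = np.ones((config.n_genes, n_samples), dtype=np.int16)

    in_block_gene = genes["in_block"].to_numpy()
    carrier_cols = np.zeros((config.n_genes, n_samples), dtype=bool)
    for blk in blocks:
        g_in = ((genes["chrom"] == blk.chrom)
                & (genes["start"] < blk.end)
                & (genes["end"] > blk.start)).to_numpy()
        carrier_cols[np.ix_(g_in, groups == blk.carrier_group)] = True
    del_rate = np.where(carrier_cols, config.del_rate_in_block,
                        config.del_rate_outside)
    del_rate[:, groups == "OPV"] *= config.opv_del_factor
    deleted = rng.random((config.n_genes, n_samples)) < del_rate

    group_private = np.full(config.n_genes, "", dtype=object)
    if config.group_del_fraction > 0:
        chosen = rng.random(config.n_genes) < config.group_del_fraction
        target = np.where(rng.random(config.n_genes) < 0.5, "B", "R")
        target[in_block_gene] = "R"  # block genes sort with the carrier pool
        group_private[chosen] = target[chosen]
        for grp in ("B", "R"):
            rows = np.flatnonzero(group_private == grp)
            cols = np.flatnonzero(groups == grp)
            if rows.size and cols.size:
                hit = rng.random((rows.size, cols.size)) < config.group_del_freq
                deleted[np.ix_(rows, cols)] |= hit

    amplified = (~deleted) & (rng.random((config.n_genes, n_samples))
                              < config.amp_rate)
    amp_copies = rng.integers(config.amp_copy_min, config.amp_copy_max + 1,
                              (config.n_genes, n_samples)).astype(np.int16)
    copy_number[amplified] = amp_copies[amplified]
    copy_number[deleted] = 0

    genes = genes.copy()
    genes["group_private_deletion"] = group_private

    truth = SyntheticTruth(
        sites=pd.DataFrame({
            "chrom": site_chrom, "pos": pos, "category": category,
            "f_OPV": f_opv, "f_B": f_b, "f_R": f_r, "clipped": clipped,
            # block adjustment overrides the carrier frequency, so the
            # category no longer describes in-block sites' final deltas
            "in_block": _in_blocks(site_chrom, pos - 1, pos, blocks),
        }),
        genes=genes,
        copy_number=copy_number,
        samples=pd.DataFrame({
            "sample_id": sample_ids, "group": groups,
            "median_coverage": coverage,
        }),
        blocks=blocks,
    )
    return panel, truth


def generate_gene_depths(config: SimConfig,
                         truth: SyntheticTruth) -> GeneDepthMatrix:
    """Per-gene mean depths from Poisson read counts.

    For gene length L, sample coverage c and relative copy number k, the
    read count is Poisson(c * L * k / read_length) and the mean depth is
    reads * read_length / L.  True copy 0 gives depth exactly 0; short
    genes at low coverage can stochastically receive zero reads,
    reproducing the depth-driven false-absence artifact.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed, 0x9E3779B9]))  # independent stream from the genotypes
    lengths = (truth.genes["end"] - truth.genes["start"]).to_numpy()
    coverage = truth.samples["median_coverage"].to_numpy()
    lam = (coverage[None, :] * lengths[:, None] / config.read_length_bp
           * truth.copy_number)
    reads = rng.poisson(lam)
    depth = reads * config.read_length_bp / lengths[:, None]
    return GeneDepthMatrix(
        genes=truth.genes[["gene_id", "chrom", "start", "end",
                           "annotation"]].reset_index(drop=True),
        samples=truth.samples["sample_id"].tolist(),
        depth=depth,
    )


def build_ancestry_track(config: SimConfig,
                         truth: SyntheticTruth | None = None) -> pd.DataFrame:
    """Windowed non-landrace ancestry track tiling every chromosome.

    Windows overlapping an R-carried block take the block's ancestry
    level; all others draw a low baseline value.  Deterministic in the
    config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed, 0x51A5C817]))
    blocks = truth.blocks if truth is not None else config.blocks()
    rows = []
    for chrom in config.chrom_names():
        starts = np.arange(0, config.chrom_length_bp, config.ancestry_window_bp,
                           dtype=np.int64)
        ends = np.minimum(starts + config.ancestry_window_bp,
                          config.chrom_length_bp)
        anc = rng.uniform(0.0, config.ancestry_baseline_max, len(starts))
        for blk in blocks:
            if blk.carrier_group != "R" or blk.chrom != chrom:
                continue
            hit = (starts < blk.end) & (ends > blk.start)
            anc[hit] = blk.ancestry_level
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                  "end": ends, "ancestry": anc}))
    return pd.concat(rows, ignore_index=True)


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write gene models as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g['gene_id']};Note={g['annotation']}"
            fh.write(f"{g['chrom']}\theteropool\tgene\t{g['start'] + 1}\t"
                     f"{g['end']}\t.\t+\t.\t{attrs}\n")


def read_gff3_genes(path) -> pd.DataFrame:
    """Read gene features from a GFF3 into the internal 0-based half-open
    convention (columns gene_id, chrom, start, end, annotation)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9 or parts[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            rows.append({
                "gene_id": attrs.get("ID", f"{parts[0]}:{parts[3]}"),
                "chrom": parts[0],
                "start": int(parts[3]) - 1,
                "end": int(parts[4]),
                "annotation": attrs.get("Note", ""),
            })
    return pd.DataFrame(rows)


def write_outputs(panel: GenotypePanel, depths: GeneDepthMatrix,
                  truth: SyntheticTruth, config: SimConfig, outdir) -> dict:
    """Serialize the generated panel in the formats the pipeline consumes.

    Emits panel.vcf (v4.2, GT:DP), genes.gff3, gene_depth.tsv,
    ancestry.bed (BED3+score, 0-based half-open), samples.tsv and the
    truth ledger under truth/.  Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "panel.vcf",
        "gff3": outdir / "genes.gff3",
        "gene_depth": outdir / "gene_depth.tsv",
        "ancestry": outdir / "ancestry.bed",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth",
    }
    write_vcf(panel, paths["vcf"])
    write_gff3(truth.genes, paths["gff3"])
    depths.to_frame().to_csv(paths["gene_depth"], sep="\t", index=False,
                             float_format="%.6g")
    track = build_ancestry_track(config, truth)
    track.to_csv(paths["ancestry"], sep="\t", index=False, header=False,
                 float_format="%.6g")
    write_sample_table(
        panel, paths["samples"],
        median_depth=truth.samples["median_coverage"].to_numpy())
    truth.write(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
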