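import numpy as np
import pandas as pd
import pytest

from heteropool.gene_depth import GeneDepthMatrix, classify_copy_state
from heteropool.synthetic_data import SimConfig, generate_genotypes
from heteropool.variant_io import MISSING, GenotypePanel


def make_panel(dosage, groups, pos=None, chrom=None, qual=None, depth=None,
               info=None, biallelic=None):
    """Build a GenotypePanel directly from a dosage matrix for unit tests."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    groups = np.asarray(groups, dtype=object)
    samples = [f"s{i}" for i in range(n_samples)]
    if pos is None:
        pos = np.arange(1, n_sites + 1, dtype=np.int64)
    if chrom is None:
        chrom = np.asarray(["chr01"] * n_sites, dtype=object)
    if qual is None:
        qual = np.full(n_sites, 100.0)
    if depth is None:
        depth = np.full((n_sites, n_samples), 10, dtype=np.int32)
    base_info = {k: np.full(n_sites, 5.0) for k in ("SAR", "SAF", "RPL", "RPR")}
    if info:
        base_info.update(info)
    if biallelic is None:
        biallelic = np.ones(n_sites, dtype=bool)
    return GenotypePanel(
        samples=samples,
        groups=groups,
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(["A"] * n_sites, dtype=object),
        alt=np.asarray(["T"] * n_sites, dtype=object),
        qual=np.asarray(qual, dtype=float),
        info=base_info,
        is_biallelic_snp=np.asarray(biallelic, dtype=bool),
        dosage=dosage,
        depth=np.asarray(depth, dtype=np.int32),
    )


def random_dosage(rng, n_sites, n_samples, missing_frac=0.1):
    dos = rng.integers(0, 3, (n_sites, n_samples)).astype(np.int8)
    dos[rng.random((n_sites, n_samples)) < missing_frac] = MISSING
    return dos


def make_states(depths, genes=None, samples=None):
    """CopyStateMatrix from a raw depth array via the production classifier."""
    depths = np.asarray(depths, dtype=float)
    n_genes, n_samples = depths.shape
    if genes is None:
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "chrom": "chr01",
            "start": np.arange(n_genes) * 1000,
            "end": np.arange(n_genes) * 1000 + 500,
            "annotation": "hypothetical protein",
        })
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return classify_copy_state(
        GeneDepthMatrix(genes=genes, samples=samples, depth=depths))


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_opv=5, n_b=18, n_r=14, n_chrom=3,
                     chrom_length_bp=2_000_000, n_sites=800, n_genes=150,
                     introgression_blocks=[], seed=42)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return generate_genotypes(small_config)
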