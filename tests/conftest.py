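import numpy as np
import pandas as pd
import pytest

from qtsgwas import GenotypePanel, SimConfig, simulate_genotypes


@pytest.fixture(scope="session")
def small_panel() -> GenotypePanel:
    """316-accession two-subpopulation panel with weak LD."""
    cfg = SimConfig(
        n_accessions=316, n_snps=120, n_chromosomes=4, n_subpops=2,
        divergence=0.15, ld_block_bp=1_000.0, seed=11,
    )
    return simulate_genotypes(cfg)


def toy_panel(codes: np.ndarray, positions=None, chrom=None) -> GenotypePanel:
    """Panel from a raw accessions x SNPs code matrix."""
    codes = np.asarray(codes, dtype=np.int8)
    n_acc, n_snp = codes.shape
    pos = np.asarray(positions) if positions is not None else 100 * (np.arange(n_snp) + 1)
    chroms = np.asarray(chrom) if chrom is not None else np.array(["C1"] * n_snp)
    snps = pd.DataFrame(
        {
            "id": [f"{c}_{p}" for c, p in zip(chroms, pos)],
            "chrom": chroms,
            "pos": pos,
        }
    )
    return GenotypePanel(
        codes=codes, accession_ids=[f"acc{i + 1}" for i in range(n_acc)], snps=snps
    )
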