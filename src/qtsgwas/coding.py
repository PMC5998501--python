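"""Genetic-effect coefficient coding for the full QTS model.

For a biallelic locus with alleles Q and q, genotypes QQ / Qq / qq receive
additive coefficients ``x_A = 1 / 0 / -1`` and dominance coefficients
``x_D = 0 / 1 / 0``.  Digenic epistasis coefficients are the products of the
single-locus columns: ``x_AA = x_A(i) * x_A(j)``, ``x_AD = x_A(i) * x_D(j)``,
``x_DA = x_D(i) * x_A(j)``, ``x_DD = x_D(i) * x_D(j)``.  Environment
interaction coefficients equal the matching genetic coefficients.

By convention Q is the major allele, so additive effects are expressed
relative to the major-allele homozygote; ``polarize="counted"`` keeps the
panel's own counted allele as Q instead (useful when the counted allele is
known to be the reference, e.g. in simulations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .panel import MISSING, GenotypePanel

EPISTASIS_CLASSES = ("aa", "ad", "da", "dd")
MAIN_CLASSES = ("a", "d")
GXE_CLASSES = ("ae", "de", "aae", "ade", "dae", "dde")

#: maps a GxE class to the genetic class whose coefficient column it reuses
GXE_PARENT = {"ae": "a", "de": "d", "aae": "aa", "ade": "ad", "dae": "da", "dde": "dd"}


@dataclass
class CodedGenotypes:
    """Additive/dominance coefficient columns for every SNP of a panel.

    ``x_a`` and ``x_d`` are float arrays of shape (n_accessions, n_snps) with
    ``NaN`` at missing genotypes.  ``flipped`` records loci where the Q
    designation was swapped away from the panel's counted allele.
    """

    x_a: np.ndarray
    x_d: np.ndarray
    snp_ids: list[str]
    flipped: np.ndarray
    accession_ids: list[str] | None = None

    @property
    def n_accessions(self) -> int:
        return self.x_a.shape[0]

    @property
    def n_snps(self) -> int:
        return self.x_a.shape[1]

    def index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not coded") from None

    def pair_columns(self, i: int, j: int) -> dict[str, np.ndarray]:
        """Epistasis coefficient columns for the ordered pair (i, j), i < j."""
        if i == j:
            raise ValueError("epistasis requires two distinct loci")
        return {
            "aa": self.x_a[:, i] * self.x_a[:, j],
            "ad": self.x_a[:, i] * self.x_d[:, j],
            "da": self.x_d[:, i] * self.x_a[:, j],
            "dd": self.x_d[:, i] * self.x_d[:, j],
        }


def code_genotypes(panel: GenotypePanel, polarize: str = "major") -> CodedGenotypes:
    """Build x_A / x_D coefficient columns for every SNP.

    Parameters
    ----------
    panel
        Genotype panel with 0/1/2 counts of its counted allele.
    polarize
        ``"major"`` designates Q as the (empirical) major allele at each
        locus; ``"counted"`` keeps the panel's counted allele as Q.

    Monomorphic loci are coded but trigger a warning: their x_A column is
    constant and carries no information.
    """
    if polarize not in ("major", "counted"):
        raise ValueError("polarize must be 'major' or 'counted'")
    codes = panel.codes.astype(float)
    codes[panel.codes == MISSING] = np.nan
    x_d = np.where(np.isnan(codes), np.nan, (codes == 1).astype(float))
    x_a = codes - 1.0
    if polarize == "major":
        freq = panel.allele_freq()
        flipped = freq < 0.5
        x_a[:, flipped] = -x_a[:, flipped]
    else:
        flipped = np.zeros(panel.n_snps, dtype=bool)
    mono = np.nanvar(x_a, axis=0) == 0
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic loci coded with constant x_A")
    return CodedGenotypes(
        x_a=x_a,
        x_d=x_d,
        snp_ids=panel.snp_ids,
        flipped=np.asarray(flipped, dtype=bool),
        accession_ids=list(panel.accession_ids),
    )


def genotype_coefficients(genotype: int) -> tuple[float, float]:
    """(x_A, x_D) for a genotype given as Q-allele count 2/1/0 (QQ/Qq/qq)."""
    if genotype not in (0, 1, 2):
        raise ValueError("genotype must be a Q-allele count in {0, 1, 2}")
    return float(genotype - 1), float(genotype == 1)
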