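"""Synthetic genotype panels and phenotypes with the study's structure.

The generator emulates the design of the cottonseed association panel: a
few hundred germplasm accessions in up to two subpopulations, dense
biallelic SNPs with intrachromosomal linkage disequilibrium decaying at a
tunable physical scale, and replicated multi-environment phenotypes drawn
exactly from the full genetic model

    y_kh = mu + sum_i a_i x_Aik + sum_i d_i x_Dik
         + sum_{i<j} (aa_ij x_AA + ad_ij x_AD + da_ij x_DA + dd_ij x_DD)
         + e_h + sum GxE_ih * u + eps_khr

with e_h ~ N(0, s2_E), each GxE effect drawn once per (component,
environment) from its class variance, and eps drawn per observation.

Genotypes: subpopulation allele frequencies follow a Balding-Nichols draw
around a shared ancestral frequency (divergence = F); haplotypes threshold
a latent Gaussian AR(1) process along each chromosome so that marginal
frequencies are exact while pairwise r2 halves at ``ld_block_bp``; a
configurable fraction of accessions are fully homozygous (selfed) lines
and the rest pair two independent haplotypes (Hardy-Weinberg within
subpopulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import code_genotypes
from .heritability import HeritabilityReport
from .panel import MISSING, GenotypePanel, make_snp_ids

_LETTERS = np.array(list("ACGT"))

GXE_KEYS = ("ae", "de", "aae", "ade", "dae", "dde")


@dataclass
class SimConfig:
    """Study-design parameters for genotype simulation.

    Defaults mirror the cottonseed panel: 316 accessions, two
    subpopulations, MAF floor 0.01, LD half-decay 160 kb, 3 environments
    with 3 replicates.  ``mean_spacing_bp`` sets the average physical gap
    between adjacent SNPs (~5 kb, the density of a ~390 K genome-wide set).
    ``inbreeding`` is the fraction of accessions that are fully homozygous
    lines (germplasm collections are largely selfed); the rest follow
    Hardy-Weinberg within their subpopulation.  A panel of partly inbred
    lines keeps per-SNP heterozygosity compatible with the 30% QC cap.
    """

    n_accessions: int = 316
    n_snps: int = 1000
    n_chromosomes: int = 5
    n_subpops: int = 2
    divergence: float = 0.15
    maf_min: float = 0.01
    ld_block_bp: float = 160_000.0
    mean_spacing_bp: float = 5_000.0
    inbreeding: float = 0.5
    n_envs: int = 3
    n_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_accessions", "n_snps", "n_chromosomes", "n_envs", "n_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_subpops not in (1, 2):
            raise ValueError("n_subpops must be 1 or 2")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")
        if not 0.0 < self.maf_min < 0.5:
            raise ValueError("maf_min must be in (0, 0.5)")
        if not 0.0 <= self.inbreeding <= 1.0:
            raise ValueError("inbreeding must be in [0, 1]")
        if self.ld_block_bp <= 0 or self.mean_spacing_bp <= 0:
            raise ValueError("length scales must be positive")


@dataclass
class TraitArchitecture:
    """Planted genetic architecture of a simulated trait.

    ``main_effects`` holds (locus index, a, d) triples; ``epistatic_effects``
    holds (i, j, aa, ad, da, dd) with i < j.  ``gxe_sds`` maps a component
    class (ae, de, aae, ade, dae, dde) to the per-class standard deviation of
    its environment interactions; every planted effect of the parent class
    receives independent per-environment draws with that sd.
    """

    mu: float = 0.0
    main_effects: list[tuple[int, float, float]] = field(default_factory=list)
    epistatic_effects: list[tuple[int, int, float, float, float, float]] = field(
        default_factory=list
    )
    env_sd: float = 0.0
    gxe_sds: dict[str, float] = field(default_factory=dict)
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        seen = set()
        for loc, _a, _d in self.main_effects:
            if loc in seen:
                raise ValueError(f"locus {loc} appears in more than one main-effect entry")
            seen.add(loc)
        for i, j, *_ in self.epistatic_effects:
            if not i < j:
                raise ValueError("epistatic pairs must satisfy i < j")
        for key, sd in self.gxe_sds.items():
            if key not in GXE_KEYS:
                raise ValueError(f"unknown GxE class {key!r}")
            if sd < 0:
                raise ValueError("GxE sds must be >= 0")
        if self.env_sd < 0 or self.residual_sd < 0:
            raise ValueError("sds must be >= 0")

    def loci(self) -> list[int]:
        out = [loc for loc, _a, _d in self.main_effects]
        for i, j, *_ in self.epistatic_effects:
            out += [i, j]
        return sorted(set(out))


#: decay-rate constant calibrated (by pilot simulation) so that the binned
#: mean genotype r2 falls to half its maximum at distance ~ ld_block_bp
_LD_DECAY_CAL = 2.6


def _simulate_haplotypes(
    rng: np.random.Generator, freqs: np.ndarray, positions: np.ndarray, n_hap: int, ld_block_bp: float
) -> np.ndarray:
    """Latent-Gaussian chain haplotypes for one chromosome.

    A standard-normal AR(1) process along the chromosome (autocorrelation
    exp(-d * ln2 / (2.6 * L)) between SNPs d bp apart) is thresholded at
    each SNP's quantile, so every SNP keeps its exact marginal allele
    frequency while allele correlation decays with distance; the constant
    2.6 places the half-decay of r2 at D = L = ``ld_block_bp``.
    """
    from scipy.stats import norm

    m = freqs.shape[0]
    thr = norm.ppf(freqs)
    u = np.empty((n_hap, m))
    u[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        gaps = np.diff(positions).astype(float)
        phi = np.exp(-gaps * np.log(2.0) / (_LD_DECAY_CAL * ld_block_bp))
        innov_sd = np.sqrt(1.0 - phi**2)
        for k in range(1, m):
            u[:, k] = phi[k - 1] * u[:, k - 1] + innov_sd[k - 1] * rng.standard_normal(n_hap)
    return (u < thr[None, :]).astype(np.int8)


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """Simulate a genotype panel under the configured design.

    Returns a panel whose codes count the major allele at every SNP.  SNPs
    whose empirical MAF falls below ``maf_min`` are dropped, so the returned
    panel can hold slightly fewer than ``n_snps`` SNPs.  Fully reproducible
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    per_chrom = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1
    per_chrom = per_chrom[per_chrom > 0]

    # subpopulation sizes and labels
    if config.n_subpops == 2:
        n0 = config.n_accessions // 2
        labels = np.array([0] * n0 + [1] * (config.n_accessions - n0))
    else:
        labels = np.zeros(config.n_accessions, dtype=int)
    # fully homozygous (selfed) lines, drawn once per accession
    inbred = rng.random(config.n_accessions) < config.inbreeding

    chrom_names, all_pos, code_blocks = [], [], []
    for c, m in enumerate(per_chrom):
        spacing = 1 + rng.exponential(config.mean_spacing_bp - 1, size=m).astype(np.int64)
        pos = np.cumsum(spacing)
        anc = rng.uniform(0.1, 0.9, size=m)
        if config.n_subpops == 2 and config.divergence > 0:
            f = config.divergence
            a = anc * (1 - f) / f
            b = (1 - anc) * (1 - f) / f
            sub_freqs = [np.clip(rng.beta(a, b), 0.001, 0.999) for _ in range(2)]
        else:
            sub_freqs = [anc] * config.n_subpops
        geno = np.empty((config.n_accessions, m), dtype=np.int8)
        for s in range(config.n_subpops):
            rows = np.flatnonzero(labels == s)
            haps = _simulate_haplotypes(rng, sub_freqs[s], pos, 2 * rows.size, config.ld_block_bp)
            h1, h2 = haps[: rows.size], haps[rows.size :]
            h2 = np.where(inbred[rows][:, None], h1, h2)
            geno[rows] = h1 + h2
        chrom_names += [f"C{c + 1}"] * m
        all_pos.append(pos)
        code_blocks.append(geno)

    codes = np.concatenate(code_blocks, axis=1)
    chrom = np.array(chrom_names)
    pos = np.concatenate(all_pos)

    # polarize so the counted allele is the major allele
    freq = codes.mean(axis=0) / 2.0
    flip = freq < 0.5
    codes[:, flip] = 2 - codes[:, flip]

    # allele letters (major/minor), drawn per SNP
    first = rng.integers(0, 4, size=codes.shape[1])
    second = (first + rng.integers(1, 4, size=codes.shape[1])) % 4

    snps = pd.DataFrame(
        {
            "id": make_snp_ids(chrom, pos),
            "chrom": chrom,
            "pos": pos,
            "major": _LETTERS[first],
            "minor": _LETTERS[second],
        }
    )
    panel = GenotypePanel(
        codes=codes,
        accession_ids=[f"acc{i + 1}" for i in range(config.n_accessions)],
        snps=snps,
        subpop_labels=labels,
    )
    keep = panel.maf() >= config.maf_min
    return panel.take_snps(keep) if not keep.all() else panel


def _architecture_columns(panel: GenotypePanel, arch: TraitArchitecture):
    """Coefficient columns for every planted effect, in a flat list.

    Returns a list of (label, class, value_or_sd_key, column) where fixed
    effects carry their effect value and GxE handled separately.
    """
    loci = arch.loci()
    if any((panel.codes[:, loc] == MISSING).any() for loc in loci):
        raise ValueError("architecture references a locus with missing genotypes")
    coded = code_genotypes(panel, polarize="counted")
    fixed = []  # (term, cls, value, column)
    for loc, a, d in arch.main_effects:
        fixed.append((panel.snp_ids[loc], "a", a, coded.x_a[:, loc]))
        fixed.append((panel.snp_ids[loc], "d", d, coded.x_d[:, loc]))
    for i, j, aa, ad, da, dd in arch.epistatic_effects:
        cols = coded.pair_columns(i, j)
        term = f"{panel.snp_ids[i]}&{panel.snp_ids[j]}"
        for cls, val in zip(("aa", "ad", "da", "dd"), (aa, ad, da, dd)):
            fixed.append((term, cls, val, cols[cls]))
    return fixed


def simulate_phenotypes(
    panel: GenotypePanel,
    arch: TraitArchitecture,
    n_envs: int,
    n_reps: int,
    seed: int,
    trait: str = "trait1",
) -> pd.DataFrame:
    """Draw replicated multi-environment phenotypes from the full model.

    Returns a long-format table (accession, env, rep, trait, value).  The
    coefficient coding treats the panel's counted allele as Q, matching
    panels produced by :func:`simulate_genotypes` (counted = major).
    """
    rng = np.random.default_rng(seed)
    fixed = _architecture_columns(panel, arch)
    n = panel.n_accessions

    g = np.zeros(n)
    for _term, _cls, value, col in fixed:
        g = g + value * col

    env_effects = rng.normal(0.0, arch.env_sd, size=n_envs) if arch.env_sd > 0 else np.zeros(n_envs)

    # one draw per (planted effect, environment) for each GxE class
    gxe = np.zeros((n, n_envs))
    for _term, cls, _value, col in fixed:
        sd = arch.gxe_sds.get(cls + "e", 0.0)
        if sd > 0:
            draws = rng.normal(0.0, sd, size=n_envs)
            gxe += col[:, None] * draws[None, :]

    rows = []
    acc = np.asarray(panel.accession_ids)
    for h in range(n_envs):
        base = arch.mu + g + env_effects[h] + gxe[:, h]
        for r in range(n_reps):
            eps = rng.normal(0.0, arch.residual_sd, size=n) if arch.residual_sd > 0 else 0.0
            rows.append(
                pd.DataFrame(
                    {
                        "accession": acc,
                        "env": h + 1,
                        "rep": r + 1,
                        "trait": trait,
                        "value": base + eps,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def true_heritabilities(panel: GenotypePanel, arch: TraitArchitecture) -> HeritabilityReport:
    """Heritabilities implied by the architecture and realized genotypes.

    Uses the same marginal variance formulas as the estimation side: a fixed
    effect contributes value^2 * Var(column), a GxE class contributes
    sd^2 * mean(column^2) per planted parent effect.  V_P is the sum of all
    contributions plus the residual variance (environment main effect
    excluded).  Classes with no planted effects report 0.
    """
    fixed = _architecture_columns(panel, arch)
    entries = []  # (term, cls, contribution)
    for term, cls, value, col in fixed:
        entries.append((term, cls, value**2 * np.var(col)))
        sd = arch.gxe_sds.get(cls + "e", 0.0)
        if sd > 0:
            entries.append((term, cls + "e", sd**2 * np.mean(col**2)))
    v_p = sum(c for *_x, c in entries) + arch.residual_sd**2
    per_effect = pd.DataFrame(
        {
            "term": [t for t, _c, _v in entries],
            "effect_type": [c for _t, c, _v in entries],
            "h2": [100.0 * v / v_p for _t, _c, v in entries],
        }
    )
    return HeritabilityReport(per_effect=per_effect, v_p=v_p)


def degrade_panel(
    panel: GenotypePanel, missing_rate: float, het_inflation: float, seed: int
) -> GenotypePanel:
    """Inject missingness and excess heterozygosity for QC testing.

    Marks each entry missing with probability ``missing_rate`` and converts
    each (remaining) homozygous entry to a heterozygote with probability
    ``het_inflation``.  Seeded and reproducible.
    """
    for name, rate in (("missing_rate", missing_rate), ("het_inflation", het_inflation)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    codes = panel.codes.copy()
    if het_inflation > 0:
        hom = (codes == 0) | (codes == 2)
        to_het = hom & (rng.random(codes.shape) < het_inflation)
        codes[to_het] = 1
    if missing_rate > 0:
        codes[rng.random(codes.shape) < missing_rate] = MISSING
    return GenotypePanel(
        codes=codes,
        accession_ids=list(panel.accession_ids),
        snps=panel.snps.copy(),
        subpop_labels=None if panel.subpop_labels is None else panel.subpop_labels.copy(),
    )


def hudson_fst(panel: GenotypePanel) -> float:
    """Hudson estimator of Fst between the panel's two subpopulations.

    Ratio-of-averages form: mean over SNPs of the numerator
    (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) divided by the mean of the
    denominator p1(1-p2) + p2(1-p1).
    """
    if panel.subpop_labels is None:
        raise ValueError("panel has no subpopulation labels")
    labels = panel.subpop_labels
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("exactly two subpopulations required")
    g1 = panel.codes[labels == groups[0]].astype(float)
    g2 = panel.codes[labels == groups[1]].astype(float)
    g1[g1 == MISSING] = np.nan
    g2[g2 == MISSING] = np.nan
    n1 = 2 * np.sum(~np.isnan(g1), axis=0)
    n2 = 2 * np.sum(~np.isnan(g2), axis=0)
    p1 = np.nansum(g1, axis=0) / n1
    p2 = np.nansum(g2, axis=0) / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(np.mean(num) / np.mean(den))
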