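"""Superior-genotype design from a fitted full QTS model.

Given estimated genetic effects, predicts the genetic value of any
multilocus genotype and finds the optimum over the allowed genotype space:

* GSL / GSH — general superior (homozygous) line / hybrid: optimize the
  main + epistatic genetic value, environment-independent;
* SL / SH — environment-specific superior line / hybrid: additionally add
  the predicted GxE effects of one environment.

Line designs restrict every locus to the homozygotes {QQ, qq}; hybrid
designs also allow Qq.  The optimum is exact: loci are partitioned into
connected components of the epistasis graph, isolated loci are optimized
independently, and each component is solved by exhaustive enumeration.
Both maximization ("+" designs) and minimization ("-" designs, e.g. for
myristic and palmitic acid) are supported.  The population mean and the
environment main effect are excluded — designs compare genotypes, not
locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import networkx as nx
import numpy as np
import pandas as pd

from .coding import GXE_PARENT, genotype_coefficients
from .model import FullModel

#: lexicographic genotype order for tie-breaking: QQ < Qq < qq
_GENO_ORDER = (2, 1, 0)
_GENO_NAME = {2: "QQ", 1: "Qq", 0: "qq"}

MAX_COMPONENT = 20


@dataclass
class DesignTarget:
    mode: str  # GSL | GSH | SL | SH
    objective: str = "max"
    environment: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("GSL", "GSH", "SL", "SH"):
            raise ValueError("mode must be one of GSL, GSH, SL, SH")
        if self.objective not in ("max", "min"):
            raise ValueError("objective must be 'max' or 'min'")
        env_specific = self.mode in ("SL", "SH")
        if env_specific and self.environment is None:
            raise ValueError(f"{self.mode} design requires an environment id")
        if not env_specific and self.environment is not None:
            raise ValueError(f"{self.mode} design takes no environment id")

    @property
    def allowed_genotypes(self) -> tuple[int, ...]:
        return (2, 1, 0) if self.mode in ("GSH", "SH") else (2, 0)


@dataclass
class DesignResult:
    """Optimal per-QTS genotype assignment and its predicted value."""

    target: DesignTarget
    assignment: dict[str, int]  # qts -> Q-allele count
    value: float
    genotype_labels: dict[str, str] = field(default_factory=dict)
    per_env_values: dict[int, float] = field(default_factory=dict)


def _coerce_genotype(g) -> int:
    if isinstance(g, str):
        mapping = {"QQ": 2, "Qq": 1, "qQ": 1, "qq": 0}
        if g not in mapping:
            raise ValueError(f"unknown genotype label {g!r}")
        return mapping[g]
    if g not in (0, 1, 2):
        raise ValueError("genotype must be a Q-allele count in {0, 1, 2}")
    return int(g)


def genetic_value(
    assignment: dict[str, int | str],
    model: FullModel,
    environment: int | None = None,
    include_epistasis_gxe: bool = True,
) -> float:
    """Predicted genetic value of a complete multilocus genotype.

    Sums main effects, epistatic effects and — when ``environment`` is
    given — the predicted GxE effects for that environment, each times its
    coefficient.  mu is excluded (pure genetic value).
    """
    geno = {q: _coerce_genotype(g) for q, g in assignment.items()}
    missing = [q for q in model.qts_ids if q not in geno]
    if missing:
        raise ValueError(f"incomplete assignment; missing {missing}")
    if environment is not None and model.environments and environment not in model.environments:
        raise ValueError(f"unknown environment {environment}")

    def coeff(term: str, cls: str) -> float:
        if "&" in term:
            qi, qj = term.split("&")
            xai, xdi = genotype_coefficients(geno[qi])
            xaj, xdj = genotype_coefficients(geno[qj])
            return {
                "aa": xai * xaj, "ad": xai * xdj, "da": xdi * xaj, "dd": xdi * xdj,
            }[cls]
        xa, xd = genotype_coefficients(geno[term])
        return xa if cls == "a" else xd

    value = 0.0
    for _i, row in model.effects.iterrows():
        value += float(row["estimate"]) * coeff(str(row["term"]), row["effect_type"])
    if environment is not None and len(model.gxe):
        sub = model.gxe[model.gxe["env"] == environment]
        for _i, row in sub.iterrows():
            cls = row["effect_type"]
            parent = GXE_PARENT[cls]
            if not include_epistasis_gxe and len(parent) == 2:
                continue
            value += float(row["estimate"]) * coeff(str(row["term"]), parent)
    return float(value)


def _component_value(model, geno, loci_set, environment, include_epistasis_gxe) -> float:
    """Genetic value restricted to effects whose loci are all in loci_set."""

    def coeff(term, cls):
        if "&" in term:
            qi, qj = term.split("&")
            xai, xdi = genotype_coefficients(geno[qi])
            xaj, xdj = genotype_coefficients(geno[qj])
            return {"aa": xai * xaj, "ad": xai * xdj, "da": xdi * xaj, "dd": xdi * xdj}[cls]
        xa, xd = genotype_coefficients(geno[term])
        return xa if cls == "a" else xd

    value = 0.0
    for _i, row in model.effects.iterrows():
        term = str(row["term"])
        members = term.split("&")
        if all(m in loci_set for m in members):
            value += float(row["estimate"]) * coeff(term, row["effect_type"])
    if environment is not None and len(model.gxe):
        for _i, row in model.gxe[model.gxe["env"] == environment].iterrows():
            term = str(row["term"])
            members = term.split("&")
            parent = GXE_PARENT[row["effect_type"]]
            if not include_epistasis_gxe and len(parent) == 2:
                continue
            if all(m in loci_set for m in members):
                value += float(row["estimate"]) * coeff(term, parent)
    return value


def design_superior(
    model: FullModel, target: DesignTarget, include_epistasis_gxe: bool = True
) -> DesignResult:
    """Exact optimum genotype over the target's allowed per-locus space.

    Ties break lexicographically (QQ < Qq < qq, locus order by QTS id).
    Refuses epistasis components larger than ``MAX_COMPONENT`` loci.
    """
    qts = model.qts_ids
    if not qts:
        raise ValueError("model holds no QTSs")
    graph = nx.Graph()
    graph.add_nodes_from(qts)
    graph.add_edges_from(model.epistatic_pairs())

    allowed = [g for g in _GENO_ORDER if g in target.allowed_genotypes]
    env = target.environment
    sign = 1.0 if target.objective == "max" else -1.0

    assignment: dict[str, int] = {}
    for comp in nx.connected_components(graph):
        loci = sorted(comp)
        if len(loci) > MAX_COMPONENT:
            raise ValueError(
                f"epistasis component with {len(loci)} loci exceeds {MAX_COMPONENT}; "
                "split the model or solve this component externally"
            )
        best, best_val = None, -np.inf
        for combo in product(allowed, repeat=len(loci)):
            geno = dict(zip(loci, combo))
            val = sign * _component_value(model, geno, set(loci), env, include_epistasis_gxe)
            if val > best_val:
                best, best_val = geno, val
        assignment.update(best)

    value = genetic_value(assignment, model, env, include_epistasis_gxe)
    labels = {q: allele_pair_label(model, q, g) for q, g in assignment.items()}
    per_env = {
        h: genetic_value(assignment, model, h, include_epistasis_gxe)
        for h in model.environments
    }
    return DesignResult(
        target=target,
        assignment=assignment,
        value=value,
        genotype_labels=labels,
        per_env_values=per_env,
    )


def allele_pair_label(model: FullModel, qts: str, genotype: int) -> str:
    """Allele-pair label ("AA", "AG", ...) using major/minor metadata.

    Falls back to QQ/Qq/qq when the model has no allele letters for the
    locus.
    """
    alleles = model.qts_alleles.get(qts)
    if alleles is None:
        return _GENO_NAME[genotype]
    maj, mino = alleles
    return {2: maj + maj, 1: maj + mino, 0: mino + mino}[genotype]


def pleiotropy_conflict_report(
    models: dict[str, FullModel], targets: dict[str, DesignTarget]
) -> pd.DataFrame:
    """Per-trait optimal genotypes at shared QTSs, with conflict flags.

    For every QTS appearing in at least two trait models, lists each
    trait's optimal genotype (from that trait's design) and flags the QTS
    when the optima disagree.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 traits")
    designs = {t: design_superior(m, targets[t]) for t, m in models.items()}
    qts_traits: dict[str, list[str]] = {}
    for t, m in models.items():
        for q in m.qts_ids:
            qts_traits.setdefault(q, []).append(t)
    rows = []
    for q, ts in sorted(qts_traits.items()):
        if len(ts) < 2:
            continue
        genos = {t: designs[t].assignment[q] for t in ts}
        conflict = len(set(genos.values())) > 1
        for t in ts:
            rows.append(
                {
                    "qts": q,
                    "trait": t,
                    "genotype": _GENO_NAME[genos[t]],
                    "label": designs[t].genotype_labels[q],
                    "conflict": conflict,
                }
            )
    return pd.DataFrame(rows, columns=["qts", "trait", "genotype", "label", "conflict"])
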