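"""End-to-end orchestration: QC -> GMDR screen -> scans -> permutation
thresholds -> full-model fit -> heritability -> superior-genotype design ->
reports.

Each trait is analyzed separately (multi-trait runs loop over traits with
shared genotypes).  Every stage logs its funnel counts, the run manifest
records inputs, seeds and stage summaries, and stage outputs are written as
TSV/JSON so a run can be inspected or resumed per stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coding import code_genotypes
from .design import DesignResult, DesignTarget, design_superior
from .gmdr import ScreenConfig, screen_snps
from .heritability import HeritabilityReport
from .model import FullModel, fit_full_model, model_heritability, permutation_threshold, scan_1d_all, scan_2d_all
from .panel import GenotypePanel, read_phenotypes
from .qc import QCConfig, apply_snp_filters

logger = logging.getLogger(__name__)


@dataclass
class ScanSettings:
    n_perm: int = 1000
    alpha: float = 0.05
    n_iter: int = 20_000
    burn_in: int = 2_000
    max_pair_candidates: int = 15  # 2-D scan runs over pairs of the top-m 1-D loci


@dataclass
class PipelineConfig:
    genotypes: str
    phenotypes: str
    out_dir: str
    traits: list[str] | None = None
    seed: int = 0
    qc: QCConfig = field(default_factory=QCConfig)
    screen: ScreenConfig | None = None
    scan: ScanSettings = field(default_factory=ScanSettings)
    designs: list[DesignTarget] = field(
        default_factory=lambda: [
            DesignTarget("GSL", "max"),
            DesignTarget("GSH", "max"),
        ]
    )

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("genotypes", "phenotypes"):
            if key in raw and not Path(raw[key]).exists():
                raise FileNotFoundError(f"{key} file not found: {raw[key]}")
        kwargs = dict(raw)
        if "qc" in raw:
            kwargs["qc"] = QCConfig(**raw["qc"])
        if "screen" in raw and raw["screen"] is not None:
            kwargs["screen"] = ScreenConfig(**raw["screen"])
        if "scan" in raw:
            kwargs["scan"] = ScanSettings(**raw["scan"])
        if "designs" in raw:
            kwargs["designs"] = [DesignTarget(**d) for d in raw["designs"]]
        return cls(**kwargs)


def _load_panel(path: str) -> GenotypePanel:
    if str(path).endswith(".vcf"):
        return GenotypePanel.from_vcf(path)
    return GenotypePanel.from_tsv(path)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    manifest["inputs"] = {"genotypes": str(config.genotypes), "phenotypes": str(config.phenotypes)}

    if not Path(config.phenotypes).exists():
        raise FileNotFoundError(f"phenotype file not found: {config.phenotypes}")
    if not Path(config.genotypes).exists():
        raise FileNotFoundError(f"genotype file not found: {config.genotypes}")

    panel = _load_panel(config.genotypes)
    pheno = read_phenotypes(config.phenotypes)
    traits = config.traits or sorted(pheno["trait"].unique())

    try:
        panel, report = apply_snp_filters(panel, config.qc)
        report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    except Exception as e:
        raise StageError("qc", e) from e
    manifest["stages"]["qc"] = {"snps_after_qc": panel.n_snps}

    for trait in traits:
        _run_trait(config, panel, pheno, trait, out, manifest)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _run_trait(config, panel, pheno, trait, out: Path, manifest: dict) -> None:
    tdir = out / trait
    tdir.mkdir(exist_ok=True)
    seed = config.seed
    scan_cfg = config.scan
    summary: dict = {}

    try:
        # ---- GMDR screen --------------------------------------------------
        if config.screen is not None:
            cand = screen_snps(panel, pheno, config.screen, trait=trait)
            cand.support.to_csv(tdir / "gmdr_support.tsv", sep="\t", index=False)
            work = panel.take_snps(sorted(panel.snp_index(s) for s in cand.retained))
            summary["screened_snps"] = work.n_snps
        else:
            work = panel
            summary["screened_snps"] = panel.n_snps

        coded = code_genotypes(work)

        # ---- 1-D scan + threshold ----------------------------------------
        res1 = scan_1d_all(coded, pheno, trait=trait)
        thr1 = permutation_threshold(
            coded, pheno, family="1d", n_perm=scan_cfg.n_perm,
            alpha=scan_cfg.alpha, seed=seed, trait=trait,
        )
        res1["significant"] = res1["statistic"] > thr1
        res1.to_csv(tdir / "scan_1d.tsv", sep="\t", index=False)
        sig1 = res1.index[res1["significant"]].tolist()
        summary["scan_1d"] = {"threshold": thr1, "significant": len(sig1)}

        # ---- 2-D scan over candidate pairs -------------------------------
        top = res1.sort_values("statistic", ascending=False).index[
            : scan_cfg.max_pair_candidates
        ]
        pairs = [(int(i), int(j)) for k, i in enumerate(top) for j in top[k + 1 :]]
        sig_pairs: list[tuple[int, int]] = []
        if pairs:
            res2 = scan_2d_all(coded, pheno, pairs, trait=trait)
            thr2 = permutation_threshold(
                coded, pheno, family="2d", pairs=pairs, n_perm=scan_cfg.n_perm,
                alpha=scan_cfg.alpha, seed=seed + 1, trait=trait,
            )
            res2["significant"] = res2["statistic"] > thr2
            res2.to_csv(tdir / "scan_2d.tsv", sep="\t", index=False)
            sig_pairs = [
                (work.snp_index(r["snp_i"]), work.snp_index(r["snp_j"]))
                for _x, r in res2[res2["significant"]].iterrows()
            ]
            summary["scan_2d"] = {"threshold": thr2, "significant": len(sig_pairs)}

        # ---- full model ---------------------------------------------------
        qts = sorted(set(sig1) | {k for p in sig_pairs for k in p})
        alleles = {}
        if "major" in work.snps.columns and "minor" in work.snps.columns:
            for k in qts:
                alleles[work.snp_ids[k]] = (
                    str(work.snps["major"].iloc[k]),
                    str(work.snps["minor"].iloc[k]),
                )
        model = fit_full_model(
            coded, pheno, qts=qts, pairs=sig_pairs, n_iter=scan_cfg.n_iter,
            burn_in=scan_cfg.burn_in, seed=seed, trait=trait, qts_alleles=alleles,
        )
        summary["full_model"] = {
            "n_qts": len(qts), "n_pairs": len(sig_pairs),
            "rhat_max": model.diagnostics.get("rhat_max"),
        }

        herit = model_heritability(model, coded) if len(model.effects) else None
        designs = {}
        if model.qts_ids:
            for target in config.designs:
                name = target.mode + ("" if target.environment is None else str(target.environment))
                designs[name] = design_superior(model, target)
        write_reports(model, herit, designs, tdir, trait=trait)
        summary["designs"] = {k: d.value for k, d in designs.items()}
    except StageError:
        raise
    except Exception as e:
        raise StageError(trait, e) from e
    manifest["stages"][trait] = summary


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

_EFFECT_COLUMNS = ["trait", "qts", "effect_type", "estimate", "neglog10p", "h2", "significant_label"]


def write_reports(
    model: FullModel,
    herit: HeritabilityReport | None,
    designs: dict[str, DesignResult],
    out_dir,
    trait: str = "trait",
) -> dict[str, str]:
    """Write effect, heritability, design and network reports.

    Produces ``effects.tsv`` (Table 2/3 layout: effect type, predicted
    effect, -log10 p, h2, with the conventional -log10 p > 7 label),
    ``heritability.tsv`` (Table 1 layout: class aggregates + h2_T),
    ``design.tsv`` (Table 5 layout: one row per QTS, one column per design)
    and the epistasis network as ``network_edges.tsv``/``network.json``.
    Empty models yield headers-only files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    # effects table (fixed effects + per-environment GxE rows)
    h2map = {}
    if herit is not None:
        for _i, r in herit.per_effect.iterrows():
            h2map[(r["term"], r["effect_type"])] = r["h2"]
    rows = []
    for _i, r in model.effects.iterrows():
        rows.append(
            {
                "trait": trait,
                "qts": r["term"],
                "effect_type": r["effect_type"],
                "estimate": r["estimate"],
                "neglog10p": r["neglog10p"],
                "h2": h2map.get((r["term"], r["effect_type"]), np.nan),
                "significant_label": bool(
                    pd.notna(r["neglog10p"]) and r["neglog10p"] > 7
                ),
            }
        )
    for _i, r in model.gxe.iterrows():
        et = f"{r['effect_type']}{int(r['env'])}" if r["env"] else r["effect_type"]
        rows.append(
            {
                "trait": trait,
                "qts": r["term"],
                "effect_type": et,
                "estimate": r["estimate"],
                "neglog10p": np.nan,
                "h2": h2map.get((r["term"], r["effect_type"]), np.nan),
                "significant_label": False,
            }
        )
    eff = pd.DataFrame(rows, columns=_EFFECT_COLUMNS)
    eff.to_csv(out / "effects.tsv", sep="\t", index=False)
    files["effects"] = str(out / "effects.tsv")

    # heritability aggregates
    if herit is not None:
        agg = herit.to_row()
        hrow = pd.DataFrame([{"trait": trait, **agg}])
    else:
        hrow = pd.DataFrame(columns=["trait"])
    hrow.to_csv(out / "heritability.tsv", sep="\t", index=False)
    files["heritability"] = str(out / "heritability.tsv")

    # design table: one row per QTS, one column per design
    drows = []
    for q in model.qts_ids:
        row = {"qts": q, "trait": trait}
        for name, res in designs.items():
            row[name] = res.genotype_labels.get(q, "")
        drows.append(row)
    ddf = pd.DataFrame(drows, columns=["qts", "trait", *designs.keys()])
    if designs:
        vals = {"qts": "_value", "trait": trait}
        vals.update({name: res.value for name, res in designs.items()})
        ddf = pd.concat([ddf, pd.DataFrame([vals])], ignore_index=True)
    ddf.to_csv(out / "design.tsv", sep="\t", index=False)
    files["design"] = str(out / "design.tsv")

    # epistasis network
    nodes, edges = network_export(model)
    edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    with open(out / "network.json", "w") as fh:
        json.dump(
            {
                "nodes": nodes.to_dict(orient="records"),
                "edges": edges.to_dict(orient="records"),
            },
            fh,
            indent=2,
        )
    files["network"] = str(out / "network_edges.tsv")
    return files


def network_export(model: FullModel) -> tuple[pd.DataFrame, pd.DataFrame]:
    """QTS network: nodes with effect-class flags, edges for epistatic pairs."""
    has = lambda term, cls: bool(  # noqa: E731
        ((model.effects["term"] == term) & (model.effects["effect_type"] == cls)).any()
    )
    has_gxe = lambda term, cls: bool(  # noqa: E731
        len(model.gxe)
        and ((model.gxe["term"] == term) & (model.gxe["effect_type"] == cls)).any()
    )
    nodes = pd.DataFrame(
        [
            {
                "qts": q,
                "additive": has(q, "a"),
                "dominance": has(q, "d"),
                "additive_env": has_gxe(q, "ae"),
                "dominance_env": has_gxe(q, "de"),
            }
            for q in model.qts_ids
        ],
        columns=["qts", "additive", "dominance", "additive_env", "dominance_env"],
    )
    erows = []
    for qi, qj in model.epistatic_pairs():
        term = f"{qi}&{qj}"
        classes = model.effects[model.effects["term"] == term]["effect_type"].tolist()
        gxe_classes = (
            model.gxe[model.gxe["term"] == term]["effect_type"].unique().tolist()
            if len(model.gxe)
            else []
        )
        erows.append(
            {
                "qts_i": qi,
                "qts_j": qj,
                "classes": ",".join(classes),
                "gxe": ",".join(gxe_classes),
            }
        )
    edges = pd.DataFrame(erows, columns=["qts_i", "qts_j", "classes", "gxe"])
    return nodes, edges
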