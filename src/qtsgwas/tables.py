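"""Loaders for the packaged reference tables of the cottonseed study.

Three plain-text fixtures ship with the package:

* ``table1_heritability.tsv`` — per-trait heritability class aggregates
  (h2_A ... h2_ADE) and the total broad-sense heritability h2_T for the
  seven cottonseed traits (protein, oil, five fatty acids);
* ``table2_effects.tsv`` — per-effect estimates (effect, -log10 p, h2) for
  the protein and oil contents;
* ``table3_effects.tsv`` — per-effect estimates for the five fatty acids.

These encode published summary tables and are used as inputs to the
aggregation identities (class sums, pair totals, row-sum checks) and to
fixture-driven report tests; they are not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_CLASS_COLUMNS = [
    "h2_A", "h2_D", "h2_AA", "h2_AD", "h2_DA", "h2_DD",
    "h2_AE", "h2_DE", "h2_AAE", "h2_ADE",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("qtsgwas.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_table1() -> pd.DataFrame:
    """Per-trait heritability aggregates; one row per trait."""
    return _read("table1_heritability.tsv")


def load_table2() -> pd.DataFrame:
    """Per-effect table for protein and oil."""
    return _read("table2_effects.tsv")


def load_table3() -> pd.DataFrame:
    """Per-effect table for the five fatty acids."""
    return _read("table3_effects.tsv")


def load_effect_tables() -> pd.DataFrame:
    """Concatenated per-effect tables for all seven traits."""
    return pd.concat([load_table2(), load_table3()], ignore_index=True)


def table1_class_columns() -> list[str]:
    return list(_CLASS_COLUMNS)


def qts_total_heritability(effects: pd.DataFrame, trait: str, qts_ids: list[str]) -> float:
    """Sum of all h2 entries involving any of the given QTSs for a trait.

    An epistatic entry (pair id ``"i&j"``) counts if either member is in
    ``qts_ids``; each table row counts once.
    """
    sub = effects[effects["trait"] == trait]
    total = 0.0
    for _, row in sub.iterrows():
        members = str(row["qts"]).split("&")
        if any(m in qts_ids for m in members) and pd.notna(row["h2"]):
            total += float(row["h2"])
    return total
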