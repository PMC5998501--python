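"""Heritability partition for the full QTS model.

Each significant effect contributes a slice of the phenotypic variance:

* a fixed genetic effect with estimate ``b`` and coefficient column ``c``
  (over accessions) contributes ``b^2 * Var(c)``;
* a random GxE component with variance ``s2`` and coefficient column ``c``
  contributes ``s2 * mean(c^2)`` (its design column is ``c`` expanded over
  environments, so the marginal phenotypic variance it injects scales with
  the second moment of ``c``).

Heritability is the contribution divided by the phenotypic variance ``V_P``
of environment-centered phenotypes, in percent.  Class aggregates (h2_A,
h2_D, the four epistasis classes, the six GxE classes) are sums of their
member effects, and the total broad-sense heritability h2_T is the sum of
the class aggregates, so the partition is additive by construction.
Covariances between non-orthogonal coefficient columns are ignored in this
marginal decomposition; see :func:`joint_genetic_variance` for the joint
alternative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: recognized effect classes, in report order
CLASS_ORDER = ["a", "d", "aa", "ad", "da", "dd", "ae", "de", "aae", "ade", "dae", "dde"]

_AGG_LABEL = {c: "h2_" + c.upper() for c in CLASS_ORDER}

_ENV_SUFFIX = re.compile(r"^(a|d|aa|ad|da|dd)e(\d*)$")


def normalize_class(effect_type: str) -> str:
    """Map an effect-type label to its base class.

    Environment-specific labels such as ``ae1`` or ``dde3`` collapse to their
    class (``ae``, ``dde``).  Unknown labels raise ``ValueError``.
    """
    et = effect_type.strip().lower()
    if et in CLASS_ORDER:
        return et
    m = _ENV_SUFFIX.match(et)
    if m:
        return m.group(1) + "e"
    raise ValueError(f"unknown effect class {effect_type!r}")


def effect_heritability(value: float, column: np.ndarray, v_p: float, kind: str = "fixed") -> float:
    """Percent heritability of a single effect.

    Parameters
    ----------
    value
        Effect estimate (fixed effects) or variance component (``kind=
        "variance"``).
    column
        Coefficient column over accessions (NaN entries ignored).
    v_p
        Phenotypic variance of environment-centered phenotypes; must be > 0.
    kind
        ``"fixed"`` for genetic main/epistatic effects, ``"variance"`` for
        random GxE components.
    """
    if v_p <= 0:
        raise ValueError("V_P must be positive")
    column = np.asarray(column, dtype=float)
    if kind == "fixed":
        contrib = value**2 * np.nanvar(column)
    elif kind == "variance":
        if value < 0:
            raise ValueError("variance component must be >= 0")
        contrib = value * np.nanmean(column**2)
    else:
        raise ValueError("kind must be 'fixed' or 'variance'")
    return 100.0 * contrib / v_p


def aggregate_heritability(per_effect: pd.DataFrame) -> tuple[dict[str, float], float]:
    """Class aggregates and total from a per-effect table.

    ``per_effect`` needs columns ``effect_type`` (or ``cls``) and ``h2``.
    Returns ``(aggregates, h2_T)`` where ``aggregates`` maps ``h2_A`` ...
    ``h2_DDE`` to the sum of member effects (classes with no members are 0).
    """
    col = "effect_type" if "effect_type" in per_effect.columns else "cls"
    totals = {label: 0.0 for label in _AGG_LABEL.values()}
    for et, h2 in zip(per_effect[col], per_effect["h2"]):
        if pd.isna(h2):
            continue
        totals[_AGG_LABEL[normalize_class(str(et))]] += float(h2)
    h2_t = float(sum(totals.values()))
    return totals, h2_t


@dataclass
class HeritabilityReport:
    """Per-effect heritabilities plus derived class aggregates.

    ``per_effect`` columns: ``term`` (QTS id or "i&j" pair id),
    ``effect_type``, ``h2`` (percent).
    """

    per_effect: pd.DataFrame
    v_p: float | None = None

    def class_totals(self) -> dict[str, float]:
        return aggregate_heritability(self.per_effect)[0]

    @property
    def h2_total(self) -> float:
        return aggregate_heritability(self.per_effect)[1]

    def to_row(self) -> dict[str, float]:
        """Single summary row: class aggregates + h2_T."""
        row = self.class_totals()
        row["h2_T"] = self.h2_total
        return row

    def to_tsv(self, path) -> None:
        self.per_effect.to_csv(path, sep="\t", index=False)


def joint_genetic_variance(effects: list[tuple[float, np.ndarray]]) -> float:
    """Variance of the summed fixed-effect predictor, covariances included.

    ``effects`` is a list of (estimate, coefficient column) pairs.  This is
    the joint counterpart to the marginal per-effect decomposition; the two
    differ when coefficient columns are correlated.
    """
    if not effects:
        return 0.0
    total = np.zeros_like(np.asarray(effects[0][1], dtype=float))
    for value, col in effects:
        total = total + value * np.asarray(col, dtype=float)
    return float(np.nanvar(total))


def genotypic_correlation(model_a, model_b, panel) -> float:
    """Genotypic correlation r_g between two fitted trait models.

    Pearson correlation across accessions of the total predicted genetic
    values (main + epistatic effects; no environment or GxE terms).  Both
    models must be defined on the same panel.
    """
    ga = np.asarray(model_a.genetic_values(panel), dtype=float)
    gb = np.asarray(model_b.genetic_values(panel), dtype=float)
    if np.var(ga) == 0 or np.var(gb) == 0:
        raise ValueError("zero genetic variance in one of the traits")
    return float(np.corrcoef(ga, gb)[0, 1])
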