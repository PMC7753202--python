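"""Per-assay quantification and genotype-vs-control comparisons.

The unit of analysis throughout is the biological replicate (one vial or
plate), not the individual fly. Genotypes are compared with their
background-matched control using an unpaired, pooled-variance (equal
variances assumed) two-sample Student t test with two-sided p-values.
"""

from __future__ import annotations

import logging
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CafeResult",
    "TTestResult",
    "cafe_consumption",
    "fif_percentage",
    "larval_fraction",
    "normalise_per_fly",
    "student_t_test",
    "pooled_t_arrays",
    "compare_to_control",
]


class CafeResult(NamedTuple):
    """Evaporation-corrected per-fly consumption with a QC flag."""

    value: float  # µl/fly/24h
    flagged: bool  # True when the corrected consumption is negative


class TTestResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def cafe_consumption(
    capillary_volumes: Sequence[float],
    evaporation: float,
    n_flies: int = 8,
    duration_h: float = 24.0,
) -> CafeResult:
    """Per-fly food consumption from one CAFE vial.

    Sums the volume drawn from each capillary, subtracts the evaporation
    measured in a fly-free vial from each, rescales to a 24 h window and
    divides by the number of flies. Negative corrected values (evaporation
    exceeding the measured displacement) are retained — clipping would
    bias vial means upward — but the vial is flagged for QC.
    """
    if n_flies < 1:
        raise ValidationError("n_flies must be >= 1")
    if len(capillary_volumes) < 1:
        raise ValidationError("at least one capillary is required")
    if evaporation < 0:
        raise ValidationError("evaporation must be >= 0")
    if duration_h <= 0:
        raise ValidationError("duration must be > 0")
    consumed = float(np.sum(np.asarray(capillary_volumes, dtype=float) - evaporation))
    value = consumed * (24.0 / duration_h) / n_flies
    return CafeResult(value, value < 0)


def fif_percentage(dyed: int, total: int) -> float:
    """Percentage of flies in a vial with dye visible in the abdomen."""
    if total < 1:
        raise ValidationError("total must be >= 1")
    if not 0 <= dyed <= total:
        raise ValidationError("dyed count must lie in [0, total]")
    return 100.0 * dyed / total


def larval_fraction(in_food: int, total: int) -> float:
    """Percentage of larvae found in the food after 20 min (one plate)."""
    return fif_percentage(in_food, total)


def normalise_per_fly(total_quantity: float, n_flies: int) -> float:
    """Per-fly quantity from a group measurement (mass, triglyceride)."""
    if n_flies < 1:
        raise ValidationError("n_flies must be >= 1")
    return total_quantity / n_flies


def pooled_t_arrays(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, int, np.ndarray]:
    """Vectorised pooled-variance two-sample t along the last axis.

    Degenerate rule for zero pooled variance: p = 1 when the means are
    equal, p = 0 otherwise (with t = 0 / ±inf respectively).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.shape[-1], b.shape[-1]
    df = n1 + n2 - 2
    mean_a, mean_b = a.mean(-1), b.mean(-1)
    var_a, var_b = a.var(-1, ddof=1), b.var(-1, ddof=1)
    pooled = ((n1 - 1) * var_a + (n2 - 1) * var_b) / df
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero = se == 0
    if np.any(zero):
        diff = mean_a - mean_b
        sign_inf = np.where(diff > 0, np.inf, -np.inf)
        t = np.where(zero, np.where(diff == 0, 0.0, sign_inf), t)
        p = np.where(zero, np.where(diff == 0, 1.0, 0.0), p)
    return t, df, p


def student_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Unpaired homoscedastic two-sample Student t test, two-sided.

    Uses the pooled variance estimate with ``df = n1 + n2 - 2``. Each
    group must contain at least two finite values.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("groups must contain finite values only")
    t, df, p = pooled_t_arrays(a, b)
    return TTestResult(float(t), int(df), float(p))


def compare_to_control(
    replicates: pd.DataFrame, control_map: Mapping[str, str]
) -> pd.DataFrame:
    """Compare every mapped genotype with its background control per assay.

    Parameters
    ----------
    replicates
        Tidy replicate table with columns ``genotype, assay, replicate,
        value`` (``n_flies`` optional).
    control_map
        genotype -> background-control genotype id; the control must have
        replicates in the table.

    Returns one row per genotype x assay with columns ``genotype, assay,
    control, mean_ratio, t_statistic, p_value, df``. An assay missing for
    either member of a pair is omitted and logged; a missing control
    genotype raises, naming the genotype it backs.
    """
    required = {"genotype", "assay", "replicate", "value"}
    if not required.issubset(replicates.columns):
        raise ValidationError(f"replicate table must have columns {sorted(required)}")
    wide = replicates.pivot(
        index=["genotype", "assay"], columns="replicate", values="value"
    )
    present = wide.index
    genotypes_present = present.get_level_values(0).unique()
    assays_by_genotype: dict[str, list[str]] = {}
    for g, assay in present:
        assays_by_genotype.setdefault(g, []).append(assay)

    pairs: list[tuple[str, str, str]] = []
    for genotype in sorted(control_map):
        if genotype not in assays_by_genotype:
            continue
        control = control_map[genotype]
        if control not in assays_by_genotype:
            raise ValidationError(
                f"control {control!r} for genotype {genotype!r} has no replicates"
            )
        control_assays = set(assays_by_genotype[control])
        for assay in assays_by_genotype[genotype]:
            if assay not in control_assays:
                logger.info(
                    "assay %s missing for control %s; comparison with %s omitted",
                    assay, control, genotype,
                )
                continue
            pairs.append((genotype, assay, control))
    if not pairs:
        return pd.DataFrame(
            columns=["genotype", "assay", "control", "mean_ratio",
                     "t_statistic", "p_value", "df"]
        )

    geno_idx = [(g, a) for g, a, _ in pairs]
    ctrl_idx = [(c, a) for _, a, c in pairs]
    a_vals = wide.loc[geno_idx].to_numpy()
    b_vals = wide.loc[ctrl_idx].to_numpy()
    ragged = np.isnan(a_vals).any() or np.isnan(b_vals).any()
    rows = []
    if not ragged:
        t, df, p = pooled_t_arrays(a_vals, b_vals)
        mean_a, mean_b = a_vals.mean(1), b_vals.mean(1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = mean_a / mean_b
        for k, (g, assay, c) in enumerate(pairs):
            rows.append((g, assay, c, ratio[k], t[k], p[k], df))
    else:  # unequal replicate counts: drop the padding NaNs pair by pair
        for k, (g, assay, c) in enumerate(pairs):
            a = a_vals[k][~np.isnan(a_vals[k])]
            b = b_vals[k][~np.isnan(b_vals[k])]
            res = student_t_test(a, b)
            rows.append((g, assay, c, a.mean() / b.mean(),
                         res.statistic, res.pvalue, res.df))
    return pd.DataFrame(
        rows,
        columns=["genotype", "assay", "control", "mean_ratio",
                 "t_statistic", "p_value", "df"],
    )
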