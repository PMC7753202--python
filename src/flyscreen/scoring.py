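"""Integrated phenotype score, hit classification, and its calibration.

The score for one gene is ``1 - (p_cafe + p_fif + p_mass)``, where the
three p-values come from comparing the gene's neuronal knockdown with its
background-matched control in the three adult assays. More significant
results therefore push the score towards 1; the score lives in (-2, 1].
A gene is a *hit* at score >= 0.80 and merits *consideration* at
score >= 0.70; both boundaries are inclusive and applied to the unrounded
score (rounding to 2 decimals is display-only).

Because only p-values enter, the score is direction-agnostic: a gene whose
knockdown halves food intake scores the same as one that doubles it. This
is deliberate — the screen flags any perturbation of energy homeostasis.

Under the global null with continuous data the three p-values are
independent Uniform(0, 1), so P(score >= 0.8) = P(p1 + p2 + p3 <= 0.2) =
0.2**3 / 6 ~= 1.33e-3 (the volume of the corner simplex). The Monte-Carlo
calibration utilities below recompute that probability — and the screen's
power against planted effects — through the full simulate -> t-test ->
score path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .assays import compare_to_control, student_t_test
from .config import SCORE_ASSAYS, SyntheticConfig, ValidationError
from .synthetic import generate_assay_table

__all__ = [
    "ControlPanel",
    "ControlValidation",
    "MonteCarloRate",
    "integrated_score",
    "classify_gene",
    "score_genes",
    "validate_controls",
    "null_hit_rate",
    "power_at_effect",
]

THRESHOLD_HIT = 0.80
THRESHOLD_CONSIDER = 0.70


@dataclass(frozen=True)
class ControlPanel:
    """Positive/negative control gene sets and the hit thresholds."""

    positive: frozenset[str]
    negative: frozenset[str]
    threshold_hit: float = THRESHOLD_HIT
    threshold_consider: float = THRESHOLD_CONSIDER

    def __post_init__(self) -> None:
        object.__setattr__(self, "positive", frozenset(self.positive))
        object.__setattr__(self, "negative", frozenset(self.negative))
        overlap = self.positive & self.negative
        if overlap:
            raise ValidationError(
                f"control panels overlap: {sorted(overlap)}"
            )
        if not 0 < self.threshold_consider <= self.threshold_hit <= 1:
            raise ValidationError(
                "thresholds must satisfy 0 < consider <= hit <= 1"
            )


class ControlValidation(NamedTuple):
    """Separation of positive from negative control scores."""

    separation_t: float
    separation_p: float
    df: int
    n_positive: int
    n_negative: int
    mean_positive: float
    mean_negative: float
    #: closed interval of thresholds (evaluated at observed score cut
    #: points) that minimise panel misclassification
    threshold_range: tuple[float, float]


class MonteCarloRate(NamedTuple):
    """A simulated hit probability with a binomial (Wilson) 95% CI."""

    estimate: float
    ci_low: float
    ci_high: float
    n_hits: int
    n_genes: int


def integrated_score(p_cafe: float, p_fif: float, p_mass: float) -> float:
    """``1 - (p_cafe + p_fif + p_mass)``; strictly decreasing in each p."""
    for name, p in (("p_cafe", p_cafe), ("p_fif", p_fif), ("p_mass", p_mass)):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"{name}={p} outside [0, 1]")
    return 1.0 - (p_cafe + p_fif + p_mass)


def classify_gene(
    score: float,
    threshold_hit: float = THRESHOLD_HIT,
    threshold_consider: float = THRESHOLD_CONSIDER,
) -> str:
    """``hit`` / ``consider`` / ``negative`` with inclusive boundaries."""
    if not 0 < threshold_consider <= threshold_hit <= 1:
        raise ValidationError("thresholds must satisfy 0 < consider <= hit <= 1")
    if score >= threshold_hit:
        return "hit"
    if score >= threshold_consider:
        return "consider"
    return "negative"


def score_genes(
    comparisons: pd.DataFrame,
    mass_source: str = "mass",
    threshold_hit: float = THRESHOLD_HIT,
    threshold_consider: float = THRESHOLD_CONSIDER,
) -> pd.DataFrame:
    """Score every genotype from its per-assay comparison p-values.

    ``mass_source`` selects the third p-value: ``"mass"``/``"wet_mass"``
    for wet mass or ``"tag"`` to use triglyceride instead (mass is a
    validated proxy for TAG, so either completes the trio). Genes missing
    any of the three assays are *not* scored — no p-value is imputed —
    and carry classification ``unscored`` with NaN score.

    Returns columns ``gene, p_cafe, p_fif, p_mass, score, classification``
    (``p_mass`` holds the configured third p-value).
    """
    aliases = {"mass": "mass", "wet_mass": "mass", "tag": "tag"}
    if mass_source not in aliases:
        raise ValidationError(f"mass_source must be one of {sorted(aliases)}")
    third = aliases[mass_source]
    needed = ("cafe", "fif", third)
    p = comparisons.pivot(index="genotype", columns="assay", values="p_value")
    rows = []
    for gene, row in p.iterrows():
        ps = [row.get(a, np.nan) for a in needed]
        if any(pd.isna(v) for v in ps):
            rows.append((gene, *ps, np.nan, "unscored"))
            continue
        score = integrated_score(*ps)
        rows.append(
            (gene, *ps, score, classify_gene(score, threshold_hit, threshold_consider))
        )
    return pd.DataFrame(
        rows, columns=["gene", "p_cafe", "p_fif", "p_mass", "score", "classification"]
    )


def _overlap_minimising_range(
    positive: np.ndarray, negative: np.ndarray
) -> tuple[float, float]:
    """Range of thresholds minimising panel misclassification.

    A threshold t classifies score >= t as positive. Candidate cut points
    are the observed scores (plus one point above the maximum); the
    returned (lo, hi) are the extreme candidates attaining the minimum
    error count.
    """
    cuts = np.unique(np.concatenate([positive, negative]))
    cand = np.append(cuts, cuts[-1] + 1.0)
    errors = [
        int((negative >= c).sum() + (positive < c).sum()) for c in cand
    ]
    best = min(errors)
    winners = [c for c, e in zip(cand, errors) if e == best]
    return (float(winners[0]), float(winners[-1]))


def validate_controls(
    scores: pd.DataFrame, panel: ControlPanel
) -> ControlValidation:
    """Test whether positive controls out-score negative controls.

    Runs the screen's pooled-variance t test on the two score vectors and
    reports the threshold range that minimises overlap between the panels.
    Requires at least two scored genes in each arm.
    """
    scored = scores.dropna(subset=["score"]).set_index("gene")["score"]
    pos = scored[scored.index.isin(panel.positive)].to_numpy(dtype=float)
    neg = scored[scored.index.isin(panel.negative)].to_numpy(dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError(
            "need at least 2 scored genes in each control arm "
            f"(got {len(pos)} positive, {len(neg)} negative)"
        )
    res = student_t_test(pos, neg)
    return ControlValidation(
        separation_t=res.statistic,
        separation_p=res.pvalue,
        df=res.df,
        n_positive=len(pos),
        n_negative=len(neg),
        mean_positive=float(pos.mean()),
        mean_negative=float(neg.mean()),
        threshold_range=_overlap_minimising_range(pos, neg),
    )


def _simulated_hit_rate(
    effects: Mapping[str, float],
    config: SyntheticConfig,
    n_genes: int,
    seed: int | None,
    threshold: float,
    assays: Sequence[str],
) -> MonteCarloRate:
    """Full simulate -> compare -> score round trip for one effect vector.

    Each simulated gene gets its own background control so gene-level
    outcomes are independent and the binomial CI is exact in design.
    """
    genes = [f"sim_{i:06d}" for i in range(n_genes)]
    ctrls = [f"simctl_{i:06d}" for i in range(n_genes)]
    effect_map = {g: dict(effects) for g in genes} if effects else {}
    cfg = dataclasses.replace(
        config,
        seed=config.seed if seed is None else seed,
        effect_by_genotype=effect_map,
    )
    replicates = generate_assay_table(cfg, genes + ctrls, assays=assays)
    comparisons = compare_to_control(replicates, dict(zip(genes, ctrls)))
    scores = score_genes(comparisons)  # hits counted on the raw score below
    hits = int((scores["score"] >= threshold).sum())
    lo, hi = proportion_confint(hits, n_genes, alpha=0.05, method="wilson")
    return MonteCarloRate(hits / n_genes, float(lo), float(hi), hits, n_genes)


def null_hit_rate(
    n_genes: int,
    config: SyntheticConfig,
    seed: int | None = None,
    threshold: float = THRESHOLD_HIT,
    assays: Sequence[str] = SCORE_ASSAYS,
) -> MonteCarloRate:
    """P(a null gene scores >= ``threshold``), by full-pipeline simulation.

    With continuous assays the analytic value at threshold 0.8 is
    ``0.2**3 / 6``; the binomial FIF assay leaves this essentially
    unchanged. Requires ``n_genes >= 1000`` for a usable estimate.
    """
    if n_genes < 1000:
        raise ValidationError("n_genes must be >= 1000 for a stable null estimate")
    return _simulated_hit_rate({}, config, n_genes, seed, threshold, assays)


def power_at_effect(
    effects: Mapping[str, float],
    config: SyntheticConfig,
    n_sim: int = 500,
    seed: int | None = None,
    threshold: float = THRESHOLD_HIT,
    assays: Sequence[str] = SCORE_ASSAYS,
) -> MonteCarloRate:
    """P(a gene with multiplicative ``effects`` scores >= ``threshold``).

    ``effects`` maps assay -> multiplicative effect on the control mean;
    unlisted assays are null. Monotone non-decreasing in each effect
    magnitude. With all effects at 1.0 this reduces to the null hit rate.
    """
    if n_sim < 100:
        raise ValidationError("n_sim must be >= 100")
    unknown = set(effects) - set(assays)
    if unknown:
        raise ValidationError(f"effects name assays not simulated: {sorted(unknown)}")
    return _simulated_hit_rate(dict(effects), config, n_sim, seed, threshold, assays)
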