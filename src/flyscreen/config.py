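"""Configuration objects for the synthetic screen and its fixtures.

The screen measures each genotype in up to five assays:

``cafe``
    Capillary feeder assay; per-fly liquid-food consumption over 24 h
    (µl/fly/24 h), 8 flies per vial.
``fif``
    Fasting-induced feeding; percentage of flies per vial with dye visible
    in the abdomen after a fast–refeed cycle (15 flies per vial).
``mass``
    Wet mass per fly (mg/fly), weighed in groups of 15.
``tag``
    Triglyceride content per fly (µg/fly).
``larval``
    Percentage of third-instar larvae found in the food after 20 min
    (20 larvae per plate).

Replicate-level noise is modelled on the replicate mean (vials/plates are
the unit of analysis): continuous assays are normal with SD = CV × mean,
the two count-based assays (``fif``, ``larval``) are binomial per vial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

ASSAYS = ("cafe", "fif", "mass", "tag", "larval")
CONTINUOUS_ASSAYS = ("cafe", "mass", "tag")
BINOMIAL_ASSAYS = ("fif", "larval")

#: Adult assays feeding the integrated score (third slot switchable to tag).
SCORE_ASSAYS = ("cafe", "fif", "mass")

DEFAULT_CONTROL_MEANS: dict[str, float] = {
    "cafe": 1.2,    # µl/fly/24h, typical adult male intake of 5% sucrose/yeast
    "fif": 0.5,     # proportion of flies with dyed abdomens after a fast
    "mass": 0.8,    # mg/fly wet mass, adult male
    "tag": 10.0,    # µg/fly triglyceride
    "larval": 0.56, # proportion of fed larvae found in food after 20 min
}

#: Coefficient of variation of the replicate-level mean for continuous assays.
DEFAULT_CVS: dict[str, float] = {"cafe": 0.20, "mass": 0.08, "tag": 0.25}


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic replicate-level data generator.

    Parameters
    ----------
    seed
        Global seed. Each genotype draws from its own deterministic
        substream keyed on the genotype name, so adding or removing a
        genotype never perturbs the draws of the others.
    n_replicates
        Biological replicates (independent crosses) per genotype per assay.
    flies_per_replicate, flies_per_cafe_vial, larvae_per_plate
        Group sizes: 15 flies per sample for FIF/mass/TAG, 8 flies per
        CAFE vial, 20 larvae per plate.
    control_mean_by_assay
        Control (background) mean per assay: µl/fly/24 h for cafe,
        a proportion in [0, 1] for fif and larval, mg/fly for mass,
        µg/fly for tag.
    cv_by_assay
        Coefficient of variation of the replicate mean, continuous assays
        only; count assays get binomial noise instead.
    effect_by_genotype
        Nested mapping genotype -> assay -> multiplicative effect on the
        control mean (1.0 = null). Missing entries mean no effect.
    tag_mass_correlation
        Population correlation used when drawing paired (mass, TAG)
        measurements.
    """

    seed: int = 0
    n_replicates: int = 5
    flies_per_replicate: int = 15
    flies_per_cafe_vial: int = 8
    larvae_per_plate: int = 20
    control_mean_by_assay: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_MEANS)
    )
    cv_by_assay: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CVS))
    effect_by_genotype: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    tag_mass_correlation: float = 0.6

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        for n, label in (
            (self.flies_per_replicate, "flies_per_replicate"),
            (self.flies_per_cafe_vial, "flies_per_cafe_vial"),
            (self.larvae_per_plate, "larvae_per_plate"),
        ):
            if n < 1:
                raise ValidationError(f"{label} must be >= 1")
        for assay, mean in self.control_mean_by_assay.items():
            if assay not in ASSAYS:
                raise ValidationError(f"unknown assay {assay!r}")
            if not (mean > 0) or not math.isfinite(mean):
                raise ValidationError(f"control mean for {assay!r} must be > 0")
            if assay in BINOMIAL_ASSAYS and mean > 1:
                raise ValidationError(
                    f"control mean for {assay!r} is a proportion and must be <= 1"
                )
        for assay, cv in self.cv_by_assay.items():
            if not (cv > 0) or not math.isfinite(cv):
                raise ValidationError(f"CV for {assay!r} must be > 0")
        if not -1.0 <= self.tag_mass_correlation <= 1.0:
            raise ValidationError("tag_mass_correlation must lie in [-1, 1]")

    def effect(self, genotype: str, assay: str) -> float:
        """Multiplicative effect of ``genotype`` in ``assay`` (1.0 if unset)."""
        return float(self.effect_by_genotype.get(genotype, {}).get(assay, 1.0))

    def group_size(self, assay: str) -> int:
        if assay == "cafe":
            return self.flies_per_cafe_vial
        if assay == "larval":
            return self.larvae_per_plate
        return self.flies_per_replicate


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of the genomic and transcriptomic selection fixtures.

    ``n_snps`` loci are planted, each with ``n_genes_per_locus`` annotated
    gene intervals at known distances (0-based, half-open); the candidate
    window extends ``window_bp`` either side of the SNP. The expression
    fixture plants exactly ``n_reciprocal`` genes that satisfy the
    reciprocal-regulation rule (fold >= ``fold_threshold`` in one neuron
    population and <= 1/``fold_threshold`` in the other, p < ``p_threshold``
    in both) among ``n_expression_genes`` total.
    """

    n_snps: int = 36
    n_genes_per_locus: int = 3
    window_bp: int = 500_000
    n_expression_genes: int = 200
    n_reciprocal: int = 20
    fold_threshold: float = 1.5
    p_threshold: float = 0.05
    identity_range: tuple[float, float] = (10.0, 90.0)

    def __post_init__(self) -> None:
        if self.n_snps < 1 or self.n_genes_per_locus < 1:
            raise ValidationError("n_snps and n_genes_per_locus must be >= 1")
        if self.window_bp <= 0:
            raise ValidationError("window_bp must be > 0")
        if self.n_reciprocal > self.n_expression_genes:
            raise ValidationError("n_reciprocal cannot exceed n_expression_genes")
        if self.fold_threshold <= 1:
            raise ValidationError("fold_threshold must be > 1")
        if not 0 < self.p_threshold < 1:
            raise ValidationError("p_threshold must lie in (0, 1)")
        lo, hi = self.identity_range
        if not (0 <= lo < hi <= 100):
            raise ValidationError("identity_range must be within [0, 100] with lo < hi")
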