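"""Synthetic data with planted ground truth for every stage of the screen.

Every generator is deterministic given its seed, and every selection-stage
fixture returns a *truth* table recording what was planted, so downstream
operations can be checked for exact recovery. Randomness is drawn from
per-entity substreams (hash of the entity name mixed into the seed), which
keeps one genotype's draws stable when the genotype list changes.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    ASSAYS,
    BINOMIAL_ASSAYS,
    SCORE_ASSAYS,
    FixtureSpec,
    SyntheticConfig,
    ValidationError,
)

__all__ = [
    "generate_assay_table",
    "generate_tag_mass_pairs",
    "generate_locus_fixture",
    "generate_expression_fixture",
    "generate_orthology_table",
    "simulate_screen",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for ``name`` under the global ``seed``.

    The name is hashed (SHA-256) into two 31-bit words that are mixed into
    the seed sequence, giving a collision probability below 1e-9 even for
    screens of 10^5 genotypes.
    """
    digest = hashlib.sha256(name.encode()).digest()
    k1 = int.from_bytes(digest[:4], "big") % 2**31
    k2 = int.from_bytes(digest[4:8], "big") % 2**31
    return np.random.default_rng(np.random.SeedSequence((int(seed) % 2**31, k1, k2)))


def generate_assay_table(
    config: SyntheticConfig,
    genotypes: Sequence[str],
    assays: Sequence[str] = SCORE_ASSAYS,
) -> pd.DataFrame:
    """Draw replicate-level measurements for each genotype x assay.

    Continuous assays (cafe, mass, tag) are normal with mean
    ``control_mean x effect`` and SD ``CV x mean``; count assays (fif,
    larval) are binomial per vial with success probability
    ``min(1, control proportion x effect)``, reported as a percentage.
    When both mass and tag are generated, their replicate noise is
    coupled at ``config.tag_mass_correlation`` (triglyceride tracks wet
    mass); all other assays are independent.

    Returns a tidy frame with columns ``genotype, assay, replicate, value,
    n_flies`` and exactly ``n_replicates`` rows per genotype x assay.

    Raises
    ------
    ValidationError
        If a genotype effect produces a non-positive mean. A scaled
        binomial probability above 1 is clamped to 1 with a warning.
    """
    if len(genotypes) == 0:
        raise ValidationError("genotypes must be non-empty")
    if len(set(genotypes)) != len(genotypes):
        raise ValidationError("genotype ids must be unique")
    for assay in assays:
        if assay not in ASSAYS:
            raise ValidationError(f"unknown assay {assay!r}")
        if assay not in config.control_mean_by_assay:
            raise ValidationError(f"no control mean configured for assay {assay!r}")

    n = config.n_replicates
    geno_col: list[str] = []
    assay_col: list[str] = []
    values: list[np.ndarray] = []
    n_flies_col: list[int] = []
    rho = config.tag_mass_correlation
    pair = [a for a in assays if a in ("mass", "tag")]
    for genotype in genotypes:
        rng = substream(config.seed, genotype)
        pair_z: np.ndarray | None = None  # noise of the first of mass/tag
        for assay in assays:
            effect = config.effect(genotype, assay)
            base = config.control_mean_by_assay[assay]
            if assay in BINOMIAL_ASSAYS:
                if effect < 0:
                    raise ValidationError(
                        f"effect {effect} for {genotype!r}/{assay} yields a "
                        "negative success probability"
                    )
                prob = base * effect
                if prob > 1:
                    warnings.warn(
                        f"success probability {prob:.3f} for {genotype!r}/{assay} "
                        "clamped to 1",
                        stacklevel=2,
                    )
                    prob = 1.0
                size = config.group_size(assay)
                counts = rng.binomial(size, prob, n)
                vals = counts / size * 100.0
            else:
                mean = base * effect
                if mean <= 0:
                    raise ValidationError(
                        f"effect {effect} for {genotype!r}/{assay} yields a "
                        "non-positive mean"
                    )
                sd = config.cv_by_assay.get(assay, 0.15) * mean
                z = rng.standard_normal(n)
                if len(pair) == 2 and assay in pair:
                    if pair_z is None:
                        pair_z = z
                    else:
                        z = rho * pair_z + np.sqrt(max(0.0, 1 - rho * rho)) * z
                vals = mean + sd * z
            geno_col.extend([genotype] * n)
            assay_col.extend([assay] * n)
            values.append(vals)
            n_flies_col.extend([config.group_size(assay)] * n)
    return pd.DataFrame(
        {
            "genotype": geno_col,
            "assay": assay_col,
            "replicate": np.tile(np.arange(1, n + 1), len(geno_col) // n),
            "value": np.concatenate(values),
            "n_flies": n_flies_col,
        }
    )


def generate_tag_mass_pairs(
    config: SyntheticConfig, n: int, seed: int | None = None
) -> pd.DataFrame:
    """Paired per-genotype (mass, triglyceride) means, bivariate normal.

    The population correlation is ``config.tag_mass_correlation``; at
    |rho| = 1 pairs are exactly collinear. Requires ``n >= 3`` because a
    sample correlation is undefined below that.
    """
    if n < 3:
        raise ValidationError("n must be >= 3 for a defined sample correlation")
    rho = config.tag_mass_correlation
    rng = substream(config.seed if seed is None else seed, "tag_mass_pairs")
    z_mass = rng.standard_normal(n)
    z_extra = rng.standard_normal(n)
    z_tag = rho * z_mass + np.sqrt(max(0.0, 1.0 - rho * rho)) * z_extra
    m_mass = config.control_mean_by_assay["mass"]
    m_tag = config.control_mean_by_assay["tag"]
    cv_mass = config.cv_by_assay.get("mass", 0.08)
    cv_tag = config.cv_by_assay.get("tag", 0.25)
    return pd.DataFrame(
        {
            "mass": m_mass * (1.0 + cv_mass * z_mass),
            "tag": m_tag * (1.0 + cv_tag * z_tag),
        }
    )


def generate_locus_fixture(
    spec: FixtureSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Plant SNP loci with gene intervals at known distances.

    Each SNP sits on its own chromosome with ``n_genes_per_locus`` genes:
    the first is the (unique) nearest gene — sometimes containing the SNP —
    and subsequent genes lie at strictly increasing distances; when three
    or more genes are planted, the last is placed beyond ``window_bp`` to
    exercise the window cut-off. Intervals are 0-based, half-open.
    Every second SNP is flagged multi-gene (locus expansion applies only
    to flagged SNPs).

    Returns ``(snps, genes, truth)``; the truth table records the planted
    nearest gene, its distance, and the planted within-window gene set
    (semicolon-joined, sorted).
    """
    rng = substream(seed, "locus_fixture")
    snp_rows, gene_rows, truth_rows = [], [], []
    for i in range(spec.n_snps):
        chrom = f"chr{i + 1}"
        snp_id = f"rs{1000 + i}"
        position = int(spec.window_bp + 1_000_000 + rng.integers(0, 1_000_000))
        multi = spec.n_genes_per_locus > 1 and i % 2 == 1
        distances: list[int] = []
        for j in range(spec.n_genes_per_locus):
            if j == 0:
                d = 0 if rng.random() < 0.3 else int(rng.integers(1, 100_000))
            elif j == spec.n_genes_per_locus - 1 and spec.n_genes_per_locus >= 3:
                d = spec.window_bp + int(rng.integers(50_000, 200_000))
            else:
                d = distances[-1] + int(rng.integers(50_000, 150_000))
            distances.append(d)
        in_window: list[str] = []
        for j, d in enumerate(distances):
            gene = f"gene_{i + 1:02d}_{j}"
            width = int(rng.integers(5_000, 50_000))
            if d == 0:
                start = position - width // 2
                end = start + width
            elif rng.random() < 0.5:  # right of the SNP
                start = position + d
                end = start + width
            else:  # left: nearest base is end - 1
                end = position - d + 1
                start = end - width
            gene_rows.append(
                {"gene": gene, "chromosome": chrom, "start": start, "end": end}
            )
            if d <= spec.window_bp:
                in_window.append(gene)
        snp_rows.append(
            {
                "snp": snp_id,
                "chromosome": chrom,
                "position": position,
                "multi_gene_flag": multi,
            }
        )
        truth_rows.append(
            {
                "snp": snp_id,
                "nearest_gene": f"gene_{i + 1:02d}_0",
                "nearest_distance": distances[0],
                "window_genes": ";".join(sorted(in_window)),
                "multi_gene_flag": multi,
            }
        )
    return (
        pd.DataFrame(snp_rows),
        pd.DataFrame(gene_rows),
        pd.DataFrame(truth_rows),
    )


def generate_expression_fixture(
    spec: FixtureSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant fed->fasted regulation in POMC and AgRP neuron populations.

    Exactly ``n_reciprocal`` genes satisfy the reciprocal rule, split as
    evenly as possible between orexigenic (POMC down, AgRP up on fasting)
    and anorexigenic (POMC up, AgRP down); every other gene violates at
    least one clause (same direction, insufficient fold, or a
    non-significant p-value), with a >= 5% margin around each threshold so
    classification is unambiguous under floating point.

    Returns ``(expression, truth)``; the truth class is one of
    ``orexigenic``, ``anorexigenic``, ``non_reciprocal``.
    """
    rng = substream(seed, "expression_fixture")
    f = spec.fold_threshold
    alpha = spec.p_threshold
    n_orex = spec.n_reciprocal // 2
    rows, truth_rows = [], []

    def sig_p() -> float:
        return float(rng.uniform(1e-4, alpha * 0.9))

    def up_fold() -> float:
        return float(rng.uniform(f * 1.05, f * 3.0))

    def down_fold() -> float:
        return float(rng.uniform(0.2, (1.0 / f) * 0.95))

    for i in range(spec.n_expression_genes):
        gene = f"mg{i:04d}"
        if i < n_orex:
            cls = "orexigenic"
            pomc = (down_fold(), sig_p())
            agrp = (up_fold(), sig_p())
        elif i < spec.n_reciprocal:
            cls = "anorexigenic"
            pomc = (up_fold(), sig_p())
            agrp = (down_fold(), sig_p())
        else:
            cls = "non_reciprocal"
            mode = int(rng.integers(0, 4))
            if mode == 0:  # both up
                pomc, agrp = (up_fold(), sig_p()), (up_fold(), sig_p())
            elif mode == 1:  # both down
                pomc, agrp = (down_fold(), sig_p()), (down_fold(), sig_p())
            elif mode == 2:  # reciprocal folds, one p not significant
                bad_p = float(rng.uniform(alpha * 1.1, 0.9))
                if rng.random() < 0.5:
                    pomc, agrp = (down_fold(), bad_p), (up_fold(), sig_p())
                else:
                    pomc, agrp = (up_fold(), sig_p()), (down_fold(), bad_p)
            else:  # one fold inside the dead zone (1/f, f)
                dead = float(rng.uniform((1.0 / f) * 1.05, f * 0.95))
                if rng.random() < 0.5:
                    pomc, agrp = (dead, sig_p()), (up_fold(), sig_p())
                else:
                    pomc, agrp = (down_fold(), sig_p()), (dead, sig_p())
        rows.append(
            {"gene": gene, "population": "POMC", "fold_change": pomc[0], "p_value": pomc[1]}
        )
        rows.append(
            {"gene": gene, "population": "AgRP", "fold_change": agrp[0], "p_value": agrp[1]}
        )
        truth_rows.append({"gene": gene, "class": cls})
    expression = pd.DataFrame(rows).iloc[rng.permutation(2 * spec.n_expression_genes)]
    return expression.reset_index(drop=True), pd.DataFrame(truth_rows)


def generate_orthology_table(
    source_genes: Iterable[str],
    seed: int,
    identity_range: tuple[float, float] = (10.0, 90.0),
) -> pd.DataFrame:
    """Mammal->fly orthology records with filterable attributes.

    Each source gene maps to one or two fly genes with a percent
    amino-acid identity drawn from ``identity_range``, a CNS-expression
    flag, an RNAi-line availability flag, and an off-target count.
    """
    rng = substream(seed, "orthology_table")
    lo, hi = identity_range
    rows = []
    k = 0
    for source in source_genes:
        for _ in range(int(rng.integers(1, 3))):
            rows.append(
                {
                    "source_gene": source,
                    "fly_gene": f"CG{10000 + k}",
                    "percent_identity": float(np.round(rng.uniform(lo, hi), 1)),
                    "cns_expressed": bool(rng.random() < 0.8),
                    "rnai_available": bool(rng.random() < 0.9),
                    "off_target_count": int(rng.choice([0, 0, 0, 1, 2, 5])),
                }
            )
            k += 1
    return pd.DataFrame(rows)


def simulate_screen(
    config: SyntheticConfig,
    n_candidates: int = 36,
    n_positive: int = 4,
    n_negative: int = 10,
    candidate_effects: Mapping[str, Mapping[str, float]] | None = None,
    assays: Sequence[str] = SCORE_ASSAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full screen: candidates plus positive/negative panels.

    Positive-control genotypes are planted with the effect magnitudes
    positive controls show in practice — 1.5x food intake in the CAFE
    assay, a strong (1.8x) increase in the fasting-induced feeding
    proportion, and a 1.15x mass change (energy-homeostasis genes
    perturb both intake and mass); negative controls and unlisted
    candidates are null.
    ``candidate_effects`` plants effects into named candidate genotypes.
    Every genotype is compared against a single background control
    genotype ``control``.

    Returns ``(replicates, controls)`` where ``controls`` has columns
    ``genotype, control, panel`` with panel in
    {positive, negative, candidate}.
    """
    candidates = [f"cand_{i + 1:03d}" for i in range(n_candidates)]
    positives = [f"pos_{i + 1:02d}" for i in range(n_positive)]
    negatives = [f"neg_{i + 1:02d}" for i in range(n_negative)]
    effects: dict[str, dict[str, float]] = {
        g: dict(e) for g, e in (candidate_effects or {}).items()
    }
    for g in effects:
        if g not in candidates:
            raise ValidationError(f"candidate_effects names unknown genotype {g!r}")
    for g in positives:
        effects[g] = {"cafe": 1.5, "fif": 1.8, "mass": 1.15}
    cfg = replace(config, effect_by_genotype={**config.effect_by_genotype, **effects})
    genotypes = ["control"] + positives + negatives + candidates
    replicates = generate_assay_table(cfg, genotypes, assays=assays)
    controls = pd.DataFrame(
        {
            "genotype": positives + negatives + candidates,
            "control": "control",
            "panel": (
                ["positive"] * n_positive
                + ["negative"] * n_negative
                + ["candidate"] * n_candidates
            ),
        }
    )
    return replicates, controls
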