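"""End-to-end orchestration: simulate -> compare -> score -> select -> report.

``run_screen`` composes the stage functions into one deterministic run
(given config + seed), writing every stage output plus a JSON report. Any
stage failure aborts with the stage name attached so the offending record
is findable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from . import io
from .assays import compare_to_control
from .config import SyntheticConfig, ValidationError
from .scoring import ControlPanel, ControlValidation, score_genes, validate_controls
from .selection import (
    ViabilitySummary,
    reciprocal_filter,
    filter_orthologues,
    select_gwas_candidates,
    summarise_viability,
)
from .synthetic import simulate_screen

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ScreenReport",
    "PipelineError",
    "tag_mass_correlation",
    "rank_report",
    "run_screen",
]


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class CorrelationResult(NamedTuple):
    r: float
    pvalue: float
    n: int


class RankResult(NamedTuple):
    table: pd.DataFrame
    unscored: list[str]


def tag_mass_correlation(
    mass, tag, method: str = "t", seed: int | None = None
) -> CorrelationResult:
    """Pearson correlation between wet mass and triglyceride content.

    ``method="t"`` uses the t transform ``r * sqrt((n-2)/(1-r^2))`` with a
    two-sided p (the scipy default); ``method="permutation"`` runs a
    permutation test instead, preferable at small n.
    """
    mass = np.asarray(mass, dtype=float)
    tag = np.asarray(tag, dtype=float)
    if mass.size != tag.size or mass.size < 3:
        raise ValidationError("need >= 3 paired observations")
    if np.std(mass) == 0 or np.std(tag) == 0:
        raise ValidationError("correlation undefined: a column has zero variance")
    if method == "t":
        res = stats.pearsonr(mass, tag)
    elif method == "permutation":
        res = stats.pearsonr(
            mass, tag,
            method=stats.PermutationMethod(n_resamples=9999, rng=seed),
        )
    else:
        raise ValidationError("method must be 't' or 'permutation'")
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(mass.size))


def rank_report(scores: pd.DataFrame) -> RankResult:
    """Rank scored genes by descending (unrounded) score, ties by gene id.

    Unscored genes are dropped from the ranking and returned as a QC
    note so the report stays auditable.
    """
    if scores.empty:
        raise ValidationError("scores table is empty")
    unscored = scores.loc[scores["score"].isna(), "gene"].tolist()
    ranked = (
        scores.dropna(subset=["score"])
        .sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return RankResult(ranked, unscored)


@dataclass(frozen=True)
class RunConfig:
    """One reproducible screen run.

    Either point the table paths at existing TSVs, or leave
    ``replicates_path`` unset to simulate a screen from ``synthetic``
    (with ``n_candidates``/``n_positive``/``n_negative`` genotypes).
    """

    out_dir: str = "screen_out"
    seed: int = 0
    threshold_hit: float = 0.80
    threshold_consider: float = 0.70
    fold_threshold: float = 1.5
    alpha: float = 0.05
    min_identity: float = 30.0
    window_bp: int = 500_000
    mass_source: str = "mass"
    correlation_level: str = "genotype"  # or "replicate"
    # input tables (TSV / BED); unset sections are skipped
    replicates_path: str | None = None
    controls_path: str | None = None
    snps_path: str | None = None
    genes_bed_path: str | None = None
    orthology_path: str | None = None
    expression_path: str | None = None
    viability_path: str | None = None
    # simulation settings, used when replicates_path is unset
    n_candidates: int = 36
    n_positive: int = 4
    n_negative: int = 10
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        if not 0 < self.threshold_consider <= self.threshold_hit <= 1:
            raise ValidationError("need 0 < threshold_consider <= threshold_hit <= 1")
        if self.fold_threshold <= 1:
            raise ValidationError("fold_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.window_bp <= 0:
            raise ValidationError("window_bp must be > 0")
        if self.correlation_level not in ("genotype", "replicate"):
            raise ValidationError("correlation_level must be genotype or replicate")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = io.read_yaml(path)
        syn = raw.pop("synthetic", None)
        if syn is not None:
            if "control_mean_by_assay" in syn:
                syn["control_mean_by_assay"] = {
                    k: float(v) for k, v in syn["control_mean_by_assay"].items()
                }
            raw["synthetic"] = SyntheticConfig(**syn)
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


@dataclass
class ScreenReport:
    """Everything one run produced, ready for ranking and follow-up."""

    ranked: pd.DataFrame
    n_hits: int
    hits: list[str]
    control_validation: ControlValidation | None = None
    viability: ViabilitySummary | None = None
    tag_mass: CorrelationResult | None = None
    gwas_candidates: pd.DataFrame | None = None
    transcriptome_candidates: pd.DataFrame | None = None
    qc: dict[str, Any] = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - relabel with stage name
            raise PipelineError(name, exc) from exc
    return wrap


def run_screen(config: RunConfig, write: bool = True) -> ScreenReport:
    """Run the full screen described by ``config``.

    Deterministic given the config (which embeds the seed): running twice
    yields byte-identical outputs. Stages whose inputs are not configured
    (e.g. no SNP table) are skipped.
    """
    out = Path(config.out_dir)
    tag_line = f"flyscreen config={io.config_hash(config.to_dict())} seed={config.seed}"

    # --- inputs -----------------------------------------------------------
    if config.replicates_path:
        replicates = _stage("load")(io.read_tsv, config.replicates_path)
        controls = _stage("load")(io.read_tsv, config.controls_path)
    else:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        assays = ["cafe", "fif", "mass", "tag"]  # tag kept for the proxy check
        replicates, controls = _stage("simulate")(
            simulate_screen, syn,
            n_candidates=config.n_candidates,
            n_positive=config.n_positive,
            n_negative=config.n_negative,
            assays=assays,
        )
    control_map = dict(zip(controls["genotype"], controls["control"]))

    # --- compare and score ------------------------------------------------
    comparisons = _stage("compare")(compare_to_control, replicates, control_map)
    scores = _stage("score")(
        score_genes, comparisons,
        mass_source=config.mass_source,
        threshold_hit=config.threshold_hit,
        threshold_consider=config.threshold_consider,
    )
    ranked, unscored = _stage("rank")(rank_report, scores)
    hits = ranked.loc[ranked["score"] >= config.threshold_hit, "gene"].tolist()

    report = ScreenReport(
        ranked=ranked,
        n_hits=len(hits),
        hits=hits,
        qc={
            "unscored_genes": unscored,
            "n_comparisons": int(len(comparisons)),
        },
    )

    # --- control-panel validation ----------------------------------------
    if "panel" in controls.columns:
        pos = frozenset(controls.loc[controls["panel"] == "positive", "genotype"])
        neg = frozenset(controls.loc[controls["panel"] == "negative", "genotype"])
        if len(pos) >= 2 and len(neg) >= 2:
            panel = ControlPanel(
                pos, neg, config.threshold_hit, config.threshold_consider
            )
            report.control_validation = _stage("validate-controls")(
                validate_controls, scores, panel
            )

    # --- optional side analyses ------------------------------------------
    if config.viability_path:
        report.viability = _stage("viability")(
            summarise_viability, io.read_tsv(config.viability_path)
        )
    have_tag_mass = {"mass", "tag"}.issubset(set(replicates["assay"].unique()))
    if have_tag_mass:
        wide = replicates.pivot_table(
            index="genotype" if config.correlation_level == "genotype"
            else ["genotype", "replicate"],
            columns="assay", values="value",
        )[["mass", "tag"]].dropna()
        report.tag_mass = _stage("tag-mass-correlation")(
            tag_mass_correlation, wide["mass"], wide["tag"]
        )

    # --- candidate selection ---------------------------------------------
    if config.snps_path and config.genes_bed_path:
        snps = io.read_tsv(config.snps_path)
        genes = io.read_bed(config.genes_bed_path)
        report.gwas_candidates = _stage("select-gwas")(
            select_gwas_candidates, snps, genes, config.window_bp
        )
    if config.expression_path and config.orthology_path:
        expression = io.read_tsv(config.expression_path)
        orthology = io.read_tsv(config.orthology_path)
        reciprocal = _stage("select-transcriptome")(
            reciprocal_filter, expression, config.fold_threshold, config.alpha
        )
        kept = _stage("select-transcriptome")(
            filter_orthologues,
            orthology[orthology["source_gene"].isin(reciprocal["gene"])],
            config.min_identity,
        )
        report.transcriptome_candidates = kept.merge(
            reciprocal, left_on="source_gene", right_on="gene"
        )[["source_gene", "class", "fly_gene", "percent_identity"]]

    # --- outputs ----------------------------------------------------------
    if write:
        io.write_tsv(comparisons, out / "comparisons.tsv", tag_line)
        io.write_tsv(scores, out / "scores.tsv", tag_line)
        io.write_tsv(ranked, out / "ranked_report.tsv", tag_line)
        if report.gwas_candidates is not None:
            io.write_tsv(report.gwas_candidates, out / "candidates_gwas.tsv", tag_line)
        if report.transcriptome_candidates is not None:
            io.write_tsv(
                report.transcriptome_candidates,
                out / "candidates_transcriptome.tsv", tag_line,
            )
        if report.control_validation is not None:
            io.write_json(
                report.control_validation._asdict(), out / "control_validation.json"
            )
        summary: dict[str, Any] = {
            "config_hash": io.config_hash(config.to_dict()),
            "seed": config.seed,
            "thresholds": {
                "hit": config.threshold_hit,
                "consider": config.threshold_consider,
            },
            "n_genes_ranked": int(len(ranked)),
            "n_hits": report.n_hits,
            "hits": report.hits,
            "qc": report.qc,
        }
        if report.viability is not None:
            summary["viability"] = dataclasses.asdict(report.viability)
        if report.tag_mass is not None:
            summary["tag_mass_correlation"] = report.tag_mass._asdict()
        io.write_json(summary, out / "report.json")
        logger.info("screen run complete: %d genes, %d hits -> %s",
                    len(ranked), report.n_hits, out)
    return report
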