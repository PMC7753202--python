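"""Candidate-gene selection: GWAS loci and reciprocally regulated transcripts.

Two entry routes feed the screen with candidates:

* **GWAS route** — for each BMI-associated SNP, take the nearest annotated
  gene; at loci flagged as multi-gene, additionally take every gene whose
  interval overlaps a symmetric window (default 500 kb) around the SNP.
* **Transcriptomics route** — keep mouse genes whose fed->fasted fold
  change is reciprocal between POMC and AgRP hypothalamic neurons
  (>= 1.5-fold one way in one population and <= 1/1.5 the other way in the
  other, p < 0.05 in both), then map them to fly orthologues and keep
  those with amino-acid identity strictly above 30%, CNS expression and an
  available RNAi line without excess off-target effects.

Gene intervals are 0-based, half-open; the distance from a SNP to a gene
is 0 inside the interval and otherwise the distance to the closer of
``start`` and ``end - 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ViabilitySummary",
    "nearest_gene",
    "genes_in_window",
    "select_gwas_candidates",
    "reciprocal_filter",
    "filter_orthologues",
    "dedupe_fly_genes",
    "summarise_viability",
    "aggregate_source_hits",
]


def _gene_distances(position: int, genes: pd.DataFrame) -> np.ndarray:
    start = genes["start"].to_numpy()
    end = genes["end"].to_numpy()
    inside = (start <= position) & (position < end)
    d = np.minimum(np.abs(position - start), np.abs(position - (end - 1)))
    return np.where(inside, 0, d)


def _on_chromosome(chromosome: str, genes: pd.DataFrame) -> pd.DataFrame:
    sub = genes[genes["chromosome"] == chromosome]
    if sub.empty:
        raise ValidationError(f"no annotated gene on chromosome {chromosome!r}")
    return sub


def nearest_gene(chromosome: str, position: int, genes: pd.DataFrame) -> str:
    """Gene id minimising interval distance to the SNP.

    Ties are broken by smaller ``start``, then lexicographic gene id.
    """
    sub = _on_chromosome(chromosome, genes)
    d = _gene_distances(position, sub)
    order = sub.assign(_d=d).sort_values(["_d", "start", "gene"])
    return str(order.iloc[0]["gene"])


def genes_in_window(
    chromosome: str, position: int, genes: pd.DataFrame, window: int = 500_000
) -> set[str]:
    """Genes whose interval overlaps ``[position - window, position + window]``."""
    if window <= 0:
        raise ValidationError("window must be > 0")
    sub = genes[genes["chromosome"] == chromosome]
    hit = (sub["start"] <= position + window) & (sub["end"] - 1 >= position - window)
    return set(sub.loc[hit, "gene"].astype(str))


def select_gwas_candidates(
    snps: pd.DataFrame, genes: pd.DataFrame, window: int = 500_000
) -> pd.DataFrame:
    """Nearest gene per SNP, plus the window set at multi-gene loci.

    ``snps`` needs columns ``snp, chromosome, position, multi_gene_flag``;
    ``genes`` needs ``gene, chromosome, start, end``. Locus expansion to
    the window applies only where ``multi_gene_flag`` is set; other SNPs
    contribute exactly their nearest gene.

    Returns one row per (snp, gene) with columns ``snp, gene,
    nearest_flag, distance``.
    """
    rows = []
    for rec in snps.itertuples(index=False):
        near = nearest_gene(rec.chromosome, int(rec.position), genes)
        selected = {near}
        if bool(rec.multi_gene_flag):
            selected |= genes_in_window(rec.chromosome, int(rec.position), genes, window)
        sub = _on_chromosome(rec.chromosome, genes)
        dist = dict(zip(sub["gene"], _gene_distances(int(rec.position), sub)))
        for gene in sorted(selected):
            rows.append((rec.snp, gene, gene == near, int(dist[gene])))
    return pd.DataFrame(rows, columns=["snp", "gene", "nearest_flag", "distance"])


def reciprocal_filter(
    records: pd.DataFrame,
    fold_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Genes reciprocally regulated between POMC and AgRP on fasting.

    ``records`` holds one row per gene x population with columns ``gene,
    population, fold_change, p_value`` (fold = fasted/fed, so values
    below 1 are down-regulation). A gene passes iff its fold change is
    >= ``fold_threshold`` with p < ``p_threshold`` in one population and
    <= 1/``fold_threshold`` with p < ``p_threshold`` in the other.
    Classes follow the feeding circuitry: POMC down + AgRP up on fasting
    is *orexigenic*, the converse *anorexigenic*.

    Genes lacking a record for either population are excluded and logged;
    duplicated (gene, population) rows raise.

    Returns columns ``gene, class`` sorted by gene id.
    """
    if fold_threshold <= 1:
        raise ValidationError("fold_threshold must be > 1")
    dup = records.duplicated(subset=["gene", "population"])
    if dup.any():
        raise ValidationError(
            f"duplicate (gene, population) records: "
            f"{records.loc[dup, 'gene'].unique().tolist()}"
        )
    if (records["fold_change"] <= 0).any():
        raise ValidationError("fold changes must be > 0 (fasted/fed ratios)")
    pops = records["population"].str.upper()
    if not pops.isin(["POMC", "AGRP"]).all():
        raise ValidationError("population must be POMC or AgRP")
    wide_fold = records.assign(population=pops).pivot(
        index="gene", columns="population", values="fold_change"
    )
    wide_p = records.assign(population=pops).pivot(
        index="gene", columns="population", values="p_value"
    )
    for col in ("POMC", "AGRP"):
        if col not in wide_fold:
            wide_fold[col] = np.nan
            wide_p[col] = np.nan
    incomplete = wide_fold.isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "excluding %d gene(s) missing a population record: %s",
            int(incomplete.sum()), wide_fold.index[incomplete].tolist(),
        )
        wide_fold, wide_p = wide_fold[~incomplete], wide_p[~incomplete]

    sig = wide_p < p_threshold
    up = (wide_fold >= fold_threshold) & sig
    down = (wide_fold <= 1.0 / fold_threshold) & sig
    orex = down["POMC"] & up["AGRP"]
    anorex = up["POMC"] & down["AGRP"]
    out = pd.DataFrame(
        {
            "gene": wide_fold.index[orex | anorex],
            "class": np.where(orex[orex | anorex], "orexigenic", "anorexigenic"),
        }
    )
    return out.sort_values("gene", ignore_index=True)


def filter_orthologues(
    records: pd.DataFrame,
    min_identity: float = 30.0,
    require_cns: bool = True,
    require_rnai: bool = True,
    max_off_targets: int | None = None,
) -> pd.DataFrame:
    """Keep orthologue records passing the screenability filters.

    Identity must be *strictly* greater than ``min_identity`` percent.
    A source gene may keep several fly orthologues and two source genes
    may keep the same fly gene (use :func:`dedupe_fly_genes` for assay
    planning). The output is always a row subset of the input.
    """
    keep = records["percent_identity"] > min_identity
    if require_cns:
        keep &= records["cns_expressed"].astype(bool)
    if require_rnai:
        keep &= records["rnai_available"].astype(bool)
    if max_off_targets is not None:
        keep &= records["off_target_count"] <= max_off_targets
    return records[keep].reset_index(drop=True)


def dedupe_fly_genes(records: pd.DataFrame) -> pd.DataFrame:
    """One row per fly gene for assay planning, provenance preserved.

    Source genes are joined with ``;`` (sorted, unique); the reported
    identity is the maximum across the contributing records.
    """
    return (
        records.groupby("fly_gene")
        .agg(
            source_genes=("source_gene", lambda s: ";".join(sorted(set(s)))),
            percent_identity=("percent_identity", "max"),
        )
        .reset_index()
    )


@dataclass(frozen=True)
class ViabilitySummary:
    """Non-viability of RNAi knockdown lines by driver."""

    n_lines: int
    pct_ubiquitous_nonviable: float  # unrounded percentage
    pct_neuronal_nonviable: float
    display_ubiquitous: int  # rounded to the nearest integer percent
    display_neuronal: int


def summarise_viability(lines: pd.DataFrame) -> ViabilitySummary:
    """Percent of lines non-viable under ubiquitous / neuronal knockdown.

    ``lines`` needs boolean columns ``ubiquitous_viable`` and
    ``neuronal_viable`` (one row per RNAi line). Display values are
    rounded to the nearest integer percent; unrounded values retained.
    """
    if lines.empty:
        raise ValidationError("viability table is empty")
    n = len(lines)
    ubi = 100.0 * (~lines["ubiquitous_viable"].astype(bool)).sum() / n
    neu = 100.0 * (~lines["neuronal_viable"].astype(bool)).sum() / n
    return ViabilitySummary(n, ubi, neu, int(round(ubi)), int(round(neu)))


def aggregate_source_hits(
    scores: pd.DataFrame, orthology: pd.DataFrame
) -> pd.DataFrame:
    """Roll fly-gene hit calls up to the mammalian source gene.

    A source (human/mouse) gene is a hit when *any* of its fly orthologues
    is classified as a hit. Returns columns ``source_gene, n_orthologues,
    n_scored, hit``.
    """
    merged = orthology.merge(
        scores[["gene", "classification"]],
        left_on="fly_gene", right_on="gene", how="left",
    )
    grouped = merged.groupby("source_gene")
    return pd.DataFrame(
        {
            "source_gene": grouped.size().index,
            "n_orthologues": grouped.size().to_numpy(),
            "n_scored": grouped["classification"].count().to_numpy(),
            "hit": (grouped["classification"]
                    .apply(lambda s: bool((s == "hit").any())).to_numpy()),
        }
    )
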