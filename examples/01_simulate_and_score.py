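"""Simulate a small screen, compare genotypes with their control, and rank.

Each genotype is measured in three adult assays (CAFE food intake,
fasting-induced feeding, wet mass) with 5 biological replicates, compared
with a background-matched control by pooled-variance t tests, and scored
as 1 minus the sum of the three p-values. Scores >= 0.80 are hits.
"""

from flyscreen import (
    SyntheticConfig,
    compare_to_control,
    rank_report,
    score_genes,
    simulate_screen,
)

# 12 candidates; two of them are planted with a real feeding phenotype
planted = {
    "cand_003": {"cafe": 1.6, "fif": 1.7, "mass": 1.2},
    "cand_009": {"cafe": 0.6, "fif": 0.6},  # eats less: scores identically high
}
replicates, controls = simulate_screen(
    SyntheticConfig(seed=42), n_candidates=12, candidate_effects=planted
)
comparisons = compare_to_control(
    replicates, dict(zip(controls["genotype"], controls["control"]))
)
scores = score_genes(comparisons)
ranked, unscored = rank_report(scores)

print(ranked.head(8).to_string(index=False))
print(
    f"\n{int((ranked.score >= 0.8).sum())} hit(s) at score >= 0.80; "
    f"{len(unscored)} unscored gene(s)."
)
print(
    "Both planted genes rank far above the null bulk regardless of the\n"
    "direction of their effect: the score uses p-values only, so a gene\n"
    "that eats less is flagged just like one that eats more."
)
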