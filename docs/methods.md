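# Methods

## The screen's statistical model

The unit of analysis is the biological replicate (one vial or plate, one
independent cross), not the individual fly. Each genotype × assay cell
holds 5 replicate means; genotype and background-matched control are
compared with an unpaired, pooled-variance (homoscedastic) Student
*t* test, two-sided, df = n₁ + n₂ − 2. Two-sidedness is the conservative
choice for a screen that cares about perturbation in either direction.
No multiple-testing correction is applied across genes: the integrated
score consumes raw p-values, and the hit threshold is calibrated
directly on the composite null (below).

The integrated score for a gene is `S = 1 − (p_cafe + p_fif + p_mass)`.
Properties relied on throughout:

* strictly decreasing in each p-value, permutation-invariant across the
  three assays, and bounded in (−2, 1] with S = 1 iff all p = 0;
* direction-agnostic: only significance enters, so an anorexigenic
  knockdown scores like an orexigenic one. This is deliberate — the
  screen flags any perturbation of energy homeostasis;
* scores are never clipped at 0 (clipping would destroy monotonicity of
  the ranking) and never rounded except for display (2 decimals);
* classification: hit at S ≥ 0.80, consider at S ≥ 0.70, both inclusive
  and evaluated on the unrounded score. Genes missing any of the three
  p-values are reported as unscored; no p-value is imputed.

One known arithmetic curiosity is documented rather than resolved: a
published score of 0.99 for a gene whose two printed p-values already
sum to 0.0162 cannot be produced by this formula (they cap the score at
0.9838); the formula as stated is implemented verbatim.

Wet mass may be replaced by triglyceride as the third p-value
(`mass_source="tag"`): the two readouts correlate strongly (the
generator's default pairing uses ρ = 0.6, and the pipeline recomputes
the sample Pearson r, by default on per-genotype means, with a
per-replicate option).

### Null calibration

Under the global null with continuous data the three p-values are
independent Uniform(0, 1), so

```
P(S ≥ 0.8) = P(p₁ + p₂ + p₃ ≤ 0.2) = 0.2³/6 ≈ 1.333 × 10⁻³,
```

the volume of the corner simplex. The FIF assay is binomial (counts out
of 15 flies), so its t-test p-value is discrete and only approximately
uniform; by simulation the resulting deviation of P(S ≥ 0.8) is ~5×10⁻⁵,
negligible at screen scale. `null_hit_rate` recomputes the probability
through the full simulate → compare → score code path, giving each
simulated gene its own background control so gene-level outcomes are
independent and the Wilson binomial CI is exact in design.

`power_at_effect` uses the same machinery for genes with planted
multiplicative effects. Its contract is the probability that the
*integrated score* clears the threshold — which is why a strong effect
in a single assay yields low power (the other two p-values stay
uniform, and P(p₂ + p₃ ≤ 0.2) ≈ 0.02): the sensitivity of the screen
comes from consistency across assays, not from any single readout.
Power is monotone non-decreasing in each effect magnitude; tests check
the null-reduction case, monotonicity under common random numbers, and
near-certain detection of a strong three-assay effect.

### Degenerate cases

Zero pooled variance (possible with discrete counts on synthetic edge
cases) is resolved explicitly: p = 1 if the group means are equal, else
p = 0 with t = ±∞. Negative evaporation-corrected CAFE values are
retained — clipping would bias vial means upward — but flagged for QC
and surfaced in reports.

## The synthetic-data generator

The generator emulates the screen's design conditions: 5 biological
replicates per genotype, 15 flies per replicate (8 per CAFE vial, 20
larvae per plate). Continuous assays (CAFE, mass, TAG) draw replicate
means from a normal with mean `control_mean × effect` and
SD = CV × mean; count assays (FIF, larval) draw binomial counts per vial
with success probability `min(1, proportion × effect)` (clamping warns).
Noise is modelled at the replicate level because that is the unit the
statistics consume; per-fly simulation would add nothing to what the
tests exercise.

Default control means are plausible values for adult males on a normal
diet — CAFE 1.2 µl/fly/24 h, FIF proportion 0.5, mass 0.8 mg/fly, TAG
10 µg/fly, larval in-food proportion 0.56 — and default CVs of the
replicate mean are 0.20 (CAFE), 0.08 (mass), 0.25 (TAG). No published
variance estimates exist for these assays, so the CVs are the package's
own choices, ordered by how noisy each readout is in practice
(behavioural > biochemical > gravimetric); every calibration property
checked by the tests is scale-free, so these choices set power, not
correctness. Positive-control genotypes in `simulate_screen` are
planted with cafe 1.5×, fif 1.8× and mass 1.15× — the magnitude a
genuine energy-homeostasis gene shows — so the control-panel separation
behaves like a real validation panel.

Each genotype draws from a deterministic substream (SHA-256 of the
genotype name mixed into the seed), so outputs are byte-identical under
a fixed seed and adding a genotype never perturbs the draws of others.

Fixture generators plant ground truth and return it: locus fixtures
place each SNP on its own chromosome with genes at strictly increasing
known distances (the farthest beyond the window when three or more are
planted, to exercise the cut-off), 0-based half-open intervals;
expression fixtures plant exactly `n_reciprocal` genes passing the
reciprocal rule with ≥5 % margins around every threshold so
classification is float-proof, and every other gene violates exactly one
identified clause. Recovery must be exact on every seed.

What the generator does *not* model: circadian, age, mating and
temperature effects (experimental controls, not model features),
per-fly heterogeneity, batch effects across replicates, or correlated
noise between assays other than the explicit mass–TAG pairing. Passing
tests therefore show the statistics are implemented correctly under the
screen's design assumptions, not that real assay noise is normal.

## Selection workflows

* SNP→gene distance: 0 inside the interval, else distance to the closer
  of `start` and `end − 1` (annotation is half-open); ties broken by
  smaller start, then gene id. The 500-kb window is symmetric around the
  SNP point and uses interval-overlap semantics (a gene overlapping the
  boundary by one base is included). Window expansion applies only to
  SNPs flagged multi-gene; which loci get flagged is input annotation,
  not a computed property.
* Reciprocal regulation: fold ≥ 1.5 with p < 0.05 in one population and
  fold ≤ 1/1.5 with p < 0.05 in the other (fold boundaries inclusive,
  p strict). Fold changes are fasted/fed ratios; values below 1 encode
  down-regulation. POMC-down/AgRP-up is orexigenic, the converse
  anorexigenic. Genes missing a population record are excluded and
  logged; duplicates are an error.
* Orthologue filter: identity strictly > 30 %, CNS expression and RNAi
  availability required by default, optional off-target cap. A source
  gene may keep several fly orthologues; shared fly genes are
  deduplicated only for assay planning, with provenance preserved, and
  a source gene counts as a hit if any of its orthologues is.
* Viability summary: percentage of lines non-viable per driver, rounded
  to integer percent for display with the unrounded value retained.

## Pipeline and reproducibility

`run_screen` composes simulate/load → compare → score → rank →
validate-controls → select → report. Outputs are TSV with fixed column
order and a config-hash comment line, plus a JSON summary; ranking is
strictly by unrounded score with ties broken by gene id, and the
reported hit count is recomputed from the ranked table. The correlation
p-value uses the t transform by default with an exact-permutation
option for small n. All stage errors are re-raised labelled with the
stage name.

Problem sizes used by the test suite and the acceptance script — 50,000
simulated null genes for the threshold calibration, 10,000 for p-value
uniformity, 20 fixture seeds for planted-truth recovery, 5,000 pairs
for the correlation check — were chosen so Monte-Carlo error is small
relative to each tolerance (3 binomial SEs, the Fisher-z ±0.03 band)
while the whole suite stays fast on a laptop.

## Known limitations

* The generator's effect model is multiplicative on the mean with
  proportional SD; real knockdowns may change variance independently.
* The score's additive-p composition is the screen's defining contract;
  alternatives (Fisher, Stouffer) are deliberately not offered as
  substitutes.
* The control-separation t test is run on n = 4 vs 10 scores, so its p
  is itself noisy across seeds; the threshold range reported alongside
  it is evaluated only at observed score cut points.
* Off-target counts, CNS expression and orthologue identity are consumed
  as input annotation; no sequence-level computation is performed.
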