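"""SNP-to-gene locus selection and reciprocal-regulation filtering."""

import numpy as np
import pandas as pd
import pytest

from flyscreen import (
    FixtureSpec,
    ValidationError,
    aggregate_source_hits,
    dedupe_fly_genes,
    filter_orthologues,
    generate_expression_fixture,
    generate_locus_fixture,
    genes_in_window,
    nearest_gene,
    reciprocal_filter,
    select_gwas_candidates,
    summarise_viability,
)


def genes_df(rows):
    return pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end"])


class TestNearestGene:
    def test_snp_inside_gene_wins_at_distance_zero(self):
        genes = genes_df(
            [("inside", "chr1", 900, 1100), ("near", "chr1", 1200, 1300)]
        )
        assert nearest_gene("chr1", 1000, genes) == "inside"

    def test_interval_distance_uses_closer_end(self):
        genes = genes_df(
            [
                ("geneA", "chr1", 1_100_000, 1_200_000),  # 100,000 away
                ("geneB", "chr1", 700_000, 800_000),      # 200,001 away (end-1)
            ]
        )
        assert nearest_gene("chr1", 1_000_000, genes) == "geneA"

    def test_tie_broken_by_smaller_start_then_gene_id(self):
        genes = genes_df(
            [("right", "chr1", 1100, 1200), ("left", "chr1", 800, 901)]
        )
        # both at distance 100: left's end-1 = 900, right's start = 1100? no:
        # position 1000 -> left distance 100, right distance 100
        assert nearest_gene("chr1", 1000, genes) == "left"
        same_start = genes_df(
            [("b_gene", "chr1", 1100, 1300), ("a_gene", "chr1", 1100, 1200)]
        )
        assert nearest_gene("chr1", 1000, same_start) == "a_gene"

    def test_no_gene_on_chromosome_is_an_error(self):
        genes = genes_df([("g", "chr2", 0, 10)])
        with pytest.raises(ValidationError):
            nearest_gene("chr1", 5, genes)


class TestGenesInWindow:
    genes = genes_df(
        [
            ("far", "chr1", 1_600_000, 1_650_000),       # starts 600 kb away
            ("edge", "chr1", 1_500_000, 1_550_000),      # starts exactly at +500 kb
            ("left_edge", "chr1", 450_000, 500_001),     # ends exactly at -500 kb
            ("gone", "chr1", 400_000, 499_000),          # 1 base past the window
        ]
    )

    def test_window_overlap_semantics(self):
        hits = genes_in_window("chr1", 1_000_000, self.genes, 500_000)
        assert hits == {"edge", "left_edge"}

    def test_unflagged_snp_yields_only_the_nearest_gene(self):
        snps = pd.DataFrame(
            {
                "snp": ["rs1"],
                "chromosome": ["chr1"],
                "position": [1_000_000],
                "multi_gene_flag": [False],
            }
        )
        out = select_gwas_candidates(snps, self.genes)
        assert out["gene"].tolist() == ["left_edge"]  # nearest at 499,999... no:
        # distances: edge 500000, left_edge 500000, gone 501001, far 600000
        # tie edge/left_edge broken by smaller start -> left_edge
        assert out["nearest_flag"].all()

    def test_nearest_gene_always_inside_any_sufficient_window(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pos = int(rng.integers(100_000, 2_000_000))
            starts = rng.integers(0, 3_000_000, size=5)
            genes = genes_df(
                [
                    (f"g{i}", "chr1", int(s), int(s) + int(rng.integers(1000, 30000)))
                    for i, s in enumerate(starts)
                ]
            )
            near = nearest_gene("chr1", pos, genes)
            sub = genes
            start = sub["start"].to_numpy()
            end = sub["end"].to_numpy()
            inside = (start <= pos) & (pos < end)
            d = np.where(
                inside, 0, np.minimum(np.abs(pos - start), np.abs(pos - (end - 1)))
            )
            # the invariant holds for any window >= the nearest distance
            for window in (int(d.min()) + 1, int(d.min()) + 500_000, 5_000_000):
                assert near in genes_in_window("chr1", pos, genes, window)

    def test_window_must_be_positive(self):
        with pytest.raises(ValidationError):
            genes_in_window("chr1", 100, self.genes, 0)


class TestReciprocalFilter:
    @staticmethod
    def records(rows):
        return pd.DataFrame(
            rows, columns=["gene", "population", "fold_change", "p_value"]
        )

    def test_pomc_down_agrp_up_is_orexigenic(self):
        out = reciprocal_filter(
            self.records(
                [("g", "POMC", 0.5, 0.01), ("g", "AgRP", 2.0, 0.02)]
            )
        )
        assert out.to_dict("records") == [{"gene": "g", "class": "orexigenic"}]

    def test_pomc_up_agrp_down_is_anorexigenic(self):
        out = reciprocal_filter(
            self.records([("g", "POMC", 2.0, 0.01), ("g", "AgRP", 0.5, 0.01)])
        )
        assert out["class"].tolist() == ["anorexigenic"]

    @pytest.mark.parametrize(
        "rows",
        [
            [("g", "POMC", 2.0, 0.01), ("g", "AgRP", 2.0, 0.01)],   # same direction
            [("g", "POMC", 1.6, 0.2), ("g", "AgRP", 0.5, 0.01)],    # p clause fails
            [("g", "POMC", 1.2, 0.01), ("g", "AgRP", 0.5, 0.01)],   # fold too weak
        ],
    )
    def test_violating_one_clause_excludes_the_gene(self, rows):
        assert reciprocal_filter(self.records(rows)).empty

    def test_fold_boundaries_are_inclusive(self):
        out = reciprocal_filter(
            self.records([("g", "POMC", 1.5, 0.01), ("g", "AgRP", 1 / 1.5, 0.01)])
        )
        assert out["class"].tolist() == ["anorexigenic"]

    def test_invariant_to_row_order_and_population_relabelling(self):
        rows = [
            ("g1", "POMC", 0.4, 0.01), ("g1", "AgRP", 1.9, 0.03),
            ("g2", "POMC", 3.0, 0.001), ("g2", "AgRP", 0.3, 0.001),
            ("g3", "POMC", 1.0, 0.5), ("g3", "AgRP", 1.0, 0.5),
        ]
        base = reciprocal_filter(self.records(rows))
        shuffled = reciprocal_filter(self.records(rows[::-1]))
        pd.testing.assert_frame_equal(base, shuffled)
        swapped = self.records(
            [(g, {"POMC": "AgRP", "AgRP": "POMC"}[p], f, pv) for g, p, f, pv in rows]
        )
        out = reciprocal_filter(swapped).set_index("gene")["class"]
        assert out["g1"] == "anorexigenic" and out["g2"] == "orexigenic"

    def test_missing_population_record_is_excluded(self, caplog):
        rows = [
            ("lonely", "POMC", 0.4, 0.01),
            ("ok", "POMC", 0.4, 0.01), ("ok", "AgRP", 2.0, 0.01),
        ]
        with caplog.at_level("WARNING"):
            out = reciprocal_filter(self.records(rows))
        assert out["gene"].tolist() == ["ok"]
        assert "lonely" in caplog.text

    def test_duplicate_record_is_an_error(self):
        rows = [("g", "POMC", 0.4, 0.01), ("g", "POMC", 0.5, 0.01)]
        with pytest.raises(ValidationError):
            reciprocal_filter(self.records(rows))


class TestOrthologueFilter:
    @staticmethod
    def records(rows):
        return pd.DataFrame(
            rows,
            columns=[
                "source_gene", "fly_gene", "percent_identity",
                "cns_expressed", "rnai_available", "off_target_count",
            ],
        )

    def test_identity_threshold_is_strict(self):
        table = self.records(
            [
                ("h1", "f1", 28.0, True, True, 0),
                ("h2", "f2", 30.0, True, True, 0),  # exactly 30 -> excluded
                ("h3", "f3", 36.0, True, True, 0),
            ]
        )
        assert filter_orthologues(table)["fly_gene"].tolist() == ["f3"]

    def test_boolean_requirements_and_off_target_cap(self):
        table = self.records(
            [
                ("h1", "f1", 50.0, False, True, 0),
                ("h2", "f2", 50.0, True, False, 0),
                ("h3", "f3", 50.0, True, True, 5),
                ("h4", "f4", 50.0, True, True, 1),
            ]
        )
        kept = filter_orthologues(table, max_off_targets=1)
        assert kept["fly_gene"].tolist() == ["f4"]

    def test_filters_compose_commutatively_and_output_is_subset(self):
        rng = np.random.default_rng(1)
        table = self.records(
            [
                (f"h{i}", f"f{i}", float(rng.uniform(10, 90)),
                 bool(rng.random() < 0.5), bool(rng.random() < 0.5),
                 int(rng.integers(0, 4)))
                for i in range(50)
            ]
        )
        a = filter_orthologues(
            filter_orthologues(table, require_cns=False, require_rnai=False),
            min_identity=0, require_rnai=False,
        )
        b = filter_orthologues(
            filter_orthologues(table, min_identity=0, require_rnai=False),
            require_cns=False, require_rnai=False,
        )
        pd.testing.assert_frame_equal(a, b)
        full = filter_orthologues(table, max_off_targets=1)
        merged = full.merge(table, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()

    def test_shared_fly_gene_deduplicated_with_provenance(self):
        table = self.records(
            [("h1", "f1", 40.0, True, True, 0), ("h2", "f1", 55.0, True, True, 0)]
        )
        deduped = dedupe_fly_genes(table)
        assert len(deduped) == 1
        assert deduped.iloc[0]["source_genes"] == "h1;h2"
        assert deduped.iloc[0]["percent_identity"] == 55.0

    def test_source_gene_hit_if_any_orthologue_hits(self):
        scores = pd.DataFrame(
            {"gene": ["f1", "f2", "f3"],
             "classification": ["negative", "hit", "negative"]}
        )
        orth = self.records(
            [("h1", "f1", 40, True, True, 0), ("h1", "f2", 40, True, True, 0),
             ("h2", "f3", 40, True, True, 0)]
        )
        agg = aggregate_source_hits(scores, orth).set_index("source_gene")
        assert bool(agg.loc["h1", "hit"]) and not bool(agg.loc["h2", "hit"])


class TestViability:
    def test_screen_scale_counts_round_to_55_percent(self):
        lines = pd.DataFrame(
            {
                "fly_gene": [f"g{i}" for i in range(53)],
                "ubiquitous_viable": [False] * 29 + [True] * 24,
                "neuronal_viable": [True] * 53,
            }
        )
        summary = summarise_viability(lines)
        assert summary.display_ubiquitous == 55
        assert summary.pct_ubiquitous_nonviable == pytest.approx(100 * 29 / 53)
        assert summary.display_neuronal == 0

    @pytest.mark.parametrize(
        "viable, expected", [([True] * 10, 0), ([False] * 7, 100)]
    )
    def test_degenerate_panels(self, viable, expected):
        lines = pd.DataFrame(
            {
                "fly_gene": [f"g{i}" for i in range(len(viable))],
                "ubiquitous_viable": viable,
                "neuronal_viable": viable,
            }
        )
        assert summarise_viability(lines).display_ubiquitous == expected

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValidationError):
            summarise_viability(pd.DataFrame(columns=["ubiquitous_viable",
                                                      "neuronal_viable"]))


class TestPlantedTruthRecovery:
    @pytest.mark.parametrize("seed", range(5))
    def test_locus_truth_recovered(self, seed):
        spec = FixtureSpec(n_snps=10, n_genes_per_locus=3)
        snps, genes, truth = generate_locus_fixture(spec, seed)
        for snp, t in zip(snps.itertuples(), truth.itertuples()):
            assert nearest_gene(snp.chromosome, snp.position, genes) == t.nearest_gene
            got = genes_in_window(snp.chromosome, snp.position, genes, spec.window_bp)
            assert got == set(t.window_genes.split(";"))

    @pytest.mark.parametrize("seed", range(5))
    def test_expression_truth_recovered(self, seed):
        spec = FixtureSpec(n_expression_genes=80, n_reciprocal=16)
        expr, truth = generate_expression_fixture(spec, seed)
        out = reciprocal_filter(expr, spec.fold_threshold, spec.p_threshold)
        expected = (
            truth[truth["class"] != "non_reciprocal"]
            .rename(columns={"class": "class"})
            .sort_values("gene", ignore_index=True)
        )
        pd.testing.assert_frame_equal(out, expected)
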