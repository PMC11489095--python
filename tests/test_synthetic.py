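import numpy as np
import pandas as pd
import pytest

from apakit import io, motifs
from apakit.synthetic import (
    EffectSpec,
    SampleDesign,
    SizingError,
    SyntheticGenomeSpec,
    generate_genome,
    plant_usage,
    simulate_3p_counts,
    simulate_intensity_table,
)


class TestGenerateGenome:
    def test_empty_spec_gives_empty_outputs(self):
        genome, genes, truth = generate_genome(SyntheticGenomeSpec(n_genes=0, seed=1))
        assert genes == [] and len(truth) == 0

    def test_deterministic_files_given_seed(self, tmp_path):
        """Same spec and seed twice: byte-identical FASTA and GFF3."""
        spec = SyntheticGenomeSpec(n_genes=12, seed=5)
        paths = []
        for run in (0, 1):
            genome, genes, _ = generate_genome(spec)
            fa, gff = tmp_path / f"g{run}.fa", tmp_path / f"a{run}.gff3"
            io.write_fasta(genome, fa)
            io.write_gff3(genes, gff)
            paths.append((fa.read_bytes(), gff.read_bytes()))
        assert paths[0] == paths[1]

    def test_earlier_genes_stable_when_cohort_grows(self):
        _, genes_small, truth_small = generate_genome(
            SyntheticGenomeSpec(n_genes=5, seed=9)
        )
        _, genes_big, truth_big = generate_genome(
            SyntheticGenomeSpec(n_genes=10, seed=9)
        )
        assert [g.exons for g in genes_big[:5]] == [g.exons for g in genes_small]
        small_sites = truth_small[["site_id", "pos"]]
        big_sites = truth_big[truth_big.gene_id.isin(truth_small.gene_id)][
            ["site_id", "pos"]
        ]
        pd.testing.assert_frame_equal(
            small_sites.reset_index(drop=True), big_sites.reset_index(drop=True)
        )

    def test_sizing_error_when_genes_exceed_chromosome(self):
        with pytest.raises(SizingError):
            generate_genome(SyntheticGenomeSpec(n_genes=50, chrom_length=10_000, seed=0))

    def test_every_gene_has_intron_when_min_two_exons(self):
        _, genes, _ = generate_genome(SyntheticGenomeSpec(n_genes=20, seed=2))
        assert all(len(g.introns) >= 1 for g in genes)

    def test_strands_alternate_equally(self):
        _, genes, _ = generate_genome(SyntheticGenomeSpec(n_genes=20, seed=2))
        assert sum(g.strand == "+" for g in genes) == 10

    def test_full_cassette_rate_means_every_intron_scans_positive(self):
        """With cassette_fraction_introns=1 every designated intron site
        carries all three elements under the default windows (the scanner
        is the oracle for the generator's planting)."""
        genome, _, truth = generate_genome(
            SyntheticGenomeSpec(n_genes=30, cassette_fraction_introns=1.0, seed=3)
        )
        introns = truth[truth.site_type == "intronic"]
        flags = motifs.scan_sites(genome, introns[["chrom", "pos", "strand"]])
        assert flags[["UGUA", "PAS", "U_rich"]].all(axis=1).all()
        assert introns.cassette.all()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticGenomeSpec(cassette_fraction_introns=1.2)
        with pytest.raises(ValueError):
            SyntheticGenomeSpec(gene_length_range=(500, 100))


class TestPlantUsage:
    def test_usage_sums_to_one_per_gene_and_condition(self, recovery_cohort):
        truth = recovery_cohort["truth"]
        sums = truth.groupby("gene_id")[["usage_WT", "usage_U1KD"]].sum()
        assert np.allclose(sums.to_numpy(), 1.0)

    def test_null_effect_plants_no_events(self):
        genome, genes, truth = generate_genome(SyntheticGenomeSpec(n_genes=10, seed=4))
        design = SampleDesign()
        out = plant_usage(truth, design, EffectSpec("intronic_pCPA", delta_usage=0.0))
        # affected genes exist but carry no usage difference
        assert np.allclose(out["usage_WT"], out["usage_U1KD"])

    def test_affected_drawn_only_from_cassette_candidates(self, recovery_cohort):
        truth = recovery_cohort["truth"]
        affected_candidates = truth[
            truth.affected & truth.is_candidate & (truth.site_type == "intronic")
        ]
        assert affected_candidates.cassette.all()

    def test_tandem_effect_direction(self):
        genome, genes, truth = generate_genome(
            SyntheticGenomeSpec(n_genes=20, tandem_site_fraction=1.0, seed=6)
        )
        out = plant_usage(truth, SampleDesign(), EffectSpec("tandem_utr_shift", 0.4))
        tandem = out[(out.site_type == "tandem") & out.affected]
        assert len(tandem) > 0
        assert np.allclose(tandem["usage_WT"], 0.7)
        assert np.allclose(tandem["usage_U1KD"], 0.3)
        assert (tandem["planted_direction"] == "enhanced").all()


class TestSimulate3pCounts:
    def make_single_gene_truth(self):
        spec = SyntheticGenomeSpec(n_genes=1, tandem_site_fraction=1.0, seed=8)
        genome, genes, truth = generate_genome(spec)
        return genome, genes, truth

    def test_binomial_allocation_at_planted_usage(self):
        """Two sites at usage 0.7/0.3 and depth 1000 with no jitter: the
        proximal count stays within 3 binomial standard deviations of 700."""
        _, genes, truth = self.make_single_gene_truth()
        truth = truth[truth.site_type.isin(["tandem", "distal"])].copy()
        truth["usage_WT"] = np.where(truth.site_type == "tandem", 0.7, 0.3)
        truth["usage_U1KD"] = truth["usage_WT"]
        design = SampleDesign(replicates_per_condition=1, reads_per_gene=1000.0)
        counts, _ = simulate_3p_counts(genes, truth, design, seed=13, jitter=0)
        tandem_pos = truth.loc[truth.site_type == "tandem", "pos"].iloc[0]
        prox = counts[(counts["pos"] == tandem_pos) & (counts["sample"] == "WT_rep1")][
            "count"
        ].sum()
        total = counts[counts["sample"] == "WT_rep1"]["count"].sum()
        sd = np.sqrt(total * 0.7 * 0.3)
        assert abs(prox - 0.7 * total) <= 3 * sd

    def test_zero_depth_yields_empty_table(self):
        _, genes, truth = self.make_single_gene_truth()
        design = SampleDesign(reads_per_gene=0.0)
        counts, _ = simulate_3p_counts(genes, truth, design, seed=1)
        assert counts.empty
        assert list(counts.columns) == ["chrom", "pos", "strand", "sample", "count"]

    def test_unknown_condition_label_rejected(self):
        _, genes, truth = self.make_single_gene_truth()
        planted = plant_usage(truth, SampleDesign(), EffectSpec())
        bad_design = SampleDesign(conditions=("WT", "mystery"))
        with pytest.raises(ValueError, match="unknown condition"):
            simulate_3p_counts(genes, planted, bad_design, seed=1)

    def test_jitter_stays_within_radius(self):
        _, genes, truth = self.make_single_gene_truth()
        design = SampleDesign(reads_per_gene=200.0)
        counts, planted = simulate_3p_counts(genes, truth, design, seed=2, jitter=5)
        site_pos = planted.loc[planted[["usage_WT", "usage_U1KD"]].sum(axis=1) > 0,
                               "pos"].to_numpy()
        for pos in counts["pos"]:
            assert np.abs(site_pos - pos).min() <= 5

    def test_deterministic_given_seed(self):
        _, genes, truth = self.make_single_gene_truth()
        design = SampleDesign()
        a, _ = simulate_3p_counts(genes, truth, design, seed=3)
        b, _ = simulate_3p_counts(genes, truth, design, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_overdispersed_totals_spread_wider_than_poisson(self):
        spec = SyntheticGenomeSpec(n_genes=40, seed=14)
        genome, genes, truth = generate_genome(spec)
        design_nb = SampleDesign(reads_per_gene=100.0, overdispersion=0.5)
        counts, _ = simulate_3p_counts(genes, truth, design_nb, seed=15, jitter=0)
        merged = counts.merge(
            truth[["chrom", "pos", "strand", "gene_id"]], on=["chrom", "pos", "strand"]
        )
        totals = merged.groupby(["gene_id", "sample"])["count"].sum()
        # NB variance mu + 0.5 mu^2 >> Poisson mu at mu=100
        assert totals.var() > 3 * totals.mean()


class TestIntensityTable:
    def test_enriched_means_elevated(self):
        table, labels = simulate_intensity_table(100, 10, effect_log2fc=5.0, seed=1)
        bait = table[[c for c in table if c.startswith("bait")]].mean(axis=1)
        ctrl = table[[c for c in table if c.startswith("ctrl")]].mean(axis=1)
        diff = (bait - ctrl)[labels]
        assert diff.mean() == pytest.approx(5.0, abs=0.5)

    def test_missingness_prefers_controls(self):
        table, _ = simulate_intensity_table(2000, 0, missing_rate=0.4, seed=2)
        ctrl_missing = table[[c for c in table if c.startswith("ctrl")]].isna().mean().mean()
        bait_missing = table[[c for c in table if c.startswith("bait")]].isna().mean().mean()
        assert ctrl_missing == pytest.approx(0.4, abs=0.05)
        assert bait_missing < ctrl_missing / 2

    def test_n_enriched_bounds(self):
        with pytest.raises(ValueError):
            simulate_intensity_table(5, 6)
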