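"""Generator contracts: genomes, reads, gametologues, expression."""

import numpy as np
import pytest

from neoxy.dating import pairwise_ds
from neoxy.errors import ConfigurationError
from neoxy.simulate import (
    PAR,
    X_HEMI,
    Genome,
    SimConfig,
    Stratum,
    dosage_factor,
    make_expression_truth,
    simulate_expression,
    simulate_gametologues,
    simulate_genome_pair,
    simulate_reads,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,needle",
        [
            (dict(x_length=0), "x_length"),
            (dict(autosome_lengths=(100, -1)), "autosome_lengths[1]"),
            (dict(par_segments=((0, 600_000),)), "par_segments[0]"),
            (dict(par_segments=((0, 60_000),),
                  strata=(Stratum((50_000, 100_000), 62.0),)), "overlap"),
            (dict(strata=(Stratum((50_000, 60_000), -1.0),)), "arrest"),
            (dict(y_gene_retention=1.5), "y_gene_retention"),
            (dict(syn_rate=-0.1), "syn_rate"),
            (dict(dosage_model="partial:2.5"), "partial"),
            (dict(dosage_model="sometimes"), "dosage_model"),
        ],
    )
    def test_errors_name_the_offending_field(self, kwargs, needle):
        with pytest.raises(ConfigurationError, match=None) as err:
            SimConfig(**kwargs).validate()
        assert needle.split("[")[0] in str(err.value)

    def test_dosage_factor_values(self):
        assert dosage_factor("full", "blood") == 2.0
        assert dosage_factor("none", "blood") == 1.0
        assert dosage_factor("partial:1.5", "blood") == 1.5
        assert dosage_factor({"blood": "full", "default": "none"}, "brain") == 1.0


class TestGenomePair:
    def test_published_degeneration_regime(self):
        # 287 ancestral genes with retention tuned to 13 surviving Y copies
        cfg = SimConfig(
            autosome_lengths=(50_000,),
            x_length=120_000,
            par_segments=(),
            strata=(Stratum((0, 120_000), 62.0),),
            n_genes=287,
            n_codons_per_gene=100,
            y_gene_retention=13 / 287,
            seed=5,
        )
        male, _, truth = simulate_genome_pair(cfg)
        assert int((truth.genes["y_copy"] == "retained").sum()) == 13

    def test_all_par_x_means_identical_y(self, small_sim):
        cfg = SimConfig(
            autosome_lengths=(50_000,), x_length=60_000,
            par_segments=((0, 60_000),), strata=(), n_genes=6, seed=2,
        )
        male, female, truth = simulate_genome_pair(cfg)
        assert male.sequences["Y"] == male.sequences["X"]
        assert truth.label_window("X", 0, 60_000) == PAR
        assert truth.y_transcript_ids == set()

    def test_same_seed_reproduces_everything(self):
        cfg = SimConfig(autosome_lengths=(60_000,), x_length=60_000,
                        par_segments=((0, 6_000),),
                        strata=(Stratum((6_000, 60_000), 40.0),),
                        n_genes=8, seed=9)
        m1, f1, t1 = simulate_genome_pair(cfg)
        m2, f2, t2 = simulate_genome_pair(cfg)
        assert m1.sequences == m2.sequences
        assert f1.sequences == f2.sequences
        assert t1.genes.equals(t2.genes)

    def test_female_is_autosomes_plus_two_x(self, small_sim):
        female = small_sim["female"]
        assert "Y" not in female.sequences
        assert female.ploidy["X"] == 2

    def test_every_gene_has_exactly_one_label(self, small_sim):
        genes = small_sim["truth"].genes
        assert genes["label"].isin(["AUTOSOMAL", PAR, X_HEMI]).all()
        assert genes["gene_id"].is_unique

    def test_y_transcripts_are_retained_y_genes(self, small_sim):
        truth = small_sim["truth"]
        retained = {f"{g}_Y" for g in
                    truth.genes[truth.genes["y_copy"] == "retained"]["gene_id"]}
        assert truth.y_transcript_ids <= retained

    def test_truth_round_trips_through_json_dict(self, small_sim):
        truth = small_sim["truth"]
        restored = type(truth).from_dict(truth.to_dict())
        assert restored.y_transcript_ids == truth.y_transcript_ids
        assert restored.label_window("X", 0, 10_000) == truth.label_window("X", 0, 10_000)


class TestReads:
    def test_read_count_arithmetic(self):
        genome = Genome("g", {"chr": "ACGT" * 250_000}, {"chr": 1})
        reads = simulate_reads(genome, depth=6.0, read_length=100, seed=0)
        assert len(reads) == 60_000

    def test_depth_conservation_within_one_percent(self):
        genome = Genome("g", {"chr": "ACGT" * 250_000}, {"chr": 1})
        reads = simulate_reads(genome, depth=6.0, read_length=100, seed=1)
        total_bases = sum(len(r.seq) for r in reads)
        assert total_bases / 1_000_000 == pytest.approx(6.0, rel=0.01)

    def test_read_length_longer_than_sequence_is_an_error(self):
        genome = Genome("g", {"chr": "ACGT" * 10}, {"chr": 1})
        with pytest.raises(ConfigurationError):
            simulate_reads(genome, depth=1.0, read_length=100, seed=0)

    def test_empty_genome_is_an_error(self):
        with pytest.raises(ConfigurationError):
            simulate_reads(Genome("g", {}, {}), depth=1.0, read_length=50, seed=0)

    def test_same_seed_same_reads(self):
        genome = Genome("g", {"chr": "ACGTAACCGGTT" * 100}, {"chr": 2})
        r1 = simulate_reads(genome, 2.0, 50, seed=3)
        r2 = simulate_reads(genome, 2.0, 50, seed=3)
        assert [(r.id, r.seq) for r in r1] == [(r.id, r.seq) for r in r2]


class TestGametologues:
    def test_arrest_zero_gives_identical_gametologues(self):
        cfg = SimConfig(strata=(Stratum((50_000, 450_000), 0.0),),
                        par_segments=((0, 50_000),), n_codons_per_gene=60)
        alns = simulate_gametologues(cfg, seed=1, n_per_stratum=(3,))
        for aln in alns:
            assert aln.sequences["X"] == aln.sequences["Y"]
            assert pairwise_ds(aln.sequences["X"], aln.sequences["Y"]) == 0.0

    def test_mean_ds_matches_closed_form_expectation(self):
        # dS expectation is 2 * rate * t; Monte-Carlo mean within 2 SE
        cfg = SimConfig(par_segments=(), strata=(Stratum((0, 500_000), 50.0),),
                        syn_rate=0.002, nonsyn_rate=0.002, n_codons_per_gene=300)
        alns = simulate_gametologues(cfg, seed=8, n_per_stratum=(200,))
        ds = np.array([pairwise_ds(a.sequences["X"], a.sequences["Y"]) for a in alns])
        se = ds.std(ddof=1) / np.sqrt(len(ds))
        assert abs(ds.mean() - 0.2) < 2 * se + 1e-3

    def test_older_stratum_has_larger_ds(self):
        cfg = SimConfig()  # strata at 62 and 20 Ma
        alns = simulate_gametologues(cfg, seed=4, n_per_stratum=(8, 8))
        mean = {
            s: np.mean([pairwise_ds(a.sequences["X"], a.sequences["Y"])
                        for a in alns if a.stratum == s])
            for s in (1, 2)
        }
        assert mean[1] > mean[2]

    def test_no_internal_stops_introduced(self):
        cfg = SimConfig(n_codons_per_gene=100)
        alns = simulate_gametologues(cfg, seed=6, n_per_stratum=(2, 2))
        for aln in alns:
            for seq in aln.sequences.values():
                codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
                assert not any(c in ("TAA", "TAG", "TGA") for c in codons)

    def test_arrest_beyond_calibration_node_is_an_error(self):
        cfg = SimConfig(strata=(Stratum((50_000, 450_000), 120.0),))
        with pytest.raises(ConfigurationError, match="arrest"):
            simulate_gametologues(cfg, seed=0)


class TestExpression:
    @pytest.mark.parametrize(
        "model,expected_median,tol",
        [("full", 0.0, 0.08), ("none", -1.0, 0.08), ("partial:1.5", -0.415, 0.08)],
    )
    def test_median_ratio_per_dosage_model(self, model, expected_median, tol):
        truth = make_expression_truth(500, 0)
        cfg = SimConfig(dosage_model=model, tissues=("blood",))
        em = simulate_expression(truth, cfg, seed=13)
        x_genes = em.genes_of_class("X")
        ratios = np.log2(em.values.loc[x_genes, "male_blood"]
                         / em.values.loc[x_genes, "female_blood"])
        assert np.median(ratios) == pytest.approx(expected_median, abs=tol)

    def test_y_rows_only_for_retained_genes(self):
        truth = make_expression_truth(20, 5, n_y=4)
        em = simulate_expression(truth, SimConfig(tissues=("blood",)), seed=2)
        y_genes = em.genes_of_class("Y")
        assert len(y_genes) == 4
        assert (em.values.loc[y_genes, "female_blood"] == 0).all()

    def test_expected_tpm_recorded_in_truth(self):
        truth = make_expression_truth(5, 2)
        cfg = SimConfig(dosage_model="none", tissues=("blood",))
        simulate_expression(truth, cfg, seed=3)
        male = truth.expected_tpm[("X_g000", "male", "blood")]
        female = truth.expected_tpm[("X_g000", "female", "blood")]
        assert male == pytest.approx(female / 2.0)

    def test_unknown_dosage_model_is_an_error(self):
        truth = make_expression_truth(5, 0)
        with pytest.raises(ConfigurationError):
            simulate_expression(truth, SimConfig(dosage_model="half"), seed=0)
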