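"""Synonymous divergence, strata assignment, branch fitting and calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import oracle_counts
from neoxy import _codon
from neoxy.dating import (

    GametologueRecord,
    bootstrap_concatenation,
    calibrate_and_date,
    classify_stratum,
    concatenate,
    ds_matrix,
    fit_branch_lengths,
    gametologue_topology,
    ng86_counts,
    pairwise_ds,
    rescale_age,
)
from neoxy.errors import (
    ConfigurationError,
    InternalStopError,
    LengthMismatchError,
    SaturationError,
)

SENSE = _codon.SENSE_CODONS


class TestPairwiseDs:
    def test_identical_sequences_give_zero(self):
        seq = "ATGGGTAAACCC"
        assert pairwise_ds(seq, seq) == 0.0

    def test_hand_computed_glycine_example(self):
        # ten GGT codons vs the same with one GGT->GGC change: every third
        # position of GGT is fourfold degenerate, so S = 10, Sd = 1, pS = 0.1
        a = "GGT" * 10
        b = "GGC" + "GGT" * 9
        s, sd = ng86_counts(a, b)
        assert s == pytest.approx(10.0)
        assert sd == pytest.approx(1.0)
        assert pairwise_ds(a, b) == pytest.approx(0.1073, abs=5e-5)

    def test_exhaustive_single_codon_pairs_match_oracle(self):
        # every sense-codon pair, compared against the brute-force oracle
        for ca in SENSE[::3]:
            for cb in SENSE:
                s, sd = ng86_counts(ca, cb)
                s_o, sd_o = oracle_counts(ca, cb)
                assert s == pytest.approx(s_o, abs=1e-9), (ca, cb)
                assert sd == pytest.approx(sd_o, abs=1e-9), (ca, cb)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(SENSE), min_size=4, max_size=4),
           st.lists(st.sampled_from(SENSE), min_size=4, max_size=4))
    def test_four_codon_alignments_match_oracle(self, codons_a, codons_b):
        a, b = "".join(codons_a), "".join(codons_b)
        s, sd = ng86_counts(a, b)
        s_o, sd_o = oracle_counts(a, b)
        assert s == pytest.approx(s_o, abs=1e-9)
        assert sd == pytest.approx(sd_o, abs=1e-9)

    def test_ambiguous_codons_excluded_pairwise(self):
        a = "GGTNNNGGT"
        b = "GGCGGGGGT"
        s, sd = ng86_counts(a, b)
        assert s == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "a,b,err",
        [
            ("GGTGG", "GGTGG", LengthMismatchError),  # not codon-sized
            ("GGTGGT", "GGT", LengthMismatchError),
            ("TAAGGT", "GGTGGT", InternalStopError),
        ],
    )
    def test_distinct_input_errors(self, a, b, err):
        with pytest.raises(err):
            pairwise_ds(a, b)

    def test_saturation_is_an_error(self):
        # fourfold-degenerate third positions shifted in every codon
        a = "GGT" * 50
        b = "GGC" * 50
        with pytest.raises(SaturationError):
            pairwise_ds(a, b)


class TestClassifyStratum:
    @pytest.mark.parametrize(
        "ds,presence,expected",
        [
            (0.42, True, 1),     # old gametologue, Y present in the outgroup
            (0.22, False, 2),    # dS above threshold but evidence overrides
            (0.05, None, 2),     # provisional threshold call
            (0.35, None, 1),
            (None, None, "unassigned"),
        ],
    )
    def test_evidence_overrides_threshold(self, ds, presence, expected):
        rec = classify_stratum(GametologueRecord("g", ds=ds, outgroup_presence=presence))
        assert rec.stratum == expected


class TestBootstrap:
    def _alignments(self):
        rng = np.random.default_rng(3)
        return [
            {t: _codon.decode_codons(_codon.random_sense_codons(20, rng))
             for t in ("X", "Y", "Out")}
            for _ in range(3)
        ]

    def test_replicates_keep_original_length_and_frame(self):
        alns = self._alignments()
        original = concatenate(alns)
        reps = bootstrap_concatenation(alns, n_rounds=10, seed=4)
        assert len(reps) == 10
        for rep in reps:
            assert set(rep) == set(original)
            for t in rep:
                assert len(rep[t]) == len(original[t])
                assert len(rep[t]) % 3 == 0

    def test_codon_columns_stay_linked_across_taxa(self):
        alns = self._alignments()
        original = concatenate(alns)
        pairs = {
            tuple(original[t][3 * i : 3 * i + 3] for t in sorted(original))
            for i in range(len(original["X"]) // 3)
        }
        rep = bootstrap_concatenation(alns, n_rounds=1, seed=5)[0]
        for i in range(len(rep["X"]) // 3):
            col = tuple(rep[t][3 * i : 3 * i + 3] for t in sorted(rep))
            assert col in pairs

    def test_fixed_seed_reproducible(self):
        alns = self._alignments()
        assert bootstrap_concatenation(alns, 5, seed=9) == bootstrap_concatenation(alns, 5, seed=9)

    def test_empty_concatenation_is_an_error(self):
        with pytest.raises(ConfigurationError):
            bootstrap_concatenation([], 10, seed=0)
        with pytest.raises(ConfigurationError):
            bootstrap_concatenation([{"X": "", "Y": ""}], 10, seed=0)


class TestBranchLengths:
    def test_two_taxa_sum_to_pairwise_distance(self):
        d = pd.DataFrame([[0.0, 0.3], [0.3, 0.0]], index=["A", "B"], columns=["A", "B"])
        tree = fit_branch_lengths("(A,B);", d)
        total = sum(e.length for e in tree.preorder_edge_iter()
                    if e.head_node is not tree.seed_node and e.length)
        assert total == pytest.approx(0.3)

    def test_additive_quartet_recovered_exactly(self):
        # distances generated additively on ((A,B),(C,D)) with known lengths
        lengths = {"A": 0.1, "B": 0.2, "C": 0.15, "D": 0.05, "internal": 0.08}
        taxa = ["A", "B", "C", "D"]
        d = pd.DataFrame(0.0, index=taxa, columns=taxa)
        paths = {
            ("A", "B"): ["A", "B"],
            ("A", "C"): ["A", "internal", "C"],
            ("A", "D"): ["A", "internal", "D"],
            ("B", "C"): ["B", "internal", "C"],
            ("B", "D"): ["B", "internal", "D"],
            ("C", "D"): ["C", "D"],
        }
        for (a, b), path in paths.items():
            d.loc[a, b] = d.loc[b, a] = sum(lengths[e] for e in path)
        tree = fit_branch_lengths("((A,B),(C,D));", d)
        fitted = tree.phylogenetic_distance_matrix()
        for t1 in tree.taxon_namespace:
            for t2 in tree.taxon_namespace:
                if t1 is t2:
                    continue
                assert fitted.patristic_distance(t1, t2) == pytest.approx(
                    d.loc[t1.label, t2.label], abs=1e-9)

    def test_missing_taxon_is_an_error(self):
        d = pd.DataFrame([[0.0, 0.3], [0.3, 0.0]], index=["A", "Z"], columns=["A", "Z"])
        with pytest.raises(ConfigurationError):
            fit_branch_lengths("(A,B);", d)

    def test_saturated_pair_error_names_the_pair(self):
        a = "GGT" * 50
        b = "GGC" * 50
        with pytest.raises(SaturationError, match="X.*Y|Y.*X"):
            ds_matrix({"X": a, "Y": b})


def _clock_matrix(xy_depth, calib_depth):
    taxa = ["Anolis_carolinensis", "X", "Y"]
    d = pd.DataFrame(0.0, index=taxa, columns=taxa)
    d.loc["X", "Y"] = d.loc["Y", "X"] = 2 * xy_depth
    for t in ("X", "Y"):
        d.loc[t, "Anolis_carolinensis"] = d.loc["Anolis_carolinensis", t] = 2 * calib_depth
    return d


class TestCalibration:
    TOPO = gametologue_topology("(Basiliscus_vittatus:85.7,Anolis_carolinensis:85.7);")

    def test_half_depth_xy_split_dates_to_half_the_calibration(self):
        tree = fit_branch_lengths(self.TOPO, _clock_matrix(0.1, 0.2))
        dated = calibrate_and_date(tree, ("X", "Anolis_carolinensis"), 88.0)
        assert dated.xy_age_ma == pytest.approx(44.0)

    def test_age_scales_linearly_with_calibration(self):
        tree = fit_branch_lengths(self.TOPO, _clock_matrix(0.13, 0.2))
        ages = [
            calibrate_and_date(tree, ("X", "Anolis_carolinensis"), c).xy_age_ma
            for c in (40.0, 80.0, 120.0)
        ]
        assert ages[1] == pytest.approx(2 * ages[0])
        assert ages[2] == pytest.approx(3 * ages[0])

    def test_ultrametric_root_to_tip_ages_equal(self):
        tree = fit_branch_lengths(self.TOPO, _clock_matrix(0.1, 0.2))
        dated = calibrate_and_date(tree, ("X", "Anolis_carolinensis"), 85.7)
        root_age = max(dated.node_ages_ma.values())
        assert root_age == pytest.approx(85.7, abs=1e-9)

    def test_recalibration_is_proportional(self):
        assert rescale_age(61.05, 85.7, 88.0) == pytest.approx(61.05 * 88.0 / 85.7)

    def test_bootstrap_ci_width_grows_as_alignment_shrinks(self):
        from neoxy.dating import date_xy_system
        from neoxy.simulate import SimConfig, Stratum, simulate_gametologues

        widths = []
        for n_codons in (1800, 600, 200):
            cfg = SimConfig(par_segments=(),
                            strata=(Stratum((0, 500_000), 62.0),),
                            n_codons_per_gene=n_codons)
            alns = simulate_gametologues(cfg, seed=41, n_per_stratum=(3,))
            dated = date_xy_system(
                [a.sequences for a in alns], self.TOPO,
                ("X", "Anolis_carolinensis"), 85.7, n_bootstrap=60, seed=42)
            widths.append(dated.ci95_ma[1] - dated.ci95_ma[0])
        assert widths[0] < widths[1] < widths[2]

    def test_summary_reports_the_estimate(self):
        tree = fit_branch_lengths(self.TOPO, _clock_matrix(0.1, 0.2))
        dated = calibrate_and_date(tree, ("X", "Anolis_carolinensis"), 88.0)
        table = dated.summary()
        assert table.loc[table["quantity"] == "xy_age_ma", "value"].iloc[0] == pytest.approx(44.0)
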