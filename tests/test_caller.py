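"""Interaction-caller contracts: filtering, assignment, null, significance."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_peaks, make_pet, pet_frame, planted_scenario
from roninloops.caller import (CallerConfig, assign_pets_to_peaks, bound_genes,
                               call_interactions, classify_anchors,
                               classify_pets, compare_interaction_sets,
                               deduplicate_pets, loops_vs_rbm, pair_counts,
                               shuffle_null)


class TestDeduplicate:
    def test_identical_pets_collapse(self):
        p = make_pet("chr1", 100, 150, "+", "chr1", 9_000, 9_050, "-")
        out, removed = deduplicate_pets(pet_frame(p, p))
        assert len(out) == 1 and removed == 1

    def test_strand_is_part_of_the_key(self):
        a = make_pet("chr1", 100, 150, "+", "chr1", 9_000, 9_050, "-")
        b = make_pet("chr1", 100, 150, "+", "chr1", 9_000, 9_050, "+")
        out, removed = deduplicate_pets(pet_frame(a, b))
        assert len(out) == 2 and removed == 0

    def test_idempotent(self):
        pets = pet_frame(
            make_pet("chr1", 100, 150, "+", "chr1", 9_000, 9_050, "-"),
            make_pet("chr1", 100, 150, "+", "chr1", 9_000, 9_050, "-"),
            make_pet("chr2", 5, 55, "-", "chr1", 700, 750, "+"))
        once, _ = deduplicate_pets(pets)
        twice, removed = deduplicate_pets(once)
        assert removed == 0
        pd.testing.assert_frame_equal(once, twice)

    def test_normalization_orders_ends(self):
        # ends swapped on input -> same PET after normalization
        a = make_pet("chr1", 9_000, 9_050, "-", "chr1", 100, 150, "+")
        b = make_pet("chr1", 100, 150, "+", "chr1", 9_000, 9_050, "-")
        out, removed = deduplicate_pets(pet_frame(a, b))
        assert len(out) == 1 and removed == 1


class TestClassify:
    def test_self_ligation_boundary_is_strict(self):
        # end-1 midpoint is 50, so midpoint spans are 3,999 and 4,000
        near = make_pet("chr1", 0, 100, "+", "chr1", 3_999, 4_099, "+")
        edge = make_pet("chr1", 0, 100, "+", "chr1", 4_000, 4_100, "+")
        out = classify_pets(pet_frame(near, edge), min_span=4_000)
        assert list(out["category"]) == ["self_ligation", "intra"]

    def test_interchromosomal(self):
        out = classify_pets(pet_frame(
            make_pet("chr1", 0, 100, "+", "chr2", 0, 100, "+")))
        assert out.loc[0, "category"] == "inter"
        assert np.isnan(out.loc[0, "span"])

    def test_output_independent_of_input_order(self):
        pets = [make_pet("chr1", i * 10_000, i * 10_000 + 100, "+",
                         "chr1", i * 10_000 + 50_000, i * 10_000 + 50_100, "-",
                         name=f"p{i}") for i in range(6)]
        a = classify_pets(pet_frame(*pets))
        b = classify_pets(pet_frame(*reversed(pets)))
        pd.testing.assert_frame_equal(a.drop(columns="name"),
                                      b.drop(columns="name"))


class TestAssign:
    peaks = make_peaks([10_000, 20_000, 40_000], [1, 1, 1], width=2000)

    def test_both_ends_in_distinct_peaks(self):
        pets = pet_frame(make_pet("chr1", 9_500, 9_600, "+",
                                  "chr1", 19_500, 19_600, "-"))
        assigned, counts, _ = assign_pets_to_peaks(pets, self.peaks)
        assert counts["n_assigned"] == 1
        assert (assigned.loc[0, "peak_a"], assigned.loc[0, "peak_b"]) == (0, 1)

    def test_one_end_outside_all_peaks_unassigned(self):
        pets = pet_frame(make_pet("chr1", 10_950, 11_050, "+",   # 50 bp inside
                                  "chr1", 30_000, 30_100, "-"))  # gap region
        assigned, counts, _ = assign_pets_to_peaks(pets, self.peaks)
        assert counts["n_unassigned"] == 1 and counts["n_assigned"] == 0

    def test_single_bp_overlap_counts(self):
        pets = pet_frame(make_pet("chr1", 8_901, 9_001, "+",     # 1 bp in peak 0
                                  "chr1", 19_500, 19_600, "-"))
        assigned, counts, _ = assign_pets_to_peaks(pets, self.peaks, min_overlap=1)
        assert counts["n_assigned"] == 1

    def test_tie_goes_to_leftmost_peak(self):
        touching = pd.DataFrame(
            [("chr1", 10_000, 12_000, 1.0, "PA"),
             ("chr1", 12_000, 14_000, 1.0, "PB"),
             ("chr1", 40_000, 42_000, 1.0, "PC")],
            columns=["chrom", "start", "end", "intensity", "peak_id"])
        # end straddles the junction with 10 bp in each touching peak
        pets = pet_frame(make_pet("chr1", 11_990, 12_010, "+",
                                  "chr1", 40_500, 40_600, "-"))
        assigned, _, peaks_sorted = assign_pets_to_peaks(pets, touching)
        assert peaks_sorted.loc[assigned.loc[0, "peak_a"], "peak_id"] == "PA"

    def test_same_peak_pets_dropped_from_pair_statistics(self):
        pets = pet_frame(make_pet("chr1", 9_200, 9_300, "+",
                                  "chr1", 10_800, 10_900, "-"))
        assigned, counts, _ = assign_pets_to_peaks(pets, self.peaks)
        assert counts["n_same_peak"] == 1 and counts["n_assigned"] == 0


class TestShuffleNull:
    def test_two_pet_null_is_the_enumerable_permutation_set(self):
        peaks = make_peaks([10_000, 20_000, 40_000, 60_000], [1, 1, 1, 1])
        pets = pet_frame(
            make_pet("chr1", 9_500, 9_600, "+", "chr1", 19_500, 19_600, "+"),
            make_pet("chr1", 39_500, 39_600, "+", "chr1", 59_500, 59_600, "+"))
        assigned, _, _ = assign_pets_to_peaks(pets, peaks)
        null_p, _ = shuffle_null(assigned, n_shuffles=2000, seed=1, fdr=0.05)
        # identity keeps pairs {01, 23}; the swap yields {03, 21}; p-values
        # are identical by symmetry (k=1, n_a=n_b=1, N=2) -> p = pmf-based
        enumerated = {round(p, 12) for p in null_p}
        assert len(enumerated) == 1
        assert null_p.size == 2 * 2000

    def test_planted_pair_beats_cutoff(self):
        pets, peaks, truth = planted_scenario(3, n_peaks=50, n_planted=1,
                                              extra=20, n_background=2_000)
        calls, log = call_interactions(pets, peaks,
                                       CallerConfig(fdr=0.01, seed=3))
        sig = calls[calls["significant"]]
        assert set(zip(sig["anchor_a"], sig["anchor_b"])) >= truth

    def test_requires_shuffles_and_pets(self):
        peaks = make_peaks([10_000, 20_000], [1, 1])
        pets = pet_frame(make_pet("chr1", 9_500, 9_600, "+",
                                  "chr1", 19_500, 19_600, "+"))
        assigned, _, _ = assign_pets_to_peaks(pets, peaks)
        with pytest.raises(ValueError):
            shuffle_null(assigned, n_shuffles=0, seed=1, fdr=0.05)
        with pytest.raises(ValueError):
            shuffle_null(assigned, n_shuffles=10, seed=1, fdr=0.05)


class TestCallInteractions:
    def test_no_pets_gives_empty_calls(self):
        peaks = make_peaks([10_000, 20_000], [1, 1])
        calls, log = call_interactions(pet_frame().reindex(
            columns=["chrom1", "start1", "end1", "strand1", "chrom2",
                     "start2", "end2", "strand2", "name"]), peaks)
        assert calls.empty

    def test_empty_peaks_warns_and_returns_empty(self, caplog):
        pets = pet_frame(make_pet("chr1", 0, 100, "+", "chr1", 9_000, 9_100, "+"))
        empty = pd.DataFrame(columns=["chrom", "start", "end", "intensity",
                                      "peak_id"])
        with caplog.at_level("WARNING"):
            calls, log = call_interactions(pets, empty)
        assert calls.empty and "empty peak set" in caplog.text

    def test_two_pet_pair_is_never_high_confidence(self):
        pets, peaks, truth = planted_scenario(5, n_peaks=60, n_planted=2,
                                              extra=2, n_background=1_000)
        calls, _ = call_interactions(pets, peaks, CallerConfig(fdr=0.05, seed=5))
        sig = calls[calls["significant"]]
        assert (sig["pet_count"] >= 3).all()
        planted_rows = calls[[tuple(x) in truth for x in
                              zip(calls["anchor_a"], calls["anchor_b"])]]
        assert not planted_rows["significant"].any()

    def test_planted_recovery_with_high_precision(self):
        pets, peaks, truth = planted_scenario(8)
        calls, _ = call_interactions(pets, peaks, CallerConfig(fdr=0.01, seed=8))
        sig = calls[calls["significant"]]
        called = set(zip(sig["anchor_a"], sig["anchor_b"]))
        assert len(called & truth) == len(truth)
        assert len(called & truth) / max(len(called), 1) >= 0.9

    def test_conservation_identity(self):
        pets, peaks, _ = planted_scenario(2, n_peaks=40, n_background=2_000)
        # add duplicates and junk categories
        extra = pd.concat([pets.iloc[:50], pets.iloc[:10]], ignore_index=True)
        all_pets = pd.concat([pets, extra], ignore_index=True)
        calls, log = call_interactions(all_pets, peaks, CallerConfig(seed=2))
        assert log["n_input"] == (log["n_duplicates_removed"]
                                  + log["n_self_ligation"] + log["n_inter"]
                                  + log["n_unassigned"] + log["n_same_peak"]
                                  + log["n_assigned"])


class TestAnchorsAndGenes:
    genes = pd.DataFrame(
        [("G0", "chr1", "+", 50_000, 70_000, True, False, 0)],
        columns=["gene_id", "chrom", "strand", "tss", "tes",
                 "housekeeping", "metabolic", "cluster_id"])

    def mk_calls(self, *anchors):
        rows = []
        for (ca, sa, ea), (cb, sb, eb) in anchors:
            rows.append((ca, sa, ea, "A", cb, sb, eb, "B", 5, 1e-4, 1e-3,
                         True, "other", abs(sb - sa)))
        return pd.DataFrame(rows, columns=[
            "chrom_a", "start_a", "end_a", "anchor_a",
            "chrom_b", "start_b", "end_b", "anchor_b",
            "pet_count", "p_value", "q_value", "significant", "category",
            "span"])

    def test_promoter_wins_dual_overlap(self):
        enhancers = pd.DataFrame([("chr1", 48_000, 52_000)],
                                 columns=["chrom", "start", "end"])
        calls = self.mk_calls((("chr1", 49_000, 51_000),
                               ("chr1", 200_000, 202_000)))
        out = classify_anchors(calls, self.genes, enhancers)
        assert out.loc[0, "anchor_a_label"] == "promoter"

    def test_promoter_window_is_half_open(self):
        # anchor starting exactly at TSS + 2,500 falls outside the window
        calls = self.mk_calls((("chr1", 52_500, 54_500),
                               ("chr1", 200_000, 202_000)))
        out = classify_anchors(calls, self.genes, promoter_window=2_500)
        assert out.loc[0, "anchor_a_label"] == "other"
        inside = self.mk_calls((("chr1", 52_499, 54_499),
                                ("chr1", 200_000, 202_000)))
        out2 = classify_anchors(inside, self.genes, promoter_window=2_500)
        assert out2.loc[0, "anchor_a_label"] == "promoter"

    def test_pp_category(self):
        genes2 = pd.concat([self.genes, pd.DataFrame(
            [("G1", "chr1", "+", 300_000, 310_000, True, False, 0)],
            columns=self.genes.columns)], ignore_index=True)
        calls = self.mk_calls((("chr1", 49_000, 51_000),
                               ("chr1", 299_000, 301_000)))
        out = classify_anchors(calls, genes2)
        assert out.loc[0, "category"] == "P-P"

    def test_bound_genes_window(self):
        covering = make_peaks([50_000], [1.0])
        assert bound_genes(covering, self.genes) == {"G0"}
        far = make_peaks([52_100], [1.0])   # nearest edge 1,100 bp from TSS
        assert bound_genes(far, self.genes, bound_window=1_000) == set()
        assert bound_genes(far.iloc[:0], self.genes) == set()


class TestCompareSets:
    def mk(self, n, chrom="chr1"):
        rows = []
        for i in range(n):
            rows.append((chrom, 10_000 + 50_000 * i, 12_000 + 50_000 * i, f"A{i}",
                         chrom, 1_000_000 + 50_000 * i, 1_002_000 + 50_000 * i,
                         f"B{i}", 4, 1e-5, 1e-4, True, "P-P", 990_000.0))
        return pd.DataFrame(rows, columns=[
            "chrom_a", "start_a", "end_a", "anchor_a",
            "chrom_b", "start_b", "end_b", "anchor_b",
            "pet_count", "p_value", "q_value", "significant", "category",
            "span"])

    def test_identical_sets_fully_retained(self):
        a = self.mk(5)
        rep = compare_interaction_sets(a, a.copy())
        assert rep["frac_retained"] == 1.0 and rep["n_gained"] == 0

    def test_disjoint_sets_nothing_retained(self):
        a = self.mk(3)
        b = self.mk(3)
        b[["start_a", "end_a", "start_b", "end_b"]] += 10_000_000
        rep = compare_interaction_sets(a, b)
        assert rep["frac_retained"] == 0.0

    def test_removing_one_of_n(self):
        a = self.mk(5)
        b = a.iloc[1:].reset_index(drop=True)
        rep = compare_interaction_sets(a, b)
        assert rep["frac_retained"] == pytest.approx(4 / 5)
        assert rep["n_lost"] == 1

    def test_disjoint_namespaces_rejected(self):
        a = self.mk(2, chrom="chr1")
        b = self.mk(2, chrom="chrX")
        with pytest.raises(ValueError):
            compare_interaction_sets(a, b)


class TestLoopsVsRbm:
    def test_positive_correlation_when_loops_track_rbm_count(self):
        """Planted loop strength proportional to promoter RBM count yields a
        positive rank correlation in >= 18 of 20 seeds."""
        from roninloops.synthetic import SyntheticConfig, simulate_pets
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_peaks = 50
            peaks = make_peaks([50_000 + 100_000 * i for i in range(n_peaks)],
                               np.ones(n_peaks))
            rbm_counts = rng.integers(1, 6, size=n_peaks)
            genes = pd.DataFrame(
                [(f"G{i}", "chr1", "+", 50_000 + 100_000 * i,
                  60_000 + 100_000 * i, True, False, 0)
                 for i in range(n_peaks)],
                columns=["gene_id", "chrom", "strand", "tss", "tes",
                         "housekeeping", "metabolic", "cluster_id"])
            motifs = pd.DataFrame(
                [("chr1", 50_000 + 100_000 * i - 81 - 15 * c,
                  50_000 + 100_000 * i - 81 - 15 * c + 15, "+", "x", f"G{i}")
                 for i in range(n_peaks) for c in range(rbm_counts[i])],
                columns=["chrom", "start", "end", "strand", "sequence",
                         "gene_id"])
            ids = peaks["peak_id"].to_numpy()
            # one planted loop per promoter, strength proportional to its
            # RBM count, partners forming a fixed permutation
            planted = []
            for i in range(n_peaks):
                j = (i + 17) % n_peaks
                a, b = sorted((i, j))
                planted.append((ids[a], ids[b], int(4 * rbm_counts[i])))
            cfg = SyntheticConfig(n_background_pets=2_000,
                                  planted_loops=tuple(planted),
                                  self_ligation_fraction=0,
                                  inter_fraction=0, duplicate_rate=0,
                                  seed=seed)
            pets, _ = simulate_pets(peaks, cfg)
            calls, _ = call_interactions(pets, peaks,
                                         CallerConfig(fdr=0.01, seed=seed))
            res = loops_vs_rbm(calls, motifs, genes)
            if res["defined"] and res["spearman_rho"] > 0 \
                    and res["spearman_p"] < 0.05:
                wins += 1
        assert wins >= 18

    def test_constant_rbm_count_flagged_undefined(self):
        genes = pd.DataFrame(
            [("G0", "chr1", "+", 50_000, 60_000, True, False, 0),
             ("G1", "chr1", "+", 150_000, 160_000, True, False, 0),
             ("G2", "chr1", "+", 250_000, 260_000, True, False, 0)],
            columns=["gene_id", "chrom", "strand", "tss", "tes",
                     "housekeeping", "metabolic", "cluster_id"])
        motifs = pd.DataFrame(
            [("chr1", t - 81, t - 66, "+", "x", g)
             for g, t in [("G0", 50_000), ("G1", 150_000), ("G2", 250_000)]],
            columns=["chrom", "start", "end", "strand", "sequence", "gene_id"])
        calls = pd.DataFrame(
            [("chr1", 49_000, 51_000, "PA", "chr1", 149_000, 151_000, "PB",
              5, 1e-6, 1e-5, True, "P-P", 100_000.0),
             ("chr1", 49_000, 51_000, "PA", "chr1", 249_000, 251_000, "PC",
              5, 1e-6, 1e-5, True, "P-P", 200_000.0)],
            columns=["chrom_a", "start_a", "end_a", "anchor_a",
                     "chrom_b", "start_b", "end_b", "anchor_b",
                     "pet_count", "p_value", "q_value", "significant",
                     "category", "span"])
        res = loops_vs_rbm(calls, motifs, genes)
        assert not res["defined"]
        assert np.isnan(res["pearson_r"])

    def test_single_promoter_emits_pair_without_correlation(self):
        genes = pd.DataFrame(
            [("G0", "chr1", "+", 50_000, 60_000, True, False, 0)],
            columns=["gene_id", "chrom", "strand", "tss", "tes",
                     "housekeeping", "metabolic", "cluster_id"])
        motifs = pd.DataFrame(
            [("chr1", 49_919, 49_934, "+", "x", "G0")] * 3,
            columns=["chrom", "start", "end", "strand", "sequence", "gene_id"])
        calls = pd.DataFrame(
            [("chr1", 49_000, 51_000, "PA", "chr1", 149_000, 151_000, "PB",
              5, 1e-6, 1e-5, True, "P-P", 100_000.0)],
            columns=["chrom_a", "start_a", "end_a", "anchor_a",
                     "chrom_b", "start_b", "end_b", "anchor_b",
                     "pet_count", "p_value", "q_value", "significant",
                     "category", "span"])
        res = loops_vs_rbm(calls, motifs, genes)
        assert len(res["table"]) == 1
        # duplicated motif interval counts once
        assert res["table"].loc[0, "rbm_count"] == 1
        assert res["table"].loc[0, "loop_degree"] == 1
        assert not res["defined"]
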