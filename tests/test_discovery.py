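import numpy as np
import pytest

from phasemotif.discovery import (
    compute_fold_scores,
    count_occurrences,
    count_presence_frequency,
    count_universe,
    discover,
    discover_per_family,
    embedded_fraction,
    enumerate_candidates,
    family_unique_motifs,
    motif_set_summary,
    per_region_counts,
    select_enriched,
)
from phasemotif.io import ProteinRecord, RegionAnnotation


def brute_force_presence_frequency(motif, sequences):
    """Character-by-character scan, independent of the production counting path."""
    presence = frequency = 0
    for seq in sequences:
        hits = 0
        for i in range(len(seq) - len(motif) + 1):
            if all(seq[i + j] == motif[j] for j in range(len(motif))):
                hits += 1
        if hits:
            presence += 1
            frequency += hits
    return presence, frequency


class TestEnumeration:
    def test_sliding_windows(self):
        assert enumerate_candidates(["GGGG"], 3, 4) == {"GGG", "GGGG"}

    def test_single_window(self):
        assert enumerate_candidates(["GSR"], 3, 3) == {"GSR"}

    def test_short_region_contributes_nothing(self):
        assert enumerate_candidates(["GS"], 3, 6) == set()

    def test_sentinel_windows_excluded(self):
        assert enumerate_candidates(["GGxGG"], 3, 3) == set()

    def test_bad_k_range(self):
        with pytest.raises(ValueError):
            enumerate_candidates(["GGG"], 0, 3)
        with pytest.raises(ValueError):
            enumerate_candidates(["GGG"], 4, 3)


class TestCounting:
    def test_overlapping_occurrences_counted(self):
        # the homorepeat pair: QQQQ occurs twice in QQQQQ
        assert count_presence_frequency("QQQQ", ["QQQQQ"]) == (1, 2)

    def test_presence_counts_sequences_once(self):
        seqs = ["AGSRA", "GSR", "GGG", "GSRGSR", "AAA"]
        assert count_presence_frequency("GSR", seqs) == (3, 4)

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(2)
        letters = list("GSPAQR")
        seqs = ["".join(rng.choice(letters, 40)) for _ in range(50)]
        for _ in range(20):
            k = int(rng.integers(3, 7))
            motif = "".join(rng.choice(letters, k))
            assert count_presence_frequency(motif, seqs) == \
                brute_force_presence_frequency(motif, seqs)

    def test_bulk_counter_agrees_with_single_motif_path(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("GSPA"), 30)) for _ in range(10)]
        presence, frequency = count_universe(seqs, range(3, 7))
        for motif in ["GSP", "GGGG", "SPAS"]:
            p, f = count_presence_frequency(motif, seqs)
            assert presence.get(motif, 0) == p
            assert frequency.get(motif, 0) == f


class TestFoldScores:
    def test_minmax_endpoints(self):
        stats = compute_fold_scores(
            ["AAA", "GGG"],
            pos_counts=({"AAA": 10, "GGG": 1}, {"AAA": 10, "GGG": 1}),
            neg_counts=({"AAA": 1, "GGG": 1}, {"AAA": 1, "GGG": 1}),
        )
        by_motif = {s.motif: s for s in stats}
        assert by_motif["AAA"].pf == 1.0
        assert by_motif["GGG"].pf == 0.0

    def test_cf_is_equal_weight_combination(self):
        stats = compute_fold_scores(
            ["AAA", "GGG", "SSS"],
            pos_counts=({"AAA": 4, "GGG": 8, "SSS": 10}, {"AAA": 10, "GGG": 2, "SSS": 12}),
            neg_counts=({"AAA": 1, "GGG": 1, "SSS": 1}, {"AAA": 1, "GGG": 1, "SSS": 1}),
        )
        for s in stats:
            assert s.cf == pytest.approx(0.5 * s.pf + 0.5 * s.ff)

    def test_denominator_floored_when_absent_from_negatives(self):
        (s,) = [
            s for s in compute_fold_scores(
                ["AAA", "GGG"],
                pos_counts=({"AAA": 7, "GGG": 1}, {"AAA": 7, "GGG": 1}),
                neg_counts=({"GGG": 2}, {"GGG": 2}),
            ) if s.motif == "AAA"
        ]
        assert s.pf_raw == 7.0
        assert s.neg_floored

    def test_degenerate_normalization_all_zero(self):
        stats = compute_fold_scores(
            ["AAA", "GGG"],
            pos_counts=({"AAA": 2, "GGG": 2}, {"AAA": 2, "GGG": 2}),
            neg_counts=({"AAA": 1, "GGG": 1}, {"AAA": 1, "GGG": 1}),
        )
        assert all(s.cf == 0.0 for s in stats)

    def test_cf_monotone_in_positive_presence(self):
        def cf_of_aaa(presence_pos):
            stats = compute_fold_scores(
                ["AAA", "GGG", "SSS"],
                pos_counts=({"AAA": presence_pos, "GGG": 8, "SSS": 2},
                            {"AAA": presence_pos, "GGG": 8, "SSS": 2}),
                neg_counts=({"AAA": 2, "GGG": 2, "SSS": 2},
                            {"AAA": 2, "GGG": 2, "SSS": 2}),
            )
            return next(s.cf for s in stats if s.motif == "AAA")

        values = [cf_of_aaa(p) for p in range(1, 12)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_frequency_at_least_presence_in_discovery(self):
        rng = np.random.default_rng(4)
        dprs = ["".join(rng.choice(list("GSPAQ"), 40)) for _ in range(20)]
        negs = ["".join(rng.choice(list("LVIAF"), 40)) for _ in range(20)]
        stats, _ = discover(dprs, negs, k_min=3, k_max=4)
        for s in stats:
            assert s.frequency_pos >= s.presence_pos >= 1
            assert s.frequency_neg >= s.presence_neg >= 0


class TestSelection:
    @staticmethod
    def _stats(cf_values):
        return compute_fold_scores(
            [f"AA{chr(67 + i)}" for i in range(len(cf_values))],
            pos_counts=({f"AA{chr(67 + i)}": v for i, v in enumerate(cf_values)},
                        {f"AA{chr(67 + i)}": v for i, v in enumerate(cf_values)}),
            neg_counts=({}, {}),
        )

    def test_threshold_is_inclusive(self):
        from phasemotif.discovery import MotifStats
        stats = [MotifStats(m, 1, 1, 0, 0, cf=cf)
                 for m, cf in [("AAA", 0.25), ("CCC", 0.20), ("DDD", 0.19)]]
        assert [s.motif for s in select_enriched(stats, 0.2)] == ["AAA", "CCC"]

    def test_zero_threshold_keeps_all(self):
        from phasemotif.discovery import MotifStats
        stats = [MotifStats("AAA", 1, 1, 0, 0, cf=0.0)]
        assert len(select_enriched(stats, 0.0)) == 1

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            select_enriched([], 1.01)


class TestSetCharacterization:
    def test_embedded_worked_pairs(self):
        frac, hosts = embedded_fraction({"QQQQ", "QQQQQ"})
        assert frac == 0.5
        assert hosts == {"QQQQ": ["QQQQQ"]}
        frac, hosts = embedded_fraction({"GRGG", "GGRGG"})
        assert "GRGG" in hosts

    def test_no_containment(self):
        frac, hosts = embedded_fraction({"AAA", "CCC"})
        assert frac == 0.0 and hosts == {}

    def test_summary_small_set(self):
        length_pct, membership = motif_set_summary({"GGG", "GGGG"})
        assert length_pct == {3: 50.0, 4: 50.0}
        assert membership == {"G": 100.0}

    def test_membership_counts_motif_once_per_residue(self):
        _, membership = motif_set_summary({"GSR"})
        assert membership == {"G": 100.0, "R": 100.0, "S": 100.0}

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            motif_set_summary(set())


class TestPerRegionCounts:
    def _regions(self):
        return [
            RegionAnnotation("P1", 0, 12, "DPR", "YSPTYSPTYSPT"),
            RegionAnnotation("P2", 0, 8, "DPR", "GGGGGGGG"),
        ]

    def test_row_per_region_with_count(self):
        rows = per_region_counts(["YSPT"], self._regions())
        assert len(rows) == 1
        assert rows[0].count == 3

    def test_counts_sum_to_frequency(self):
        regions = self._regions()
        rows = per_region_counts(["GGG"], regions)
        _, frequency = count_presence_frequency("GGG", [r.subsequence for r in regions])
        assert sum(r.count for r in rows) == frequency


class TestPerFamily:
    def test_disjoint_planted_motifs_recovered_per_family(self):
        rng = np.random.default_rng(6)

        def region(planted):
            base = "".join(rng.choice(list("GSPA"), 30))
            return base[:10] + planted + base[10 + len(planted):]

        records, regions = [], []
        for i in range(8):
            fam, motif = ("RNA-binding", "WWYWW") if i < 4 else ("hydrolase", "MCMCM")
            seq = region(motif)
            pid = f"P{i}"
            records.append(ProteinRecord(pid, seq, family=fam))
            regions.append(RegionAnnotation(pid, 0, len(seq), "DPR", seq))
        negatives = ["".join(rng.choice(list("LVIAF"), 60)) for _ in range(10)]
        per_family = discover_per_family(records, regions, negatives, k_min=5, k_max=5)
        rna = {s.motif for s in per_family["RNA-binding"]}
        hyd = {s.motif for s in per_family["hydrolase"]}
        assert "WWYWW" in rna and "WWYWW" not in hyd
        assert "MCMCM" in hyd and "MCMCM" not in rna
        unique = family_unique_motifs(per_family)
        assert "WWYWW" in unique["RNA-binding"]

    def test_single_family_matches_global_discovery(self):
        rng = np.random.default_rng(8)
        records, regions = [], []
        for i in range(5):
            seq = "".join(rng.choice(list("GSPAQ"), 40))
            records.append(ProteinRecord(f"P{i}", seq, family="structure"))
            regions.append(RegionAnnotation(f"P{i}", 0, 40, "DPR", seq))
        negatives = ["".join(rng.choice(list("LVIAF"), 40)) for _ in range(5)]
        per_family = discover_per_family(records, regions, negatives, k_min=3, k_max=4)
        _, global_selected = discover(
            [r.subsequence for r in regions], negatives, k_min=3, k_max=4)
        assert {s.motif for s in per_family["structure"]} == \
            {s.motif for s in global_selected}
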