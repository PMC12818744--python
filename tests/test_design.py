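import itertools

import numpy as np
import pytest

from phasemotif.design import (
    DesignedPeptide,
    build_peptides,
    filter_candidates,
    merge_ordered,
    pair_cooccurrence,
    rank_designs,
    score_all_trios,
    score_trio,
)
from phasemotif.params import NOT_APPLICABLE, compute_all


def spacered(*motifs, spacer="AAAA"):
    return spacer + spacer.join(motifs) + spacer


class TestPairCooccurrence:
    def test_set_intersection(self):
        regions = [spacered("WWW"), spacered("WWW", "CCC"), spacered("CCC", "WWW"),
                   spacered("CCC"), spacered()]
        assert pair_cooccurrence("WWW", "CCC", regions) == 2

    def test_disjoint_supports(self):
        assert pair_cooccurrence("WWW", "CCC", [spacered("WWW"), spacered("CCC")]) == 0

    def test_idempotent(self):
        regions = [spacered("WWW"), spacered("WWW"), spacered()]
        assert pair_cooccurrence("WWW", "WWW", regions) == 2


class TestScoreTrio:
    def test_perfect_coexistence_scores_100(self):
        regions = [spacered("GRGG", "YGGF", "DRGG") for _ in range(10)]
        score = score_trio("GRGG", "YGGF", "DRGG", regions)
        assert score.coverage == 1.0
        assert score.symmetry == 1.0
        assert score.fs == 100.0

    def test_no_cooccurrence_scores_0(self):
        regions = [spacered("GRGG"), spacered("YGGF"), spacered("DRGG")]
        assert score_trio("GRGG", "YGGF", "DRGG", regions).fs == 0.0

    def test_partial_coexistence_fixture(self):
        # 4 regions with all three; 4 with A,B only; 4 with C only:
        # n_ab=8, n_ac=n_bc=4, n_abc=4, min presence 8
        # -> coverage 0.5, symmetry 0.5, FS 50
        regions = (
            [spacered("WWW", "CCC", "MMM") for _ in range(4)]
            + [spacered("WWW", "CCC") for _ in range(4)]
            + [spacered("MMM") for _ in range(4)]
        )
        score = score_trio("WWW", "CCC", "MMM", regions)
        # pair counts follow the canonical (lexicographic) storage order
        assert sorted((score.n_ab, score.n_ac, score.n_bc)) == [4, 4, 8]
        assert score.n_abc == 4
        assert score.coverage == 0.5
        assert score.symmetry == 0.5
        assert score.fs == 50.0

    def test_invariant_under_argument_permutation(self):
        rng = np.random.default_rng(0)
        regions = ["".join(rng.choice(list("GSPARW"), 40)) for _ in range(15)]
        scores = {
            score_trio(*perm, regions).fs
            for perm in itertools.permutations(["GSP", "ARW", "SPA"])
        }
        assert len(scores) == 1

    def test_adding_triple_region_never_decreases_fs(self):
        rng = np.random.default_rng(1)
        regions = ["".join(rng.choice(list("GSPARW"), 40)) for _ in range(12)]
        before = score_trio("GSP", "ARW", "SPA", regions).fs
        after = score_trio("GSP", "ARW", "SPA",
                           regions + [spacered("GSP", "ARW", "SPA")]).fs
        assert after >= before

    def test_duplicate_motifs_rejected(self):
        with pytest.raises(ValueError):
            score_trio("GGG", "GGG", "SSS", ["GGGSSS"])


class TestScoreAllTrios:
    def test_combination_counts(self):
        regions = [spacered("WWW", "CCC", "MMM", "HHH", "FFF")]
        assert len(score_all_trios(["WWW", "CCC", "MMM"], regions)) == 1
        assert len(score_all_trios(["WWW", "CCC", "MMM", "HHH", "FFF"], regions)) == 10

    def test_planted_perfect_trio_ranks_first(self):
        rng = np.random.default_rng(2)
        noise = ["".join(rng.choice(list("GSPA"), 30)) for _ in range(10)]
        regions = [spacered("WWW", "CCC", "MMM") for _ in range(10)] + noise
        scores = score_all_trios(["WWW", "CCC", "MMM", "GSP", "PAS"], regions)
        assert set(scores[0].motifs) == {"WWW", "CCC", "MMM"}
        assert scores[0].fs == 100.0

    def test_agrees_with_single_trio_scorer(self):
        rng = np.random.default_rng(3)
        regions = ["".join(rng.choice(list("GSPARW"), 40)) for _ in range(20)]
        motifs = ["GSP", "ARW", "SPA", "RWG"]
        all_scores = {s.motifs: s.fs for s in score_all_trios(motifs, regions)}
        for trio in itertools.combinations(sorted(motifs), 3):
            assert all_scores[trio] == pytest.approx(score_trio(*trio, regions).fs)

    def test_too_few_motifs(self):
        with pytest.raises(ValueError):
            score_all_trios(["AAA", "GGG"], ["AAAGGG"])


class TestMerging:
    def test_maximal_suffix_prefix_overlap(self):
        assert merge_ordered(["GRGG", "RGGF"]) == "GRGGF"

    def test_contained_motif_skipped(self):
        assert merge_ordered(["GGRGG", "GRG"]) == "GGRGG"

    def test_trio_minimal_superstring(self):
        candidates = build_peptides(("FGGG", "RGGF", "GGDRGG"))
        minimal = candidates[0]
        assert minimal.is_minimal
        assert minimal.sequence == "FGGGDRGGF"
        assert len(minimal.sequence) == 9
        for motif in ("FGGG", "RGGF", "GGDRGG"):
            assert motif in minimal.sequence

    def test_substring_redundancy_dropped(self):
        candidates = build_peptides(("QQQ", "QQQQ", "GGG"))
        for cand in candidates:
            assert "QQQQ" in cand.sequence and "GGG" in cand.sequence
        # built from the two survivors only: QQQQ+GGG in both orders
        assert {c.sequence for c in candidates} == {"QQQQGGG", "GGGQQQQ"}

    def test_every_candidate_contains_all_motifs_under_20(self):
        rng = np.random.default_rng(4)
        letters = list("GRSPY")
        for _ in range(20):
            trio = tuple("".join(rng.choice(letters, int(rng.integers(3, 7))))
                         for _ in range(3))
            if len(set(trio)) < 3:
                continue
            for cand in build_peptides(trio):
                assert len(cand.sequence) < 20
                for motif in trio:
                    assert motif in cand.sequence


class TestFilterAndRank:
    def test_mid_range_passes(self):
        (cand,) = filter_candidates([DesignedPeptide("GRGGSGGDRGG", ("A",) * 3, ("A",))])
        assert cand.passes_filter and cand.filter_failures == []

    def test_failure_listed_by_name(self):
        # all-Leu peptide: hydropathy and disorder fraction both out of range
        (cand,) = filter_candidates([DesignedPeptide("LLLLLLLLLL", ("A",) * 3, ("A",))])
        assert not cand.passes_filter
        assert "disorder_fraction" in cand.filter_failures
        assert "mean_hydropathy" in cand.filter_failures

    def test_kappa_na_policy(self):
        uncharged = DesignedPeptide("GGGGSSGGGG", ("A",) * 3, ("A",))
        (cand,) = filter_candidates([uncharged], kappa_na_policy="pass")
        assert cand.params.kappa is NOT_APPLICABLE
        assert "kappa" not in cand.filter_failures
        (cand,) = filter_candidates(
            [DesignedPeptide("GGGGSSGGGG", ("A",) * 3, ("A",))],
            kappa_na_policy="fail")
        assert "kappa" in cand.filter_failures

    def test_malformed_range_rejected(self):
        with pytest.raises(ValueError):
            filter_candidates([], ranges={"fcr": (0.7, 0.0)})

    def test_rank_passing_first_then_fs_then_length(self):
        def peptide(seq, fs, passes):
            cand = DesignedPeptide(seq, ("A",) * 3, ("A",), fs=fs)
            cand.params = compute_all(seq)
            cand.passes_filter = passes
            return cand

        ranked = rank_designs([
            peptide("GGGGSSGGGGSSGG", 61.26, True),
            peptide("GRGGSGGDRG", 74.0, True),
            peptide("GGGGSSGGGG", 74.0, True),
            peptide("LLLLLLLLLL", 99.0, False),
        ])
        assert [p.fs for p in ranked[:3]] == [74.0, 74.0, 61.26]
        assert len(ranked[0].sequence) <= len(ranked[1].sequence)
        assert ranked[-1].passes_filter is False
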