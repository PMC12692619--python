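"""k-of-n residue-overlap consensus and the packaged allergen fixtures."""

import numpy as np
import pytest

from allermap.consensus import (
    ConsensusConfig,
    ToolPrediction,
    consensus_regions,
    extract_peptides,
    residue_support,
)
from allermap.fixtures import (
    ALLERGENS,
    CORRECTIONS,
    fixture_length,
    is_rule_consistent,
    load_fixture,
)
from allermap.seqio import ProteinRecord


def support_oracle(predictions, length):
    """Independent per-residue counting using sets."""
    counts = []
    for pos in range(1, length + 1):
        tools = {p.tool for p in predictions
                 if any(s <= pos <= e for s, e in p.intervals)}
        counts.append(len(tools))
    return counts


def regions_oracle(predictions, k, min_len, length):
    counts = support_oracle(predictions, length)
    regions, start = [], None
    for pos in range(1, length + 2):
        ok = pos <= length and counts[pos - 1] >= k
        if ok and start is None:
            start = pos
        elif not ok and start is not None:
            if pos - start >= min_len:
                regions.append((start, pos - 1))
            start = None
    return regions


def random_instance(rng):
    length = int(rng.integers(20, 201))
    n_tools = int(rng.integers(1, 5))
    preds = []
    for t in range(n_tools):
        intervals = []
        for _ in range(rng.integers(0, 8)):
            s = int(rng.integers(1, length + 1))
            e = min(length, s + int(rng.integers(0, 30)))
            intervals.append((s, e))
        preds.append(ToolPrediction(f"tool-{t}", intervals))
    return preds, length


class TestResidueSupport:
    def test_single_tool_counts(self):
        counts = residue_support([ToolPrediction("a", [(1, 3)])], 5)
        assert counts.tolist() == [1, 1, 1, 0, 0]

    def test_two_tools_same_interval(self):
        preds = [ToolPrediction("a", [(2, 4)]), ToolPrediction("b", [(2, 4)])]
        assert residue_support(preds, 5).tolist() == [0, 2, 2, 2, 0]

    def test_duplicate_coverage_within_one_tool_counts_once(self):
        counts = residue_support([ToolPrediction("a", [(1, 3), (2, 5)])], 6)
        assert counts.tolist() == [1, 1, 1, 1, 1, 0]

    def test_out_of_bounds_names_tool_and_interval(self):
        with pytest.raises(ValueError, match=r"bepi.*9"):
            residue_support([ToolPrediction("bepi", [(4, 9)])], 6)


class TestConsensusRegions:
    def test_worked_example_common_segment(self):
        # residues 1..8 labelled so positions 3..7 spell CDEFG
        seq = ProteinRecord("labels", "AACDEFGH")
        preds = [ToolPrediction("A", [(1, 7)]), ToolPrediction("B", [(3, 8)])]
        config = ConsensusConfig(k=2, n=2, min_len=5)
        (region,) = consensus_regions(preds, config, 8, sequence=seq)
        assert region.as_tuple() == (3, 7)
        assert region.peptide == "CDEFG"

    def test_disjoint_single_tool_intervals_give_nothing(self):
        preds = [ToolPrediction("a", [(1, 10)]), ToolPrediction("b", [(20, 30)]),
                 ToolPrediction("c", [])]
        assert consensus_regions(preds, ConsensusConfig(), 40) == []

    def test_matches_counting_oracle_on_random_instances(self):
        rng = np.random.default_rng(99)
        config = ConsensusConfig(k=2, n=4, min_len=5)
        for _ in range(300):
            preds, length = random_instance(rng)
            got = [r.as_tuple() for r in consensus_regions(preds, config, length)]
            assert got == regions_oracle(preds, config.k, config.min_len, length)

    def test_tool_permutation_invariance(self):
        rng = np.random.default_rng(17)
        preds, length = random_instance(rng)
        config = ConsensusConfig(k=2, n=4, min_len=3)
        base = [r.as_tuple() for r in consensus_regions(preds, config, length)]
        for _ in range(5):
            rng.shuffle(preds)
            assert [r.as_tuple()
                    for r in consensus_regions(preds, config, length)] == base

    def test_splitting_a_tool_interval_into_abutting_parts_is_neutral(self):
        whole = [ToolPrediction("a", [(5, 20)]), ToolPrediction("b", [(10, 25)])]
        split = [ToolPrediction("a", [(5, 12), (13, 20)]),
                 ToolPrediction("b", [(10, 25)])]
        config = ConsensusConfig(k=2, n=2, min_len=5)
        assert ([r.as_tuple() for r in consensus_regions(whole, config, 30)]
                == [r.as_tuple() for r in consensus_regions(split, config, 30)])

    def test_k1_minlen1_reduces_to_sorted_union(self):
        preds = [ToolPrediction("a", [(8, 12), (1, 3)]),
                 ToolPrediction("b", [(2, 5)])]
        config = ConsensusConfig(k=1, n=2, min_len=1)
        got = [r.as_tuple() for r in consensus_regions(preds, config, 15)]
        assert got == [(1, 5), (8, 12)]

    def test_every_region_satisfies_invariants(self):
        rng = np.random.default_rng(31)
        config = ConsensusConfig(k=2, n=4, min_len=5)
        for _ in range(50):
            preds, length = random_instance(rng)
            support = residue_support(preds, length)
            for region in consensus_regions(preds, config, length):
                assert len(region) >= config.min_len
                assert (support[region.start - 1 : region.end] >= config.k).all()
                assert region.support  # at least one covering tool recorded


class TestExtractPeptides:
    def test_interval_to_peptide(self):
        seq = ProteinRecord("labels", "AACDEFGH")
        assert extract_peptides(seq, [(3, 7)]) == [((3, 7), "CDEFG")]

    def test_single_residue_interval(self):
        seq = ProteinRecord("p", "MKV")
        assert extract_peptides(seq, [(1, 1)]) == [((1, 1), "M")]

    def test_beyond_length_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            extract_peptides(ProteinRecord("p", "MKV"), [(2, 9)])


class TestFixtures:
    def test_ses_i_2_tables_as_printed(self):
        preds, expected, corrections = load_fixture("Ses i 2")
        by_tool = {p.tool: p.intervals for p in preds}
        assert by_tool["fixture:dnastar"] == (
            (38, 40), (61, 64), (76, 76), (78, 79), (111, 113), (139, 139))
        assert corrections == []
        assert expected == [(75, 79)]

    def test_ses_i_1_correction_applied_and_logged(self):
        preds, _, corrections = load_fixture("Ses i 1")
        assert [c.printed_value for c in corrections] == ["5~52"]
        dnastar = {p.tool: p.intervals for p in preds}["fixture:dnastar"]
        assert (50, 52) in dnastar
        assert (5, 52) not in dnastar

    def test_ses_i_7_position_typo_corrected(self):
        preds, _, corrections = load_fixture("Ses i 7")
        assert [c.printed_value for c in corrections] == ["4576~459"]
        bepi = {p.tool: p.intervals for p in preds}["fixture:bepipred"]
        assert (457, 459) in bepi

    def test_ses_i_5_expected_consensus_row(self):
        _, expected, _ = load_fixture("Ses i 5")
        assert expected == [(5, 13), (103, 110), (132, 145)]

    def test_unknown_allergen_rejected(self):
        with pytest.raises(ValueError, match="unknown allergen"):
            load_fixture("Ses i 9")

    def test_rule_consistency_flags_match_recomputation(self):
        config = ConsensusConfig(k=2, n=3, min_len=5)
        for name in ALLERGENS:
            preds, expected, _ = load_fixture(name)
            got = [r.as_tuple()
                   for r in consensus_regions(preds, config,
                                              fixture_length(name))]
            assert (got == expected) == is_rule_consistent(name)

    def test_all_corrections_are_test_visible(self):
        assert {(c.allergen, c.printed_value) for c in CORRECTIONS} == {
            ("Ses i 1", "5~52"), ("Ses i 7", "4576~459")}
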