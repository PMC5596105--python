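"""Tag mapping, locus calling, duplex validation and guide/star rules."""

import numpy as np
import pandas as pd
import pytest

from sporomir.discovery import (
    assign_guide_star,
    call_loci,
    dedupe_and_name,
    extract_windows,
    map_tags,
    modal_tag,
    prepare_mappings,
    validate_duplex,
)
from sporomir.annotate import ReferenceMature
from sporomir.fold import fold
from sporomir.sequences import random_seq, revcomp


def brute_force_map(tag, loci, max_mm=2):
    """All-positions Hamming scan over both strands of every locus."""
    out = set()
    for lid, seq in loci.items():
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for i in range(len(s) - len(tag) + 1):
                mm = sum(a != b for a, b in zip(tag, s[i : i + len(tag)]))
                if mm <= max_mm:
                    out.add((lid, strand, i, mm))
    return out


def test_exact_substring_maps_once(rng):
    locus = random_seq(rng, 300)
    tag = locus[100:121]
    df = map_tags([tag], {"L1": locus})
    plus = df[df.strand == "+"]
    assert len(plus) == 1
    assert (plus.iloc[0].start, plus.iloc[0].n_mismatches) == (100, 0)


def test_three_mismatches_do_not_map():
    locus = "AGGCTTACGATCCGTAACGTC"
    tag = "AGGATTACGCTCCGTGACGTC"  # Hamming 3
    assert len(map_tags([tag], {"L1": locus})) == 0


def test_mapping_equals_brute_force_scan(rng):
    """Pigeonhole seed mapping == all-positions Hamming scan."""
    locus = random_seq(rng, 500)
    loci = {"L1": locus}
    tags = []
    for i in range(20):
        if i % 2 == 0:
            tags.append(random_seq(rng, int(rng.integers(19, 28))))
        else:
            start = int(rng.integers(0, 470))
            sub = list(locus[start : start + 21])
            for _ in range(int(rng.integers(0, 3))):
                p = int(rng.integers(21))
                sub[p] = "ACGT"[int(rng.integers(4))]
            seq = "".join(sub)
            tags.append(seq if i % 4 == 1 else revcomp(seq))
    df = map_tags(tags, loci)
    got = {
        (t.tag, t.locus, t.strand, int(t.start_local), int(t.n_mismatches))
        for t in df.itertuples(index=False)
    }
    expected = set()
    for tag in set(tags):
        for lid, strand, i, mm in brute_force_map(tag, loci):
            expected.add((tag, lid, strand, i, mm))
    assert got == expected


class TestCallLoci:
    def _mappings(self, total):
        tags = pd.Series({"A" * 21: total})
        m = pd.DataFrame(
            {
                "tag": ["A" * 21],
                "locus": ["L1"],
                "strand": ["+"],
                "start": [50],
                "start_local": [50],
                "n_mismatches": [0],
                "n_placements": [1],
            }
        )
        return m, tags

    def test_locus_threshold_is_at_least_100(self):
        m, tags = self._mappings(99)
        assert call_loci(m, tags) == []
        m, tags = self._mappings(100)
        assert len(call_loci(m, tags)) == 1

    def test_distant_stacks_stay_separate(self):
        tags = pd.Series({"A" * 21: 200, "C" * 21: 200})
        m = pd.DataFrame(
            {
                "tag": ["A" * 21, "C" * 21],
                "locus": ["L1", "L1"],
                "strand": ["+", "+"],
                "start": [10, 510],
                "start_local": [10, 510],
                "n_mismatches": [0, 0],
                "n_placements": [1, 1],
            }
        )
        out = call_loci(m, tags)
        assert len(out) == 2

    def test_multi_mapping_counts_fractionally(self):
        tags = pd.Series({"A" * 21: 150})
        m = pd.DataFrame(
            {
                "tag": ["A" * 21] * 2,
                "locus": ["L1", "L2"],
                "strand": ["+", "+"],
                "start": [10, 20],
                "start_local": [10, 20],
                "n_mismatches": [0, 0],
                "n_placements": [2, 2],
            }
        )
        # 150 reads over two placements: 75 each, below the threshold
        assert call_loci(m, tags) == []

    def test_lowering_threshold_never_removes_loci(self, small_run):
        _, _, result = small_run
        totals = result.tags.sum(axis=1)
        accepted_100 = result.discovery.accepted_loci
        prepared = pd.concat([s.tags for s in accepted_100], ignore_index=True)
        keys_100 = {(s.locus_id, s.strand, s.start) for s in accepted_100}
        accepted_50 = call_loci(prepared, totals, min_reads=50)
        keys_50 = {(s.locus_id, s.strand, s.start) for s in accepted_50}
        assert keys_100 <= keys_50


class TestExtractWindows:
    def test_centered_window_length(self):
        seq = "A" * 1000
        ws, we, trunc = next(extract_windows(seq, 500, 521, flanks=(100,)))
        assert (ws, we) == (400, 621)
        assert we - ws == 2 * 100 + 21
        assert not trunc

    def test_truncation_at_locus_bounds_is_flagged(self):
        seq = "A" * 200
        ws, we, trunc = next(extract_windows(seq, 30, 51, flanks=(80,)))
        assert (ws, we) == (0, 131)
        assert trunc

    def test_growth_stops_when_saturated(self):
        seq = "A" * 100
        wins = list(extract_windows(seq, 40, 61, flanks=(80, 100, 120)))
        assert len(wins) == 1  # already the whole locus at the first flank


def perfect_hairpin(m=21, loop=8, rng=None):
    rng = rng or np.random.default_rng(0)
    arm = random_seq(rng, m)
    loop_seq = "C" * loop
    return arm + loop_seq + revcomp(arm), arm


class TestValidateDuplex:
    def test_perfect_hairpin_guide_on_5p_arm_passes(self):
        hp_seq, arm = perfect_hairpin()
        d = validate_duplex(fold(hp_seq), 0, len(arm))
        assert d.passed
        assert d.n_unpaired == 0
        assert d.n_bulged == 0
        assert d.arm == "5p"

    def test_guide_centered_on_terminal_loop_fails(self):
        hp_seq, arm = perfect_hairpin(m=21, loop=8)
        # a 21-nt "guide" straddling the loop pairs within itself
        mid = len(hp_seq) // 2
        d = validate_duplex(fold(hp_seq), mid - 10, mid + 11)
        assert not d.passed

    def test_guide_outside_window_is_contract_violation(self):
        hp_seq, arm = perfect_hairpin()
        with pytest.raises(ValueError):
            validate_duplex(fold(hp_seq), 0, len(hp_seq) + 5)

    @pytest.mark.parametrize("n_mm,expected", [(3, True), (6, False)])
    def test_designed_mismatch_budget(self, n_mm, expected, rng):
        # G/C-only arms with A-A designed mismatches: the mismatched bases
        # cannot pair anywhere in the hairpin
        m = 21
        arm = "".join(rng.choice(["G", "C"], size=m))
        partner = list(revcomp(arm))
        positions = np.linspace(2, m - 3, n_mm).astype(int)
        arm_l = list(arm)
        for p in positions:
            arm_l[p] = "A"
            partner[m - 1 - p] = "A"
        hp_seq = "".join(arm_l) + "C" * 8 + "".join(partner)
        d = validate_duplex(fold(hp_seq), 0, m)
        assert d.passed == expected


class TestAssignGuideStar:
    def _setup(self, star_offset=0):
        rng = np.random.default_rng(1)
        m = 21
        arm = random_seq(rng, m)
        pad = "AAAAAA"
        window = pad + arm + "C" * 10 + revcomp(arm) + pad
        hp = fold(window)
        duplex = validate_duplex(hp, len(pad), len(pad) + m)
        assert duplex.passed
        ideal_s = duplex.min_partner
        ideal_e = duplex.max_partner + 3
        star_seq = window[ideal_s + star_offset : ideal_e + star_offset]
        rows = pd.DataFrame(
            {
                "tag": [arm, star_seq],
                "start_local": [len(pad), ideal_s + star_offset],
                "total": [500.0, 120.0],
                "tag_len": [m, len(star_seq)],
            }
        )
        guide_row = rows.iloc[0]
        return rows, hp, guide_row, duplex

    def test_higher_frequency_tag_is_guide(self):
        rows, hp, guide_row, duplex = self._setup()
        cand = assign_guide_star(rows, hp, 0, guide_row, duplex, "L1", "+", len(hp.sequence))
        assert cand.guide_count == 500.0
        assert cand.star_count == 120.0
        assert cand.guide_count >= cand.star_count

    @pytest.mark.parametrize("offset,accepted", [(6, True), (7, False)])
    def test_star_shift_boundary(self, offset, accepted):
        rows, hp, guide_row, duplex = self._setup(star_offset=offset)
        cand = assign_guide_star(rows, hp, 0, guide_row, duplex, "L1", "+", len(hp.sequence))
        assert cand.star_observed == accepted

    def test_missing_star_emits_theoretical_sequence(self):
        rows, hp, guide_row, duplex = self._setup()
        rows = rows.iloc[[0]]
        cand = assign_guide_star(rows, hp, 0, guide_row, duplex, "L1", "+", len(hp.sequence))
        assert not cand.star_observed
        assert cand.star_count == 0
        assert len(cand.star_seq) >= 19

    def test_role_swap_when_opposite_arm_dominates(self):
        rows, hp, guide_row, duplex = self._setup()
        rows.loc[1, "total"] = 900.0  # the "star" tag is the abundant strand
        cand = assign_guide_star(rows, hp, 0, guide_row, duplex, "L1", "+", len(hp.sequence))
        assert cand.guide_count == 900.0
        assert cand.star_count == 500.0


class TestDedupeAndName:
    def _candidate(self, guide, arm="5p", count=100.0, locus="L1"):
        from sporomir.discovery import DuplexStats, MirnaCandidate

        return MirnaCandidate(
            guide_seq=guide, guide_arm=arm, guide_count=count,
            star_seq="", star_count=0, star_shift=0, star_observed=False,
            locus_id=locus, strand="+", window_start=0, window_end=100,
            precursor="A" * 100, structure="." * 100,
            duplex=DuplexStats(True, ""),
        )

    def test_reference_guides_are_not_novel(self, rng):
        seq = random_seq(rng, 21)
        refs = [ReferenceMature("ref1", "miR166", seq)]
        novel, conserved = dedupe_and_name(
            [self._candidate(seq), self._candidate(random_seq(rng, 21))], refs
        )
        assert len(novel) == 1
        assert len(conserved) == 1
        assert conserved[0][1].ref_id == "ref1"
        assert all(c.guide_seq != seq for c in novel)

    def test_shared_guide_collapses_with_precursor_list(self, rng):
        seq = random_seq(rng, 21)
        novel, _ = dedupe_and_name(
            [self._candidate(seq, locus="L1"), self._candidate(seq, locus="L2")], []
        )
        assert len(novel) == 1
        assert len(novel[0].precursors) == 2

    def test_novel_names_are_serial(self, rng):
        cands = [self._candidate(random_seq(rng, 21), count=c) for c in (50, 500)]
        novel, _ = dedupe_and_name(cands, [])
        assert [c.name for c in novel] == ["Pab-miRn1_5p", "Pab-miRn2_5p"]
        assert novel[0].guide_count == 500  # most abundant first


def test_novel_set_disjoint_from_planted_conserved(small_run):
    _, sim, result = small_run
    conserved_guides = {
        l.guide_seq for l in sim.truth.loci if l.conserved
    }
    novel_guides = {c.guide_seq for c in result.discovery.novel}
    assert not (novel_guides & conserved_guides)


def test_all_candidates_respect_duplex_limits(small_run):
    """Post-hoc sweep: every accepted candidate re-validates."""
    _, _, result = small_run
    for cand in result.discovery.candidates:
        d = cand.duplex
        assert d.passed
        assert d.n_paired >= 14
        assert d.n_unpaired <= 5
        assert d.n_bulged <= 3
        assert cand.guide_count >= cand.star_count
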