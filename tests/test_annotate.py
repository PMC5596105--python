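"""Conserved matching against brute force, and isomiR classification."""

import numpy as np
import pandas as pd
import pytest

from sporomir.annotate import (
    ConservedHit,
    ReferenceMature,
    classify_isomir,
    family_census,
    match_conserved,
    match_tags,
)
from sporomir.sequences import random_seq


def brute_force_best(tag, references, max_subs=2, max_off=4, min_overlap=17):
    """Exhaustive scan over every reference x offset placement."""
    best = None
    for ref in references:
        lr, lt = len(ref.sequence), len(tag)
        for d in range(-max_off, max_off + 1):
            o5, o3 = -d, d + lt - lr
            if abs(o5) > max_off or abs(o3) > max_off:
                continue
            lo, hi = max(d, 0), min(d + lt, lr)
            if hi - lo < min_overlap:
                continue
            subs = sum(tag[p - d] != ref.sequence[p] for p in range(lo, hi))
            if subs > max_subs:
                continue
            key = (subs, abs(o5) + abs(o3), ref.id)
            if best is None or key < best[0]:
                best = (key, ConservedHit(tag, ref.id, ref.family, subs, o5, o3))
    return None if best is None else best[1]


@pytest.fixture
def refs(rng):
    return [
        ReferenceMature(f"ref{i:02d}", f"fam{i % 7}", random_seq(rng, int(rng.integers(19, 25))))
        for i in range(50)
    ]


def test_identical_tag_hits_with_zero_offsets(refs):
    hit = match_conserved(refs[0].sequence, refs)
    assert hit is not None
    assert (hit.n_substitutions, hit.offset_5p, hit.offset_3p) == (0, 0, 0)


def test_three_mismatches_everywhere_is_no_hit():
    ref = ReferenceMature("r1", "famX", "AGGCTTACGATCCGTAACGTC")
    tag = "AGGATTACGCTCCGTGACGTC"  # Hamming distance 3; no offset rescues it
    assert sum(a != b for a, b in zip(tag, ref.sequence)) == 3
    assert brute_force_best(tag, [ref]) is None
    assert match_conserved(tag, [ref]) is None


def test_two_substitutions_found_and_counted():
    ref = ReferenceMature("r1", "famX", "ACGTACGTACGTACGTACGTA")
    tag = list(ref.sequence)
    tag[5] = "A" if tag[5] != "A" else "C"
    tag[11] = "A" if tag[11] != "A" else "C"
    tag = "".join(tag)
    hit = match_conserved(tag, [ref])
    assert hit.n_substitutions == 2
    assert hit == brute_force_best(tag, [ref])


def test_matcher_equals_brute_force_on_random_instances(refs, rng):
    """Sliding-window matcher == exhaustive placement scan, 50 x 50."""
    tags = []
    for i in range(50):
        if i % 2 == 0:
            tags.append(random_seq(rng, int(rng.integers(19, 28))))
        else:  # perturbed copies of references: trims, extensions, subs
            base = refs[int(rng.integers(len(refs)))].sequence
            tag = list(base)
            for _ in range(int(rng.integers(0, 4))):
                p = int(rng.integers(len(tag)))
                tag[p] = "ACGT"[int(rng.integers(4))]
            tag = "".join(tag)
            cut = int(rng.integers(0, 3))
            tag = tag[cut:] + random_seq(rng, int(rng.integers(0, 3)))
            if len(tag) < 19:
                tag = tag + random_seq(rng, 19 - len(tag))
            tags.append(tag)
    bulk = match_tags(tags, refs).set_index("tag")
    for tag in tags:
        expected = brute_force_best(tag, refs)
        got = match_conserved(tag, refs)
        if expected is None:
            assert got is None
            assert tag not in bulk.index
        else:
            assert got == expected
            row = bulk.loc[tag]
            assert (
                row.ref_id, row.n_substitutions, row.offset_5p, row.offset_3p
            ) == (
                expected.ref_id,
                expected.n_substitutions,
                expected.offset_5p,
                expected.offset_3p,
            )


class TestIsomirClassification:
    # a non-repetitive mature: no alternative offset can beat the intended
    # placement
    ref = ReferenceMature(
        "r1", "miR166", "AGGCTTACGATCCGTAACGTC", flank5="TTTTTTTTGG", flank3="GCACGTACGT"
    )

    def test_exact_tag_is_canonical(self):
        hit = match_conserved(self.ref.sequence, [self.ref])
        call = classify_isomir(hit, self.ref)
        assert call.classes == frozenset({"canonical"})

    def test_canonical_call_is_idempotent(self):
        hit = match_conserved(self.ref.sequence, [self.ref])
        for _ in range(2):
            assert classify_isomir(hit, self.ref).classes == frozenset({"canonical"})

    def test_three_prime_u_tail_against_non_u_genome(self):
        # appended T where the genomic downstream base is G -> nontemplated U
        tag = self.ref.sequence + "T"
        call = classify_isomir(match_conserved(tag, [self.ref]), self.ref)
        assert call.classes == frozenset({"tail3_U"})

    def test_three_prime_templated_extension(self):
        tag = self.ref.sequence + self.ref.flank3[:2]
        call = classify_isomir(match_conserved(tag, [self.ref]), self.ref)
        assert call.classes == frozenset({"ext3_templated"})

    def test_five_prime_trim(self):
        tag = self.ref.sequence[2:]
        call = classify_isomir(match_conserved(tag, [self.ref]), self.ref)
        assert call.classes == frozenset({"trim5"})

    def test_trim_with_a_tail(self):
        tag = self.ref.sequence[:-3] + "AA"
        call = classify_isomir(match_conserved(tag, [self.ref]), self.ref)
        # best placement: 3-nt trim then a nontemplated AA reads as a 1-nt
        # trim with offsets, classified from the signed end offsets
        assert call.classes & {"tail3_A", "trim3", "substitution"}

    def test_extension_without_context_reports_template_unknown(self):
        bare = ReferenceMature("r1", "miR166", self.ref.sequence)
        tag = self.ref.sequence + "G"
        call = classify_isomir(match_conserved(tag, [bare]), bare)
        assert "template-unknown" in call.detail


def test_family_census_counts_distinct_tags():
    hits = pd.DataFrame(
        {
            "tag": ["A" * 21, "C" * 21, "G" * 21],
            "ref_id": ["r1", "r1", "r2"],
            "family": ["miR166", "miR166", "miR166"],
            "n_substitutions": [0, 1, 0],
            "offset_5p": [0, 0, 0],
            "offset_3p": [0, 0, 0],
        }
    )
    census = family_census(hits)
    assert census["miR166"] == 3


def test_family_census_empty():
    assert len(family_census(pd.DataFrame(columns=["tag", "family"]))) == 0


def test_census_matches_planted_families_without_variation(tmp_path):
    """With no isomiRs and no sequencing error, each conserved family's
    census equals the number of planted loci carrying it."""
    from collections import Counter

    from sporomir.config import SimConfig
    from sporomir.pipeline import run_pipeline
    from sporomir.simulate import simulate

    cfg = SimConfig(
        seed=5,
        reads_per_library=10_000,
        n_mir_loci=12,
        n_transcripts=80,
        n_regulator_transcripts=30,
        isomir_rates={k: 0.0 for k in SimConfig().isomir_rates},
        seq_error_rate=0.0,
        # no background fragments: planted guides are the only tag source,
        # so the family census has a closed-form truth
        length_mixture={21: 0.6, 22: 0.4, 24: 0.0, 31: 0.0, "uniform": 0.0},
    )
    sim = simulate(cfg, tmp_path / "sim")
    result = run_pipeline(tmp_path / "sim")
    planted = Counter(sim.truth.family_labels.values())
    census = result.family_counts
    assert dict(census) == dict(planted)
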