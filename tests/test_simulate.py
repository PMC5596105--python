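"""Synthetic-data generator: determinism, geometry, planted signal."""

import filecmp

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sporomir.config import SimConfig
from sporomir.discovery import validate_duplex
from sporomir.fold import fold
from sporomir.sequences import revcomp
from sporomir.simulate import (
    SizingError,
    generate_genome,
    plant_mir_loci,
    simulate,
    simulate_mrna_expression,
)


def small_cfg(**kw):
    base = dict(
        seed=9,
        reads_per_library=5_000,
        n_mir_loci=10,
        n_transcripts=60,
        n_regulator_transcripts=20,
    )
    base.update(kw)
    return SimConfig(**base)


def test_outputs_byte_identical_under_fixed_seed(tmp_path):
    simulate(small_cfg(), tmp_path / "a")
    simulate(small_cfg(), tmp_path / "b")
    for name in ["genome.fa", "transcripts.fa", "annotations.gff3", "truth.json"]:
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)
    for fq in sorted((tmp_path / "a" / "libraries").glob("*.fastq")):
        assert filecmp.cmp(fq, tmp_path / "b" / "libraries" / fq.name, shallow=False)


def test_zero_transcripts_is_a_valid_degenerate_genome(rng):
    cfg = SimConfig(n_transcripts=0, n_mir_loci=0, n_regulator_transcripts=0)
    genome, transcripts = generate_genome(cfg, rng)
    assert len(genome) == cfg.genome_length
    assert transcripts == []


def test_transcripts_non_overlapping_by_interval_scan(rng):
    cfg = SimConfig(seed=0)
    _, transcripts = generate_genome(cfg, rng)
    assert len(transcripts) == 300
    intervals = sorted((t.start, t.end) for t in transcripts)
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        assert e1 <= s2, "gene models overlap"


def test_sizing_error_names_the_shortfall(rng):
    cfg = SimConfig(genome_length=10_000, n_transcripts=100, n_mir_loci=10,
                    n_regulator_transcripts=20)
    with pytest.raises(SizingError, match="shortfall"):
        generate_genome(cfg, rng)


def test_planted_locus_geometry(tmp_path):
    sim = simulate(small_cfg(), tmp_path)
    loci = sim.truth.loci
    assert len(loci) == 10
    assert len({l.locus_id for l in loci}) == 10
    for loc in loci:
        hairpin = sim.genome[loc.hp_start : loc.hp_end]
        assert hairpin == loc.arm5p + loc.loop + loc.arm3p
        assert loc.guide_seq in hairpin
        if loc.n_designed_mismatches == 0:
            assert loc.arm3p == revcomp(loc.arm5p)
        else:
            mm = sum(
                a != b for a, b in zip(loc.arm3p, revcomp(loc.arm5p))
            )
            assert mm == loc.n_designed_mismatches


def test_planted_windows_pass_duplex_validation(tmp_path):
    """Folding the first discovery window of every planted locus with the
    discovery folder yields a validated hairpin."""
    sim = simulate(small_cfg(seed=13), tmp_path)
    for loc in sim.truth.loci:
        ws = loc.guide_start - 80
        we = loc.guide_end + 80
        window = sim.genome[ws:we]
        d = validate_duplex(fold(window), 80, 80 + len(loc.guide_seq))
        assert d.passed, f"{loc.locus_id}: {d.reason}"


def test_read_count_conservation(tmp_path):
    sim = simulate(small_cfg(), tmp_path)
    totals = sim.truth_counts.sum(axis=0)
    assert (totals == small_cfg().reads_per_library).all()


def test_conserved_loci_in_reference_set_novel_absent(tmp_path):
    sim = simulate(small_cfg(), tmp_path)
    ref_seqs = set()
    for line in (tmp_path / "reference_matures.fa").read_text().splitlines():
        if not line.startswith(">"):
            ref_seqs.add(line.strip())
    for loc in sim.truth.loci:
        if loc.conserved:
            assert loc.guide_seq in ref_seqs
        else:
            assert loc.guide_seq not in ref_seqs


def test_pure_reads_without_variation(tmp_path):
    """With isomiR rates and error rate zero, every miRNA-derived read is an
    exact planted guide or star."""
    cfg = small_cfg(
        isomir_rates={k: 0.0 for k in SimConfig().isomir_rates},
        seq_error_rate=0.0,
    )
    sim = simulate(cfg, tmp_path)
    mir_seqs = {l.guide_seq for l in sim.truth.loci} | {
        l.star_seq for l in sim.truth.loci
    }
    n_mir_reads = 0
    for fq in (tmp_path / "libraries").glob("*.fastq"):
        lines = fq.read_text().splitlines()
        for seq in lines[1::4]:
            if seq in mir_seqs:
                n_mir_reads += 1
    expected = sim.truth_counts.drop(index="background").values.sum()
    assert n_mir_reads >= expected  # background may coincide, never undershoot


def test_length_mixture_goodness_of_fit(tmp_path):
    """Read lengths follow the configured mixture (no isomiR/error/DE
    distortion) within multinomial sampling error."""
    cfg = small_cfg(
        reads_per_library=20_000,
        isomir_rates={k: 0.0 for k in SimConfig().isomir_rates},
        seq_error_rate=0.0,
        frac_de_mirnas=0.0,
    )
    sim = simulate(cfg, tmp_path)
    lengths = []
    for fq in (tmp_path / "libraries").glob("*.fastq"):
        lengths.extend(len(s) for s in fq.read_text().splitlines()[1::4])
    counts = pd.Series(lengths).value_counts().sort_index()
    mix = cfg.length_mixture
    expected = {}
    for ln in range(15, 36):
        p = mix["uniform"] / 21
        if ln in (21, 22, 24, 31):
            p += mix[ln]
        expected[ln] = p * len(lengths)
    obs = np.array([counts.get(ln, 0) for ln in range(15, 36)], dtype=float)
    exp = np.array([expected[ln] for ln in range(15, 36)])
    chi = sps.chisquare(obs, exp * obs.sum() / exp.sum())
    assert chi.pvalue > 0.01


def test_planted_de_profile_orders_condition_counts(tmp_path):
    """A miRNA planted low/low/high over 18/23/28 degC shows the matching
    rank order in its simulated per-library counts."""
    cfg = small_cfg(seed=21, reads_per_library=20_000)
    sim = simulate(cfg, tmp_path)
    model = sim.truth.expression_model
    target = next(
        (g for g, info in model.items() if info["profile"] == "28>18=23"), None
    )
    assert target is not None
    counts = sim.truth_counts.loc[target]
    by_temp = {
        t: counts[[c for c in counts.index if c.endswith(f"T{t}")]].mean()
        for t in (18, 23, 28)
    }
    assert by_temp[18] < by_temp[28]
    assert by_temp[23] < by_temp[28]


class TestMrnaExpression:
    def test_linked_pairs_hit_exact_anticorrelation(self, tmp_path):
        cfg = small_cfg()
        sim = simulate(cfg, tmp_path)
        model = sim.truth.expression_model
        conds = ["18", "23", "28"]
        rs = []
        for lk in sim.truth.target_links:
            m = np.array([model[lk.mirna]["multipliers"][c] for c in conds])
            t = sim.mrna.loc[lk.transcript, conds].values.astype(float)
            rs.append(np.corrcoef(m, t)[0, 1])
        assert np.allclose(rs, cfg.anticorrelation_strength, atol=1e-9)

    def test_strength_minus_one_gives_exact_negatives(self, tmp_path):
        cfg = small_cfg(anticorrelation_strength=-1.0)
        sim = simulate(cfg, tmp_path)
        model = sim.truth.expression_model
        conds = ["18", "23", "28"]
        lk = sim.truth.target_links[0]
        m = np.array([model[lk.mirna]["multipliers"][c] for c in conds])
        t = sim.mrna.loc[lk.transcript, conds].values.astype(float)
        assert np.corrcoef(m, t)[0, 1] == pytest.approx(-1.0)

    def test_table_shape_and_unlinked_neutrality(self, tmp_path, rng):
        cfg = small_cfg()
        sim = simulate(cfg, tmp_path)
        assert sim.mrna.shape == (cfg.n_transcripts, 3)
        model = sim.truth.expression_model
        linked = {lk.transcript for lk in sim.truth.target_links}
        conds = ["18", "23", "28"]
        de_profiles = [
            np.array([info["multipliers"][c] for c in conds])
            for info in model.values()
            if info["is_de"]
        ]
        rs = []
        for tid in sim.mrna.index:
            if tid in linked:
                continue
            t = sim.mrna.loc[tid, conds].values.astype(float)
            for m in de_profiles[:5]:
                r = np.corrcoef(m, t)[0, 1]
                if not np.isnan(r):
                    rs.append(r)
        assert abs(np.mean(rs)) < 0.1
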