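"""Planted-truth recovery metrics for a pipeline run.

Scores a :class:`~sporomir.pipeline.PipelineResult` against the simulator's
:class:`~sporomir.simulate.GroundTruth`: guide/arm recovery, star recovery,
DEM sensitivity for the planted temperature-responsive miRNAs, and recovery
of the planted anti-correlated regulator links as retained, correctly
categorised pairs.
"""

from __future__ import annotations

from sporomir.pipeline import PipelineResult
from sporomir.simulate import GroundTruth


def evaluate(result: PipelineResult, truth: GroundTruth) -> dict:
    cands = result.discovery.novel + [c for c, _ in result.discovery.conserved]
    by_guide = {}
    for cand in cands:
        by_guide.setdefault(cand.guide_seq, []).append(cand)

    n_loci = len(truth.loci)
    recovered = arm_ok = star_ok = 0
    for loc in truth.loci:
        hits = by_guide.get(loc.guide_seq, [])
        if not hits:
            continue
        recovered += 1
        if any(c.guide_arm == loc.guide_arm for c in hits):
            arm_ok += 1
        if any(c.star_observed and c.star_seq == loc.star_seq for c in hits):
            star_ok += 1

    seq_to_member = {seq: name for name, seq in result.catalog.items()}
    dems = set(result.dems)
    de_guides = [
        loc for loc in truth.loci if truth.expression_model[loc.guide_name]["is_de"]
    ]
    dem_found = sum(
        1
        for loc in de_guides
        if seq_to_member.get(loc.guide_seq) in dems
    )

    retained = result.pairs[result.pairs["retained"]]
    pair_keys = {
        (row.mirna, row.transcript): row.category
        for row in retained.itertuples(index=False)
    }
    reg_links = [lk for lk in truth.target_links if lk.is_regulator]
    link_found = 0
    for lk in reg_links:
        member = seq_to_member.get(lk.guide_seq)
        if member is None:
            continue
        cat = pair_keys.get((member, lk.transcript))
        if cat is not None and cat == truth.regulator_categories[lk.transcript]:
            link_found += 1

    host_span = {loc.host_id: (loc.hp_start, loc.hp_end) for loc in truth.loci}
    by_id = {t.id: t for t in truth.transcripts}
    spurious = 0
    for stack in result.discovery.accepted_loci:
        span = host_span.get(stack.locus_id)
        if span is None:
            spurious += 1
            continue
        # stack coords are transcript-local and strand-local; compare with
        # the planted hairpin on forward transcript coordinates
        tr = by_id[stack.locus_id]
        s, e = span[0] - tr.start, span[1] - tr.start
        tl = tr.end - tr.start
        if stack.strand == "+":
            fs, fe = stack.start, stack.end
        else:
            fs, fe = tl - stack.end, tl - stack.start
        if fe <= s or fs >= e or stack.strand == "-":
            spurious += 1
    return {
        "n_planted": n_loci,
        "n_recovered": recovered,
        "guide_recovery_pct": 100.0 * recovered / n_loci if n_loci else 0.0,
        "guide_arm_recovery_pct": 100.0 * arm_ok / n_loci if n_loci else 0.0,
        "star_recovery_pct": 100.0 * star_ok / recovered if recovered else 0.0,
        "n_planted_de": len(de_guides),
        "dem_sensitivity_pct": 100.0 * dem_found / len(de_guides) if de_guides else 0.0,
        "n_planted_regulator_links": len(reg_links),
        "regulator_link_recovery_pct": (
            100.0 * link_found / len(reg_links) if reg_links else 0.0
        ),
        "n_spurious_accepted_loci": spurious,
        "n_accepted_loci": len(result.discovery.accepted_loci),
        "n_retained_pairs": int(len(retained)),
    }
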