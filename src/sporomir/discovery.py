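"""Novel miRNA discovery: tag mapping, locus calling, hairpin validation
and guide/star assignment.

Tags are mapped ungapped to gene-model sequences on both strands with up to
2 mismatches (pigeonhole seed search: one third of the tag must match
exactly, verified by Hamming distance).  Overlapping mapped tags on one
strand merge into read stacks; a stack whose (multi-mapping-weighted) read
total reaches the locus threshold (default 100) becomes a candidate locus.
Windows around the modal tag are grown stepwise, folded, and the modal
tag's placement validated as one arm of a miRNA/miRNA* duplex; the star is
the best opposite-arm tag consistent with a 2-nt 3' overhang up to a 6-nt
positional shift, with the theoretical star emitted (count 0) when no star
tag was sequenced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from sporomir.annotate import ReferenceMature, match_conserved
from sporomir.fold import Hairpin, fold
from sporomir.sequences import encode, revcomp

SEED_K = 6

# window growth schedule: 20-nt steps to the standard flank maximum, then
# coarser 100-nt steps up to the extended maximum
DEFAULT_FLANKS = tuple(range(80, 301, 20)) + tuple(range(400, 1001, 100))


# ---------------------------------------------------------------------------
# tag mapping
# ---------------------------------------------------------------------------

@njit(cache=True)
def _map_kernel(
    concat,
    unit_of_pos,
    unit_start,
    unit_end,
    kmer_first,
    pos_sorted,
    tags_mat,
    tag_lens,
    max_mm,
    out_tag,
    out_unit,
    out_start,
    out_mm,
):  # pragma: no cover - exercised via map_tags()
    n_out = 0
    cap = out_tag.size
    found_unit = np.empty(512, dtype=np.int64)
    found_start = np.empty(512, dtype=np.int64)
    for ti in range(tags_mat.shape[0]):
        L = tag_lens[ti]
        n_found = 0
        third = L // 3
        for seg in range(3):
            off = seg * third
            if off + SEED_K > L:
                off = L - SEED_K
            code = 0
            for q in range(SEED_K):
                code = code * 4 + tags_mat[ti, off + q]
            for pi in range(kmer_first[code], kmer_first[code + 1]):
                p = pos_sorted[pi]
                cand = p - off
                u = unit_of_pos[p]
                if cand < unit_start[u] or cand + L > unit_end[u]:
                    continue
                dup = False
                for f in range(n_found):
                    if found_unit[f] == u and found_start[f] == cand:
                        dup = True
                        break
                if dup:
                    continue
                mm = 0
                for q in range(L):
                    if concat[cand + q] != tags_mat[ti, q]:
                        mm += 1
                        if mm > max_mm:
                            break
                if mm <= max_mm:
                    if n_found < found_unit.size:
                        found_unit[n_found] = u
                        found_start[n_found] = cand
                        n_found += 1
                    if n_out >= cap:
                        return -1
                    out_tag[n_out] = ti
                    out_unit[n_out] = u
                    out_start[n_out] = cand - unit_start[u]
                    out_mm[n_out] = mm
                    n_out += 1
    return n_out


def map_tags(
    tags: list[str] | pd.Index, loci: dict[str, str], max_mismatches: int = 2
) -> pd.DataFrame:
    """All ungapped placements of each tag on each locus, both strands.

    Returns one row per placement: tag, locus, strand, ``start`` (0-based on
    the forward strand), ``start_local`` (0-based on the strand the tag maps
    to, i.e. on the reverse complement for minus placements) and
    ``n_mismatches``; ``n_placements`` counts a tag's placements for
    fractional locus counting.

    The seed search is exhaustive for tags of >= 3 x seed length (18 nt);
    shorter tags may miss 2-mismatch placements.
    """
    tags = list(tags)
    locus_ids = list(loci)
    units = []  # (locus_idx, strand)
    seqs = []
    for li, lid in enumerate(locus_ids):
        seq = loci[lid].upper().replace("U", "T")
        units.append((li, "+"))
        seqs.append(seq)
        units.append((li, "-"))
        seqs.append(revcomp(seq))
    if not tags or not seqs:
        return pd.DataFrame(
            columns=[
                "tag", "locus", "strand", "start", "start_local",
                "n_mismatches", "n_placements",
            ]
        )
    concat = np.concatenate([encode(s) for s in seqs])
    lens = np.array([len(s) for s in seqs], dtype=np.int64)
    unit_end = np.cumsum(lens)
    unit_start = unit_end - lens
    unit_of_pos = np.repeat(np.arange(len(seqs), dtype=np.int64), lens)
    # seed index over all positions fully inside a unit
    codes = np.full(concat.size, -1, dtype=np.int64)
    valid = np.ones(concat.size, dtype=bool)
    acc = np.zeros(concat.size - SEED_K + 1, dtype=np.int64)
    for q in range(SEED_K):
        acc = acc * 4 + concat[q : concat.size - SEED_K + 1 + q]
    codes[: acc.size] = acc
    valid[: acc.size] = (
        unit_of_pos[: acc.size] == unit_of_pos[SEED_K - 1 : acc.size + SEED_K - 1]
    )
    valid[acc.size :] = False
    pos = np.nonzero(valid)[0]
    order = np.argsort(codes[pos], kind="stable")
    pos_sorted = pos[order]
    kmer_first = np.searchsorted(
        codes[pos_sorted], np.arange(4**SEED_K + 1), side="left"
    ).astype(np.int64)

    max_len = max(len(t) for t in tags)
    tags_mat = np.zeros((len(tags), max_len), dtype=np.uint8)
    tag_lens = np.empty(len(tags), dtype=np.int64)
    for i, t in enumerate(tags):
        enc = encode(t)
        tags_mat[i, : enc.size] = enc
        tag_lens[i] = enc.size

    cap = max(4 * len(tags), 1024)
    while True:
        out = [np.empty(cap, dtype=np.int64) for _ in range(4)]
        n = _map_kernel(
            concat, unit_of_pos, unit_start, unit_end, kmer_first, pos_sorted,
            tags_mat, tag_lens, max_mismatches, *out,
        )
        if n >= 0:
            break
        cap *= 4
    t_idx, u_idx, s_loc, mm = (a[:n] for a in out)
    if n == 0:
        return pd.DataFrame(
            columns=[
                "tag", "locus", "strand", "start", "start_local",
                "n_mismatches", "n_placements",
            ]
        )
    strands = np.array([s for _, s in units])
    locus_idx = np.array([li for li, _ in units])
    df = pd.DataFrame(
        {
            "tag": [tags[i] for i in t_idx],
            "locus": [locus_ids[locus_idx[u]] for u in u_idx],
            "strand": strands[u_idx],
            "start_local": s_loc,
            "n_mismatches": mm,
        }
    )
    tag_len = df["tag"].str.len()
    unit_len = lens[u_idx]
    df["start"] = np.where(
        df["strand"] == "+", df["start_local"], unit_len - df["start_local"] - tag_len
    )
    df["n_placements"] = df.groupby("tag")["tag"].transform("size")
    return df[
        ["tag", "locus", "strand", "start", "start_local", "n_mismatches", "n_placements"]
    ]


# ---------------------------------------------------------------------------
# locus calling
# ---------------------------------------------------------------------------

@dataclass
class CandidateLocus:
    locus_id: str
    strand: str
    start: int  # strand-local, 0-based half-open on the oriented sequence
    end: int
    total_reads: float  # multi-mapping weighted
    n_distinct_tags: int
    tags: pd.DataFrame  # placements with tag totals


def prepare_mappings(mappings: pd.DataFrame, tag_totals: pd.Series) -> pd.DataFrame:
    """Attach tag totals, fractional weights and interval ends to mappings."""
    df = mappings.copy()
    df["total"] = df["tag"].map(tag_totals).astype(float)
    df["weight"] = df["total"] / df["n_placements"]
    df["tag_len"] = df["tag"].str.len()
    df["end_local"] = df["start_local"] + df["tag_len"]
    return df


def call_loci(
    mappings: pd.DataFrame, tag_totals: pd.Series, min_reads: float = 100
) -> list[CandidateLocus]:
    """Merge overlapping placements into stacks and apply the read threshold.

    A tag mapping to k places contributes total/k to each stack it joins
    (fractional multi-mapper counting); a stack is accepted when its
    weighted read total is at least ``min_reads``.
    """
    if len(mappings) == 0:
        return []
    df = mappings if "weight" in mappings.columns else prepare_mappings(mappings, tag_totals)
    out = []
    for (locus, strand), grp in df.groupby(["locus", "strand"], sort=True):
        grp = grp.sort_values(["start_local", "end_local"], kind="stable")
        block_end = -1
        block_rows: list[int] = []
        blocks = []
        for idx, row in enumerate(grp.itertuples(index=False)):
            if block_rows and row.start_local >= block_end:
                blocks.append(block_rows)
                block_rows = []
                block_end = -1
            block_rows.append(idx)
            block_end = max(block_end, row.end_local)
        if block_rows:
            blocks.append(block_rows)
        for rows in blocks:
            sub = grp.iloc[rows]
            total = float(sub["weight"].sum())
            if total >= min_reads:
                out.append(
                    CandidateLocus(
                        locus_id=locus,
                        strand=strand,
                        start=int(sub["start_local"].min()),
                        end=int(sub["end_local"].max()),
                        total_reads=total,
                        n_distinct_tags=int(sub["tag"].nunique()),
                        tags=sub.reset_index(drop=True),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

def modal_tag(stack: pd.DataFrame) -> pd.Series:
    """Highest-count placement; ties broken by longer tag then sequence."""
    ranked = stack.sort_values(
        ["total", "tag_len", "tag"], ascending=[False, False, True], kind="stable"
    )
    return ranked.iloc[0]


def extract_windows(
    oriented_seq: str,
    modal_start: int,
    modal_end: int,
    flanks: tuple[int, ...] = DEFAULT_FLANKS,
):
    """Yield (window_start, window_end, truncated) growing around the modal
    tag, truncating at the locus bounds and stopping once saturated."""
    L = len(oriented_seq)
    prev = None
    for flank in flanks:
        ws = max(0, modal_start - flank)
        we = min(L, modal_end + flank)
        truncated = ws == 0 or we == L
        if (ws, we) == prev:
            return
        prev = (ws, we)
        yield ws, we, truncated


# ---------------------------------------------------------------------------
# duplex validation
# ---------------------------------------------------------------------------

@dataclass
class DuplexStats:
    passed: bool
    reason: str
    n_paired: int = 0
    n_unpaired: int = 0
    n_bulged: int = 0
    arm: str = ""  # "5p" if the guide precedes its partners
    min_partner: int = -1
    max_partner: int = -1


def validate_duplex(
    hairpin: Hairpin,
    guide_start: int,
    guide_end: int,
    max_unpaired: int = 5,
    max_bulged: int = 3,
    min_paired: int = 14,
) -> DuplexStats:
    """Check that a guide placement forms one arm of a miRNA/miRNA* duplex.

    Pass requires: no guide base paired within the guide itself (the guide
    must not span the terminal loop), at least ``min_paired`` guide bases
    paired to a single opposite arm, at most ``max_unpaired`` guide bases
    unpaired in that duplex and at most ``max_bulged`` unpaired bases
    interior to it.
    """
    n = len(hairpin.sequence)
    if not (0 <= guide_start < guide_end <= n):
        raise ValueError("guide placement outside the folded window")
    partner = hairpin.partner
    L = guide_end - guide_start
    left, right = [], []
    for i in range(guide_start, guide_end):
        p = int(partner[i])
        if p < 0:
            continue
        if guide_start <= p < guide_end:
            return DuplexStats(False, "spans loop")
        (left if p < guide_start else right).append(i)
    dominant = left if len(left) >= len(right) else right
    if not dominant:
        return DuplexStats(False, "no duplex pairs", n_paired=0, n_unpaired=L)
    # coherent stem: keep the longest antiparallel run (partners strictly
    # decreasing with guide position, small bulge jumps allowed), dropping
    # stray pairs to positions outside the true opposite arm
    runs, run = [], [dominant[0]]
    for i in dominant[1:]:
        p_prev, p_cur = int(partner[run[-1]]), int(partner[i])
        step = i - run[-1]
        if p_cur < p_prev and (p_prev - p_cur) <= step + 3:
            run.append(i)
        else:
            runs.append(run)
            run = [i]
    runs.append(run)
    # merge consecutive runs while partners keep descending and the partner
    # span stays duplex-sized (a stray far-away pair cannot join)
    merged = [runs[0]]
    for nxt in runs[1:]:
        cur = merged[-1]
        span_ok = int(partner[cur[0]]) - int(partner[nxt[-1]]) + 1 <= L + 6
        if int(partner[nxt[0]]) < int(partner[cur[-1]]) and span_ok:
            merged[-1] = cur + nxt
        else:
            merged.append(nxt)
    dominant = max(merged, key=len)
    n_paired = len(dominant)
    n_unpaired = L - n_paired
    first, last = dominant[0], dominant[-1]
    n_bulged = sum(
        1 for i in range(first, last + 1) if i not in set(dominant)
    )
    partners = sorted(int(partner[i]) for i in dominant)
    arm = "5p" if guide_start < partners[0] else "3p"
    stats = DuplexStats(
        True, "", n_paired, n_unpaired, n_bulged, arm, partners[0], partners[-1]
    )
    if n_paired < min_paired:
        return DuplexStats(False, f"only {n_paired} paired", n_paired, n_unpaired, n_bulged, arm)
    if n_unpaired > max_unpaired:
        return DuplexStats(False, f"{n_unpaired} unpaired", n_paired, n_unpaired, n_bulged, arm)
    if n_bulged > max_bulged:
        return DuplexStats(False, f"{n_bulged} bulged", n_paired, n_unpaired, n_bulged, arm)
    return stats


# ---------------------------------------------------------------------------
# guide / star assignment
# ---------------------------------------------------------------------------

@dataclass
class MirnaCandidate:
    guide_seq: str
    guide_arm: str
    guide_count: float
    star_seq: str
    star_count: float
    star_shift: int
    star_observed: bool
    locus_id: str
    strand: str
    window_start: int  # strand-local coordinates of the folded window
    window_end: int
    precursor: str
    structure: str
    duplex: DuplexStats
    name: str = ""
    precursors: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.precursors:
            self.precursors = [f"{self.locus_id}:{self.window_start}-{self.window_end}{self.strand}"]


def _star_candidates(
    window_tags: pd.DataFrame,
    window_start: int,
    window_end: int,
    guide_row,
    gs: int,
    ge: int,
    duplex: DuplexStats,
    max_star_shift: int,
) -> list:
    """Opposite-arm placements within ``max_star_shift`` of the ideal star.

    The ideal star spans the guide's duplex partners with a 2-nt 3'
    overhang; the positional shift is the larger of the two end
    displacements.
    """
    ideal_s = duplex.min_partner
    ideal_e = duplex.max_partner + 1 + 2
    cands = []
    for row in window_tags.itertuples(index=False):
        ts = int(row.start_local) - window_start
        te = ts + len(row.tag)
        if ts < 0 or te > window_end - window_start:
            continue
        if row.tag == guide_row.tag and ts == gs:
            continue
        # the star lies on the opposite arm, i.e. on the partner side
        if duplex.arm == "5p" and not ts >= ge:
            continue
        if duplex.arm == "3p" and not te <= gs:
            continue
        shift = max(abs(ts - ideal_s), abs(te - ideal_e))
        if shift <= max_star_shift:
            cands.append((row, shift, ts, te))
    cands.sort(key=lambda c: (-c[0].total, -len(c[0].tag), c[0].tag, c[1]))
    return cands


def assign_guide_star(
    window_tags: pd.DataFrame,
    hairpin: Hairpin,
    window_start: int,
    guide_row,
    duplex: DuplexStats,
    locus_id: str,
    strand: str,
    window_end: int,
    max_star_shift: int = 6,
) -> MirnaCandidate:
    """Pick guide and star tags for a validated hairpin.

    ``window_tags`` holds every placement on this locus and strand (both
    arms can fall into separate read stacks, so the search is not limited
    to the triggering stack).  The star is the highest-count opposite-arm
    tag within ``max_star_shift`` nt of the ideal duplex-partner interval;
    if that tag is *more* abundant than the current guide the roles swap
    ("higher frequency" defines the guide).  Without an observed star tag
    the theoretical star sequence is emitted with count 0.
    """
    gs = int(guide_row.start_local) - window_start
    ge = gs + len(guide_row.tag)
    cands = _star_candidates(
        window_tags, window_start, window_end, guide_row, gs, ge, duplex, max_star_shift
    )
    if cands and float(cands[0][0].total) > float(guide_row.total):
        # opposite-arm tag is the more abundant strand: it becomes the guide
        new_guide, _, nts, nte = cands[0]
        new_duplex = validate_duplex(hairpin, nts, nte)
        if new_duplex.passed:
            guide_row, duplex = new_guide, new_duplex
            gs, ge = nts, nte
            cands = _star_candidates(
                window_tags, window_start, window_end, guide_row, gs, ge,
                duplex, max_star_shift,
            )
    ideal_s = duplex.min_partner
    ideal_e = duplex.max_partner + 1 + 2
    if cands:
        star_row, shift, _, _ = cands[0]
        star_seq, star_count, observed = star_row.tag, float(star_row.total), True
        star_shift = int(shift)
    else:
        w = hairpin.sequence
        star_seq = w[max(0, ideal_s) : min(len(w), ideal_e)]
        star_count, observed, star_shift = 0.0, False, 0
    return MirnaCandidate(
        guide_seq=guide_row.tag,
        guide_arm=duplex.arm,
        guide_count=float(guide_row.total),
        star_seq=star_seq,
        star_count=star_count,
        star_shift=star_shift,
        star_observed=observed,
        locus_id=locus_id,
        strand=strand,
        window_start=window_start,
        window_end=window_end,
        precursor=hairpin.sequence,
        structure=hairpin.structure,
        duplex=duplex,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryResult:
    candidates: list[MirnaCandidate]
    novel: list[MirnaCandidate]
    conserved: list[tuple[MirnaCandidate, object]]  # candidate + ConservedHit
    accepted_loci: list[CandidateLocus]
    log: dict


def discover_candidates(
    accepted: list[CandidateLocus],
    loci_seqs: dict[str, str],
    all_mappings: pd.DataFrame | None = None,
    flanks: tuple[int, ...] = DEFAULT_FLANKS,
    max_star_shift: int = 6,
) -> tuple[list[MirnaCandidate], dict]:
    """Grow/fold/validate windows for every accepted stack.

    ``all_mappings`` (a prepared mapping table) supplies the opposite-arm
    placements for star assignment; without it the stack's own tags are
    used.
    """
    candidates = []
    log = {"stacks": len(accepted), "windows_folded": 0, "validated": 0}
    groups = (
        dict(tuple(all_mappings.groupby(["locus", "strand"], sort=False)))
        if all_mappings is not None and len(all_mappings)
        else {}
    )
    for stack_locus in accepted:
        seq = loci_seqs[stack_locus.locus_id].upper().replace("U", "T")
        oriented = seq if stack_locus.strand == "+" else revcomp(seq)
        guide_row = modal_tag(stack_locus.tags)
        ms = int(guide_row.start_local)
        me = ms + len(guide_row.tag)
        window_tags = groups.get(
            (stack_locus.locus_id, stack_locus.strand), stack_locus.tags
        )
        for ws, we, _trunc in extract_windows(oriented, ms, me, flanks):
            log["windows_folded"] += 1
            hp = fold(oriented[ws:we])
            duplex = validate_duplex(hp, ms - ws, me - ws)
            if duplex.passed:
                log["validated"] += 1
                candidates.append(
                    assign_guide_star(
                        window_tags, hp, ws, guide_row, duplex,
                        stack_locus.locus_id, stack_locus.strand, we,
                        max_star_shift=max_star_shift,
                    )
                )
                break
    return candidates, log


def dedupe_and_name(
    candidates: list[MirnaCandidate],
    references: list[ReferenceMature],
) -> tuple[list[MirnaCandidate], list[tuple[MirnaCandidate, object]]]:
    """Partition candidates into conserved and novel; collapse shared guides.

    Candidates whose guide hits the reference set join the conserved side
    (precursor attached); the rest are novel and named ``Pab-miRn{serial}_{arm}``
    by descending guide count.  Identical guide sequences from several loci
    collapse into one miRNA with the precursor list concatenated.
    """
    by_guide: dict[tuple[str, str], MirnaCandidate] = {}
    for cand in sorted(
        candidates, key=lambda c: (-c.guide_count, c.guide_seq, c.locus_id)
    ):
        key = (cand.guide_seq, cand.guide_arm)
        if key in by_guide:
            by_guide[key].precursors.extend(cand.precursors)
        else:
            by_guide[key] = cand
    novel, conserved = [], []
    for cand in by_guide.values():
        hit = match_conserved(cand.guide_seq, references)
        if hit is not None:
            conserved.append((cand, hit))
        else:
            novel.append(cand)
    novel.sort(key=lambda c: (-c.guide_count, c.guide_seq))
    for serial, cand in enumerate(novel, start=1):
        cand.name = f"Pab-miRn{serial}_{cand.guide_arm}"
    return novel, conserved


def discover(
    tags: pd.DataFrame,
    loci_seqs: dict[str, str],
    references: list[ReferenceMature],
    min_locus_reads: float = 100,
    flanks: tuple[int, ...] = DEFAULT_FLANKS,
    max_star_shift: int = 6,
    max_mismatches: int = 2,
) -> DiscoveryResult:
    """Full discovery pass over a collapsed tag matrix."""
    totals = tags.sum(axis=1)
    mappings = map_tags(tags.index, loci_seqs, max_mismatches=max_mismatches)
    prepared = prepare_mappings(mappings, totals)
    accepted = call_loci(prepared, totals, min_reads=min_locus_reads)
    candidates, log = discover_candidates(
        accepted, loci_seqs, prepared, flanks=flanks, max_star_shift=max_star_shift
    )
    novel, conserved = dedupe_and_name(candidates, references)
    log.update(
        n_mappings=int(len(mappings)),
        n_accepted_loci=len(accepted),
        n_candidates=len(candidates),
        n_novel=len(novel),
        n_conserved_with_precursor=len(conserved),
    )
    return DiscoveryResult(candidates, novel, conserved, accepted, log)
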