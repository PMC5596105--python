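"""Conserved-miRNA annotation and isomiR classification.

Tags are matched against a reference set of mature miRNAs (a miRBase-style
FASTA plus a family table) with an ungapped sliding alignment: end offsets
up to +/-4 nt, overlap >= 17 nt and at most 2 substitutions in the overlap.
The best hit minimises (substitutions, |offset_5p| + |offset_3p|, reference
id).  Hits are then classified into isomiR modification classes — end
trimming, templated extension, nontemplated 3' U/A tailing, internal
substitution — using the reference's genomic flanks when available.

Offset signs: ``offset_5p`` / ``offset_3p`` are positive when the tag
*extends* past the reference at that end and negative when it is trimmed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sporomir.sequences import encode, normalize


@dataclass(frozen=True)
class ReferenceMature:
    id: str
    family: str
    sequence: str
    flank5: str = ""  # genomic context upstream of the mature 5' end
    flank3: str = ""  # genomic context downstream of the mature 3' end


@dataclass(frozen=True)
class ConservedHit:
    tag: str
    ref_id: str
    family: str
    n_substitutions: int
    offset_5p: int
    offset_3p: int


@dataclass(frozen=True)
class IsomiRCall:
    classes: frozenset
    detail: str = ""


ISOMIR_CLASS_SET = frozenset(
    {
        "canonical",
        "substitution",
        "trim5",
        "trim3",
        "ext5_templated",
        "ext3_templated",
        "tail3_U",
        "tail3_A",
        "tail3_other",
    }
)


def load_references(
    fasta: str | Path, families_tsv: str | Path, flanks_tsv: str | Path | None = None
) -> list[ReferenceMature]:
    from Bio import SeqIO

    fams = pd.read_csv(families_tsv, sep="\t").set_index("id")["family"]
    flanks = (
        pd.read_csv(flanks_tsv, sep="\t", keep_default_na=False).set_index("id")
        if flanks_tsv
        else None
    )
    refs = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        f5 = f3 = ""
        if flanks is not None and rec.id in flanks.index:
            f5 = str(flanks.loc[rec.id, "flank5"])
            f3 = str(flanks.loc[rec.id, "flank3"])
        refs.append(
            ReferenceMature(rec.id, str(fams[rec.id]), normalize(str(rec.seq)), f5, f3)
        )
    return refs


def _alignment_offsets(d: int, lt: int, lr: int) -> tuple[int, int]:
    """(offset_5p, offset_3p) for a tag starting at ``d`` relative to the
    reference start; positive = tag extends past the reference end."""
    return -d, d + lt - lr


def match_conserved(
    tag: str,
    references: list[ReferenceMature],
    max_subs: int = 2,
    max_end_offset: int = 4,
    min_overlap: int = 17,
) -> ConservedHit | None:
    """Best ungapped reference hit for one tag, or None.

    The tag slides over each reference; a placement is a hit when both end
    offsets are within ``max_end_offset``, the overlap is at least
    ``min_overlap`` nt and the overlap has at most ``max_subs``
    substitutions.
    """
    tag = normalize(tag)
    lt = len(tag)
    best = None
    for ref in sorted(references, key=lambda r: r.id):
        lr = len(ref.sequence)
        placements = []
        for d in range(-max_end_offset, max_end_offset + 1):
            o5, o3 = _alignment_offsets(d, lt, lr)
            if abs(o5) > max_end_offset or abs(o3) > max_end_offset:
                continue
            lo, hi = max(d, 0), min(d + lt, lr)
            if hi - lo < min_overlap:
                continue
            subs = sum(
                tag[p - d] != ref.sequence[p] for p in range(lo, hi)
            )
            if subs <= max_subs:
                placements.append((subs, abs(o5) + abs(o3), d, o5, o3))
        for subs, offsum, d, o5, o3 in sorted(placements, key=lambda x: x[:3]):
            cand = (subs, offsum)
            if best is None or cand < (best.n_substitutions,
                                       abs(best.offset_5p) + abs(best.offset_3p)):
                best = ConservedHit(tag, ref.id, ref.family, subs, o5, o3)
            break  # only the best placement per reference matters
    return best


def match_tags(
    tags: list[str] | pd.Index,
    references: list[ReferenceMature],
    max_subs: int = 2,
    max_end_offset: int = 4,
    min_overlap: int = 17,
) -> pd.DataFrame:
    """Vectorised best-hit matching for a large tag collection.

    Produces one row per tag with a hit (columns tag, ref_id, family,
    n_substitutions, offset_5p, offset_3p); agrees with
    :func:`match_conserved` tag by tag.
    """
    tags = [normalize(t) for t in tags]
    refs = sorted(references, key=lambda r: r.id)
    by_len: dict[int, list[int]] = {}
    for i, t in enumerate(tags):
        by_len.setdefault(len(t), []).append(i)
    n = len(tags)
    big = 10**9
    best_key = np.full((n, 2), big, dtype=np.int64)  # (subs, offsum)
    best_hit: list[ConservedHit | None] = [None] * n
    for lt, idxs in by_len.items():
        mat = np.vstack([encode(tags[i]) for i in idxs])
        for ref in refs:
            lr = len(ref.sequence)
            rseq = encode(ref.sequence)
            ds = []
            for d in range(-max_end_offset, max_end_offset + 1):
                o5, o3 = _alignment_offsets(d, lt, lr)
                if abs(o5) > max_end_offset or abs(o3) > max_end_offset:
                    continue
                lo, hi = max(d, 0), min(d + lt, lr)
                if hi - lo < min_overlap:
                    continue
                ds.append((abs(o5) + abs(o3), d, o5, o3, lo, hi))
            for offsum, d, o5, o3, lo, hi in sorted(ds):
                subs = (mat[:, lo - d : hi - d] != rseq[lo:hi]).sum(axis=1)
                ok = subs <= max_subs
                for row in np.nonzero(ok)[0]:
                    i = idxs[row]
                    key = (int(subs[row]), offsum)
                    if key < tuple(best_key[i]):
                        best_key[i] = key
                        best_hit[i] = ConservedHit(
                            tags[i], ref.id, ref.family, int(subs[row]), o5, o3
                        )
    rows = [h for h in best_hit if h is not None]
    return pd.DataFrame(
        [
            (h.tag, h.ref_id, h.family, h.n_substitutions, h.offset_5p, h.offset_3p)
            for h in rows
        ],
        columns=["tag", "ref_id", "family", "n_substitutions", "offset_5p", "offset_3p"],
    )


def classify_isomir(hit: ConservedHit, reference: ReferenceMature) -> IsomiRCall:
    """IsomiR modification classes for a conserved hit.

    Negative offsets are trims, positive offsets extensions; extensions are
    split into templated (the bases continue the reference's genomic flank)
    versus nontemplated 3' tails (uridylation / adenylation / other).
    Without genomic context an extension is reported with a
    "template-unknown" detail.
    """
    classes: set[str] = set()
    details: list[str] = []
    tag, ref = hit.tag, reference.sequence
    if hit.n_substitutions > 0:
        classes.add("substitution")
        details.append(f"{hit.n_substitutions} substitution(s)")
    if hit.offset_5p < 0:
        classes.add("trim5")
        details.append(f"5' trimmed {-hit.offset_5p} nt")
    elif hit.offset_5p > 0:
        ext = tag[: hit.offset_5p]
        if not reference.flank5:
            classes.add("ext5_templated")
            details.append("5' extension, template-unknown")
        elif reference.flank5.endswith(ext):
            classes.add("ext5_templated")
            details.append(f"5' templated extension {ext}")
        else:
            details.append(f"5' nontemplated extension {ext}")
    if hit.offset_3p < 0:
        classes.add("trim3")
        details.append(f"3' trimmed {-hit.offset_3p} nt")
    elif hit.offset_3p > 0:
        ext = tag[len(tag) - hit.offset_3p :]
        if not reference.flank3:
            classes.add("ext3_templated")
            details.append("3' extension, template-unknown")
        else:
            k = 0
            while k < len(ext) and k < len(reference.flank3) and ext[k] == reference.flank3[k]:
                k += 1
            if k == len(ext):
                classes.add("ext3_templated")
                details.append(f"3' templated extension {ext}")
            else:
                if k > 0:
                    classes.add("ext3_templated")
                    details.append(f"3' templated extension {ext[:k]}")
                rest = ext[k:]
                if set(rest) == {"T"}:
                    classes.add("tail3_U")
                    details.append(f"3' U tail {rest}")
                elif set(rest) == {"A"}:
                    classes.add("tail3_A")
                    details.append(f"3' A tail {rest}")
                else:
                    classes.add("tail3_other")
                    details.append(f"3' nontemplated tail {rest}")
    if not classes:
        classes.add("canonical")
    return IsomiRCall(frozenset(classes), "; ".join(details))


def family_census(hits: pd.DataFrame) -> pd.Series:
    """Number of distinct tag sequences best-hitting each family."""
    if len(hits) == 0:
        return pd.Series(dtype=int, name="n_isomirs")
    return (
        hits.groupby("family")["tag"].nunique().rename("n_isomirs").sort_index()
    )
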