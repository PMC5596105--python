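"""Plant miRNA target-site prediction with an expectation-style penalty
score.

A transcript window is scored against the miRNA in antiparallel orientation
(miRNA position 1 = 5' end pairs the window's 3' end).  The expectation E
is the penalty sum: match 0, G:U wobble 0.5, mismatch 1, gap 2, with every
penalty doubled when the miRNA position lies in the seed region (positions
2-13 from the 5' end).  At most one gap is allowed by default (the site may
be one base shorter or longer than the miRNA); a site is reported when
E <= cutoff (default 3.0).  Sites with any non-match at miRNA positions
9-11 are labelled translational repression, otherwise cleavage.

Penalties are handled internally in half-units (x2 integers), so E values
are exact half-integers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from sporomir.sequences import encode, normalize

SEED_START, SEED_END = 2, 13  # 1-based miRNA positions, inclusive
CENTRAL = (9, 10, 11)

# penalty x2: [match, GU, mismatch]; gap x2 = 4
_PEN2 = (0, 1, 2)
_GAP2 = 4

# pair class lookup on encoded bases: miRNA base m vs *reversed* (not
# complemented) site base v.  Match when comp(m) == site base, i.e. the
# reversed-window base equals... we store explicit classes instead:
# class 0 = WC match, 1 = GU wobble, 2 = mismatch
_PAIR_CLASS = np.full((4, 4), 2, dtype=np.int64)
_IDX = {b: i for i, b in enumerate("ACGT")}
for _m, _t in [("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")]:
    _PAIR_CLASS[_IDX[_m], _IDX[_t]] = 0
for _m, _t in [("G", "T"), ("T", "G")]:  # G:U wobble (U stored as T)
    _PAIR_CLASS[_IDX[_m], _IDX[_t]] = 1


def _seed_mult(length: int) -> np.ndarray:
    mult = np.ones(length, dtype=np.int64)
    for k in range(length):
        if SEED_START <= k + 1 <= SEED_END:
            mult[k] = 2
    return mult


@dataclass(frozen=True)
class DuplexScore:
    """Scored miRNA/target alignment.

    ``states[k]`` is the state at miRNA position k+1 (1-based):
    match / GU / mismatch / gap; a target bulge (site one base longer) is
    recorded as detail, not a miRNA-position state.
    """

    expectation: float
    states: tuple
    gap_detail: str = ""

    @property
    def mode(self) -> str:
        bad = any(self.states[p - 1] != "match" for p in CENTRAL if p - 1 < len(self.states))
        return "translational" if bad else "cleavage"


def _pen2_at(m_code: int, t_code: int, k: int) -> int:
    mult = 2 if SEED_START <= k + 1 <= SEED_END else 1
    return _PEN2[_PAIR_CLASS[m_code, t_code]] * mult


def score_duplex(mirna: str, site: str, max_gaps: int = 1) -> DuplexScore:
    """Best-scoring full-length alignment of a miRNA against one site.

    The site is the transcript window 5'->3'; its length must be within
    ``max_gaps`` of the miRNA length.  Enumerates all placements of at most
    one gap (site one base shorter: a miRNA base is unpaired; site one base
    longer: a target base bulges out) and returns the minimum-E alignment.
    """
    u = encode(normalize(mirna))
    v = encode(normalize(site))[::-1]  # reversed: v[k] faces miRNA position k+1
    L, M = u.size, v.size
    if abs(M - L) > max_gaps:
        raise ValueError(
            f"site length {M} incompatible with miRNA length {L} and "
            f"max_gaps={max_gaps}"
        )

    def ungapped(uu, vv, offset=0):
        states, tot = [], 0
        for k in range(len(uu)):
            cls = _PAIR_CLASS[uu[k], vv[k]]
            tot += _pen2_at(uu[k], vv[k], k + offset)
            states.append(("match", "GU", "mismatch")[cls])
        return tot, states

    best = None
    if M == L:
        tot, states = ungapped(u, v)
        best = (tot, tuple(states), "")
    elif M == L - 1:
        for g in range(L):  # miRNA position g+1 unpaired (gap in site)
            tot = _GAP2 * (2 if SEED_START <= g + 1 <= SEED_END else 1)
            states = []
            for k in range(L):
                if k == g:
                    states.append("gap")
                    continue
                j = k if k < g else k - 1
                tot += _pen2_at(u[k], v[j], k)
                states.append(("match", "GU", "mismatch")[_PAIR_CLASS[u[k], v[j]]])
            cand = (tot, tuple(states), f"gap at miRNA position {g + 1}")
            if best is None or cand[0] < best[0]:
                best = cand
    else:  # M == L + 1: one site base bulges out
        for h in range(M):  # v[h] unaligned
            gpos = min(h + 1, L)
            tot = _GAP2 * (2 if SEED_START <= gpos <= SEED_END else 1)
            states = []
            for k in range(L):
                j = k if k < h else k + 1
                tot += _pen2_at(u[k], v[j], k)
                states.append(("match", "GU", "mismatch")[_PAIR_CLASS[u[k], v[j]]])
            cand = (tot, tuple(states), f"target bulge opposite miRNA position {gpos}")
            if best is None or cand[0] < best[0]:
                best = cand
    return DuplexScore(best[0] / 2.0, best[1], best[2])


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

@njit(cache=True)
def _scan_kernel(u, t, pair_class, pen2, gap2, seed_mult, max_gaps, cutoff2):
    """Best E (x2) per (start, site length) over one transcript.

    Returns arrays (start, site_len, e2) for windows with e2 <= cutoff2.
    """
    L = u.size
    N = t.size
    cap = 64
    starts = np.empty(cap, dtype=np.int64)
    slens = np.empty(cap, dtype=np.int64)
    e2s = np.empty(cap, dtype=np.int64)
    n = 0
    for start in range(N):
        for dM in range(-max_gaps, max_gaps + 1):
            M = L + dM
            if M < 1 or start + M > N:
                continue
            # v = reversed window
            best = -1
            if dM == 0:
                tot = 0
                for k in range(L):
                    tot += pen2[pair_class[u[k], t[start + M - 1 - k]]] * seed_mult[k]
                best = tot
            elif dM == -1:
                for g in range(L):
                    tot = gap2 * seed_mult[g]
                    for k in range(L):
                        if k == g:
                            continue
                        j = k if k < g else k - 1
                        tot += pen2[pair_class[u[k], t[start + M - 1 - j]]] * seed_mult[k]
                    if best < 0 or tot < best:
                        best = tot
            else:  # dM == +1
                for h in range(M):
                    gpos = h if h < L else L - 1
                    tot = gap2 * seed_mult[gpos]
                    for k in range(L):
                        j = k if k < h else k + 1
                        tot += pen2[pair_class[u[k], t[start + M - 1 - j]]] * seed_mult[k]
                    if best < 0 or tot < best:
                        best = tot
            if 0 <= best <= cutoff2:
                if n >= cap:
                    cap *= 2
                    ns = np.empty(cap, dtype=np.int64)
                    nl = np.empty(cap, dtype=np.int64)
                    ne = np.empty(cap, dtype=np.int64)
                    ns[:n] = starts[:n]
                    nl[:n] = slens[:n]
                    ne[:n] = e2s[:n]
                    starts, slens, e2s = ns, nl, ne
                starts[n] = start
                slens[n] = M
                e2s[n] = best
                n += 1
    return starts[:n], slens[:n], e2s[:n]


_PEN2_ARR = np.array(_PEN2, dtype=np.int64)


def scan(
    mirna: str,
    transcripts: dict[str, str],
    cutoff: float = 3.0,
    max_gaps: int = 1,
    orientation: str = "sense",
) -> pd.DataFrame:
    """All best sites of one miRNA across a transcript set.

    Per (miRNA, transcript) pair only the minimum-E site is kept (ties:
    leftmost, then ungapped/shorter site).  ``orientation="antisense"``
    scans the reverse complement of each transcript and reports mirrored
    coordinates.
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    u = encode(normalize(mirna))
    seed_mult = _seed_mult(u.size)
    cutoff2 = int(round(cutoff * 2))
    rows = []
    for tid, seq in transcripts.items():
        seq = normalize(seq)
        if orientation == "antisense":
            from sporomir.sequences import revcomp

            scanned = revcomp(seq)
        else:
            scanned = seq
        t = encode(scanned)
        if t.size == 0:
            continue
        starts, slens, e2s = _scan_kernel(
            u, t, _PAIR_CLASS, _PEN2_ARR, _GAP2, seed_mult, max_gaps, cutoff2
        )
        if len(starts) == 0:
            continue
        # best site per transcript: min E, then leftmost, then site length
        # closest to the miRNA length
        order = sorted(
            range(len(starts)),
            key=lambda i: (e2s[i], starts[i], abs(slens[i] - u.size), slens[i]),
        )
        i = order[0]
        s, M = int(starts[i]), int(slens[i])
        if orientation == "antisense":
            site_start, site_end = len(seq) - (s + M), len(seq) - s
        else:
            site_start, site_end = s, s + M
        site_seq = scanned[s : s + M]
        ds = score_duplex(mirna, site_seq, max_gaps=max_gaps)
        rows.append(
            {
                "mirna": mirna,
                "transcript": tid,
                "start": site_start,
                "end": site_end,
                "site": site_seq,
                "expectation": e2s[i] / 2.0,
                "mode": ds.mode,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["mirna", "transcript", "start", "end", "site", "expectation", "mode"],
    )


def target_table(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    cutoff: float = 3.0,
    max_gaps: int = 1,
) -> tuple[pd.DataFrame, dict[str, pd.Series]]:
    """Best site per (miRNA, transcript) pair plus target census.

    ``mirnas`` maps miRNA id -> mature sequence.  Returns the long-format
    site table (with miRNA ids) and a census dict with targets-per-miRNA
    and miRNAs-per-target counts.
    """
    frames = []
    for mid, seq in mirnas.items():
        df = scan(seq, transcripts, cutoff=cutoff, max_gaps=max_gaps)
        if len(df):
            df = df.assign(mirna=mid)
            frames.append(df)
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(
            columns=["mirna", "transcript", "start", "end", "site", "expectation", "mode"]
        )
    census = {
        "targets_per_mirna": table.groupby("mirna")["transcript"].nunique(),
        "mirnas_per_target": table.groupby("transcript")["mirna"].nunique(),
    }
    return table, census
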