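"""FASTQ loading, tag collapsing, length/singleton filtering and length
profiling.

Reads are collapsed into *tags* — unique sequences with one count per
library.  The working representation is a pandas DataFrame indexed by
sequence with one integer column per library; ``U`` is normalised to ``T``
on input and reads containing ``N`` (or other non-ACGT characters) are
discarded and counted.

The default length window is 19-27 nt inclusive and singleton removal uses
the total pooled over all libraries (a per-library mode is available), both
configurable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from sporomir.sequences import normalize

_VALID = frozenset("ACGT")


class FastqFormatError(ValueError):
    """A FASTQ record could not be parsed."""


@dataclass
class PreprocessStats:
    """Read accounting through preprocessing.

    Satisfies the conservation identity
    ``reads_in == reads_with_n + removed_by_length + removed_singletons +
    surviving``.
    """

    reads_in: int = 0
    reads_with_n: int = 0
    removed_by_length: int = 0
    removed_singletons: int = 0
    surviving: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def load_and_collapse(
    fastq_paths: list[str | Path], stats: PreprocessStats | None = None
) -> pd.DataFrame:
    """Collapse FASTQ reads into a tag x library count matrix.

    Column order follows the input file order; reads containing non-ACGT
    characters are discarded (counted in ``stats.reads_with_n``).
    """
    counters: list[Counter] = []
    names: list[str] = []
    n_in = 0
    n_bad = 0
    for path in fastq_paths:
        path = Path(path)
        names.append(path.stem)
        counter: Counter = Counter()
        with open(path) as fh:
            try:
                for _title, seq, _qual in FastqGeneralIterator(fh):
                    n_in += 1
                    seq = normalize(seq)
                    if set(seq) <= _VALID and seq:
                        counter[seq] += 1
                    else:
                        n_bad += 1
            except ValueError as exc:
                raise FastqFormatError(
                    f"{path}: malformed FASTQ near record {n_in + 1}: {exc}"
                ) from exc
        counters.append(counter)
    all_tags = sorted(set().union(*counters)) if counters else []
    mat = np.zeros((len(all_tags), len(counters)), dtype=np.int64)
    index = {t: i for i, t in enumerate(all_tags)}
    for j, counter in enumerate(counters):
        for seq, c in counter.items():
            mat[index[seq], j] = c
    tags = pd.DataFrame(mat, index=pd.Index(all_tags, name="sequence"), columns=names)
    if stats is not None:
        stats.reads_in += n_in
        stats.reads_with_n += n_bad
    return tags


def length_filter(
    tags: pd.DataFrame,
    min_len: int = 19,
    max_len: int = 27,
    stats: PreprocessStats | None = None,
) -> pd.DataFrame:
    """Keep tags with min_len <= length <= max_len (both inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len={min_len} exceeds max_len={max_len}")
    lengths = tags.index.str.len()
    keep = (lengths >= min_len) & (lengths <= max_len)
    if stats is not None:
        stats.removed_by_length += int(tags.loc[~keep].values.sum())
    return tags.loc[keep]


def drop_singletons(
    tags: pd.DataFrame,
    min_total: int = 2,
    per_library: bool = False,
    stats: PreprocessStats | None = None,
) -> pd.DataFrame:
    """Remove tags seen fewer than ``min_total`` times.

    By default the threshold applies to the total pooled over libraries;
    with ``per_library=True`` a tag must reach the threshold in at least one
    single library.
    """
    if per_library:
        keep = (tags >= min_total).any(axis=1)
    else:
        keep = tags.sum(axis=1) >= min_total
    if stats is not None:
        stats.removed_singletons += int(tags.loc[~keep].values.sum())
        stats.surviving = int(tags.loc[keep].values.sum())
    return tags.loc[keep]


@dataclass
class LengthProfile:
    """Per-library and pooled read-count histograms over 15-35 nt."""

    per_library: pd.DataFrame  # length x library
    pooled: pd.Series  # length -> total reads
    modes: list[int] = field(default_factory=list)  # local maxima, largest first

    def __post_init__(self):
        if not self.modes:
            maxima = _local_maxima(self.pooled)
            self.modes = sorted(maxima, key=lambda ln: -self.pooled[ln])


def _local_maxima(hist: pd.Series) -> list[int]:
    """Lengths that are strict-or-plateau local maxima with nonzero counts."""
    lengths = list(hist.index)
    vals = hist.values
    modes = []
    for i, ln in enumerate(lengths):
        if vals[i] == 0:
            continue
        left = vals[i - 1] if i > 0 else -1
        right = vals[i + 1] if i < len(vals) - 1 else -1
        if vals[i] >= left and vals[i] > right:
            modes.append(ln)
        elif vals[i] > left and vals[i] >= right:
            modes.append(ln)
    return modes


def length_distribution(
    tags: pd.DataFrame, min_len: int = 15, max_len: int = 35
) -> LengthProfile:
    """Exact integer read-count histograms by length."""
    lengths = tags.index.str.len()
    grouped = tags.groupby(lengths.values).sum()
    idx = pd.Index(range(min_len, max_len + 1), name="length")
    per_library = grouped.reindex(idx, fill_value=0)
    return LengthProfile(per_library, per_library.sum(axis=1))


def run(
    fastq_paths: list[str | Path],
    min_len: int = 19,
    max_len: int = 27,
    min_total: int = 2,
    per_library: bool = False,
) -> tuple[pd.DataFrame, LengthProfile, PreprocessStats]:
    """Full preprocessing: collapse, profile, length-filter, de-singleton.

    Returns the surviving tag matrix, the *pre-filter* length profile and
    the read accounting.
    """
    stats = PreprocessStats()
    tags = load_and_collapse(fastq_paths, stats=stats)
    profile = length_distribution(tags)
    tags = length_filter(tags, min_len, max_len, stats=stats)
    tags = drop_singletons(tags, min_total, per_library=per_library, stats=stats)
    return tags, profile, stats


def write_collapsed_fasta(tags: pd.DataFrame, path: str | Path) -> None:
    """Emit collapsed tags as FASTA with ``>tag{i}_x{total}`` headers."""
    totals = tags.sum(axis=1)
    with open(path, "w") as fh:
        for i, (seq, total) in enumerate(totals.items()):
            fh.write(f">tag{i + 1}_x{int(total)}\n{seq}\n")
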