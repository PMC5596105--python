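"""Small sequence utilities shared across modules.

Sequences are stored as uppercase DNA strings (``ACGT``); ``U`` is converted
to ``T`` on input.  For the numba kernels sequences are encoded as uint8
arrays with A=0, C=1, G=2, T=3.
"""

from __future__ import annotations

import numpy as np

DNA = "ACGT"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# base -> code used by the numba kernels
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(DNA):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

#: bases of the *target/partner* strand that pair a given miRNA/guide base,
#: Watson-Crick plus G:U wobble (G pairs U/T, U/T pairs G)
PAIRING_PARTNERS = {"A": {"T"}, "C": {"G"}, "G": {"C", "T"}, "T": {"A", "G"}}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize(seq: str) -> str:
    """Uppercase and convert RNA ``U`` to DNA ``T``."""
    return seq.upper().replace("U", "T")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0, C=1, G=2, T=3)."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(arr: np.ndarray) -> str:
    return "".join(DNA[c] for c in arr)


def random_seq(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA sequence."""
    return "".join(rng.choice(list(DNA), size=length))


def pairs_with(guide_base: str, partner_base: str) -> bool:
    """True if two bases pair (Watson-Crick or G:U wobble)."""
    return partner_base in PAIRING_PARTNERS[guide_base]


def non_pairing_base(rng: np.random.Generator, guide_base: str) -> str:
    """A base that neither WC- nor wobble-pairs ``guide_base``.

    Used to design mismatches that a maximum-pairing folder cannot rescue.
    """
    choices = [b for b in DNA if b not in PAIRING_PARTNERS[guide_base]]
    return str(rng.choice(choices))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
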