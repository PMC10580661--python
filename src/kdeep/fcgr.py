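"""Frequency chaos game representation (FCGR) of short nucleotide words.

An FCGR at resolution ``k2`` is a ``2**k2 x 2**k2`` grid whose cells are in
bijection with the ``4**k2`` possible k2-mers; the cell value counts how many
sliding windows of the word land on that k-mer.  The bijection used here is
the lexicographic digit encoding A=0, C=1, G=2, T=3 (any fixed bijection
carries the same information; lexicographic indices are auditable by hand).

Windows containing ``N`` are distributed fractionally: a window with ``m``
ambiguous positions adds ``1/4**m`` to every cell compatible with
substituting the Ns, so the total count is conserved at ``W - k2 + 1``
whether or not the word contains Ns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

_DIGIT = {"A": 0, "C": 1, "G": 2, "T": 3}
BASES = "ACGT"


@dataclass(frozen=True)
class FcgrGrid:
    """A ``2**k2 x 2**k2`` non-negative count grid over k2-mers."""

    k2: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        side = 2 ** self.k2
        if self.counts.shape != (side, side):
            raise ValueError(
                f"FCGR grid for k2={self.k2} must be {side}x{side}, "
                f"got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("FCGR counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def flatten(self) -> np.ndarray:
        """Row-major flattening to a length ``4**k2`` vector."""
        return self.counts.reshape(-1)


def kmer_cell_index(word: str, k2: int) -> int:
    """Map an N-free word of length ``k2`` to its cell index in ``[0, 4**k2)``.

    The index is the base-4 number with digits A=0, C=1, G=2, T=3 read left
    to right, i.e. lexicographic rank among all k2-mers.
    """
    if len(word) != k2:
        raise ValueError(f"word {word!r} has length {len(word)}, expected k2={k2}")
    idx = 0
    for ch in word:
        d = _DIGIT.get(ch)
        if d is None:
            raise ValueError(f"word {word!r} contains non-ACGT character {ch!r}")
        idx = idx * 4 + d
    return idx


def fcgr_vector(word: str, k2: int) -> np.ndarray:
    """Profile the k2-mers of ``word`` as a flat vector of length ``4**k2``.

    A window of size ``k2`` slides over ``word`` with step 1.  N-free windows
    add 1 to their cell; a window with ``m`` Ns adds ``1/4**m`` to each of the
    ``4**m`` compatible cells, so the vector always sums to
    ``len(word) - k2 + 1``.
    """
    if k2 < 1:
        raise ValueError("k2 must be a positive integer")
    w = len(word)
    if w < k2:
        raise ValueError(f"word of length {w} is shorter than k2={k2}")
    vec = np.zeros(4 ** k2, dtype=float)
    for i in range(w - k2 + 1):
        window = word[i : i + k2]
        n_pos = [j for j, ch in enumerate(window) if ch == "N"]
        if not n_pos:
            vec[kmer_cell_index(window, k2)] += 1.0
        else:
            weight = 1.0 / 4 ** len(n_pos)
            chars = list(window)
            for subs in itertools.product(BASES, repeat=len(n_pos)):
                for j, b in zip(n_pos, subs):
                    chars[j] = b
                vec[kmer_cell_index("".join(chars), k2)] += weight
    return vec


def fcgr_grid(word: str, k2: int) -> FcgrGrid:
    """Reshape :func:`fcgr_vector` into the ``2**k2 x 2**k2`` grid (row-major)."""
    side = 2 ** k2
    return FcgrGrid(k2=k2, counts=fcgr_vector(word, k2).reshape(side, side))
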