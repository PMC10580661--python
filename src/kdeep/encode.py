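"""The 2Lk two-level encoding and the one-hot baseline.

2Lk(k1, k2) slides a window of size ``k1`` (stride 1) over a strand of
length ``L`` and represents each windowed word by its flattened FCGR count
vector at resolution ``k2``, producing an ``(L - k1 + 1) x 4**k2`` matrix.
Each row sums to ``k1 - k2 + 1`` (the number of inner k2-windows in a
k1-word).  Because every row is a function of its k1-word alone, the whole
encoding factors through a lookup table over the ``5**k1`` words on
{A,C,G,T,N} — 125 entries for k1 = 3 — independent of dataset size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from kdeep.fcgr import fcgr_vector
from kdeep.seqio import LabeledDataset, NucleotideStrand

Scheme = Literal["2lk", "onehot"]
_ONEHOT_ROW = {
    "A": (1.0, 0.0, 0.0, 0.0),
    "C": (0.0, 1.0, 0.0, 0.0),
    "G": (0.0, 0.0, 1.0, 0.0),
    "T": (0.0, 0.0, 0.0, 1.0),
    "N": (0.0, 0.0, 0.0, 0.0),
}


@dataclass(frozen=True)
class KmerWindowing:
    """Outer sliding-window parameters of the 2Lk encoding."""

    k1: int
    stride: int = 1

    def __post_init__(self) -> None:
        if self.k1 < 1 or self.stride < 1:
            raise ValueError("k1 and stride must be positive integers")


@dataclass(frozen=True)
class EncodedStrand:
    """An encoded strand: the 2Lk matrix or the L x 4 one-hot matrix."""

    strand_id: str
    matrix: np.ndarray
    scheme: Scheme


@dataclass
class LookupTable:
    """Precomputed fcgr_vector for every length-k1 word over {A,C,G,T,N}."""

    k1: int
    k2: int
    entries: dict[str, np.ndarray] = field(repr=False)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, word: str) -> np.ndarray:
        return self.entries[word]


def kmerize(strand: NucleotideStrand, windowing: KmerWindowing) -> list[str]:
    """Left-to-right k1-words of the strand under the sliding window.

    With stride 1 this yields exactly ``L - k1 + 1`` words.
    """
    k1, stride = windowing.k1, windowing.stride
    if strand.L < k1:
        raise ValueError(
            f"strand {strand.id!r} of length {strand.L} is shorter than k1={k1}"
        )
    seq = strand.sequence
    return [seq[i : i + k1] for i in range(0, strand.L - k1 + 1, stride)]


def build_lookup(k1: int, k2: int) -> LookupTable:
    """Enumerate fcgr_vector for all ``5**k1`` words over {A,C,G,T,N}."""
    if not 1 <= k2 <= k1:
        raise ValueError(f"require 1 <= k2 <= k1, got k1={k1}, k2={k2}")
    entries = {
        "".join(word): fcgr_vector("".join(word), k2)
        for word in itertools.product("ACGTN", repeat=k1)
    }
    return LookupTable(k1=k1, k2=k2, entries=entries)


def encode_2lk(
    strand: NucleotideStrand,
    k1: int,
    k2: int,
    lookup: LookupTable | None = None,
) -> EncodedStrand:
    """2Lk(k1, k2) encoding: row i is the FCGR vector of the i-th k1-word."""
    if lookup is not None and (lookup.k1, lookup.k2) != (k1, k2):
        raise ValueError("lookup table parameters do not match (k1, k2)")
    words = kmerize(strand, KmerWindowing(k1=k1))
    if lookup is not None:
        rows = [lookup[w] for w in words]
    else:
        rows = [fcgr_vector(w, k2) for w in words]
    return EncodedStrand(
        strand_id=strand.id,
        matrix=np.asarray(rows, dtype=np.float32),
        scheme="2lk",
    )


def encode_onehot(strand: NucleotideStrand) -> EncodedStrand:
    """L x 4 one-hot encoding, columns in A,C,G,T order; N rows are all zero."""
    matrix = np.array(
        [_ONEHOT_ROW[ch] for ch in strand.sequence], dtype=np.float32
    )
    return EncodedStrand(strand_id=strand.id, matrix=matrix, scheme="onehot")


def encode_batch(
    dataset: LabeledDataset,
    scheme: Scheme = "2lk",
    k1: int = 3,
    k2: int = 2,
    pad_policy: str = "zero-right",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode a dataset into a padded 3-axis tensor plus validity mask.

    Shorter strands are right-padded with all-zero rows to the batch maximum
    row count; ``mask[i, r]`` is True where row r of strand i is real data.

    Returns
    -------
    (tensor, mask, labels):
        ``tensor`` has shape (n_strands, max_rows, n_cols) float32, ``mask``
        shape (n_strands, max_rows) bool, ``labels`` the dataset's matrix.
    """
    if pad_policy != "zero-right":
        raise ValueError(f"unsupported pad_policy {pad_policy!r}")
    if len(dataset) == 0:
        raise ValueError("cannot encode an empty dataset")
    if scheme == "2lk":
        lookup = build_lookup(k1, k2)
        encoded = [encode_2lk(s, k1, k2, lookup=lookup) for s in dataset.strands]
    elif scheme == "onehot":
        encoded = [encode_onehot(s) for s in dataset.strands]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    rows = [e.matrix.shape[0] for e in encoded]
    max_rows, n_cols = max(rows), encoded[0].matrix.shape[1]
    tensor = np.zeros((len(encoded), max_rows, n_cols), dtype=np.float32)
    mask = np.zeros((len(encoded), max_rows), dtype=bool)
    for i, e in enumerate(encoded):
        r = e.matrix.shape[0]
        tensor[i, :r] = e.matrix
        mask[i, :r] = True
    return tensor, mask, dataset.labels.copy()


def footprint_report(
    L: int, n_strands: int, scheme: Scheme, k1: int | None = None, k2: int | None = None
) -> dict[str, int]:
    """Shape and memory-footprint arithmetic of an encoded dataset.

    For 2Lk(k1, k2) a strand of length L occupies ``(L - k1 + 1) x 4**k2``
    values (e.g. 373 x 16 for L=375, k1=3, k2=2); one-hot occupies L x 4.
    """
    if scheme == "2lk":
        if k1 is None or k2 is None:
            raise ValueError("2lk footprint requires k1 and k2")
        rows, cols = L - k1 + 1, 4 ** k2
    elif scheme == "onehot":
        rows, cols = L, 4
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return {
        "rows": rows,
        "cols": cols,
        "total_values": n_strands * rows * cols,
    }


def save_encoded(
    path: str | Path,
    tensor: np.ndarray,
    mask: np.ndarray,
    ids: Sequence[str],
    scheme: Scheme,
    k1: int | None = None,
    k2: int | None = None,
    labels: np.ndarray | None = None,
) -> None:
    """Persist an encoded batch (tensor, mask, ids, parameters) as one file."""
    meta = dict(
        tensor=tensor,
        mask=mask,
        ids=np.array(list(ids)),
        scheme=np.array(scheme),
        k1=np.array(-1 if k1 is None else k1),
        k2=np.array(-1 if k2 is None else k2),
    )
    if labels is not None:
        meta["labels"] = np.asarray(labels)
    np.savez_compressed(path, **meta)


def load_encoded(path: str | Path) -> dict:
    """Load a batch written by :func:`save_encoded`."""
    with np.load(path, allow_pickle=False) as data:
        out = {
            "tensor": data["tensor"],
            "mask": data["mask"],
            "ids": [str(s) for s in data["ids"]],
            "scheme": str(data["scheme"]),
            "k1": int(data["k1"]),
            "k2": int(data["k2"]),
        }
        if "labels" in data:
            out["labels"] = data["labels"]
    return out
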