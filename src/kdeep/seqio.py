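"""Sequence and label I/O with alphabet normalization.

Sequences are carried as :class:`NucleotideStrand` records over the alphabet
{A, C, G, T, N}.  RNA is handled by mapping U to T at ingest so one encoder
serves both strand types; IUPAC ambiguity codes other than A/C/G/T collapse
to N.  Labels live in a plain tab-separated sidecar file with one row per
strand: ``id<TAB>l1[<TAB>l2...]``, no header, every value 0 or 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")
# IUPAC nucleotide one-letter codes (upper case, after U->T folding).
_IUPAC = frozenset("ACGTUNRYSWKMBDHV")


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


@dataclass(frozen=True)
class NucleotideStrand:
    """An identified sequence over {A,C,G,T,N}; ``L`` is its length."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"strand {self.id!r} has an empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"strand {self.id!r} contains non-normalized characters {sorted(bad)}; "
                "pass the raw string through normalize_strand first"
            )

    @property
    def L(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Ordered strands plus a binary label matrix (one row per strand)."""

    strands: list[NucleotideStrand]
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim == 1:
            self.labels = self.labels[:, None]
        if self.labels.shape[0] != len(self.strands):
            raise ValueError(
                f"{self.labels.shape[0]} label rows for {len(self.strands)} strands"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        self.labels = self.labels.astype(np.int8)

    def __len__(self) -> int:
        return len(self.strands)

    @property
    def n_targets(self) -> int:
        return self.labels.shape[1]


def normalize_strand(raw: str) -> str:
    """Upper-case, fold U to T, and collapse IUPAC ambiguity codes to N.

    Raises ``ValueError`` naming the offending character and its 0-based
    position for anything outside the IUPAC nucleotide codes.
    """
    if not raw:
        raise ValueError("cannot normalize an empty sequence")
    out = []
    for pos, ch in enumerate(raw):
        up = ch.upper()
        if up not in _IUPAC:
            raise ValueError(
                f"invalid nucleotide character {ch!r} at position {pos}"
            )
        if up == "U":
            up = "T"
        elif up not in "ACGT":
            up = "N"
        out.append(up)
    return "".join(out)


def _check_fasta_structure(path: Path) -> None:
    # Bio.SeqIO does not report line numbers; pre-scan for the one structural
    # error we promise to localize (sequence data before any header).
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                return
            raise FastaParseError(
                f"{path}: sequence data before any '>' header at line {lineno}"
            )


def read_fasta(path: str | Path) -> list[NucleotideStrand]:
    """Read a FASTA file into normalized strands, order preserved.

    An empty file yields an empty list; a sequence line before any header
    raises :class:`FastaParseError` naming the line number.
    """
    path = Path(path)
    _check_fasta_structure(path)
    strands = []
    for record in SeqIO.parse(str(path), "fasta"):
        strands.append(
            NucleotideStrand(id=record.id, sequence=normalize_strand(str(record.seq)))
        )
    return strands


def write_fasta(strands: Sequence[NucleotideStrand], path: str | Path) -> None:
    """Write strands as FASTA, wrapped at 80 columns; round-trips read_fasta."""
    records = [
        SeqRecord(Seq(s.sequence), id=s.id, description="") for s in strands
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=80)
        writer.write_file(records)


def read_labels(
    path: str | Path, n_targets: int, ids: Sequence[str] | None = None
) -> np.ndarray:
    """Read the tab-separated label sidecar into an (n, n_targets) 0/1 matrix.

    Parameters
    ----------
    path:
        File with rows ``id<TAB>l1[<TAB>l2...]``, no header.
    n_targets:
        Expected number of label columns.
    ids:
        Strand ids from the paired FASTA.  When given, rows are re-ordered to
        this order and any missing/extra ids raise a ``ValueError``.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    rows: dict[str, np.ndarray] = {}
    order: list[str] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_targets + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_targets + 1} tab-separated "
                    f"fields, got {len(parts)}"
                )
            sid, values = parts[0], parts[1:]
            for v in values:
                if v not in ("0", "1"):
                    raise ValueError(
                        f"{path}:{lineno}: non-binary label value {v!r}"
                    )
            rows[sid] = np.array([int(v) for v in values], dtype=np.int8)
            order.append(sid)
    if ids is None:
        return np.array([rows[s] for s in order], dtype=np.int8).reshape(
            -1, n_targets
        )
    missing = [s for s in ids if s not in rows]
    extra = [s for s in order if s not in set(ids)]
    if missing or extra:
        raise ValueError(
            f"label ids do not match FASTA ids; missing={missing} extra={extra}"
        )
    return np.stack([rows[s] for s in ids]).astype(np.int8)


def write_labels(
    ids: Sequence[str], labels: np.ndarray, path: str | Path
) -> None:
    """Write the tab-separated label sidecar (inverse of :func:`read_labels`)."""
    labels = np.atleast_2d(np.asarray(labels))
    if labels.shape[0] != len(ids):
        raise ValueError("one label row per id required")
    with open(path, "w") as handle:
        for sid, row in zip(ids, labels):
            handle.write(sid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
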