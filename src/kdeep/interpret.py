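"""Turn first-layer convolution filters into sequence motifs.

A filter of width F (in encoded rows) scans an S-row encoded strand at
P = S - F + 1 sites.  For each filter and each strand the maximal-activation
site is harvested (activation = plain inner product of the filter with the
spanned rows); sites whose activation reaches a fraction of the filter's
global maximum over the scanned set are kept, decoded back to nucleotide
space (a filter spanning F consecutive k1-words covers W = F + k1 - 1
bases), aligned into a position frequency matrix, and normalized with a
pseudocount into a position weight matrix.  Motifs are written in MEME
minimal format for downstream comparison tools such as TOMTOM.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from kdeep.encode import build_lookup, encode_2lk
from kdeep.model import KDeepModel, attention_scores
from kdeep.seqio import NucleotideStrand

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_ROWS = "ACGT"


@dataclass(frozen=True)
class Pfm:
    """Position frequency matrix: raw base counts per motif column.

    ``column_totals`` tracks per-column support; it equals ``n_sites`` except
    where harvested substrings carried Ns (which contribute nothing).
    """

    counts: np.ndarray
    n_sites: int
    column_totals: np.ndarray


@dataclass(frozen=True)
class Pwm:
    """Column-stochastic 4 x W position weight matrix with provenance."""

    probs: np.ndarray
    filter_index: int
    n_sites: int

    def __post_init__(self) -> None:
        if self.probs.shape[0] != 4:
            raise ValueError("PWM must have 4 rows (A,C,G,T)")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]


def scan_activations(filter_matrix: np.ndarray, encoded: np.ndarray) -> tuple[np.ndarray, int]:
    """Inner-product activations of one filter at all P = S - F + 1 sites.

    Returns the activation vector and the argmax site (ties to the leftmost).
    """
    filter_matrix = np.asarray(filter_matrix, dtype=float)
    encoded = np.asarray(encoded, dtype=float)
    F, S = filter_matrix.shape[0], encoded.shape[0]
    if F > S:
        raise ValueError(f"filter width {F} exceeds the {S} encoded rows")
    if filter_matrix.shape[1] != encoded.shape[1]:
        raise ValueError("filter and encoding column counts differ")
    P = S - F + 1
    acts = np.array(
        [float((filter_matrix * encoded[p : p + F]).sum()) for p in range(P)]
    )
    return acts, int(acts.argmax())


def _batch_activations(model: KDeepModel, strands, k1: int, k2: int):
    """Per-strand activation matrices (P_s x n_filters), bias-free."""
    cfg = model.config
    filters = model.params["Wc"]  # (F*C, K)
    lookup = build_lookup(k1, k2)
    per_strand = []
    for strand in strands:
        enc = encode_2lk(strand, k1, k2, lookup=lookup).matrix.astype(float)
        S, F = enc.shape[0], cfg.filter_width
        if F > S:
            raise ValueError(
                f"filter width {F} exceeds the {S} encoded rows of {strand.id!r}"
            )
        windows = np.lib.stride_tricks.sliding_window_view(enc, F, axis=0)
        flat = windows.transpose(0, 2, 1).reshape(S - F + 1, -1)
        per_strand.append(flat @ filters)
    return per_strand


def harvest_substrings(
    model: KDeepModel,
    strands: Sequence[NucleotideStrand],
    activation_fraction: float = 0.5,
    k1: int = 3,
    k2: int = 2,
) -> list[list[str]]:
    """Max-activation nucleotide substrings per filter.

    For each (filter, strand) the maximal-activation site is taken; it is
    kept when its activation reaches ``activation_fraction`` of that filter's
    maximum over all scanned strands (0 means keep every site regardless of
    sign; with a positive fraction, filters that are never positive yield an
    empty list).  Site p decodes to the substring covering bases
    p .. p + F + k1 - 2, i.e. width W = F + k1 - 1.
    """
    if len(strands) == 0:
        raise ValueError("cannot harvest from an empty strand set")
    cfg = model.config
    acts = _batch_activations(model, strands, k1, k2)
    per_filter_max = np.max(
        np.stack([a.max(axis=0) for a in acts]), axis=0
    )  # (K,)
    width = cfg.filter_width + k1 - 1
    out: list[list[str]] = [[] for _ in range(cfg.n_filters)]
    for strand, a in zip(strands, acts):
        best_sites = a.argmax(axis=0)  # leftmost on ties
        best_vals = a[best_sites, np.arange(cfg.n_filters)]
        for k in range(cfg.n_filters):
            if activation_fraction > 0:
                if per_filter_max[k] <= 0:
                    continue
                if best_vals[k] < activation_fraction * per_filter_max[k]:
                    continue
            p = int(best_sites[k])
            out[k].append(strand.sequence[p : p + width])
    return out


def pfm_from_substrings(substrings: Sequence[str], width: int) -> Pfm:
    """Tally base counts per column; N positions contribute nothing."""
    counts = np.zeros((4, width), dtype=int)
    for sub in substrings:
        if len(sub) != width:
            raise ValueError(
                f"substring {sub!r} has width {len(sub)}, expected {width}"
            )
        for j, ch in enumerate(sub):
            idx = _BASE_INDEX.get(ch)
            if idx is not None:
                counts[idx, j] += 1
    return Pfm(
        counts=counts,
        n_sites=len(substrings),
        column_totals=counts.sum(axis=0),
    )


def pwm_from_pfm(pfm: Pfm, pseudocount: float = 0.25, filter_index: int = -1) -> Pwm:
    """Pseudocount-regularized column normalization of a PFM.

    probs[b][j] = (counts[b][j] + pc) / (column_total[j] + 4 pc); a
    zero-count column becomes uniform.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    probs = (pfm.counts + pseudocount) / (
        pfm.column_totals[None, :] + 4.0 * pseudocount
    )
    return Pwm(probs=probs, filter_index=filter_index, n_sites=pfm.n_sites)


def extract_motifs(
    model: KDeepModel,
    strands: Sequence[NucleotideStrand],
    activation_fraction: float = 0.5,
    pseudocount: float = 0.25,
    k1: int = 3,
    k2: int = 2,
) -> list[Pwm]:
    """One PWM per first-layer filter, each of width F + k1 - 1.

    Filters with no qualifying substrings still yield a motif: the
    zero-count PFM normalizes to the uniform PWM.
    """
    width = model.config.filter_width + k1 - 1
    harvested = harvest_substrings(model, strands, activation_fraction, k1, k2)
    pwms = []
    for k, subs in enumerate(harvested):
        pfm = pfm_from_substrings(subs, width)
        pwms.append(pwm_from_pfm(pfm, pseudocount, filter_index=k))
    return pwms


def write_meme(
    pwms: Sequence[Pwm], path: str | Path, alphabet: str = "ACGT"
) -> None:
    """Write motifs in MEME minimal format (TOMTOM's input).

    ``alphabet="ACGU"`` selects RNA mode: the T row is emitted under U.
    """
    if alphabet not in ("ACGT", "ACGU"):
        raise ValueError("alphabet must be 'ACGT' or 'ACGU'")
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write(f"ALPHABET= {alphabet}\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{ch} 0.25000" for ch in alphabet) + "\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF filter_{pwm.filter_index}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= {max(pwm.n_sites, 1)} E= 0\n"
            )
            for j in range(pwm.width):
                fh.write(
                    " ".join(f"{pwm.probs[b, j]:.6f}" for b in range(4)) + "\n"
                )
            fh.write("\n")


def read_meme(path: str | Path) -> list[Pwm]:
    """Read back motifs written by :func:`write_meme` (MEME minimal format)."""
    pwms = []
    with open(path) as fh:
        lines = iter(fh)
        for line in lines:
            if line.startswith("MOTIF"):
                name = line.split()[1]
                header = next(lines)
                parts = header.split()
                fields = dict(zip(parts[2::2], parts[3::2]))
                width = int(fields["w="])
                nsites = int(fields.get("nsites=", 1))
                cols = [
                    [float(v) for v in next(lines).split()] for _ in range(width)
                ]
                probs = np.array(cols).T
                probs = probs / probs.sum(axis=0, keepdims=True)
                idx = int(name.rsplit("_", 1)[-1]) if "_" in name else -1
                pwms.append(Pwm(probs=probs, filter_index=idx, n_sites=nsites))
    return pwms


def motif_similarity(pwm: np.ndarray, reference: np.ndarray) -> float:
    """Best mean per-column Pearson correlation over alignment offsets.

    Slides the narrower matrix along the wider one; at each offset the mean
    over overlapping columns of the Pearson correlation between the two
    4-vectors is taken, and the best offset's value is returned.
    """
    a, b = np.asarray(pwm, dtype=float), np.asarray(reference, dtype=float)
    if a.shape[1] < b.shape[1]:
        a, b = b, a
    wide, narrow = a, b
    best = -1.0
    for off in range(wide.shape[1] - narrow.shape[1] + 1):
        cors = []
        for j in range(narrow.shape[1]):
            x, y = wide[:, off + j], narrow[:, j]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                cors.append(0.0)
            else:
                cors.append(float(np.corrcoef(x, y)[0, 1]))
        best = max(best, float(np.mean(cors)))
    return best


def attention_heatmap(
    model: KDeepModel,
    tensor: np.ndarray,
    mask: np.ndarray,
    path_prefix: str | Path,
) -> np.ndarray:
    """Attention score matrix (strands x pooled positions) + rendered image.

    Writes ``<prefix>.tsv`` (the score matrix) and ``<prefix>.png`` (a
    heatmap).  Requires a model built with attention.
    """
    scores = attention_scores(model, tensor, mask)
    path_prefix = Path(path_prefix)
    np.savetxt(path_prefix.with_suffix(".tsv"), scores, delimiter="\t", fmt="%.6g")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(scores, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xlabel("pooled position")
    ax.set_ylabel("strand")
    fig.colorbar(im, ax=ax, label="attention score")
    fig.tight_layout()
    fig.savefig(path_prefix.with_suffix(".png"), dpi=120)
    plt.close(fig)
    return scores
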