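"""ENAC (Enhanced Nucleic Acid Composition) encoding of RNA windows.

A length-L window is scanned with a short sliding window (default length 2,
stride 1); each placement contributes one row holding the nucleotide
frequencies (count / window length) inside the sub-window, in fixed channel
order A, C, G, U. With the defaults this turns a length-L sequence into an
(L-1) x 4 row-stochastic matrix, the input representation of the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .datasets import SequenceSample

__all__ = [
    "CHANNEL_ORDER",
    "EncodedMatrix",
    "enac_encode",
    "enac_encode_batch",
    "enac_decode_positions",
    "enac_reconstruct",
    "write_encoded_tsv",
]

CHANNEL_ORDER = ("A", "C", "G", "U")
_INDEX = {b: i for i, b in enumerate(CHANNEL_ORDER)}


@dataclass(frozen=True)
class EncodedMatrix:
    """ENAC representation of one sample: rows are sub-window frequency vectors."""

    values: np.ndarray
    sample_id: str = ""
    channel_order: tuple[str, ...] = CHANNEL_ORDER


def _seq_to_indices(sequence: str) -> np.ndarray:
    try:
        return np.array([_INDEX[b] for b in sequence], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGU character {exc.args[0]!r} in sequence") from exc


def enac_encode(
    sample: SequenceSample | str, window: int = 2, stride: int = 1
) -> EncodedMatrix:
    """Encode one window; row i covers positions [i*stride, i*stride + window)."""
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be >= 1")
    if isinstance(sample, SequenceSample):
        seq, sid = sample.sequence, sample.id
    else:
        seq, sid = sample, ""
    if len(seq) < window:
        raise ValueError(f"sequence length {len(seq)} shorter than window {window}")
    idx = _seq_to_indices(seq)
    n_rows = (len(seq) - window) // stride + 1
    onehot = np.zeros((len(seq), 4))
    onehot[np.arange(len(seq)), idx] = 1.0
    rows = np.empty((n_rows, 4))
    for r in range(n_rows):
        start = r * stride
        rows[r] = onehot[start : start + window].sum(axis=0) / window
    return EncodedMatrix(rows, sample_id=sid)


def enac_encode_batch(
    samples: Sequence[SequenceSample], window: int = 2, stride: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Encode many same-length samples.

    Returns ``(X, y)`` where ``X`` has shape (N, rows, 4) and ``y`` is the 0/1
    label vector (1 = positive).
    """
    if not samples:
        raise ValueError("no samples to encode")
    X = np.stack([enac_encode(s, window, stride).values for s in samples])
    y = np.array([1.0 if s.label == "positive" else 0.0 for s in samples])
    return X, y


def enac_decode_positions(row_index: int, window: int = 2) -> set[int]:
    """Nucleotide positions covered by one encoded row (stride 1)."""
    if row_index < 0:
        raise ValueError("row index must be non-negative")
    return set(range(row_index, row_index + window))


def _peel(vals: np.ndarray, first_two: tuple[int, int]) -> list[int] | None:
    """Extend a candidate first 2-mer left-to-right; None if inconsistent."""
    bases = list(first_two)
    for r in range(1, vals.shape[0]):
        rem = vals[r].copy()
        rem[bases[-1]] -= 0.5
        if rem.min() < -1e-9:
            return None
        cand = np.flatnonzero(rem > 0.25)
        if cand.size != 1:
            return None
        bases.append(int(cand[0]))
    return bases


def enac_reconstruct(encoded: EncodedMatrix | np.ndarray, window: int = 2) -> str:
    """Invert the default encoding (window 2, stride 1) back to the sequence.

    Each row overlaps the next by one nucleotide, so subtracting the known
    left member of every 2-mer peels the sequence off left to right. The only
    possible ambiguity is a fully alternating two-letter sequence (xyxy...),
    whose two readings encode identically; since valid samples carry a known
    adenine at the central position, that case is resolved by preferring the
    reading with a central A.
    """
    if window != 2:
        raise ValueError("reconstruction implemented for window=2 only")
    vals = encoded.values if isinstance(encoded, EncodedMatrix) else np.asarray(encoded)
    first = vals[0]
    if np.isclose(first.max(), 1.0):
        b = int(first.argmax())
        starts = [(b, b)]
    else:
        a, c = (int(i) for i in np.flatnonzero(np.isclose(first, 0.5)))
        starts = [(a, c), (c, a)]
    readings = [bases for s in starts if (bases := _peel(vals, s)) is not None]
    if not readings:
        raise ValueError("matrix is not a valid window-2 ENAC encoding")
    center = len(readings[0]) // 2
    for bases in readings:
        if CHANNEL_ORDER[bases[center]] == "A":
            return "".join(CHANNEL_ORDER[b] for b in bases)
    return "".join(CHANNEL_ORDER[b] for b in readings[0])


def write_encoded_tsv(encoded: EncodedMatrix, path: str | Path) -> None:
    """Debug export: one encoded row per line, channels A/C/G/U."""
    header = "row\t" + "\t".join(CHANNEL_ORDER)
    lines = [header]
    for i, row in enumerate(encoded.values):
        lines.append(f"{i}\t" + "\t".join(f"{v:.6g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")
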