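"""Benchmark dataset construction for m6A site classification.

Positive sites are experimentally determined N6-methyladenosine positions on
transcripts; negatives are adenines sampled far from any positive. Both are
restricted to the DRACH consensus context (D = A/G/U, R = A/G, then A, C,
H = A/C/U) in which m6A deposition occurs, and each retained site is expanded
into a fixed-length window with the candidate adenine at the center.

All coordinates are 0-based offsets into the supplied (mature mRNA)
transcript sequence; mapping genomic coordinates onto transcripts is the
caller's responsibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SiteRecord",
    "SequenceSample",
    "WindowRejection",
    "is_drach",
    "read_sites",
    "write_sites",
    "extract_window",
    "extract_windows",
    "sample_negatives",
    "reduce_redundancy",
    "split_train_test",
    "read_fasta",
    "write_fasta",
    "read_transcripts",
]

RNA_ALPHABET = "ACGU"

_D = frozenset("AGU")
_R = frozenset("AG")
_H = frozenset("ACU")

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class SiteRecord:
    """One candidate modification site on a transcript.

    ``position`` is the 0-based offset of the central adenine within the
    transcript sequence.
    """

    transcript_id: str
    position: int
    label: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(
                f"label must be '{POSITIVE}' or '{NEGATIVE}', got {self.label!r}"
            )


@dataclass(frozen=True)
class SequenceSample:
    """A fixed-length, A-centered RNA window with a binary label.

    The window length is odd (L = 2n + 1); the central base is the candidate
    adenine and the 5-mer centered on it matches the DRACH consensus.
    """

    sequence: str
    label: str
    id: str = ""

    @property
    def center(self) -> int:
        return len(self.sequence) // 2

    def validate(self) -> None:
        """Check the central-A / DRACH invariants, raising on violation."""
        seq = self.sequence
        if len(seq) % 2 == 0:
            raise ValueError(f"sample {self.id!r}: window length must be odd")
        c = self.center
        if seq[c] != "A":
            raise ValueError(f"sample {self.id!r}: central base is not A")
        if c < 2 or not is_drach(seq[c - 2 : c + 3]):
            raise ValueError(f"sample {self.id!r}: central 5-mer is not DRACH")


@dataclass(frozen=True)
class WindowRejection:
    """A site excluded from the benchmark, with a machine-readable reason."""

    site: SiteRecord
    reason: str


def is_drach(window5: str) -> bool:
    """Return True iff a 5-mer matches the DRACH consensus.

    D = A/G/U, R = A/G, position 3 = A, position 4 = C, H = A/C/U.
    """
    if len(window5) != 5:
        raise ValueError(f"DRACH test requires a 5-mer, got {window5!r}")
    if any(b not in RNA_ALPHABET for b in window5):
        raise ValueError(f"non-ACGU character in 5-mer {window5!r}")
    return (
        window5[0] in _D
        and window5[1] in _R
        and window5[2] == "A"
        and window5[3] == "C"
        and window5[4] in _H
    )


def _normalize_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


# ---------------------------------------------------------------------------
# site file I/O (TSV dialect: transcript_id <TAB> position <TAB> label [<TAB> source])
# ---------------------------------------------------------------------------

def read_sites(path: str | Path) -> list[SiteRecord]:
    """Read a BED-like TSV of sites (transcript_id, 0-based position, label)."""
    records: list[SiteRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"columns (transcript_id, position, label), got {len(fields)}"
                )
            tid, pos_str, label = fields[0], fields[1], fields[2]
            source = fields[3] if len(fields) > 3 else ""
            try:
                pos = int(pos_str)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer position {pos_str!r}"
                ) from exc
            records.append(SiteRecord(tid, pos, label, source))
    return records


def write_sites(sites: Iterable[SiteRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.transcript_id}\t{s.position}\t{s.label}\t{s.source}\n")


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

def extract_window(
    transcript: str, site: SiteRecord, flank: int = 100
) -> SequenceSample | WindowRejection:
    """Extract the (2*flank+1)-nt window centered on ``site.position``.

    Sites whose window overruns the transcript ends are rejected rather than
    padded, as are sites whose central base is not adenine or whose central
    5-mer fails the DRACH consensus. Rejections carry a reason code
    (``out_of_bounds`` / ``central_not_a`` / ``not_drach``).
    """
    if flank < 2:
        raise ValueError("flank must be >= 2 so the central DRACH 5-mer fits")
    seq = _normalize_rna(transcript)
    pos = site.position
    if pos < 0 or pos >= len(seq):
        return WindowRejection(site, "out_of_bounds")
    if seq[pos] != "A":
        return WindowRejection(site, "central_not_a")
    if pos - flank < 0 or pos + flank >= len(seq):
        return WindowRejection(site, "out_of_bounds")
    if not is_drach(seq[pos - 2 : pos + 3]):
        return WindowRejection(site, "not_drach")
    window = seq[pos - flank : pos + flank + 1]
    sample_id = f"{site.transcript_id}:{site.position}"
    return SequenceSample(window, site.label, sample_id)


def extract_windows(
    transcripts: Mapping[str, str],
    sites: Iterable[SiteRecord],
    flank: int = 100,
) -> tuple[list[SequenceSample], list[WindowRejection]]:
    """Vector version of :func:`extract_window`; unknown transcripts are rejected."""
    samples: list[SequenceSample] = []
    rejections: list[WindowRejection] = []
    for site in sites:
        if site.transcript_id not in transcripts:
            rejections.append(WindowRejection(site, "unknown_transcript"))
            continue
        out = extract_window(transcripts[site.transcript_id], site, flank)
        if isinstance(out, SequenceSample):
            samples.append(out)
        else:
            rejections.append(out)
    return samples, rejections


# ---------------------------------------------------------------------------
# negative sampling
# ---------------------------------------------------------------------------

def sample_negatives(
    transcripts: Mapping[str, str],
    positives: Sequence[SiteRecord],
    n_target: int,
    min_distance: int = 200,
    seed: int = 0,
) -> list[SiteRecord]:
    """Sample negative sites: DRACH-context adenines far from every positive.

    Eligible candidates are all adenines in DRACH context that do not coincide
    with a positive and lie at least ``min_distance`` nt from every positive on
    the same transcript. ``n_target`` candidates are then drawn uniformly
    without replacement (seeded); if fewer exist, all are returned with a
    warning. This two-step scheme (enumerate eligible, then subsample to
    balance) mirrors the usual balanced-benchmark construction.
    """
    if not transcripts:
        raise ValueError("empty transcript set")
    pos_by_tx: dict[str, list[int]] = {}
    for p in positives:
        pos_by_tx.setdefault(p.transcript_id, []).append(p.position)

    candidates: list[SiteRecord] = []
    for tid in sorted(transcripts):
        seq = _normalize_rna(transcripts[tid])
        pos_positions = np.asarray(pos_by_tx.get(tid, []), dtype=int)
        for i in range(2, len(seq) - 2):
            if seq[i] != "A" or not is_drach(seq[i - 2 : i + 3]):
                continue
            if pos_positions.size:
                d = np.abs(pos_positions - i)
                if d.min() < min_distance:  # also excludes i == positive (d=0)
                    continue
            candidates.append(SiteRecord(tid, i, NEGATIVE, source="sampled"))

    if len(candidates) <= n_target:
        if len(candidates) < n_target:
            warnings.warn(
                f"only {len(candidates)} eligible negative candidates for "
                f"n_target={n_target}; returning all"
            )
        return candidates
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n_target, replace=False)
    return [candidates[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# redundancy reduction
# ---------------------------------------------------------------------------

def _seq_matrix(samples: Sequence[SequenceSample]) -> np.ndarray:
    lengths = {len(s.sequence) for s in samples}
    if len(lengths) > 1:
        raise ValueError(f"samples have mixed lengths: {sorted(lengths)}")
    arr = np.frombuffer(
        "".join(s.sequence for s in samples).encode(), dtype=np.uint8
    )
    return arr.reshape(len(samples), -1)


def reduce_redundancy(
    samples: Sequence[SequenceSample], identity_threshold: float = 0.8
) -> list[SequenceSample]:
    """Greedy redundancy removal at a pairwise-identity threshold.

    Samples are scanned in input order; a sample is discarded iff its identity
    to any already-retained sample is >= ``identity_threshold``. Because all
    windows are equal-length and aligned on the central adenine, identity is
    the ungapped positionwise match fraction.
    """
    if not samples:
        return []
    mat = _seq_matrix(samples)
    length = mat.shape[1]
    kept_rows: list[np.ndarray] = []
    kept: list[SequenceSample] = []
    for i, sample in enumerate(samples):
        row = mat[i]
        if kept_rows:
            stack = np.vstack(kept_rows)
            identity = (stack == row).sum(axis=1) / length
            if (identity >= identity_threshold).any():
                continue
        kept_rows.append(row)
        kept.append(sample)
    return kept


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------

def split_train_test(
    samples: Sequence[SequenceSample],
    train_fraction: float = 0.9,
    seed: int = 0,
) -> tuple[list[SequenceSample], list[SequenceSample]]:
    """Seeded, label-stratified split into train and independent test sets.

    Within each label class, round(train_fraction * n) samples go to train.
    A class with fewer than 2 samples is kept whole in train, with a warning.
    """
    if len(samples) < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(seed)
    train: list[SequenceSample] = []
    test: list[SequenceSample] = []
    for label in (POSITIVE, NEGATIVE):
        group = [s for s in samples if s.label == label]
        if not group:
            continue
        if len(group) < 2:
            warnings.warn(f"label class {label!r} has < 2 samples; kept in train")
            train.extend(group)
            continue
        n_train = int(round(train_fraction * len(group)))
        order = rng.permutation(len(group))
        train.extend(group[i] for i in order[:n_train])
        test.extend(group[i] for i in order[n_train:])
    return train, test


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

_LABEL_SUFFIX = {POSITIVE: "pos", NEGATIVE: "neg"}
_SUFFIX_LABEL = {v: k for k, v in _LABEL_SUFFIX.items()}


def write_fasta(samples: Iterable[SequenceSample], path: str | Path) -> None:
    """Write labeled windows as FASTA; the label rides in the header as ``|pos`` / ``|neg``."""
    records = [
        SeqRecord(Seq(s.sequence), id=f"{s.id}|{_LABEL_SUFFIX[s.label]}", description="")
        for s in samples
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[SequenceSample]:
    """Read labeled windows from FASTA (header suffix ``|pos`` / ``|neg``).

    T is treated as a synonym of U; duplicate ids and empty records produce
    warnings, empty records are skipped.
    """
    samples: list[SequenceSample] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalize_rna(str(rec.seq))
        if not seq:
            warnings.warn(f"{path}: empty record {rec.id!r} skipped")
            continue
        header = rec.id
        if "|" in header:
            sid, _, suffix = header.rpartition("|")
            label = _SUFFIX_LABEL.get(suffix)
            if label is None:
                raise ValueError(f"{path}: unknown label suffix {suffix!r} in {header!r}")
        else:
            raise ValueError(f"{path}: header {header!r} lacks a |pos / |neg label suffix")
        if sid in seen:
            warnings.warn(f"{path}: duplicate id {sid!r}")
        seen.add(sid)
        samples.append(SequenceSample(seq, label, sid))
    return samples


def read_transcripts(path: str | Path) -> dict[str, str]:
    """Read transcript sequences as an id -> RNA-string map (T read as U)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            warnings.warn(f"{path}: duplicate transcript id {rec.id!r}; keeping first")
            continue
        out[rec.id] = _normalize_rna(str(rec.seq))
    return out
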