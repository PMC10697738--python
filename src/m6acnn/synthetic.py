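"""Synthetic benchmark data with known ground truth.

The generator emulates balanced positive/negative sets of A-centered windows
in a DRACH context. Crucially, the central 5-mer is drawn uniformly from the
18 DRACH 5-mers for BOTH classes, so the classes are exchangeable at the
center and any learnable signal comes only from motifs planted in the flanks
of positives at a configurable insertion rate. That construction is what
makes motif-recovery and attribution-localization checks meaningful: the
ground-truth signal positions are known per sample.

A transcript-level generator plants positive sites on random transcripts so
the dataset-construction pipeline (negative sampling, window extraction,
redundancy reduction, splitting) can be exercised end to end.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .datasets import (
    NEGATIVE,
    POSITIVE,
    SequenceSample,
    SiteRecord,
    is_drach,
)
from .encoding import CHANNEL_ORDER
from .interpretation import MotifPFM

__all__ = [
    "DRACH_5MERS",
    "PlantedMotif",
    "SimSpec",
    "motif_pfm_from_consensus",
    "generate_dataset",
    "generate_transcripts",
]

#: All 18 5-mers matching the DRACH consensus (D x R x A x C x H).
DRACH_5MERS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("AGU", "AG", "A", "C", "ACU")
)

_IDX = {b: i for i, b in enumerate(CHANNEL_ORDER)}


def motif_pfm_from_consensus(consensus: str, certainty: float = 1.0) -> MotifPFM:
    """One-hot-ish PFM for a consensus string; off-consensus mass is spread
    uniformly when ``certainty`` < 1."""
    freq = np.full((len(consensus), 4), (1.0 - certainty) / 3.0)
    for i, b in enumerate(consensus):
        freq[i] = (1.0 - certainty) / 3.0
        freq[i, _IDX[b]] = certainty
    return MotifPFM(freq, support=0)


@dataclass(frozen=True)
class PlantedMotif:
    """A motif inserted into positive samples.

    ``offset`` is the start of the motif relative to the central adenine
    (negative = upstream). Either a fixed offset or a uniform [low, high]
    range; the motif must never overlap the central DRACH 5-mer.
    """

    pfm: MotifPFM
    offset: int | None = None
    offset_range: tuple[int, int] | None = None
    insertion_rate: float = 1.0

    def __post_init__(self) -> None:
        if (self.offset is None) == (self.offset_range is None):
            raise ValueError("specify exactly one of offset / offset_range")
        if not (0.0 <= self.insertion_rate <= 1.0):
            raise ValueError("insertion_rate must be in [0, 1]")

    def draw_offset(self, rng: np.random.Generator) -> int:
        if self.offset is not None:
            return self.offset
        lo, hi = self.offset_range
        return int(rng.integers(lo, hi + 1))


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one synthetic dataset."""

    n_pos: int
    n_neg: int
    length: int = 201
    background_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted_motifs: tuple[PlantedMotif, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 11 or self.length % 2 == 0:
            raise ValueError("length must be odd and >= 11")
        if not np.isclose(sum(self.background_probs), 1.0):
            raise ValueError("background_probs must sum to 1")
        center = self.length // 2
        for m in self.planted_motifs:
            mlen = m.pfm.length
            offsets = (
                [m.offset] if m.offset is not None else list(m.offset_range)
            )
            for off in offsets:
                start, end = center + off, center + off + mlen  # [start, end)
                if start < 0 or end > self.length:
                    raise ValueError(
                        f"motif (length {mlen}, offset {off}) exceeds the window"
                    )
                if start <= center + 2 and end > center - 2:
                    raise ValueError(
                        f"motif at offset {off} would overlap the central DRACH 5-mer"
                    )


def _sample_from_pfm(pfm: MotifPFM, rng: np.random.Generator) -> str:
    return "".join(
        CHANNEL_ORDER[rng.choice(4, p=row / row.sum())] for row in pfm.freq
    )


def generate_dataset(
    spec: SimSpec, return_truth: bool = False
) -> list[SequenceSample] | tuple[list[SequenceSample], dict]:
    """Generate a balanced labeled dataset under ``spec``.

    Positives receive each planted motif with its insertion rate at an offset
    drawn from its distribution; negatives are pure background around the
    DRACH center. With ``return_truth`` the planted (start, end) nucleotide
    spans per sample id are also returned.
    """
    rng = np.random.default_rng(spec.seed)
    center = spec.length // 2
    p_bg = np.asarray(spec.background_probs, dtype=float)
    truth: dict[str, list[tuple[int, int]]] = {}
    samples: list[SequenceSample] = []
    for label, n, prefix in (
        (POSITIVE, spec.n_pos, "pos"),
        (NEGATIVE, spec.n_neg, "neg"),
    ):
        for i in range(n):
            seq = rng.choice(4, size=spec.length, p=p_bg)
            seq = [CHANNEL_ORDER[b] for b in seq]
            central = DRACH_5MERS[rng.integers(len(DRACH_5MERS))]
            seq[center - 2 : center + 3] = list(central)
            sid = f"{prefix}_{i:05d}"
            spans: list[tuple[int, int]] = []
            if label == POSITIVE:
                for m in spec.planted_motifs:
                    if rng.random() >= m.insertion_rate:
                        continue
                    off = m.draw_offset(rng)
                    start = center + off
                    ins = _sample_from_pfm(m.pfm, rng)
                    seq[start : start + len(ins)] = list(ins)
                    spans.append((start, start + len(ins)))
            samples.append(SequenceSample("".join(seq), label, sid))
            truth[sid] = spans
    if return_truth:
        return samples, truth
    return samples


def generate_transcripts(
    n: int,
    length_range: tuple[int, int] = (600, 1200),
    sites_per_transcript: int = 2,
    seed: int = 0,
    flank: int = 100,
    min_site_spacing: int = 250,
    background_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[dict[str, str], list[SiteRecord]]:
    """Random transcripts with planted positive sites in DRACH context.

    Sites are placed at least ``flank`` nt from the ends (so windows extract
    cleanly) and at least ``min_site_spacing`` nt apart. Returns the
    transcript map and the positive site list in the site-file dialect.
    """
    if length_range[0] < 2 * flank + 1:
        raise ValueError("transcripts must be at least 2*flank+1 long")
    rng = np.random.default_rng(seed)
    p_bg = np.asarray(background_probs, dtype=float)
    transcripts: dict[str, str] = {}
    sites: list[SiteRecord] = []
    for t in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = [CHANNEL_ORDER[b] for b in rng.choice(4, size=length, p=p_bg)]
        tid = f"tx{t:04d}"
        # place sorted jittered positions: guarantees the minimum spacing
        # whenever the transcript is long enough, without rejection sampling
        span = length - 2 * flank - 1  # valid positions: [flank, length-flank-1]
        slack = span - (sites_per_transcript - 1) * min_site_spacing
        if slack < 0:
            raise ValueError(
                f"cannot place {sites_per_transcript} sites {min_site_spacing} nt "
                f"apart on a transcript of length {length}; relax spacing or lengths"
            )
        jitter = np.sort(rng.integers(0, slack + 1, size=sites_per_transcript))
        placed = [
            flank + i * min_site_spacing + int(jitter[i])
            for i in range(sites_per_transcript)
        ]
        for pos in placed:
            central = DRACH_5MERS[rng.integers(len(DRACH_5MERS))]
            seq[pos - 2 : pos + 3] = list(central)
        transcripts[tid] = "".join(seq)
        for pos in sorted(placed):
            sites.append(SiteRecord(tid, pos, POSITIVE, source="planted"))
    return transcripts, sites


def write_truth_json(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=0))
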