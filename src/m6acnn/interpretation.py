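"""Interpretation of the fitted classifier.

Two complementary strategies are implemented.

Model-based (filter-level): the first convolutional layer scans the encoded
sequence, so each filter behaves as a motif detector. Sub-sequences that
activate a filter above half of that filter's maximum activation over the
test set are collected and summarized as a position frequency matrix (PFM);
each filter also gets an *activated amount* (mean number of activating
sub-sequences per test sequence) and an *impact score* measured by virtual
pruning — zeroing the filter's parameters and recording the mean absolute
change in predicted probability.

Propagation-based (per-sequence attribution): forward attribution by
in-silico mutagenesis (every position mutated to each alternative
nucleotide, recording the prediction change) and backward attribution by the
input gradient of the model output, re-projected from encoded (L-1) x 4
space to a 4 x L nucleotide-space attribution map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average as _average_linkage, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .datasets import SequenceSample
from .encoding import CHANNEL_ORDER, enac_encode, enac_encode_batch

__all__ = [
    "MotifPFM",
    "FilterReport",
    "AttributionMap",
    "LinearENACScorer",
    "first_layer_activations",
    "extract_activated_subsequences",
    "build_pfm",
    "activated_amount",
    "impact_score",
    "auc_drop",
    "filter_reports",
    "motif_pcc",
    "best_offset_pcc",
    "pcc_matrix",
    "cluster_motifs",
    "ism_attribution",
    "gradient_attribution",
    "global_position_profile",
    "filter_position_profile",
    "attribution_similarity",
    "export_meme",
    "read_meme",
]

_IDX = {b: i for i, b in enumerate(CHANNEL_ORDER)}


@dataclass(frozen=True)
class MotifPFM:
    """Position frequency matrix (motif_length x 4, rows sum to 1)."""

    freq: np.ndarray
    support: int
    filter_index: int = -1

    @property
    def length(self) -> int:
        return self.freq.shape[0]


@dataclass(frozen=True)
class FilterReport:
    """Per-filter interpretation summary."""

    filter_index: int
    activated_amount: float
    impact_score: float
    pfm: MotifPFM


@dataclass(frozen=True)
class AttributionMap:
    """Per-nucleotide influence scores, shape 4 x L (channels A, C, G, U)."""

    values: np.ndarray
    method: str
    sample_id: str = ""


class LinearENACScorer:
    """Linear scorer over ENAC features: score = sum(W * X) + b.

    Serves as the analytically tractable limit of the classifier: its ISM
    attribution and input gradient have closed forms, so both attribution
    routes can be verified exactly against it.
    """

    def __init__(self, W: np.ndarray, b: float = 0.0) -> None:
        self.W = np.asarray(W, dtype=float)
        self.b = float(b)

    def score(self, X: np.ndarray, output: str = "logit") -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        z = np.einsum("nrc,rc->n", X, self.W) + self.b
        if output == "logit":
            return z
        if output == "prob":
            return 1.0 / (1.0 + np.exp(-z))
        raise ValueError("output must be 'prob' or 'logit'")

    def input_gradient(self, X: np.ndarray, output: str = "logit") -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if output == "logit":
            return np.broadcast_to(self.W, X.shape).copy()
        p = self.score(X, "prob")
        return (p * (1 - p))[:, None, None] * self.W


# ---------------------------------------------------------------------------
# model-based interpretation
# ---------------------------------------------------------------------------

def first_layer_activations(results, X) -> np.ndarray:
    """Post-ReLU activations of the first convolutional layer.

    Shape (N, out_len, n_filters); position p indexes the encoded row at
    which the filter placement starts.
    """
    if len(X) and isinstance(X[0], SequenceSample):
        X, _ = enac_encode_batch(X)
    net = getattr(results, "net", results)
    if not hasattr(net, "first_conv_activations"):
        raise TypeError("results object has no convolutional layer to analyze")
    return net.first_conv_activations(np.asarray(X, dtype=float))


def _filter_thresholds(activations: np.ndarray, threshold_fraction: float) -> np.ndarray:
    return threshold_fraction * activations.max(axis=(0, 1))


def subsequence_length(kernel_rows: int, window: int = 2) -> int:
    """Nucleotides covered by a filter spanning ``kernel_rows`` encoded rows."""
    return kernel_rows + window - 1


def extract_activated_subsequences(
    activations: np.ndarray,
    samples: Sequence[SequenceSample],
    kernel_rows: int,
    threshold_fraction: float = 0.5,
    window: int = 2,
) -> list[list[str]]:
    """Per filter, the nucleotide sub-sequences activating it above threshold.

    The threshold is ``threshold_fraction`` times the filter's maximum
    activation over the whole set (strictly above counts). A placement at
    encoded row p covers nucleotides p .. p + kernel_rows + window - 2.
    """
    n, out_len, n_filters = activations.shape
    if len(samples) != n:
        raise ValueError("activations and samples disagree on N")
    sub_len = subsequence_length(kernel_rows, window)
    thresholds = _filter_thresholds(activations, threshold_fraction)
    out: list[list[str]] = []
    for f in range(n_filters):
        if activations[:, :, f].max() <= 0:
            out.append([])
            continue
        sids, positions = np.nonzero(activations[:, :, f] > thresholds[f])
        subs = [
            samples[i].sequence[p : p + sub_len]
            for i, p in zip(sids, positions)
        ]
        out.append(subs)
    return out


def build_pfm(subsequences: Sequence[str], filter_index: int = -1) -> MotifPFM:
    """Column-wise nucleotide frequencies of aligned equal-length sub-sequences.

    An empty set yields a uniform matrix with support 0 (and a warning) so
    dead filters still produce a well-formed report.
    """
    if not subsequences:
        warnings.warn("no activated subsequences; returning uniform PFM")
        return MotifPFM(np.full((1, 4), 0.25), support=0, filter_index=filter_index)
    lengths = {len(s) for s in subsequences}
    if len(lengths) > 1:
        raise ValueError(f"subsequences have mixed lengths: {sorted(lengths)}")
    length = lengths.pop()
    counts = np.zeros((length, 4))
    for s in subsequences:
        for i, b in enumerate(s):
            counts[i, _IDX[b]] += 1
    return MotifPFM(
        counts / len(subsequences), support=len(subsequences), filter_index=filter_index
    )


def activated_amount(
    activations: np.ndarray, threshold_fraction: float = 0.5
) -> np.ndarray:
    """Mean number of above-threshold placements per test sequence, per filter."""
    n = activations.shape[0]
    thresholds = _filter_thresholds(activations, threshold_fraction)
    counts = (activations > thresholds[None, None, :]).sum(axis=(0, 1))
    dead = activations.max(axis=(0, 1)) <= 0
    counts[dead] = 0
    return counts / n


def impact_score(results, X, filter_index: int, signed: bool = False) -> float:
    """Virtual-pruning impact of one first-layer filter.

    The filter's weights and bias are temporarily zeroed and the score is the
    mean (absolute, by default) change in predicted probability over ``X``;
    the model is restored afterwards.
    """
    X = results._encode_if_needed(X) if hasattr(results, "_encode_if_needed") else X
    p0 = results.predict_proba(X)
    with results.net.filters_nullified([filter_index]):
        p1 = results.predict_proba(X)
    delta = p1 - p0
    return float(np.mean(delta if signed else np.abs(delta)))


def auc_drop(results, X, y, filter_index: int) -> float:
    """AUC(original) - AUC(filter nullified) on a labeled set."""
    from .evaluation import roc_auc

    y = np.asarray(y, dtype=float)
    a0 = roc_auc(y, results.predict_proba(X))
    with results.net.filters_nullified([filter_index]):
        a1 = roc_auc(y, results.predict_proba(X))
    return a0 - a1


def filter_reports(
    results,
    samples: Sequence[SequenceSample],
    threshold_fraction: float = 0.5,
    window: int = 2,
) -> list[FilterReport]:
    """Full per-filter interpretation of the first convolutional layer."""
    X, _ = enac_encode_batch(samples, window=window)
    acts = first_layer_activations(results, X)
    kernel_rows = results.config.conv_blocks[0]["kernel_rows"]
    subs = extract_activated_subsequences(
        acts, samples, kernel_rows, threshold_fraction, window
    )
    amounts = activated_amount(acts, threshold_fraction)
    reports = []
    for f in range(acts.shape[2]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pfm = build_pfm(subs[f], filter_index=f)
        reports.append(
            FilterReport(
                filter_index=f,
                activated_amount=float(amounts[f]),
                impact_score=impact_score(results, X, f),
                pfm=pfm,
            )
        )
    return reports


def reports_to_frame(reports: Sequence[FilterReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "filter_index": [r.filter_index for r in reports],
            "activated_amount": [r.activated_amount for r in reports],
            "impact_score": [r.impact_score for r in reports],
            "support": [r.pfm.support for r in reports],
        }
    )


# ---------------------------------------------------------------------------
# motif comparison and clustering
# ---------------------------------------------------------------------------

def motif_pcc(a: MotifPFM | np.ndarray, b: MotifPFM | np.ndarray) -> float:
    """Pearson correlation of two flattened PFMs; NaN if either is constant."""
    fa = (a.freq if isinstance(a, MotifPFM) else np.asarray(a)).ravel()
    fb = (b.freq if isinstance(b, MotifPFM) else np.asarray(b)).ravel()
    if fa.shape != fb.shape:
        raise ValueError("PFMs must have equal shapes")
    if np.ptp(fa) == 0 or np.ptp(fb) == 0:
        return float("nan")
    return float(pearsonr(fa, fb)[0])


def best_offset_pcc(query: MotifPFM | np.ndarray, target: MotifPFM | np.ndarray) -> float:
    """Maximum PCC over all ungapped alignments of the shorter PFM in the longer."""
    q = query.freq if isinstance(query, MotifPFM) else np.asarray(query)
    t = target.freq if isinstance(target, MotifPFM) else np.asarray(target)
    if q.shape[0] > t.shape[0]:
        q, t = t, q
    best = -np.inf
    for off in range(t.shape[0] - q.shape[0] + 1):
        r = motif_pcc(q, t[off : off + q.shape[0]])
        if not np.isnan(r) and r > best:
            best = r
    return float(best) if np.isfinite(best) else float("nan")


def pcc_matrix(pfms: Sequence[MotifPFM]) -> np.ndarray:
    """Symmetric pairwise-PCC matrix with unit diagonal (NaN where undefined)."""
    n = len(pfms)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = motif_pcc(pfms[i], pfms[j])
    return out


def cluster_motifs(
    pfms: Sequence[MotifPFM], n_clusters: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage hierarchical clustering at distance 1 - PCC.

    PFMs with undefined correlations (constant matrices) are excluded with a
    warning and labeled 0 in the output; valid PFMs get cluster labels 1..k.
    Returns (linkage matrix over the valid PFMs, labels for all inputs).
    """
    if len(pfms) < 2:
        raise ValueError("need at least 2 PFMs to cluster")
    corr = pcc_matrix(pfms)
    valid = np.array([np.ptp(p.freq) > 0 for p in pfms])
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} PFM(s) with undefined correlation excluded"
        )
    vidx = np.flatnonzero(valid)
    if vidx.size < 2:
        raise ValueError("fewer than 2 PFMs with defined pairwise correlations")
    dist = 1.0 - corr[np.ix_(vidx, vidx)]
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = _average_linkage(squareform(dist, checks=False))
    sub_labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    labels = np.zeros(len(pfms), dtype=int)
    labels[vidx] = sub_labels
    return Z, labels


# ---------------------------------------------------------------------------
# propagation-based interpretation
# ---------------------------------------------------------------------------

def ism_attribution(
    scorer,
    sample: SequenceSample,
    output: str = "prob",
    window: int = 2,
) -> AttributionMap:
    """In-silico mutagenesis attribution map (4 x L).

    Entry (b, i) is score(sequence with position i set to b) - score(original)
    for b != x_i, and 0 at the observed nucleotide. Every mutant is re-encoded
    before scoring, so the encoded rows overlapping the mutated position
    change consistently.
    """
    seq = sample.sequence
    L = len(seq)
    X0 = enac_encode(sample, window=window).values
    mutants: list[np.ndarray] = []
    slots: list[tuple[int, int]] = []
    for i in range(L):
        for b in CHANNEL_ORDER:
            if b == seq[i]:
                continue
            mutants.append(
                enac_encode(seq[:i] + b + seq[i + 1 :], window=window).values
            )
            slots.append((_IDX[b], i))
    scores = scorer.score(np.stack(mutants + [X0]), output)
    base = scores[-1]
    values = np.zeros((4, L))
    for (bi, i), s in zip(slots, scores[:-1]):
        values[bi, i] = s - base
    return AttributionMap(values, method="ism", sample_id=sample.id)


def gradient_attribution(
    scorer,
    sample: SequenceSample,
    output: str = "prob",
    window: int = 2,
) -> AttributionMap:
    """Backward-propagation attribution map (4 x L).

    The gradient of the model output w.r.t. the encoded (L-1) x 4 input is
    re-projected to nucleotide space: entry (c, p) sums the gradients of all
    encoded rows covering position p, scaled by 1/window (each row spreads
    one nucleotide's identity over ``window`` frequency entries).
    """
    seq = sample.sequence
    L = len(seq)
    X0 = enac_encode(sample, window=window).values
    g = scorer.input_gradient(X0[None], output)[0]  # (L-window+1, 4)
    n_rows = g.shape[0]
    values = np.zeros((4, L))
    for p in range(L):
        lo = max(0, p - window + 1)
        hi = min(n_rows - 1, p)
        values[:, p] = g[lo : hi + 1].sum(axis=0) / window
    return AttributionMap(values, method="gradient", sample_id=sample.id)


def global_position_profile(maps: Sequence[AttributionMap]) -> np.ndarray:
    """Global per-position influence: mean map across samples, then the
    channel-wise absolute sum at each position (length-L vector)."""
    if not maps:
        raise ValueError("no attribution maps given")
    stack = np.stack([m.values for m in maps])
    mean_map = stack.mean(axis=0)
    return np.abs(mean_map).sum(axis=0)


def filter_position_profile(
    activations: np.ndarray,
    kernel_rows: int,
    seq_len: int,
    threshold_fraction: float = 0.5,
    window: int = 2,
) -> np.ndarray:
    """Filter-based position profile: mean per-sequence count, at each
    nucleotide position, of activated sub-sequences covering it (accumulated
    over filters)."""
    n, out_len, n_filters = activations.shape
    sub_len = subsequence_length(kernel_rows, window)
    thresholds = _filter_thresholds(activations, threshold_fraction)
    live = activations.max(axis=(0, 1)) > 0
    hits = activations > thresholds[None, None, :]
    hits[:, :, ~live] = False
    per_start = hits.sum(axis=(0, 2)).astype(float)  # placements starting at row p
    profile = np.zeros(seq_len)
    for p, c in enumerate(per_start):
        profile[p : p + sub_len] += c
    return profile / n


def attribution_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two attribution-derived vectors (NaN if either is 0)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(np.dot(a, b) / (na * nb))


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def export_meme(pfms: Sequence[MotifPFM], path: str | Path, names: Sequence[str] | None = None) -> None:
    """Write PFMs in MEME minimal motif format (RNA alphabet), e.g. for TOMTOM."""
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGU",
        "",
        "strands: +",
        "",
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 U 0.25",
        "",
    ]
    for i, pfm in enumerate(pfms):
        rows = np.asarray(pfm.freq)
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PFM {i}: rows must sum to 1")
        name = names[i] if names is not None else f"filter_{pfm.filter_index}"
        lines.append(f"MOTIF {name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pfm.length} "
            f"nsites= {max(pfm.support, 1)} E= 0"
        )
        for row in rows:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_meme(path: str | Path) -> list[MotifPFM]:
    """Parse a MEME minimal motif file back into PFMs (round-trip check)."""
    pfms: list[MotifPFM] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if lines[i].startswith("MOTIF"):
            header = lines[i + 1]
            parts = dict(
                zip(
                    [p.rstrip("=") for p in header.split()[2::2]],
                    header.split()[3::2],
                )
            )
            w = int(parts["w"])
            nsites = int(parts.get("nsites", 1))
            rows = [
                [float(v) for v in lines[i + 2 + r].split()] for r in range(w)
            ]
            pfms.append(MotifPFM(np.asarray(rows), support=nsites))
            i += 2 + w
        else:
            i += 1
    return pfms
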