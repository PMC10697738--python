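"""Reference simulation experiments with known ground truth.

These functions wire the package end to end under fixed, documented study
conditions: balanced planted-motif datasets (the GGACU consensus inserted
into the 5' flank of positives at rate 0.9), a matched null condition with no
planted signal, and a three-condition transfer design in which two conditions
share a motif and a third carries a different one. They are used by the test
suite and by the reproduction script; all randomness flows from a single
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr

from .datasets import POSITIVE, SequenceSample, split_train_test
from .encoding import enac_encode_batch
from .evaluation import cross_condition_matrix, roc_auc
from .interpretation import (
    FilterReport,
    auc_drop,
    best_offset_pcc,
    filter_reports,
    ism_attribution,
)
from .model import M6AConvNet, M6AConvNetResults, preset_config
from .synthetic import (
    PlantedMotif,
    SimSpec,
    generate_dataset,
    motif_pfm_from_consensus,
)

__all__ = [
    "PlantedExperiment",
    "run_planted_experiment",
    "filter_recovery_pcc",
    "impact_aucdrop_spearman",
    "ism_localization_ratio",
    "forward_backward_cosine",
    "run_transfer_experiment",
]

DEFAULT_MOTIF = "GGACU"


def _five_prime_offsets(length: int, motif_len: int) -> tuple[int, int]:
    """Uniform motif-start offsets spanning the whole 5' flank without
    touching the central DRACH 5-mer."""
    center = length // 2
    return (-center, -(motif_len + 2))


@dataclass
class PlantedExperiment:
    """One trained planted-motif condition with its held-out test split."""

    train: list[SequenceSample]
    test: list[SequenceSample]
    truth: dict
    results: M6AConvNetResults
    test_auc: float

    @property
    def test_encoded(self):
        return enac_encode_batch(self.test)


def run_planted_experiment(
    seed: int,
    n_pos: int = 2000,
    n_neg: int = 2000,
    length: int = 101,
    motif: str = DEFAULT_MOTIF,
    insertion_rate: float = 0.9,
    max_epochs: int = 20,
) -> PlantedExperiment:
    """Generate, split 9:1, train the small preset, evaluate held-out AUC.

    With ``insertion_rate`` 0 the planted motif is omitted entirely, giving
    the matched null condition (classes exchangeable, expected AUC 1/2).
    """
    motifs = ()
    if insertion_rate > 0:
        motifs = (
            PlantedMotif(
                motif_pfm_from_consensus(motif),
                offset_range=_five_prime_offsets(length, len(motif)),
                insertion_rate=insertion_rate,
            ),
        )
    spec = SimSpec(n_pos, n_neg, length=length, planted_motifs=motifs, seed=seed)
    samples, truth = generate_dataset(spec, return_truth=True)
    train, test = split_train_test(samples, 0.9, seed=seed)
    Xtr, ytr = enac_encode_batch(train)
    config = preset_config(len(train), seed=seed).replace(max_epochs=max_epochs)
    results = M6AConvNet(Xtr, ytr, config).fit()
    Xte, yte = enac_encode_batch(test)
    return PlantedExperiment(
        train=train,
        test=test,
        truth=truth,
        results=results,
        test_auc=roc_auc(yte, results.predict_proba(Xte)),
    )


def filter_recovery_pcc(
    reports: Sequence[FilterReport],
    motif: str = DEFAULT_MOTIF,
    n_shuffles: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Best filter-vs-planted-motif PCC against position-shuffled controls.

    Returns (best PCC of any filter PFM against the planted motif PFM at its
    best ungapped offset, maximum of the same statistic over ``n_shuffles``
    column-shuffled versions of the motif PFM).
    """
    target = motif_pfm_from_consensus(motif).freq
    pfms = [r.pfm for r in reports if r.pfm.support > 0]
    real = max(best_offset_pcc(p, target) for p in pfms)
    rng = np.random.default_rng(seed)
    control = -np.inf
    for _ in range(n_shuffles):
        shuffled = target[rng.permutation(target.shape[0])]
        while (shuffled == target).all():  # e.g. permutations swapping repeated letters
            shuffled = target[rng.permutation(target.shape[0])]
        control = max(control, max(best_offset_pcc(p, shuffled) for p in pfms))
    return float(real), float(control)


def impact_aucdrop_spearman(exp: PlantedExperiment,
                            reports: Sequence[FilterReport]) -> float:
    """Spearman correlation between virtual-pruning impact scores and the AUC
    drop each filter's nullification causes on the test set."""
    X, y = exp.test_encoded
    impacts = [r.impact_score for r in reports]
    drops = [auc_drop(exp.results, X, y, r.filter_index) for r in reports]
    return float(spearmanr(impacts, drops)[0])


def ism_localization_ratio(exp: PlantedExperiment, max_samples: int = 100) -> float:
    """Mean |ISM attribution| over planted-motif positions divided by the mean
    over background positions, averaged over held-out positives."""
    planted_vals: list[float] = []
    background_vals: list[float] = []
    center_span = None
    n_done = 0
    for s in exp.test:
        spans = exp.truth.get(s.id, [])
        if s.label != POSITIVE or not spans:
            continue
        amap = np.abs(ism_attribution(exp.results, s).values)
        L = amap.shape[1]
        c = L // 2
        planted_mask = np.zeros(L, dtype=bool)
        for a, b in spans:
            planted_mask[a:b] = True
        # the central DRACH 5-mer is class-exchangeable, not background signal:
        # exclude it from both sides of the comparison
        exclude = np.zeros(L, dtype=bool)
        exclude[c - 2 : c + 3] = True
        planted_vals.append(amap[:, planted_mask & ~exclude].mean())
        background_vals.append(amap[:, ~planted_mask & ~exclude].mean())
        n_done += 1
        if n_done >= max_samples:
            break
    return float(np.mean(planted_vals) / np.mean(background_vals))


def forward_backward_cosine(exp: PlantedExperiment, max_samples: int = 50) -> float:
    """Mean per-sample cosine similarity between the forward (ISM) and
    backward (gradient) attribution position vectors on held-out samples."""
    from .interpretation import attribution_similarity, gradient_attribution

    sims = []
    for s in exp.test[:max_samples]:
        f = np.abs(ism_attribution(exp.results, s).values).sum(axis=0)
        b = np.abs(gradient_attribution(exp.results, s).values).sum(axis=0)
        sim = attribution_similarity(f, b)
        if np.isfinite(sim):
            sims.append(sim)
    return float(np.mean(sims))


def run_transfer_experiment(
    seed: int,
    shared_motif: str = DEFAULT_MOTIF,
    distinct_motif: str = "UCCUC",
    n_pos: int = 1500,
    n_neg: int = 1500,
    length: int = 101,
    insertion_rate: float = 0.9,
    max_epochs: int = 15,
):
    """Three-condition transfer design: A and B share one planted motif, C
    carries a different one. Returns the predictor-by-dataset AUC matrix."""
    conditions = {"A": shared_motif, "B": shared_motif, "C": distinct_motif}
    models = {}
    testsets = {}
    for i, (name, motif) in enumerate(conditions.items()):
        exp = run_planted_experiment(
            seed + 1000 * (i + 1),
            n_pos=n_pos,
            n_neg=n_neg,
            length=length,
            motif=motif,
            insertion_rate=insertion_rate,
            max_epochs=max_epochs,
        )
        models[name] = exp.results
        testsets[name] = exp.test_encoded
    return cross_condition_matrix(models, testsets)
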