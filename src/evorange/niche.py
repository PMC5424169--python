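"""Static-niche-model post-processing.

The dynamic simulator needs four quantities derived from correlative
niche-model output: a skill-weighted ensemble of per-model occurrence
probability maps (models with TSS < 0.3 discarded), a presence mask via a
TSS-maximizing threshold, the niche width ``V_SENM`` (per-variable
environmental variance over predicted-occupied cells) that anchors the
selection variances, and a per-grid global genotype (mean environment
over predicted-occupied cells) for no-evolution baseline runs.

Model fitting itself is out of scope: callers supply per-model
probability maps and truth labels (or use the synthetic generators in
:mod:`evorange.fixtures`). Where a time-resolved suitability layer is
needed for reporting, :func:`suitability_from_environment` provides a
logistic stand-in driven by the distance from the niche centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


__all__ = [
    "NicheSummary",
    "tss",
    "tss_from_masks",
    "ensemble",
    "binarize",
    "niche_summary",
    "global_genotype",
    "suitability_from_environment",
    "TSS_DISCARD",
]

#: models with a TSS below this value are discarded from the ensemble
TSS_DISCARD = 0.3


def tss(tp: int, fp: int, tn: int, fn: int) -> float:
    """True Skill Statistic: sensitivity + specificity − 1."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("TSS undefined: one truth class is empty")
    return tp / (tp + fn) + tn / (tn + fp) - 1.0


def tss_from_masks(predicted: np.ndarray, truth: np.ndarray) -> float:
    """TSS of a boolean prediction against boolean truth."""
    predicted = np.asarray(predicted, dtype=bool).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    tp = int(np.sum(predicted & truth))
    fp = int(np.sum(predicted & ~truth))
    tn = int(np.sum(~predicted & ~truth))
    fn = int(np.sum(~predicted & truth))
    return tss(tp, fp, tn, fn)


def ensemble(predictions: np.ndarray, tss_scores: np.ndarray,
             discard_below: float = TSS_DISCARD) -> np.ndarray:
    """TSS-weighted ensemble of per-model probability maps.

    ``predictions`` has shape ``(n_models, …)``. Models with TSS below
    ``discard_below`` are dropped; the rest are averaged with weights
    ``TSS_i / Σ TSS_j``.
    """
    predictions = np.asarray(predictions, dtype=float)
    scores = np.asarray(tss_scores, dtype=float)
    if predictions.shape[0] != scores.shape[0]:
        raise ValueError("one TSS score per model is required")
    keep = scores >= discard_below
    if not keep.any():
        raise ValueError("all models discarded (TSS below threshold)")
    w = scores[keep] / scores[keep].sum()
    return np.tensordot(w, predictions[keep], axes=(0, 0))


def binarize(probability: np.ndarray, truth: np.ndarray,
             ) -> tuple[np.ndarray, float]:
    """Presence mask from a TSS-maximizing probability threshold.

    Scans every distinct predicted probability as candidate threshold
    (presence = probability >= threshold) and returns ``(mask,
    threshold)`` for the maximizer; ties resolve to the lowest
    threshold.
    """
    p = np.asarray(probability, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("probability map and truth must share a shape")
    if not t.any() or t.all():
        raise ValueError("degenerate truth: a single class only")
    candidates = np.unique(p)
    if candidates.size < 2:
        raise ValueError("all predictions equal: threshold undefined")
    best_thr, best_tss = None, -np.inf
    for thr in candidates:  # ascending, so ties keep the lowest threshold
        score = tss_from_masks(p >= thr, t)
        if score > best_tss:
            best_thr, best_tss = float(thr), score
    return p >= best_thr, best_thr


@dataclass
class NicheSummary:
    """Niche width and centre over predicted-occupied cells."""

    V_SENM: np.ndarray    # per-variable sample variance
    mean_env: np.ndarray  # per-variable mean
    n_occupied: int

    @property
    def usable(self) -> np.ndarray:
        """Variables with positive niche width."""
        return self.V_SENM > 0


def niche_summary(env: np.ndarray, presence: np.ndarray) -> NicheSummary:
    """Niche width ``V_SENM`` and mean environment of occupied cells.

    ``env`` has shape ``(R, C, T)`` (or ``(n, T)``), ``presence`` is the
    matching boolean mask. Sample variance (ddof=1) per variable.
    """
    env = np.asarray(env, dtype=float)
    mask = np.asarray(presence, dtype=bool)
    values = env.reshape(-1, env.shape[-1])[mask.ravel()]
    if values.shape[0] < 2:
        raise ValueError("need at least 2 occupied cells for a niche width")
    return NicheSummary(values.var(axis=0, ddof=1), values.mean(axis=0),
                        values.shape[0])


def global_genotype(env: np.ndarray, presence: np.ndarray) -> np.ndarray:
    """Per-grid single genotypic value: mean environment over occupied cells.

    Used for no-evolution baseline runs where every individual carries
    this fixed genotype (free to disperse, unable to evolve).
    """
    env = np.asarray(env, dtype=float)
    mask = np.asarray(presence, dtype=bool)
    values = env.reshape(-1, env.shape[-1])[mask.ravel()]
    if values.shape[0] == 0:
        raise ValueError("no occupied cell in grid")
    return values.mean(axis=0)


def suitability_from_environment(env: np.ndarray, centre: np.ndarray,
                                 width: np.ndarray,
                                 steepness: float = 4.0) -> np.ndarray:
    """Synthetic stand-in for projected niche-model suitability.

    Logistic response to the squared environmental distance from the
    niche centre (Mahalanobis with diagonal widths): suitability 0.5 at
    one niche width, higher inside, lower outside. Shape follows
    ``env[..., T] -> env[...]``; values lie in (0, 1).
    """
    env = np.asarray(env, dtype=float)
    centre = np.asarray(centre, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(width <= 0):
        raise ValueError("niche widths must be > 0")
    d2 = np.sum((env - centre) ** 2 / width, axis=-1)
    return 1.0 / (1.0 + np.exp(steepness * (d2 - 1.0)))
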