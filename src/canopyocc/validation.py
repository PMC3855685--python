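"""Predictive evaluation: k-means probability cutoffs, ROC/AUC, and
leave-one-out cross-validation of occupancy predictions.

Predicted occupancy probabilities are dichotomized at the midpoint of the
two centres found by 1-D k-means (k = 2), AUC is the rank (Mann-Whitney)
statistic, and LOOCV refits the model on every n-1 subset to predict each
held-out site. Because true occupancy is latent in the field, ROC labels
default to the observed any-detection indicator; on synthetic data the
true latent state can be evaluated as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import roc_auc_score

from .occupancy import DetectionData, ModelSpec, fit

__all__ = ["RocResult", "LoocvReport", "kmeans_cutoff", "auc", "roc_evaluate", "loocv_auc"]


def kmeans_cutoff(probs: np.ndarray, k: int = 2, seed: int = 0) -> float:
    """Classification cutoff = midpoint of the two 1-D k-means centres.

    Best of 10 seeded restarts; probabilities at or above the cutoff are
    classified as predicted presence.
    """
    probs = np.asarray(probs, dtype=float).reshape(-1, 1)
    if np.unique(probs).size < 2:
        raise ValueError("need at least 2 distinct probabilities for a cutoff")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(probs)
    centers = np.sort(km.cluster_centers_.ravel())
    return float(0.5 * (centers[-2] + centers[-1]))


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    labels = np.asarray(labels, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class RocResult:
    """AUC plus the confusion counts at the k-means cutoff."""

    auc: float
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    validated: bool  # True for LOOCV predictions, False for apparent

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def roc_evaluate(
    labels: np.ndarray, probs: np.ndarray, seed: int = 0, validated: bool = False
) -> RocResult:
    cutoff = kmeans_cutoff(probs, seed=seed)
    pred = np.asarray(probs) >= cutoff
    lab = np.asarray(labels).astype(bool)
    return RocResult(
        auc=auc(lab, probs),
        cutoff=cutoff,
        tp=int(np.sum(pred & lab)),
        fp=int(np.sum(pred & ~lab)),
        tn=int(np.sum(~pred & ~lab)),
        fn=int(np.sum(~pred & lab)),
        validated=validated,
    )


@dataclass
class LoocvReport:
    apparent: RocResult
    loocv: RocResult
    n_failed_refits: int
    loocv_probs: np.ndarray
    apparent_probs: np.ndarray
    labels: np.ndarray


def loocv_auc(
    spec: ModelSpec,
    data: DetectionData,
    seed: int = 0,
    labels: np.ndarray | None = None,
) -> LoocvReport:
    """Apparent and leave-one-out AUC for one occupancy model.

    Each site is predicted from a refit on the remaining n-1 sites; refits
    are warm-started at the full-data optimum. ``labels`` defaults to the
    observed any-detection indicator. Sites whose refit fails are skipped
    with a warning and counted.
    """
    if labels is None:
        labels = np.nanmax(data.y, axis=1)
    labels = np.asarray(labels, dtype=float)

    full = fit(spec, data, seed=seed)
    apparent_probs = full.predict_psi(data.site_covariates)
    warm = np.concatenate([full.beta_psi, full.beta_p])

    n = data.n_sites
    held_out = np.full(n, np.nan)
    n_failed = 0
    for i in range(n):
        rest = np.array([j for j in range(n) if j != i])
        try:
            m = fit(spec, data.subset(rest), n_starts=1, seed=seed, warm_start=warm)
            held_out[i] = m.predict_psi(data.site_covariates.iloc[[i]])[0]
        except Exception as exc:
            n_failed += 1
            warnings.warn(f"LOOCV refit failed for site {i}: {exc}")
    ok = ~np.isnan(held_out)
    if n_failed:
        warnings.warn(f"{n_failed} LOOCV refits failed and were skipped")

    apparent = roc_evaluate(labels, apparent_probs, seed=seed, validated=False)
    loocv = roc_evaluate(labels[ok], held_out[ok], seed=seed, validated=True)
    return LoocvReport(
        apparent=apparent,
        loocv=loocv,
        n_failed_refits=n_failed,
        loocv_probs=held_out,
        apparent_probs=apparent_probs,
        labels=labels,
    )
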