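"""Align individual gradient sets to group-average maps.

Eigenvector order and sign are arbitrary per subject, so individual modes
are matched to group modes by maximum total absolute spatial correlation
(optimal one-to-one assignment; a literal greedy pairwise-swap variant is
available), sign-flipped where the matched correlation is negative, and
retained only when |r| reaches the quality-control threshold (0.50 by
default). Retention proportions across subjects drive the selection of how
many gradients to keep.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import GradientSet
from .errors import ArgumentError, DegenerateModeError, DimensionError

RETENTION_THRESHOLD = 0.50


@dataclasses.dataclass
class AlignmentReport:
    """Per-gradient alignment outcome for one subject.

    ``matched_index[k]`` is the individual mode assigned to group mode k;
    ``r[k]`` the signed spatial correlation after matching (before any
    flip); ``flipped[k]`` whether the mode was inverted; ``retained[k]``
    whether |r| met the threshold.
    """

    subject_id: str
    matched_index: np.ndarray
    r: np.ndarray
    flipped: np.ndarray
    retained: np.ndarray
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        k = len(self.matched_index)
        return pd.DataFrame({
            "subject_id": [self.subject_id] * k,
            "gradient": np.arange(k),
            "matched_index": self.matched_index,
            "r": self.r,
            "flipped": self.flipped,
            "retained": self.retained,
        })


def _correlation_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """corr(a[:, i], b[:, j]) for all column pairs."""
    az = a - a.mean(axis=0)
    bz = b - b.mean(axis=0)
    sa = np.sqrt((az ** 2).sum(axis=0))
    sb = np.sqrt((bz ** 2).sum(axis=0))
    if np.any(sa == 0) or np.any(sb == 0):
        raise DegenerateModeError("constant mode has no spatial correlation")
    return (az.T @ bz) / np.outer(sa, sb)


def _greedy_swap_order(absr: np.ndarray) -> np.ndarray:
    """Literal pairwise procedure: repeatedly swap two assigned modes when
    the exchange increases both matched |r| sums."""
    k = absr.shape[0]
    perm = np.arange(k)
    improved = True
    while improved:
        improved = False
        for i in range(k):
            for j in range(i + 1, k):
                cur = absr[i, perm[i]] + absr[j, perm[j]]
                swp = absr[i, perm[j]] + absr[j, perm[i]]
                if swp > cur + 1e-15:
                    perm[i], perm[j] = perm[j], perm[i]
                    improved = True
    return perm


def align_subject(individual: GradientSet, group: GradientSet,
                  threshold: float = RETENTION_THRESHOLD, *,
                  subject_id: str = "", greedy_swap: bool = False):
    """Match, flip and QC one subject's gradients against the group maps.

    Returns ``(report, aligned)`` where ``aligned`` is the individual
    GradientSet reordered to group order, with matched-negative modes
    inverted (g -> 1 - g on normalized values, otherwise g -> -g).
    """
    if individual.n_modes != group.n_modes:
        raise DimensionError(f"K mismatch: {individual.n_modes} vs "
                             f"{group.n_modes}")
    if individual.n_voxels != group.n_voxels:
        raise DimensionError("voxel count mismatch")
    if not 0 < threshold <= 1:
        raise ArgumentError("threshold must be in (0, 1]")
    corr = _correlation_matrix(group.modes, individual.modes)
    absr = np.abs(corr)
    if greedy_swap:
        perm = _greedy_swap_order(absr)
    else:
        # linear_sum_assignment with row order 0..K-1 breaks exact ties in
        # favour of the lowest group index
        _, perm = linear_sum_assignment(-absr)
    matched_r = corr[np.arange(group.n_modes), perm]
    flipped = matched_r < 0
    retained = np.abs(matched_r) >= threshold
    modes = individual.modes[:, perm].copy()
    for k in np.nonzero(flipped)[0]:
        modes[:, k] = 1.0 - modes[:, k] if individual.normalized else -modes[:, k]
    aligned = GradientSet(modes, individual.eigenvalues[perm],
                          normalized=individual.normalized)
    report = AlignmentReport(subject_id, perm, matched_r, flipped, retained,
                             threshold)
    return report, aligned


def retention_table(reports) -> np.ndarray:
    """Per-gradient proportion of subjects retained after QC."""
    reports = list(reports)
    if not reports:
        raise ArgumentError("need at least one subject")
    retained = np.stack([r.retained for r in reports])
    return retained.mean(axis=0)


def reports_frame(reports) -> pd.DataFrame:
    return pd.concat([r.to_frame() for r in reports], ignore_index=True)


def select_n_gradients(retention, min_retention: float = 0.50,
                       drop_threshold: float = 0.20) -> int:
    """Number of gradients before the first sharp decline in retention.

    A gradient marks the decline when its retention falls below
    ``min_retention`` or drops by more than ``drop_threshold`` relative to
    the previous gradient; with no decline, all gradients are kept.
    """
    retention = np.asarray(retention, dtype=float)
    if retention.size == 0:
        raise ArgumentError("empty retention vector")
    if np.any((retention < 0) | (retention > 1)):
        raise ArgumentError("retention proportions must be in [0, 1]")
    for k, p in enumerate(retention):
        if p < min_retention:
            return k
        if k > 0 and retention[k - 1] - p > drop_threshold:
            return k
    return retention.size
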