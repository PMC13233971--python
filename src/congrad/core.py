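"""Connectopic-mapping engine.

Pipeline per run: connectivity fingerprints (ROI voxel x grey-matter
target correlations) -> eta-squared affinity over ROI voxels -> Laplacian
eigenmaps on the affinity graph -> 0-1 normalization of the resulting
gradient maps. Group-level maps are obtained by averaging subject affinity
matrices (temporal concatenation available as an option).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import linalg
from scipy.sparse.csgraph import connected_components

from .errors import (
    ArgumentError,
    ConnectivityError,
    DegenerateModeError,
    DimensionError,
)
from .image_io import BoldRun

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class GradientSet:
    """K spatial modes over ROI voxels with their Laplacian eigenvalues.

    Modes are columns of ``modes`` (ROI voxel x K), ordered by ascending
    non-zero eigenvalue; mode 0 is the dominant ("zeroth-order") gradient.
    ``normalized`` records whether each mode has been affinely rescaled to
    the range [0, 1].
    """

    modes: np.ndarray
    eigenvalues: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.modes = np.atleast_2d(np.asarray(self.modes, dtype=float))
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float).ravel()
        if self.modes.shape[1] != self.eigenvalues.size:
            raise DimensionError("one eigenvalue per mode required")

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.modes.shape[0]


def _standardize_columns(x):
    """Column z-scores; zero-variance columns become zero with a warning."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    bad = sd == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance series set to zero "
                      "correlation", RuntimeWarning, stacklevel=3)
    sd = np.where(bad, 1.0, sd)
    z = (x - mu) / sd
    z[:, bad] = 0.0
    return z


def compute_fingerprints(run: BoldRun, reduce_dim: int | None = None) -> np.ndarray:
    """Connectivity fingerprints: ROI voxel x target correlation matrix.

    Row v holds the Pearson correlations between ROI voxel v's time series
    and every out-of-ROI grey-matter voxel's series. With ``reduce_dim``
    the target series are first projected onto their top left singular
    vectors and rows are correlations with those component time courses.

    Zero-variance voxels are flagged and enter as zero-correlation
    rows/columns (a logged warning) rather than NaN.
    """
    roi = run.roi_data()
    targets = run.target_data()
    if roi.shape[1] == 0 or targets.shape[1] == 0:
        raise DimensionError("empty ROI or target voxel set")
    t = run.n_timepoints
    if reduce_dim is not None:
        if not 1 <= reduce_dim < t:
            raise ArgumentError("reduce_dim must be in [1, timepoints)")
        centered = targets - targets.mean(axis=0)
        u, _, _ = np.linalg.svd(centered, full_matrices=False)
        targets = u[:, :reduce_dim]
    zr = _standardize_columns(roi)
    zt = _standardize_columns(targets)
    fp = (zr.T @ zt) / t
    return np.clip(fp, -1.0, 1.0)


def eta2_affinity(fingerprints: np.ndarray) -> np.ndarray:
    """eta-squared similarity between all pairs of fingerprint rows.

    For rows a, b with entries x_ai, x_bi the similarity is
    ``1 - sum_i[(x_ai-m_i)^2 + (x_bi-m_i)^2] / sum_i[(x_ai-M)^2 + (x_bi-M)^2]``
    with m_i the pairwise elementwise mean and M the grand mean of both
    rows. Identical rows score 1 (including the degenerate constant-pair
    case); the diagonal is set to 1 exactly.
    """
    f = np.atleast_2d(np.asarray(fingerprints, dtype=float))
    n, p = f.shape
    if n < 2:
        raise DimensionError("need at least 2 ROI voxels")
    s = f.sum(axis=1)
    q = np.einsum("ij,ij->i", f, f)
    gram = f @ f.T
    qq = q[:, None] + q[None, :]
    num = (qq - 2.0 * gram) / 2.0
    den = qq - (s[:, None] + s[None, :]) ** 2 / (2.0 * p)
    with np.errstate(invalid="ignore", divide="ignore"):
        eta = 1.0 - num / den
    eta[den <= 0] = 1.0  # identical (possibly constant) rows
    eta = np.clip(eta, 0.0, 1.0)
    eta = (eta + eta.T) / 2.0
    np.fill_diagonal(eta, 1.0)
    return eta


def _check_connected(w: np.ndarray):
    ncomp, labels = connected_components(w > 0, directed=False)
    if ncomp > 1:
        sizes = np.bincount(labels)
        raise ConnectivityError(sizes.tolist())


def laplacian_eigenmaps(affinity: np.ndarray, n_modes: int,
                        laplacian_kind: str = "random-walk") -> GradientSet:
    """Gradient extraction: smallest non-trivial Laplacian eigenvectors.

    ``random-walk`` (default) solves the generalized problem L v = lambda D v
    with L = D - W; ``unnormalized`` solves L v = lambda v. The trivial
    constant eigenvector at lambda = 0 is discarded and the next ``n_modes``
    eigenvectors are returned in ascending eigenvalue order. Each mode's
    sign is fixed so its correlation with the voxel raster index is >= 0
    (ties broken by making the first non-zero entry positive).
    """
    w = np.asarray(affinity, dtype=float)
    n = w.shape[0]
    if w.shape != (n, n):
        raise DimensionError("affinity must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ArgumentError("affinity must be symmetric")
    if not 1 <= n_modes <= n - 1:
        raise ArgumentError(f"n_modes must be in [1, {n - 1}]")
    if laplacian_kind not in ("random-walk", "unnormalized"):
        raise ArgumentError("laplacian_kind must be 'random-walk' or 'unnormalized'")
    wdiagless = w.copy()
    np.fill_diagonal(wdiagless, 0.0)
    _check_connected(wdiagless)
    d = wdiagless.sum(axis=1)
    lap = np.diag(d) - wdiagless
    if laplacian_kind == "random-walk":
        vals, vecs = linalg.eigh(lap, np.diag(d))
    else:
        vals, vecs = linalg.eigh(lap)
    # drop the constant eigenvector at lambda = 0
    vals, vecs = vals[1:], vecs[:, 1:]
    if n_modes > vals.size:
        raise ArgumentError("n_modes too large after dropping the trivial mode")
    vals, vecs = vals[:n_modes].copy(), vecs[:, :n_modes].copy()
    raster = np.arange(n, dtype=float)
    rc = raster - raster.mean()
    for k in range(n_modes):
        corr = float(rc @ (vecs[:, k] - vecs[:, k].mean()))
        if corr < 0:
            vecs[:, k] *= -1
        elif corr == 0:
            nz = np.nonzero(vecs[:, k])[0]
            if nz.size and vecs[nz[0], k] < 0:
                vecs[:, k] *= -1
    return GradientSet(vecs, np.maximum(vals, 0.0), normalized=False)


def normalize_gradients(gradients: GradientSet) -> GradientSet:
    """Affinely rescale each mode to min 0, max 1 (display convention)."""
    modes = gradients.modes.copy()
    for k in range(gradients.n_modes):
        lo, hi = modes[:, k].min(), modes[:, k].max()
        if hi == lo:
            raise DegenerateModeError(f"mode {k} is constant")
        modes[:, k] = (modes[:, k] - lo) / (hi - lo)
    return GradientSet(modes, gradients.eigenvalues.copy(), normalized=True)


def subject_affinity(run: BoldRun, reduce_dim: int | None = None) -> np.ndarray:
    return eta2_affinity(compute_fingerprints(run, reduce_dim=reduce_dim))


def subject_gradients(run: BoldRun, k: int, *, reduce_dim: int | None = None,
                      laplacian_kind: str = "random-walk",
                      normalize: bool = True) -> GradientSet:
    """Single-subject pipeline: fingerprints -> eta^2 -> eigenmaps -> 0-1."""
    grads = laplacian_eigenmaps(subject_affinity(run, reduce_dim), k,
                                laplacian_kind=laplacian_kind)
    return normalize_gradients(grads) if normalize else grads


def group_gradients(runs, k: int, *, reduce_dim: int | None = None,
                    laplacian_kind: str = "random-walk",
                    aggregation: str = "affinity-mean",
                    normalize: bool = True) -> GradientSet:
    """Group-average gradients from a list of runs.

    ``affinity-mean`` (default) averages subject eta-squared affinity
    matrices before the eigenmap step; ``concat`` concatenates time series
    across subjects and runs the single-subject path on the pooled run.
    """
    runs = list(runs)
    if not runs:
        raise ArgumentError("need at least one run")
    ref = runs[0]
    for r in runs[1:]:
        if (r.roi_mask.shape != ref.roi_mask.shape
                or not np.array_equal(r.roi_mask, ref.roi_mask)
                or not np.array_equal(r.gm_mask, ref.gm_mask)
                or not np.allclose(r.affine, ref.affine, atol=1e-4)):
            raise DimensionError(f"masks/affine of {r.subject_id!r} do not "
                                 f"match {ref.subject_id!r}")
    if aggregation == "affinity-mean":
        aff = np.mean([subject_affinity(r, reduce_dim) for r in runs], axis=0)
    elif aggregation == "concat":
        pooled = BoldRun(np.vstack([r.data for r in runs]), ref.roi_mask,
                         ref.gm_mask, ref.affine, ref.tr_seconds, "group")
        aff = subject_affinity(pooled, reduce_dim)
    else:
        raise ArgumentError("aggregation must be 'affinity-mean' or 'concat'")
    grads = laplacian_eigenmaps(aff, k, laplacian_kind=laplacian_kind)
    return normalize_gradients(grads) if normalize else grads
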