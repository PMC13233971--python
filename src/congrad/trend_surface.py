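"""Trend surface models (TSM): polynomial regression of a masked scalar
field on its world coordinates.

The slope coefficients form a low-dimensional spatial descriptor used by
all correspondence statistics. The supported bases are pure per-axis
monomials (no cross terms):

* k = 6  : {X, X^2, Y, Y^2, Z, Z^2}
* k = 9  : {X, X^2, X^3, Y, Y^2, Y^3, Z, Z^2, Z^3}   (default)
* k = 12 : degrees 1..4 per axis

Coordinates are standardized per axis (mean 0, SD 1 over in-mask voxels)
before basis expansion to control monomial collinearity, and the field is
z-scored over the mask so coefficient magnitudes are comparable across
gradients and templates; the standardization record is stored with the fit.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .errors import ArgumentError, CollinearityError, DegenerateModeError
from .image_io import MaskedVolume, world_coordinates

SUPPORTED_ORDERS = (6, 9, 12)
_AXES = "XYZ"


def basis_labels(order_k: int) -> list[str]:
    """Ordered slope labels, e.g. ['X', 'X^2', 'X^3', 'Y', ...] for k=9."""
    if order_k not in SUPPORTED_ORDERS:
        raise ArgumentError(f"order_k must be one of {SUPPORTED_ORDERS}")
    deg = order_k // 3
    return [f"{ax}^{d}" if d > 1 else ax for ax in _AXES
            for d in range(1, deg + 1)]


@dataclasses.dataclass
class TSMCoefficients:
    """Result of a trend-surface fit.

    ``slopes`` follow the fixed basis order of :func:`basis_labels`;
    ``coordinate_standardization`` records the per-axis (mean, scale) used
    so a fit is reproducible on the same mask.
    """

    slopes: np.ndarray
    intercept: float
    r_squared: float
    order_k: int
    coordinate_standardization: dict
    name: str = ""

    def __post_init__(self):
        self.slopes = np.asarray(self.slopes, dtype=float).ravel()
        if self.order_k not in SUPPORTED_ORDERS:
            raise ArgumentError(f"order_k must be one of {SUPPORTED_ORDERS}")
        if self.slopes.size != self.order_k:
            raise ArgumentError(
                f"{self.slopes.size} slopes for order_k={self.order_k}")

    def to_dict(self) -> dict:
        return {
            "order_k": self.order_k,
            "basis": basis_labels(self.order_k),
            "slopes": self.slopes.tolist(),
            "intercept": float(self.intercept),
            "r_squared": float(self.r_squared),
            "coordinate_standardization": {
                ax: [float(m), float(s)]
                for ax, (m, s) in self.coordinate_standardization.items()
            },
            "name": self.name,
        }


def design_matrix(coords: np.ndarray, order_k: int,
                  standardization: dict | None = None):
    """Polynomial design matrix (without intercept column) and the
    standardization actually applied."""
    coords = np.asarray(coords, dtype=float)
    deg = order_k // 3
    if standardization is None:
        means = coords.mean(axis=0)
        scales = coords.std(axis=0)
        for ax, sc in zip(_AXES, scales):
            if sc == 0:
                raise CollinearityError(
                    f"axis {ax} has zero coordinate spread (planar ROI)")
        standardization = {ax: (m, s) for ax, m, s in zip(_AXES, means, scales)}
    std = np.column_stack([
        (coords[:, i] - standardization[ax][0]) / standardization[ax][1]
        for i, ax in enumerate(_AXES)
    ])
    cols = [std[:, i] ** d for i in range(3) for d in range(1, deg + 1)]
    return np.column_stack(cols), standardization


def fit_tsm(vol: MaskedVolume, order_k: int = 9,
            standardization: dict | None = None) -> TSMCoefficients:
    """Ordinary least squares trend-surface fit of a masked field.

    The field is z-scored over the mask before fitting (a constant field
    is degenerate and raises). Raises :class:`CollinearityError` for
    rank-deficient designs, naming the deficient axis where detectable.
    """
    if order_k not in SUPPORTED_ORDERS:
        raise ArgumentError(f"order_k must be one of {SUPPORTED_ORDERS}")
    y = vol.values
    if y.size <= order_k + 1:
        raise ArgumentError(
            f"need more than {order_k + 1} voxels for order_k={order_k}")
    sd = y.std()
    if sd == 0:
        raise DegenerateModeError(f"field {vol.name!r} is constant")
    yz = (y - y.mean()) / sd
    coords = world_coordinates(vol)
    x, standardization = design_matrix(coords, order_k, standardization)
    xd = np.column_stack([np.ones(len(yz)), x])
    beta, _, rank, _ = np.linalg.lstsq(xd, yz, rcond=None)
    if rank < xd.shape[1]:
        # identify which axis' monomials collapsed, if any
        for i, ax in enumerate(_AXES):
            sub = x[:, i * (order_k // 3):(i + 1) * (order_k // 3)]
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                raise CollinearityError(f"rank-deficient design on axis {ax}")
        raise CollinearityError("rank-deficient design matrix")
    resid = yz - xd @ beta
    # yz has zero mean and unit variance, so TSS = n
    r2 = 1.0 - float(resid @ resid) / len(yz)
    return TSMCoefficients(beta[1:], float(beta[0]),
                           float(np.clip(r2, 0.0, 1.0)), order_k,
                           standardization, name=vol.name)


def tsm_similarity(a: TSMCoefficients, b: TSMCoefficients):
    """Pearson r between two slope vectors and its Fisher z of |r|.

    Returns ``(r, fisher_z)`` with ``fisher_z = atanh(|r|)``; |r| = 1 gives
    +inf with a warning (atanh singularity).
    """
    if a.order_k != b.order_k:
        raise ArgumentError(f"order mismatch: {a.order_k} vs {b.order_k}")
    va, vb = a.slopes, b.slopes
    if va.std() == 0 or vb.std() == 0:
        raise DegenerateModeError("constant slope vector has no correlation")
    r = float(np.corrcoef(va, vb)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        warnings.warn("|r| = 1: Fisher z is infinite", RuntimeWarning,
                      stacklevel=2)
        return r, float("inf")
    return r, float(np.arctanh(abs(r)))
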