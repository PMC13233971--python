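"""Gradient-to-template spatial correspondence statistics.

The core statistic per (gradient, template) pair is the Fisher r-to-z
transformed absolute Pearson correlation between the two TSM slope
vectors. Its significance is assessed three ways:

* a permutation null built by shuffling each template-TSM coefficient
  position independently across the template set (N = 10,000 by default),
* a parametric t-test on the Pearson r with df = k - 2,
* a plain voxel-wise correlation between the two maps as a model-free
  companion.

All p-value families are Benjamini-Hochberg FDR adjusted.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ArgumentError, DimensionError, UndefinedCorrelationError
from .image_io import MaskedVolume
from .trend_surface import TSMCoefficients

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 10_000


@dataclasses.dataclass
class CorrespondenceResult:
    """Tidy per-pair correspondence table plus run metadata."""

    table: pd.DataFrame  # gradient, template, r_tsm, abs_z, p_perm, ...
    n_permutations: int
    seed: int | None
    order_k: int
    scheme: str
    family: str = "all-pairs"


def _slope_matrix(tsms, what: str) -> np.ndarray:
    tsms = list(tsms)
    if not tsms:
        raise ArgumentError(f"no {what} TSMs given")
    k = tsms[0].order_k
    for t in tsms:
        if t.order_k != k:
            raise DimensionError(f"mixed order_k in {what} TSMs")
    return np.stack([t.slopes for t in tsms])


def _rowwise_corr(g: np.ndarray, t: np.ndarray) -> np.ndarray:
    """corr(g[i], t[..., j, :]) over the last axis, broadcasting leading
    axes of t; returns shape t.shape[:-2] + (n_g, n_t)."""
    gz = g - g.mean(axis=-1, keepdims=True)
    gz /= np.sqrt((gz ** 2).sum(axis=-1, keepdims=True))
    tz = t - t.mean(axis=-1, keepdims=True)
    tz /= np.sqrt((tz ** 2).sum(axis=-1, keepdims=True))
    return np.clip(np.einsum("gk,...mk->...gm", gz, tz), -1.0, 1.0)


def _abs_fisher_z(r: np.ndarray) -> np.ndarray:
    a = np.abs(r)
    out = np.full_like(a, np.inf)
    ok = a < 1.0
    out[ok] = np.arctanh(a[ok])
    return out


def _exhaustive_null(t: np.ndarray) -> np.ndarray:
    """All joint per-coefficient shuffles of the template matrix
    (m!)^k arrangements; only feasible for tiny m and k."""
    m, k = t.shape
    perms = list(itertools.permutations(range(m)))
    combos = itertools.product(perms, repeat=k)
    out = np.empty((len(perms) ** k, m, k))
    for b, combo in enumerate(combos):
        for j, pj in enumerate(combo):
            out[b, :, j] = t[list(pj), j]
    return out


def permutation_test(gradient_tsms, template_tsms,
                     n_perm: int = DEFAULT_N_PERM, seed: int | None = 0,
                     scheme: str = "across", exhaustive: bool = False
                     ) -> CorrespondenceResult:
    """Permutation test of TSM-coefficient correspondence.

    Observed statistic per (gradient, template): ``atanh(|r|)`` between
    slope vectors. The null shuffles each coefficient position
    independently across the template set (``scheme='across'``), breaking
    template-specific coefficient patterns while preserving per-coefficient
    marginals; ``scheme='within'`` shuffles within each template's own
    coefficient vector instead (also the fallback when only one template is
    supplied). p = (1 + #{null >= observed}) / (1 + n_perm).

    With ``exhaustive=True`` the full set of distinct per-coefficient
    shuffles is enumerated instead of sampled (tiny problems only).
    """
    g = _slope_matrix(gradient_tsms, "gradient")
    t = _slope_matrix(template_tsms, "template")
    if g.shape[1] != t.shape[1]:
        raise DimensionError("gradient/template order_k mismatch")
    if n_perm < 1:
        raise ArgumentError("n_perm must be >= 1")
    if scheme not in ("across", "within"):
        raise ArgumentError("scheme must be 'across' or 'within'")
    m, k = t.shape
    if scheme == "across" and m < 2:
        logger.warning("single template: falling back to within-vector "
                       "permutation scheme")
        scheme = "within"
    rng = np.random.default_rng(seed)
    obs_r = _rowwise_corr(g, t)
    obs_z = _abs_fisher_z(obs_r)
    if exhaustive:
        if scheme != "across":
            raise ArgumentError("exhaustive enumeration implemented for the "
                                "across-template scheme only")
        null_t = _exhaustive_null(t)
        n_used = null_t.shape[0]
    elif scheme == "across":
        null_t = rng.permuted(
            np.broadcast_to(t, (n_perm, m, k)).copy(), axis=1)
        n_used = n_perm
    else:  # within-vector
        null_t = rng.permuted(
            np.broadcast_to(t, (n_perm, m, k)).copy(), axis=2)
        n_used = n_perm
    null_z = _abs_fisher_z(_rowwise_corr(g, null_t))  # (B, n_g, m)
    exceed = (null_z >= obs_z[None]).sum(axis=0)
    p_perm = (1.0 + exceed) / (1.0 + n_used)
    rows = []
    for gi in range(g.shape[0]):
        for ti in range(m):
            rows.append({
                "gradient": gi, "template": ti,
                "r_tsm": float(obs_r[gi, ti]),
                "abs_z": float(obs_z[gi, ti]),
                "p_perm": float(p_perm[gi, ti]),
            })
    table = pd.DataFrame(rows)
    table["q_perm"] = fdr_adjust(table["p_perm"].to_numpy())
    return CorrespondenceResult(table, n_used, seed, k, scheme)


def parametric_test(gradient_tsms, template_tsms) -> pd.DataFrame:
    """Two-sided t-test for the Pearson r of slope vectors, df = k - 2."""
    g = _slope_matrix(gradient_tsms, "gradient")
    t = _slope_matrix(template_tsms, "template")
    k = g.shape[1]
    if k < 3:
        raise ArgumentError("parametric test needs order_k >= 3")
    r = _rowwise_corr(g, t)
    rows = []
    for gi in range(g.shape[0]):
        for ti in range(t.shape[0]):
            rv = float(r[gi, ti])
            if abs(rv) >= 1.0:
                warnings.warn("|r| = 1: parametric p is 0", RuntimeWarning,
                              stacklevel=2)
                p = 0.0
            else:
                tval = rv * np.sqrt((k - 2) / (1.0 - rv ** 2))
                p = 2.0 * stats.t.sf(abs(tval), df=k - 2)
            rows.append({"gradient": gi, "template": ti, "r_tsm": rv,
                         "p_param": float(p)})
    table = pd.DataFrame(rows)
    table["q_param"] = fdr_adjust(table["p_param"].to_numpy())
    return table


def voxelwise_correlation(gradient: MaskedVolume, template: MaskedVolume
                          ) -> float:
    """Pearson r over shared in-mask voxel values."""
    if gradient.mask.shape != template.mask.shape or \
            not np.array_equal(gradient.mask, template.mask):
        raise DimensionError("gradient and template masks differ")
    if not np.allclose(gradient.affine, template.affine, atol=1e-4):
        raise DimensionError("gradient and template affines differ")
    a, b = gradient.values, template.values
    if a.std() == 0 or b.std() == 0:
        raise UndefinedCorrelationError("constant map has no correlation")
    return float(np.clip(np.corrcoef(a, b)[0, 1], -1.0, 1.0))


def fdr_adjust(pvalues, family: str = "all-pairs") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values over one family."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        raise ArgumentError(f"empty p-value family {family!r}")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ArgumentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def subgroup_split(table: pd.DataFrame, variable: str,
                   rule: str = "median") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split subjects into two subgroups for robustness re-analysis.

    ``median``: median split of a numeric column, ties assigned to the low
    group. ``boolean``: exact partition on a boolean/0-1 column. Subgroups
    smaller than 3 trigger a warning (downstream statistics should be
    suppressed for them).
    """
    if variable not in table.columns:
        raise ArgumentError(f"no column {variable!r} in subject table")
    col = table[variable]
    if rule == "median":
        cutoff = float(col.median())
        low = table[col <= cutoff]
        high = table[col > cutoff]
    elif rule == "boolean":
        vals = col.astype(bool)
        low = table[~vals]
        high = table[vals]
    else:
        raise ArgumentError("rule must be 'median' or 'boolean'")
    for name, part in (("low", low), ("high", high)):
        if len(part) < 3:
            warnings.warn(f"{name} subgroup has {len(part)} subjects; "
                          "statistics suppressed", RuntimeWarning,
                          stacklevel=2)
    return low, high
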