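"""Per-subject gradient-template similarity and brain-behavior statistics.

Individual similarity is the Fisher r-to-z transformed absolute Pearson
correlation between a subject's (aligned, retained) gradient TSM slopes
and a template's TSM slopes. Associations with behavioral outcomes use
Spearman rank correlation (exact two-sided p for n <= 10, t-approximation
above), optionally on covariate-residualized outcomes, with BH-FDR across
the declared outcome x pair family. Correlations from two independent
cohorts are compared with Fisher's z test.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .correspondence import fdr_adjust
from .errors import ArgumentError, CollinearityError, UndefinedCorrelationError
from .trend_surface import TSMCoefficients, fit_tsm, tsm_similarity

logger = logging.getLogger(__name__)


def subject_similarity(subject_tsms: dict, template_tsms: dict,
                       retained: dict | None = None) -> pd.DataFrame:
    """Tidy per-(subject, gradient, template) similarity table.

    Parameters
    ----------
    subject_tsms
        ``{subject_id: {gradient_index: TSMCoefficients}}`` for aligned
        subject gradients.
    template_tsms
        ``{template_name: TSMCoefficients}``.
    retained
        Optional ``{subject_id: {gradient_index: bool}}``; gradients
        QC-excluded for a subject are absent from the output (logged).
    """
    rows = []
    for sid, grads in subject_tsms.items():
        for gi, gtsm in grads.items():
            if retained is not None and not retained.get(sid, {}).get(gi, True):
                logger.info("subject %s gradient %d excluded by QC", sid, gi)
                continue
            for tname, ttsm in template_tsms.items():
                r, z = tsm_similarity(gtsm, ttsm)
                rows.append({"subject_id": sid, "gradient": gi,
                             "template": tname, "r": r, "abs_z": z})
    return pd.DataFrame(rows,
                        columns=["subject_id", "gradient", "template",
                                 "r", "abs_z"])


def _spearman_exact_p(xr: np.ndarray, yr: np.ndarray, r_obs: float) -> float:
    """Two-sided exact p by enumerating all n! orderings of one rank
    vector (mid-ranks kept, so ties are handled)."""
    n = len(xr)
    xz = xr - xr.mean()
    xnorm = math.sqrt(float(xz @ xz))
    total = math.factorial(n)
    count = 0
    it = itertools.permutations(range(n))
    chunk = 100_000
    while True:
        flat = np.fromiter(itertools.chain.from_iterable(
            itertools.islice(it, chunk)), dtype=np.int64)
        if flat.size == 0:
            break
        perms = flat.reshape(-1, n)
        yperm = yr[perms]
        yz = yperm - yperm.mean(axis=1, keepdims=True)
        ynorm = np.sqrt((yz ** 2).sum(axis=1))
        with np.errstate(invalid="ignore"):
            rs = (yz @ xz) / (ynorm * xnorm)
        count += int(np.sum(np.abs(rs) >= abs(r_obs) - 1e-12))
    return count / total


def spearman_correlation(x, y) -> tuple[float, float, int]:
    """Spearman r with mid-rank ties and a two-sided p.

    Exact permutation enumeration for n <= 10, t-approximation above.
    Pairs with missing values are dropped; returns (r_s, p, n_used).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ArgumentError(f"need >= 4 paired observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("constant column in Spearman test")
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    r = float(np.corrcoef(xr, yr)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if 1.0 - abs(r) < 1e-12:  # snap exact rank agreement to +-1
        r = float(np.sign(r))
    if n <= 10:
        p = _spearman_exact_p(xr, yr, r)
    elif abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, min(p, 1.0), n


def spearman_association(similarities: pd.DataFrame, behavior: pd.DataFrame,
                         outcomes, value_col: str = "abs_z") -> pd.DataFrame:
    """Associate per-subject similarity values with behavioral outcomes.

    ``similarities`` must carry subject_id / gradient / template /
    ``value_col``; ``behavior`` one row per subject with the outcome
    columns. One Spearman test per (gradient, template, outcome), BH-FDR
    adjusted across all of them.
    """
    merged = similarities.merge(behavior, on="subject_id", how="inner")
    rows = []
    for (gi, tname), part in merged.groupby(["gradient", "template"],
                                            sort=True):
        for outcome in outcomes:
            r, p, n = spearman_correlation(part[value_col], part[outcome])
            rows.append({"outcome": outcome, "gradient": gi,
                         "template": tname, "n": n, "r_s": r, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = fdr_adjust(table["p"].to_numpy())
    return table


def residualize(table: pd.DataFrame, outcomes, covariates) -> pd.DataFrame:
    """OLS residuals of each outcome column on the covariates + intercept.

    Returns a copy of ``table`` with each outcome column replaced by its
    residuals (listwise deletion on missing covariates is the caller's
    responsibility; missing values here raise).
    """
    cov = table[list(covariates)].to_numpy(dtype=float)
    if np.isnan(cov).any():
        raise ArgumentError("missing covariate values; apply listwise "
                            "deletion first")
    x = np.column_stack([np.ones(len(table)), cov])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise CollinearityError("collinear covariates")
    out = table.copy()
    beta_all, _, _, _ = np.linalg.lstsq(
        x, table[list(outcomes)].to_numpy(dtype=float), rcond=None)
    resid = table[list(outcomes)].to_numpy(dtype=float) - x @ beta_all
    for j, name in enumerate(outcomes):
        out[name] = resid[:, j]
    return out


def compare_correlations(r1: float, n1: int, r2: float, n2: int
                         ) -> tuple[float, float]:
    """Fisher's z test for two correlations from independent samples.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided
    normal p.
    """
    if n1 <= 3 or n2 <= 3:
        raise ArgumentError("both sample sizes must exceed 3")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ArgumentError("|r| must be < 1 for Fisher's z comparison")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p
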