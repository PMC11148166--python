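"""Simplified negative-binomial differential transcription.

A deliberately transparent stand-in for the DESeq2 workflow, covering the
pieces the downstream screens depend on: median-of-ratios size factors, a
method-of-moments dispersion estimate shrunk toward a mean–dispersion
trend, a per-feature two-group NB Wald test (log-linear model with
size-factor offsets, fixed dispersion), Benjamini–Hochberg adjustment per
contrast, and a variance-stabilizing transform. No LFC shrinkage, Cook's
filtering or independent filtering is performed.

The NB model is mean mu_ij = s_j exp(b0_i + b1_i x_j) with variance
mu + alpha mu^2; the Wald statistic is b1 / se(b1) with the expected
Fisher information. Fitting is iteratively reweighted least squares,
vectorized across features (all features share the two-group design).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests
from scipy import stats

from .genomic import CountMatrix

_LN2 = np.log(2.0)
_ALPHA_FLOOR = 1e-8


@dataclass
class Contrast:
    """A named two-group comparison: ``test`` vs ``ref`` sample ids."""

    name: str
    test: list
    ref: list


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    Features with a zero in any sample are excluded from the reference;
    if none remain, falls back to total-count ratios.
    """
    values = counts.values.to_numpy(float)
    if values.shape[1] == 1:
        return pd.Series([1.0], index=counts.sample_ids, name="size_factor")
    all_nonzero = (values > 0).all(axis=1)
    if all_nonzero.sum() == 0:
        import warnings

        warnings.warn("no feature nonzero in all samples; using total-count size factors")
        totals = values.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(sf, index=counts.sample_ids, name="size_factor")
    sub = values[all_nonzero]
    log_ref = np.mean(np.log(sub), axis=1)
    sf = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.sample_ids, name="size_factor")


def estimate_dispersion(
    counts: CountMatrix, sf: pd.Series, groups: list[list] | None = None
) -> pd.DataFrame:
    """Per-feature NB dispersion alpha (variance = mu + alpha mu^2).

    Method-of-moments on normalized counts within replicate groups, floored
    at 1e-8, then shrunk 50/50 on the log scale toward a fitted
    mean-dispersion trend a0 + a1/mu. ``groups`` lists replicate sample-id
    groups; default treats all samples as one group.
    """
    if groups is None:
        groups = [list(counts.sample_ids)]
    q = counts.values.to_numpy(float) / sf.reindex(counts.sample_ids).to_numpy()
    cols = {s: i for i, s in enumerate(counts.sample_ids)}
    num = np.zeros(q.shape[0])
    den = np.zeros(q.shape[0])
    base_mean = q.mean(axis=1)
    for grp in groups:
        idx = [cols[s] for s in grp]
        if len(idx) < 2:
            continue
        sub = q[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / np.square(m)
        ok = np.isfinite(a)
        w = len(idx) - 1
        num[ok] += w * a[ok]
        den[ok] += w
    with np.errstate(invalid="ignore"):
        alpha_mom = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    alpha_mom = np.where(np.isfinite(alpha_mom), alpha_mom, _ALPHA_FLOOR)
    alpha_mom = np.maximum(alpha_mom, _ALPHA_FLOOR)

    alpha_trend = _fit_dispersion_trend(base_mean, alpha_mom)
    alpha = np.exp(0.5 * np.log(alpha_mom) + 0.5 * np.log(alpha_trend))
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "alpha_mom": alpha_mom,
            "alpha_trend": alpha_trend,
            "alpha": alpha,
        },
        index=counts.feature_ids,
    )


def _fit_dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Robust least-squares fit of alpha ~ a0 + a1/mu over informative features."""
    use = (mu > 0) & (alpha > 10 * _ALPHA_FLOOR)
    if use.sum() < 10:
        const = float(np.median(alpha[alpha > 0])) if (alpha > 0).any() else _ALPHA_FLOOR
        return np.full_like(alpha, max(const, _ALPHA_FLOOR))
    a0, a1 = np.median(alpha[use]), 0.0
    for _ in range(5):
        X = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
        coef, *_ = np.linalg.lstsq(X, alpha[use], rcond=None)
        a0, a1 = float(max(coef[0], _ALPHA_FLOOR)), float(max(coef[1], 0.0))
        fitted = a0 + a1 / mu[use]
        ratio = alpha[use] / fitted
        keep = (ratio < 10) & (ratio > 1e-3)
        if keep.all():
            break
        idx = np.flatnonzero(use)
        use = np.zeros_like(use)
        use[idx[keep]] = True
        if use.sum() < 10:
            break
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mu, 1e-12)
    return np.maximum(np.where(mu > 0, trend, a0), _ALPHA_FLOOR)


def _irls_two_group(
    y: np.ndarray, sf: np.ndarray, x: np.ndarray, alpha: np.ndarray, max_iter: int = 50
):
    """Vectorized IRLS for the two-group NB log-linear model.

    y: features x samples; sf: per-sample size factors; x: 0/1 group
    indicator per sample; alpha: per-feature dispersion. Returns
    (b0, b1, se_b1) in natural-log units.
    """
    eps = 1e-8
    ref, tst = x == 0, x == 1
    q = y / sf
    m0 = q[:, ref].mean(axis=1)
    m1 = q[:, tst].mean(axis=1)
    b0 = np.log(np.maximum(m0, eps))
    b1 = np.log(np.maximum(m1, eps)) - b0
    log_sf = np.log(sf)
    alpha = alpha[:, None]
    bound = 30.0
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x[None, :]
        mu = np.exp(np.clip(eta + log_sf[None, :], -300, 300))
        mu = np.maximum(mu, 1e-10)
        w = mu / (1.0 + alpha * mu)
        z = eta + (y - mu) / mu
        sw0 = w[:, ref].sum(axis=1)
        sw1 = w[:, tst].sum(axis=1)
        swz0 = (w * z)[:, ref].sum(axis=1)
        swz1 = (w * z)[:, tst].sum(axis=1)
        new_b0 = swz0 / np.maximum(sw0, 1e-300)
        new_b1 = swz1 / np.maximum(sw1, 1e-300) - new_b0
        new_b0 = np.clip(new_b0, -bound, bound)
        new_b1 = np.clip(new_b1, -bound, bound)
        delta = np.maximum(np.abs(new_b0 - b0), np.abs(new_b1 - b1))
        b0, b1 = new_b0, new_b1
        if np.all(delta < 1e-10):
            break
    eta = b0[:, None] + b1[:, None] * x[None, :]
    mu = np.maximum(np.exp(np.clip(eta + log_sf[None, :], -300, 300)), 1e-10)
    w = mu / (1.0 + alpha * mu)
    sw0 = w[:, ref].sum(axis=1)
    sw1 = w[:, tst].sum(axis=1)
    se_b1 = np.sqrt(1.0 / np.maximum(sw0, 1e-300) + 1.0 / np.maximum(sw1, 1e-300))
    return b0, b1, se_b1


def nb_wald(
    counts: CountMatrix,
    sf: pd.Series,
    contrast: Contrast,
    alpha: pd.Series | float = 0.05,
) -> pd.DataFrame:
    """Two-group NB Wald test for one contrast.

    Returns a frame indexed by feature_id with columns contrast, base_mean,
    log2fc, se (log2 scale), p, padj. Features with zero counts on both
    sides get NA statistics and are excluded from the BH denominator.
    """
    samples = list(contrast.ref) + list(contrast.test)
    if len(contrast.ref) < 2 or len(contrast.test) < 2:
        raise ValueError("nb_wald requires >= 2 replicates on each side of the contrast")
    y = counts.values[samples].to_numpy(float)
    s = sf.reindex(samples).to_numpy(float)
    x = np.array([0] * len(contrast.ref) + [1] * len(contrast.test), dtype=float)
    if np.isscalar(alpha):
        alpha_vec = np.full(y.shape[0], float(alpha))
    else:
        alpha_vec = pd.Series(alpha).reindex(counts.feature_ids).to_numpy(float)
    alpha_vec = np.maximum(np.nan_to_num(alpha_vec, nan=_ALPHA_FLOOR), _ALPHA_FLOOR)

    informative = y.sum(axis=1) > 0
    b0 = np.full(y.shape[0], np.nan)
    b1 = np.full(y.shape[0], np.nan)
    se = np.full(y.shape[0], np.nan)
    if informative.any():
        b0_i, b1_i, se_i = _irls_two_group(y[informative], s, x, alpha_vec[informative])
        b0[informative], b1[informative], se[informative] = b0_i, b1_i, se_i
    with np.errstate(invalid="ignore", divide="ignore"):
        wald_z = b1 / se
        p = 2.0 * stats.norm.sf(np.abs(wald_z))
    p[~informative] = np.nan
    base_mean = (y / s).mean(axis=1)
    out = pd.DataFrame(
        {
            "contrast": contrast.name,
            "base_mean": base_mean,
            "log2fc": b1 / _LN2,
            "se": se / _LN2,
            "p": p,
        },
        index=counts.feature_ids,
    )
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment; NaNs propagated, excluded from m."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def vst(counts: CountMatrix, sf: pd.Series, pseudocount: float = 4.0) -> pd.DataFrame:
    """Variance-stabilizing transform: log2(normalized count + pseudocount).

    The pseudocount (default 4) flattens the variance of low counts,
    approximating the DESeq2 VST's behavior near zero while converging to
    log2 at high abundance.
    """
    q = counts.values.to_numpy(float) / sf.reindex(counts.sample_ids).to_numpy()
    return pd.DataFrame(
        np.log2(q + pseudocount), index=counts.feature_ids, columns=counts.sample_ids
    )


def significant(
    de: pd.DataFrame,
    lfc_min: float = 1.0,
    padj_max: float = 0.01,
    direction: str = "up",
    lfc_inclusive: bool = True,
    padj_inclusive: bool = False,
) -> pd.Index:
    """Feature ids passing a (log2fc, padj) screen.

    ``direction`` 'up' tests log2fc >= lfc_min, 'down' tests
    log2fc <= -lfc_min, 'both' tests |log2fc| >= lfc_min. Comparisons are
    inclusive or strict exactly as configured (the clustering screen uses
    lfc >= 1 and padj < 0.01; the dependence screen uses padj <= 0.05).
    """
    lfc = de["log2fc"]
    if direction == "up":
        pass_lfc = lfc >= lfc_min if lfc_inclusive else lfc > lfc_min
    elif direction == "down":
        pass_lfc = lfc <= -lfc_min if lfc_inclusive else lfc < -lfc_min
    elif direction == "both":
        pass_lfc = lfc.abs() >= lfc_min if lfc_inclusive else lfc.abs() > lfc_min
    else:
        raise ValueError(f"unknown direction {direction!r}")
    padj = de["padj"]
    pass_p = padj <= padj_max if padj_inclusive else padj < padj_max
    return de.index[pass_lfc & pass_p & padj.notna()]
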