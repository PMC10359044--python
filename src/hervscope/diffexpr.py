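"""Negative-binomial Wald differential expression between two conditions.

Per feature we fit an NB GLM with a log link, an intercept, a single
condition coefficient and log size-factor offsets, using a per-feature
method-of-moments dispersion shrunk halfway toward the mean dispersion of
features in the same expression decile.  The Wald statistic
coefficient / SE is referred to a standard normal; Benjamini-Hochberg
controls the FDR, and features are classified up / down / ns for
volcano-style reporting.  The GLM is fit on the natural-log scale and
coefficients are reported in log2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .matrix import CountMatrix
from .preprocess import size_factors

_LN2 = np.log(2.0)
_DISP_FLOOR = 1e-8

DE_COLUMNS = ["feature_id", "base_mean", "log2fc", "se", "wald", "p", "q", "status"]


@dataclass
class DESummary:
    n_up: int
    n_down: int
    n_ns: int


def estimate_dispersions(
    m: CountMatrix, factors: np.ndarray, n_bins: int = 10
) -> np.ndarray:
    """Per-feature NB dispersion: method-of-moments with decile shrinkage.

    The raw estimate alpha = max((s2 - mu) / mu^2, 1e-8) uses the pooled
    within-condition variance of normalized counts; each estimate is then
    averaged 50/50 with the mean raw estimate of its expression decile,
    which stabilizes the small-sample moments.
    """
    norm_counts = m.counts.to_numpy(dtype=float) / factors[None, :]
    conds = m.conditions
    mu_bar = norm_counts.mean(axis=1)
    ss = np.zeros(len(mu_bar))
    dof = 0
    for c in np.unique(conds):
        sub = norm_counts[:, conds == c]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += sub.shape[1] - 1
    s2 = ss / max(dof, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu_bar > 0, (s2 - mu_bar) / mu_bar**2, _DISP_FLOOR)
    raw = np.maximum(raw, _DISP_FLOOR)

    order = np.argsort(mu_bar)
    bins = np.array_split(order, n_bins)
    trend = np.empty_like(raw)
    for idx in bins:
        if len(idx):
            trend[idx] = raw[idx].mean()
    return 0.5 * raw + 0.5 * trend


def nb_wald_de(
    m: CountMatrix,
    factors: pd.Series | np.ndarray | None = None,
    case_label: str = "case",
) -> pd.DataFrame:
    """NB GLM Wald test per feature; returns the volcano-ready table."""
    conds = m.conditions
    levels = set(conds)
    if case_label not in levels or len(levels) != 2:
        raise ValueError(
            f"need exactly two conditions including {case_label!r}; got {sorted(levels)}"
        )
    for c in levels:
        if (conds == c).sum() < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 samples")

    if factors is None:
        factors = size_factors(m)
    f = np.asarray(factors, dtype=float)
    # geometric-mean-1 convention: makes the fit invariant to a global
    # rescaling of the factors (the constant moves into the intercept)
    f = f / np.exp(np.log(f).mean())
    offset = np.log(f)
    is_case = (conds == case_label).astype(float)
    X = np.column_stack([np.ones_like(is_case), is_case])

    counts = m.counts.to_numpy(dtype=float)
    norm_counts = counts / f[None, :]
    base_mean = norm_counts.mean(axis=1)
    alphas = estimate_dispersions(m, f)

    n_feat = counts.shape[0]
    lfc = np.zeros(n_feat)
    se = np.full(n_feat, np.nan)
    wald = np.zeros(n_feat)
    pvals = np.ones(n_feat)
    flagged = np.zeros(n_feat, dtype=bool)

    for i in range(n_feat):
        y = counts[i]
        if not y.any():
            flagged[i] = True
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(
                    y,
                    X,
                    family=sm.families.NegativeBinomial(alpha=float(alphas[i])),
                    offset=offset,
                ).fit(maxiter=100)
            coef, bse = fit.params[1], fit.bse[1]
            if not (np.isfinite(coef) and np.isfinite(bse) and bse > 0):
                raise ValueError("degenerate fit")
        except Exception:
            # moment fallback (e.g. one group all zero): pseudo-count ratio
            mu1 = norm_counts[i, is_case == 1].mean() + 0.5
            mu0 = norm_counts[i, is_case == 0].mean() + 0.5
            lfc[i] = np.log2(mu1 / mu0)
            flagged[i] = True
            continue
        lfc[i] = coef / _LN2
        se[i] = bse / _LN2
        wald[i] = coef / bse
        pvals[i] = 2.0 * norm.sf(abs(wald[i]))

    res = pd.DataFrame(
        {
            "feature_id": m.feature_ids,
            "base_mean": base_mean,
            "log2fc": lfc,
            "se": se,
            "wald": wald,
            "p": np.clip(pvals, np.nextafter(0, 1), 1.0),
            "flagged": flagged,
        }
    )
    res["q"] = bh_adjust(res["p"].to_numpy())
    return res


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_de(
    results: pd.DataFrame, fdr_threshold: float = 0.2
) -> tuple[pd.DataFrame, DESummary]:
    """Attach up/down/ns status at a strict FDR threshold (q == threshold is ns)."""
    if "q" not in results.columns:
        raise ValueError("results must carry BH-adjusted q values")
    out = results.copy()
    sig = out["q"] < fdr_threshold
    status = np.where(
        sig & (out["log2fc"] > 0),
        "up",
        np.where(sig & (out["log2fc"] < 0), "down", "ns"),
    )
    out["status"] = status
    summary = DESummary(
        n_up=int((status == "up").sum()),
        n_down=int((status == "down").sum()),
        n_ns=int((status == "ns").sum()),
    )
    return out, summary
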