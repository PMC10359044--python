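"""Correlation of locus expression with immune genes and signatures.

Pearson correlations between individual retroviral loci (or family sums)
and a target gene such as TLR8, or the per-sample summed expression of an
interferon-stimulated gene signature, on variance-stabilized expression;
plus exhaustive gene-vs-locus association ranking by squared correlation
(a deterministic stand-in for tree-ensemble importance scores).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """Correlation is undefined for a constant vector."""


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-test p on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc, yc = x - x.mean(), y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ZeroVarianceError("correlation undefined: zero-variance input")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * t_dist.sf(abs(t), n - 2))
    return r, p


def signature_sum(vst_matrix: pd.DataFrame, gene_list: set[str] | list[str]) -> pd.Series:
    """Per-sample summed VST expression of the signature genes present."""
    gene_list = set(gene_list)
    present = [g for g in vst_matrix.index if g in gene_list]
    missing = sorted(gene_list - set(present))
    if not present:
        raise ValueError("no signature gene present in the matrix")
    if missing:
        logger.info("signature genes absent from matrix: %s", missing)
    return vst_matrix.loc[present].sum(axis=0)


def _resolve_target(
    vst_matrix: pd.DataFrame, target: str | pd.Series | np.ndarray
) -> tuple[str, np.ndarray]:
    if isinstance(target, str):
        if target not in vst_matrix.index:
            raise KeyError(f"target {target!r} not in matrix")
        return target, vst_matrix.loc[target].to_numpy(dtype=float)
    name = getattr(target, "name", None) or "signature"
    return str(name), np.asarray(target, dtype=float)


@dataclass
class CorrelationSummary:
    n_significant: int
    n_positive_of_significant: int


def locus_target_correlations(
    vst_matrix: pd.DataFrame,
    loci: list[str],
    target: str | pd.Series | np.ndarray,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> tuple[pd.DataFrame, CorrelationSummary]:
    """Per-locus Pearson correlation with a target gene or signature vector.

    Returns the correlation table (r, p, BH q, n) and the summary counts
    of significant loci and positive-among-significant — the
    "19/23 positive" style readout.
    """
    if not loci:
        raise ValueError("empty locus set")
    tname, tvec = _resolve_target(vst_matrix, target)
    rows = []
    for lid in loci:
        if lid not in vst_matrix.index:
            raise KeyError(f"locus {lid!r} not in matrix")
        x = vst_matrix.loc[lid].to_numpy(dtype=float)
        try:
            r, p = pearson_correlation(x, tvec)
            rows.append({"unit_id": lid, "target": tname, "r": r, "p": p,
                         "n": len(x), "undefined": False})
        except ZeroVarianceError:
            rows.append({"unit_id": lid, "target": tname, "r": np.nan, "p": 1.0,
                         "n": len(x), "undefined": True})
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    crit = df["q"] if use_adjusted else df["p"]
    sig = (crit < alpha) & ~df["undefined"]
    summary = CorrelationSummary(
        n_significant=int(sig.sum()),
        n_positive_of_significant=int((sig & (df["r"] > 0)).sum()),
    )
    return df, summary


def family_sum_correlation(
    vst_matrix: pd.DataFrame,
    family_map: dict[str, str],
    family: str,
    target: str | pd.Series | np.ndarray,
) -> tuple[float, float]:
    """Correlation of a family's summed VST expression with the target.

    Family-level sums dilute locus-specific signal: when only a few loci of
    a family track the target, the summed profile typically does not.
    """
    members = [l for l, f in family_map.items() if f == family and l in vst_matrix.index]
    if not members:
        raise ValueError(f"family {family!r} has no locus in the matrix")
    _tname, tvec = _resolve_target(vst_matrix, target)
    fam_sum = vst_matrix.loc[members].sum(axis=0).to_numpy(dtype=float)
    return pearson_correlation(fam_sum, tvec)


def rank_gene_herv_associations(
    vst_matrix: pd.DataFrame,
    gene_ids: list[str],
    herv_ids: list[str],
    top_k: int = 5,
) -> pd.DataFrame:
    """Rank gene-locus pairs by squared Pearson correlation.

    All gene x locus pairs are scored (gene-gene and locus-locus pairs are
    never emitted); constant rows score 0 and are flagged.  Ties break
    lexicographically on (gene, herv).
    """
    if not gene_ids or not herv_ids:
        raise ValueError("both gene and locus id sets must be nonempty")
    G = vst_matrix.loc[list(gene_ids)].to_numpy(dtype=float)
    H = vst_matrix.loc[list(herv_ids)].to_numpy(dtype=float)
    Gc = G - G.mean(axis=1, keepdims=True)
    Hc = H - H.mean(axis=1, keepdims=True)
    gn = np.sqrt((Gc**2).sum(axis=1))
    hn = np.sqrt((Hc**2).sum(axis=1))
    const_g, const_h = gn == 0, hn == 0
    gn[const_g] = 1.0
    hn[const_h] = 1.0
    r = (Gc / gn[:, None]) @ (Hc / hn[:, None]).T
    imp = r**2
    imp[const_g, :] = 0.0
    imp[:, const_h] = 0.0

    rows = [
        {
            "gene": g,
            "herv": h,
            "importance": float(imp[i, j]),
            "flagged": bool(const_g[i] or const_h[j]),
        }
        for i, g in enumerate(gene_ids)
        for j, h in enumerate(herv_ids)
    ]
    df = pd.DataFrame(rows).sort_values(
        ["importance", "gene", "herv"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return df.head(top_k)
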