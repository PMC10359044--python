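"""Count-matrix preprocessing: Y-gene removal, batch adjustment, adaptive
filtering, normalization, variance stabilization and PCA QC.

The default pipeline order is drop_y_genes -> batch_adjust -> jaccard_filter,
after which matrices go to differential expression; every stage is also
individually callable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import nbinom
from sklearn.decomposition import PCA

from .annotation import GeneAnnotation
from .matrix import CountMatrix

logger = logging.getLogger(__name__)

_Y_ALIASES = {"Y", "chrY"}
_DISPERSION_FLOOR = 1e-4


def drop_y_genes(m: CountMatrix, genes: list[GeneAnnotation]) -> CountMatrix:
    """Remove features annotated as genes on the Y chromosome.

    Sex-linked genes inject sex-specific variance unrelated to condition.
    The rule applies to *genes* only: features without a gene annotation
    (retroviral loci among them, wherever they sit) are retained.
    """
    chrom_of = {g.gene_id: g.chrom for g in genes}
    keep, dropped, unannotated = [], [], []
    for fid in m.feature_ids:
        chrom = chrom_of.get(fid)
        if chrom is None:
            unannotated.append(fid)
            keep.append(fid)
        elif chrom in _Y_ALIASES:
            dropped.append(fid)
        else:
            keep.append(fid)
    if unannotated:
        logger.info("retained %d features without gene annotation", len(unannotated))
    if dropped:
        logger.info("dropped %d Y-chromosome genes", len(dropped))
    return m.subset_features(keep)


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios library size factors (the DESeq normalization).

    Features with a zero in any sample are excluded from the reference;
    factor_j = median over remaining features of count_ij / geomean_i.
    """
    counts = m.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature is nonzero in every sample; median-of-ratios is "
            "undefined (consider a pseudo-reference fallback)"
        )
    ref = counts[all_pos]
    geomean = np.exp(np.log(ref).mean(axis=1))
    factors = np.median(ref / geomean[:, None], axis=0)
    return pd.Series(factors, index=m.sample_ids, name="size_factor")


def _mom_dispersion(y: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments NB dispersion pooled over within-group moments."""
    mu_bar = y.mean()
    if mu_bar <= 0:
        return _DISPERSION_FLOOR
    ss, dof = 0.0, 0
    for g in np.unique(groups):
        sub = y[groups == g]
        if len(sub) > 1:
            ss += ((sub - sub.mean()) ** 2).sum()
            dof += len(sub) - 1
    s2 = ss / dof if dof else 0.0
    return max((s2 - mu_bar) / mu_bar**2, _DISPERSION_FLOOR)


def batch_adjust(m: CountMatrix) -> CountMatrix:
    """Remove batch effects from NB counts by quantile matching.

    Per feature, per (batch, condition) cell we estimate a source NB
    distribution (cell mean, per-batch dispersion) and a batch-free target
    NB (condition mean pooled over batches, pooled dispersion), then map
    each observed count through the source CDF to a quantile and back
    through the target inverse CDF.  The condition effect is retained; the
    batch effect is removed.  Counts stay integral and non-negative.
    """
    batches = m.batches
    conds = m.conditions
    batch_levels = np.unique(batches)
    if len(batch_levels) < 2:
        return m.copy()
    cond_levels = np.unique(conds)
    for b in batch_levels:
        present = set(conds[batches == b])
        if present != set(cond_levels):
            missing = set(cond_levels) - present
            raise ValueError(
                f"batch {b!r} lacks condition(s) {sorted(missing)}: batch is "
                "confounded with condition, adjustment refused"
            )

    counts = m.counts.to_numpy(dtype=float)
    n_feat, _ = counts.shape
    adjusted = counts.copy()

    # cell means and batch-size weights
    cell_mean = {
        (b, c): counts[:, (batches == b) & (conds == c)].mean(axis=1)
        for b in batch_levels
        for c in cond_levels
    }
    batch_weight = {b: (batches == b).sum() / len(batches) for b in batch_levels}
    # batch-free target mean per condition: batch-size weighted pool
    target_mean = {
        c: sum(batch_weight[b] * cell_mean[(b, c)] for b in batch_levels)
        for c in cond_levels
    }

    groups = np.array([f"{b}|{c}" for b, c in zip(batches, conds)])
    disp_batch = {
        b: np.array(
            [
                _mom_dispersion(counts[i, batches == b], groups[batches == b])
                for i in range(n_feat)
            ]
        )
        for b in batch_levels
    }
    disp_pooled = np.array(
        [_mom_dispersion(counts[i], groups) for i in range(n_feat)]
    )

    for b in batch_levels:
        for c in cond_levels:
            cols = np.flatnonzero((batches == b) & (conds == c))
            mu_s = cell_mean[(b, c)]
            mu_t = target_mean[c]
            ok = (mu_s > 0) & (mu_t > 0)
            if not ok.any():
                continue
            n_s = 1.0 / disp_batch[b][ok]
            p_s = n_s / (n_s + mu_s[ok])
            n_t = 1.0 / disp_pooled[ok]
            p_t = n_t / (n_t + mu_t[ok])
            y = counts[np.ix_(np.flatnonzero(ok), cols)]
            # mid-quantile mapping keeps the discrete map approximately unbiased
            p_lo = nbinom.cdf(y - 1, n_s[:, None], p_s[:, None])
            p_hi = nbinom.cdf(y, n_s[:, None], p_s[:, None])
            q = np.clip((p_lo + p_hi) / 2.0, 0.0, 1.0 - 1e-12)
            new = nbinom.ppf(q, n_t[:, None], p_t[:, None])
            adjusted[np.ix_(np.flatnonzero(ok), cols)] = new

    out = pd.DataFrame(
        np.maximum(np.rint(adjusted), 0).astype(np.int64),
        index=m.feature_ids,
        columns=m.sample_ids,
    )
    return CountMatrix(out, list(m.samples))


@dataclass
class JaccardFilterResult:
    matrix: CountMatrix
    threshold: float
    similarity_curve: list[tuple[float, float]]


def jaccard_filter(m: CountMatrix, max_grid: int = 200) -> JaccardFilterResult:
    """Adaptive low-expression filter maximizing within-condition Jaccard.

    Counts are size-factor normalized, binarized at each candidate
    threshold s (normalized count > s), and the mean Jaccard index over
    within-condition sample pairs is computed; the threshold s* maximizing
    it defines the filter.  Features exceeding s* in at least one sample
    are retained.
    """
    counts = m.counts.to_numpy(dtype=float)
    if not counts.any():
        raise ValueError("all-zero matrix cannot be filtered")
    factors = size_factors(m).to_numpy()
    norm = counts / factors[None, :]

    # candidate thresholds: 0 plus the positive normalized values strictly
    # below the global max (binarization is strict, so thresholding at the
    # max would blank the matrix), capped at the 95th percentile
    vals = np.unique(norm[norm > 0])
    vals = vals[vals < vals[-1]]
    vals = vals[vals <= np.quantile(vals, 0.95)] if len(vals) else vals
    if len(vals) > max_grid - 1:
        idx = np.linspace(0, len(vals) - 1, max_grid - 1).round().astype(int)
        vals = vals[np.unique(idx)]
    vals = np.concatenate([[0.0], vals])

    conds = m.conditions
    pairs = [
        (i, j)
        for c in np.unique(conds)
        for ii in [np.flatnonzero(conds == c)]
        for a, i in enumerate(ii)
        for j in ii[a + 1:]
    ]
    if not pairs:
        raise ValueError("need >= 2 samples in at least one condition")

    curve = []
    for s in vals:
        B = norm > s
        sims = []
        for i, j in pairs:
            union = np.logical_or(B[:, i], B[:, j]).sum()
            if union == 0:
                continue
            inter = np.logical_and(B[:, i], B[:, j]).sum()
            sims.append(inter / union)
        curve.append((float(s), float(np.mean(sims)) if sims else 0.0))

    best = max(range(len(curve)), key=lambda k: (curve[k][1], -curve[k][0]))
    s_star = curve[best][0]
    keep_mask = (norm > s_star).any(axis=1)
    keep = [f for f, k in zip(m.feature_ids, keep_mask) if k]
    return JaccardFilterResult(m.subset_features(keep), s_star, curve)


def vst(m: CountMatrix, factors: pd.Series | np.ndarray | None = None) -> pd.DataFrame:
    """log2(count / size_factor + 1) variance-stabilizing transform."""
    if factors is None:
        factors = size_factors(m)
    f = np.asarray(factors, dtype=float)
    if (f <= 0).any():
        raise ValueError("size factors must be positive")
    return pd.DataFrame(
        np.log2(m.counts.to_numpy(dtype=float) / f[None, :] + 1.0),
        index=m.feature_ids,
        columns=m.sample_ids,
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray


def pca_qc(x: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Sample-space PCA of a (features x samples) expression matrix."""
    X = x.to_numpy(dtype=float).T  # samples x features
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if max_comp < 1:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > max_comp:
        warnings.warn(
            f"n_components truncated from {n_components} to rank bound {max_comp}"
        )
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    return PCAResult(
        scores=pd.DataFrame(
            scores,
            index=list(x.columns),
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        variance_explained=pca.explained_variance_ratio_,
    )
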