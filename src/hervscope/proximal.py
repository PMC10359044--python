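"""Proximal-gene mapping and rank-based pathway enrichment.

Retroviral loci are hypothesized to act as cis-regulators of nearby genes,
so each differentially expressed locus is mapped to its closest upstream
gene, closest downstream gene and any genes it physically intersects
(genomic left/right, strand-agnostic by default).  The locus' DE
coefficient is transferred to those genes and a two-sample Wilcoxon
rank-sum test compares each pathway's member scores against the rest of
the scored universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .annotation import GeneAnnotation, LocusAnnotation
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class ProximalMap:
    herv_id: str
    upstream: tuple[str, int] | None = None  # (gene_id, distance bp)
    downstream: tuple[str, int] | None = None
    intersecting: list[str] = field(default_factory=list)


def map_proximal_genes(
    loci: list[LocusAnnotation],
    genes: list[GeneAnnotation],
    stranded: bool = False,
) -> list[ProximalMap]:
    """Closest upstream / downstream / intersecting genes per locus.

    Upstream means the nearest non-overlapping gene ending at or before the
    locus start (distance = locus.start - gene.end); downstream the nearest
    gene starting at or after the locus end.  Adjacency (distance 0) counts
    as flanking.  Ties break toward the lexicographically smaller gene id.
    With ``stranded`` the up/down roles are swapped for minus-strand loci.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gl in by_chrom.values():
        gl.sort(key=lambda g: (g.start, g.gene_id))

    out = []
    for locus in sorted(loci, key=lambda l: l.locus_id):
        gl = by_chrom.get(locus.chrom, [])
        if not gl:
            logger.info("locus %s: no genes on %s", locus.locus_id, locus.chrom)
            out.append(ProximalMap(locus.locus_id))
            continue
        intersecting = sorted(
            g.gene_id for g in gl if g.overlaps(locus.start, locus.end)
        )
        up = min(
            (
                (locus.start - g.end, g.gene_id)
                for g in gl
                if g.end <= locus.start
            ),
            default=None,
        )
        down = min(
            (
                (g.start - locus.end, g.gene_id)
                for g in gl
                if g.start >= locus.end
            ),
            default=None,
        )
        upstream = (up[1], up[0]) if up else None
        downstream = (down[1], down[0]) if down else None
        if stranded and locus.strand == "-":
            upstream, downstream = downstream, upstream
        out.append(ProximalMap(locus.locus_id, upstream, downstream, intersecting))
    return out


def transfer_scores(
    de: pd.DataFrame,
    pmap: list[ProximalMap],
    collision: str = "max_abs",
) -> dict[str, float]:
    """Assign each DE locus' log2fc to its proximal genes.

    A gene hit by several loci keeps the score of largest absolute value
    (``collision='max_abs'``, logged) or the mean (``collision='mean'``).
    """
    if collision not in ("max_abs", "mean"):
        raise ValueError("collision must be 'max_abs' or 'mean'")
    lfc_of = dict(zip(de["feature_id"], de["log2fc"]))
    received: dict[str, list[float]] = {}
    for pm in sorted(pmap, key=lambda p: p.herv_id):
        if pm.herv_id not in lfc_of:
            raise KeyError(f"no DE coefficient for locus {pm.herv_id}")
        score = float(lfc_of[pm.herv_id])
        targets = list(pm.intersecting)
        for flank in (pm.upstream, pm.downstream):
            if flank is not None:
                targets.append(flank[0])
        for g in targets:
            received.setdefault(g, []).append(score)

    scores = {}
    for g, vals in received.items():
        if len(vals) > 1:
            logger.info("gene %s received %d scores", g, len(vals))
        if collision == "mean":
            scores[g] = float(np.mean(vals))
        else:
            scores[g] = max(vals, key=abs)
    return scores


def _exact_ranksum_p(ranks: np.ndarray, member: np.ndarray) -> float:
    """Two-sided exact p of the member rank-sum by full enumeration."""
    k = int(member.sum())
    obs = ranks[member].sum()
    sums = np.array(
        [sum(c) for c in combinations(ranks, k)]
    )
    eps = 1e-9
    p_ge = np.mean(sums >= obs - eps)
    p_le = np.mean(sums <= obs + eps)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def pathway_enrichment(
    scores: dict[str, float],
    gmt: dict[str, set[str]],
    min_size: int = 3,
) -> pd.DataFrame:
    """Wilcoxon rank-sum enrichment of pathway member scores.

    Member scores are compared against non-member scores over the scored
    universe, two-sided; small universes (<= 10 scored genes) use exact
    enumeration over all member-set assignments, larger ones the normal
    approximation with tie correction.  q is BH over tested pathways;
    median member score conveys directionality.
    """
    if not scores:
        raise ValueError("empty score map")
    universe = sorted(scores)
    values = np.array([scores[g] for g in universe])
    ranks = rankdata(values)
    idx_of = {g: i for i, g in enumerate(universe)}

    rows = []
    for name in sorted(gmt):
        members = gmt[name] & set(universe)
        n_matched = len(members)
        if n_matched == 0:
            logger.info("pathway %s: no scored genes, skipped", name)
            continue
        if n_matched < min_size:
            continue
        if n_matched == len(universe):
            logger.info("pathway %s covers the whole universe, skipped", name)
            continue
        member_mask = np.zeros(len(universe), dtype=bool)
        member_mask[[idx_of[g] for g in members]] = True
        if len(universe) <= 10:
            p = _exact_ranksum_p(ranks, member_mask)
            stat = float(ranks[member_mask].sum())
        else:
            res = mannwhitneyu(
                values[member_mask],
                values[~member_mask],
                alternative="two-sided",
                method="asymptotic",
            )
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "pathway_id": name,
                "n_matched": n_matched,
                "median_score": float(np.median(values[member_mask])),
                "rank_stat": stat,
                "p": p,
            }
        )
    df = pd.DataFrame(rows, columns=["pathway_id", "n_matched", "median_score", "rank_stat", "p"])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values("p").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df
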