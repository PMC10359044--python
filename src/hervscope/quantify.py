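"""EM reassignment of multi-mapped fragments to individual retroviral loci.

Repetitive loci attract ambiguous alignments: one fragment may align
acceptably to several insertions of the same family.  We model the observed
alignments as draws from a mixture over loci with unknown mixing proportions
pi, convert alignment scores to relative likelihoods, and fit pi by
expectation-maximization with a symmetric Dirichlet prior (a telescope-style
reassignment).  The E-step posterior weights then yield locus-level counts
under three reduction modes (best / fractional / unique).

Alignments that overlap no annotated locus are kept as a reserved
``no_feature`` mixture component so that the proportions remain a simplex
over everything the library produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import scipy.sparse as sp

from .annotation import LocusAnnotation

NO_FEATURE = "__no_feature__"


@dataclass
class EMConfig:
    """Tuning knobs of the mixture fit.

    theta_prior is the *total* Dirichlet pseudo-weight, spread evenly over
    the K mixture components; score_scale divides alignment scores before
    exponentiation, so larger values flatten the likelihood.
    """

    theta_prior: float = 200_000.0
    max_iter: int = 200
    tol: float = 1e-6
    score_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.theta_prior < 0:
            raise ValueError("theta_prior must be non-negative")
        if self.max_iter < 1 or self.tol <= 0 or self.score_scale <= 0:
            raise ValueError("max_iter, tol and score_scale must be positive")


@dataclass
class FragmentAssignmentMatrix:
    """Sparse fragments x candidate-loci alignment scores.

    The sparsity structure *is* the candidacy relation; stored values are
    the best alignment score seen for the (fragment, locus) pair and may be
    legitimately zero, so explicit zeros are never eliminated.
    """

    fragment_ids: list[str]
    locus_ids: list[str]  # includes NO_FEATURE as the last entry
    scores: sp.csr_matrix

    def __post_init__(self) -> None:
        n, k = self.scores.shape
        if n != len(self.fragment_ids) or k != len(self.locus_ids):
            raise ValueError("score matrix shape mismatch")
        if n and (np.diff(self.scores.indptr) == 0).any():
            raise ValueError("every fragment must have at least one candidate")
        if not np.all(np.isfinite(self.scores.data)):
            raise ValueError("alignment scores must be finite")

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_ids)

    def candidates_per_fragment(self) -> np.ndarray:
        return np.diff(self.scores.indptr)


@dataclass
class ReassignmentResult:
    """Fitted mixture proportions, posteriors and the EM trace."""

    pi: pd.Series
    posterior: sp.csr_matrix
    fragment_ids: list[str]
    locus_ids: list[str]
    n_iter: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)


class MissingScoreTagError(ValueError):
    pass


def load_alignments(
    sam_path: str | Path,
    loci: list[LocusAnnotation],
    score_tag: str = "AS",
    stranded: bool = False,
) -> FragmentAssignmentMatrix:
    """Build the fragment x locus score matrix from a SAM file.

    An alignment is a candidate for every locus its interval overlaps by at
    least one base (all overlapped loci receive the same score); alignments
    overlapping no locus feed the ``no_feature`` pseudo-locus.  Per
    (fragment, locus) pair only the best score is kept.  Unmapped records
    are ignored.  Overlap is strand-agnostic unless ``stranded``.
    """
    by_chrom: dict[str, list[LocusAnnotation]] = {}
    for l in loci:
        by_chrom.setdefault(l.chrom, []).append(l)
    chrom_arrays = {
        c: (
            np.array([l.start for l in ls]),
            np.array([l.end for l in ls]),
            ls,
        )
        for c, ls in by_chrom.items()
    }

    locus_ids = [l.locus_id for l in loci] + [NO_FEATURE]
    col_of = {lid: j for j, lid in enumerate(locus_ids)}
    best: dict[tuple[str, int], float] = {}
    frag_order: list[str] = []
    seen: set[str] = set()

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        n_records = 0
        for aln in sam:
            if aln.is_unmapped:
                continue
            n_records += 1
            if not aln.has_tag(score_tag):
                raise MissingScoreTagError(
                    f"alignment {aln.query_name} lacks the {score_tag}:i score tag"
                )
            score = float(aln.get_tag(score_tag))
            name = aln.query_name
            if name not in seen:
                seen.add(name)
                frag_order.append(name)
            hits: list[int] = []
            entry = chrom_arrays.get(aln.reference_name)
            if entry is not None:
                starts, ends, ls = entry
                s, e = aln.reference_start, aln.reference_end
                mask = (starts < e) & (s < ends)
                if stranded:
                    aln_strand = "-" if aln.is_reverse else "+"
                    mask &= np.array([l.strand in (aln_strand, ".") for l in ls])
                hits = [col_of[ls[i].locus_id] for i in np.flatnonzero(mask)]
            if not hits:
                hits = [col_of[NO_FEATURE]]
            for j in hits:
                key = (name, j)
                if key not in best or score > best[key]:
                    best[key] = score

    if not frag_order:
        warnings.warn("SAM contains no mapped records; returning empty matrix")
        return FragmentAssignmentMatrix(
            [], locus_ids, sp.csr_matrix((0, len(locus_ids)))
        )

    row_of = {f: i for i, f in enumerate(frag_order)}
    rows = np.array([row_of[f] for f, _j in best])
    cols = np.array([j for _f, j in best])
    vals = np.array(list(best.values()))
    scores = sp.coo_matrix(
        (vals, (rows, cols)), shape=(len(frag_order), len(locus_ids))
    ).tocsr()
    return FragmentAssignmentMatrix(frag_order, locus_ids, scores)


def _penalized_loglik(
    L: sp.csr_matrix, pi: np.ndarray, theta: float
) -> float:
    mix = np.asarray(L @ pi).ravel()
    ll = float(np.log(mix).sum())
    if theta > 0:
        with np.errstate(divide="ignore"):
            logpi = np.where(pi > 0, np.log(np.maximum(pi, 1e-300)), -np.inf)
        ll += float(theta * logpi.sum()) if np.all(pi > 0) else -np.inf
    return ll


def em_reassign(
    matrix: FragmentAssignmentMatrix, config: EMConfig | None = None
) -> ReassignmentResult:
    """Fit mixture proportions over loci by penalized EM.

    Candidate likelihoods are ``exp(score / score_scale)`` (zero for
    non-candidates).  The M-step is the MAP update
    ``pi_k ∝ sum_f w(f,k) + theta_prior / K``; iteration stops when
    ``max |Δpi| < tol`` or after ``max_iter`` rounds.  The penalized
    log-likelihood trace is non-decreasing.
    """
    config = config or EMConfig()
    if matrix.n_fragments == 0:
        raise ValueError("cannot fit EM on an empty assignment matrix")

    K = len(matrix.locus_ids)
    N = matrix.n_fragments
    L = matrix.scores.copy().astype(float)
    with np.errstate(over="ignore"):
        L.data = np.exp(L.data / config.score_scale)
    if not np.all(np.isfinite(L.data)):
        raise OverflowError(
            "alignment scores overflow the likelihood map; "
            "increase EMConfig.score_scale"
        )

    theta_k = config.theta_prior / K
    pi = np.full(K, 1.0 / K)
    trace: list[float] = []
    converged = False
    n_iter = 0
    W = L  # placeholder until first E-step
    for n_iter in range(1, config.max_iter + 1):
        # E-step: w(f, k) ∝ pi_k * L(f, k) over the candidate structure
        W = L.multiply(pi[None, :]).tocsr()
        row_sums = np.asarray(W.sum(axis=1)).ravel()
        W.data /= np.repeat(row_sums, np.diff(W.indptr))
        # M-step (MAP with symmetric Dirichlet pseudo-counts)
        new_pi = np.asarray(W.sum(axis=0)).ravel() + theta_k
        new_pi /= new_pi.sum()
        trace.append(_penalized_loglik(L, new_pi, theta_k))
        delta = np.max(np.abs(new_pi - pi))
        pi = new_pi
        if delta < config.tol:
            converged = True
            break
    # final posterior at the converged pi
    W = L.multiply(pi[None, :]).tocsr()
    row_sums = np.asarray(W.sum(axis=1)).ravel()
    W.data /= np.repeat(row_sums, np.diff(W.indptr))

    return ReassignmentResult(
        pi=pd.Series(pi, index=matrix.locus_ids, name="pi"),
        posterior=W,
        fragment_ids=matrix.fragment_ids,
        locus_ids=matrix.locus_ids,
        n_iter=n_iter,
        converged=converged,
        objective_trace=trace,
    )


def counts_from_posterior(
    result: ReassignmentResult, mode: str = "best"
) -> tuple[pd.Series, list[str]]:
    """Reduce posteriors to per-locus counts.

    best: each fragment adds 1 to its argmax-posterior locus; exact
    posterior ties exclude the fragment (returned in the tie list) so the
    pipeline stays deterministic.  fractional: fragments contribute their
    posterior weights.  unique: only single-candidate fragments count.
    """
    if mode not in ("best", "fractional", "unique"):
        raise ValueError(f"unknown mode {mode!r}; use best|fractional|unique")
    W = result.posterior
    K = len(result.locus_ids)
    counts = np.zeros(K)
    ties: list[str] = []

    if mode == "fractional":
        counts = np.asarray(W.sum(axis=0)).ravel()
    else:
        indptr, indices, data = W.indptr, W.indices, W.data
        for i, frag in enumerate(result.fragment_ids):
            lo, hi = indptr[i], indptr[i + 1]
            row = data[lo:hi]
            if mode == "unique":
                if hi - lo == 1:
                    counts[indices[lo]] += 1
                continue
            top = row.max()
            winners = np.flatnonzero(np.abs(row - top) <= 1e-9 * max(top, 1e-300))
            if len(winners) > 1:
                ties.append(frag)
            else:
                counts[indices[lo + winners[0]]] += 1
    return pd.Series(counts, index=result.locus_ids, name="count"), ties


def run_report(
    matrix: FragmentAssignmentMatrix, result: ReassignmentResult, ties: list[str]
) -> dict:
    """Summary statistics of a quantification run."""
    cands = matrix.candidates_per_fragment()
    nf_col = matrix.locus_ids.index(NO_FEATURE)
    # count via the sparsity structure: stored scores may legitimately be 0
    nf_hits = sum(
        1
        for i in range(matrix.n_fragments)
        if nf_col in matrix.scores.indices[matrix.scores.indptr[i]:matrix.scores.indptr[i + 1]]
    )
    return {
        "n_fragments": matrix.n_fragments,
        "n_unique": int((cands == 1).sum()),
        "n_ambiguous": int((cands > 1).sum()),
        "n_no_feature": nf_hits,
        "n_ties_excluded": len(ties),
        "iterations": result.n_iter,
        "converged": result.converged,
    }
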