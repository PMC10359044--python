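"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: dense grid search
for the EM mixture optimum, the literal step-up definition for BH, and an
all-pairs scan for proximal-gene mapping.
"""

import numpy as np


_GRID_CACHE: dict = {}


def _simplex_grid(K: int, step: float) -> np.ndarray:
    key = (K, step)
    if key not in _GRID_CACHE:
        grid = np.arange(step, 1.0, step)
        if K == 2:
            P = np.column_stack([grid, 1.0 - grid])
        elif K == 3:
            A, B = np.meshgrid(grid, grid)
            mask = A + B < 1.0 - step / 2
            P = np.column_stack([A[mask], B[mask], 1.0 - A[mask] - B[mask]])
        else:
            raise ValueError("grid oracle supports K in {2, 3}")
        _GRID_CACHE[key] = P
    return _GRID_CACHE[key]


def grid_search_pi(L_dense: np.ndarray, theta_total: float, step: float = 1e-3) -> np.ndarray:
    """Maximize sum_f log(L @ pi) + (theta/K) * sum_k log pi_k over the simplex."""
    _n, K = L_dense.shape
    theta_k = theta_total / K
    P = _simplex_grid(K, step)
    ll = np.log(L_dense @ P.T).sum(axis=0)
    if theta_k > 0:
        ll = ll + theta_k * np.log(P).sum(axis=1)
    return P[np.argmax(ll)]


def bh_stepup_bruteforce(p: np.ndarray) -> np.ndarray:
    """Literal BH step-up: q_(i) = min_{k >= i} n * p_(k) / k, O(n^2)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    for pos, idx in enumerate(order):
        cands = [n * p[order[k]] / (k + 1) for k in range(pos, n)]
        q[idx] = min(1.0, min(cands))
    return q


def proximal_bruteforce(loci, genes):
    """All-pairs nearest upstream/downstream/intersecting scan."""
    out = {}
    for l in loci:
        inter, up, down = [], None, None
        for g in genes:
            if g.chrom != l.chrom:
                continue
            if g.start < l.end and l.start < g.end:
                inter.append(g.gene_id)
            elif g.end <= l.start:
                cand = (l.start - g.end, g.gene_id)
                if up is None or cand < up:
                    up = cand
            elif g.start >= l.end:
                cand = (g.start - l.end, g.gene_id)
                if down is None or cand < down:
                    down = cand
        out[l.locus_id] = (
            (up[1], up[0]) if up else None,
            (down[1], down[0]) if down else None,
            sorted(inter),
        )
    return out
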