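"""Numba kernels for the single-trait repeatability animal-model Gibbs sampler.

The sampler targets model

    y = NSL + HYS + a + p + eps,   a ~ N(0, A sa2), p ~ N(0, I sp2),
                                   eps ~ N(0, I se2)

with flat (improper, bounded-below-at-zero) priors on the three variances
and bounded-uniform priors on the fixed effects.  Location effects are
updated one scalar at a time (Gauss-Seidel single-site sampling on the
mixed-model equations); variances are drawn from their scaled-inverse
chi-square full conditionals with prior df = -2 and scale 0, i.e.
sigma2 ~ SS / chisq(q - 2), which is the flat-prior convention of the
classical animal-breeding Gibbs samplers.

The first NSL level is held at zero during sampling so the fixed part is
identifiable; the intercept is absorbed into the HYS block.
"""

from __future__ import annotations

import numpy as np
from numba import njit


def build_csr(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Record lists per effect level as CSR (indptr, record indices)."""
    order = np.argsort(levels, kind="stable").astype(np.int64)
    indptr = np.searchsorted(levels[order], np.arange(n_levels + 1)).astype(np.int64)
    return indptr, order


@njit(cache=True)
def _sample_block_iid(e, theta, lam, ptr, recs, ve, start):
    """Single-site update of an effect block with iid prior N(0, ve/lam per
    unit); lam = 0 gives a fixed (flat-prior) effect.  ``start`` skips
    constrained leading levels."""
    for i in range(start, theta.shape[0]):
        n_i = float(ptr[i + 1] - ptr[i])
        c = n_i + lam
        if c <= 0.0:
            continue
        s = n_i * theta[i]
        for k in range(ptr[i], ptr[i + 1]):
            s += e[recs[k]]
        new = s / c + np.sqrt(ve / c) * np.random.standard_normal()
        delta = new - theta[i]
        theta[i] = new
        for k in range(ptr[i], ptr[i + 1]):
            e[recs[k]] -= delta


@njit(cache=True)
def _sample_animals(e, a, lam_a, ai_ptr, ai_idx, ai_val, ai_diag, ptr, recs, ve):
    """Animal-effect sweep with A-inverse held in CSR form (the inverse
    numerator relationship matrix is sparse for any pedigree)."""
    n_anim = a.shape[0]
    for i in range(n_anim):
        n_i = float(ptr[i + 1] - ptr[i])
        c = n_i + lam_a * ai_diag[i]
        s = n_i * a[i]
        for k in range(ptr[i], ptr[i + 1]):
            s += e[recs[k]]
        off = 0.0
        for k in range(ai_ptr[i], ai_ptr[i + 1]):
            off += ai_val[k] * a[ai_idx[k]]
        off = lam_a * (off - ai_diag[i] * a[i])
        new = (s - off) / c + np.sqrt(ve / c) * np.random.standard_normal()
        delta = new - a[i]
        a[i] = new
        for k in range(ptr[i], ptr[i + 1]):
            e[recs[k]] -= delta


def sparsify(m: np.ndarray, tol: float = 1e-10
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """CSR (indptr, indices, data, diagonal) of a symmetric matrix,
    dropping entries below ``tol`` times the largest magnitude."""
    mask = np.abs(m) > tol * np.abs(m).max()
    indptr = np.zeros(m.shape[0] + 1, dtype=np.int64)
    indptr[1:] = mask.sum(axis=1).cumsum()
    rows, cols = np.nonzero(mask)
    return indptr, cols.astype(np.int64), m[rows, cols], np.diag(m).copy()


@njit(cache=True)
def animal_model_chain(y, rec_nsl, rec_hys, rec_anim, rec_cow,
                       nsl_ptr, nsl_rec, hys_ptr, hys_rec,
                       anim_ptr, anim_rec, cow_ptr, cow_rec,
                       ai_ptr, ai_idx, ai_val, ai_diag, n_iter, seed, v0):
    """Run the Gibbs chain; returns an (n_iter, 3) array of
    (sigma_a2, sigma_p2, sigma_e2) draws, one row per iteration."""
    np.random.seed(seed)
    n = y.shape[0]
    n_nsl = nsl_ptr.shape[0] - 1
    n_hys = hys_ptr.shape[0] - 1
    n_anim = anim_ptr.shape[0] - 1
    n_cow = cow_ptr.shape[0] - 1
    theta_nsl = np.zeros(n_nsl)
    theta_hys = np.zeros(n_hys)
    a = np.zeros(n_anim)
    p = np.zeros(n_cow)
    e = y.copy()
    va, vp, ve = v0[0], v0[1], v0[2]
    chains = np.empty((n_iter, 3))

    for it in range(n_iter):
        _sample_block_iid(e, theta_nsl, 0.0, nsl_ptr, nsl_rec, ve, 1)
        _sample_block_iid(e, theta_hys, 0.0, hys_ptr, hys_rec, ve, 0)
        _sample_animals(e, a, ve / va, ai_ptr, ai_idx, ai_val, ai_diag,
                        anim_ptr, anim_rec, ve)
        _sample_block_iid(e, p, ve / vp, cow_ptr, cow_rec, ve, 0)

        quad = 0.0
        for i in range(n_anim):
            row = 0.0
            for k in range(ai_ptr[i], ai_ptr[i + 1]):
                row += ai_val[k] * a[ai_idx[k]]
            quad += a[i] * row
        va = quad / np.random.chisquare(n_anim - 2)
        sp = 0.0
        for i in range(n_cow):
            sp += p[i] * p[i]
        vp = sp / np.random.chisquare(n_cow - 2)
        sse = 0.0
        for r in range(n):
            sse += e[r] * e[r]
        ve = sse / np.random.chisquare(n - 2)

        chains[it, 0] = va
        chains[it, 1] = vp
        chains[it, 2] = ve

        if (it + 1) % 200 == 0:  # refresh residual against drift
            for r in range(n):
                e[r] = (y[r] - theta_nsl[rec_nsl[r]] - theta_hys[rec_hys[r]]
                        - a[rec_anim[r]] - p[rec_cow[r]])
    return chains
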