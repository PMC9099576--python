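"""Bayesian multi-kernel (RKHS) regression by Gibbs sampling.

Model for the sire-by-HYS daughter-yield-deviations y:

    y_ij = mu + g_i + e_j (+ ge_ij) + eps_ij

with g ~ N(0, G sg2) over sires, e ~ N(0, E se2) over HYS classes (E = I
for the Base model, a Bayesian ridge on HYS indicators), an optional
interaction ge ~ N(0, (ZGZ' o WEW') sge2) at observation level, and
heteroscedastic residuals eps_ij ~ N(0, seps2 / EDC_ij).

Each kernel is eigendecomposed once, K = F F' with F = V sqrt(Lambda)
restricted to eigenvalues above a relative tolerance, and the effect is
sampled as independent regression coefficients on the columns of F — the
standard reproducing-kernel reparameterization.  Coefficients are updated
one at a time against a running residual; variances have scaled-inverse
chi-square full conditionals with a mildly informative prior (df = 5, a
configurable prior variance split), or flat priors on request.

Phenotypes of validation rows can be masked out of the likelihood while
their sires and HYS classes remain in the kernels, so predictions for
masked cells borrow strength through the covariance structure alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from spectragp.diagnostics import geweke_z
from spectragp.errors import ConfigError, DegenerateStatisticError, KernelError
from spectragp.kernels import CvDesign, KernelMatrix, expand_and_interact
from spectragp.stage1 import ChainConfig

MODEL_NAMES = ("Base", "AWN", "PC2", "PC10", "PC20", "PC30", "PC40", "PROD")


def eigendecompose_kernel(k: np.ndarray, tol: float = 1e-8
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Factor a symmetric PSD kernel as K ~= F F'.

    Returns (F, eigenvalues) with F = V sqrt(Lambda) over eigenvalues
    larger than ``tol * max eigenvalue``; eigenvalues below the negative
    tolerance raise.  The Frobenius reconstruction error is bounded by the
    discarded spectrum.
    """
    k = np.asarray(k, dtype=float)
    if k.ndim != 2 or k.shape[0] != k.shape[1]:
        raise KernelError("kernel must be square")
    if np.abs(k - k.T).max() > 1e-8 * max(1.0, np.abs(k).max()):
        raise KernelError("kernel must be symmetric")
    lam, vec = np.linalg.eigh((k + k.T) / 2)
    lmax = lam.max() if len(lam) else 0.0
    if lmax <= 0:
        raise KernelError("kernel has no positive eigenvalue")
    if lam.min() < -tol * lmax:
        raise KernelError(f"kernel not PSD within tolerance (min eigenvalue {lam.min():.3e})")
    keep = lam > tol * lmax
    lam = lam[keep]
    f = vec[:, keep] * np.sqrt(lam)
    return f, lam


@dataclass
class RandomTerm:
    """One kernel-backed random effect: full-row factor matrix (all
    observations, including any later masked for validation)."""

    name: str
    factors: np.ndarray  # (n_obs, m)


@dataclass
class PriorConfig:
    """Variance hyper-priors: scaled-inverse chi-square with ``df0`` degrees
    of freedom and scale set so the prior splits ``r2`` of the phenotypic
    variance equally across kernel terms (the remainder to the residual).
    ``flat = True`` uses the improper df = -2, scale = 0 prior instead."""

    df0: float = 5.0
    r2: float = 0.5
    flat: bool = False


@dataclass
class ModelSpec:
    """One entry of the model menu (Base, AWN, PC2..PC40, PROD), with or
    without the Hadamard interaction.  Base has no environmental kernel, so
    the interaction cannot be fitted with it."""

    name: str
    include_gxe: bool = False
    chain: ChainConfig = field(default_factory=lambda: ChainConfig(75000, 25000, 10, 0))
    prior: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ConfigError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")
        if self.name == "Base" and self.include_gxe:
            raise ConfigError("Base has no environmental kernel; the interaction "
                              "term cannot be fitted")

    @property
    def label(self) -> str:
        return self.name + ("+GxE" if self.include_gxe else "")


@dataclass
class PosteriorSummary:
    mu: float
    terms: list
    variances: dict        # name -> {"mean": float, "sd": float}; includes "residual"
    chains: dict           # name -> 1-D posterior chain (post burn-in, thinned)
    coef: dict             # name -> posterior-mean coefficients in the eigenbasis
    effects: dict          # name -> posterior-mean effect per observation row
    geweke: dict           # name -> z


@njit(cache=True)
def _rkhs_chain(y, w, u, term_ptr, col_sumsq, s0, df0, se0, dfe,
                n_iter, burn_in, thin, seed, v0, ve0,
                update_variances, fit_intercept):
    np.random.seed(seed)
    n = y.shape[0]
    n_terms = term_ptr.shape[0] - 1
    m_total = u.shape[1]
    delta = np.zeros(m_total)
    mu = 0.0
    v = v0.copy()
    ve = ve0
    e = y.copy()
    sw = w.sum()
    n_keep = (n_iter - burn_in + thin - 1) // thin
    chains = np.empty((n_keep, n_terms + 1))
    # posterior means are Rao-Blackwellized: the running averages accumulate
    # each coordinate's full-conditional mean rather than its draw, which
    # sharply reduces Monte-Carlo error at the same chain length
    cond_mu = 0.0
    cond_delta = np.zeros(m_total)
    delta_sum = np.zeros(m_total)
    mu_sum = 0.0
    kept = 0

    for it in range(n_iter):
        ve_safe = ve if ve > 1e-12 else 1e-12
        if fit_intercept:
            s = sw * mu
            for i in range(n):
                s += w[i] * e[i]
            cond_mu = s / sw
            new = cond_mu + np.sqrt(ve_safe / sw) * np.random.standard_normal()
            d = new - mu
            mu = new
            for i in range(n):
                e[i] -= d

        for k in range(n_terms):
            vk = v[k] if v[k] > 1e-12 else 1e-12
            for j in range(term_ptr[k], term_ptr[k + 1]):
                cj = col_sumsq[j]
                prec = cj / ve_safe + 1.0 / vk
                s = cj * delta[j]
                for i in range(n):
                    s += w[i] * u[i, j] * e[i]
                mean = (s / ve_safe) / prec
                cond_delta[j] = mean
                new = mean + np.random.standard_normal() / np.sqrt(prec)
                d = new - delta[j]
                delta[j] = new
                for i in range(n):
                    e[i] -= u[i, j] * d

        if update_variances:
            for k in range(n_terms):
                m_k = float(term_ptr[k + 1] - term_ptr[k])
                ss = 0.0
                for j in range(term_ptr[k], term_ptr[k + 1]):
                    ss += delta[j] * delta[j]
                v[k] = (ss + df0[k] * s0[k]) / np.random.chisquare(m_k + df0[k])
            sse = 0.0
            for i in range(n):
                sse += w[i] * e[i] * e[i]
            ve = (sse + dfe * se0) / np.random.chisquare(n + dfe)

        if it >= burn_in and (it - burn_in) % thin == 0:
            for k in range(n_terms):
                chains[kept, k] = v[k]
            chains[kept, n_terms] = ve
            delta_sum += cond_delta
            mu_sum += cond_mu
            kept += 1

        if (it + 1) % 200 == 0:
            for i in range(n):
                acc = y[i] - mu
                for j in range(m_total):
                    acc -= u[i, j] * delta[j]
                e[i] = acc

    return chains[:kept], delta_sum / kept, mu_sum / kept


def fit_gibbs_rkhs(y: np.ndarray, terms: list[RandomTerm],
                   weights: np.ndarray | None = None,
                   train_mask: np.ndarray | None = None,
                   chain: ChainConfig | None = None,
                   prior: PriorConfig | None = None,
                   fixed_variances: dict | None = None,
                   fit_intercept: bool = True) -> PosteriorSummary:
    """Gibbs-sample the multi-kernel model and summarize the posterior.

    ``train_mask`` selects the rows that contribute to the likelihood;
    effect posterior means are still returned for every row through the
    full factor matrices.  ``fixed_variances`` (name -> value, plus
    ``"residual"``) freezes the variances, which turns the sampler into a
    draw from the conditional Gaussian posterior of the effects.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotypes")
    n_all = len(y)
    if weights is None:
        weights = np.ones(n_all)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("residual weights must be strictly positive")
    if train_mask is None:
        train_mask = np.ones(n_all, dtype=bool)
    train_mask = np.asarray(train_mask, dtype=bool)
    if chain is None:
        chain = ChainConfig(75000, 25000, 10, 0)
    if prior is None:
        prior = PriorConfig()

    y_tr = y[train_mask]
    w_tr = weights[train_mask]
    # Rotate each term's factor columns into the eigenbasis of its weighted
    # training cross-product U'WU.  The prior on the coefficients is
    # isotropic, so the rotation leaves the model (and the term's effect
    # U delta) unchanged while making the coefficients of a term mutually
    # conditionally independent: the single-site sweep then performs an
    # exact block update per term, which mixes far better than raw
    # coordinate-wise sampling.
    u_full = []
    rotations = []
    for t in terms:
        f = np.ascontiguousarray(t.factors, dtype=float)
        b = f[train_mask].T * w_tr @ f[train_mask]
        _, q = np.linalg.eigh((b + b.T) / 2)
        rotations.append(q)
        u_full.append(f @ q)
    u = np.hstack([f[train_mask] for f in u_full])
    term_ptr = np.cumsum([0] + [f.shape[1] for f in u_full]).astype(np.int64)
    col_sumsq = (w_tr[:, None] * u * u).sum(axis=0)

    vy = float(np.average((y_tr - np.average(y_tr, weights=w_tr)) ** 2, weights=w_tr))
    n_terms = len(terms)
    if prior.flat:
        df0 = np.full(n_terms, -2.0)
        s0 = np.zeros(n_terms)
        dfe, se0 = -2.0, 0.0
    else:
        df0 = np.full(n_terms, prior.df0)
        s0 = np.empty(n_terms)
        for k, f in enumerate(u_full):
            mean_diag = float((f[train_mask] ** 2).sum(axis=1).mean())
            share = vy * prior.r2 / max(n_terms, 1)
            s0[k] = share * (prior.df0 + 2) / prior.df0 / mean_diag if mean_diag > 0 else 0.0
        dfe = prior.df0
        se0 = vy * (1 - prior.r2) * (dfe + 2) / dfe

    if fixed_variances is not None:
        v0 = np.array([float(fixed_variances[t.name]) for t in terms])
        ve0 = float(fixed_variances["residual"])
        update = False
    else:
        v0 = np.full(n_terms, max(vy, 1e-12) * prior.r2 / max(n_terms, 1))
        # on the coefficient scale: divide by the mean kernel diagonal
        for k, f in enumerate(u_full):
            md = float((f[train_mask] ** 2).sum(axis=1).mean())
            if md > 0:
                v0[k] /= md
        ve0 = max(vy, 1e-12) * (1 - prior.r2)
        update = True

    chains, delta_mean, mu_mean = _rkhs_chain(
        y_tr, w_tr, u, term_ptr, col_sumsq, s0, df0, se0, dfe,
        chain.n_iter, chain.burn_in, chain.thin, chain.seed % (2 ** 31),
        v0, ve0, update, fit_intercept)

    names = [t.name for t in terms] + ["residual"]
    variances, chain_out, gz = {}, {}, {}
    for k, name in enumerate(names):
        c = chains[:, k]
        variances[name] = {"mean": float(c.mean()), "sd": float(c.std(ddof=1))}
        chain_out[name] = c
        try:
            gz[name] = geweke_z(c)
        except DegenerateStatisticError:
            gz[name] = float("nan")
    # coefficients reported in the original (unrotated) eigenbasis so that
    # entity-level effects are factor @ coef for the caller's factors
    coef = {t.name: rotations[k] @ delta_mean[term_ptr[k]:term_ptr[k + 1]]
            for k, t in enumerate(terms)}
    effects = {t.name: np.asarray(t.factors, dtype=float) @ coef[t.name]
               for t in terms}
    return PosteriorSummary(float(mu_mean), [t.name for t in terms],
                            variances, chain_out, coef, effects, gz)


def variance_proportions(summary: PosteriorSummary) -> dict[str, float]:
    """Share of each variance component (kernel terms plus residual) in
    their sum of posterior means; sums to 1 exactly."""
    names = summary.terms + ["residual"]
    vals = np.array([summary.variances[n]["mean"] for n in names])
    total = vals.sum()
    if total <= 0:
        raise DegenerateStatisticError("all posterior variances are zero")
    return dict(zip(names, vals / total))


# ---------------------------------------------------------------------------
# model-level driver on Data 2


@dataclass
class RkhsModelFit:
    spec: ModelSpec
    mu: float
    g: pd.Series                    # posterior-mean genetic effect per sire
    e: pd.Series                    # posterior-mean environmental effect per HYS
    ge: pd.Series | None            # per data2 row (kernel support), or None
    summary: PosteriorSummary


def fit_model(data2: pd.DataFrame, g_kernel: KernelMatrix,
              env_kernel: KernelMatrix | None, spec: ModelSpec,
              train_mask: np.ndarray | None = None,
              eig_tol: float = 1e-8) -> RkhsModelFit:
    """Fit one menu model to Data 2.

    ``env_kernel`` must be None exactly for the Base model, whose HYS
    effect is iid (a ridge on HYS indicators).  Residual weights are the
    EDC column.  Validation rows (``train_mask`` False) keep their sires
    and HYS classes in the kernels but contribute no likelihood.
    """
    if (env_kernel is None) != (spec.name == "Base"):
        raise ConfigError("env_kernel must be supplied for every model except Base")
    design = CvDesign.from_data2(data2)
    y = data2["dyd"].to_numpy(dtype=float)
    w = data2["edc"].to_numpy(dtype=float)

    sire_labels = list(g_kernel.labels)
    f_g, _ = eigendecompose_kernel(g_kernel.values, eig_tol)
    sire_pos = {s: i for i, s in enumerate(sire_labels)}
    missing = set(design.sires) - set(sire_pos)
    if missing:
        raise KernelError(f"sires absent from genomic kernel: {sorted(missing)[:5]}")
    gi = np.array([sire_pos[s] for s in design.sires])

    if env_kernel is None:
        hys_labels = list(pd.unique(design.hys))
        f_e = np.eye(len(hys_labels))
    else:
        hys_labels = list(env_kernel.labels)
        f_e, _ = eigendecompose_kernel(env_kernel.values, eig_tol)
    hys_pos = {h: i for i, h in enumerate(hys_labels)}
    missing = set(design.hys) - set(hys_pos)
    if missing:
        raise KernelError(f"HYS classes absent from environmental kernel: {sorted(missing)[:5]}")
    ei = np.array([hys_pos[h] for h in design.hys])

    terms = [RandomTerm("G", f_g[gi]), RandomTerm("E", f_e[ei])]
    if spec.include_gxe:
        _, _, k_ge = expand_and_interact(g_kernel, env_kernel, design, with_gxe=True)
        f_ge, _ = eigendecompose_kernel(k_ge, eig_tol)
        terms.append(RandomTerm("GxE", f_ge))

    summary = fit_gibbs_rkhs(y, terms, weights=w, train_mask=train_mask,
                             chain=spec.chain, prior=spec.prior)

    g_entity = pd.Series(f_g @ summary.coef["G"], index=sire_labels, name="g")
    e_entity = pd.Series(f_e @ summary.coef["E"], index=hys_labels, name="e")
    ge_rows = (pd.Series(summary.effects["GxE"], index=data2.index, name="ge")
               if spec.include_gxe else None)
    return RkhsModelFit(spec, summary.mu, g_entity, e_entity, ge_rows, summary)


def predict(fit: RkhsModelFit, sires, hys, rows=None) -> np.ndarray:
    """Predicted hysDYD: mu + g_sire + e_hys (+ ge_row when fitted).

    ``rows`` indexes the Data-2 rows the interaction effect was fitted on
    and is required for interaction models; a sire or HYS outside the
    kernel support raises (predictions cannot leave the kernels' span).
    """
    sires = np.asarray(sires)
    hys = np.asarray(hys)
    g = fit.g.reindex(sires)
    if g.isna().any():
        raise KernelError(f"sires outside kernel support: "
                          f"{sorted(set(sires[g.isna().to_numpy()]))[:5]}")
    e = fit.e.reindex(hys)
    if e.isna().any():
        raise KernelError(f"HYS classes outside kernel support: "
                          f"{sorted(set(hys[e.isna().to_numpy()]))[:5]}")
    pred = fit.mu + g.to_numpy() + e.to_numpy()
    if fit.ge is not None:
        if rows is None:
            raise KernelError("interaction model prediction needs Data-2 row labels")
        ge = fit.ge.reindex(rows)
        if ge.isna().any():
            raise KernelError("rows outside the interaction kernel support")
        pred = pred + ge.to_numpy()
    return pred


def predict_rows(fit: RkhsModelFit, data2: pd.DataFrame) -> np.ndarray:
    return predict(fit, data2["sire_id"].to_numpy(), data2["hys_id"].to_numpy(),
                   rows=data2.index if fit.ge is not None else None)
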