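"""Stage 1: editing, class construction, variance components and HYS BLUEs.

Every phenotype (milk yield, somatic cell score, and each spectral
wavenumber) is analyzed with the same univariate repeatability animal
model

    y_ijkl = NSL_i + HYS_j + a_k + p_k + eps_ijkl

with NSL (lactation number x stage of lactation, 52 classes) and HYS
(herd-year-season) fixed, the additive genetic effect ``a`` correlated
through the pedigree relationship matrix A, and an iid cow
permanent-environment effect ``p``.  Variance components come from a Gibbs
sampler with flat priors; model solutions are then obtained from
Henderson's mixed-model equations with the variances fixed, and the HYS
BLUEs across phenotypes — standardized column-wise — become the
environmental coordinates used by the later stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from sklearn.decomposition import PCA

from spectragp import gibbs
from spectragp.diagnostics import geweke_z
from spectragp.errors import (AlignmentError, DegenerateStatisticError,
                              EmptyDataError, RankError)
from spectragp.pedigree import AMatrix

#: days per monthly stage-of-lactation class (365/12); class 13 is open up
#: to the 540-day editing horizon
STAGE_DAYS = 30.4


# ---------------------------------------------------------------------------
# class construction and editing


def assign_classes(records: pd.DataFrame) -> pd.DataFrame:
    """Attach year, season, hys_id, stage and nsl_id columns.

    Seasons are calendar quarters (Jan-Mar = 1 ... Oct-Dec = 4).  The stage
    class is ``min(ceil(dim / 30.4), 13)`` and the lactation class is
    capped at 4 ("fourth or later"), giving ``nsl_id = 13 * (lact_class - 1)
    + stage`` in 1..52.  Records with a missing test date or herd are kept
    but flagged ``class_valid = False``.
    """
    out = records.copy()
    dates = pd.to_datetime(out["test_date"], errors="coerce")
    valid = dates.notna() & out["herd_id"].notna() & (out["herd_id"].astype(str) != "")
    out["year"] = dates.dt.year
    out["season"] = ((dates.dt.month - 1) // 3 + 1).astype("Int64")
    out["hys_id"] = np.where(
        valid,
        out["herd_id"].astype(str) + "_" + out["year"].astype(str) + "_" + out["season"].astype(str),
        "",
    )
    stage = np.minimum(np.ceil(out["dim"].to_numpy(dtype=float) / STAGE_DAYS), 13).astype(int)
    stage = np.maximum(stage, 1)
    lact_class = np.minimum(out["lactation_number"].to_numpy(dtype=int), 4)
    out["stage"] = stage
    out["nsl_id"] = 13 * (lact_class - 1) + stage
    out["class_valid"] = valid.to_numpy()
    return out


@dataclass
class EditThresholds:
    """Editing rules; defaults mirror the standard milk-recording edits
    (540-day horizon, >= 12 records per cow, >= 20 records per HYS, spectral
    values within 5 SD of the column mean)."""

    max_dim: int = 540
    min_cow_records: int = 12
    min_hys_size: int = 20
    spectral_sd: float = 5.0
    iterate_spectral: bool = True


def apply_editing(records: pd.DataFrame, thresholds: EditThresholds | None = None
                  ) -> pd.DataFrame:
    """Apply the editing rules jointly, iterated to a fixed point.

    The cow-count and HYS-size rules interact (dropping an HYS can push a
    cow below the record minimum and vice versa), so all rules are
    re-applied until no record is removed; the result is idempotent.  With
    ``iterate_spectral = False`` the 5-SD spectral rule is applied once, on
    the first pass, with column statistics from the incoming data.
    """
    if thresholds is None:
        thresholds = EditThresholds()
    df = records
    if "class_valid" in df.columns:
        df = df[df["class_valid"]]
    wvn_cols = [c for c in df.columns if c.startswith("wvn_")]
    df = df[df["dim"].to_numpy(dtype=float) <= thresholds.max_dim]

    first = True
    while True:
        n_before = len(df)
        if wvn_cols and np.isfinite(thresholds.spectral_sd) and (first or thresholds.iterate_spectral):
            x = df[wvn_cols].to_numpy(dtype=float)
            mu = x.mean(axis=0)
            sd = x.std(axis=0)
            sd = np.where(sd == 0, np.inf, sd)
            keep = (np.abs(x - mu) <= thresholds.spectral_sd * sd).all(axis=1)
            df = df[keep]
        first = False
        if thresholds.min_cow_records > 0:
            counts = df.groupby("cow_id")["cow_id"].transform("size")
            df = df[counts >= thresholds.min_cow_records]
        if thresholds.min_hys_size > 0:
            counts = df.groupby("hys_id")["hys_id"].transform("size")
            df = df[counts >= thresholds.min_hys_size]
        if len(df) == n_before:
            break
        if len(df) == 0:
            raise EmptyDataError("no data survived editing")
    if len(df) == 0:
        raise EmptyDataError("no data survived editing")
    return df.copy()


def vc_estimation_subset(records: pd.DataFrame, min_hys_per_herd: int = 30) -> pd.DataFrame:
    """Reduced dataset for variance-component estimation: herds with at
    least ``min_hys_per_herd`` HYS classes."""
    n_hys = records.groupby("herd_id")["hys_id"].transform("nunique")
    sub = records[n_hys >= min_hys_per_herd]
    if len(sub) == 0:
        raise EmptyDataError(f"no herd has >= {min_hys_per_herd} HYS classes")
    return sub


# ---------------------------------------------------------------------------
# variance components


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_p2: float
    sigma_e2: float
    chains: dict | None = None
    geweke: dict | None = None

    def __post_init__(self):
        if min(self.sigma_a2, self.sigma_p2, self.sigma_e2) < 0:
            raise ValueError("variance components must be nonnegative")


def genetic_parameters(vc: VarianceComponents) -> tuple[float, float]:
    """Heritability h2 = sa2 / (sa2 + sp2 + se2) and repeatability
    r2 = (sa2 + sp2) / (sa2 + sp2 + se2)."""
    total = vc.sigma_a2 + vc.sigma_p2 + vc.sigma_e2
    if total == 0:
        raise DegenerateStatisticError("all variance components are zero")
    return vc.sigma_a2 / total, (vc.sigma_a2 + vc.sigma_p2) / total


@dataclass
class ChainConfig:
    """MCMC run lengths; defaults are full-scale settings, tests and the
    desk-scale pipeline pass shorter chains."""

    n_iter: int = 35000
    burn_in: int = 5000
    thin: int = 10
    seed: int = 0
    geweke_threshold: float = 3.0


@dataclass
class MmeStructure:
    """Shared design structure for one edited dataset: factorized effect
    levels, per-level record lists, the fixed cross-product matrix and the
    inverse relationship matrix.  Built once and reused across phenotypes."""

    records: pd.DataFrame
    nsl_levels: np.ndarray
    hys_levels: np.ndarray
    animal_ids: list
    cow_ids: list
    rec_nsl: np.ndarray
    rec_hys: np.ndarray
    rec_anim: np.ndarray
    rec_cow: np.ndarray
    csr: dict
    ainv: np.ndarray
    ainv_csr: tuple
    wtw: np.ndarray = field(repr=False)
    offsets: dict = field(default_factory=dict)

    @property
    def n_effects(self) -> int:
        return self.wtw.shape[0]


def build_mme_structure(records: pd.DataFrame, a_matrix: AMatrix) -> MmeStructure:
    rec_nsl, nsl_levels = pd.factorize(records["nsl_id"], sort=True)
    rec_hys, hys_levels = pd.factorize(records["hys_id"], sort=True)
    animal_ids = list(a_matrix.ids)
    apos = {aid: i for i, aid in enumerate(animal_ids)}
    missing = set(records["cow_id"]) - set(apos)
    if missing:
        raise AlignmentError(f"animals absent from A matrix: {sorted(missing)[:5]}")
    rec_anim = records["cow_id"].map(apos).to_numpy(dtype=np.int64)
    rec_cow, cow_levels = pd.factorize(records["cow_id"], sort=True)

    n_nsl, n_hys = len(nsl_levels), len(hys_levels)
    n_anim, n_cow = len(animal_ids), len(cow_levels)
    csr = {
        "nsl": gibbs.build_csr(rec_nsl, n_nsl),
        "hys": gibbs.build_csr(rec_hys, n_hys),
        "anim": gibbs.build_csr(rec_anim, n_anim),
        "cow": gibbs.build_csr(rec_cow, n_cow),
    }

    # fixed cross-products W'W over all four blocks (NSL reference level
    # dropped -> column -1), for the MME solver
    offsets = {"nsl": 0, "hys": n_nsl - 1, "anim": n_nsl - 1 + n_hys,
               "cow": n_nsl - 1 + n_hys + n_anim}
    p = n_nsl - 1 + n_hys + n_anim + n_cow
    cols = [
        np.where(rec_nsl == 0, -1, rec_nsl - 1 + offsets["nsl"]),
        rec_hys + offsets["hys"],
        rec_anim + offsets["anim"],
        rec_cow + offsets["cow"],
    ]
    wtw = np.zeros((p, p))
    for u in cols:
        for v in cols:
            mask = (u >= 0) & (v >= 0)
            np.add.at(wtw, (u[mask], v[mask]), 1.0)

    ainv = a_matrix.inverse()
    return MmeStructure(records, np.asarray(nsl_levels), np.asarray(hys_levels),
                        animal_ids, list(cow_levels), rec_nsl.astype(np.int64),
                        rec_hys.astype(np.int64), rec_anim, rec_cow.astype(np.int64),
                        csr, ainv, gibbs.sparsify(ainv), wtw, offsets)


def gibbs_variance_components(records: pd.DataFrame, phenotype: str,
                              a_matrix: AMatrix, chain_cfg: ChainConfig | None = None,
                              mme: MmeStructure | None = None) -> VarianceComponents:
    """Posterior means of (sigma_a2, sigma_p2, sigma_e2) for one phenotype.

    Runs the flat-prior Gibbs sampler of :mod:`spectragp.gibbs`, discards
    ``burn_in`` iterations, thins the remainder, and reports posterior
    means together with the retained chains and Geweke z-scores.  A
    convergence warning (not an error) is attached when every component
    exceeds the Geweke threshold.
    """
    if chain_cfg is None:
        chain_cfg = ChainConfig()
    if mme is None:
        mme = build_mme_structure(records, a_matrix)
    if (pd.Series(mme.rec_cow).value_counts() < 2).all():
        raise DegenerateStatisticError(
            "no cow has repeated records; sigma_p2 is unidentifiable")
    y = mme.records[phenotype].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite values in phenotype {phenotype!r}")
    vy = y.var()
    v0 = np.array([vy / 4, vy / 4, vy / 2])
    chains = gibbs.animal_model_chain(
        y, mme.rec_nsl, mme.rec_hys, mme.rec_anim, mme.rec_cow,
        *mme.csr["nsl"], *mme.csr["hys"], *mme.csr["anim"], *mme.csr["cow"],
        *mme.ainv_csr, chain_cfg.n_iter, chain_cfg.seed % (2 ** 31), v0)
    kept = chains[chain_cfg.burn_in::chain_cfg.thin]
    names = ("sigma_a2", "sigma_p2", "sigma_e2")
    post = kept.mean(axis=0)
    gz = {}
    for i, name in enumerate(names):
        try:
            gz[name] = geweke_z(kept[:, i])
        except DegenerateStatisticError:
            gz[name] = float("nan")
    if all(abs(z) > chain_cfg.geweke_threshold for z in gz.values() if np.isfinite(z)):
        warnings.warn(f"Gibbs chain for {phenotype!r} may not have converged "
                      f"(Geweke |z| > {chain_cfg.geweke_threshold} on all components)")
    return VarianceComponents(float(post[0]), float(post[1]), float(post[2]),
                              chains={n: kept[:, i] for i, n in enumerate(names)},
                              geweke=gz)


# ---------------------------------------------------------------------------
# mixed-model equations with fixed variances


@dataclass
class ModelFit:
    """Solutions of Henderson's MME for one phenotype.

    HYS BLUEs absorb the intercept; NSL solutions are recentered to sum to
    zero so the two fixed blocks are uniquely identified.  Standard errors
    are square roots of the coefficient-matrix inverse diagonal times
    sigma_e2 (NaN when the inverse was not requested).
    """

    phenotype: str
    hys: pd.DataFrame       # index hys_id; columns blue, se
    nsl: pd.DataFrame       # index nsl_id; columns blue, se
    blup_a: pd.Series
    blup_p: pd.Series
    vc: VarianceComponents


def solve_mme_fixed_vc(records: pd.DataFrame, phenotype: str, a_matrix: AMatrix,
                       vc: VarianceComponents, compute_se: bool = True,
                       mme: MmeStructure | None = None) -> ModelFit:
    """Solve the mixed-model equations at fixed variance components.

    lambda_a = se2/sa2 scales the inverse relationship matrix on the
    additive block and lambda_p = se2/sp2 the identity on the
    permanent-environment block.  A zero sigma_a2 (or sigma_p2) drops the
    corresponding random effect, the lambda -> infinity limit.
    """
    if vc.sigma_e2 <= 0:
        raise ValueError("sigma_e2 must be strictly positive")
    if mme is None:
        mme = build_mme_structure(records, a_matrix)
    y = mme.records[phenotype].to_numpy(dtype=float)
    n_nsl, n_hys = len(mme.nsl_levels), len(mme.hys_levels)
    n_anim, n_cow = len(mme.animal_ids), len(mme.cow_ids)
    off = mme.offsets

    use_a = vc.sigma_a2 > 0
    use_p = vc.sigma_p2 > 0
    c = mme.wtw.copy()
    if use_a:
        lam_a = vc.sigma_e2 / vc.sigma_a2
        sl = slice(off["anim"], off["anim"] + n_anim)
        c[sl, sl] += lam_a * mme.ainv
    if use_p:
        lam_p = vc.sigma_e2 / vc.sigma_p2
        idx = np.arange(off["cow"], off["cow"] + n_cow)
        c[idx, idx] += lam_p

    keep = np.ones(c.shape[0], dtype=bool)
    if not use_a:
        keep[off["anim"]:off["anim"] + n_anim] = False
    if not use_p:
        keep[off["cow"]:off["cow"] + n_cow] = False
    c = c[np.ix_(keep, keep)]

    rhs = np.zeros(mme.n_effects)
    cols = [
        np.where(mme.rec_nsl == 0, -1, mme.rec_nsl - 1 + off["nsl"]),
        mme.rec_hys + off["hys"], mme.rec_anim + off["anim"], mme.rec_cow + off["cow"],
    ]
    for u in cols:
        mask = u >= 0
        np.add.at(rhs, u[mask], y[mask])
    rhs = rhs[keep]

    try:
        factor = cho_factor(c, lower=True)
    except LinAlgError as exc:
        diag = np.diag(mme.wtw)
        empty = np.where(diag[:n_nsl - 1 + n_hys] == 0)[0]
        aliased = []
        for j in empty:
            if j < n_nsl - 1:
                aliased.append(f"NSL {mme.nsl_levels[j + 1]}")
            else:
                aliased.append(f"HYS {mme.hys_levels[j - (n_nsl - 1)]}")
        raise RankError(
            "fixed-effect equations singular after constraint"
            + (f"; classes without records: {aliased[:10]}" if aliased else "")) from exc
    sol = cho_solve(factor, rhs)
    if compute_se:
        cinv_diag = np.einsum("ij,ij->j",
                              cho_solve(factor, np.eye(c.shape[0])), np.eye(c.shape[0]))
        se = np.sqrt(np.clip(cinv_diag, 0, None) * vc.sigma_e2)
    else:
        se = np.full(c.shape[0], np.nan)

    full = np.zeros(mme.n_effects)
    full_se = np.full(mme.n_effects, np.nan)
    full[keep] = sol
    full_se[keep] = se

    nsl_sol = np.concatenate([[0.0], full[off["nsl"]:off["nsl"] + n_nsl - 1]])
    nsl_se = np.concatenate([[0.0], full_se[off["nsl"]:off["nsl"] + n_nsl - 1]])
    hys_sol = full[off["hys"]:off["hys"] + n_hys].copy()
    hys_se = full_se[off["hys"]:off["hys"] + n_hys]
    # sum-to-zero recentring of NSL; the shift moves into the HYS levels so
    # HYS BLUEs are directly comparable standalone environment estimates
    shift = nsl_sol.mean()
    nsl_sol = nsl_sol - shift
    hys_sol = hys_sol + shift

    blup_a = pd.Series(full[off["anim"]:off["anim"] + n_anim] if use_a
                       else np.zeros(n_anim), index=mme.animal_ids, name="blup_a")
    blup_p = pd.Series(full[off["cow"]:off["cow"] + n_cow] if use_p
                       else np.zeros(n_cow), index=mme.cow_ids, name="blup_p")
    return ModelFit(
        phenotype=phenotype,
        hys=pd.DataFrame({"blue": hys_sol, "se": hys_se}, index=pd.Index(mme.hys_levels, name="hys_id")),
        nsl=pd.DataFrame({"blue": nsl_sol, "se": nsl_se}, index=pd.Index(mme.nsl_levels, name="nsl_id")),
        blup_a=blup_a, blup_p=blup_p, vc=vc,
    )


# ---------------------------------------------------------------------------
# HYS BLUE table and PCA


@dataclass
class HysBlueTable:
    """HYS x phenotype matrix of BLUEs with standard errors and a
    column-standardized copy (zero mean, unit population variance)."""

    blues: pd.DataFrame
    se: pd.DataFrame
    std: pd.DataFrame

    @property
    def hys_ids(self) -> pd.Index:
        return self.blues.index


def extract_hys_blues(fits: dict[str, ModelFit]) -> HysBlueTable:
    """Assemble HYS BLUEs across phenotype fits and standardize.

    All fits must share the same HYS class set; constant BLUE columns
    cannot be standardized and are dropped with a warning.
    """
    if not fits:
        raise ValueError("no fits supplied")
    items = list(fits.items())
    ref = items[0][1].hys.index
    offenders = {}
    for name, fit in items[1:]:
        diff = ref.symmetric_difference(fit.hys.index)
        if len(diff):
            offenders[name] = list(diff[:5])
    if offenders:
        raise AlignmentError(f"HYS sets differ across fits: {offenders}")
    blues = pd.DataFrame({name: fit.hys["blue"] for name, fit in items})
    se = pd.DataFrame({name: fit.hys["se"] for name, fit in items})
    sd = blues.std(ddof=0)
    dead = sd[sd <= 1e-12].index
    if len(dead):
        warnings.warn(f"dropping constant BLUE columns (zero variance): {list(dead)}")
        blues = blues.drop(columns=dead)
        se = se.drop(columns=dead)
        sd = sd.drop(dead)
    std = (blues - blues.mean()) / sd
    return HysBlueTable(blues, se, std)


def pca_hys_blues(table: HysBlueTable, k: int, columns: list[str] | None = None
                  ) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the (standardized) HYS BLUEs.

    PCA is on the covariance matrix of the standardized table, the usual
    convention for spectral HYS deviations.  By default the spectral
    (``wvn_``) columns are used when present, otherwise all columns.
    Returns per-HYS scores for the first ``k`` components and the
    cumulative explained-variance fractions.
    """
    if columns is None:
        wvn = [c for c in table.std.columns if c.startswith("wvn_")]
        columns = wvn if wvn else list(table.std.columns)
    x = table.std[columns].to_numpy()
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    if not 1 <= k <= min(x.shape):
        raise ValueError(f"k must be in [1, {min(x.shape)}], got {k}")
    if k > rank:
        raise ValueError(f"k = {k} exceeds the matrix rank {rank}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    scores = pd.DataFrame(scores, index=table.hys_ids,
                          columns=[f"pc_{i + 1}" for i in range(k)])
    return scores, cum


# ---------------------------------------------------------------------------
# multi-phenotype driver


def fit_all_phenotypes(records: pd.DataFrame, a_matrix: AMatrix,
                       phenotypes: list[str], chain_cfg: ChainConfig,
                       vc_records: pd.DataFrame | None = None,
                       se_phenotypes: set[str] | None = None,
                       ) -> tuple[dict[str, ModelFit], dict[str, VarianceComponents]]:
    """Two-pass stage-1 driver: variance components on ``vc_records`` (the
    reduced subset; defaults to the full data), then MME solutions on the
    full records with the variances fixed.  Standard errors are computed
    only for the phenotypes named in ``se_phenotypes`` (all when None)."""
    mme_full = build_mme_structure(records, a_matrix)
    if vc_records is None or vc_records is records:
        mme_vc = mme_full
    else:
        mme_vc = build_mme_structure(vc_records, a_matrix)
    fits, vcs = {}, {}
    for i, pheno in enumerate(phenotypes):
        cfg = ChainConfig(chain_cfg.n_iter, chain_cfg.burn_in, chain_cfg.thin,
                          (chain_cfg.seed + i) % (2 ** 31), chain_cfg.geweke_threshold)
        vc = gibbs_variance_components(mme_vc.records, pheno, a_matrix, cfg, mme=mme_vc)
        want_se = se_phenotypes is None or pheno in se_phenotypes
        fits[pheno] = solve_mme_fixed_vc(mme_full.records, pheno, a_matrix, vc,
                                         compute_se=want_se, mme=mme_full)
        vcs[pheno] = vc
    return fits, vcs
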